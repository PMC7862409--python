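"""Heart-sound isolation and per-frame features for the segmenters.

The displacement signal is dominated by respiration (millimetres, < 1 Hz)
and the pulse wave; the heart sounds are micro-vibrations in the tens of
micrometres concentrated between roughly 15 and 80 Hz. After zero-phase
band-passing, four per-frame features are computed at a reduced feature
rate: the homomorphic envelope, the Hilbert envelope, a short-time PSD band
power, and an autocorrelation heart-rate estimate broadcast over its
analysis window. Envelopes are z-normalised per record.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigurationError, InvalidInputError
from .types import DisplacementSignal, FeatureTrack

#: Default heart-sound band (Hz): standard phonocardiography range, above
#: respiration/pulse-wave energy and below detector noise.
DEFAULT_BAND = (16.0, 80.0)

#: Feature frame rate (Hz): 20 ms frames resolve S1/S2 durations (~60-120 ms)
#: and sit well inside the 75 ms beat-scoring tolerance.
DEFAULT_FEATURE_FS = 50.0

#: Admissible autocorrelation heart-rate search range (bpm).
HR_RANGE_BPM = (40.0, 135.0)

EPS = 1e-12


@dataclass
class HeartSoundSignal:
    """Band-passed displacement containing the heart-sound component."""

    y: np.ndarray
    fs: float
    band: tuple[float, float]


def bandpass_heart_sound(x: DisplacementSignal,
                         band: tuple[float, float] = DEFAULT_BAND,
                         order: int = 4) -> HeartSoundSignal:
    """Zero-phase Butterworth band-pass isolating the heart-sound band."""
    low, high = band
    if not 0 < low < high < x.fs / 2:
        raise InvalidConfigurationError(
            f"band {band} infeasible for fs={x.fs} Hz")
    if x.fs < 4 * high:
        raise InvalidConfigurationError(
            f"fs={x.fs} Hz < 4x band top {high} Hz")
    sos = sps.butter(order, band, btype="bandpass", fs=x.fs, output="sos")
    y = sps.sosfiltfilt(sos, x.x)
    return HeartSoundSignal(y=y, fs=x.fs, band=(low, high))


def hilbert_envelope(y: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal."""
    return np.abs(sps.hilbert(np.asarray(y, dtype=float)))


def homomorphic_envelope(y: np.ndarray, fs: float, lpf_cutoff: float = 8.0,
                         eps: float = EPS) -> np.ndarray:
    """exp(lowpass(log(|analytic(y)| + eps))): a smoothed, positive envelope.

    The log/exp sandwich turns the multiplicative amplitude modulation into
    an additive one so a first-order zero-phase low-pass can smooth it
    without smearing burst onsets the way direct envelope smoothing would.
    """
    env = hilbert_envelope(y) + eps
    sos = sps.butter(1, lpf_cutoff, btype="lowpass", fs=fs, output="sos")
    return np.exp(sps.sosfiltfilt(sos, np.log(env)))


def psd_envelope(y: np.ndarray, fs: float, frame_len: float = 0.05,
                 hop: float = 0.02,
                 band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Mean spectral power inside the heart-sound band per analysis frame."""
    y = np.asarray(y, dtype=float)
    nperseg = int(round(frame_len * fs))
    nhop = int(round(hop * fs))
    if len(y) < nperseg:
        raise InvalidInputError(
            f"record of {len(y)} samples shorter than one {nperseg}-sample frame")
    freqs, _, sxx = sps.spectrogram(y, fs=fs, window="hann", nperseg=nperseg,
                                    noverlap=nperseg - nhop, mode="psd")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return sxx[sel].mean(axis=0)


def estimate_heart_rate_autocorr(y: np.ndarray, fs: float,
                                 bpm_range: tuple[float, float] = HR_RANGE_BPM,
                                 significance_floor: float = 0.25,
                                 ) -> tuple[float, bool]:
    """Heart rate from the autocorrelation peak of the heart-sound envelope.

    Searches lags corresponding to ``bpm_range`` (default 40-135 bpm) for
    the maximum of the normalised autocorrelation of the mean-removed
    homomorphic envelope. Returns ``(bpm, reliable)``; the estimate is
    flagged unreliable when the peak falls below ``significance_floor``
    times the zero-lag value: periodic heart-sound envelopes score well
    above 0.3 there while broadband noise stays below ~0.2.
    """
    env = homomorphic_envelope(y, fs)
    env = env - env.mean()
    n = len(env)
    lag_min = int(np.floor(60.0 / bpm_range[1] * fs))
    lag_max = int(np.ceil(60.0 / bpm_range[0] * fs))
    if n < 2 * lag_max:
        raise InvalidInputError(
            f"window of {n / fs:.1f}s too short for the {bpm_range[0]} bpm lag")
    ac = sps.correlate(env, env, mode="full", method="fft")[n - 1:]
    if ac[0] <= 0:
        return float("nan"), False
    ac = ac / ac[0]
    seg = ac[lag_min:lag_max + 1]
    k = int(np.argmax(seg))
    # parabolic refinement around the discrete peak
    tau = lag_min + k
    if 0 < k < len(seg) - 1:
        denom = seg[k - 1] - 2 * seg[k] + seg[k + 1]
        if denom < 0:
            tau = tau + 0.5 * (seg[k - 1] - seg[k + 1]) / denom
    bpm = 60.0 * fs / tau
    reliable = bool(seg[k] >= significance_floor)
    return float(bpm), reliable


def build_feature_track(envelopes: np.ndarray, fs: float,
                        hr_bpm_per_frame: np.ndarray,
                        feature_fs: float = DEFAULT_FEATURE_FS,
                        t0: float = 0.0) -> FeatureTrack:
    """Downsample envelopes to the feature rate and z-normalise per record.

    ``envelopes`` is (n_samples, 3) at rate ``fs`` (homomorphic, Hilbert,
    PSD — the PSD column already at frame rate is accepted at sample rate
    after upsampling by the caller); ``hr_bpm_per_frame`` has one value per
    output frame. Zero-variance columns are set to 0 with a warning.
    """
    envelopes = np.atleast_2d(np.asarray(envelopes, dtype=float))
    if envelopes.shape[0] < envelopes.shape[1]:
        envelopes = envelopes.T
    n_frames = int(np.floor(envelopes.shape[0] / fs * feature_fs))
    frame_t = np.arange(n_frames) / feature_fs
    sample_t = np.arange(envelopes.shape[0]) / fs
    cols = [np.interp(frame_t, sample_t, envelopes[:, c])
            for c in range(envelopes.shape[1])]
    hr = np.asarray(hr_bpm_per_frame, dtype=float)
    if len(hr) != n_frames:
        raise InvalidInputError(
            f"hr_bpm_per_frame has {len(hr)} values for {n_frames} frames")
    raw = np.column_stack(cols + [hr])
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    feats = np.zeros_like(raw)
    for c in range(raw.shape[1]):
        if std[c] > 0:
            feats[:, c] = (raw[:, c] - mean[c]) / std[c]
        else:
            warnings.warn(f"feature column {c} has zero variance; set to 0")
    return FeatureTrack(features=feats, feature_fs=feature_fs, hr_bpm=hr,
                        norm_mean=mean, norm_std=std, t0=t0)


def extract_features(x: DisplacementSignal,
                     band: tuple[float, float] = DEFAULT_BAND,
                     feature_fs: float = DEFAULT_FEATURE_FS,
                     hr_window: float = 10.0,
                     ) -> tuple[FeatureTrack, HeartSoundSignal]:
    """Full chain: band-pass, three envelopes, windowed HR, feature track.

    The heart rate is estimated once per non-overlapping ``hr_window``
    (default 10 s) and broadcast to every frame of that window; windows too
    short for the slowest admissible period reuse the previous estimate.
    """
    hs = bandpass_heart_sound(x, band)
    homo = homomorphic_envelope(hs.y, hs.fs)
    hilb = hilbert_envelope(hs.y)
    psd = psd_envelope(hs.y, hs.fs, hop=1.0 / feature_fs, band=band)
    # upsample the frame-rate PSD back to sample rate for uniform handling
    psd_t = np.arange(len(psd)) / feature_fs
    sample_t = np.arange(len(hs.y)) / hs.fs
    psd_up = np.interp(sample_t, psd_t, psd)

    n_frames = int(np.floor(len(hs.y) / hs.fs * feature_fs))
    hr = np.full(n_frames, np.nan)
    win_samples = int(round(hr_window * hs.fs))
    last_bpm = np.nan
    for w0 in range(0, len(hs.y), win_samples):
        seg = hs.y[w0:w0 + win_samples]
        try:
            bpm, reliable = estimate_heart_rate_autocorr(seg, hs.fs)
            if reliable:
                last_bpm = bpm
        except InvalidInputError:
            pass
        f0 = int(np.floor(w0 / hs.fs * feature_fs))
        f1 = int(np.floor(min(w0 + win_samples, len(hs.y)) / hs.fs * feature_fs))
        hr[f0:min(f1, n_frames)] = last_bpm
    if np.isnan(hr).all():
        raise InvalidInputError("no reliable heart-rate estimate in any window")
    # backfill leading NaNs from the first reliable window
    first = np.flatnonzero(~np.isnan(hr))[0]
    hr[:first] = hr[first]
    track = build_feature_track(np.column_stack([homo, hilb, psd_up]), hs.fs,
                                hr[:n_frames], feature_fs)
    return track, hs
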