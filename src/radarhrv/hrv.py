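"""Heart rate variability indices from beat times.

Chain: beat times -> RR sequence -> artefact removal -> time-domain
(triangular index) and frequency-domain indices. For the spectral indices
the valid intervals are linearly interpolated onto a uniform 4 Hz grid,
standardised (zero mean, unit variance), Hann-tapered, zero-padded to the
next power of two, and Fourier-transformed; band powers are sums of squared
spectral magnitudes over the LF band [0.04, 0.15) Hz and the HF band
[0.15, 0.4) Hz. Normalised units express each band as a percentage of the
combined LF+HF power.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .types import BeatList, RRSequence

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Uniform resampling rate for the interval series (community standard).
INTERP_FS = 4.0

#: Triangular-index histogram bin width: 1/128 s, the standard discrete
#: sampling grid for geometric HRV measures.
TRI_BIN_WIDTH = 1.0 / 128.0

#: Relative deviation from the running median above which an interval is
#: considered an artefact.
ARTEFACT_THRESHOLD = 0.20


def beats_to_rr(beats: BeatList) -> RRSequence:
    """RR intervals from successive beat times; interval i ends at beat i+1."""
    t = beats.times
    if len(t) < 2:
        raise InvalidInputError(f"need >= 2 beats, got {len(t)}")
    return RRSequence(times=t[1:], intervals=np.diff(t))


def remove_artefacts(rr: RRSequence, threshold: float = ARTEFACT_THRESHOLD,
                     median_window: int = 5) -> RRSequence:
    """Flag, split, or merge implausible intervals.

    Each interval is compared to the running median of the last
    ``median_window`` accepted intervals. An interval deviating more than
    ``threshold`` (relative) is an artefact:

    * ~2x the running median (a missed beat): replaced by two halves;
    * together with the next flagged interval ~1x the median (a false
      detection splitting a true interval): the two are merged;
    * otherwise: flagged invalid and excluded downstream.

    If more than 30% of the input intervals are flagged, the output carries
    ``low_quality=True``.
    """
    if len(rr) < median_window:
        raise InvalidInputError(
            f"need >= {median_window} intervals, got {len(rr)}")
    out_t: list[float] = []
    out_rr: list[float] = []
    out_ok: list[bool] = []
    recent: list[float] = []
    n_flagged = 0
    ivs = list(rr.intervals)
    ts = list(rr.times)
    i = 0
    while i < len(ivs):
        iv, t = ivs[i], ts[i]
        med = float(np.median(recent[-median_window:])) if recent else iv
        dev = abs(iv / med - 1.0)
        if dev <= threshold:
            out_t.append(t); out_rr.append(iv); out_ok.append(True)
            recent.append(iv)
            i += 1
            continue
        n_flagged += 1
        if abs(iv / (2.0 * med) - 1.0) <= threshold:
            # missed beat: split into two halves
            half = iv / 2.0
            out_t.extend([t - half, t]); out_rr.extend([half, half])
            out_ok.extend([True, True])
            recent.extend([half, half])
            i += 1
            continue
        if i + 1 < len(ivs):
            nxt = ivs[i + 1]
            nxt_dev = abs(nxt / med - 1.0)
            if nxt_dev > threshold and abs((iv + nxt) / med - 1.0) <= threshold:
                # false detection: merge the two fragments
                n_flagged += 1
                out_t.append(ts[i + 1]); out_rr.append(iv + nxt)
                out_ok.append(True)
                recent.append(iv + nxt)
                i += 2
                continue
        out_t.append(t); out_rr.append(iv); out_ok.append(False)
        i += 1
    low_quality = n_flagged > 0.3 * len(rr)
    if low_quality:
        warnings.warn(
            f"{n_flagged}/{len(rr)} intervals flagged; RR sequence low quality")
    return RRSequence(times=np.array(out_t), intervals=np.array(out_rr),
                      valid=np.array(out_ok), low_quality=low_quality)


def compute_tri(rr: RRSequence, bin_width: float = TRI_BIN_WIDTH) -> float:
    """Triangular index: total valid count / count in the modal histogram bin.

    Bins are aligned to multiples of ``bin_width``, so identical intervals
    fall into one bin (TRI = 1) and k equally filled bins give TRI = k.
    """
    iv = rr.valid_intervals
    if len(iv) == 0:
        raise InvalidInputError("no valid intervals")
    bins = np.floor(iv / bin_width).astype(np.int64)
    counts = np.bincount(bins - bins.min())
    return float(len(iv) / counts.max())


def rr_to_uniform(rr: RRSequence, fs_interp: float = INTERP_FS,
                  t_start: float | None = None, t_end: float | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of (beat time, interval) onto a uniform grid.

    Returns ``(t_grid, series)`` with ``floor(duration * fs) + 1`` points
    spanning [t_start, t_end] (defaults: first to last valid beat time).
    Gaps of flagged intervals longer than 5 s are bridged with a warning.
    """
    t = rr.valid_times
    iv = rr.valid_intervals
    if len(iv) < 2:
        raise InvalidInputError("need >= 2 valid intervals to interpolate")
    if np.any(np.diff(t) > 5.0):
        warnings.warn("interpolating across a gap of flagged intervals > 5 s")
    t0 = t[0] if t_start is None else t_start
    t1 = t[-1] if t_end is None else t_end
    n = int(np.floor((t1 - t0) * fs_interp)) + 1
    grid = t0 + np.arange(n) / fs_interp
    return grid, np.interp(grid, t, iv)


def spectral_powers(series: np.ndarray, fs_interp: float = INTERP_FS,
                    window: float = 90.0) -> dict[str, float]:
    """LF/HF band powers of the standardised, tapered, zero-padded series.

    The first ``window`` seconds of the series are standardised to zero
    mean and unit variance, Hann-tapered (a rectangular window would leak a
    few percent of an in-band tone into the neighbouring band), zero-padded
    to the next power of two, and transformed; each band power is the sum
    of squared magnitudes over bins with frequency in [low, high).
    """
    series = np.asarray(series, dtype=float)
    n_win = int(round(window * fs_interp))
    if len(series) < n_win:
        raise InvalidInputError(
            f"series of {len(series) / fs_interp:.1f}s shorter than the "
            f"{window:.0f}s analysis window")
    seg = series[:n_win]
    sd = seg.std()
    if sd == 0:
        return {"lf_power": 0.0, "hf_power": 0.0}
    seg = (seg - seg.mean()) / sd
    seg = seg * np.hanning(n_win)
    nfft = 1 << int(np.ceil(np.log2(n_win)))
    spec = np.fft.rfft(seg, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_interp)
    power = np.abs(spec) ** 2

    def band(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(power[sel].sum())

    return {"lf_power": band(*LF_BAND), "hf_power": band(*HF_BAND)}


def normalised_units(lf_power: float, hf_power: float) -> dict[str, float]:
    """LF/HF as percentages of their combined power, plus the LF/HF ratio."""
    total = lf_power + hf_power
    if total <= 0:
        warnings.warn("LF + HF power is zero; normalised units undefined")
        return {"lf_norm": float("nan"), "hf_norm": float("nan"),
                "lf_hf_ratio": float("nan")}
    return {
        "lf_norm": 100.0 * lf_power / total,
        "hf_norm": 100.0 * hf_power / total,
        "lf_hf_ratio": lf_power / hf_power if hf_power > 0 else float("inf"),
    }


@dataclass
class HrvIndices:
    """The per-window index set: HR, band powers, normalised units, TRI."""

    heart_rate: float
    lf_power: float
    hf_power: float
    lf_norm: float
    hf_norm: float
    lf_hf_ratio: float
    tri: float
    n_intervals: int
    low_confidence: bool = False

    def to_dict(self) -> dict:
        return {
            "heart_rate": self.heart_rate,
            "lf_power": self.lf_power,
            "hf_power": self.hf_power,
            "lf_norm": self.lf_norm,
            "hf_norm": self.hf_norm,
            "lf_hf_ratio": self.lf_hf_ratio,
            "tri": self.tri,
            "n_intervals": self.n_intervals,
            "low_confidence": self.low_confidence,
        }


def hrv_indices(rr: RRSequence, window: float | None = None,
                fs_interp: float = INTERP_FS) -> HrvIndices:
    """Index set over one RR (sub)sequence; spectral window defaults to the
    full covered span rounded down to a whole second."""
    iv = rr.valid_intervals
    if len(iv) == 0:
        raise InvalidInputError("no valid intervals")
    hr = 60.0 / float(iv.mean())
    tri = compute_tri(rr)
    grid, series = rr_to_uniform(rr, fs_interp)
    if window is None:
        window = np.floor(len(series) / fs_interp)
    powers = spectral_powers(series, fs_interp, window=window)
    norms = normalised_units(**powers)
    return HrvIndices(heart_rate=hr, tri=tri, n_intervals=int(len(iv)),
                      low_confidence=len(iv) < 30, **powers, **norms)


def windowed_hrv(rr: RRSequence, windows: dict[str, tuple[float, float]],
                 fs_interp: float = INTERP_FS) -> dict[str, HrvIndices]:
    """One :class:`HrvIndices` per named (start, length) scenario window.

    An interval belongs to a window when its closing beat time lies inside
    it. Windows with fewer than 30 valid intervals are flagged
    ``low_confidence``.
    """
    out: dict[str, HrvIndices] = {}
    for name, (start, length) in windows.items():
        sel = (rr.times >= start) & (rr.times < start + length)
        if sel.sum() < 2:
            raise InvalidInputError(f"window {name!r} covers < 2 intervals")
        sub = RRSequence(times=rr.times[sel], intervals=rr.intervals[sel],
                         valid=rr.valid[sel])
        iv = sub.valid_intervals
        hr = 60.0 / float(iv.mean())
        tri = compute_tri(sub)
        grid, series = rr_to_uniform(sub, fs_interp)
        window_s = min(length, np.floor(len(series) / fs_interp))
        powers = spectral_powers(series, fs_interp, window=window_s)
        norms = normalised_units(**powers)
        out[name] = HrvIndices(heart_rate=hr, tri=tri,
                               n_intervals=int(len(iv)),
                               low_confidence=len(iv) < 30,
                               **powers, **norms)
    return out


@dataclass
class AgreementStats:
    """Pearson correlation and Bland-Altman agreement between two methods."""

    pearson_r: float
    mean_difference: float
    loa_low: float
    loa_high: float
    relative_error_pct: float
    n: int = 0
    differences: np.ndarray = field(default=None, repr=False)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mean_difference": self.mean_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "relative_error_pct": self.relative_error_pct,
            "n": self.n,
        }


def agreement(a, b) -> AgreementStats:
    """Method-agreement statistics between paired measurements a and b.

    Differences are ``d = a - b`` (a: test method, b: reference); limits of
    agreement are mean(d) ± 1.96 sd(d); the relative error is
    mean(|d| / b) x 100. Pearson r is NaN when either vector is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise InvalidInputError("need two equal-length vectors of length >= 3")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance; Pearson r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b)[0])
    rel = float(np.mean(np.abs(d) / np.abs(b)) * 100.0)
    return AgreementStats(pearson_r=r, mean_difference=mean_d,
                          loa_low=mean_d - 1.96 * sd_d,
                          loa_high=mean_d + 1.96 * sd_d,
                          relative_error_pct=rel, n=len(a), differences=d)
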