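"""Four-state hidden semi-Markov segmentation of the feature track.

The state topology is the fixed cardiac cycle S1 -> systole -> S2 ->
diastole -> S1. Emissions are per-state multivariate Gaussians over the
four features. Sojourn (duration) distributions are Gaussians over frames,
truncated at ±3 sd: the heart-sound states S1/S2 have heart-rate
independent durations (~100 ms and ~80 ms), while systole and diastole
scale with the cycle period 60/HR, which is how the decoder uses the
a-priori heart-rate estimate. Decoding is a duration-explicit Viterbi
maximising

    sum_frames log N(x_t | mu_s, Sigma_s) + sum_segments log P_s(d) + log 1/4

over all legal cyclic segmentations (edge segments score with the same
truncated pmf as interior ones). Ties resolve toward the shorter sojourn.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import (
    HeartRateOutOfRangeError,
    InvalidInputError,
    InvalidTrainingDataError,
)
from .types import N_STATES, CardiacState, FeatureTrack, StateSequence

#: Admissible heart-rate range for decoding (matches the autocorrelation
#: search range).
ADMISSIBLE_HR = (40.0, 135.0)

#: prev(s) under the fixed cycle (who can transition *into* s).
PREV_STATE = np.array([int(CardiacState.DIA), int(CardiacState.S1),
                       int(CardiacState.SYS), int(CardiacState.S2)])

#: Which states have HR-independent absolute durations.
ABSOLUTE_DURATION = {int(CardiacState.S1), int(CardiacState.S2)}

_MIN_SD_FRAMES = 0.5


@dataclass
class HsmmModel:
    """Fitted emission and duration parameters.

    ``dur_mean``/``dur_sd`` are in seconds for S1/S2 and in fractions of the
    cycle period for SYS/DIA.
    """

    means: np.ndarray        # (4, n_features)
    covs: np.ndarray         # (4, n_features, n_features)
    dur_mean: np.ndarray     # (4,)
    dur_sd: np.ndarray       # (4,)
    feature_fs: float

    def duration_frames(self, state: int, hr_bpm: float) -> tuple[float, float]:
        """Sojourn mean/sd in frames for a state at a given heart rate."""
        period_frames = 60.0 / hr_bpm * self.feature_fs
        if state in ABSOLUTE_DURATION:
            return (self.dur_mean[state] * self.feature_fs,
                    max(self.dur_sd[state] * self.feature_fs, _MIN_SD_FRAMES))
        return (self.dur_mean[state] * period_frames,
                max(self.dur_sd[state] * period_frames, _MIN_SD_FRAMES))

    def duration_logpmf(self, state: int, hr_bpm: float) -> np.ndarray:
        """Log pmf over integer durations 1..dmax (index 0 unused, -inf).

        Discretised Gaussian truncated at ±3 sd and renormalised.
        """
        mean, sd = self.duration_frames(state, hr_bpm)
        dmin = max(1, int(np.floor(mean - 3 * sd)))
        dmax = max(dmin, int(np.ceil(mean + 3 * sd)))
        d = np.arange(dmax + 1, dtype=float)
        logp = np.full(dmax + 1, -np.inf)
        w = np.exp(-0.5 * ((d[dmin:] - mean) / sd) ** 2)
        total = w.sum()
        if total <= 0:
            w[:] = 1.0 / len(w)
            total = 1.0
        logp[dmin:] = np.log(w / total)
        return logp

    def emission_loglik(self, features: np.ndarray) -> np.ndarray:
        """(T, 4) per-frame log densities under each state's Gaussian."""
        T, k = features.shape
        out = np.empty((T, N_STATES))
        for s in range(N_STATES):
            cov = self.covs[s]
            chol = np.linalg.cholesky(cov)
            diff = features - self.means[s]
            sol = np.linalg.solve(chol, diff.T)
            maha = np.sum(sol ** 2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, s] = -0.5 * (maha + logdet + k * np.log(2 * np.pi))
        return out

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "dur_mean": self.dur_mean.tolist(),
            "dur_sd": self.dur_sd.tolist(),
            "feature_fs": self.feature_fs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HsmmModel":
        return cls(means=np.array(d["means"]), covs=np.array(d["covs"]),
                   dur_mean=np.array(d["dur_mean"]),
                   dur_sd=np.array(d["dur_sd"]),
                   feature_fs=float(d["feature_fs"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "HsmmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _state_runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start_frame, length) runs of a label sequence."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((int(states[start]), start, i - start))
            start = i
    return runs


def train_hsmm(tracks: list[FeatureTrack],
               labels: list[StateSequence],
               cov_reg: float = 1e-6) -> HsmmModel:
    """Fit emissions from labelled frames and durations from labelled runs.

    Edge runs (truncated by the record boundaries) are excluded from the
    duration fit. SYS/DIA durations are fitted as fractions of the local
    cycle period implied by the track's heart-rate estimate.
    """
    if len(tracks) != len(labels):
        raise InvalidInputError("tracks and labels must pair up")
    for tr, lb in zip(tracks, labels):
        if tr.n_frames != len(lb):
            raise InvalidInputError(
                f"track has {tr.n_frames} frames but labels {len(lb)}")
    feats_by_state: list[list[np.ndarray]] = [[] for _ in range(N_STATES)]
    durs_by_state: list[list[float]] = [[] for _ in range(N_STATES)]
    fs = tracks[0].feature_fs
    for tr, lb in zip(tracks, labels):
        s = lb.states
        for st in range(N_STATES):
            sel = s == st
            if sel.any():
                feats_by_state[st].append(tr.features[sel])
        runs = _state_runs(s)
        for st, start, length in runs[1:-1]:
            if st in ABSOLUTE_DURATION:
                durs_by_state[st].append(length / fs)
            else:
                hr = tr.hr_bpm[start]
                period_frames = 60.0 / hr * fs
                durs_by_state[st].append(length / period_frames)
    missing = [CardiacState(s).name for s in range(N_STATES)
               if not feats_by_state[s] or not durs_by_state[s]]
    if missing:
        raise InvalidTrainingDataError(
            f"states absent from training labels: {', '.join(missing)}")
    n_feat = tracks[0].features.shape[1]
    means = np.empty((N_STATES, n_feat))
    covs = np.empty((N_STATES, n_feat, n_feat))
    dur_mean = np.empty(N_STATES)
    dur_sd = np.empty(N_STATES)
    for s in range(N_STATES):
        x = np.vstack(feats_by_state[s])
        means[s] = x.mean(axis=0)
        covs[s] = np.cov(x, rowvar=False) + cov_reg * np.eye(n_feat)
        d = np.array(durs_by_state[s])
        dur_mean[s] = d.mean()
        dur_sd[s] = max(d.std(), 1e-3 * d.mean())
    return HsmmModel(means=means, covs=covs, dur_mean=dur_mean,
                     dur_sd=dur_sd, feature_fs=fs)


def viterbi_segment(model: HsmmModel, track: FeatureTrack,
                    hr_bpm: float | None = None) -> StateSequence:
    """Maximum a-posteriori cyclic segmentation via duration-explicit Viterbi.

    ``hr_bpm`` conditions the SYS/DIA sojourn distributions; it defaults to
    the track's mean autocorrelation estimate and must lie inside
    ``ADMISSIBLE_HR`` — the semi-Markov prior is only valid there.
    """
    if hr_bpm is None:
        hr_bpm = float(np.nanmean(track.hr_bpm))
    if not ADMISSIBLE_HR[0] <= hr_bpm <= ADMISSIBLE_HR[1]:
        raise HeartRateOutOfRangeError(
            f"heart rate {hr_bpm:.1f} bpm outside admissible "
            f"range {ADMISSIBLE_HR}")
    em = model.emission_loglik(track.features)
    T = em.shape[0]
    if T == 0:
        return StateSequence(states=np.array([], dtype=int),
                             feature_fs=track.feature_fs, t0=track.t0)
    logpmf = [model.duration_logpmf(s, hr_bpm) for s in range(N_STATES)]
    dmax = [len(p) - 1 for p in logpmf]
    # cumulative emissions: C[s][t] = sum of em[:t, s]
    C = np.vstack([np.concatenate(([0.0], np.cumsum(em[:, s])))
                   for s in range(N_STATES)])
    log_init = -np.log(N_STATES)
    delta = np.full((T, N_STATES), -np.inf)
    bp_dur = np.zeros((T, N_STATES), dtype=np.int64)  # 0 => initial segment
    for t in range(T):
        for s in range(N_STATES):
            best = -np.inf
            best_d = 0
            # initial segment covering frames 0..t entirely in state s
            d0 = t + 1
            if d0 <= dmax[s] and np.isfinite(logpmf[s][d0]):
                best = log_init + logpmf[s][d0] + C[s, t + 1]
            # interior segment of duration d ending at t (ties: shorter d
            # wins because argmax takes the first maximum in ascending d)
            hi = min(dmax[s], t)
            if hi >= 1:
                ds = np.arange(1, hi + 1)
                lp = logpmf[s][1:hi + 1]
                cand = delta[t - ds, PREV_STATE[s]] + lp + (C[s, t + 1] - C[s, t + 1 - ds])
                k = int(np.argmax(cand))
                if cand[k] > best:
                    best = float(cand[k])
                    best_d = int(ds[k])
            delta[t, s] = best
            bp_dur[t, s] = best_d
    # backtrack
    states = np.empty(T, dtype=int)
    s = int(np.argmax(delta[T - 1]))
    if not np.isfinite(delta[T - 1, s]):
        raise InvalidInputError(
            "no legal segmentation: record shorter than one sojourn?")
    t = T - 1
    while t >= 0:
        d = int(bp_dur[t, s])
        if d == 0:
            states[:t + 1] = s
            break
        states[t - d + 1:t + 1] = s
        t -= d
        s = int(PREV_STATE[s])
    return StateSequence(states=states, feature_fs=track.feature_fs,
                        t0=track.t0)


def path_score(model: HsmmModel, track: FeatureTrack, states: np.ndarray,
               hr_bpm: float) -> float:
    """Score of a given legal path under the decoder's objective.

    Useful for optimality checks: Viterbi's score must dominate any legal
    path's score, including the ground truth's.
    """
    em = model.emission_loglik(track.features)
    logpmf = [model.duration_logpmf(s, hr_bpm) for s in range(N_STATES)]
    total = -np.log(N_STATES)
    for st, start, length in _state_runs(np.asarray(states, dtype=int)):
        if length >= len(logpmf[st]):
            return -np.inf
        total += logpmf[st][length] + em[start:start + length, st].sum()
    return float(total)
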