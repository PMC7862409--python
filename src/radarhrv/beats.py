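"""Beat extraction from state sequences and tolerance-based beat scoring.

A heartbeat reference point is the onset of each first heart sound (the
first S1 frame of each cycle). Detected beats are scored against reference
beats with a one-to-one matching: a pair is admissible when the two times
differ by at most the tolerance (default 75 ms, half the recognised 150 ms
tolerance for R-peak detection). Among matchings with maximal true-positive
count, the one with minimal total |Δt| is chosen; since both lists are
sorted and admissibility is an interval condition, an optimal matching is
found by a non-crossing dynamic programme.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import BeatList, CardiacState, StateSequence

DEFAULT_TOLERANCE = 0.075


def states_to_beats(seq: StateSequence) -> BeatList:
    """One beat per S1 onset; time = frame start time of the first S1 frame."""
    s = seq.states
    if len(s) == 0:
        return BeatList(times=np.array([]))
    onset = (s == int(CardiacState.S1)) & np.r_[True, s[:-1] != int(CardiacState.S1)]
    times = seq.t0 + np.flatnonzero(onset) / seq.feature_fs
    return BeatList(times=times)


def refine_beats(beats: BeatList, envelope: np.ndarray, fs: float,
                 search_before: float = 0.03, search_after: float = 0.10,
                 onset_shift: float = 0.0) -> BeatList:
    """Sharpen beat times to sub-frame precision against the envelope.

    Segmentation localises each S1 onset only to one feature frame (20 ms
    at the default rate), which injects broadband quantisation noise into
    the RR series and inflates spectral HRV indices. For each coarse beat
    time this looks at the (smoothed) heart-sound envelope at the full
    signal rate inside ``[t - search_before, t + search_after]`` and moves
    the beat to the envelope maximum, refined to sub-sample precision by
    parabolic interpolation. The peak sits mid-burst, so callers typically
    pass half the mean S1 sojourn as ``onset_shift`` to report onsets;
    a shift common to all beats cancels in the RR intervals either way.
    Beats whose refinement would break monotonicity keep their coarse time.
    """
    env = np.asarray(envelope, dtype=float)
    refined = []
    prev = -np.inf
    for t in beats.times:
        lo = max(int((t - search_before) * fs), 0)
        hi = min(int((t + search_after) * fs) + 1, len(env))
        t_new = t
        if hi - lo >= 3:
            seg = env[lo:hi]
            pk = int(np.argmax(seg))
            p = float(pk)
            if 0 < pk < len(seg) - 1:
                denom = seg[pk - 1] - 2 * seg[pk] + seg[pk + 1]
                if denom < 0:
                    p = pk + 0.5 * (seg[pk - 1] - seg[pk + 1]) / denom
            if seg[pk] > 0:
                t_new = max((lo + p) / fs - onset_shift, 0.0)
        if t_new <= prev:
            t_new = t if t > prev else prev + 1.0 / fs
        refined.append(t_new)
        prev = refined[-1]
    return BeatList(times=np.array(refined))


def refine_beats_waveform(beats: BeatList, y: np.ndarray, fs: float,
                          half_width: float = 0.06, search: float = 0.008,
                          onset_shift: float = 0.0) -> BeatList:
    """Polish beat times against the band-passed waveform itself.

    Builds the record's mean S1 waveform template from segments centred on
    the (envelope-refined) beat times, then aligns each beat to the
    template by local cross-correlation with sub-sample (parabolic)
    interpolation. The search range is kept below a quarter of the
    heart-sound carrier period (default ±8 ms at ~30 Hz) so the
    correlation cannot slip to a neighbouring carrier cycle; the envelope
    stage must therefore run first. Consistent alignment to the common
    template reduces beat-to-beat timing jitter to well under a
    millisecond on clean signals. ``onset_shift`` is subtracted at the
    end (see :func:`refine_beats`).
    """
    env_y = np.asarray(y, dtype=float)
    w = int(half_width * fs)
    s = max(int(search * fs), 1)
    centres = [int(round(t * fs)) for t in beats.times]
    segs = [env_y[c - w:c + w] for c in centres
            if c - w >= 0 and c + w < len(env_y)]
    if len(segs) < 3:
        return BeatList(np.maximum(beats.times - onset_shift, 0.0))
    template = np.mean(segs, axis=0)
    out = list(beats.times)
    for k, c in enumerate(centres):
        lo, hi = c - w - s, c + w + s
        if lo < 0 or hi > len(env_y):
            continue
        cc = np.correlate(env_y[lo:hi], template, mode="valid")
        j = int(np.argmax(cc))
        p = float(j)
        if 0 < j < len(cc) - 1:
            denom = cc[j - 1] - 2 * cc[j] + cc[j + 1]
            if denom < 0:
                p = j + 0.5 * (cc[j - 1] - cc[j + 1]) / denom
        out[k] = (lo + p + w) / fs
    refined = np.maximum(np.asarray(out) - onset_shift, 0.0)
    keep = np.r_[True, np.diff(refined) > 0]
    return BeatList(refined[keep])


@dataclass
class MatchResult:
    """Outcome of tolerance-based one-to-one beat matching."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[float, float]]  # (ref_time, det_time)
    tolerance: float


def match_beats(ref: BeatList, det: BeatList,
                tolerance: float = DEFAULT_TOLERANCE) -> MatchResult:
    """Optimal one-to-one matching maximising TP, then minimising total |Δt|.

    dp[i][j] holds the best (TP, -total_dt) over ref[:i] vs det[:j];
    restricting to non-crossing matchings is lossless for interval
    tolerances on sorted lists (crossing pairs can always be uncrossed
    without increasing any |Δt|).
    """
    r = ref.times
    d = det.times
    n, m = len(r), len(d)
    tp_tab = np.zeros((n + 1, m + 1), dtype=np.int64)
    dt_tab = np.zeros((n + 1, m + 1))  # total |Δt| of the stored matching
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # candidates: skip ref[i-1], skip det[j-1], or pair them
            best_tp, best_dt = tp_tab[i - 1, j], dt_tab[i - 1, j]
            if (tp_tab[i, j - 1], -dt_tab[i, j - 1]) > (best_tp, -best_dt):
                best_tp, best_dt = tp_tab[i, j - 1], dt_tab[i, j - 1]
            delta = abs(r[i - 1] - d[j - 1])
            if delta <= tolerance:
                cand_tp = tp_tab[i - 1, j - 1] + 1
                cand_dt = dt_tab[i - 1, j - 1] + delta
                if (cand_tp, -cand_dt) > (best_tp, -best_dt):
                    best_tp, best_dt = cand_tp, cand_dt
            tp_tab[i, j], dt_tab[i, j] = best_tp, best_dt
    # backtrack
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        delta = abs(r[i - 1] - d[j - 1])
        if (delta <= tolerance
                and tp_tab[i, j] == tp_tab[i - 1, j - 1] + 1
                and np.isclose(dt_tab[i, j], dt_tab[i - 1, j - 1] + delta)):
            pairs.append((float(r[i - 1]), float(d[j - 1])))
            i, j = i - 1, j - 1
        elif tp_tab[i, j] == tp_tab[i - 1, j] and np.isclose(dt_tab[i, j], dt_tab[i - 1, j]):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    tp = int(tp_tab[n, m])
    assert len(pairs) == tp, "backtrack inconsistent with DP table"
    return MatchResult(tp=tp, fp=m - tp, fn=n - tp, pairs=pairs,
                       tolerance=tolerance)


def scores(m: MatchResult) -> dict[str, float]:
    """Sensitivity, precision, F1, accuracy from the match counts.

    sens = TP/(TP+FN), prec = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN),
    acc = TP/(TP+FP+FN). Undefined ratios (empty denominator) are NaN with
    a warning.
    """
    tp, fp, fn = m.tp, m.fp, m.fn

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    return {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "precision": ratio(tp, tp + fp, "precision"),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        "accuracy": ratio(tp, tp + fp + fn, "accuracy"),
    }
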