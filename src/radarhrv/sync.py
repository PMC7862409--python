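"""Offline synchronisation of two asynchronously sampled recordings.

Both devices record the same binary Gold-code watermark. Alignment is a
two-parameter problem: a resampling factor (clock-rate ratio) found by
maximising the peak normalised cross-correlation, and an integer latency
(asynchronous start) read off the cross-correlation argmax once both
sequences share a rate.

Conventions
-----------
``resample_by_factor(b, f)[m] = b[m * f]`` (linear interpolation): if b was
sampled at ``fs * f``, the result is b on the fs grid. A positive latency
means the second sequence's content starts *later* than the first's.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import (
    InsufficientOverlapError,
    InvalidConfigurationError,
    SyncFailureError,
)

#: Peak normalised correlation below which synchronisation is refused.
MIN_PEAK_CORRELATION = 0.5


# ---------------------------------------------------------------------------
# Gold codes
# ---------------------------------------------------------------------------

#: Preferred pair of primitive polynomials for degree 10 (taps as exponents,
#: descending; feedback is the XOR of the tapped register stages).
DEFAULT_TAPS_A = (10, 3)
DEFAULT_TAPS_B = (10, 8, 3, 2)


def _m_sequence(degree: int, taps: tuple[int, ...], seed: int = 1) -> np.ndarray:
    """Maximal-length LFSR sequence (Fibonacci form), values in {0, 1}."""
    if max(taps) != degree:
        raise InvalidConfigurationError(
            f"tap polynomial degree {max(taps)} != register degree {degree}")
    length = 2 ** degree - 1
    state = [(seed >> k) & 1 for k in range(degree)]
    if not any(state):
        raise InvalidConfigurationError("LFSR seed must be non-zero")
    out = np.empty(length, dtype=np.int8)
    for n in range(length):
        out[n] = state[-1]
        fb = 0
        for tp in taps:
            fb ^= state[tp - 1]
        state = [fb] + state[:-1]
    # primitivity check: the register must visit all 2^degree - 1 states,
    # equivalently the sequence is balanced with ones = zeros + 1
    if int(out.sum()) != 2 ** (degree - 1):
        raise InvalidConfigurationError(
            f"taps {taps} are not primitive for degree {degree}")
    return out


def generate_gold_sequence(degree: int = 10,
                           taps_a: tuple[int, ...] = None,
                           taps_b: tuple[int, ...] = None,
                           shift: int = 0) -> np.ndarray:
    """Gold code: XOR of a preferred pair of m-sequences, one circularly shifted.

    Returns one period of length ``2**degree - 1`` with values in {0, 1}.
    ``shift`` selects the code from the Gold family (the relative phase of
    the second component).
    """
    if taps_a is None or taps_b is None:
        if degree != 10 and (taps_a is None or taps_b is None):
            raise InvalidConfigurationError(
                "tap polynomials must be given explicitly for degree != 10")
        taps_a = taps_a or DEFAULT_TAPS_A
        taps_b = taps_b or DEFAULT_TAPS_B
    a = _m_sequence(degree, taps_a)
    b = _m_sequence(degree, taps_b)
    return np.bitwise_xor(a, np.roll(b, shift)).astype(np.int8)


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def _centred(seq: np.ndarray) -> np.ndarray:
    """Map a two-level sequence to +-1 and remove the mean."""
    s = np.asarray(seq, dtype=float)
    lo, hi = s.min(), s.max()
    if hi > lo:
        s = 2.0 * (s - lo) / (hi - lo) - 1.0
    return s - s.mean()


def resample_by_factor(x: np.ndarray, factor: float) -> np.ndarray:
    """Linear-interpolation resampling: ``out[m] = x[m * factor]``."""
    n_out = int(np.floor((len(x) - 1) / factor)) + 1
    idx = np.arange(n_out) * factor
    return np.interp(idx, np.arange(len(x)), x)


def _peak_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Peak of the full cross-correlation, normalised by the signal energies.

    Returns (peak value, displacement tau) where a[n] best matches b[n - tau].
    """
    c = signal.correlate(a, b, mode="full", method="fft")
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0.0, 0
    k = int(np.argmax(c))
    tau = k - (len(b) - 1)
    return float(c[k] / denom), tau


@dataclass
class SyncSolution:
    """Resampling factor and latency mapping record B onto record A's clock."""

    resampling_factor: float
    latency_samples: int
    target_fs: float
    peak_correlation: float

    def to_dict(self) -> dict:
        return {
            "factor": self.resampling_factor,
            "latency_samples": self.latency_samples,
            "target_fs": self.target_fs,
            "peak_correlation": self.peak_correlation,
        }


def _min_run_length(seq: np.ndarray) -> int:
    """Shortest run of equal values: the samples-per-chip of a binary code."""
    s = np.asarray(seq)
    change = np.flatnonzero(np.diff(s) != 0)
    if len(change) < 2:
        return 1
    runs = np.diff(change)
    return int(max(runs.min(), 1))


def _decimate(x: np.ndarray, d: int) -> np.ndarray:
    """Boxcar-average decimation (adequate anti-aliasing for square chips)."""
    if d <= 1:
        return x
    n = (len(x) // d) * d
    return x[:n].reshape(-1, d).mean(axis=1)


def estimate_resampling_factor(seq_a: np.ndarray, seq_b: np.ndarray,
                               bounds: tuple[float, float] = (0.9, 1.1),
                               tol: float = 1e-6) -> float:
    """Clock-ratio estimate maximising the peak cross-correlation.

    The full-record objective has a very narrow basin: the correlation peak
    collapses once the accumulated clock drift exceeds one code chip, i.e.
    for factor errors beyond ~ chip / record length. The search therefore
    proceeds multi-resolution: short central slices of B (wide capture
    range, decimated for speed) localise the factor coarsely, successively
    longer slices narrow it, and a bounded scalar minimisation on the
    full-record objective polishes to ``tol``.
    """
    a = _centred(seq_a)
    b = _centred(seq_b)
    if np.all(a == 0) or np.all(b == 0):
        raise SyncFailureError("constant synchronisation sequence")
    lo, hi = bounds
    if not 0 < lo < hi:
        raise InvalidConfigurationError(f"invalid bounds {bounds}")

    chip = _min_run_length(np.asarray(seq_b))
    total_chips = max(len(b) // chip, 1)
    best = 0.5 * (lo + hi)
    search_half_width = 0.5 * (hi - lo)
    for n_chips in (100, 1000, total_chips):
        n_chips = min(n_chips, total_chips)
        w = min(len(b), n_chips * chip)
        start = (len(b) - w) // 2
        sl = b[start:start + w]
        decim = max(1, chip // 2) if n_chips < total_chips else 1
        a_d, s_d = _decimate(a, decim), _decimate(sl, decim)
        capture = 1.0 / max(w // chip, 2)
        step = capture / 3.0
        grid = np.arange(best - search_half_width, best + search_half_width + step, step)
        grid = np.unique(np.clip(grid, lo, hi))
        vals = [_peak_corr(a_d, resample_by_factor(s_d, f))[0] for f in grid]
        best = float(grid[int(np.argmax(vals))])
        search_half_width = 2.0 * capture
        if n_chips == total_chips:
            break

    def neg_obj(f: float) -> float:
        return -_peak_corr(a, resample_by_factor(b, f))[0]

    res = optimize.minimize_scalar(
        neg_obj, bounds=(max(lo, best - search_half_width),
                         min(hi, best + search_half_width)),
        method="bounded", options={"xatol": tol})
    best_f, best_v = float(res.x), float(res.fun)
    v0 = neg_obj(best)
    if v0 < best_v:
        best_f, best_v = best, v0
    if -best_v < MIN_PEAK_CORRELATION:
        raise SyncFailureError(
            f"peak correlation {-best_v:.2f} < {MIN_PEAK_CORRELATION} at "
            f"factor {best_f:.6f}; true ratio outside bounds {bounds}?")
    return best_f


def estimate_latency(seq_a: np.ndarray, seq_b_resampled: np.ndarray) -> int:
    """Integer lag between two same-rate sequences.

    Positive lag means ``seq_b``'s content starts later than ``seq_a``'s:
    b[n] = a[n - lag], so the underlying event at a-index m appears at
    b-index m + lag.
    """
    a = _centred(seq_a)
    b = _centred(seq_b_resampled)
    peak, tau = _peak_corr(a, b)
    if peak < MIN_PEAK_CORRELATION:
        raise SyncFailureError(f"flat cross-correlation (peak {peak:.2f})")
    # a[n] matches b[n - tau]; b delayed by L has b[n] = a[n - L] => tau = -L
    return -tau


def _windowed_lag(a: np.ndarray, b: np.ndarray, k: int, w: int,
                  lag0: int, search: int = 30) -> float | None:
    """Local lag of b's window [k, k+w) against a, searched near lag0."""
    win = b[k:k + w]
    c = signal.correlate(a, win, mode="full", method="fft")
    taus = np.arange(-(len(win) - 1), len(a))
    expect = k - lag0
    sel = np.flatnonzero((taus >= expect - search) & (taus <= expect + search))
    if len(sel) == 0:
        return None
    j = sel[int(np.argmax(c[sel]))]
    tau = float(taus[j])
    if 0 < j < len(c) - 1:
        denom = c[j - 1] - 2 * c[j] + c[j + 1]
        if denom < 0:  # sub-sample apex of the correlation peak
            tau += 0.5 * float(c[j - 1] - c[j + 1]) / float(denom)
    return float(k - tau)


def solve_sync(seq_a: np.ndarray, seq_b: np.ndarray, target_fs: float = 2000.0,
               bounds: tuple[float, float] = (0.9, 1.1)) -> SyncSolution:
    """Estimate factor then latency in one call.

    The global correlation argmax reflects the lag averaged over the
    record; any residual factor error turns into a linear lag drift, so
    the latency is refined by measuring the local lag in an early and a
    late window and extrapolating to the start of the record (where the
    latency is defined).
    """
    factor = estimate_resampling_factor(seq_a, seq_b, bounds=bounds)
    b_r = resample_by_factor(np.asarray(seq_b, dtype=float), factor)
    a_c = _centred(seq_a)
    b_c = _centred(b_r)
    peak, _ = _peak_corr(a_c, b_c)
    latency = estimate_latency(seq_a, b_r)
    w = len(b_c) // 3
    if w >= 1000:
        l1 = _windowed_lag(a_c, b_c, 0, w, latency)
        l2 = _windowed_lag(a_c, b_c, len(b_c) - w, w, latency)
        if l1 is not None and l2 is not None:
            c1 = w / 2.0
            c2 = (len(b_c) - w) + w / 2.0
            slope = (l2 - l1) / (c2 - c1)
            latency = int(round(l1 - slope * c1))
    return SyncSolution(resampling_factor=factor, latency_samples=latency,
                        target_fs=target_fs, peak_correlation=peak)


def align_records(rec_a: np.ndarray, rec_b: np.ndarray, solution: SyncSolution,
                  fs_a: float | None = None, min_overlap: float = 10.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Resample B by the solved factor, undo the latency, trim to overlap.

    ``rec_a`` and ``rec_b`` may be 1-D or (n, channels); both outputs share
    the target rate and length. Records whose native rate differs from
    ``solution.target_fs`` should be passed through :func:`resample_by_factor`
    with ``fs_native / target_fs`` first (``fs_a`` does this for A).
    """
    a = np.asarray(rec_a, dtype=float)
    b = np.asarray(rec_b, dtype=float)

    def _resample(x: np.ndarray, f: float) -> np.ndarray:
        if abs(f - 1.0) < 1e-15:
            return x
        if x.ndim == 1:
            return resample_by_factor(x, f)
        return np.stack([resample_by_factor(x[:, c], f)
                         for c in range(x.shape[1])], axis=1)

    if fs_a is not None and fs_a != solution.target_fs:
        a = _resample(a, fs_a / solution.target_fs)
    b = _resample(b, solution.resampling_factor)

    lag = solution.latency_samples
    if lag >= 0:
        # b's content is delayed: b[lag] corresponds to a[0]
        b = b[lag:]
    else:
        a = a[-lag:]
    n = min(len(a), len(b))
    if n / solution.target_fs < min_overlap:
        raise InsufficientOverlapError(
            f"aligned overlap {n / solution.target_fs:.1f}s < {min_overlap}s")
    return a[:n], b[:n]
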