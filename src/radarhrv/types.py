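"""Core data containers shared by the pipeline stages.

The containers are thin ``dataclass`` wrappers over numpy arrays that carry
the sampling metadata each stage needs, plus cheap structural validation.
All signal arrays are 1-D ``float64`` unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import InvalidInputError

#: Free-space wavelength of the 24 GHz carrier in metres (c / 24e9).
WAVELENGTH_24GHZ = 299_792_458.0 / 24e9


class CardiacState(IntEnum):
    """The four segmentation states, in cyclic order."""

    S1 = 0
    SYS = 1
    S2 = 2
    DIA = 3


#: Successor of each state under the fixed cardiac cycle S1->SYS->S2->DIA->S1.
NEXT_STATE = {
    CardiacState.S1: CardiacState.SYS,
    CardiacState.SYS: CardiacState.S2,
    CardiacState.S2: CardiacState.DIA,
    CardiacState.DIA: CardiacState.S1,
}

N_STATES = 4


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class BasebandRecord:
    """Four Six-Port power-detector channels B3..B6 at a common sampling rate.

    The two differential pairs (B5 - B6, B3 - B4) carry the in-phase and
    quadrature components of the complex baseband signal.
    """

    b3: np.ndarray
    b4: np.ndarray
    b5: np.ndarray
    b6: np.ndarray
    fs: float
    clip_low: float | None = None
    clip_high: float | None = None

    def __post_init__(self):
        self.b3 = _as_1d_float(self.b3, "b3")
        self.b4 = _as_1d_float(self.b4, "b4")
        self.b5 = _as_1d_float(self.b5, "b5")
        self.b6 = _as_1d_float(self.b6, "b6")
        n = {len(self.b3), len(self.b4), len(self.b5), len(self.b6)}
        if len(n) != 1:
            raise InvalidInputError(f"channel lengths differ: {sorted(n)}")
        if not self.fs > 0:
            raise InvalidInputError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return len(self.b3)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels(self) -> dict[str, np.ndarray]:
        return {"b3": self.b3, "b4": self.b4, "b5": self.b5, "b6": self.b6}


@dataclass
class IQSignal:
    """In-phase / quadrature baseband pair; ``z`` is the complex view."""

    i: np.ndarray
    q: np.ndarray
    fs: float

    def __post_init__(self):
        self.i = _as_1d_float(self.i, "i")
        self.q = _as_1d_float(self.q, "q")
        if len(self.i) != len(self.q):
            raise InvalidInputError("i and q must have equal length")

    @property
    def z(self) -> np.ndarray:
        return self.i + 1j * self.q


@dataclass
class DisplacementSignal:
    """Relative chest displacement in metres (defined up to a constant)."""

    x: np.ndarray
    fs: float
    wavelength: float = WAVELENGTH_24GHZ

    def __post_init__(self):
        self.x = _as_1d_float(self.x, "x")
        if not np.all(np.isfinite(self.x)):
            raise InvalidInputError("displacement contains non-finite samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.x)) / self.fs


@dataclass
class FeatureTrack:
    """Per-frame feature matrix for the segmenters.

    Columns: homomorphic envelope, Hilbert envelope, PSD envelope, heart-rate
    estimate — each z-normalised per record. ``hr_bpm`` keeps the raw
    (un-normalised) autocorrelation heart-rate estimate per frame.
    """

    features: np.ndarray  # (n_frames, 4)
    feature_fs: float
    hr_bpm: np.ndarray
    norm_mean: np.ndarray
    norm_std: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise InvalidInputError("features must be 2-D (frames x channels)")
        if not np.all(np.isfinite(self.features)):
            raise InvalidInputError("features contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.feature_fs


@dataclass
class StateSequence:
    """Per-frame cardiac-state labels at the feature rate."""

    states: np.ndarray  # int array of CardiacState values
    feature_fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1:
            raise InvalidInputError("states must be one-dimensional")
        if self.states.size and not np.all((self.states >= 0) & (self.states < N_STATES)):
            raise InvalidInputError("states contain labels outside the four-state alphabet")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.states)) / self.feature_fs

    def is_cyclic(self) -> bool:
        """True iff every transition is a self-loop or the cyclic successor."""
        s = self.states
        if len(s) < 2:
            return True
        nxt = np.array([NEXT_STATE[CardiacState(v)] for v in range(N_STATES)])
        ok = (s[1:] == s[:-1]) | (s[1:] == nxt[s[:-1]])
        return bool(np.all(ok))


@dataclass
class BeatList:
    """Strictly increasing heartbeat reference times in seconds."""

    times: np.ndarray

    def __post_init__(self):
        self.times = _as_1d_float(self.times, "times")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise InvalidInputError("beat times must be strictly increasing")
            if self.times[0] < 0:
                raise InvalidInputError("beat times must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RRSequence:
    """Inter-beat intervals with per-interval validity flags.

    ``times[i]`` is the end time of ``intervals[i]`` (the beat closing the
    interval); flagged-invalid intervals are excluded from all statistics.
    """

    times: np.ndarray
    intervals: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_quality: bool = False

    def __post_init__(self):
        self.times = _as_1d_float(self.times, "times")
        self.intervals = _as_1d_float(self.intervals, "intervals")
        if len(self.times) != len(self.intervals):
            raise InvalidInputError("times and intervals must have equal length")
        if np.any(self.intervals <= 0):
            raise InvalidInputError("intervals must be positive")
        if self.valid is None:
            self.valid = np.ones(len(self.intervals), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def valid_intervals(self) -> np.ndarray:
        return self.intervals[self.valid]

    @property
    def valid_times(self) -> np.ndarray:
        return self.times[self.valid]
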