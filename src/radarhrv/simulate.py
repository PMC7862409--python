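"""Forward simulator for Six-Port radar heart-sound recordings.

The generator produces the full causal chain with known ground truth:

1. an RR tachogram with low-frequency (~0.1 Hz, baroreflex-like) and
   high-frequency (respiratory sinus arrhythmia, ~0.25 Hz) modulation plus
   white jitter;
2. chest displacement = respiration sinusoid + a pulse-wave bump per beat +
   Gaussian-windowed tone bursts for the first and second heart sound
   (S1 at the beat reference time, S2 after the systolic fraction of the
   current RR interval), with per-sample state labels;
3. the four Six-Port baseband channels via the inverse of the arctangent
   demodulation model (phase modulation of the 24 GHz carrier), with
   additive detector noise and optional rail clipping.

Amplitudes default to the orders of magnitude of radar vital-sign
measurements: millimetre respiration, sub-millimetre pulse wave, and
tens-of-micrometre heart-sound micro-vibrations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigurationError
from .types import (
    BasebandRecord,
    BeatList,
    CardiacState,
    DisplacementSignal,
    StateSequence,
    WAVELENGTH_24GHZ,
)


@dataclass
class BurstParams:
    """A heart-sound micro-vibration: Gaussian-windowed tone burst."""

    centre_freq: float  # Hz
    duration: float     # s, full support of the burst (±3 sigma)
    amplitude: float    # m, peak displacement


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic subject.

    ``hf_amp_profile`` optionally modulates the HF (respiratory) coupling
    amplitude over time as a list of ``(start_s, end_s, scale)`` triples;
    outside all triples the scale is 1. This is how cold-pressor "Response"
    windows raise or lower vagal modulation.
    """

    duration: float = 60.0
    fs: float = 2000.0
    mean_rr: float = 1.0
    lf_amp: float = 0.03
    lf_freq: float = 0.1
    hf_amp: float = 0.05
    hf_freq: float = 0.25
    rr_jitter_sd: float = 0.005
    s1: BurstParams = field(default_factory=lambda: BurstParams(30.0, 0.100, 30e-6))
    s2: BurstParams = field(default_factory=lambda: BurstParams(35.0, 0.080, 20e-6))
    systole_fraction: float = 0.35
    pulse_amplitude: float = 0.4e-3
    resp_amp: float = 3e-3
    resp_freq: float = 0.25
    noise_sd: float = 0.01
    detector_amplitude: float = 1.0
    wavelength: float = WAVELENGTH_24GHZ
    phase_offset: float = 0.0
    clip_rails: tuple[float, float] | None = None
    hf_amp_profile: tuple[tuple[float, float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (60.0 / 135.0 <= self.mean_rr <= 60.0 / 40.0):
            raise InvalidConfigurationError(
                f"mean_rr {self.mean_rr:.3f}s outside the 40-135 bpm range")
        if self.lf_amp + self.hf_amp >= self.mean_rr / 2:
            raise InvalidConfigurationError("modulation amplitudes >= mean_rr/2")
        if self.fs <= 4 * self.s1.centre_freq:
            raise InvalidConfigurationError("fs must exceed 4x the S1 centre frequency")


@dataclass
class GroundTruth:
    """Everything the simulator knows about a record."""

    beats: BeatList
    rr_intervals: np.ndarray        # true tachogram (s), one per closing beat
    state_labels: StateSequence     # per-sample labels at cfg.fs
    hf_scale_at_beats: np.ndarray   # HF amplitude scale active at each beat


def _hf_scale(cfg: SimulationConfig, t: float) -> float:
    if cfg.hf_amp_profile:
        for start, end, scale in cfg.hf_amp_profile:
            if start <= t < end:
                return scale
    return 1.0


def simulate_tachogram(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[BeatList, np.ndarray]:
    """Place beats iteratively from the modulated instantaneous RR interval.

    RR(t) = mean_rr + lf_amp*sin(2*pi*f_LF*t) + s(t)*hf_amp*sin(2*pi*f_HF*t)
            + N(0, jitter_sd), evaluated at the previous beat time.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    times = [0.0]
    rrs = []
    while True:
        t = times[-1]
        rr = (cfg.mean_rr
              + cfg.lf_amp * np.sin(2 * np.pi * cfg.lf_freq * t)
              + _hf_scale(cfg, t) * cfg.hf_amp * np.sin(2 * np.pi * cfg.hf_freq * t))
        if cfg.rr_jitter_sd > 0:
            rr += rng.normal(0.0, cfg.rr_jitter_sd)
        if rr <= 0.3:
            raise InvalidConfigurationError(
                f"generated RR interval {rr:.3f}s <= 0.3s; reduce modulation/jitter")
        if t + rr > cfg.duration:
            break
        times.append(t + rr)
        rrs.append(rr)
    return BeatList(times=np.array(times)), np.array(rrs)


def _gaussian_burst(t: np.ndarray, onset: float, p: BurstParams) -> np.ndarray:
    """Tone burst whose Gaussian window spans [onset, onset + duration]."""
    tc = onset + p.duration / 2.0
    sigma = p.duration / 6.0
    return p.amplitude * np.exp(-0.5 * ((t - tc) / sigma) ** 2) * \
        np.sin(2 * np.pi * p.centre_freq * (t - tc))


def simulate_displacement(beats: BeatList, cfg: SimulationConfig,
                          ) -> tuple[DisplacementSignal, StateSequence]:
    """Render chest displacement and per-sample state labels for given beats."""
    bt = beats.times
    if np.any(np.diff(bt) <= 0):
        raise InvalidConfigurationError("beat times must be strictly increasing")
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_freq * t)
    labels = np.full(n, int(CardiacState.DIA))

    rr_next = np.diff(bt)
    for k, beat in enumerate(bt):
        rr = rr_next[k] if k < len(rr_next) else (rr_next[-1] if len(rr_next) else cfg.mean_rr)
        s1_on = beat
        s2_on = beat + cfg.systole_fraction * rr
        if s2_on + cfg.s2.duration >= beat + rr:
            raise InvalidConfigurationError(
                f"S2 burst overlaps the next beat at t={beat:.2f}s (RR={rr:.3f}s)")
        # pulse-wave bump: raised cosine over the first 40% of the cycle
        bump_w = 0.4 * rr
        sl = slice(int(np.ceil(s1_on * cfg.fs)), min(int((s1_on + bump_w) * cfg.fs), n))
        tb = t[sl] - s1_on
        x[sl] += cfg.pulse_amplitude * 0.5 * (1 - np.cos(2 * np.pi * tb / bump_w))
        # heart-sound bursts (evaluate only on their local support, ±duration)
        for onset, p in ((s1_on, cfg.s1), (s2_on, cfg.s2)):
            lo = max(int((onset - 0.5 * p.duration) * cfg.fs), 0)
            hi = min(int((onset + 1.5 * p.duration) * cfg.fs) + 1, n)
            x[lo:hi] += _gaussian_burst(t[lo:hi], onset, p)
        # labels: S1 support, systole, S2 support, diastole elsewhere
        i0 = int(np.ceil(s1_on * cfg.fs))
        i1 = min(int(np.ceil((s1_on + cfg.s1.duration) * cfg.fs)), n)
        i2 = int(np.ceil(s2_on * cfg.fs))
        i3 = min(int(np.ceil((s2_on + cfg.s2.duration) * cfg.fs)), n)
        labels[i0:i1] = int(CardiacState.S1)
        labels[i1:i2] = int(CardiacState.SYS)
        labels[i2:i3] = int(CardiacState.S2)
    return (DisplacementSignal(x=x, fs=cfg.fs, wavelength=cfg.wavelength),
            StateSequence(states=labels, feature_fs=cfg.fs))


def modulate_radar(disp: DisplacementSignal, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None) -> BasebandRecord:
    """Inverse of the demodulation model: displacement -> four channels.

    phi = 2*pi * (2x) / lambda + phi0; the differential pairs carry
    A*cos(phi) and A*sin(phi) split symmetrically about a common bias so
    that b5 - b6 = A cos(phi) and b3 - b4 = A sin(phi).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    phi = 2 * np.pi * (2.0 * disp.x) / cfg.wavelength + cfg.phase_offset
    a = cfg.detector_amplitude
    bias = a  # detector outputs are non-negative in practice
    half_i = 0.5 * a * np.cos(phi)
    half_q = 0.5 * a * np.sin(phi)
    chans = {
        "b3": bias + half_q,
        "b4": bias - half_q,
        "b5": bias + half_i,
        "b6": bias - half_i,
    }
    if cfg.noise_sd > 0:
        for k in chans:
            chans[k] = chans[k] + rng.normal(0.0, cfg.noise_sd, size=len(disp.x))
    clip_low = clip_high = None
    if cfg.clip_rails is not None:
        clip_low, clip_high = cfg.clip_rails
        for k in chans:
            chans[k] = np.clip(chans[k], clip_low, clip_high)
    return BasebandRecord(fs=disp.fs, clip_low=clip_low, clip_high=clip_high, **chans)


def simulate_record(cfg: SimulationConfig) -> tuple[BasebandRecord, GroundTruth]:
    """Full forward chain for one subject: tachogram -> displacement -> baseband."""
    rng = np.random.default_rng(cfg.seed)
    beats, rrs = simulate_tachogram(cfg, rng)
    disp, labels = simulate_displacement(beats, cfg)
    rec = modulate_radar(disp, cfg, rng)
    hf_scales = np.array([_hf_scale(cfg, t) for t in beats.times])
    truth = GroundTruth(beats=beats, rr_intervals=rrs, state_labels=labels,
                        hf_scale_at_beats=hf_scales)
    return rec, truth


# ---------------------------------------------------------------------------
# Synchronisation test pairs
# ---------------------------------------------------------------------------

def generate_sync_pair(fs: float, duration: float, factor: float, lag: float,
                       chip_rate: float = 25.0, degree: int = 10,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sample one underlying Gold-code waveform at two mismatched rates.

    Returns ``(seq_a, seq_b)`` where ``seq_a[n] = c(n / fs)`` and
    ``seq_b[n] = c(n / (fs * factor) - lag)``: the second device runs at
    ``fs * factor`` and starts ``lag`` seconds later (positive lag means
    seq_b's content starts later in the underlying timeline).

    The code repeats cyclically, so the latency is only identifiable modulo
    one code period (2^degree - 1 chips / chip_rate); the default 25 chips/s
    gives a 40.9 s period, which disambiguates lags within ±15 s via the
    larger overlap of the true alignment.
    """
    from .sync import generate_gold_sequence  # local import to avoid cycle

    if factor <= 0:
        raise InvalidConfigurationError("factor must be positive")
    rng = np.random.default_rng(seed)
    code = generate_gold_sequence(degree, shift=int(rng.integers(0, 2 ** degree - 1)))
    period = len(code)

    def c(t: np.ndarray) -> np.ndarray:
        chips = np.floor(t * chip_rate).astype(np.int64) % period
        return code[chips].astype(float)

    n_a = int(round(duration * fs))
    n_b = int(round(duration * fs * factor))
    seq_a = c(np.arange(n_a) / fs)
    seq_b = c(np.arange(n_b) / (fs * factor) - lag)
    return seq_a, seq_b


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: The cold-pressor protocol layout used by :func:`make_cohort`:
#: named scenario windows (start, length) in seconds, 90 s parts with 60 s
#: pauses, after a 10 s lead-in.
CPT_WINDOWS = {
    "Baseline": (10.0, 90.0),
    "Response": (160.0, 90.0),
    "Recovery": (310.0, 90.0),
}
CPT_DURATION = 410.0


@dataclass
class CohortPlan:
    """Per-subject HF-modulation scaling during the Response window.

    ``response_hf_scale[i] < 1`` emulates a vagal-withdrawal ("negative",
    HF norm decreasing) reaction to the ice-water stimulus; ``> 1`` the
    opposite ("positive") reaction.
    """

    response_hf_scale: tuple[float, ...] = (0.5, 0.5, 1.8, 1.8, 0.5, 1.8)
    windows: dict = field(default_factory=lambda: dict(CPT_WINDOWS))
    duration: float = CPT_DURATION

    @property
    def n_subjects(self) -> int:
        return len(self.response_hf_scale)

    def is_negative(self, i: int) -> bool:
        return self.response_hf_scale[i] < 1.0


def make_cohort(n_subjects: int, plan: CohortPlan | None = None,
                seed: int = 0, base_cfg: SimulationConfig | None = None,
                ) -> list[tuple[BasebandRecord, GroundTruth, SimulationConfig]]:
    """Simulate a cohort with per-subject seeds and CPT response plans.

    Subject ``i`` uses seed ``seed + 1000 * i`` and a mean RR drawn
    deterministically from a physiological spread so subjects differ.
    """
    if n_subjects < 1:
        raise InvalidConfigurationError("n_subjects must be >= 1")
    if plan is None:
        plan = CohortPlan()
    if n_subjects > plan.n_subjects:
        raise InvalidConfigurationError(
            f"plan covers {plan.n_subjects} subjects, {n_subjects} requested")
    if base_cfg is None:
        base_cfg = SimulationConfig()
    start, length = plan.windows["Response"]
    out = []
    mean_rrs = np.linspace(0.75, 1.05, n_subjects)
    for i in range(n_subjects):
        cfg = replace(
            base_cfg,
            duration=plan.duration,
            mean_rr=float(mean_rrs[i]),
            hf_amp_profile=((start, start + length, plan.response_hf_scale[i]),),
            seed=seed + 1000 * i,
        )
        rec, truth = simulate_record(cfg)
        out.append((rec, truth, cfg))
    return out
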