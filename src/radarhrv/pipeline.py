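"""End-to-end orchestration: baseband record -> HRV report.

Per subject: clipping check (clipped records are excluded, not silently
processed), phase demodulation, feature extraction, heart-sound
segmentation (HSMM or LSTM), beat scoring against the reference beats,
artefact removal, and windowed HRV indices. Per cohort: leave-one-subject-
out segmenter training, the positive/negative group split by the reference
direction of the HF-norm response, and per-index agreement statistics
between radar-derived and reference HRV values.

Stage failures are isolated per subject: a failed subject is reported with
the failing stage and the cohort run continues.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import beats as beats_mod
from . import features as feat_mod
from . import hrv as hrv_mod
from . import hsmm as hsmm_mod
from . import lstm as lstm_mod
from . import sixport
from .errors import InvalidInputError, RadarHrvError
from .simulate import CPT_WINDOWS, GroundTruth
from .types import (
    BasebandRecord,
    BeatList,
    FeatureTrack,
    StateSequence,
    WAVELENGTH_24GHZ,
)

#: HRV indices compared between radar and reference per scenario.
AGREEMENT_INDICES = ("heart_rate", "hf_power", "hf_norm", "lf_power",
                     "lf_hf_ratio", "tri")


@dataclass
class PipelineConfig:
    """Knobs for a full pipeline run."""

    method: str = "hsmm"  # "hsmm" | "lstm"
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CPT_WINDOWS))
    band: tuple[float, float] = feat_mod.DEFAULT_BAND
    feature_fs: float = feat_mod.DEFAULT_FEATURE_FS
    tolerance: float = beats_mod.DEFAULT_TOLERANCE
    wavelength: float = WAVELENGTH_24GHZ
    remove_dc: bool = False
    refine_beats: bool = True
    lstm_config: lstm_mod.LstmConfig | None = None

    def __post_init__(self):
        if self.method not in ("hsmm", "lstm"):
            raise InvalidInputError(f"unknown segmentation method {self.method!r}")


def truth_feature_labels(truth: GroundTruth, feature_fs: float,
                         n_frames: int) -> StateSequence:
    """Downsample the simulator's per-sample labels to the feature frames."""
    src = truth.state_labels
    idx = np.minimum((np.arange(n_frames) / feature_fs * src.feature_fs)
                     .astype(int), len(src.states) - 1)
    return StateSequence(states=src.states[idx], feature_fs=feature_fs)


def _state_runs_of(seq: StateSequence):
    from .hsmm import _state_runs
    return _state_runs(seq.states)


def _segment(segmenter, track: FeatureTrack) -> StateSequence:
    if isinstance(segmenter, hsmm_mod.HsmmModel):
        return hsmm_mod.viterbi_segment(segmenter, track)
    return lstm_mod.predict_states(segmenter, track)[1]


@dataclass
class SubjectReport:
    """Per-subject outcome: status, beat scores, and HRV per scenario."""

    status: str                     # "ok" | "excluded" | "failed"
    failed_stage: str | None = None
    clipping: dict | None = None
    beat_scores: dict | None = None           # overall + per-window scores
    hrv: dict | None = None                   # window name -> HrvIndices dict
    n_beats_detected: int = 0
    n_beats_reference: int = 0

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "failed_stage": self.failed_stage,
            "clipping": self.clipping,
            "beat_scores": self.beat_scores,
            "hrv": self.hrv,
            "n_beats_detected": self.n_beats_detected,
            "n_beats_reference": self.n_beats_reference,
        }


def run_subject(cfg: PipelineConfig, record: BasebandRecord,
                reference_beats: BeatList, segmenter) -> SubjectReport:
    """Run the full chain for one subject with a pre-trained segmenter."""
    report = SubjectReport(status="ok")
    stage = "clipping"
    try:
        clip = sixport.detect_clipping(record)
        report.clipping = {"fractions": clip.fractions, "flagged": clip.flagged}
        if clip.flagged:
            report.status = "excluded"
            return report
        stage = "demodulation"
        disp = sixport.demodulate(record, cfg.wavelength, remove_dc=cfg.remove_dc)
        stage = "features"
        track, hs = feat_mod.extract_features(disp, band=cfg.band,
                                              feature_fs=cfg.feature_fs)
        stage = "segmentation"
        seq = _segment(segmenter, track)
        stage = "beat-eval"
        det = beats_mod.states_to_beats(seq)
        if cfg.refine_beats and len(det):
            s1_runs = [l for s, _, l in _state_runs_of(seq)
                       if s == 0]  # S1 sojourn lengths in frames
            shift = (np.mean(s1_runs) / seq.feature_fs / 2.0
                     if s1_runs else 0.05)
            det = beats_mod.refine_beats(
                det, feat_mod.homomorphic_envelope(hs.y, hs.fs), hs.fs)
            det = beats_mod.refine_beats_waveform(
                det, hs.y, hs.fs, onset_shift=float(shift))
        report.n_beats_detected = len(det)
        report.n_beats_reference = len(reference_beats)
        m = beats_mod.match_beats(reference_beats, det, tolerance=cfg.tolerance)
        per_window = {}
        for name, (start, length) in cfg.windows.items():
            sel_r = BeatList(reference_beats.times[
                (reference_beats.times >= start)
                & (reference_beats.times < start + length)])
            sel_d = BeatList(det.times[(det.times >= start)
                                       & (det.times < start + length)])
            per_window[name] = beats_mod.scores(
                beats_mod.match_beats(sel_r, sel_d, tolerance=cfg.tolerance))
        report.beat_scores = {"overall": beats_mod.scores(m), **per_window}
        stage = "hrv"
        rr = hrv_mod.remove_artefacts(hrv_mod.beats_to_rr(det))
        indices = hrv_mod.windowed_hrv(rr, cfg.windows)
        report.hrv = {k: v.to_dict() for k, v in indices.items()}
    except RadarHrvError as exc:
        report.status = "failed"
        report.failed_stage = f"{stage}: {exc}"
    return report


@dataclass
class CohortReport:
    """Cohort-level outcome: subjects, group split, agreement statistics."""

    subjects: list[SubjectReport]
    reference_hrv: list[dict | None]
    groups: list[str | None]        # "negative" | "positive" per subject
    agreement: dict                  # scenario -> index -> AgreementStats dict
    mean_f1: float

    def to_json(self, path=None) -> str:
        doc = {
            "subjects": [s.to_dict() for s in self.subjects],
            "reference_hrv": self.reference_hrv,
            "groups": self.groups,
            "agreement": self.agreement,
            "mean_f1": self.mean_f1,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def reference_windowed_hrv(truth: GroundTruth,
                           windows: dict[str, tuple[float, float]],
                           ) -> dict[str, hrv_mod.HrvIndices]:
    """Ground-truth HRV per scenario window from the simulator's beats."""
    rr = hrv_mod.beats_to_rr(truth.beats)
    return hrv_mod.windowed_hrv(rr, windows)


def run_cohort(cfg: PipelineConfig,
               cohort: list[tuple[BasebandRecord, GroundTruth]],
               ) -> CohortReport:
    """LOSOCV cohort run with group split and agreement statistics.

    The segmenter for each subject is trained on the *other* subjects'
    feature tracks and ground-truth labels. Group membership (HF-norm
    response direction) is read from the reference indices. Agreement is
    computed across non-excluded subjects per scenario and index.
    """
    n = len(cohort)
    if n < 3:
        raise InvalidInputError(f"cohort needs >= 3 subjects, got {n}")
    # precompute tracks and labels once (stage failures isolate per subject)
    tracks: list[FeatureTrack | None] = []
    labels: list[StateSequence | None] = []
    prep_fail: list[str | None] = []
    for rec, truth in cohort:
        try:
            if sixport.detect_clipping(rec).flagged:
                raise InvalidInputError("clipping")
            disp = sixport.demodulate(rec, cfg.wavelength, remove_dc=cfg.remove_dc)
            track, _ = feat_mod.extract_features(disp, band=cfg.band,
                                                 feature_fs=cfg.feature_fs)
            tracks.append(track)
            labels.append(truth_feature_labels(truth, cfg.feature_fs,
                                               track.n_frames))
            prep_fail.append(None)
        except RadarHrvError as exc:
            tracks.append(None)
            labels.append(None)
            prep_fail.append(str(exc))
    usable = [i for i in range(n) if prep_fail[i] is None]
    if len(usable) < 3:
        raise InvalidInputError(
            f"only {len(usable)} usable subjects after preprocessing")

    subjects: list[SubjectReport] = []
    ref_hrv: list[dict | None] = []
    groups: list[str | None] = []
    for i, (rec, truth) in enumerate(cohort):
        if prep_fail[i] is not None:
            subjects.append(SubjectReport(status="excluded",
                                          failed_stage=prep_fail[i]))
            ref_hrv.append(None)
            groups.append(None)
            continue
        train_idx = [j for j in usable if j != i]
        if cfg.method == "hsmm":
            segmenter = hsmm_mod.train_hsmm([tracks[j] for j in train_idx],
                                            [labels[j] for j in train_idx])
        else:
            lcfg = cfg.lstm_config or lstm_mod.LstmConfig.desk()
            segmenter = lstm_mod.train_lstm([tracks[j] for j in train_idx],
                                            [labels[j] for j in train_idx],
                                            lcfg)
        subjects.append(run_subject(cfg, rec, truth.beats, segmenter))
        ref = reference_windowed_hrv(truth, cfg.windows)
        ref_hrv.append({k: v.to_dict() for k, v in ref.items()})
        if "Response" in ref and "Baseline" in ref:
            groups.append("negative" if ref["Response"].hf_norm
                          < ref["Baseline"].hf_norm else "positive")
        else:
            groups.append(None)

    ok = [i for i in range(n) if subjects[i].status == "ok"]
    agreement: dict = {}
    for name in cfg.windows:
        per_index = {}
        for index in AGREEMENT_INDICES:
            radar = [subjects[i].hrv[name][index] for i in ok]
            ref = [ref_hrv[i][name][index] for i in ok]
            if len(radar) >= 3:
                per_index[index] = hrv_mod.agreement(radar, ref).to_dict()
        agreement[name] = per_index
    f1s = [subjects[i].beat_scores["overall"]["f1"] for i in ok]
    mean_f1 = float(np.mean(f1s)) if f1s else float("nan")
    return CohortReport(subjects=subjects, reference_hrv=ref_hrv,
                        groups=groups, agreement=agreement, mean_f1=mean_f1)
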