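"""RR sequences, artefact filtering, TRI, spectral indices, agreement."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarhrv import (
    BeatList,
    RRSequence,
    agreement,
    beats_to_rr,
    compute_tri,
    normalised_units,
    remove_artefacts,
    rr_to_uniform,
    spectral_powers,
    windowed_hrv,
)
from radarhrv.errors import InvalidInputError


def _rr_from_intervals(intervals, t0=0.0):
    times = t0 + np.cumsum(intervals)
    return RRSequence(times=times, intervals=np.asarray(intervals, float))


class TestBeatsToRR:
    def test_intervals_are_differences(self):
        rr = beats_to_rr(BeatList(np.array([0.0, 1.0, 2.1])))
        assert np.allclose(rr.intervals, [1.0, 1.1])
        assert np.allclose(rr.times, [1.0, 2.1])

    def test_equally_spaced_beats(self):
        rr = beats_to_rr(BeatList(np.arange(0, 8, 0.8)))
        assert np.allclose(rr.intervals, 0.8)

    def test_non_monotone_input_rejected(self):
        with pytest.raises(InvalidInputError):
            BeatList(np.array([0.0, 2.0, 1.0]))

    def test_too_few_beats_rejected(self):
        with pytest.raises(InvalidInputError):
            beats_to_rr(BeatList(np.array([1.0])))


class TestArtefactRemoval:
    def test_clean_sequence_unchanged(self):
        rr = _rr_from_intervals(np.full(60, 1.0))
        out = remove_artefacts(rr)
        assert np.allclose(out.intervals, 1.0)
        assert out.valid.all()
        assert not out.low_quality

    def test_missed_beat_restored_by_splitting(self):
        beats = list(np.arange(0, 30, 1.0))
        del beats[15]  # drop one beat -> one 2.0 s interval
        out = remove_artefacts(beats_to_rr(BeatList(np.array(beats))))
        assert np.allclose(out.intervals, 1.0, atol=1e-9)
        assert len(out) == 29  # the doubled interval became two

    def test_spurious_beat_merged(self):
        beats = np.sort(np.r_[np.arange(0, 30, 1.0), 15.3])  # extra at 15.3
        out = remove_artefacts(beats_to_rr(BeatList(beats)))
        assert np.allclose(out.intervals, 1.0, atol=1e-9)

    def test_unresolvable_artefact_flagged_invalid(self):
        iv = np.full(30, 1.0)
        iv[10] = 1.5  # 50% off, neither doubled nor splittable
        out = remove_artefacts(_rr_from_intervals(iv))
        assert not out.valid[10]
        assert out.valid.sum() == 29

    def test_low_quality_warning(self):
        rng = np.random.default_rng(0)
        iv = np.where(rng.random(40) < 0.5, 1.0, 1.6)
        with pytest.warns(UserWarning):
            out = remove_artefacts(_rr_from_intervals(iv))
        assert out.low_quality


class TestTriangularIndex:
    def test_identical_intervals_give_one(self):
        assert compute_tri(_rr_from_intervals(np.full(50, 0.8))) == 1.0

    def test_hand_counted_histogram(self):
        # bin counts {2, 6, 2} -> TRI = 10/6
        bw = 1.0 / 128.0
        iv = np.concatenate([np.full(2, 0.80 + 0.2 * bw),
                             np.full(6, 0.80 + 1.2 * bw),
                             np.full(2, 0.80 + 2.2 * bw)])
        assert compute_tri(_rr_from_intervals(iv)) == pytest.approx(10 / 6)

    def test_uniform_over_k_bins_gives_k(self):
        bw = 1.0 / 128.0
        k = 5
        iv = np.concatenate([np.full(7, 0.9 + (j + 0.5) * bw)
                             for j in range(k)])
        assert compute_tri(_rr_from_intervals(iv)) == pytest.approx(k)

    @given(st.permutations(list(range(12))))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, perm):
        base = 0.7 + 0.01 * np.arange(12)
        tri_a = compute_tri(_rr_from_intervals(base))
        tri_b = compute_tri(_rr_from_intervals(base[np.array(perm)]))
        assert tri_a == pytest.approx(tri_b)

    def test_non_decreasing_with_dispersion(self):
        bw = 1.0 / 128.0
        narrow = np.concatenate([np.full(10, 0.9 + 0.5 * bw),
                                 np.full(2, 0.9 + 1.5 * bw)])
        wide = np.concatenate([np.full(6, 0.9 + 0.5 * bw),
                               np.full(6, 0.9 + 1.5 * bw)])
        assert compute_tri(_rr_from_intervals(wide)) \
            >= compute_tri(_rr_from_intervals(narrow))


class TestUniformResampling:
    def test_constant_series(self):
        grid, series = rr_to_uniform(_rr_from_intervals(np.full(40, 1.0)))
        assert np.allclose(series, 1.0)

    def test_alternating_series_mean(self):
        iv = np.tile([0.9, 1.1], 50)
        _, series = rr_to_uniform(_rr_from_intervals(iv))
        assert series.mean() == pytest.approx(1.0, abs=0.01)

    def test_grid_length(self):
        rr = _rr_from_intervals(np.full(41, 1.0))  # spans 40 s of beat times
        grid, series = rr_to_uniform(rr, fs_interp=4.0)
        duration = rr.times[-1] - rr.times[0]
        assert len(grid) == int(np.floor(duration * 4.0)) + 1


def _modulated_series(freq, fs=4.0, dur=90.0, amp=0.05, base=1.0):
    t = np.arange(int(dur * fs)) / fs
    return base + amp * np.sin(2 * np.pi * freq * t)


class TestSpectralPowers:
    def test_pure_lf_tone(self):
        p = spectral_powers(_modulated_series(0.10))
        assert p["lf_power"] / (p["lf_power"] + p["hf_power"]) >= 0.99

    def test_pure_hf_tone(self):
        p = spectral_powers(_modulated_series(0.25))
        assert p["hf_power"] / (p["lf_power"] + p["hf_power"]) >= 0.99

    def test_equal_mix_balances(self):
        t = np.arange(360) / 4.0
        series = 1.0 + 0.03 * np.sin(2 * np.pi * 0.10 * t) \
            + 0.03 * np.sin(2 * np.pi * 0.25 * t + 0.7)
        p = spectral_powers(series)
        assert p["lf_power"] / p["hf_power"] == pytest.approx(1.0, abs=0.05)

    def test_standardisation_makes_powers_affine_invariant(self):
        s = _modulated_series(0.2)
        p1 = spectral_powers(s)
        p2 = spectral_powers(3.0 * s + 17.0)
        assert p1["lf_power"] == pytest.approx(p2["lf_power"], rel=1e-9)
        assert p1["hf_power"] == pytest.approx(p2["hf_power"], rel=1e-9)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(InvalidInputError):
            spectral_powers(np.ones(100), window=90.0)


class TestNormalisedUnits:
    def test_equal_powers(self):
        n = normalised_units(2.0, 2.0)
        assert n["lf_norm"] == 50.0 and n["hf_norm"] == 50.0
        assert n["lf_hf_ratio"] == 1.0

    def test_three_to_one(self):
        n = normalised_units(3.0, 1.0)
        assert n["lf_norm"] == 75.0 and n["hf_norm"] == 25.0
        assert n["lf_hf_ratio"] == 3.0

    @given(lf=st.floats(1e-6, 1e6), hf=st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_norms_always_sum_to_100(self, lf, hf):
        n = normalised_units(lf, hf)
        assert n["lf_norm"] + n["hf_norm"] == pytest.approx(100.0, abs=1e-9)

    def test_zero_powers_undefined(self):
        with pytest.warns(UserWarning):
            n = normalised_units(0.0, 0.0)
        assert np.isnan(n["hf_norm"])


class TestWindowedHrv:
    def _cpt_like_rr(self, hf_amp_mid=0.08, hf_amp_out=0.03):
        rng = np.random.default_rng(1)
        t, beats = 0.0, [0.0]
        while t < 290.0:
            amp = hf_amp_mid if 95.0 <= t < 190.0 else hf_amp_out
            t += 1.0 + amp * np.sin(2 * np.pi * 0.25 * t) \
                + 0.03 * np.sin(2 * np.pi * 0.1 * t)
            beats.append(t)
        return beats_to_rr(BeatList(np.array(beats)))

    WINDOWS = {"Baseline": (0.0, 90.0), "Response": (95.0, 90.0),
               "Recovery": (190.0, 90.0)}

    def test_three_windows_reported(self):
        out = windowed_hrv(self._cpt_like_rr(), self.WINDOWS)
        assert set(out) == set(self.WINDOWS)

    def test_constant_intervals_give_exact_heart_rate(self):
        rr = _rr_from_intervals(np.full(300, 1.0))
        out = windowed_hrv(rr, {"w": (0.0, 90.0)})
        assert out["w"].heart_rate == 60.0

    def test_raised_hf_modulation_in_middle_window(self):
        out = windowed_hrv(self._cpt_like_rr(), self.WINDOWS)
        assert out["Response"].hf_norm > out["Baseline"].hf_norm
        assert out["Response"].hf_norm > out["Recovery"].hf_norm


class TestAgreement:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement(a, a)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.mean_difference == 0.0
        assert (s.loa_low, s.loa_high) == (0.0, 0.0)
        assert s.relative_error_pct == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement(a, a + 2.0)
        assert s.mean_difference == pytest.approx(-2.0)
        assert s.loa_low == pytest.approx(-2.0)
        assert s.loa_high == pytest.approx(-2.0)
        assert s.pearson_r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 2.0, 4.0, 4.0])
        s = agreement(a, b)
        # definition-level recomputation
        d = a - b
        r_num = np.sum((a - a.mean()) * (b - b.mean()))
        r_den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert s.pearson_r == pytest.approx(r_num / r_den)
        assert s.mean_difference == pytest.approx(d.mean())
        assert s.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert s.relative_error_pct == pytest.approx(
            np.mean(np.abs(d) / b) * 100)

    def test_zero_variance_r_is_nan(self):
        with pytest.warns(UserWarning):
            s = agreement(np.ones(5), np.arange(5.0) + 1)
        assert np.isnan(s.pearson_r)
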