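"""Biomarker extraction: perturbation measures, HNR, MFCC, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxfuse.audio import Waveform
from voxfuse.biomarkers import (
    DEFAULT_SCHEMA,
    UCI_SCHEMA,
    AmplitudeSequence,
    BiomarkerVector,
    FilterbankEnergies,
    PeriodSequence,
    apply_standardization,
    assemble_biomarker_vector,
    extract_amplitude_sequence,
    extract_period_sequence,
    f0_statistics,
    fit_standardization,
    harmonics_to_noise_ratio,
    hnr_from_r,
    jitter_features,
    mel_cepstral_coefficients,
    mel_filterbank_energies,
    read_feature_table,
    shimmer_features,
    write_feature_table,
)
from voxfuse.errors import NoVoicingError, ValidationError
from voxfuse.synth import PhonationSpec, generate_phonation


def oracle_jitter_pct(T):
    T = np.asarray(T, dtype=float)
    return float(np.mean(np.abs(np.diff(T)) / T[:-1]) * 100.0)


def oracle_shimmer(A):
    A = np.asarray(A, dtype=float)
    return float(np.mean(np.abs(np.diff(A)) / A[:-1]))


class TestPeriodExtraction:
    def test_pulse_train_periods_within_one_percent(self):
        rate, f0 = 16000, 100.0
        w, _ = generate_phonation(PhonationSpec(f0=f0, rate=rate, seed=0))
        p = extract_period_sequence(w)
        np.testing.assert_allclose(p.periods, 0.01, rtol=0.01)

    def test_white_noise_raises_no_voicing(self):
        rng = np.random.default_rng(0)
        w = Waveform(rng.normal(0, 0.1, 16000), 16000)
        with pytest.raises(NoVoicingError):
            extract_period_sequence(w)

    def test_jittered_periods_track_ground_truth(self):
        w, gt = generate_phonation(PhonationSpec(jitter_rel=0.02, seed=5))
        p = extract_period_sequence(w)
        n = min(len(p.periods), len(gt.periods))
        # align by best offset lag (extraction may drop edge cycles)
        best_r = max(
            np.corrcoef(p.periods[:n - k], gt.periods[k : n])[0, 1]
            for k in range(3)
        )
        assert best_r >= 0.9


class TestF0Statistics:
    def test_constant_periods(self):
        p = PeriodSequence(periods=np.full(10, 0.01), cycle_marks=np.arange(11) * 0.01)
        assert f0_statistics(p) == (100.0, 100.0, 100.0)

    def test_two_period_hand_values(self):
        p = PeriodSequence(periods=np.array([0.008, 0.010]),
                           cycle_marks=np.array([0.0, 0.008, 0.018]))
        fo, fhi, flo = f0_statistics(p)
        assert fhi == pytest.approx(125.0)
        assert flo == pytest.approx(100.0)
        assert fo == pytest.approx(112.5)

    def test_nominal_f0_recovered_from_clean_phonation(self):
        w, _ = generate_phonation(PhonationSpec(f0=150.0, seed=1))
        fo, _, _ = f0_statistics(extract_period_sequence(w))
        assert abs(fo - 150.0) / 150.0 < 0.01


class TestJitter:
    def test_constant_periods_all_zero(self):
        p = PeriodSequence(periods=np.full(10, 0.01), cycle_marks=np.arange(11) * 0.01)
        assert jitter_features(p) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_evaluated_local_jitter(self):
        T = np.array([10.0, 10.2, 10.0, 10.2, 10.0]) * 1e-3
        p = PeriodSequence(periods=T, cycle_marks=np.concatenate([[0], np.cumsum(T)]))
        expected = np.mean([0.2 / 10, 0.2 / 10.2, 0.2 / 10, 0.2 / 10.2]) * 100
        assert jitter_features(p)[0] == pytest.approx(expected, rel=1e-12)

    def test_too_few_periods_error_names_minimum(self):
        p = PeriodSequence(periods=np.array([0.01, 0.011, 0.01]),
                           cycle_marks=np.array([0.0, 0.01, 0.021, 0.031]))
        with pytest.raises(ValidationError, match="5"):
            jitter_features(p)

    @pytest.mark.parametrize("jitter_rel", [0.005, 0.01, 0.02, 0.04])
    def test_recovery_against_realized_sequence(self, jitter_rel):
        w, gt = generate_phonation(PhonationSpec(jitter_rel=jitter_rel, seed=7))
        est = jitter_features(extract_period_sequence(w))[0]
        orc = oracle_jitter_pct(gt.periods)
        assert abs(est - orc) / orc < 0.15


class TestShimmer:
    def test_constant_amplitudes_all_zero(self):
        a = AmplitudeSequence(amplitudes=np.full(10, 0.4))
        assert shimmer_features(a) == (0.0, 0.0, 0.0)

    def test_hand_evaluated_local_shimmer(self):
        a = AmplitudeSequence(amplitudes=np.array([1.0, 1.1, 1.0]))
        expected = (0.1 / 1.0 + 0.1 / 1.1) / 2
        assert shimmer_features(a)[0] == pytest.approx(expected, rel=1e-12)

    def test_non_positive_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            AmplitudeSequence(amplitudes=np.array([1.0, 0.0, 1.0]))

    @pytest.mark.parametrize("shimmer_rel", [0.01, 0.03, 0.06])
    def test_recovery_against_realized_sequence(self, shimmer_rel):
        w, gt = generate_phonation(PhonationSpec(shimmer_rel=shimmer_rel, seed=9))
        p = extract_period_sequence(w)
        est = shimmer_features(extract_amplitude_sequence(w, p))[0]
        orc = oracle_shimmer(gt.amplitudes)
        assert abs(est - orc) / orc < 0.15


class TestHNR:
    def test_closed_form_half_is_zero_db(self):
        assert hnr_from_r(0.5) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_point_nine(self):
        assert hnr_from_r(0.9) == pytest.approx(10 * np.log10(9), abs=1e-9)

    def test_ten_db_phonation_recovered(self):
        w, _ = generate_phonation(PhonationSpec(hnr_db=10.0, seed=3))
        p = extract_period_sequence(w)
        assert abs(harmonics_to_noise_ratio(w, p) - 10.0) <= 1.5

    def test_strictly_decreasing_in_noise_power(self):
        estimates = []
        for h in [25.0, 20.0, 15.0, 10.0, 5.0]:
            w, _ = generate_phonation(PhonationSpec(hnr_db=h, seed=4))
            p = extract_period_sequence(w)
            estimates.append(harmonics_to_noise_ratio(w, p))
        assert all(a > b for a, b in zip(estimates, estimates[1:]))


class TestMFCC:
    def test_flat_filterbank_gives_zero_coefficients(self):
        fb = FilterbankEnergies(energies=np.full((3, 8), 2.5), M=8)
        np.testing.assert_allclose(mel_cepstral_coefficients(fb, K=5), 0.0, atol=1e-9)

    def test_matches_naive_double_loop(self):
        S = np.array([[1.0, np.e, np.e**2, np.e**3]])
        fb = FilterbankEnergies(energies=S, M=4)
        out = mel_cepstral_coefficients(fb, K=3)
        M = 4
        for k in range(1, 4):
            expected = sum(
                np.log(S[0, n - 1]) * np.cos(np.pi * k / M * (n - 0.5))
                for n in range(1, M + 1)
            )
            assert out[k - 1] == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_on_random_filterbanks(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(5, 20))
        n_frames = int(rng.integers(1, 4))
        S = rng.uniform(0.1, 10.0, (n_frames, M))
        K = int(rng.integers(1, M))
        out = mel_cepstral_coefficients(FilterbankEnergies(S, M), K)
        naive = np.zeros(K)
        for k in range(1, K + 1):
            acc = 0.0
            for f in range(n_frames):
                for n in range(1, M + 1):
                    acc += np.log(S[f, n - 1]) * np.cos(np.pi * k / M * (n - 0.5))
            naive[k - 1] = acc / n_frames
        np.testing.assert_allclose(out, naive, atol=1e-9)

    def test_thirteen_coefficients_by_default(self):
        w, _ = generate_phonation(PhonationSpec(seed=2))
        fb = mel_filterbank_energies(w)
        assert mel_cepstral_coefficients(fb, K=13).shape == (13,)

    def test_k_not_below_filter_count_rejected(self):
        fb = FilterbankEnergies(energies=np.ones((2, 6)), M=6)
        with pytest.raises(ValidationError):
            mel_cepstral_coefficients(fb, K=6)


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [0.1, 3.0])
    def test_jitter_and_shimmer_unchanged_by_amplitude_scaling(self, scale):
        w, _ = generate_phonation(
            PhonationSpec(jitter_rel=0.01, shimmer_rel=0.03, seed=6)
        )
        scaled = Waveform(w.samples * scale, w.rate)
        p1, p2 = extract_period_sequence(w), extract_period_sequence(scaled)
        j1, j2 = jitter_features(p1)[0], jitter_features(p2)[0]
        s1 = shimmer_features(extract_amplitude_sequence(w, p1))[0]
        s2 = shimmer_features(extract_amplitude_sequence(scaled, p2))[0]
        assert j1 == pytest.approx(j2, abs=1e-6)
        assert s1 == pytest.approx(s2, abs=1e-6)


class TestAssembly:
    def test_default_schema_yields_22_finite_features(self):
        w, _ = generate_phonation(PhonationSpec(jitter_rel=0.01, hnr_db=20, seed=8))
        vec = assemble_biomarker_vector(w)
        assert len(vec) == 22
        assert np.all(np.isfinite(vec.values))

    def test_deterministic_on_identical_waveforms(self):
        w, _ = generate_phonation(PhonationSpec(jitter_rel=0.01, seed=8))
        v1 = assemble_biomarker_vector(w)
        v2 = assemble_biomarker_vector(Waveform(w.samples.copy(), w.rate))
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_pd_profile_shifts_jitter_up_and_hnr_down(self):
        # class profiles: elevated perturbation and depressed HNR for PD
        names = list(DEFAULT_SCHEMA.features)
        ji, hi = names.index("MDVP:Jitter(%)"), names.index("HNR")
        pd_vals, hc_vals = [], []
        for seed in range(8):
            w_pd, _ = generate_phonation(PhonationSpec(
                jitter_rel=0.02, shimmer_rel=0.06, hnr_db=12.0, seed=seed))
            w_hc, _ = generate_phonation(PhonationSpec(
                jitter_rel=0.005, shimmer_rel=0.02, hnr_db=22.0, seed=100 + seed))
            pd_vals.append(assemble_biomarker_vector(w_pd).values)
            hc_vals.append(assemble_biomarker_vector(w_hc).values)
        pd_mean, hc_mean = np.mean(pd_vals, axis=0), np.mean(hc_vals, axis=0)
        assert pd_mean[ji] > hc_mean[ji]
        assert pd_mean[hi] < hc_mean[hi]


class TestStandardization:
    def test_hand_evaluated_column(self):
        stats = fit_standardization(np.array([[1.0], [2.0], [3.0]]))
        z = apply_standardization(np.array([[1.0], [2.0], [3.0]]), stats)
        np.testing.assert_allclose(z.ravel(), [-1.22474487, 0.0, 1.22474487],
                                   atol=1e-6)

    def test_standardized_matrix_has_unit_moments(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 5, (50, 4))
        stats = fit_standardization(X)
        Z = apply_standardization(X, stats)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        stats = fit_standardization(X)
        Z = apply_standardization(X, stats)
        np.testing.assert_array_equal(Z[:, 1], 0.0)

    def test_apply_before_fit_errors(self):
        from voxfuse.biomarkers import StandardizationStats

        stats = StandardizationStats(mean=np.zeros(2), std=np.ones(2), fitted=False)
        with pytest.raises(ValidationError):
            apply_standardization(np.zeros((1, 2)), stats)


class TestFeatureTableIO:
    def test_roundtrip_bit_exact(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(size=(6, len(UCI_SCHEMA))), columns=list(UCI_SCHEMA.features)
        )
        df.insert(0, "name", [f"rec{i}" for i in range(6)])
        df["status"] = [0, 1, 0, 1, 1, 0]
        path = tmp_path / "uci.csv"
        write_feature_table(df, path)
        back = read_feature_table(path, UCI_SCHEMA)
        np.testing.assert_array_equal(
            back[list(UCI_SCHEMA.features)].to_numpy(),
            df[list(UCI_SCHEMA.features)].to_numpy(),
        )

    def test_rows_with_missing_cells_dropped(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,f1,f2,status\na,1.0,2.0,0\nb,,3.0,1\nc,x,4.0,1\nd,5,6,1\n")
        df = read_feature_table(path)
        assert list(df["name"]) == ["a", "d"]
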