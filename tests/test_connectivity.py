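"""wPLI/dPLI estimation, surrogate correction and network summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import hilbert

import eegmarkers as em
from eegmarkers import connectivity as conn

from conftest import make_recording
from reference import wpli_dpli_brute


def _epochs_from_data(data, fs=250.0, window_s=10.0):
    return em.epoch(make_recording(np.asarray(data, float), fs=fs), window_s)


class TestPhaseLagIndices:
    def test_quarter_cycle_lag_gives_unit_wpli_and_dpli(self):
        t = np.arange(2500) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        y = np.sin(2 * np.pi * 10 * t - np.pi / 2)  # x leads y by 90 deg
        ep = em.bandpass_alpha(_epochs_from_data(np.vstack([x, y])))
        m = em.phase_lag_indices(ep)
        assert m.wpli[0, 0, 1] == pytest.approx(1.0, abs=1e-6)
        assert m.dpli[0, 0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_lag_scaled_copy_has_zero_wpli(self):
        t = np.arange(2500) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        ep = _epochs_from_data(np.vstack([x, 2 * x]))
        m = em.phase_lag_indices(ep)
        assert m.wpli[0, 0, 1] == 0.0
        assert m.dpli[0, 0, 1] == 0.5

    def test_independent_noise_dpli_near_half(self, rng):
        data = rng.standard_normal((2, 250 * 300))
        ep = em.bandpass_alpha(_epochs_from_data(data))
        m = em.phase_lag_indices(ep)
        assert abs(m.dpli_avg[0, 1] - 0.5) < 0.05

    def test_all_zero_channel_yields_neutral_values(self, rng):
        data = np.vstack([rng.standard_normal(250 * 30), np.zeros(250 * 30)])
        m = em.phase_lag_indices(_epochs_from_data(data))
        assert np.all(m.wpli[:, 0, 1] == 0.0)
        assert np.all(m.dpli[:, 0, 1] == 0.5)

    def test_matches_brute_force_formulas_small_windows(self, rng):
        """Vectorized path equals direct summation of the printed formulas."""
        for trial in range(5):
            data = rng.standard_normal((3, 64 * 4))
            ep = em.epoch(make_recording(data, fs=32.0), 2.0)  # 64-sample wins
            m = em.phase_lag_indices(ep)
            A = np.stack([hilbert(w, axis=-1) for w in ep.windows])
            for t in range(ep.n_windows):
                for i in range(3):
                    for j in range(i + 1, 3):
                        w_ref, d_ref = wpli_dpli_brute(A[t, i], A[t, j])
                        assert m.wpli[t, i, j] == pytest.approx(w_ref, abs=1e-12)
                        assert m.dpli[t, i, j] == pytest.approx(d_ref, abs=1e-12)

    def test_common_phase_rotation_invariance(self, rng):
        data = rng.standard_normal((2, 250 * 30))
        ep = em.bandpass_alpha(_epochs_from_data(data))
        m1 = em.phase_lag_indices(ep)
        # rotate both analytic signals by a common phase: dPLI must not move
        rot = np.exp(1j * 1.1)
        rotated = ep.map_windows(
            lambda w: (hilbert(w, axis=-1) * rot).real
        )
        m2 = em.phase_lag_indices(rotated)
        np.testing.assert_allclose(m2.dpli[:, 0, 1], m1.dpli[:, 0, 1],
                                   atol=5e-3)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry_and_bounds_fuzzed(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((3, 250 * 10)) * rng.uniform(0.1, 10)
        m = em.phase_lag_indices(_epochs_from_data(data))
        assert np.all(m.wpli >= 0.0) and np.all(m.wpli <= 1.0)
        np.testing.assert_array_equal(m.wpli, m.wpli.transpose(0, 2, 1))
        np.testing.assert_allclose(
            m.dpli + m.dpli.transpose(0, 2, 1), 1.0, atol=0
        )
        assert np.all(np.diagonal(m.wpli, axis1=1, axis2=2) == 0.0)
        assert np.all(np.diagonal(m.dpli, axis1=1, axis2=2) == 0.5)


class TestSurrogateCorrect:
    def test_too_few_surrogates_for_alpha_rejected(self):
        with pytest.raises(ValueError, match="cannot resolve"):
            em.SurrogateConfig(n_surrogates=10, alpha=0.05)

    def test_common_source_zeroed_exactly(self):
        rec = em.gen_common_source(4, 250.0, 120.0, seed=1,
                                   gains=np.array([1.0, 0.5, 2.0, 1.3]))
        ep = em.bandpass_alpha(em.epoch(rec, 10.0))
        raw = em.phase_lag_indices(ep)
        corr = em.surrogate_correct(ep, raw, em.SurrogateConfig(seed=2))
        off = ~np.eye(4, dtype=bool)
        assert np.all(corr.wpli_avg[off] == 0.0)
        assert np.all(corr.dpli_avg[off] == 0.5)

    def test_strong_lag_pair_survives_correction(self, lagged_pair_epochs):
        raw = em.phase_lag_indices(lagged_pair_epochs)
        corr = em.surrogate_correct(lagged_pair_epochs, raw,
                                    em.SurrogateConfig(seed=3))
        assert corr.wpli_avg[0, 1] > 0.8
        assert corr.dpli_avg[0, 1] > 0.9

    def test_corrected_preserves_antisymmetry(self, rng):
        data = rng.standard_normal((3, 250 * 30))
        ep = em.bandpass_alpha(_epochs_from_data(data))
        raw = em.phase_lag_indices(ep)
        corr = em.surrogate_correct(ep, raw, em.SurrogateConfig(seed=4))
        np.testing.assert_allclose(
            corr.dpli + corr.dpli.transpose(0, 2, 1), 1.0, atol=0
        )

    def test_reproducible_for_fixed_seed(self, rng):
        data = rng.standard_normal((3, 250 * 30))
        ep = em.bandpass_alpha(_epochs_from_data(data))
        raw = em.phase_lag_indices(ep)
        c1 = em.surrogate_correct(ep, raw, em.SurrogateConfig(seed=5))
        c2 = em.surrogate_correct(ep, raw, em.SurrogateConfig(seed=5))
        np.testing.assert_array_equal(c1.wpli, c2.wpli)
        np.testing.assert_array_equal(c1.dpli, c2.dpli)

    def test_type_one_error_rate_calibrated(self, rng):
        """Independent channels: retention rate ≤ alpha + 3 binomial s.e."""
        n_ch = 21  # 210 pairs
        data = rng.standard_normal((n_ch, 250 * 30))
        ep = em.bandpass_alpha(_epochs_from_data(data))
        raw = em.phase_lag_indices(ep)
        corr = em.surrogate_correct(ep, raw, em.SurrogateConfig(seed=6))
        iu = np.triu_indices(n_ch, 1)
        n_tests = corr.n_windows * len(iu[0])
        alpha = 0.05
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_tests)
        for name, kept in (
            ("wpli", np.count_nonzero(corr.wpli[:, iu[0], iu[1]] != 0.0)),
            ("dpli", np.count_nonzero(corr.dpli[:, iu[0], iu[1]] != 0.5)),
        ):
            assert kept / n_tests <= bound, name


class TestNetworkSummaries:
    def test_degree_of_zero_matrix_is_zero(self):
        m = conn.ConnMatrices(("a", "b", "c"), np.zeros((1, 3, 3)),
                              np.full((1, 3, 3), 0.5), corrected=True)
        assert np.all(em.node_degree(m) == 0.0)

    def test_single_pair_degree(self):
        w = np.zeros((1, 3, 3))
        w[0, 0, 1] = w[0, 1, 0] = 0.6
        m = conn.ConnMatrices(("a", "b", "c"), w, np.full((1, 3, 3), 0.5),
                              corrected=True)
        np.testing.assert_allclose(em.node_degree(m), [0.6, 0.6, 0.0])

    def test_fp_summary_neutral_when_no_relationship(self, montage10):
        labels = montage10.labels
        C = len(labels)
        m = conn.ConnMatrices(labels, np.zeros((1, C, C)),
                              np.full((1, C, C), 0.5), corrected=True)
        fp = em.frontoparietal_summary(m, montage10)
        assert fp["L"]["mean"] == 0.5
        assert fp["R"]["mean"] == 0.5

    def test_fp_summary_feedback_dominant(self, montage10):
        labels = montage10.labels
        C = len(labels)
        d = np.full((1, C, C), 0.5)
        for hemi in ("L", "R"):
            f = labels.index(f"F{hemi}1")
            p = labels.index(f"P{hemi}1")
            d[0, f, p] = 0.9
            d[0, p, f] = 0.1
        m = conn.ConnMatrices(labels, np.zeros((1, C, C)), d, corrected=True)
        fp = em.frontoparietal_summary(m, montage10)
        assert fp["L"]["mean"] > 0.5 and fp["R"]["mean"] > 0.5

    def test_fp_summary_missing_hemisphere_reported_not_raised(self, montage10):
        labels = tuple(l for l in montage10.labels if l != "PR1")
        sub = em.Montage({l: montage10.channels[l] for l in labels})
        C = len(labels)
        m = conn.ConnMatrices(labels, np.zeros((1, C, C)),
                              np.full((1, C, C), 0.5), corrected=True)
        fp = em.frontoparietal_summary(m, sub)
        assert fp["R"]["mean"] is None
        assert fp["L"]["mean"] == 0.5

    def test_hub_index_single_mass_point(self, montage10):
        labels = montage10.labels
        deg = np.zeros(len(labels))
        deg[labels.index("FL1")] = 2.0
        score, hub = em.hub_index(deg, montage10, labels)
        assert score == pytest.approx(montage10.y_of("FL1"))
        assert hub == "FL1"

    def test_hub_index_symmetric_montage_uniform_degree(self, montage10):
        labels = montage10.labels
        score, _ = em.hub_index(np.ones(len(labels)), montage10, labels)
        assert score == pytest.approx(
            np.mean([montage10.y_of(l) for l in labels]))

    def test_hub_index_all_zero_degree_is_null(self, montage10):
        labels = montage10.labels
        score, hub = em.hub_index(np.zeros(len(labels)), montage10, labels)
        assert score is None and hub is None

    def test_hub_directionality_star_source(self):
        labels = ("hub", "a", "b", "c")
        d = np.full((1, 4, 4), 0.5)
        for j in range(1, 4):
            d[0, 0, j] = 1.0
            d[0, j, 0] = 0.0
        m = conn.ConnMatrices(labels, np.zeros((1, 4, 4)), d, corrected=True)
        hd = em.hub_directionality(m)
        assert hd[0] == pytest.approx(1.0)
        assert np.all(hd[1:] < 0.5)

    def test_hub_directionality_transitive_chain(self):
        """F leads C leads P: recovered ordering F > 0.5 > P."""
        idx = {"F": 0, "C": 1, "P": 2}
        graph = em.LagGraph(3, {(idx["F"], idx["C"]): (np.pi / 3, 1.0),
                                (idx["C"], idx["P"]): (np.pi / 3, 1.0)})
        rec = em.gen_lagged_oscillators(graph, 250.0, 30.0, 30.0, seed=11)
        ep = em.bandpass_alpha(em.epoch(rec, 10.0))
        m = em.phase_lag_indices(ep)
        hd = em.hub_directionality(m)
        assert hd[idx["F"]] > 0.5 > hd[idx["P"]]
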