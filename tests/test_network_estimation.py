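"""GGM decomposition, constrained fitting, pruning, and model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import beliefnet as bn
from beliefnet.network_estimation import (
    ConstraintSpec,
    FitError,
    fit_spec,
    interdependence,
    model_implied_sigma,
    omega_delta_from_precision,
    prune_stepup,
    sample_moments,
    select_spec,
)
from beliefnet.preprocess import WaveMatrix, wave_matrices


def _moments_from_arrays(arrays_by_wave):
    mats = [
        WaveMatrix(w, pd.DataFrame(np.asarray(a, dtype=float),
                                   columns=[f"b{j}" for j in range(np.asarray(a).shape[1])]))
        for w, a in arrays_by_wave.items()
    ]
    return sample_moments(mats)


class TestSampleMoments:
    def test_constant_column_zero_variance(self):
        m = _moments_from_arrays({"W1": np.column_stack([np.ones(9), np.arange(9.0)])})
        assert m.covs[0][0, 0] == 0.0
        assert m.means[0][0] == 1.0

    def test_identical_waves_identical_moments(self, rng):
        x = rng.standard_normal((30, 3))
        m = _moments_from_arrays({"W1": x, "W2a": x})
        np.testing.assert_allclose(m.covs[0], m.covs[1])
        np.testing.assert_allclose(m.means[0], m.means[1])

    def test_matches_hand_computed_covariance(self):
        # 5-row, 3-column fixture; textbook (n-1) covariance
        x = np.array(
            [[1.0, 2.0, 0.0],
             [2.0, 1.0, 1.0],
             [3.0, 4.0, 0.0],
             [4.0, 3.0, 1.0],
             [5.0, 5.0, 3.0]]
        )
        m = _moments_from_arrays({"W1": x})
        xc = x - x.mean(axis=0)
        np.testing.assert_allclose(m.covs[0], xc.T @ xc / 4, atol=1e-12)


class TestOmegaDeltaDecomposition:
    def test_identity_precision_gives_empty_network(self):
        omega, delta = omega_delta_from_precision(np.eye(4))
        np.testing.assert_allclose(omega, 0.0)
        np.testing.assert_allclose(delta, 1.0)

    def test_negative_precision_entry_flips_sign(self):
        prec = np.array([[1.0, -0.4], [-0.4, 1.0]])
        omega, _ = omega_delta_from_precision(prec)
        assert omega[0, 1] > 0

    @given(
        arrays(np.float64, (4, 4), elements=st.floats(-1, 1)),
    )
    @settings(deadline=None, max_examples=50)
    def test_roundtrip_inverts_precision(self, a):
        prec = a @ a.T + 4.0 * np.eye(4)
        omega, delta = omega_delta_from_precision(prec)
        np.testing.assert_allclose(
            model_implied_sigma(omega, delta), np.linalg.inv(prec), atol=1e-10
        )

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            omega_delta_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestFitSpec:
    def test_saturated_fit_equals_closed_form(self, rng):
        x = rng.multivariate_normal(
            [0, 0.2, -0.1], [[1, 0.3, 0], [0.3, 1, 0.2], [0, 0.2, 1]], size=400
        )
        m = _moments_from_arrays({"W1": x})
        model = fit_spec(m, ConstraintSpec())
        om_cf, de_cf = omega_delta_from_precision(np.linalg.inv(m.covs[0]))
        assert np.abs(model.omega_by_wave[0] - om_cf).max() < 1e-6
        assert np.abs(model.delta_by_wave[0] - de_cf).max() < 1e-6
        np.testing.assert_allclose(model.mu_by_wave[0], m.means[0], atol=1e-10)

    def test_identity_covariance_gives_iid_normal_loglik(self):
        n, k = 200, 3
        rng = np.random.default_rng(0)
        x = rng.standard_normal((n, k))
        # force exact identity moments: whiten the sample
        xc = x - x.mean(axis=0)
        chol = np.linalg.cholesky(np.cov(xc, rowvar=False, ddof=1))
        x = xc @ np.linalg.inv(chol).T
        m = _moments_from_arrays({"W1": x})
        model = fit_spec(m, ConstraintSpec())
        assert np.abs(model.omega_by_wave[0]).max() < 1e-6
        np.testing.assert_allclose(model.delta_by_wave[0], 1.0, atol=1e-6)
        expected = -0.5 * n * k * (np.log(2 * np.pi) + 1.0)
        assert abs(model.loglik - expected) < 1e-6 * abs(expected)

    def test_equal_omega_constraint_recovers_truth(self):
        gt = bn.make_ground_truth(K=6, sparsity=0.3, waves=4, seed=21)
        panel = bn.simulate_panel_ggm(gt, 3000, seed=22, dialect="continuous")
        m = sample_moments(bn.residualize(panel))
        model = fit_spec(m, ConstraintSpec(omega_equal=True))
        assert np.abs(model.omega_by_wave[0] - gt.omega).max() < 0.05
        # all waves share the constrained tie matrix
        np.testing.assert_allclose(model.omega_by_wave[0], model.omega_by_wave[3])

    def test_constraint_never_increases_loglik(self, small_truth):
        panel = bn.simulate_panel_ggm(small_truth, 400, seed=30, dialect="continuous")
        m = sample_moments(wave_matrices(panel))
        free = fit_spec(m, ConstraintSpec())
        for spec in [
            ConstraintSpec(omega_equal=True),
            ConstraintSpec(mu_equal=True),
            ConstraintSpec(delta_equal=True),
            ConstraintSpec(True, True, True),
        ]:
            constrained = fit_spec(m, spec)
            assert constrained.loglik <= free.loglik + 1e-6
            assert constrained.n_params < free.n_params

    def test_zero_mask_fixes_ties_at_zero(self, small_truth):
        panel = bn.simulate_panel_ggm(small_truth, 300, seed=31, dialect="continuous")
        m = sample_moments(wave_matrices(panel))
        model = fit_spec(m, ConstraintSpec(omega_equal=True), zero_mask={(0, 1), (2, 3)})
        assert model.omega_by_wave[0][0, 1] == 0.0
        assert model.omega_by_wave[0][2, 3] == 0.0

    def test_model_json_roundtrip(self, tmp_path, small_truth):
        panel = bn.simulate_panel_ggm(small_truth, 300, seed=32, dialect="continuous")
        m = sample_moments(wave_matrices(panel))
        model = fit_spec(m, ConstraintSpec(omega_equal=True))
        model.to_json(tmp_path / "m.json")
        import json

        payload = json.loads((tmp_path / "m.json").read_text())
        np.testing.assert_allclose(payload["omega_by_wave"][0], model.omega_by_wave[0])
        assert payload["beta_by_wave"] == pytest.approx(model.beta_by_wave)


class TestPruneStepup:
    def test_empty_network_fully_pruned(self):
        rng = np.random.default_rng(40)
        x = {w: rng.standard_normal((2000, 4)) for w in ["W1", "W2a"]}
        m = _moments_from_arrays(x)
        spec = ConstraintSpec(omega_equal=True)
        sparse = prune_stepup(m, spec, fit_spec(m, spec))
        assert np.abs(sparse.omega_by_wave[0]).max() == 0.0

    def test_single_true_tie_retained(self):
        K = 5
        omega = np.zeros((K, K))
        omega[0, 1] = omega[1, 0] = 0.3
        gt = bn.GroundTruth(
            omega=omega, delta_by_wave=[np.full(K, 0.4)], mu_by_wave=[np.zeros(K)],
            person_sd=0.0, cluster_labels=["moral"] * 2 + ["social"] * 3, seed=0,
        )
        panel = bn.simulate_panel_ggm(gt, 5000, seed=41, dialect="continuous")
        m = sample_moments(wave_matrices(panel))
        sparse = prune_stepup(m, ConstraintSpec(), fit_spec(m, ConstraintSpec()))
        nz = np.argwhere(np.triu(sparse.omega_by_wave[0], 1) != 0)
        assert nz.tolist() == [[0, 1]]

    def test_already_empty_mask_is_fixed_point(self):
        rng = np.random.default_rng(42)
        x = {"W1": rng.standard_normal((500, 3))}
        m = _moments_from_arrays(x)
        all_pairs = {(0, 1), (0, 2), (1, 2)}
        model = fit_spec(m, ConstraintSpec(), zero_mask=all_pairs)
        out = prune_stepup(m, ConstraintSpec(), model)
        assert out.zero_mask == frozenset(all_pairs)
        assert out.bic == pytest.approx(model.bic)


class TestSelectSpec:
    def test_single_wave_rejected(self, rng):
        m = _moments_from_arrays({"W1": rng.standard_normal((50, 3))})
        with pytest.raises(ValueError, match="two waves"):
            select_spec(m)

    def test_true_specification_wins(self):
        """Sparse equal-ties equal-intercepts free-scaling truth wins BIC."""
        gt = bn.make_ground_truth(K=5, sparsity=0.5, waves=3,
                                  interdependence_profile=(1.0, 1.5, 1.2), seed=50)
        panel = bn.simulate_panel_ggm(gt, 1500, seed=51, dialect="continuous")
        m = sample_moments(bn.residualize(panel))
        best, table = select_spec(m)
        assert best.spec.omega_equal and best.spec.mu_equal and best.spec.sparse
        assert not best.spec.delta_equal
        assert len(table) == 16
        assert table["bic"].min() == pytest.approx(best.bic)

    def test_wave_varying_ties_favor_free_omega(self):
        rng = np.random.default_rng(52)
        k, n = 4, 4000
        cov_a = np.eye(k) + 0.45 * (np.ones((k, k)) - np.eye(k))
        cov_b = np.eye(k)
        xa = rng.multivariate_normal(np.zeros(k), cov_a, size=n)
        xb = rng.multivariate_normal(np.zeros(k), cov_b, size=n)
        m = _moments_from_arrays({"W1": xa, "W2a": xb})
        best, _ = select_spec(m)
        assert not best.spec.omega_equal


class TestInterdependence:
    def test_conventions(self):
        model = bn.NetworkModel(
            spec=ConstraintSpec(), waves=["W1"], belief_ids=["a", "b"],
            omega_by_wave=[np.zeros((2, 2))],
            delta_by_wave=[np.array([0.5, 1.0])],
            mu_by_wave=[np.zeros(2)], zero_mask=frozenset(),
            loglik=0.0, n_params=5, bic=0.0,
        )
        assert interdependence(model, 0) == pytest.approx(1 / 0.75)
        assert interdependence(model, 0, "mean_inverse") == pytest.approx(1.5)
        uniform = bn.NetworkModel(
            spec=ConstraintSpec(), waves=["W1"], belief_ids=["a", "b"],
            omega_by_wave=[np.zeros((2, 2))],
            delta_by_wave=[np.array([1.0, 1.0])],
            mu_by_wave=[np.zeros(2)], zero_mask=frozenset(),
            loglik=0.0, n_params=5, bic=0.0,
        )
        assert interdependence(uniform, 0) == pytest.approx(1.0)

    def test_strictly_decreasing_in_delta(self):
        deltas = [np.array([0.5, 0.5]), np.array([0.5, 0.6]), np.array([0.7, 0.6])]
        betas = [1.0 / d.mean() for d in deltas]
        assert betas[0] > betas[1] > betas[2]
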