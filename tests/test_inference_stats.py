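"""Change scores, correlations, meta-analysis, and direction summaries."""

import numpy as np
import pandas as pd
import pytest

import beliefnet as bn
from beliefnet.inference_stats import (
    FISHER_Z_R,
    STD_MEAN_CHANGE,
    EffectRecord,
    change_scores,
    compare_dependent_correlations,
    correlate_by_group,
    direction_summary,
    meta_moderators,
    meta_random_effects,
    multilevel_correlation,
    standardized_mean_change,
)
from beliefnet.panel import BeliefPanel, PanelError, panel_from_arrays


def _panel(values_by_wave, dialect="rescaled", groups=None):
    first = np.asarray(next(iter(values_by_wave.values())))
    n, k = first.shape
    return panel_from_arrays(
        {w: np.asarray(v, dtype=float) for w, v in values_by_wave.items()},
        [f"p{i}" for i in range(n)],
        [f"b{j}" for j in range(k)],
        "t",
        groups or ["all"] * n,
        dialect,
    )


class TestChangeScores:
    def test_identical_waves_zero_change(self):
        x = np.array([[0.1, -0.5], [0.3, 0.2]])
        panel = _panel({"W1": x, "W2a": x})
        out = change_scores(panel, "W1", "W2a")
        assert np.abs(out["signed"]).max() == 0.0

    def test_cancellation_between_levels(self):
        """Opposite belief changes cancel in the average but not per belief."""
        a = np.array([[0.0, 0.0]])
        b = np.array([[0.5, -0.5]])
        panel = _panel({"W2a": a, "W2b": b})
        avg = change_scores(panel, "W2a", "W2b", level="average")
        assert avg["signed"].iloc[0] == pytest.approx(0.0)
        bel = change_scores(panel, "W2a", "W2b", level="belief")
        np.testing.assert_allclose(bel["absolute"].to_numpy(), [0.5, 0.5])

    def test_two_person_fixture_hand_arithmetic(self):
        a = np.array([[0.0, 0.2], [-0.4, 0.4]])
        b = np.array([[0.3, 0.1], [-0.2, 0.8]])
        panel = _panel({"W2a": a, "W2b": b})
        out = change_scores(panel, "W2a", "W2b").set_index("person_id")
        assert out.loc["p0", "signed"] == pytest.approx((0.3 + -0.1) / 2)
        assert out.loc["p1", "signed"] == pytest.approx((0.2 + 0.4) / 2)

    def test_missing_wave_rejected(self):
        panel = _panel({"W1": np.zeros((2, 2)), "W2a": np.zeros((2, 2))})
        with pytest.raises(PanelError):
            change_scores(panel, "W1", "W3")


class TestMultilevelCorrelation:
    def _frames(self, x, y):
        idx = [f"p{i}" for i in range(len(x))]
        cols = [f"b{j}" for j in range(len(x[0]))]
        return (pd.DataFrame(x, index=idx, columns=cols),
                pd.DataFrame(y, index=idx, columns=cols))

    def test_identity_gives_one(self, rng):
        x = rng.standard_normal((5, 4))
        fx, fy = self._frames(x, x)
        assert multilevel_correlation(fx, fy) == pytest.approx(1.0)

    def test_person_constants_removed(self, rng):
        x = rng.standard_normal((5, 4))
        shifts = rng.standard_normal(5)[:, None] * 10
        fx, fy = self._frames(x, x + shifts)
        assert multilevel_correlation(fx, fy) == pytest.approx(1.0)

    def test_matches_explicit_double_centering(self, rng):
        x = rng.standard_normal((5, 4))
        y = 0.5 * x + rng.standard_normal((5, 4))
        fx, fy = self._frames(x, y)
        xc = (x - x.mean(axis=1, keepdims=True)).ravel()
        yc = (y - y.mean(axis=1, keepdims=True)).ravel()
        assert multilevel_correlation(fx, fy) == pytest.approx(
            np.corrcoef(xc, yc)[0, 1]
        )

    def test_zero_variance_person_excluded(self, rng):
        x = rng.standard_normal((4, 3))
        x[0] = 1.0
        fx, fy = self._frames(x, rng.standard_normal((4, 3)))
        with pytest.warns(UserWarning, match="excluding"):
            r = multilevel_correlation(fx, fy)
        assert -1 <= r <= 1


class TestMetaRandomEffects:
    def test_equal_effects_collapse_to_common_value(self):
        effects = [EffectRecord("g", "t", 0.2, 50) for _ in range(4)]
        res = meta_random_effects(effects)
        assert res.pooled == pytest.approx(0.2, abs=1e-12)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0

    def test_single_effect_passthrough(self):
        res = meta_random_effects([EffectRecord("g", "t", 0.31, 40)])
        assert res.pooled == pytest.approx(0.31)
        assert res.Q == 0.0 and res.df == 0

    def test_homogeneous_fixture_frozen_hand_values(self):
        """r=(0.30,0.10,0.25), n=(50,80,40): hand-worked DL algebra."""
        effects = [
            EffectRecord("a", "t", 0.30, 50),
            EffectRecord("b", "t", 0.10, 80),
            EffectRecord("c", "t", 0.25, 40),
        ]
        res = meta_random_effects(effects)
        assert res.Q == pytest.approx(1.4407891474709837, abs=1e-10)
        assert res.tau2 == 0.0
        assert res.pooled_transformed == pytest.approx(0.1970404795808068, abs=1e-10)
        assert res.pooled == pytest.approx(0.19452943981986126, abs=1e-10)
        assert res.se == pytest.approx(0.07881104062391006, abs=1e-10)

    def test_heterogeneous_fixture_frozen_hand_values(self):
        """r=(0.50,0.05,0.30), n=(100,100,60): tau2 > 0 branch."""
        effects = [
            EffectRecord("a", "t", 0.50, 100),
            EffectRecord("b", "t", 0.05, 100),
            EffectRecord("c", "t", 0.30, 60),
        ]
        res = meta_random_effects(effects)
        assert res.Q == pytest.approx(12.093621015006974, abs=1e-10)
        assert res.tau2 == pytest.approx(0.061892286968455335, abs=1e-10)
        assert res.pooled_transformed == pytest.approx(0.3027503237334217, abs=1e-10)
        assert res.pooled == pytest.approx(0.2938275140666836, abs=1e-10)
        assert res.p_Q == pytest.approx(0.0023653943955314147, abs=1e-10)

    def test_matches_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects

        effects = [
            EffectRecord("a", "t", 0.50, 100),
            EffectRecord("b", "t", 0.05, 100),
            EffectRecord("c", "t", 0.30, 60),
            EffectRecord("d", "t", 0.22, 45),
        ]
        y = np.arctanh([e.effect for e in effects])
        v = 1.0 / (np.array([e.n for e in effects]) - 3)
        sm = combine_effects(y, v, method_re="dl")
        res = meta_random_effects(effects)
        assert res.tau2 == pytest.approx(float(sm.tau2), abs=1e-10)
        df = sm.summary_frame()
        assert res.pooled_transformed == pytest.approx(
            float(df.loc["random effect", "eff"]), abs=1e-8
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            EffectRecord("g", "t", 0.2, 3)


class TestMetaModerators:
    def test_constant_moderator_rejected(self):
        effects = [EffectRecord(f"g{i}", "t", 0.2 + 0.01 * i, 50) for i in range(4)]
        mods = pd.DataFrame({"m": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="rank"):
            meta_moderators(effects, mods)

    def test_fixture_frozen_hand_values(self):
        """4 effects, binary moderator: hand-worked meta-regression."""
        effects = [
            EffectRecord("a", "t", 0.45, 80),
            EffectRecord("b", "t", 0.38, 60),
            EffectRecord("c", "t", 0.12, 80),
            EffectRecord("d", "t", 0.05, 60),
        ]
        mods = pd.DataFrame({"m": [1.0, 1.0, 0.0, 0.0]})
        res = meta_moderators(effects, mods)
        assert res.Q == pytest.approx(0.3976246884828097, abs=1e-10)
        assert res.tau2 == 0.0
        assert res.moderators["b"].iloc[0] == pytest.approx(0.09057550564421041, abs=1e-10)
        assert res.moderators["b"].iloc[1] == pytest.approx(0.35812092349711205, abs=1e-10)
        assert res.QM == pytest.approx(8.592789921710434, abs=1e-10)

    def test_two_group_moderator_equals_subgroup_z_test(self):
        """With tau2=0 the binary-moderator z equals the difference of the
        fixed-effect subgroup means over its standard error."""
        effects = [
            EffectRecord("a", "t", 0.30, 120),
            EffectRecord("b", "t", 0.28, 100),
            EffectRecord("c", "t", 0.10, 120),
            EffectRecord("d", "t", 0.12, 100),
        ]
        mods = pd.DataFrame({"m": [1.0, 1.0, 0.0, 0.0]})
        res = meta_moderators(effects, mods)
        y = np.arctanh([e.effect for e in effects])
        v = 1.0 / (np.array([e.n for e in effects]) - 3)
        w = 1.0 / v
        m1 = (w[:2] * y[:2]).sum() / w[:2].sum()
        m0 = (w[2:] * y[2:]).sum() / w[2:].sum()
        se = np.sqrt(1 / w[:2].sum() + 1 / w[2:].sum())
        assert res.tau2 == 0.0
        assert res.moderators["z"].iloc[1] == pytest.approx((m1 - m0) / se, abs=1e-8)

    def test_null_moderator_type_i_rate_near_nominal(self, rng):
        """Homogeneous effects, random binary moderator: QM rejects ~5%."""
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            k = 8
            z = 0.2 + rng.standard_normal(k) * np.sqrt(1 / 97)
            effects = [
                EffectRecord(f"g{i}", "t", float(np.tanh(z[i])), 100)
                for i in range(k)
            ]
            mods = pd.DataFrame({"m": rng.integers(0, 2, k).astype(float)})
            if mods["m"].nunique() < 2:
                continue
            res = meta_moderators(effects, mods)
            rejections += res.p_QM < 0.05
        assert 0.01 < rejections / n_sim < 0.12


class TestStandardizedMeanChange:
    def test_no_change_zero(self, rng):
        x = rng.standard_normal(20)
        d, var = standardized_mean_change(x, x.copy() + rng.standard_normal(20) * 0.1)
        assert np.isfinite(d) and var > 0
        d0, _ = standardized_mean_change(np.arange(10.0), np.arange(10.0) + np.r_[np.zeros(5), 1e-3 * np.ones(5)])
        assert d0 < 0  # post slightly larger => negative d

    def test_identical_pairs_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardized_mean_change(np.arange(10.0), np.arange(10.0))

    def test_constant_positive_difference_degenerate(self):
        with pytest.raises(ValueError):
            standardized_mean_change(np.arange(10.0) + 1.0, np.arange(10.0))

    def test_ten_pair_fixture_hand_arithmetic(self):
        pre = np.array([1.2, 0.8, 1.5, 0.9, 1.1, 1.3, 0.7, 1.0, 1.4, 0.6])
        post = np.array([0.9, 0.7, 1.2, 1.0, 0.8, 1.1, 0.6, 0.9, 1.0, 0.7])
        d, var = standardized_mean_change(pre, post)
        assert d == pytest.approx(0.9341987329938277, abs=1e-12)
        assert var == pytest.approx(0.14363636363636367, abs=1e-12)


class TestDependentCorrelations:
    def test_equal_correlations_zero(self):
        z, p = compare_dependent_correlations(0.25, 0.25, 0.7, 200)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_published_formula_fixture(self):
        z, _ = compare_dependent_correlations(0.27, 0.20, 0.8, 979)
        assert z == pytest.approx(3.5676466890278125, abs=1e-10)

    def test_z_increases_with_n(self):
        zs = [compare_dependent_correlations(0.3, 0.2, 0.7, n)[0]
              for n in (50, 200, 1000)]
        assert zs[0] < zs[1] < zs[2]

    def test_invalid_triple_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.9, -0.9, 0.9, 100)


class TestCorrelateByGroup:
    def _setup(self, rng, noise=0.0):
        gt = bn.make_ground_truth(K=4, waves=4, seed=8)
        panel = bn.simulate_panel_ggm(gt, 80, seed=9, groups=["c", "e"])
        resc = bn.rescale_beliefs(panel)
        sub = resc.for_topic(resc.topics[0])
        scores = bn.dissonance_panel(sub, gt.omega)
        change = change_scores(sub, "W2a", "W2b")
        return resc, scores, change

    def test_perfect_correlation_when_change_equals_dissonance(self, rng):
        resc, scores, change = self._setup(rng)
        h = scores.totals_at("W2a")
        change = change.set_index("person_id").reindex(h.index).reset_index()
        change["absolute"] = h.to_numpy()
        effects = correlate_by_group(scores, change, resc.person_meta(), "W2a")
        assert len(effects) == 2
        assert all(e.effect == pytest.approx(1.0) for e in effects)

    def test_independent_change_gives_null_mean(self):
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            h = pd.Series(rng.standard_normal(200),
                          index=[f"p{i}" for i in range(200)])
            change = pd.DataFrame({
                "person_id": h.index,
                "absolute": rng.standard_normal(200),
            })
            rs.append(np.corrcoef(h, change["absolute"])[0, 1])
        assert abs(np.mean(rs)) < 0.02

    def test_small_group_dropped(self, rng):
        resc, scores, change = self._setup(rng)
        meta = resc.person_meta().copy()
        # shrink group "e" to two persons
        keep = meta[meta["group"] == "e"].index[:2]
        meta = pd.concat([meta[meta["group"] == "c"], meta.loc[keep]])
        change = change[change["person_id"].isin(meta.index)]
        with pytest.warns(UserWarning, match="dropped"):
            effects = correlate_by_group(scores, change, meta, "W2a")
        assert {e.group for e in effects} == {"c"}


class TestDirectionSummary:
    def test_all_positive_changes(self):
        a = np.full((6, 3), 3.0)
        b = np.full((6, 3), 5.0)
        panel = _panel({"W1": a, "W2a": b}, dialect="raw")
        out = direction_summary(panel, "t")
        assert out["prop_positive"] == 1.0

    def test_neutral_stratum_at_raw_mean_four(self):
        a = np.full((2, 3), 4.0)
        b = np.array([[5.0, 4.0, 4.0], [3.0, 4.0, 4.0]])
        panel = _panel({"W1": a, "W2a": b}, dialect="raw")
        out = direction_summary(panel, "t")
        assert out["strata_counts"] == {"neutral": 2}

    def test_strata_counts_hand_fixture(self):
        means = [2.0, 3.0, 3.4, 4.0, 4.4, 4.6, 6.0, 7.0]
        a = np.array([[m, m] for m in means])
        b = a + 1.0
        b[b > 7] = 7
        panel = _panel({"W1": a, "W2a": b}, dialect="raw")
        out = direction_summary(panel, "t")
        assert out["strata_counts"] == {"negative": 3, "neutral": 2, "positive": 3}
        assert out["n_positive"] == 7 and out["n_zero"] == 1


class TestFisherZ:
    def test_roundtrip(self, rng):
        r = rng.uniform(-0.999, 0.999, 50)
        np.testing.assert_allclose(np.tanh(np.arctanh(r)), r, atol=1e-12)
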