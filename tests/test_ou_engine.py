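import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylou import (LineageHistory, ModelSpec, GridConfig, GridPoint,
                    PhyloError, read_tree, paint_from_node_states,
                    phylo_matrices, regime_weights, build_design,
                    residual_covariance, gls_solve, profile_fit,
                    model_metrics, residual_r_squared, convert_half_life,
                    rho_factor, contrast, effect_transform)
from phylou.ou_engine import AliasedDesignError, aicc as aicc_fn
from phylou.phylo_io import SpeciesTable, lineage_epochs
from phylou.synthetic_data import (ResponseConfig, simulate_bm,
                                   simulate_response, simulate_tree,
                                   add_observation_error)

from oracles import contrasts_root_mean, ou_weight_by_quadrature

LN2 = math.log(2.0)


# ----------------------------------------------------------------------
# regime weights
# ----------------------------------------------------------------------

class TestRegimeWeights:
    def test_single_regime_closed_form(self):
        h = LineageHistory("t", [("R", 0.0, 1.0)], 1.0)
        for alpha in (0.3, 1.0, 5.0):
            anc, w = regime_weights(h, alpha)
            assert anc == pytest.approx(math.exp(-alpha))
            assert w["R"] == pytest.approx(1 - math.exp(-alpha))
            assert anc + sum(w.values()) == pytest.approx(1.0)

    def test_two_epoch_values(self):
        h = LineageHistory("t", [("A", 0.0, 0.5), ("B", 0.5, 1.0)], 1.0)
        anc, w = regime_weights(h, LN2)
        assert anc == pytest.approx(0.5)
        assert w["A"] == pytest.approx(2 ** -0.5 - 0.5, abs=1e-12)
        assert w["B"] == pytest.approx(1 - 2 ** -0.5, abs=1e-12)
        assert w["A"] == pytest.approx(0.2071, abs=1e-4)
        assert w["B"] == pytest.approx(0.2929, abs=1e-4)

    def test_against_quadrature(self):
        h = LineageHistory("t", [("A", 0.0, 0.3), ("B", 0.3, 0.85),
                                 ("A", 0.85, 1.0)], 1.0)
        alpha = 1.7
        anc, w = regime_weights(h, alpha)
        oracle = ou_weight_by_quadrature(h.epochs, alpha, 1.0)
        for r in w:
            assert w[r] == pytest.approx(oracle[r], abs=1e-6)

    def test_trend_limit_time_fractions(self):
        h = LineageHistory("t", [("A", 0.0, 0.5), ("B", 0.5, 1.0)], 1.0)
        anc, w = regime_weights(h, 0.0)
        assert anc == 1.0
        assert w == {"A": pytest.approx(0.5), "B": pytest.approx(0.5)}

    @given(st.floats(min_value=0.0, max_value=50.0),
           st.lists(st.floats(min_value=0.01, max_value=1.0),
                    min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_weights_sum_to_one(self, alpha, durations):
        total = sum(durations)
        epochs, t = [], 0.0
        for i, d in enumerate(durations):
            epochs.append((f"r{i % 3}", t, t + d))
            t += d
        h = LineageHistory("t", epochs, total)
        anc, w = regime_weights(h, alpha)
        if alpha == 0:
            assert sum(w.values()) == pytest.approx(total, rel=1e-9)
        else:
            assert anc + sum(w.values()) == pytest.approx(1.0, abs=1e-9)

    def test_negative_alpha_rejected(self):
        h = LineageHistory("t", [("R", 0.0, 1.0)], 1.0)
        with pytest.raises(PhyloError):
            regime_weights(h, -0.1)


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------

def _histories(tree, painting):
    return {lb: lineage_epochs(tree, painting, lb)
            for lb in tree.tip_labels}


class TestBuildDesign:
    def test_single_regime_trend_is_intercept(self, five_tip_tree,
                                              constant_painting):
        p = constant_painting(five_tip_tree)
        hist = _histories(five_tip_tree, p)
        df = pd.DataFrame(index=five_tip_tree.tip_labels)
        X = build_design(hist, 0.0, df, five_tip_tree.tip_labels)
        np.testing.assert_allclose(X["F"], 1.0, atol=1e-9)

    def test_matches_regime_weights(self, five_tip_tree, five_tip_painting):
        hist = _histories(five_tip_tree, five_tip_painting)
        df = pd.DataFrame(index=five_tip_tree.tip_labels)
        alpha = LN2
        X = build_design(hist, alpha, df, five_tip_tree.tip_labels)
        for i, sp in enumerate(five_tip_tree.tip_labels):
            anc, w = regime_weights(hist[sp], alpha)
            for lv in ("F", "S"):
                expected = w.get(lv, 0.0)
                if hist[sp].root_regime == lv:
                    expected += anc
                assert X.loc[sp, lv] == pytest.approx(expected)
            assert X.loc[sp].sum() == pytest.approx(1.0)

    def test_allometric_design(self, five_tip_tree):
        df = pd.DataFrame({"log_mass": [1.0, 2, 3, 4, 5]},
                          index=five_tip_tree.tip_labels)
        X = build_design(None, LN2, df, five_tip_tree.tip_labels,
                         direct=("log_mass",))
        assert list(X.columns) == ["Intercept", "log_mass"]
        np.testing.assert_allclose(X["Intercept"], 1.0)

    def test_missing_predictor_named(self, five_tip_tree):
        df = pd.DataFrame({"log_mass": [1.0, np.nan, 3, 4, 5]},
                          index=five_tip_tree.tip_labels)
        with pytest.raises(PhyloError, match="missing values"):
            build_design(None, LN2, df, five_tip_tree.tip_labels,
                         direct=("log_mass",))


# ----------------------------------------------------------------------
# residual covariance
# ----------------------------------------------------------------------

class TestResidualCovariance:
    def test_two_tip_closed_form(self, three_tip_tree):
        s, d, T = phylo_matrices(three_tip_tree)
        V = residual_covariance(GridPoint(1.0, 1.0), s, d, T)
        i = {lb: k for k, lb in enumerate(three_tip_tree.tip_labels)}
        assert V[i["A"], i["B"]] == pytest.approx(0.25)
        assert V[i["A"], i["A"]] == pytest.approx(0.75)

    def test_large_alpha_limit(self, three_tip_tree):
        s, d, T = phylo_matrices(three_tip_tree)
        obs = np.array([0.1, 0.2, 0.3])
        V = residual_covariance(GridPoint(1e-6, 2.0), s, d, T,
                                y_obs_var=obs)
        np.testing.assert_allclose(np.diag(V), 2.0 + obs, atol=1e-9)
        off = V - np.diag(np.diag(V))
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_trend_limit_is_bm(self, three_tip_tree):
        s, d, T = phylo_matrices(three_tip_tree)
        err = np.array([0.01, 0.02, 0.0])
        V = residual_covariance(GridPoint(math.inf, 0.1), s, d, T,
                                y_obs_var=err)
        np.testing.assert_allclose(V, 0.1 * s + np.diag(err), atol=1e-12)

    def test_direct_error_term(self, three_tip_tree):
        s, d, T = phylo_matrices(three_tip_tree)
        vx = np.array([0.04, 0.0, 0.01])
        V0 = residual_covariance(GridPoint(1.0, 1.0), s, d, T)
        V = residual_covariance(GridPoint(1.0, 1.0), s, d, T,
                                direct_terms=[(0.5, vx)])
        np.testing.assert_allclose(V - V0, np.diag(0.25 * vx), atol=1e-12)


# ----------------------------------------------------------------------
# GLS
# ----------------------------------------------------------------------

class TestGlsSolve:
    def test_identity_equals_ols(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20),
                          "b": rng.normal(size=20)})
        X["a"] += 1.0
        y = rng.normal(size=20)
        res = gls_solve(X, np.eye(20), y)
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        np.testing.assert_allclose(res.beta.to_numpy(), beta_ols,
                                   atol=1e-10)

    def test_hand_computed_weighted_mean(self):
        X = pd.DataFrame({"c": [1.0, 1.0, 1.0]})
        V = np.diag([1.0, 1.0, 4.0])
        y = np.array([0.0, 0.0, 3.0])
        res = gls_solve(X, V, y)
        assert res.beta["c"] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_bm_mean_equals_contrasts(self, rng):
        tree = simulate_tree(16, rng)
        s, d, T = phylo_matrices(tree)
        y = simulate_bm(tree, 1.0, 0.0, rng)
        X = pd.DataFrame({"mean": np.ones(tree.n_tips)},
                         index=tree.tip_labels)
        res = gls_solve(X, s + 1e-12 * np.eye(len(T)),
                        y.loc[tree.tip_labels].to_numpy())
        oracle = contrasts_root_mean(tree, y)
        assert res.beta["mean"] == pytest.approx(oracle, abs=1e-7)

    def test_aliased_columns_named(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "twice_a": [2.0, 4, 6]})
        with pytest.raises(AliasedDesignError) as exc:
            gls_solve(X, np.eye(3), np.array([1.0, 2, 3]))
        assert "twice_a" in exc.value.columns or "a" in exc.value.columns


# ----------------------------------------------------------------------
# profile fitting
# ----------------------------------------------------------------------

def _make_table(tree, y, extra=None):
    df = pd.DataFrame({"log_ecv": y.loc[tree.tip_labels].to_numpy()},
                      index=tree.tip_labels)
    if extra is not None:
        for k, v in extra.items():
            df[k] = np.asarray(v.loc[tree.tip_labels])
    df.index.name = "species"
    return SpeciesTable(df.reset_index())


SMALL_GRID = GridConfig(n_t_half=12, n_v_y=12)


class TestProfileFit:
    def test_half_life_recovery_support_coverage(self, constant_painting):
        hits, n_rep = 0, 20
        master = np.random.default_rng(77)
        for _ in range(n_rep):
            tree = simulate_tree(64, master)
            p = constant_painting(tree, "R")
            cfg = ResponseConfig(t_half=0.1, v_y=0.3,
                                 regime_values={"R": 1.0}, root_value=0.0)
            y = simulate_response(tree, p, cfg, master)
            spec = ModelSpec(response="log_ecv", direct=(),
                             regimes={"r": p}, obs_error_response=False)
            fit = profile_fit(spec, tree, _make_table(tree, y), SMALL_GRID)
            lo, hi = fit.support_t_half
            if lo <= 0.1 <= hi:
                hits += 1
        assert hits >= 0.9 * n_rep - 1e-9

    def test_trend_data_detected_as_trend(self, five_tip_painting,
                                          five_tip_tree):
        master = np.random.default_rng(5)
        kinds = []
        for _ in range(11):
            tree = simulate_tree(48, master)
            states = {n.index: "R" for n in tree.nodes}
            p = paint_from_node_states(tree, states)
            cfg = ResponseConfig(t_half=math.inf, v_y=0.25,
                                 regime_values={"R": 2.0}, root_value=0.0)
            y = simulate_response(tree, p, cfg, master)
            spec = ModelSpec(response="log_ecv", direct=(),
                             regimes={"r": p}, obs_error_response=False)
            fit = profile_fit(spec, tree, _make_table(tree, y), SMALL_GRID)
            kinds.append(fit.kind)
        assert kinds.count("bm-trend") > len(kinds) / 2

    def test_loglik_invariant_to_species_order(self, rng,
                                               constant_painting):
        tree = simulate_tree(24, rng)
        p = constant_painting(tree, "R")
        cfg = ResponseConfig(t_half=0.5, v_y=0.2,
                             regime_values={"R": 0.5}, root_value=0.0)
        y = simulate_response(tree, p, cfg, rng)
        spec = ModelSpec(response="log_ecv", direct=(), regimes={"r": p},
                         obs_error_response=False)
        t1 = _make_table(tree, y)
        shuffled = t1.data.sample(frac=1.0, random_state=1).reset_index()
        t2 = SpeciesTable(shuffled)
        f1 = profile_fit(spec, tree, t1, SMALL_GRID)
        f2 = profile_fit(spec, tree, t2, SMALL_GRID)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_support_contains_ml(self, rng, constant_painting):
        tree = simulate_tree(32, rng)
        p = constant_painting(tree, "R")
        cfg = ResponseConfig(t_half=0.3, v_y=0.2,
                             regime_values={"R": 1.0}, root_value=0.0)
        y = simulate_response(tree, p, cfg, rng)
        spec = ModelSpec(response="log_ecv", direct=(), regimes={"r": p},
                         obs_error_response=False)
        fit = profile_fit(spec, tree, _make_table(tree, y), SMALL_GRID)
        assert fit.support_t_half[0] <= fit.t_half <= fit.support_t_half[1]
        assert fit.support_v_y[0] <= fit.v_y <= fit.support_v_y[1]
        # coefficient covariance is symmetric PSD
        C = fit.coef_cov.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_instant_adaptation_equals_ols(self, rng):
        # alpha -> inf with no phylogenetic residual: GLS coefficients on
        # the current-regime design converge to OLS
        tree = simulate_tree(40, rng)
        states = {n.index: ("A" if rng.random() < 0.5 else "B")
                  for n in tree.nodes}
        p = paint_from_node_states(tree, states)
        hist = _histories(tree, p)
        y = rng.normal(size=tree.n_tips)
        df = pd.DataFrame(index=tree.tip_labels)
        alpha = LN2 / 1e-4
        X = build_design(hist, alpha, df, tree.tip_labels)
        s, d, T = phylo_matrices(tree)
        V = residual_covariance(GridPoint(1e-4, 0.5), s, d, T)
        res = gls_solve(X, V, y)
        # oracle: OLS on current-regime indicators
        cur = np.array([[1.0 if hist[sp].epochs[-1][0] == lv else 0.0
                         for lv in sorted(p.regimes)]
                        for sp in tree.tip_labels])
        beta_ols, *_ = np.linalg.lstsq(cur, y, rcond=None)
        np.testing.assert_allclose(res.beta.to_numpy(), beta_ols,
                                   atol=1e-3)


# ----------------------------------------------------------------------
# metrics, conversions, contrasts, transforms
# ----------------------------------------------------------------------

class TestMetrics:
    def test_residual_r2_from_pair(self):
        assert residual_r_squared(94.5, 84.5) == pytest.approx(64.516,
                                                               abs=1e-2)

    def test_equal_r2_gives_zero(self):
        assert residual_r_squared(0.845, 0.845) == pytest.approx(0.0)

    def test_full_explains_everything(self):
        assert residual_r_squared(100.0, 84.5) == pytest.approx(100.0)

    def test_mismatched_species_sets_rejected(self, rng,
                                              constant_painting):
        t1 = simulate_tree(10, rng)
        t2 = simulate_tree(12, rng)
        p1 = constant_painting(t1, "R")
        cfg = ResponseConfig(t_half=0.5, v_y=0.2, regime_values={"R": 0.0})
        y1 = simulate_response(t1, p1, cfg, rng)
        y2 = simulate_response(t2, constant_painting(t2, "R"), cfg, rng)
        spec = ModelSpec(response="log_ecv", direct=(), regimes={},
                         obs_error_response=False)
        f1 = profile_fit(spec, t1, _make_table(t1, y1), SMALL_GRID)
        f2 = profile_fit(spec, t2, _make_table(t2, y2), SMALL_GRID)
        with pytest.raises(PhyloError):
            model_metrics(f1, f2)

    def test_aicc_parameter_count(self, rng, constant_painting):
        tree = simulate_tree(20, rng)
        p = constant_painting(tree, "R")
        cfg = ResponseConfig(t_half=0.5, v_y=0.2, regime_values={"R": 0.0})
        y = simulate_response(tree, p, cfg, rng)
        spec = ModelSpec(response="log_ecv", direct=(), regimes={"r": p},
                         obs_error_response=False)
        fit = profile_fit(spec, tree, _make_table(tree, y), SMALL_GRID)
        assert fit.k == len(fit.coefficients) + 2
        assert fit.aicc == pytest.approx(
            aicc_fn(fit.loglik, fit.k, fit.n), abs=1e-9)


class TestConvertHalfLife:
    def test_alpha_ln2(self):
        assert convert_half_life(alpha=LN2)["t_half"] == pytest.approx(1.0)

    def test_platyrrhine_scaling(self):
        out = convert_half_life(t_half=0.06, original_height=22.0)
        assert out["t_half_time"] == pytest.approx(1.32)

    def test_infinite_half_life(self):
        assert convert_half_life(t_half=math.inf)["alpha"] == 0.0

    def test_exactly_one_argument(self):
        with pytest.raises(PhyloError):
            convert_half_life(alpha=1.0, t_half=1.0)
        with pytest.raises(PhyloError):
            convert_half_life()


class TestRhoFactor:
    def test_large_alpha(self):
        assert rho_factor(1e8, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_trend_limit(self):
        assert rho_factor(0.0, 1.0) == 0.0

    def test_alpha_ln2(self):
        assert rho_factor(LN2, 1.0) == pytest.approx(0.2787, abs=1e-4)


class TestContrast:
    def _fit(self, rng):
        tree = simulate_tree(40, rng)
        states = {n.index: ("A" if rng.random() < 0.5 else "B")
                  for n in tree.nodes}
        p = paint_from_node_states(tree, states)
        cfg = ResponseConfig(t_half=math.inf, v_y=0.2,
                             regime_values={"A": 1.0, "B": 0.0},
                             root_value=0.0)
        y = simulate_response(tree, p, cfg, rng)
        spec = ModelSpec(response="log_ecv", direct=(), regimes={"r": p},
                         obs_error_response=False)
        return profile_fit(spec, tree, _make_table(tree, y), SMALL_GRID)

    def test_hand_computation(self, rng):
        fit = self._fit(rng)
        # overwrite the covariance with a known one
        fit.coefficients[:] = [1.0, 0.5]
        fit.coef_cov.iloc[:, :] = [[0.04, 0.0], [0.0, 0.01]]
        est, se = contrast(fit, "A", "B")
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(math.sqrt(0.05), abs=1e-9)
        assert se == pytest.approx(0.2236, abs=1e-4)

    def test_self_contrast_zero(self, rng):
        fit = self._fit(rng)
        est, se = contrast(fit, "A", "A")
        assert est == 0.0 and se == 0.0

    def test_unknown_level(self, rng):
        fit = self._fit(rng)
        with pytest.raises(PhyloError, match="not estimated"):
            contrast(fit, "A", "Z")

    def test_trend_contrast_recovery(self):
        master = np.random.default_rng(99)
        ests = []
        for _ in range(30):
            tree = simulate_tree(48, master)
            states = {n.index: ("A" if master.random() < 0.5 else "B")
                      for n in tree.nodes}
            p = paint_from_node_states(tree, states)
            cfg = ResponseConfig(t_half=math.inf, v_y=0.2,
                                 regime_values={"A": 1.0, "B": 0.0},
                                 root_value=0.0)
            y = simulate_response(tree, p, cfg, master)
            spec = ModelSpec(response="log_ecv", direct=(),
                             regimes={"r": p}, obs_error_response=False)
            fit = profile_fit(spec, tree, _make_table(tree, y), SMALL_GRID)
            if "A" in fit.coefficients and "B" in fit.coefficients:
                ests.append(contrast(fit, "A", "B")[0])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - 1.0) <= 3 * se


class TestEffectTransform:
    def test_fold_percent(self):
        assert round(effect_transform(1.11, "percent")) == 303

    def test_percent_downward(self):
        assert round(effect_transform(-2.85, "percent_change")) == 94

    def test_percent_reduction(self):
        assert round(effect_transform(-0.44, "percent_change")) == 36

    def test_fold(self):
        assert round(effect_transform(3.15, "fold")) == 23

    def test_doubling(self):
        assert effect_transform(-0.04, "doubling_effect") == \
            pytest.approx(2.7, abs=0.05)

    def test_zero_slope(self):
        assert effect_transform(0.0, "doubling_effect") == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(PhyloError):
            effect_transform(math.inf, "fold")

    def test_unknown_kind(self):
        with pytest.raises(PhyloError):
            effect_transform(1.0, "nope")
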