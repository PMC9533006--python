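"""Factorial planning, paired execution, marginal means, significance
classification, modal windows and the stepwise interaction regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from agroecosim.sweep import (
    PARAM_COLUMNS,
    classify_effects,
    marginal_means,
    modal_window_parameters,
    paper_levels,
    plan_sweep,
    reduced_levels,
    run_sweep,
    stepwise_interaction_regression,
)
from agroecosim.simulator import SimulationConfig
from agroecosim.economics import EconParams


class TestPlan:
    def test_reference_levels_enumerate_full_factorial(self):
        plan = plan_sweep(paper_levels(), maps_per_context=8)
        assert plan.n_contexts == 3888  # 27 agronomic x 48 ecological x 3
        assert plan.n_runs == 31104
        assert len(plan.runs) == 31104

    def test_single_level_plan_is_one_run(self):
        levels = {k: [v[0]] for k, v in paper_levels().items()}
        plan = plan_sweep(levels, maps_per_context=1)
        assert plan.n_contexts == 1
        assert plan.n_runs == 1

    def test_maps_shared_within_agronomic_context(self):
        plan = plan_sweep(reduced_levels(), maps_per_context=2, master_seed=3)
        df = pd.DataFrame(list(plan.runs))
        # one distinct seed per (agronomic context, repetition), reused
        # across every ecological / pesticide context
        for _, grp in df.groupby(["agro_index", "rep"]):
            assert grp["map_seed"].nunique() == 1
        # and distinct across repetitions
        seeds = df.groupby(["agro_index", "rep"])["map_seed"].first()
        assert seeds.nunique() == len(seeds)

    def test_plan_is_deterministic_in_master_seed(self):
        p1 = plan_sweep(reduced_levels(), maps_per_context=2, master_seed=7)
        p2 = plan_sweep(reduced_levels(), maps_per_context=2, master_seed=7)
        p3 = plan_sweep(reduced_levels(), maps_per_context=2, master_seed=8)
        assert p1.runs == p2.runs
        assert p1.runs != p3.runs

    def test_missing_levels_rejected(self):
        levels = paper_levels()
        levels.pop("alpha")
        with pytest.raises(ValueError):
            plan_sweep(levels)


@pytest.fixture(scope="module")
def tiny_results():
    levels = {
        "q_bar": [3.6],
        "s_q": [1.2],
        "f": [1.0],
        "d_p": [1.0],
        "d_n": [0.1],
        "r_p": [math.log(4.0)],
        "alpha": [0.0, 4.0 / 3.0],
        "rho": [math.log(4.0)],
    }
    plan = plan_sweep(levels, maps_per_context=2, master_seed=1, n=6)
    return run_sweep(plan, EconParams(), SimulationConfig(horizon_years=4))


class TestRunSweep:
    def test_baseline_rows_have_null_effect(self, tiny_results):
        base = tiny_results[tiny_results["alpha"] == 0.0]
        assert (base["delta_pi"] == 0.0).all()
        assert (base["delta_tfi"] == 0.0).all()

    def test_every_positive_row_is_paired(self, tiny_results):
        pos = tiny_results[tiny_results["alpha"] > 0.0]
        base = tiny_results[tiny_results["alpha"] == 0.0]
        merged = pos.merge(base, on=["map_seed", "rho", "r_p", "d_p", "d_n"],
                           suffixes=("", "_b"))
        assert len(merged) == len(pos)
        assert np.allclose(merged["pi0"], merged["pi_b"])
        assert np.allclose(merged["tfi0"], merged["tfi_b"])

    def test_reproducible_table(self):
        levels = {k: [v[0]] for k, v in paper_levels().items()}
        levels["alpha"] = [0.0]
        plan = plan_sweep(levels, maps_per_context=1, master_seed=5, n=6)
        cfg = SimulationConfig(horizon_years=2)
        r1 = run_sweep(plan, EconParams(), cfg)
        r2 = run_sweep(plan, EconParams(), cfg)
        pd.testing.assert_frame_equal(r1, r2)


def _fixture_rows(rng=None, n_per_cell=2) -> pd.DataFrame:
    """Small synthetic factorial of parameter columns with outcomes."""
    rng = rng or np.random.default_rng(0)
    levels = {k: [0.0, 1.0] for k in PARAM_COLUMNS}
    levels["alpha"] = [0.5, 1.0]  # all-positive: every row has paired metrics
    rows = []
    for combo in itertools.product(*levels.values()):
        for _ in range(n_per_cell):
            rows.append(dict(zip(PARAM_COLUMNS, combo)))
    df = pd.DataFrame(rows)
    df["pi"] = 100.0
    df["tfi"] = 1.0
    df["delta_pi"] = 0.0
    df["delta_tfi"] = 0.0
    return df


class TestMarginalMeans:
    def test_identity_response_recovers_levels(self):
        df = _fixture_rows()
        df["delta_pi"] = df["f"]
        mm = marginal_means(df, "f")
        assert mm.loc[0.0, "delta_pi_mean"] == pytest.approx(0.0)
        assert mm.loc[1.0, "delta_pi_mean"] == pytest.approx(1.0)
        assert mm.loc[1.0, "delta_pi_arrow"] == pytest.approx(1.0)

    def test_independent_response_gives_grand_mean(self):
        df = _fixture_rows()
        df["delta_tfi"] = 0.25
        mm = marginal_means(df, "q_bar")
        assert np.allclose(mm["delta_tfi_mean"], 0.25)
        assert np.allclose(mm["delta_tfi_arrow"], 0.0)

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(12)
        df = _fixture_rows(rng)
        df["delta_pi"] = rng.normal(size=len(df))
        df["delta_tfi"] = rng.normal(size=len(df))
        mm = marginal_means(df, "r_p")
        for level in (0.0, 1.0):
            sub = df[df["r_p"] == level]
            assert mm.loc[level, "delta_pi_mean"] == pytest.approx(
                sub["delta_pi"].mean()
            )
            assert mm.loc[level, "delta_tfi_mean"] == pytest.approx(
                sub["delta_tfi"].mean()
            )

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            marginal_means(_fixture_rows(), "not_a_parameter")


class TestClassifyEffects:
    def test_all_null_rows_have_no_significant_effect(self):
        df = _fixture_rows()
        out = classify_effects(df)
        assert out["share_no_effect"] == 1.0
        assert out["share_significant_any"] == 0.0

    def test_constructed_quadrant_shares_recovered_exactly(self):
        df = _fixture_rows(n_per_cell=1)
        out0 = classify_effects(df)
        big_pi = 10 * out0["threshold_pi"]
        big_tfi = 10 * out0["threshold_tfi"]
        n = len(df)
        # quadrant pattern ++ / +- / -+ / -- in proportions 4:2:1:1
        signs = ([(1, 1)] * 4 + [(1, -1)] * 2 + [(-1, 1)] + [(-1, -1)])
        signs = (signs * (n // 8 + 1))[:n]
        df["delta_pi"] = [s[0] * big_pi for s in signs]
        df["delta_tfi"] = [s[1] * big_tfi for s in signs]
        out = classify_effects(df)
        assert out["share_significant_any"] == 1.0
        assert out["share_positive_quadrant"] == pytest.approx(4 / 8, abs=0.01)

    def test_perfectly_aligned_branch_has_unit_correlation(self):
        df = _fixture_rows(n_per_cell=1)
        thr = classify_effects(df)
        rng = np.random.default_rng(3)
        dpi = rng.uniform(2, 10, len(df)) * thr["threshold_pi"]
        df["delta_pi"] = dpi
        df["delta_tfi"] = 0.5 * dpi  # exact line, all in the upper branch
        out = classify_effects(df)
        assert out["corr_upper_branch"] == pytest.approx(1.0)

    def test_requires_positive_alpha_rows(self):
        df = _fixture_rows()
        df["alpha"] = 0.0
        with pytest.raises(ValueError):
            classify_effects(df)


class TestModalWindow:
    def test_single_context_window_returns_its_values(self):
        df = _fixture_rows(n_per_cell=1)
        df.loc[df.index[:1], "delta_pi"] = 100.0
        modal = modal_window_parameters(df, lambda d: d["delta_pi"] > 50)
        row = df.iloc[0]
        for col in PARAM_COLUMNS:
            assert modal[col] == [row[col]]

    def test_majority_level_recovered(self):
        df = _fixture_rows(n_per_cell=1)
        mask = (df["f"] == 1.0) & (df["alpha"] == 1.0)
        df.loc[mask, "delta_pi"] = 100.0
        modal = modal_window_parameters(df, lambda d: d["delta_pi"] > 50)
        assert modal["f"] == [1.0]
        assert modal["alpha"] == [1.0]

    def test_tie_reported_as_set(self):
        df = _fixture_rows(n_per_cell=1)
        df["delta_pi"] = 100.0  # full factorial: every level equally frequent
        modal = modal_window_parameters(df, lambda d: d["delta_pi"] > 50)
        assert modal["f"] == [0.0, 1.0]

    def test_empty_window_is_explicit(self):
        modal = modal_window_parameters(_fixture_rows(),
                                        lambda d: d["delta_pi"] > 1e9)
        assert all(v == [] for v in modal.values())


class TestStepwiseRegression:
    @staticmethod
    def _factorial_X(levels=(-1.0, 1.0), k=8):
        cols = [f"t{i}" for i in range(k)]
        rows = list(itertools.product(levels, repeat=k))
        return pd.DataFrame(rows, columns=cols)

    def test_exact_recovery_on_noiseless_factorial(self):
        X = self._factorial_X()
        y = 2.0 + 3.0 * X["t0"] - X["t1"] * X["t2"]
        res = stepwise_interaction_regression(X, y)
        assert set(res.terms) == {"t0", "t1:t2"}
        assert res.coefficients["intercept"] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients["t0"] == pytest.approx(3.0, abs=1e-8)
        assert res.coefficients["t1:t2"] == pytest.approx(-1.0, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_type_one_error_rate_on_pure_noise(self):
        # per-term false-inclusion rate across seeds stays near the
        # nominal entry level (at most one term enters per forward step)
        n_terms = 8 + 8 * 7 // 2
        included = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(120, 8)),
                             columns=[f"t{i}" for i in range(8)])
            y = rng.normal(size=120)
            res = stepwise_interaction_regression(X, y)
            included += len(res.terms)
        rate = included / (n_seeds * n_terms)
        assert rate <= 0.10

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(600, 8)),
                         columns=[f"t{i}" for i in range(8)])
        y = X["t0"] + 0.5 * X["t0"] * X["t1"] + rng.normal(0, 0.05, 600)
        res = stepwise_interaction_regression(X, y)
        assert {"t0", "t0:t1"} <= set(res.terms)
        # coefficients within 3 standard errors (sigma / sqrt(n) scale)
        assert res.coefficients["t0"] == pytest.approx(1.0, abs=3 * 0.05 / 20)
        assert res.coefficients["t0:t1"] == pytest.approx(0.5,
                                                          abs=3 * 0.05 / 20)
        assert res.r_squared > 0.99

    def test_non_finite_response_rejected(self):
        X = self._factorial_X(k=3)
        y = np.full(len(X), np.nan)
        with pytest.raises(ValueError):
            stepwise_interaction_regression(X, y)
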