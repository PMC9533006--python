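"""Factorial experiment over agronomic, ecological and pesticide contexts,
and the statistical analyses of the resulting biocontrol indicators.

A *context* is one combination of the eight varied parameters: the
agronomic triple (mean quality ``q_bar``, quality spread ``s_q``,
fragmentation ``f``), the ecological quadruple (pest and enemy diffusion
factors ``c_p``, ``c_n`` with ``D = c / n**2``, pest growth rate ``r_p``,
predation factor ``alpha``) and the pesticide-induced mortality ``rho``.
For each agronomic context a fixed set of quality maps is generated (the
only stochastic component); the same maps are shared across all ecological
and pesticide contexts so that every ``alpha > 0`` run pairs exactly with
its ``alpha = 0`` baseline on the identical map.

Analyses: per-parameter marginal means of ``delta_pi`` / ``delta_tfi``
(with the arrow deltas against the lowest level), classification of runs by
significance thresholds at a fraction of the dataset-wide mean profit and
mean TFI, modal parameter values inside outcome windows, and
forward-backward stepwise linear regression with all two-way interactions
selected by F-tests on the change in residual sum of squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ecodynamics import EcologyParams
from .economics import EconParams
from .landscape import LandscapeParams, generate_quality_map
from .simulator import SimulationConfig, biocontrol_effect, run_simulation

__all__ = [
    "SweepPlan",
    "RegressionResult",
    "PARAM_COLUMNS",
    "paper_levels",
    "reduced_levels",
    "plan_sweep",
    "run_sweep",
    "marginal_means",
    "classify_effects",
    "modal_window_parameters",
    "stepwise_interaction_regression",
]

#: the eight varied parameters, in reporting order
PARAM_COLUMNS = ["q_bar", "s_q", "f", "d_p", "d_n", "r_p", "alpha", "rho"]

#: agronomic parameters (the map depends on these only)
AGRO_COLUMNS = ["q_bar", "s_q", "f"]

Q_MAX = 12.0


def paper_levels() -> dict[str, list[float]]:
    """The reference factorial levels (3888 contexts).

    Diffusion levels ``d_p``/``d_n`` are the factors ``c`` of
    ``D = c / n**2``.
    """
    return {
        "q_bar": [Q_MAX * v for v in (0.3, 0.5, 0.7)],
        "s_q": [Q_MAX * v for v in (0.05, 0.1, 0.3)],
        "f": [-1.0, 0.0, 1.0],
        "d_p": [0.1, 1.0],
        "d_n": [0.1, 1.0],
        "r_p": [math.log(4.0), math.log(1e2), math.log(1e4)],
        "alpha": [0.0, 1.0 / 3.0, 5.0 / 6.0, 4.0 / 3.0],
        "rho": [math.log(4.0), math.log(1e2), math.log(1e4)],
    }


def reduced_levels() -> dict[str, list[float]]:
    """Scaled-down factorial for desk-size experiments.

    Keeps all three levels of the agronomic axes whose marginal direction
    is analysed (``q_bar``, ``f``), the extremes of pest diffusion, the
    lower two pest growth and pesticide levels, the strongest predation
    level (plus the ``alpha = 0`` baselines) and a single level elsewhere.
    """
    return {
        "q_bar": [Q_MAX * v for v in (0.3, 0.5, 0.7)],
        "s_q": [Q_MAX * 0.1],
        "f": [-1.0, 0.0, 1.0],
        "d_p": [0.1, 1.0],
        "d_n": [0.1],
        "r_p": [math.log(4.0), math.log(1e2)],
        "alpha": [0.0, 4.0 / 3.0],
        "rho": [math.log(4.0), math.log(1e2)],
    }


@dataclass(frozen=True)
class SweepPlan:
    """Enumerated factorial design.

    ``runs`` lists one dict per simulation (context x map repetition) with
    the eight parameter values, the agronomic context index, the repetition
    index and the derived map seed.  Map seeds depend only on (master seed,
    agronomic context, repetition), so all ecological / pesticide contexts
    of an agronomic context share the same maps and ``alpha = 0`` baselines
    pair exactly.
    """

    levels: dict[str, list[float]]
    maps_per_context: int = 8
    master_seed: int = 0
    n: int = 25
    runs: tuple = field(default=None, repr=False)

    @property
    def n_contexts(self) -> int:
        return int(np.prod([len(v) for v in self.levels.values()]))

    @property
    def n_runs(self) -> int:
        return self.n_contexts * self.maps_per_context


def _map_seed(master_seed: int, agro_index: int, rep: int) -> int:
    ss = np.random.SeedSequence([master_seed, agro_index, rep])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def plan_sweep(
    levels: dict[str, list[float]] | None = None,
    maps_per_context: int = 8,
    master_seed: int = 0,
    n: int = 25,
) -> SweepPlan:
    """Enumerate the full factorial run list deterministically."""
    if levels is None:
        levels = paper_levels()
    missing = [k for k in PARAM_COLUMNS if k not in levels or not levels[k]]
    if missing:
        raise ValueError(f"empty or missing level lists for {missing}")
    agro_grid = list(itertools.product(*(levels[k] for k in AGRO_COLUMNS)))
    other_cols = [k for k in PARAM_COLUMNS if k not in AGRO_COLUMNS]
    other_grid = list(itertools.product(*(levels[k] for k in other_cols)))
    runs = []
    for agro_idx, agro in enumerate(agro_grid):
        seeds = [
            _map_seed(master_seed, agro_idx, rep)
            for rep in range(maps_per_context)
        ]
        for other in other_grid:
            row = dict(zip(AGRO_COLUMNS, agro)) | dict(zip(other_cols, other))
            for rep in range(maps_per_context):
                runs.append(
                    row | {"agro_index": agro_idx, "rep": rep,
                           "map_seed": seeds[rep]}
                )
    plan = SweepPlan(
        levels={k: list(levels[k]) for k in PARAM_COLUMNS},
        maps_per_context=maps_per_context,
        master_seed=master_seed,
        n=n,
        runs=tuple(runs),
    )
    return plan


def run_sweep(
    plan: SweepPlan,
    econ: EconParams = EconParams(),
    cfg: SimulationConfig = SimulationConfig(),
    mcmc_iters: int | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute every run of the plan and attach paired-baseline metrics.

    Returns one row per run with the parameter values, the indicators
    ``pi`` / ``tfi``, their ``alpha = 0`` partner values ``pi0`` / ``tfi0``
    and the biocontrol indicators ``delta_pi`` / ``delta_tfi`` (zero by
    construction on the baseline rows themselves).  Quality maps are
    generated once per (agronomic context, repetition) and shared.
    """
    n = plan.n
    df = pd.DataFrame(list(plan.runs))
    rows = []
    # generate each map once
    maps = {}
    for (agro_idx, rep), grp in df.groupby(["agro_index", "rep"], sort=True):
        first = grp.iloc[0]
        lp = LandscapeParams(
            n=n,
            q_bar=float(first["q_bar"]),
            s_q=float(first["s_q"]),
            f=float(first["f"]),
            mcmc_iters=mcmc_iters,
            seed=int(first["map_seed"]),
        )
        maps[(agro_idx, rep)] = generate_quality_map(lp)

    total = len(df)
    for i, rec in enumerate(df.to_dict("records")):
        qmap = maps[(rec["agro_index"], rec["rep"])]
        eco = EcologyParams.with_factors(
            n,
            c_p=rec["d_p"],
            c_n=rec["d_n"],
            r_p=rec["r_p"],
            alpha=rec["alpha"],
        )
        sim = run_simulation(qmap, eco, replace(econ, rho=rec["rho"]), cfg)
        out = dict(rec)
        out["pi"] = sim.pi_mean
        out["tfi"] = sim.tfi_mean
        out["_pairing"] = (sim.pairing_key, rec["d_p"], rec["d_n"], rec["r_p"],
                           rec["rho"], rec["agro_index"], rec["rep"])
        rows.append(out)
        if progress and (i + 1) % 50 == 0:
            print(f"  {i + 1}/{total} runs done", flush=True)

    res = pd.DataFrame(rows)
    base = res[res["alpha"] == 0.0].set_index("_pairing")
    pi0 = res["_pairing"].map(base["pi"])
    tfi0 = res["_pairing"].map(base["tfi"])
    if pi0.isna().any():
        raise ValueError("missing alpha = 0 baseline for some runs; "
                         "include 0 in the alpha levels")
    res["pi0"] = pi0.astype(float)
    res["tfi0"] = tfi0.astype(float)
    res["delta_pi"] = res["pi"] - res["pi0"]
    res["delta_tfi"] = res["tfi0"] - res["tfi"]
    res = res.drop(columns=["_pairing"])
    # report actual diffusion coefficients alongside the factors
    res["D_P"] = res["d_p"] / n ** 2
    res["D_N"] = res["d_n"] / n ** 2
    cols = PARAM_COLUMNS + ["D_P", "D_N", "agro_index", "rep", "map_seed",
                            "pi", "tfi", "pi0", "tfi0", "delta_pi", "delta_tfi"]
    return res[cols]


# ---------------------------------------------------------------------------
# analyses


def marginal_means(rows: pd.DataFrame, focal_parameter: str) -> pd.DataFrame:
    """Per-level means of ``delta_pi`` and ``delta_tfi`` for one parameter,
    averaged across all other parameters, plus the deltas against the
    lowest level (the marginal-effect arrows)."""
    if focal_parameter not in PARAM_COLUMNS:
        raise ValueError(f"unknown parameter {focal_parameter!r}")
    g = (
        rows.groupby(focal_parameter)[["delta_pi", "delta_tfi"]]
        .mean()
        .sort_index()
    )
    g = g.rename(columns={"delta_pi": "delta_pi_mean",
                          "delta_tfi": "delta_tfi_mean"})
    g["delta_pi_arrow"] = g["delta_pi_mean"] - g["delta_pi_mean"].iloc[0]
    g["delta_tfi_arrow"] = g["delta_tfi_mean"] - g["delta_tfi_mean"].iloc[0]
    return g


def classify_effects(
    rows: pd.DataFrame, threshold_fraction: float = 0.05
) -> dict:
    """Classify ``alpha > 0`` runs by significance of the biocontrol effect.

    A run has a significant profit effect when ``|delta_pi|`` exceeds
    ``threshold_fraction`` of the dataset-wide mean profit (analogously for
    TFI).  Returns the shares significant on each / either / neither
    dimension, the share of significant runs in the positive quadrant
    (benefit on both dimensions), and Pearson correlations between
    ``delta_pi`` and ``delta_tfi`` on the upper (``delta_tfi > 0``) and
    lower (``delta_tfi < 0``) diagonal branches of the significant subset.
    """
    sub = rows[rows["alpha"] > 0.0]
    if len(sub) == 0:
        raise ValueError("no alpha > 0 rows to classify")
    thr_pi = threshold_fraction * float(sub["pi"].mean())
    thr_tfi = threshold_fraction * float(sub["tfi"].mean())
    sig_pi = sub["delta_pi"].abs() > thr_pi
    sig_tfi = sub["delta_tfi"].abs() > thr_tfi
    sig_any = sig_pi | sig_tfi
    m = int(len(sub))
    sig = sub[sig_any]

    def _corr(branch: pd.DataFrame) -> float:
        if len(branch) < 2:
            return float("nan")
        if branch["delta_pi"].std() == 0 or branch["delta_tfi"].std() == 0:
            return float("nan")
        r = np.corrcoef(branch["delta_pi"], branch["delta_tfi"])[0, 1]
        return float(r)

    pos_quadrant = (sig["delta_pi"] > 0) & (sig["delta_tfi"] > 0)
    return {
        "n_runs": m,
        "threshold_pi": thr_pi,
        "threshold_tfi": thr_tfi,
        "share_significant_pi": float(sig_pi.mean()),
        "share_significant_tfi": float(sig_tfi.mean()),
        "share_significant_any": float(sig_any.mean()),
        "share_no_effect": float((~sig_any).mean()),
        "share_positive_quadrant": (
            float(pos_quadrant.mean()) if len(sig) else float("nan")
        ),
        "corr_upper_branch": _corr(sig[sig["delta_tfi"] > 0]),
        "corr_lower_branch": _corr(sig[sig["delta_tfi"] < 0]),
    }


def modal_window_parameters(rows: pd.DataFrame, window) -> dict[str, list]:
    """Most frequent value of each parameter among rows inside a window.

    ``window`` is a boolean mask or a callable mapping the DataFrame to a
    mask (e.g. ``lambda d: (d.delta_pi > 15) & (100 * d.delta_tfi > 15)``).
    Ties are reported as multi-element lists; an empty window yields empty
    lists.
    """
    mask = window(rows) if callable(window) else np.asarray(window, dtype=bool)
    sub = rows[mask]
    out: dict[str, list] = {}
    for col in PARAM_COLUMNS:
        if len(sub) == 0:
            out[col] = []
            continue
        counts = sub[col].value_counts()
        top = counts.max()
        out[col] = sorted(counts[counts == top].index.tolist())
    return out


@dataclass(frozen=True)
class RegressionResult:
    """Retained terms of the stepwise interaction regression.

    ``terms`` are names such as ``"alpha"`` or ``"f:alpha"`` (two-way
    product); ``coefficients`` maps term -> fitted value, including the
    intercept.  ``r_squared`` is of the final fit; the entry/removal
    p-values are recorded for provenance.
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    r_squared: float
    p_enter: float
    p_remove: float
    n_obs: int


def _design_columns(X: pd.DataFrame) -> dict[str, np.ndarray]:
    cols = list(X.columns)
    out: dict[str, np.ndarray] = {}
    for c in cols:
        out[c] = X[c].to_numpy(dtype=float)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            out[f"{a}:{b}"] = out[a] * out[b]
    return out


def _sse(y: np.ndarray, columns: list[np.ndarray]) -> tuple[float, np.ndarray]:
    A = np.column_stack([np.ones_like(y)] + columns)
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def _f_pvalue(sse_small: float, sse_big: float, df_big: int, scale: float) -> float:
    """p-value of the F-test for one added term (small model nested in big)."""
    if df_big <= 0:
        return 1.0
    tol = 1e-12 * max(scale, 1.0)
    improvement = sse_small - sse_big
    if improvement <= tol:
        return 1.0  # no improvement beyond numerical noise
    if sse_big <= tol:
        return 0.0  # exact fit after adding the term
    F = improvement / (sse_big / df_big)
    return float(stats.f.sf(F, 1, df_big))


def stepwise_interaction_regression(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_iter: int = 200,
) -> RegressionResult:
    """Forward-backward stepwise selection over main effects and all
    two-way products, with F-tests on the change in residual sum of squares.

    The candidate set is the intercept (always kept), the columns of ``X``
    on their natural scales, and every pairwise product.  Forward steps add
    the candidate with the smallest p-value below ``p_enter``; backward
    steps drop the retained term with the largest p-value above
    ``p_remove``; iteration stops at a fixed point.  Aliased (rank
    deficient) candidates never improve the fit and are simply not selected.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    design = _design_columns(X)
    candidates = list(design.keys())
    n = y.size
    scale = float(((y - y.mean()) ** 2).sum())

    selected: list[str] = []
    for _ in range(max_iter):
        changed = False
        # forward
        sse_cur, _ = _sse(y, [design[t] for t in selected])
        best_term, best_p, best_sse = None, 1.0, None
        for t in candidates:
            if t in selected:
                continue
            sse_new, _ = _sse(y, [design[s] for s in selected + [t]])
            df_big = n - (len(selected) + 2)
            p = _f_pvalue(sse_cur, sse_new, df_big, scale)
            if p < best_p:
                best_term, best_p, best_sse = t, p, sse_new
        if best_term is not None and best_p < p_enter:
            selected.append(best_term)
            changed = True
        # backward
        if selected:
            sse_full, _ = _sse(y, [design[t] for t in selected])
            df_full = n - (len(selected) + 1)
            worst_term, worst_p = None, 0.0
            for t in selected:
                others = [s for s in selected if s != t]
                sse_wo, _ = _sse(y, [design[s] for s in others])
                p = _f_pvalue(sse_wo, sse_full, df_full, scale)
                if p >= worst_p:
                    worst_term, worst_p = t, p
            if worst_term is not None and worst_p > p_remove:
                selected.remove(worst_term)
                changed = True
        if not changed:
            break

    sse_final, coef = _sse(y, [design[t] for t in selected])
    r2 = 1.0 - sse_final / scale if scale > 0 else 1.0
    names = ["intercept"] + selected
    return RegressionResult(
        terms=tuple(selected),
        coefficients={nm: float(c) for nm, c in zip(names, coef)},
        r_squared=float(r2),
        p_enter=p_enter,
        p_remove=p_remove,
        n_obs=n,
    )
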