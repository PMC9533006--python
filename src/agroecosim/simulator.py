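"""Multi-year coupled simulation and biocontrol performance indicators.

Protocol: the landscape is first allocated greenfield (profit maximisation
at zero pest, no conversion costs); the natural enemy starts at carrying
capacity on the initial NCH cells and at zero elsewhere.  The system then
evolves pest-free for a burn-in period (default 3 years) letting land use
and the enemy distribution equilibrate.  At the end of the burn-in the pest
is introduced on every cell at a fraction (default 0.2) of the local
carrying capacity ``Q(x)``, and the model runs for ``T`` further years
(default 10).

Each simulated year runs: decide land use per cell -> integrate the lattice
ecology over the year -> realise yields and profits at harvest using the
end-of-year pest density (fertiliser stays at its decision-time level).

Indicators are the time-space mean profit ``pi`` (euros/ha/y) and mean
treatment frequency index ``TFI`` (unit-doses/ha/y) over the ``T``
post-introduction years.  Biocontrol is measured against the *paired*
baseline: the identical run (same map, same parameters) with predation
switched off (``alpha = 0``): ``delta_pi = pi - pi0`` and ``delta_tfi =
TFI0 - TFI`` (positive values = benefit).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ecodynamics import NCH, EcologyParams, EcoState, integrate_year
from .economics import EconParams, crop_profit, crop_yield, damage, decide_landuse, nch_profit
from .landscape import QualityMap

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "BiocontrolEffect",
    "run_simulation",
    "run_paired",
    "biocontrol_effect",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol settings: burn-in length, post-introduction horizon ``T``,
    introduction density as a fraction of ``Q(x)``, and an optional fixed
    integrator step ``dt`` (years; ``None`` = automatic policy)."""

    burnin_years: int = 3
    horizon_years: int = 10
    intro_density_fraction: float = 0.2
    dt: float | None = None
    anticipate_pesticide: bool = True

    def __post_init__(self) -> None:
        if self.burnin_years < 0:
            raise ValueError("burnin_years must be >= 0")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if not 0.0 <= self.intro_density_fraction <= 1.0:
            raise ValueError("intro_density_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationSummary:
    """Outcome of one run: headline indicators plus per-year records.

    ``years`` has one row per simulated year (burn-in included) with the
    landscape composition, mean densities, and realised profit / TFI means;
    ``pi_mean`` and ``tfi_mean`` average the post-introduction window only.
    """

    pi_mean: float
    tfi_mean: float
    years: pd.DataFrame
    alpha: float
    map_hash: str
    pairing_key: tuple
    final_state: EcoState = field(repr=False, default=None)


@dataclass(frozen=True)
class BiocontrolEffect:
    """Biocontrol indicators against the paired no-predation baseline."""

    delta_pi: float
    delta_tfi: float


def _map_hash(Q: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(Q).tobytes()).hexdigest()[:16]


def run_simulation(
    qmap: QualityMap,
    eco: EcologyParams,
    econ: EconParams,
    cfg: SimulationConfig = SimulationConfig(),
) -> SimulationSummary:
    """Run the full burn-in + introduction + horizon protocol on one map."""
    Q = qmap.Q
    n = Q.shape[0]
    n_cells = n * n
    total_years = cfg.burnin_years + cfg.horizon_years

    P = np.zeros_like(Q)
    # greenfield allocation at zero pest, no conversion costs
    lu, ant_profit, _ = decide_landuse(
        P, Q, None, eco.r_p, econ, greenfield=True,
        anticipate_pesticide=cfg.anticipate_pesticide,
    )
    N = np.where(lu.option == NCH, 1.0, 0.0)
    state = EcoState(tau=0.0, P=P, N=N)
    prev_option = None  # year 0 uses the greenfield decision above

    records = []
    pi_window = []
    tfi_window = []
    for t in range(total_years):
        if t > 0:
            lu, ant_profit, _ = decide_landuse(
                state.P, Q, prev_option, eco.r_p, econ,
                anticipate_pesticide=cfg.anticipate_pesticide,
            )
        state = integrate_year(state, lu, qmap, eco, dt=cfg.dt)

        # harvest: realised damage from the end-of-year pest density,
        # fertiliser fixed at its decision-time level
        is_crop = lu.option != NCH
        L = damage(state.P, Q)
        y_real = crop_yield(Q, lu.phi_fert, L, econ)
        if prev_option is None and t == 0:
            from_nch = np.zeros_like(is_crop)
            from_crop = np.zeros_like(is_crop)
        else:
            from_nch = (prev_option == NCH) & is_crop
            from_crop = (prev_option != NCH) & ~is_crop
        profit = np.where(
            is_crop,
            crop_profit(y_real, lu.phi_fert, lu.tfi, from_nch, econ),
            nch_profit(from_crop, econ),
        )

        in_window = t >= cfg.burnin_years
        mean_profit = float(profit.mean())
        mean_tfi = float(lu.tfi.mean())
        records.append(
            {
                "year": t,
                "post_introduction": in_window,
                "nch_fraction": float((lu.option == NCH).mean()),
                "treated_fraction": float((lu.tfi > 0).mean()),
                "mean_P": float(state.P.mean()),
                "mean_N": float(state.N.mean()),
                "mean_anticipated_profit": float(np.mean(ant_profit)),
                "mean_profit": mean_profit,
                "mean_tfi": mean_tfi,
            }
        )
        if in_window:
            pi_window.append(mean_profit)
            tfi_window.append(mean_tfi)

        prev_option = lu.option
        if t == cfg.burnin_years - 1:
            # pest introduced at the end of the burn-in, after that
            # year's harvest, on every cell
            state = EcoState(
                tau=state.tau,
                P=cfg.intro_density_fraction * Q,
                N=state.N,
            )

    pairing_key = (
        _map_hash(Q),
        eco.d_p,
        eco.d_n,
        eco.r_p,
        eco.r_n,
        eco.gamma,
        eco.l_dom,
        econ,
        cfg,
    )
    return SimulationSummary(
        pi_mean=float(np.mean(pi_window)),
        tfi_mean=float(np.mean(tfi_window)),
        years=pd.DataFrame.from_records(records),
        alpha=eco.alpha,
        map_hash=_map_hash(Q),
        pairing_key=pairing_key,
        final_state=state,
    )


def biocontrol_effect(
    sim: SimulationSummary, baseline: SimulationSummary
) -> BiocontrolEffect:
    """Biocontrol indicators ``delta_pi = pi - pi0``, ``delta_tfi = TFI0 -
    TFI`` against the paired ``alpha = 0`` baseline.  Raises if the
    baseline is not the no-predation twin of the same map and parameters."""
    if baseline.alpha != 0.0:
        raise ValueError(f"baseline must have alpha = 0, got {baseline.alpha}")
    if sim.pairing_key != baseline.pairing_key:
        raise ValueError(
            "runs are not paired: map or non-predation parameters differ"
        )
    return BiocontrolEffect(
        delta_pi=sim.pi_mean - baseline.pi_mean,
        delta_tfi=baseline.tfi_mean - sim.tfi_mean,
    )


def run_paired(
    qmap: QualityMap,
    eco: EcologyParams,
    econ: EconParams,
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[SimulationSummary, SimulationSummary, BiocontrolEffect]:
    """Run a scenario and its ``alpha = 0`` twin on the same map."""
    sim = run_simulation(qmap, eco, econ, cfg)
    base = run_simulation(qmap, replace(eco, alpha=0.0), econ, cfg)
    return sim, base, biocontrol_effect(sim, base)
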