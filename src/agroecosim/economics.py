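"""Annual land-use, crop-protection and fertilisation decisions.

Each cell is re-allocated every year by a profit-maximising farmer choosing
among four options: non-crop habitat (NCH), untreated crop, moderately
treated crop (treatment frequency index TFI = 3, pesticide mortality rho)
and highly treated crop (TFI = 6, mortality 2 rho).  For each crop option
the farmer

1. anticipates the harvest-time pest density ``P~`` from *local* growth
   only (no diffusion, no predation), starting from the observed density;
2. converts it into an anticipated damage fraction ``L~ = min(1, P~/Q)``;
3. picks the profit-maximising fertiliser dose for the Mitscherlich-Baule
   yield function ``Y = Q (1 - c1 exp(-c2 phi)) (1 - L)``;
4. computes the anticipated profit ``p Y - lambda_phi phi - lambda_pest TFI
   - nu`` minus a conversion cost if the cell changes land use.

NCH yields a fixed return ``s_NCH`` independent of quality and pest.  The
argmax is returned with ties broken by keeping the previous option, then by
lower TFI.  Decisions are purely local: no coupling between cells.

Treated-crop anticipation includes the pesticide mortality term ``-phi P~``
(without it treatment would always be dominated); set
``anticipate_pesticide=False`` for the strict local-growth-only forecast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ecodynamics import CROP_HIGH, CROP_MODERATE, CROP_UNTREATED, NCH

__all__ = [
    "EconParams",
    "LandUseGrid",
    "CellOutcome",
    "OPTION_NAMES",
    "anticipate_pest",
    "optimal_fertilizer",
    "crop_yield",
    "damage",
    "crop_profit",
    "nch_profit",
    "choose_option",
    "decide_landuse",
    "NCH",
    "CROP_UNTREATED",
    "CROP_MODERATE",
    "CROP_HIGH",
]

OPTION_NAMES = {
    NCH: "NCH",
    CROP_UNTREATED: "crop_untreated",
    CROP_MODERATE: "crop_moderate",
    CROP_HIGH: "crop_high",
}

#: TFI (unit-doses /ha/y) of each option
TFI_LEVELS = {NCH: 0.0, CROP_UNTREATED: 0.0, CROP_MODERATE: 3.0, CROP_HIGH: 6.0}


@dataclass(frozen=True)
class EconParams:
    """Economic parameters (euros, ha, years).

    Defaults are the reference calibration for a representative temperate
    cereal crop: output price ``p`` (euros/t), fertiliser price
    ``lambda_phi`` (euros/kg), pesticide price ``lambda_pesticide`` (euros
    per TFI unit-dose), fixed crop costs ``nu`` (euros/ha/y), NCH return
    ``s_nch`` (an agro-environmental payment, euros/ha/y), asymmetric
    conversion costs (establishing NCH costs more than ploughing it back),
    Mitscherlich-Baule yield-response parameters ``c1`` (dimensionless
    share) and ``c2`` (ha/kg), and the pesticide-induced mortality rate
    ``rho`` (1/y) of a single treatment level.
    """

    p: float = 150.0
    lambda_phi: float = 1.62
    lambda_pesticide: float = 33.0
    nu: float = 110.0
    s_nch: float = 300.0
    cost_c_to_nch: float = 219.4
    cost_nch_to_c: float = 27.4
    c1: float = 0.38
    c2: float = 0.015
    rho: float = math.log(100.0)

    def __post_init__(self) -> None:
        if not (self.cost_c_to_nch > self.cost_nch_to_c > 0):
            raise ValueError("need cost_c_to_nch > cost_nch_to_c > 0")
        if not (0 < self.c1 < 1):
            raise ValueError("c1 must be in (0, 1)")
        if not self.c2 > 0:
            raise ValueError("c2 must be > 0")
        for name in ("p", "lambda_phi", "lambda_pesticide", "nu", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def phi_pesticide(self, option: int) -> float:
        """Pesticide mortality rate (1/y) of a land-use option."""
        return {NCH: 0.0, CROP_UNTREATED: 0.0, CROP_MODERATE: self.rho,
                CROP_HIGH: 2.0 * self.rho}[option]


@dataclass
class LandUseGrid:
    """Per-cell land-use option with the derived input grids.

    ``phi_pesticide`` and ``tfi`` are deterministic functions of the
    option; NCH cells carry zero fertiliser.
    """

    option: np.ndarray
    phi_fert: np.ndarray
    phi_pesticide: np.ndarray
    tfi: np.ndarray

    @classmethod
    def from_options(
        cls, option: np.ndarray, phi_fert: np.ndarray, econ: EconParams
    ) -> "LandUseGrid":
        option = np.asarray(option, dtype=int)
        phi_fert = np.where(option == NCH, 0.0, np.asarray(phi_fert, dtype=float))
        phi_p = np.choose(option, [0.0, 0.0, econ.rho, 2.0 * econ.rho])
        tfi = np.choose(option, [0.0, 0.0, 3.0, 6.0])
        return cls(option=option, phi_fert=phi_fert, phi_pesticide=phi_p, tfi=tfi)


@dataclass(frozen=True)
class CellOutcome:
    """Decision-time forecast and harvest-time realisation for one cell."""

    anticipated_pest: float
    anticipated_profit: float
    realized_yield: float
    realized_profit: float


def anticipate_pest(
    P0,
    Q,
    option: int,
    r_p: float,
    phi_pesticide: float = 0.0,
    anticipate_pesticide: bool = True,
):
    """Farmer's one-year forecast of the local pest density.

    Solves the single-cell forecast dynamics in closed form: no growth over
    the first half-year, logistic growth (rate ``r_p``, capacity ``Q``)
    over the second half on crops, no growth on NCH.  For treated options
    the mortality ``-phi P~`` applies throughout the year unless
    ``anticipate_pesticide`` is False.  Accepts scalars or arrays (``P0``,
    ``Q`` broadcast together).
    """
    P0 = np.asarray(P0, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if np.any(P0 < 0):
        raise ValueError("pest density must be >= 0")
    if option == NCH:
        out = P0.copy()
        return float(out) if out.ndim == 0 else out
    phi = phi_pesticide if anticipate_pesticide else 0.0
    p_half = P0 * math.exp(-phi / 2.0)
    a = r_p - phi
    q_safe = np.where(Q > 0.0, Q, 1.0)
    if abs(a) > 1e-12:
        e = math.exp(a / 2.0)
        grown = a * p_half * e / (a + (r_p / q_safe) * p_half * (e - 1.0))
    else:
        grown = p_half / (1.0 + (r_p / q_safe) * p_half * 0.5)
    decayed = p_half * math.exp(-phi / 2.0)  # Q == 0: no growth, decay only
    out = np.where(Q > 0.0, grown, decayed)
    return float(out) if out.ndim == 0 else out


def optimal_fertilizer(Q, L_anticipated, econ: EconParams):
    """Profit-maximising fertiliser dose (kg/ha), clamped at zero.

    Interior optimum ``-(1/c2) ln(lambda_phi / (p c1 c2 Q (1 - L)))``; zero
    whenever the marginal product at zero dose does not cover the
    fertiliser price (including ``Q (1 - L) == 0``).
    """
    Q = np.asarray(Q, dtype=float)
    L = np.asarray(L_anticipated, dtype=float)
    denom = econ.p * econ.c1 * econ.c2 * Q * (1.0 - L)
    with np.errstate(divide="ignore", invalid="ignore"):
        interior = np.log(denom / econ.lambda_phi) / econ.c2
    out = np.where(denom > econ.lambda_phi, interior, 0.0)
    return float(out) if out.ndim == 0 else out


def crop_yield(Q, phi_fert, L, econ: EconParams):
    """Mitscherlich-Baule yield times damage survival (t/ha), in [0, Q]."""
    Q = np.asarray(Q, dtype=float)
    phi_fert = np.asarray(phi_fert, dtype=float)
    L = np.asarray(L, dtype=float)
    out = Q * (1.0 - econ.c1 * np.exp(-econ.c2 * phi_fert)) * (1.0 - L)
    return float(out) if out.ndim == 0 else out


def damage(P_harvest, Q):
    """Yield-loss fraction ``L = min(1, P/Q)``; ``Q == 0`` gives ``L = 1``."""
    P = np.asarray(P_harvest, dtype=float)
    Q = np.asarray(Q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = P / np.where(Q > 0.0, Q, 1.0)
    out = np.where(Q > 0.0, np.minimum(1.0, frac), 1.0)
    return float(out) if out.ndim == 0 else out


def crop_profit(yield_t, phi_fert, tfi, converted_from_nch, econ: EconParams):
    """Crop profit (euros/ha): revenue minus fertiliser, pesticide (priced
    per TFI unit-dose), fixed costs and the NCH->crop conversion cost."""
    y = np.asarray(yield_t, dtype=float)
    phi_fert = np.asarray(phi_fert, dtype=float)
    conv = np.asarray(converted_from_nch, dtype=bool)
    out = (
        econ.p * y
        - econ.lambda_phi * phi_fert
        - econ.lambda_pesticide * np.asarray(tfi, dtype=float)
        - econ.nu
        - np.where(conv, econ.cost_nch_to_c, 0.0)
    )
    return float(out) if out.ndim == 0 else out


def nch_profit(converted_from_crop, econ: EconParams):
    """NCH return (euros/ha) minus the crop->NCH conversion cost if the
    cell was cropped the previous year; independent of Q and pest."""
    conv = np.asarray(converted_from_crop, dtype=bool)
    out = econ.s_nch - np.where(conv, econ.cost_c_to_nch, 0.0)
    return float(out) if out.ndim == 0 else out


def _option_grids(
    P,
    Q,
    prev_option,
    r_p: float,
    econ: EconParams,
    greenfield: bool,
    anticipate_pesticide: bool,
):
    """Anticipated (profit, fertiliser, P~) grids for each of the 4 options."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    out = {}
    if greenfield:
        from_crop = np.zeros(P.shape, dtype=bool)
        from_nch = np.zeros(P.shape, dtype=bool)
    else:
        prev = np.asarray(prev_option, dtype=int)
        from_crop = prev != NCH
        from_nch = prev == NCH
    out[NCH] = (
        np.broadcast_to(nch_profit(from_crop, econ), P.shape).astype(float),
        np.zeros(P.shape),
        P.copy(),
    )
    for opt in (CROP_UNTREATED, CROP_MODERATE, CROP_HIGH):
        phi_p = econ.phi_pesticide(opt)
        p_ant = anticipate_pest(P, Q, opt, r_p, phi_p, anticipate_pesticide)
        l_ant = damage(p_ant, Q)
        fert = optimal_fertilizer(Q, l_ant, econ)
        y_ant = crop_yield(Q, fert, l_ant, econ)
        profit = crop_profit(y_ant, fert, TFI_LEVELS[opt], from_nch, econ)
        out[opt] = (np.asarray(profit, dtype=float), np.asarray(fert, dtype=float),
                    np.asarray(p_ant, dtype=float))
    return out


def decide_landuse(
    P,
    Q,
    prev_option,
    r_p: float,
    econ: EconParams,
    greenfield: bool = False,
    anticipate_pesticide: bool = True,
) -> tuple[LandUseGrid, np.ndarray, np.ndarray]:
    """Profit-maximising decision for every cell of the lattice.

    Returns ``(landuse, anticipated_profit, anticipated_pest)``.  Ties are
    broken by keeping the previous option, then by lower TFI (option
    enumeration order NCH, untreated, moderate, high).  With
    ``greenfield=True`` no conversion costs apply (initial allocation).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    grids = _option_grids(P, Q, prev_option, r_p, econ, greenfield,
                          anticipate_pesticide)
    if greenfield:
        prev = np.full(P.shape, -1, dtype=int)
    else:
        prev = np.atleast_2d(np.asarray(prev_option, dtype=int))

    best_opt = np.zeros(P.shape, dtype=int)
    best_profit, best_fert, best_pant = (g.copy() for g in grids[NCH])
    best_is_prev = prev == NCH
    for opt in (CROP_UNTREATED, CROP_MODERATE, CROP_HIGH):
        profit, fert, p_ant = grids[opt]
        is_prev = prev == opt
        # strict improvement, or an exact tie won by the previous option
        take = (profit > best_profit) | (
            (profit == best_profit) & is_prev & ~best_is_prev
        )
        best_opt = np.where(take, opt, best_opt)
        best_profit = np.where(take, profit, best_profit)
        best_fert = np.where(take, fert, best_fert)
        best_pant = np.where(take, p_ant, best_pant)
        best_is_prev = np.where(take, is_prev, best_is_prev)
    lu = LandUseGrid.from_options(best_opt, best_fert, econ)
    return lu, best_profit, best_pant


def choose_option(
    P_t: float,
    Q: float,
    previous_option: int | None,
    r_p: float,
    econ: EconParams,
    anticipate_pesticide: bool = True,
) -> tuple[int, float, float, float]:
    """Single-cell decision: ``(option, phi_fert, phi_pesticide,
    anticipated_profit)``.  ``previous_option=None`` means a greenfield
    allocation without conversion costs."""
    greenfield = previous_option is None
    prev = np.array([[NCH if greenfield else previous_option]])
    lu, profit, _ = decide_landuse(
        np.array([[P_t]]), np.array([[Q]]), prev, r_p, econ,
        greenfield=greenfield, anticipate_pesticide=anticipate_pesticide,
    )
    opt = int(lu.option[0, 0])
    return opt, float(lu.phi_fert[0, 0]), float(lu.phi_pesticide[0, 0]), float(
        profit[0, 0]
    )
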