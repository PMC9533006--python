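"""Intra-annual pest / natural-enemy lattice dynamics.

A lattice dynamical system (the discrete-space counterpart of a
reaction-diffusion model) describes the densities of a crop pest ``P`` and
its natural enemy ``N`` on the ``n x n`` torus over continuous time ``tau``
(years)::

    P' = D_P L[P] + g_P(tau, x, P) - alpha P N - phi(x) P
    N' = D_N L[N] + g_N(x, N)      + alpha P N - phi(x) N

``L`` is the five-point discrete Laplacian with periodic boundaries and
mesh ``dx = L_dom / n``.  Pest growth ``g_P`` is zero during the first half
of each year (the months following harvest) and logistic with rate ``r_P``
and carrying capacity ``Q(x)`` on cultivated cells during the second half;
it is zero on non-crop habitat (NCH).  The enemy declines at rate
``1/gamma`` on crops and grows logistically (rate ``r_N``, capacity 1) on
NCH.  Predation is Lotka-Volterra with a one-to-one conversion factor
``alpha``.  Pesticide adds mortality ``phi in {0, rho, 2 rho}`` to both
species on treated crops, held constant over the year.

Integration uses fixed-step explicit RK4 with substeps aligned exactly on
the half-year breakpoints where the pest growth term switches, which keeps
the discontinuous-in-time right-hand side reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EcologyParams",
    "EcoState",
    "discrete_laplacian",
    "pest_growth",
    "enemy_growth",
    "default_dt",
    "integrate",
    "integrate_year",
]

LN2 = math.log(2.0)

# land-use option codes shared with the economics module
NCH = 0
CROP_UNTREATED = 1
CROP_MODERATE = 2
CROP_HIGH = 3


@dataclass(frozen=True)
class EcologyParams:
    """Ecological rates.  Diffusion coefficients are in km^2/y on a domain
    of width ``l_dom`` (dimensionless length 1 by convention); the study
    levels are ``(c / n**2)`` with ``c in {0.1, 1}`` so that the discrete
    mixing rate ``D / dx**2 = c`` is independent of the lattice side."""

    d_p: float
    d_n: float
    r_p: float
    r_n: float = LN2
    gamma: float = 0.5
    alpha: float = 5.0 / 6.0
    l_dom: float = 1.0

    def __post_init__(self) -> None:
        for name in ("d_p", "d_n", "r_p", "r_n", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")

    @classmethod
    def with_factors(
        cls, n: int, c_p: float = 1.0, c_n: float = 1.0, **kwargs
    ) -> "EcologyParams":
        """Build params with ``D = c / n**2`` for an ``n x n`` lattice."""
        return cls(d_p=c_p / n ** 2, d_n=c_n / n ** 2, **kwargs)


@dataclass
class EcoState:
    """Pest and enemy density grids at continuous time ``tau`` (years)."""

    tau: float
    P: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.P.shape != self.N.shape:
            raise ValueError("P and N grids must share a shape")

    def copy(self) -> "EcoState":
        return EcoState(tau=self.tau, P=self.P.copy(), N=self.N.copy())


def discrete_laplacian(U: np.ndarray, dx: float) -> np.ndarray:
    """Five-point discrete Laplacian on the torus, divided by ``dx**2``."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] != U.shape[1] or U.shape[0] < 2:
        raise ValueError(f"expected a square grid with n >= 2, got {U.shape}")
    lap = (
        np.roll(U, 1, axis=0)
        + np.roll(U, -1, axis=0)
        + np.roll(U, 1, axis=1)
        + np.roll(U, -1, axis=1)
        - 4.0 * U
    )
    return lap / dx ** 2


def pest_growth(tau: float, option: int, Q: float, P: float, r_p: float) -> float:
    """Pointwise pest growth term ``g_P``.

    Zero during the first half of the year and on NCH; logistic with
    carrying capacity ``Q`` on cultivated cells in the second half.  Cells
    with ``Q == 0`` are zero-growth (logistic limit).
    """
    if option == NCH:
        return 0.0
    if (tau - math.floor(tau)) < 0.5:
        return 0.0
    if Q <= 0.0:
        return 0.0
    return r_p * P * (1.0 - P / Q)


def enemy_growth(option: int, N: float, r_n: float, gamma: float) -> float:
    """Pointwise enemy growth ``g_N``: mortality ``-N/gamma`` on crops,
    logistic toward carrying capacity 1 on NCH."""
    if option == NCH:
        return r_n * N * (1.0 - N)
    return -N / gamma


def default_dt(eco: EcologyParams, n: int, phi_max: float = 0.0) -> float:
    """Step-size policy resolving diffusion stability and the fastest rate.

    ``dt = min(0.5 / ceil(0.5 * (4 max(D)/dx^2 + r_max)), 1e-2)`` years,
    which keeps the explicit diffusion number ``D dt / dx^2 <= 1/4`` and at
    least ~100 steps per unit of the fastest reaction rate.
    """
    dx = eco.l_dom / n
    r_max = max(eco.r_p, eco.r_n, 1.0 / eco.gamma, phi_max)
    rate = 4.0 * max(eco.d_p, eco.d_n) / dx ** 2 + r_max
    return min(0.5 / math.ceil(0.5 * rate), 1e-2)


def _check_dt(dt: float, eco: EcologyParams, n: int, phi_max: float) -> None:
    dx = eco.l_dom / n
    if dt * max(eco.d_p, eco.d_n) / dx ** 2 > 0.25 + 1e-12:
        raise ValueError(
            f"dt={dt} violates the diffusion stability bound D*dt/dx^2 <= 1/4"
        )
    if dt * max(eco.r_p, eco.r_n, 1.0 / eco.gamma, phi_max) > 1.0:
        raise ValueError(f"dt={dt} does not resolve the fastest reaction rate")


def _rhs(
    P: np.ndarray,
    N: np.ndarray,
    growth_on: bool,
    crop: np.ndarray,
    qpos_crop: np.ndarray,
    q_safe: np.ndarray,
    phi: np.ndarray,
    eco: EcologyParams,
    dx: float,
) -> tuple[np.ndarray, np.ndarray]:
    lap_p = discrete_laplacian(P, dx)
    lap_n = discrete_laplacian(N, dx)
    pred = eco.alpha * P * N
    dP = eco.d_p * lap_p - pred - phi * P
    if growth_on:
        dP = dP + np.where(qpos_crop, eco.r_p * P * (1.0 - P / q_safe), 0.0)
    g_n = np.where(crop, -N / eco.gamma, eco.r_n * N * (1.0 - N))
    dN = eco.d_n * lap_n + g_n + pred - phi * N
    return dP, dN


def integrate(
    state: EcoState,
    landuse,
    qmap,
    eco: EcologyParams,
    duration: float = 1.0,
    dt: float | None = None,
) -> EcoState:
    """Advance the lattice system by ``duration`` years with fixed land use.

    ``landuse`` provides the per-cell option grid and pesticide mortality
    grid (``phi in {0, rho, 2 rho}``, constant over the year); ``qmap`` the
    quality grid.  The integration is split at every half-year breakpoint so
    no RK4 step straddles the pest growth switch.  Raises ``RuntimeError``
    if the state becomes non-finite or negative (instability diagnostic).
    """
    Q = np.asarray(qmap.Q if hasattr(qmap, "Q") else qmap, dtype=float)
    option = np.asarray(landuse.option if hasattr(landuse, "option") else landuse[0])
    phi = np.asarray(
        landuse.phi_pesticide if hasattr(landuse, "phi_pesticide") else landuse[1],
        dtype=float,
    )
    n = Q.shape[0]
    if state.P.shape != Q.shape:
        raise ValueError("state grids must match the quality map shape")
    phi_max = float(phi.max()) if phi.size else 0.0
    if dt is None:
        dt = default_dt(eco, n, phi_max)
    _check_dt(dt, eco, n, phi_max)
    dx = eco.l_dom / n

    crop = option != NCH
    qpos_crop = crop & (Q > 0.0)
    q_safe = np.where(Q > 0.0, Q, 1.0)

    P = state.P.copy()
    N = state.N.copy()
    tau = state.tau
    end = tau + duration
    eps = 1e-12
    while tau < end - eps:
        # next half-year breakpoint (or the requested end time)
        k = math.floor(tau / 0.5 + eps) + 1
        seg_end = min(k * 0.5, end)
        seg_len = seg_end - tau
        m = max(1, math.ceil(seg_len / dt - eps))
        h = seg_len / m
        growth_on = (tau + 0.5 * seg_len) % 1.0 >= 0.5
        args = (growth_on, crop, qpos_crop, q_safe, phi, eco, dx)
        for _ in range(m):
            k1p, k1n = _rhs(P, N, *args)
            k2p, k2n = _rhs(P + 0.5 * h * k1p, N + 0.5 * h * k1n, *args)
            k3p, k3n = _rhs(P + 0.5 * h * k2p, N + 0.5 * h * k2n, *args)
            k4p, k4n = _rhs(P + h * k3p, N + h * k3n, *args)
            P = P + (h / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            N = N + (h / 6.0) * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        tau = seg_end
        if not (np.isfinite(P).all() and np.isfinite(N).all()):
            raise RuntimeError(
                f"non-finite state at tau={tau:.4f} "
                f"(dt={dt}, max|P|={np.nanmax(np.abs(P)):.3g})"
            )
        if P.min() < -1e-9 or N.min() < -1e-9:
            raise RuntimeError(
                f"negative density at tau={tau:.4f}: "
                f"min P={P.min():.3g}, min N={N.min():.3g} (reduce dt)"
            )
    return EcoState(tau=end, P=P, N=N)


def integrate_year(
    state: EcoState, landuse, qmap, eco: EcologyParams, dt: float | None = None
) -> EcoState:
    """Advance exactly one year from an integer year start."""
    if abs(state.tau - round(state.tau)) > 1e-9:
        raise ValueError(f"integrate_year expects an integer tau, got {state.tau}")
    return integrate(state, landuse, qmap, eco, duration=1.0, dt=dt)
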