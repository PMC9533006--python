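"""Stochastic soil-quality landscape generation.

An agricultural landscape is an ``n x n`` lattice of 1-ha cells wrapped on a
torus.  Each cell carries a potential yield ``Q(x)`` (t/ha), the maximal
yield reachable with unlimited fertilisation and no pest damage.  Maps are
built in two steps:

1. draw ``n**2`` values from a normal distribution with mode ``q_bar`` and
   standard deviation ``s_q``, truncated to ``[Q_min, Q_max]``;
2. arrange those values in space by sampling from the Gibbs measure
   ``P(X = Q) ∝ exp(f * S(Q))`` over all permutations of the drawn values,
   where ``S(Q)`` is a fragmentation statistic summing absolute quality
   differences over four-neighbour pairs.

Positive fragmentation parameters ``f`` favour arrangements whose
neighbours differ (fragmented maps); negative values favour aggregated,
spatially auto-correlated maps.  The Gibbs measure is sampled by
Metropolis-Hastings over uniformly chosen cell-pair swaps, which preserves
the drawn multiset of values by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LandscapeParams",
    "QualityMap",
    "draw_quality_values",
    "fragmentation_statistic",
    "sample_quality_map",
    "generate_quality_map",
]

# four-neighbourhood offsets on the torus (row, col)
_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the stochastic soil-quality map model.

    Attributes
    ----------
    n : int
        Lattice side; the landscape has ``n**2`` cells of 1 ha each.
    q_bar : float
        Mode of the truncated normal quality distribution (t/ha).
    s_q : float
        Standard deviation of the quality distribution (t/ha).
    f : float
        Fragmentation parameter of the Gibbs measure (dimensionless).
        Positive values fragment the map, negative values aggregate it.
    q_min, q_max : float
        Truncation bounds for the quality values (t/ha).
    C : float
        Scaling constant of the fragmentation statistic.
    mcmc_iters : int or None
        Number of Metropolis swap proposals; ``None`` means ``100 * n**2``.
    seed : int
        Seed for both the value draw and the Metropolis chain.
    """

    n: int = 25
    q_bar: float = 6.0
    s_q: float = 1.2
    f: float = 0.0
    q_min: float = 0.0
    q_max: float = 12.0
    C: float = 10.0
    mcmc_iters: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"lattice side n must be >= 2, got {self.n}")
        if not self.q_min < self.q_max:
            raise ValueError(f"need q_min < q_max, got [{self.q_min}, {self.q_max}]")
        if not self.s_q > 0:
            raise ValueError(f"s_q must be > 0, got {self.s_q}")
        if self.mcmc_iters is not None and self.mcmc_iters < 0:
            raise ValueError("mcmc_iters must be >= 0")

    @property
    def n_iters(self) -> int:
        return 100 * self.n ** 2 if self.mcmc_iters is None else self.mcmc_iters


@dataclass(frozen=True)
class QualityMap:
    """A realised soil-quality map plus the parameters that generated it."""

    Q: np.ndarray
    params: LandscapeParams
    S: float = field(default=float("nan"))

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError(f"quality map must be square, got shape {Q.shape}")
        object.__setattr__(self, "Q", Q)
        if math.isnan(self.S):
            object.__setattr__(
                self, "S", fragmentation_statistic(Q, self.params.C)
            )


def draw_quality_values(
    params: LandscapeParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n**2`` i.i.d. soil-quality values (step 1 of map generation).

    Values follow a normal distribution with mean ``q_bar`` and s.d. ``s_q``
    truncated to ``[q_min, q_max]``.  Returns a flat array of length
    ``n**2``; reproducible from ``params.seed`` when ``rng`` is omitted.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    a = (params.q_min - params.q_bar) / params.s_q
    b = (params.q_max - params.q_bar) / params.s_q
    dist = stats.truncnorm(a, b, loc=params.q_bar, scale=params.s_q)
    return np.asarray(dist.rvs(size=params.n ** 2, random_state=rng), dtype=float)


def fragmentation_statistic(Q: np.ndarray, C: float = 10.0) -> float:
    """Fragmentation statistic ``S(Q) = (C/4) * sum |Q(x) - Q(y)|``.

    The sum runs over all *ordered* cell/four-neighbour pairs on the torus,
    so each undirected adjacency is counted twice.  Large values mean
    neighbouring cells tend to differ (fragmented maps).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"expected a square grid, got shape {Q.shape}")
    if Q.shape[0] < 2:
        raise ValueError("grid side must be >= 2")
    total = 0.0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        total += float(np.abs(Q - np.roll(Q, shift, axis=axis)).sum())
    return C / 4.0 * total


def _local_pair_energy(Q: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Sum of |Q(x)-Q(y)| over ordered neighbour pairs involving cell a or b.

    Unscaled (no C/4 factor).  Pairs (a,b)/(b,a) would be counted by both
    cells' sums, so their contribution is subtracted once; adjacency
    multiplicity handles the n == 2 double-wrap case.
    """
    n = Q.shape[0]
    total = 0.0
    adj_mult = 0
    for (i, j) in (a, b):
        q = Q[i, j]
        for di, dj in _OFFSETS:
            total += abs(q - Q[(i + di) % n, (j + dj) % n])
    for di, dj in _OFFSETS:
        if ((a[0] + di) % n, (a[1] + dj) % n) == b:
            adj_mult += 1
    # each unordered pair involving a or b appears as 2 ordered pairs
    return 2.0 * total - 2.0 * adj_mult * abs(Q[a] - Q[b])


def swap_delta_S(
    Q: np.ndarray, a: tuple[int, int], b: tuple[int, int], C: float = 10.0
) -> float:
    """Change in ``S`` if the values of cells ``a`` and ``b`` were swapped.

    Computed locally from the two cells' neighbourhoods; equals the full
    recomputation ``S(swapped) - S(Q)`` exactly.
    """
    if a == b:
        return 0.0
    before = _local_pair_energy(Q, a, b)
    Q[a], Q[b] = Q[b], Q[a]
    after = _local_pair_energy(Q, a, b)
    Q[a], Q[b] = Q[b], Q[a]
    return C / 4.0 * (after - before)


def sample_quality_map(
    values: np.ndarray,
    params: LandscapeParams,
    rng: np.random.Generator | None = None,
) -> QualityMap:
    """Arrange drawn values in space by Metropolis sampling (step 2).

    Starting from the row-major arrangement of ``values``, performs
    ``params.n_iters`` uniformly chosen cell-pair swap proposals, accepting
    each with probability ``min(1, exp(f * dS))`` where ``dS`` is the change
    in the fragmentation statistic.  The multiset of values is preserved
    exactly; after enough proposals the arrangement is approximately
    distributed according to the Gibbs measure with energy ``f * S(Q)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = params.n
    if values.size != n * n:
        raise ValueError(f"expected {n * n} values, got {values.size}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    Q = values.reshape(n, n).copy()
    n_iters = params.n_iters
    if n_iters > 0:
        idx = rng.integers(0, n * n, size=(n_iters, 2))
        log_u = np.log(rng.random(n_iters))
        f = params.f
        C = params.C
        for k in range(n_iters):
            ia, ib = int(idx[k, 0]), int(idx[k, 1])
            if ia == ib:
                continue
            a = divmod(ia, n)
            b = divmod(ib, n)
            d_s = swap_delta_S(Q, a, b, C)
            gain = f * d_s
            if gain >= 0.0 or log_u[k] < gain:
                Q[a], Q[b] = Q[b], Q[a]
    return QualityMap(Q=Q, params=params)


def generate_quality_map(params: LandscapeParams) -> QualityMap:
    """Full two-step map generation: draw values, then arrange them."""
    rng = np.random.default_rng(params.seed)
    values = draw_quality_values(params, rng=rng)
    return sample_quality_map(values, params, rng=rng)
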