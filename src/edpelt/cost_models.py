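"""Segment cost functions based on the empirical distribution.

The nonparametric segment cost treats the empirical CDF of a segment,
evaluated at a fixed threshold ``t``, as a binomial proportion: ``len *
[F log F + (1-F) log(1-F)]`` is the maximised log-likelihood of the
within-segment CDF at ``t``, and minus that is a cost.  Integrating the
cost over ``t`` with weight ``{F(t)(1-F(t))}^{-1} dF(t)`` (the weighting
behind the Anderson-Darling family of goodness-of-fit statistics) gives a
cost sensitive to changes anywhere in the distribution, not just the mean.

Three concrete cost models are provided:

``EmpiricalDistributionCost``
    The K-quantile approximation of the weighted integral.  A change of
    variables removes the weight, after which the integral is approximated
    by an equally weighted sum over ``K`` unevenly spaced quantiles of the
    full data (spaced to emphasise the tails).  With prefix count tables
    the cost of any segment is O(K); ``K = ceil(4 log n)`` by default.

``NMCDCost``
    The exact objective the approximation targets: the weighted sum over
    all ``n`` order statistics of the full series.  O(n) per segment, so
    only practical as an oracle or on screened candidate sets.

``LinearTrendCost``
    Gaussian least-squares cost for a mean that is linear in the index
    within each segment (residual sum of squares of the per-segment line
    fit), used for change-in-slope comparisons.

All costs are nonnegative and superadditive: splitting a segment never
increases the total unpenalised cost.  Superadditivity is what licenses
zero-slack pruning in PELT.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "TimeSeries",
    "QuantileGrid",
    "SegmentCostModel",
    "EmpiricalDistributionCost",
    "NMCDCost",
    "LinearTrendCost",
    "empirical_cdf",
    "segment_loglik",
    "build_quantile_grid",
    "default_K",
    "ed_segment_cost",
    "nmcd_segment_cost",
    "linear_trend_cost",
]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered univariate series ``x_1, ..., x_n`` (1-based by convention).

    Observations are assumed ordered by some covariate (time, genomic
    position, ...).  Values must be finite; missing entries are rejected.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("a time series must be one-dimensional")
        if arr.size < 2:
            raise ValueError("a segmentation task needs at least 2 observations")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series values must be finite (no NaN/inf)")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


def as_series(data: "TimeSeries | Sequence[float] | np.ndarray") -> TimeSeries:
    """Coerce raw sequences to :class:`TimeSeries` (no copy for arrays)."""
    if isinstance(data, TimeSeries):
        return data
    return TimeSeries(np.asarray(data, dtype=float))


def empirical_cdf(segment_values: Sequence[float], t: float) -> float:
    """Empirical CDF of a segment at ``t``, counting ties with weight 0.5.

    ``F_hat(t) = (1/len) * sum_j [ 1{x_j < t} + 0.5 * 1{x_j = t} ]``.
    """
    arr = np.asarray(segment_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empirical CDF of an empty segment is undefined")
    return float((np.count_nonzero(arr < t) + 0.5 * np.count_nonzero(arr == t)) / arr.size)


def segment_loglik(F_hat: float, length: int) -> float:
    """Maximised binomial log-likelihood of a segment CDF value.

    Returns ``length * [F log F + (1-F) log(1-F)]`` with ``0 log 0 := 0``.
    Always nonpositive; minus this is the single-threshold segment cost.
    """
    if not 0.0 <= F_hat <= 1.0:
        raise ValueError(f"F_hat must lie in [0, 1], got {F_hat}")
    if length < 1:
        raise ValueError("segment length must be >= 1")
    return float(length * (xlogy(F_hat, F_hat) + xlogy(1.0 - F_hat, 1.0 - F_hat)))


def default_K(n: int) -> int:
    """Default number of quantiles, ``ceil(4 log n)`` (natural log).

    Large enough that detection accuracy is empirically indistinguishable
    from using all ``n`` evaluation points, while keeping per-segment cost
    O(log n).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return int(math.ceil(4.0 * math.log(n)))


@dataclass(frozen=True)
class QuantileGrid:
    """The K evaluation points of the quantile-approximated cost.

    The change of variables ``F(t) = p(z) = (1 + exp(cz))^{-1}`` with
    ``c = -log(2n - 1)`` maps the weighted integral over ``t`` onto an
    unweighted integral over ``z in [-1, 1]``; the midpoint rule on ``z``
    then yields probabilities ``p_k`` clustered in the tails of the data.
    ``t_k`` is the ``p_k`` empirical quantile (an order statistic, no
    interpolation — exact tie handling matches the prefix count tables).

    ``prefix_lt[k, v]`` counts values strictly below ``t_k`` among
    ``x_{1:v}`` and ``prefix_eq[k, v]`` counts ties, so the segment CDF at
    any ``t_k`` over any ``(u, v]`` is an O(1) lookup.
    """

    K: int
    c: float
    z: np.ndarray  # midpoint abscissae in (-1, 1)
    p: np.ndarray  # probabilities in (0, 1), strictly increasing
    t: np.ndarray  # data-valued evaluation points
    prefix_lt: np.ndarray  # (K, n+1) int
    prefix_eq: np.ndarray  # (K, n+1) int
    n: int
    # prefix_lt + 0.5 * prefix_eq, cached for the vectorised cost kernel
    _w: np.ndarray = field(repr=False, default=None)

    def cdf(self, u: int, v: int) -> np.ndarray:
        """Segment empirical CDF at every t_k over (u, v], O(K)."""
        length = v - u
        return (self._w[:, v] - self._w[:, u]) / length


def build_quantile_grid(series: "TimeSeries | Sequence[float]", K: int) -> QuantileGrid:
    """Precompute the quantile design and prefix count tables (O(nK))."""
    ts = as_series(series)
    if K < 1:
        raise ValueError("K must be a positive integer")
    n = ts.n
    x = ts.values
    c = -math.log(2.0 * n - 1.0)
    k = np.arange(1, K + 1, dtype=float)
    z = (2.0 * k - 1.0) / K - 1.0
    p = 1.0 / (1.0 + (2.0 * n - 1.0) * np.exp(c * (2.0 * k - 1.0) / K))
    # order-statistic quantile: t_k = x_(ceil(p_k * n)), clamped to [1, n]
    idx = np.clip(np.ceil(p * n).astype(int), 1, n)
    t = np.sort(x)[idx - 1]
    lt = np.zeros((K, n + 1), dtype=np.int64)
    eq = np.zeros((K, n + 1), dtype=np.int64)
    lt[:, 1:] = np.cumsum(x[None, :] < t[:, None], axis=1)
    eq[:, 1:] = np.cumsum(x[None, :] == t[:, None], axis=1)
    w = lt + 0.5 * eq
    return QuantileGrid(
        K=K, c=c, z=z, p=p, t=t, prefix_lt=lt, prefix_eq=eq, n=n, _w=w
    )


def ed_segment_cost(grid: QuantileGrid, u: int, v: int) -> float:
    """K-quantile empirical-distribution cost of segment ``(u, v]``.

    ``C_K = (2 log(2n-1) / K) * sum_k -L_np(x_{u+1:v} | t_k)``, evaluated
    from the prefix tables in O(K).  Nonnegative; zero iff the segment CDF
    is degenerate (0 or 1) at every evaluation point.
    """
    _check_bounds(u, v, grid.n)
    length = v - u
    F = grid.cdf(u, v)
    ent = xlogy(F, F) + xlogy(1.0 - F, 1.0 - F)  # <= 0 elementwise
    return float((-2.0 * grid.c / grid.K) * (-length) * ent.sum())


def nmcd_segment_cost(series: "TimeSeries | Sequence[float]", u: int, v: int) -> float:
    """Exact weighted empirical-CDF cost of segment ``(u, v]`` (O(n)).

    The per-segment contribution to the exact objective: the single-point
    cost evaluated at every order statistic ``x_(t)`` of the full series,
    weighted by ``n / ((t - 0.5)(n - t + 0.5))``.  Sign-normalised so the
    value is nonnegative and smaller is better.
    """
    ts = as_series(series)
    _check_bounds(u, v, ts.n)
    return NMCDCost(ts).cost(u, v)


def linear_trend_cost(series: "TimeSeries | Sequence[float]", u: int, v: int) -> float:
    """Least-squares cost of fitting a line (on absolute index) to ``(u, v]``.

    ``min_{a,b} sum_{i=u+1..v} (x_i - a - b i)^2``; requires at least two
    points.  Zero exactly when the segment is perfectly linear in ``i``.
    """
    ts = as_series(series)
    _check_bounds(u, v, ts.n)
    if v - u < 2:
        raise ValueError("linear trend cost needs a segment of length >= 2")
    return LinearTrendCost(ts).cost(u, v)


def _check_bounds(u: int, v: int, n: int) -> None:
    if not (0 <= u < v <= n):
        raise IndexError(f"invalid segment bounds (u, v] = ({u}, {v}] for n = {n}")


class SegmentCostModel(ABC):
    """Contract: map 1-based segment bounds ``(u, v]`` to a real cost.

    Implementations are deterministic and expose ``n`` (series length) and
    ``min_seg_len`` (shortest admissible segment).  ``cost_batch`` computes
    the cost of ``(u, v]`` for a vector of ``u`` at fixed ``v`` — the inner
    kernel of the dynamic programs.
    """

    n: int
    min_seg_len: int = 1

    @abstractmethod
    def cost(self, u: int, v: int) -> float:
        """Cost of segment ``(u, v]``, ``0 <= u < v <= n``."""

    def cost_batch(self, us: np.ndarray, v: int) -> np.ndarray:
        """Vectorised ``cost(u, v)`` over candidate starts ``us``."""
        return np.array([self.cost(int(u), v) for u in us])


class EmpiricalDistributionCost(SegmentCostModel):
    """The K-quantile empirical-distribution cost (the ED in ED-PELT)."""

    def __init__(
        self,
        series: "TimeSeries | Sequence[float]",
        K: int | None = None,
        min_seg_len: int = 1,
    ):
        self.series = as_series(series)
        self.n = self.series.n
        self.K = default_K(self.n) if K is None else int(K)
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        self.min_seg_len = int(min_seg_len)
        self.grid = build_quantile_grid(self.series, self.K)
        self._factor = -2.0 * self.grid.c / self.K  # 2 log(2n-1) / K > 0

    def cost(self, u: int, v: int) -> float:
        return ed_segment_cost(self.grid, u, v)

    def cost_batch(self, us: np.ndarray, v: int) -> np.ndarray:
        w = self.grid._w
        length = (v - us).astype(float)
        F = (w[:, v][:, None] - w[:, us]) / length  # (K, m)
        ent = xlogy(F, F) + xlogy(1.0 - F, 1.0 - F)
        return self._factor * (-length) * ent.sum(axis=0)


class NMCDCost(SegmentCostModel):
    """Exact weighted empirical-CDF cost; O(n) per segment.

    Serves as the exact oracle for :class:`EmpiricalDistributionCost` and
    as the cost behind the Segment Neighbourhood (fixed-m) solver, with or
    without Cramér-von Mises screening of candidate changepoints.
    """

    def __init__(self, series: "TimeSeries | Sequence[float]", min_seg_len: int = 1):
        self.series = as_series(series)
        self.n = self.series.n
        self.min_seg_len = int(min_seg_len)
        x = self.series.values
        n = self.n
        self._thresholds = np.sort(x)  # the n order statistics
        t = np.arange(1, n + 1, dtype=float)
        self._weights = n / ((t - 0.5) * (n - t + 0.5))

    def cost(self, u: int, v: int) -> float:
        _check_bounds(u, v, self.n)
        seg = np.sort(self.series.values[u:v])
        length = v - u
        lt = np.searchsorted(seg, self._thresholds, side="left")
        le = np.searchsorted(seg, self._thresholds, side="right")
        F = (lt + 0.5 * (le - lt)) / length
        ent = xlogy(F, F) + xlogy(1.0 - F, 1.0 - F)
        return float(np.sum(self._weights * (-length) * ent))


class LinearTrendCost(SegmentCostModel):
    """Residual sum of squares of a per-segment line fit on absolute index.

    Prefix sums of ``x``, ``x^2`` and ``i*x`` give the closed-form OLS
    residual in O(1) per segment.  A segment of length 2 fits exactly
    (cost 0); length-1 segments are disallowed (``min_seg_len`` >= 2).
    """

    def __init__(self, series: "TimeSeries | Sequence[float]", min_seg_len: int = 2):
        if min_seg_len < 2:
            raise ValueError("linear trend cost requires min_seg_len >= 2")
        self.series = as_series(series)
        self.n = self.series.n
        self.min_seg_len = int(min_seg_len)
        x = self.series.values
        i = np.arange(1, self.n + 1, dtype=float)
        z = np.zeros(1)
        self._sy = np.concatenate([z, np.cumsum(x)])
        self._syy = np.concatenate([z, np.cumsum(x * x)])
        self._siy = np.concatenate([z, np.cumsum(i * x)])

    def cost(self, u: int, v: int) -> float:
        return float(self.cost_batch(np.asarray([u]), v)[0])

    def cost_batch(self, us: np.ndarray, v: int) -> np.ndarray:
        us = np.asarray(us)
        if np.any(us < 0) or v > self.n or np.any(v - us < 2):
            raise IndexError("linear trend cost needs 0 <= u <= v-2, v <= n")
        L = (v - us).astype(float)
        # sums of the index i over u+1..v and of i^2, closed form
        a, b = us + 1.0, float(v)
        Sx = (a + b) * L / 2.0
        Sxx = b * (b + 1.0) * (2.0 * b + 1.0) / 6.0 - (a - 1.0) * a * (2.0 * a - 1.0) / 6.0
        Sy = self._sy[v] - self._sy[us]
        Syy = self._syy[v] - self._syy[us]
        Sxy = self._siy[v] - self._siy[us]
        vx = Sxx - Sx * Sx / L
        cxy = Sxy - Sx * Sy / L
        rss = Syy - Sy * Sy / L - np.where(vx > 0, cxy * cxy / np.maximum(vx, 1e-300), 0.0)
        return np.maximum(rss, 0.0)
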