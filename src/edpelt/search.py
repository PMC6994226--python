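"""Exact segmentation solvers: PELT and Segment Neighbourhood.

``pelt`` minimises the penalised cost ``sum_i C(x_{tau_{i-1}+1 : tau_i}) +
m * xi`` jointly over the number ``m`` and positions of changepoints, via
the optimal-partitioning recursion with inequality pruning: once
``F(u) + C(u+1, v) >= F(v)`` the index ``u`` can never again be the
optimal last changepoint, because the costs here are superadditive
(splitting never increases unpenalised cost), so it is dropped from the
candidate set.  Pruning is exact — it never changes the optimum — and for
data whose number of changepoints grows with ``n`` it makes the solver
effectively linear time.

``segment_neighbourhood`` is the classical O(M n^2) dynamic program
returning the exact optimal segmentation for every fixed number of
changepoints ``m = 0..M``; combined with ``select_bic`` it reproduces the
penalised optimum and serves as an independent oracle for PELT.

Conventions: changepoints are 1-based last-indices of segments, so
``tau = (tau_1 < ... < tau_m)`` with ``0 < tau_i < n`` splits the data
into segments ``(tau_{i-1}, tau_i]``.  Ties in the inner argmin go to the
smallest candidate for cross-platform determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_models import SegmentCostModel

__all__ = ["Segmentation", "pelt", "segment_neighbourhood", "select_bic"]


@dataclass(frozen=True)
class Segmentation:
    """A segmentation of ``x_{1:n}`` into ``m + 1`` segments.

    ``tau`` holds the interior changepoints (last index of each segment
    but the final one); ``total_cost`` is the unpenalised sum of segment
    costs; ``penalty`` records the per-changepoint penalty used by the
    solver (``None`` for fixed-m results).
    """

    tau: tuple[int, ...]
    n: int
    total_cost: float
    segment_costs: tuple[float, ...]
    penalty: float | None = None

    def __post_init__(self) -> None:
        tau = tuple(int(t) for t in self.tau)
        if any(not 1 <= t <= self.n - 1 for t in tau):
            raise ValueError("changepoints must lie in [1, n-1]")
        if any(b <= a for a, b in zip(tau, tau[1:])):
            raise ValueError("changepoints must be strictly increasing")
        object.__setattr__(self, "tau", tau)

    @property
    def m(self) -> int:
        """Number of changepoints."""
        return len(self.tau)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each segment."""
        bounds = (0,) + self.tau + (self.n,)
        return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]

    def penalised_cost(self, xi: float) -> float:
        """``total_cost + m * xi`` — the score the solvers compare."""
        return self.total_cost + self.m * xi


def _finish(cost: SegmentCostModel, tau: tuple[int, ...], penalty: float | None) -> Segmentation:
    bounds = (0,) + tau + (cost.n,)
    seg_costs = tuple(cost.cost(a, b) for a, b in zip(bounds, bounds[1:]))
    return Segmentation(
        tau=tau,
        n=cost.n,
        total_cost=float(sum(seg_costs)),
        segment_costs=seg_costs,
        penalty=penalty,
    )


def pelt(
    cost: SegmentCostModel,
    penalty: float,
    min_seg_len: int | None = None,
    prune: bool = True,
) -> Segmentation:
    """Minimise the penalised segmentation cost exactly.

    Bookkeeping: ``F[0] = -penalty`` and ``F[v] = min_u F[u] + C(u+1, v) +
    penalty``, so a segmentation with ``m`` changepoints is charged exactly
    ``m * penalty`` relative to the unsplit series.  ``prune=False`` keeps
    every candidate (for verifying that pruning is exact).
    """
    n = cost.n
    msl = cost.min_seg_len if min_seg_len is None else int(min_seg_len)
    if msl < 1:
        raise ValueError("min_seg_len must be >= 1")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if n < 2 * msl:
        raise ValueError(f"series of length {n} cannot hold two segments of length {msl}")

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    back = np.zeros(n + 1, dtype=np.int64)
    cand: list[int] = [0]
    for v in range(msl, n + 1):
        u_new = v - msl
        if u_new >= msl:
            cand.append(u_new)
        us = np.asarray(cand, dtype=np.int64)
        vals = F[us] + cost.cost_batch(us, v) + penalty
        i = int(np.argmin(vals))  # first occurrence: smallest u wins ties
        F[v] = vals[i]
        back[v] = us[i]
        if prune:
            keep = vals - penalty < F[v]
            cand = [u for u, k in zip(cand, keep) if k]

    tau: list[int] = []
    v = n
    while v > 0:
        u = int(back[v])
        if u > 0:
            tau.append(u)
        v = u
    return _finish(cost, tuple(reversed(tau)), float(penalty))


def segment_neighbourhood(
    cost: SegmentCostModel,
    M: int,
    min_seg_len: int | None = None,
    candidates: "np.ndarray | list[int] | None" = None,
) -> list[Segmentation]:
    """Exact optimal segmentation for every ``m = 0..M`` changepoints.

    Returns a list indexed by ``m``; the unpenalised optimum ``Q(m)`` is
    non-increasing in ``m``.  ``candidates`` optionally restricts the
    admissible changepoint positions (the screened variant); positions 0
    and ``n`` are always admissible as outer boundaries.
    """
    n = cost.n
    msl = cost.min_seg_len if min_seg_len is None else int(min_seg_len)
    if M < 0:
        raise ValueError("M must be >= 0")
    if M > n // msl - 1:
        raise ValueError(f"M = {M} changepoints do not fit n = {n} with min_seg_len = {msl}")

    if candidates is None:
        pts = np.arange(0, n + 1, dtype=np.int64)
    else:
        inner = np.unique(np.asarray(candidates, dtype=np.int64))
        if inner.size and (inner.min() < 1 or inner.max() > n - 1):
            raise ValueError("candidate changepoints must lie in [1, n-1]")
        pts = np.concatenate([[0], inner, [n]])
    P = pts.size
    vend = np.searchsorted(pts, n)  # index of n in pts (last)

    # cost matrix over admissible (u, v) pairs, C[i, j] = cost(pts[i], pts[j]);
    # admissible starts for a given end form a prefix of the sorted pts
    C = np.full((P, P), np.inf)
    for j in range(1, P):
        v = int(pts[j])
        k = int(np.searchsorted(pts[:j], v - msl, side="right"))
        if k:
            C[:k, j] = cost.cost_batch(pts[:k], v)

    Q = np.full((M + 1, P), np.inf)  # Q[m, j]: best cost of x_{1:pts[j]} with m cps
    B = np.zeros((M + 1, P), dtype=np.int64)
    Q[0, :] = C[0, :]
    Q[0, 0] = 0.0
    for m in range(1, M + 1):
        for j in range(2, P):
            # the previous changepoint must be a real position (index >= 1)
            prev = Q[m - 1, 1:j] + C[1:j, j]
            i = int(np.argmin(prev)) + 1
            Q[m, j] = prev[i - 1]
            B[m, j] = i

    out: list[Segmentation] = []
    for m in range(M + 1):
        if not np.isfinite(Q[m, vend]):
            raise ValueError(f"no admissible segmentation with m = {m} changepoints")
        tau: list[int] = []
        j, mm = int(vend), m
        while mm > 0:
            j = int(B[mm, j])
            tau.append(int(pts[j]))
            mm -= 1
        out.append(_finish(cost, tuple(reversed(tau)), None))
    return out


def select_bic(segmentations: list[Segmentation], xi_n: float) -> Segmentation:
    """Pick ``argmin_m Q(m) + m * xi_n`` from fixed-m optima; ties -> smaller m."""
    if not segmentations:
        raise ValueError("no segmentations to select from")
    best = segmentations[0]
    for seg in segmentations[1:]:
        if seg.penalised_cost(xi_n) < best.penalised_cost(xi_n):
            best = seg
    return best
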