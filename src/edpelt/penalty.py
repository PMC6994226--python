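"""Penalty selection: a BIC-style default, CROPS and the elbow heuristic.

For a fixed penalty ``xi`` the penalised optimum is ``min_m Q(m) + m*xi``
with ``Q(m)`` the best unpenalised cost with ``m`` changepoints — a
piecewise-linear, concave envelope in ``xi``.  CROPS exploits this to
recover *every* optimal segmentation for ``xi`` in ``[xi_min, xi_max]``:
run the solver at the interval ends; whenever the optima at ``xi_a <
xi_b`` differ (``m_a > m_b``), the lines ``Q(m_a) + m_a xi`` and
``Q(m_b) + m_b xi`` cross at ``xi* = (Q(m_b) - Q(m_a)) / (m_a - m_b)``;
solving at ``xi*`` either certifies the boundary or reveals a new
segmentation, and each run after the first two reveals one, so at most
``m_min - m_max + 2`` solver runs are needed in total.

Choosing among the recovered segmentations is left to the user; the elbow
heuristic (largest discrete second difference of ``Q(m)``) is advisory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .cost_models import SegmentCostModel
from .search import Segmentation, pelt

__all__ = ["CropsResult", "crops", "elbow_curve", "suggest_elbow", "default_penalty"]


def default_penalty(n: int, p: float = 1.0) -> float:
    """SIC/BIC-style per-changepoint penalty, ``2 p log n`` (natural log).

    ``p`` plays the role of a per-segment parameter count; for the
    nonparametric cost there is no literal parameter count and ``p = 1``
    is the default operating point, exposed as a knob.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return 2.0 * p * math.log(n)


@dataclass(frozen=True)
class CropsResult:
    """All optimal segmentations over a penalty interval.

    ``intervals`` lists ``(xi_low, xi_high, segmentation)`` covering
    ``[xi_min, xi_max]`` without gaps, ordered by penalty with ``m``
    non-increasing; ``Qm`` maps each recovered ``m`` to its unpenalised
    optimal cost; ``runs`` counts solver invocations.
    """

    intervals: tuple[tuple[float, float, Segmentation], ...]
    runs: int
    Qm: dict[int, float]
    xi_min: float
    xi_max: float

    @property
    def segmentations(self) -> list[Segmentation]:
        """Distinct optimal segmentations, ordered by decreasing m."""
        return [seg for _, _, seg in self.intervals]

    def to_json(self, path=None) -> str:
        """Serialise intervals as a JSON list (optionally write to path)."""
        payload = [
            {
                "penalty_low": lo,
                "penalty_high": hi,
                "m": seg.m,
                "changepoints": list(seg.tau),
                "Q": seg.total_cost,
            }
            for lo, hi, seg in self.intervals
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def crops(
    cost: SegmentCostModel,
    xi_min: float,
    xi_max: float,
    min_seg_len: int | None = None,
) -> CropsResult:
    """Find every optimal segmentation for penalties in ``[xi_min, xi_max]``."""
    if not 0.0 <= xi_min < xi_max:
        raise ValueError("need 0 <= xi_min < xi_max")

    runs = 0

    def solve(xi: float) -> Segmentation:
        nonlocal runs
        runs += 1
        return pelt(cost, xi, min_seg_len=min_seg_len)

    s_lo = solve(xi_min)
    s_hi = solve(xi_max)
    resolved: list[tuple[float, float, Segmentation]] = []
    stack: list[tuple[float, Segmentation, float, Segmentation]] = [
        (xi_min, s_lo, xi_max, s_hi)
    ]
    while stack:
        xa, sa, xb, sb = stack.pop()
        if sa.m == sb.m:
            resolved.append((xa, xb, sa))
            continue
        # crossing of the two envelope lines; with adjacent m there is no
        # room for an intermediate optimum, so the boundary is certified
        # without another solver run
        x_star = (sb.total_cost - sa.total_cost) / (sa.m - sb.m)
        if sa.m == sb.m + 1:
            resolved.append((xa, x_star, sa))
            resolved.append((x_star, xb, sb))
            continue
        s_star = solve(x_star)
        improves = s_star.penalised_cost(x_star) < sa.penalised_cost(x_star) - 1e-9
        if improves and sb.m < s_star.m < sa.m:
            stack.append((xa, sa, x_star, s_star))
            stack.append((x_star, s_star, xb, sb))
        else:
            resolved.append((xa, x_star, sa))
            resolved.append((x_star, xb, sb))

    resolved.sort(key=lambda iv: iv[0])
    # merge adjacent intervals carrying the same segmentation, drop
    # zero-width artefacts at certified boundaries
    merged: list[tuple[float, float, Segmentation]] = []
    for lo, hi, seg in resolved:
        if hi - lo <= 0.0:
            continue
        if merged and merged[-1][2].m == seg.m:
            merged[-1] = (merged[-1][0], hi, merged[-1][2])
        else:
            merged.append((lo, hi, seg))
    Qm = {seg.m: seg.total_cost for _, _, seg in merged}
    return CropsResult(
        intervals=tuple(merged), runs=runs, Qm=Qm, xi_min=xi_min, xi_max=xi_max
    )


def elbow_curve(result: CropsResult) -> list[tuple[int, float]]:
    """Unpenalised cost ``Q(m)`` versus ``m``, sorted by m (non-increasing Q)."""
    if not result.intervals:
        raise ValueError("empty CROPS result")
    return sorted(result.Qm.items())


def suggest_elbow(curve: list[tuple[int, float]]) -> int | None:
    """Advisory elbow: the interior m maximising the discrete second difference.

    The elbow marks where adding changepoints stops buying much cost
    reduction; the choice is subjective and this suggestion is never
    applied automatically.  ``None`` if fewer than three points.
    """
    if len(curve) < 3:
        return None
    best_m, best_d2 = None, -math.inf
    for (m0, q0), (m1, q1), (m2, q2) in zip(curve, curve[1:], curve[2:]):
        # slopes per changepoint on either side of m1
        left = (q0 - q1) / (m1 - m0)
        right = (q1 - q2) / (m2 - m1)
        d2 = left - right
        if d2 > best_d2:
            best_m, best_d2 = m1, d2
    return best_m
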