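"""Candidate-changepoint screening via sliding-window Cramér-von Mises tests.

The screened variant of exact nonparametric changepoint detection slides a
window of length ``2 * N_I`` across the series and computes, at each centre
``v``, the two-sample Cramér-von Mises statistic between the ``N_I`` values
left of ``v`` (inclusive) and the ``N_I`` values right of it.  A centre is
retained as a candidate changepoint only if its statistic exceeds that of
every centre within ``N_I`` of it; the fixed-m search is then restricted to
the retained candidates.  Screening shrinks the search space dramatically
but can discard true changepoints — especially when ``N_I`` approaches the
shortest true segment — which is the accuracy cost this module exists to
study.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import cramervonmises_2samp

from .cost_models import TimeSeries, as_series

__all__ = ["default_window", "cvm_statistic", "cvm_screen"]


def default_window(n: int) -> int:
    """Default half-window, ``ceil((log n)^{3/2} / 2)`` (natural log).

    Grows slowly with ``n`` so that the window stays shorter than any
    segment one hopes to detect.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return int(math.ceil(math.log(n) ** 1.5 / 2.0))


def cvm_statistic(left: Sequence[float], right: Sequence[float]) -> float:
    """Two-sample Cramér-von Mises statistic (rank form on the pooled sample)."""
    return float(cramervonmises_2samp(left, right, method="asymptotic").statistic)


def cvm_screen(
    series: "TimeSeries | Sequence[float]",
    N_I: int | None = None,
    strict: bool = True,
) -> np.ndarray:
    """Retain local maxima of the sliding-window CvM statistic.

    Returns sorted candidate positions ``v`` in ``[N_I, n - N_I]`` (each
    the prospective last index of a left segment) whose statistic exceeds
    that of every other centre within distance ``N_I``.  With
    ``strict=True`` (default) a tied neighbour removes both candidates;
    ``strict=False`` keeps tied local maxima.
    """
    ts = as_series(series)
    n = ts.n
    if N_I is None:
        N_I = default_window(n)
    if N_I < 1:
        raise ValueError("N_I must be >= 1")
    if n < 2 * N_I:
        raise ValueError(f"window 2*{N_I} does not fit a series of length {n}")

    x = ts.values
    centres = np.arange(N_I, n - N_I + 1)
    stats = np.array(
        [cvm_statistic(x[v - N_I : v], x[v : v + N_I]) for v in centres]
    )
    keep = []
    for i, v in enumerate(centres):
        lo = max(0, i - N_I)
        neighbours = np.concatenate([stats[lo:i], stats[i + 1 : i + N_I + 1]])
        if neighbours.size == 0:
            keep.append(v)
        elif strict and stats[i] > neighbours.max():
            keep.append(v)
        elif not strict and stats[i] >= neighbours.max():
            keep.append(v)
    return np.asarray(keep, dtype=np.int64)
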