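"""Independent oracles used across the test suite.

Everything here is deliberately naive — direct transcription of the
definitions — and shares no code path with the package internals it
checks.
"""

import numpy as np


def brute_ed_cost(x, u, v, K):
    """ED segment cost recomputed per quantile from the raw slice."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    c = -np.log(2 * n - 1)
    seg = x[u:v]
    total = 0.0
    srt = np.sort(x)
    for k in range(1, K + 1):
        p = 1.0 / (1.0 + (2 * n - 1) * np.exp(c * (2 * k - 1) / K))
        t = srt[min(max(int(np.ceil(p * n)), 1), n) - 1]
        F = (np.sum(seg < t) + 0.5 * np.sum(seg == t)) / len(seg)
        if 0.0 < F < 1.0:
            total += -len(seg) * (F * np.log(F) + (1 - F) * np.log(1 - F))
    return (-2.0 * c / K) * total


def brute_nmcd_cost(x, u, v):
    """Exact weighted cost as a literal double loop over order statistics."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    seg = x[u:v]
    srt = np.sort(x)
    total = 0.0
    for t in range(1, n + 1):
        thr = srt[t - 1]
        F = (np.sum(seg < thr) + 0.5 * np.sum(seg == thr)) / len(seg)
        ll = 0.0
        if 0.0 < F < 1.0:
            ll = F * np.log(F) + (1 - F) * np.log(1 - F)
        total += n * len(seg) * (-ll) / ((t - 0.5) * (n - t + 0.5))
    return total


def cost_matrix(model, n, msl=1):
    """Dense (n+1)x(n+1) table of segment costs, inf where inadmissible."""
    C = np.full((n + 1, n + 1), np.inf)
    for u in range(n):
        for v in range(u + msl, n + 1):
            C[u, v] = model.cost(u, v)
    return C


def exhaustive_best(C, n, xi, msl=1):
    """Global minimum of the penalised cost over all segmentations.

    Depth-first enumeration of every admissible changepoint subset; the
    penalised score charges ``xi`` per segment (differs from the solver's
    per-changepoint bookkeeping by the constant ``xi``).
    """
    best = [np.inf, None]

    def rec(u, cuts, acc):
        for v in range(u + msl, n + 1):
            score = acc + C[u, v] + xi
            if v == n:
                if score < best[0]:
                    best[0] = score
                    best[1] = tuple(cuts)
            else:
                cuts.append(v)
                rec(v, cuts, score)
                cuts.pop()

    rec(0, [], 0.0)
    return best[0], best[1]
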