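"""Piecewise generators with known changepoints for the simulation study.

Three standard scenarios drive the Monte-Carlo evaluation, all of length
``n`` with changepoints at fixed fractions of ``n``:

* Model 1 — eleven changes in location only: a piecewise-constant mean
  (cumulative jumps ``h_j``) plus IID noise ``sigma * xi_i``.
* Model 2 — four changes in location and/or scale: the same construction
  with the noise scale multiplied cumulatively by ``v_j`` as each
  changepoint is passed (so some changes are scale-only, with ``h_j = 0``).
* Model 3 — three purely distributional changes: consecutive blocks drawn
  from the standard normal, the standardised chi-square with 3 df, the
  standardised chi-square with 1 df, and the standard normal again.  All
  four have mean 0 and variance 1, so nothing but shape changes.

Noise distributions for Models 1-2: standard normal, Student's t with 3 df
(raw, variance 3), and standardised chi-squares ``(chi2_v - v)/sqrt(2v)``.
The noise scale ``sigma`` defaults to 0.5 — jump sizes around 2 then sit
roughly four noise standard deviations apart under normal errors, the
operating point of the original study design this harness replicates.

Changepoints are reported as the 1-based last index of each segment:
observation ``i`` carries the mean/scale of the segment ``tau_{j-1} < i
<= tau_j``, so the jump happens strictly after ``tau_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cost_models import TimeSeries

__all__ = [
    "SimulationSpec",
    "MODEL1_TAU_FRAC",
    "MODEL1_JUMPS",
    "MODEL2_TAU_FRAC",
    "MODEL2_JUMPS",
    "MODEL2_SCALE_MULTS",
    "MODEL3_TAU_FRAC",
    "simulate",
    "simulate_model1",
    "simulate_model2",
    "simulate_model3",
    "simulate_piecewise",
]

MODEL1_TAU_FRAC = (0.1, 0.13, 0.15, 0.23, 0.25, 0.40, 0.44, 0.65, 0.76, 0.78, 0.81)
MODEL1_JUMPS = (2.01, -2.51, 1.51, -2.01, 2.51, -2.11, 1.05, 2.16, -1.56, 2.56, -2.11)

MODEL2_TAU_FRAC = (0.20, 0.40, 0.65, 0.85)
MODEL2_JUMPS = (3.0, 0.0, -2.0, 0.0)
MODEL2_SCALE_MULTS = (1.0, 5.0, 1.0, 0.25)

MODEL3_TAU_FRAC = (0.20, 0.50, 0.75)

ERROR_DISTS = ("normal", "t3", "chisq1_std", "chisq3_std")


def _draw_errors(dist: str, size: int, rng: np.random.Generator) -> np.ndarray:
    if dist == "normal":
        return rng.standard_normal(size)
    if dist == "t3":
        # raw t_3 (variance 3), deliberately not rescaled to unit variance
        return rng.standard_t(3, size)
    if dist == "chisq1_std":
        return (rng.chisquare(1, size) - 1.0) / np.sqrt(2.0)
    if dist == "chisq3_std":
        return (rng.chisquare(3, size) - 3.0) / np.sqrt(6.0)
    raise ValueError(f"unknown error distribution {dist!r}; choose from {ERROR_DISTS}")


def _integer_taus(n: int, tau_frac: Sequence[float]) -> np.ndarray:
    taus = np.rint(np.asarray(tau_frac, dtype=float) * n).astype(np.int64)
    if np.any(taus < 1) or np.any(taus > n - 1) or np.any(np.diff(taus) < 1):
        raise ValueError("n too small: changepoint fractions collapse or leave [1, n-1]")
    return taus


@dataclass(frozen=True)
class SimulationSpec:
    """A reproducible description of one simulated scenario.

    ``model_id`` 1-3 fixes the standard scenario (custom fields ignored
    except ``n``, noise and seed); ``"custom"`` uses ``tau_frac``/``jumps``
    (and optionally ``scale_mults``) with the generic generator.
    """

    model_id: "int | str" = 1
    n: int = 1000
    error_dist: str = "normal"
    sigma: float = 0.5
    seed: int | None = None
    tau_frac: tuple[float, ...] = ()
    jumps: tuple[float, ...] = ()
    scale_mults: tuple[float, ...] | None = None


def simulate(spec: SimulationSpec) -> tuple[TimeSeries, np.ndarray]:
    """Generate a series plus its true changepoints from a spec."""
    if spec.model_id == 1:
        return simulate_model1(spec.n, spec.error_dist, spec.sigma, spec.seed)
    if spec.model_id == 2:
        return simulate_model2(spec.n, spec.error_dist, spec.sigma, spec.seed)
    if spec.model_id == 3:
        return simulate_model3(spec.n, spec.seed)
    if spec.model_id == "custom":
        return simulate_piecewise(
            spec.n, spec.tau_frac, spec.jumps, spec.error_dist, spec.sigma,
            spec.seed, scale_mults=spec.scale_mults,
        )
    raise ValueError(f"unknown model_id {spec.model_id!r}")


def simulate_piecewise(
    n: int,
    tau_frac: Sequence[float],
    jumps: Sequence[float],
    error_dist: str = "normal",
    sigma: float = 0.5,
    seed: int | None = None,
    scale_mults: Sequence[float] | None = None,
) -> tuple[TimeSeries, np.ndarray]:
    """Generic piecewise location(/scale) generator.

    ``x_i = sum_j h_j 1{i > tau_j} + sigma * xi_i * prod_{j: tau_j < i} v_j``
    with ``tau_j = round(n * tau_frac_j)``.  Returns the series and the
    integer changepoints.
    """
    tau_frac = tuple(tau_frac)
    jumps = tuple(jumps)
    if len(jumps) != len(tau_frac):
        raise ValueError("need one jump per changepoint fraction")
    if any(not 0.0 < f < 1.0 for f in tau_frac) or any(
        b <= a for a, b in zip(tau_frac, tau_frac[1:])
    ):
        raise ValueError("tau_frac must be strictly increasing within (0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    taus = _integer_taus(n, tau_frac)
    i = np.arange(1, n + 1)
    # segment index s(i) = number of changepoints strictly before i
    s = np.searchsorted(taus, i, side="left")
    mean = np.concatenate([[0.0], np.cumsum(jumps)])[s]
    scale = np.full(n, sigma)
    if scale_mults is not None:
        mults = np.asarray(scale_mults, dtype=float)
        if mults.size != taus.size or np.any(mults <= 0):
            raise ValueError("scale_mults must be positive, one per changepoint")
        scale = sigma * np.concatenate([[1.0], np.cumprod(mults)])[s]
    x = mean + scale * _draw_errors(error_dist, n, rng)
    return TimeSeries(x), taus


def simulate_model1(
    n: int = 1000,
    error_dist: str = "normal",
    sigma: float = 0.5,
    seed: int | None = None,
) -> tuple[TimeSeries, np.ndarray]:
    """Model 1: eleven location shifts (jumps ~2-2.6 in size)."""
    if n < 100:
        raise ValueError("Model 1 needs n >= 100 to keep its 11 changepoints distinct")
    return simulate_piecewise(n, MODEL1_TAU_FRAC, MODEL1_JUMPS, error_dist, sigma, seed)


def simulate_model2(
    n: int = 1000,
    error_dist: str = "normal",
    sigma: float = 0.5,
    seed: int | None = None,
) -> tuple[TimeSeries, np.ndarray]:
    """Model 2: four changes mixing location shifts and scale multipliers."""
    if n < 100:
        raise ValueError("Model 2 needs n >= 100")
    return simulate_piecewise(
        n, MODEL2_TAU_FRAC, MODEL2_JUMPS, error_dist, sigma, seed,
        scale_mults=MODEL2_SCALE_MULTS,
    )


def simulate_model3(
    n: int = 1000, seed: int | None = None
) -> tuple[TimeSeries, np.ndarray]:
    """Model 3: purely distributional changes at mean 0, variance 1.

    Segments: standard normal | standardised chi2(3) | standardised
    chi2(1) | standard normal.  Changes live in skewness and kurtosis.
    """
    if n < 100:
        raise ValueError("Model 3 needs n >= 100")
    rng = np.random.default_rng(seed)
    taus = _integer_taus(n, MODEL3_TAU_FRAC)
    bounds = [0, *taus.tolist(), n]
    dists = ("normal", "chisq3_std", "chisq1_std", "normal")
    parts = [
        _draw_errors(d, b - a, rng) for d, a, b in zip(dists, bounds, bounds[1:])
    ]
    return TimeSeries(np.concatenate(parts)), taus
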