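"""The Resistance statistic R: percent of binding signal surviving a perturbation.

Three fitted binding curves enter: a reference (e.g. vehicle/DMSO), a
perturbed condition (drug added, or a binding-site mutation), and a
non-binding collision control (e.g. the Bad4E mutant) whose FRET reflects
random encounters rather than binding.  All three are interpolated at a
fixed acceptor:donor intensity ratio — 0.5 for Bcl-XL complexes, 0.25 for
Bcl-2 complexes, chosen where the assay's dynamic range is largest — giving
efficiencies A (reference), B (perturbed) and C (background).  Then

    R = 100 * (B - C) / (A - C)

R ~ 0 means the perturbation reduced binding to the collision background;
R ~ 100 means the complex fully resisted displacement.  R is reported
unclamped (sampling noise and genuine affinity increases can push it past
100) with a parametric-bootstrap 95% CI that propagates the parameter
covariance of all three fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binding import HILL_BOUNDS, HillFit, LinearFit, _prediction_gradient
from .exceptions import ConfigurationError, UndefinedResistanceError

__all__ = [
    "ResistanceResult",
    "resistance_statistic",
    "default_interpolation_ratio",
    "resistance_ci",
]

#: Default interpolation ratios per anti-apoptotic target protein.
INTERPOLATION_RATIOS = {"BclXL": 0.5, "Bcl2": 0.25}

MIN_SIGNAL_OVER_BACKGROUND = 0.5  # E% units; below this R is undefined


@dataclass
class ResistanceResult:
    """R (%) with 95% CI and the three interpolated efficiencies behind it."""

    r_percent: float
    ci95: tuple[float, float]
    ratio_used: float
    components: tuple[float, float, float]  # (A reference, B perturbed, C background)

    def to_dict(self) -> dict:
        return {
            "r_percent": self.r_percent,
            "ci95": list(self.ci95),
            "ratio_used": self.ratio_used,
            "components": {
                "A_reference": self.components[0],
                "B_perturbed": self.components[1],
                "C_background": self.components[2],
            },
        }


def default_interpolation_ratio(target: str, ratio: float | None = None) -> float:
    """Interpolation ratio by target: Bcl-XL -> 0.5, Bcl-2 -> 0.25.

    ``target="custom"`` requires an explicit ``ratio``.
    """
    if target in INTERPOLATION_RATIOS:
        return INTERPOLATION_RATIOS[target]
    if target == "custom":
        if ratio is None or ratio <= 0:
            raise ConfigurationError("custom target requires an explicit positive ratio")
        return float(ratio)
    raise ConfigurationError(
        f"unknown target {target!r}; expected one of {sorted(INTERPOLATION_RATIOS)} or 'custom'"
    )


def _point_r(a: float, b: float, c: float) -> float:
    return 100.0 * (b - c) / (a - c)


def resistance_statistic(
    reference: HillFit,
    perturbed: HillFit,
    background: HillFit | LinearFit,
    ratio: float,
    n_draws: int = 2000,
    seed: int = 0,
) -> ResistanceResult:
    """Compute R = 100*(B-C)/(A-C) at the given ratio, with a bootstrap CI."""
    if ratio <= 0:
        raise ConfigurationError(f"ratio must be > 0, got {ratio}")
    a = float(reference.predict(ratio))
    b = float(perturbed.predict(ratio))
    c = float(background.predict(ratio))
    if a - c <= MIN_SIGNAL_OVER_BACKGROUND:
        raise UndefinedResistanceError(
            f"reference efficiency ({a:.3f}%) indistinguishable from background ({c:.3f}%)"
        )
    r = _point_r(a, b, c)
    ci = resistance_ci(reference, perturbed, background, ratio, n_draws=n_draws, seed=seed)
    return ResistanceResult(r_percent=r, ci95=ci, ratio_used=float(ratio), components=(a, b, c))


def _draw_params(fit, n: int, rng: np.random.Generator) -> np.ndarray:
    """MVN parameter draws honoring the fit's bounds, by redraw (10x oversampling)."""
    mean = fit.params.astype(float)
    cov = np.asarray(fit.covariance, dtype=float)
    if not np.any(cov):
        return np.tile(mean, (n, 1))
    draws = rng.multivariate_normal(mean, cov, size=10 * n, method="svd")
    if isinstance(fit, HillFit):
        lo, hi = HILL_BOUNDS
        ok = np.all((draws > lo) & (draws <= hi), axis=1)
        draws = draws[ok]
    if len(draws) < n:  # fall back to the point estimate for the shortfall
        pad = np.tile(mean, (n - len(draws), 1))
        draws = np.vstack([draws, pad])
    return draws[:n]


def resistance_ci(
    reference: HillFit,
    perturbed: HillFit,
    background: HillFit | LinearFit,
    ratio: float,
    n_draws: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap 95% CI for R.

    Parameter vectors are drawn from each fit's multivariate normal (mean =
    estimates, covariance = fit covariance), R recomputed per draw, and the
    2.5/97.5 percentiles returned.  Uncertainty from all three curves is
    propagated.  Singular covariances trigger a delta-method fallback.
    """
    rng = np.random.default_rng(seed)
    fits = (reference, perturbed, background)
    covs = [np.asarray(f.covariance, dtype=float) for f in fits]
    for f, cov in zip(fits, covs):
        if cov.shape != (len(f.params), len(f.params)) or not np.all(np.isfinite(cov)):
            import warnings

            warnings.warn("singular or invalid covariance; using delta-method CI", stacklevel=2)
            return _delta_ci(reference, perturbed, background, ratio)

    draws = [_draw_params(f, n_draws, rng) for f in fits]
    a = np.array([reference.predict_from(p, ratio) for p in draws[0]])
    b = np.array([perturbed.predict_from(p, ratio) for p in draws[1]])
    c = np.array([background.predict_from(p, ratio) for p in draws[2]])
    denom = a - c
    r = np.where(np.abs(denom) > 1e-12, 100.0 * (b - c) / denom, np.nan)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return _delta_ci(reference, perturbed, background, ratio)
    lo, hi = np.percentile(r, [2.5, 97.5])
    return float(lo), float(hi)


def _delta_ci(reference, perturbed, background, ratio) -> tuple[float, float]:
    """First-order (delta-method) CI for R from the three fit covariances."""
    a = float(reference.predict(ratio))
    b = float(perturbed.predict(ratio))
    c = float(background.predict(ratio))
    denom = a - c
    r = _point_r(a, b, c)
    # dR/dA, dR/dB, dR/dC
    dA = -100.0 * (b - c) / denom**2
    dB = 100.0 / denom
    dC = 100.0 * (b - a) / denom**2
    var = 0.0
    for fit, dR in ((reference, dA), (perturbed, dB), (background, dC)):
        cov = np.asarray(fit.covariance, dtype=float)
        if cov.size and np.all(np.isfinite(cov)):
            g = _prediction_gradient(fit, ratio)
            var += dR**2 * float(g @ cov @ g)
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return r - half, r + half
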