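"""Cell-free FRET titration and quenching analysis.

For purified, dye-labelled protein pairs, FRET efficiency is measured as the
fractional loss of donor fluorescence in the presence of the labelled versus
unlabelled acceptor protein:

    E% = (1 - F_labeled / F_unlabeled) * 100

Displacement of a bound BH3 protein by a titrated inhibitor is expressed as
fraction bound = F / F_max * 100 (F_max the saturated, drug-free efficiency)
and fitted to a four-parameter logistic dose-response curve with a Hill
slope; for poorly displaced proteins the bottom plateau may be constrained
to 0 (complete displacement assumed at infinite drug).

Solvent accessibility of site-specifically attached NBD dye is quantified by
iodide quenching with the collisional Stern-Volmer model F0/F = 1 + Ksv*[Q];
smaller Ksv means the probe is shielded from the aqueous quencher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    FitFailureError,
    FlatResponseError,
    InsufficientDataError,
    ParameterError,
)
from .synthgen import QuenchSeries, four_pl

__all__ = [
    "DoseResponseFit",
    "SternVolmerFit",
    "fret_efficiency",
    "fraction_bound",
    "fit_dose_response",
    "fit_stern_volmer",
]


def fret_efficiency(f_labeled, f_unlabeled):
    """E% = (1 - F_labeled/F_unlabeled) * 100; negatives allowed with a warning."""
    f_l = np.asarray(f_labeled, dtype=float)
    f_u = np.asarray(f_unlabeled, dtype=float)
    if np.any(f_u <= 0):
        raise ParameterError("f_unlabeled must be > 0")
    e = (1.0 - f_l / f_u) * 100.0
    if np.any(np.asarray(e) < 0):
        warnings.warn("negative FRET efficiency (labeled brighter than unlabeled)", stacklevel=2)
    return e if e.ndim else float(e)


def fraction_bound(efficiency, f_max: float):
    """Percent bound = E / E_max * 100 relative to the saturated efficiency."""
    if f_max <= 0:
        raise ParameterError(f"f_max must be > 0, got {f_max}")
    e = np.asarray(efficiency, dtype=float)
    out = e / f_max * 100.0
    return out if out.ndim else float(out)


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit on log-concentration."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    covariance: np.ndarray          # 4x4 over (ic50, hill, top, bottom)
    bottom_fixed: bool = False
    residual_dof: int = 0
    metadata: dict = field(default_factory=dict)

    def predict(self, conc):
        return four_pl(conc, self.ic50, self.hill_slope, self.top, self.bottom)

    def to_dict(self) -> dict:
        return {
            "model": "dose_response_4pl",
            "ic50": self.ic50,
            "hill_slope": self.hill_slope,
            "top": self.top,
            "bottom": self.bottom,
            "bottom_fixed": self.bottom_fixed,
            "covariance": np.asarray(self.covariance).tolist(),
            "residual_dof": self.residual_dof,
            "metadata": self.metadata,
        }


def _dr_model(theta, conc, bottom_fixed):
    """theta = (log10_ic50, hill, top[, bottom]); fit runs on log10(IC50)."""
    ic50 = 10.0 ** theta[0]
    bottom = 0.0 if bottom_fixed else theta[3]
    return four_pl(conc, ic50, theta[1], theta[2], bottom)


def fit_dose_response(
    conc,
    response,
    constrain_bottom_zero: bool = False,
    orientation: str | None = None,
) -> DoseResponseFit:
    """Fit a four-parameter logistic dose-response curve.

    IC50 is parameterized as log10(IC50) during optimization; zero
    concentrations are legitimate anchor points handled through the model's
    asymptote rather than log-transformed.  Orientation (inhibitor:
    decreasing, hill > 0; agonist: increasing, hill < 0) is inferred from
    the data by multistart over both signs unless forced via ``orientation``
    in {"inhibitor", "agonist"}.  The reported covariance is on the natural
    (ic50, hill, top, bottom) scale.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.shape != y.shape:
        raise ParameterError("conc and response must have the same length")
    if len(c) < 5:
        raise InsufficientDataError(f"need >= 5 points for a dose-response fit, got {len(c)}")
    if len(np.unique(c[c > 0])) < 3:
        raise InsufficientDataError("need >= 3 distinct positive concentrations")
    if np.any(c < 0):
        raise ParameterError("concentrations must be nonnegative")
    span = float(y.max() - y.min())
    noise_scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * noise_scale:
        raise FlatResponseError("responses are flat; IC50 unidentifiable")

    pos = c > 0
    log_mid = float(np.median(np.log10(c[pos])))
    top0, bot0 = float(y.max()), float(y.min())
    hill_signs = {"inhibitor": [1.0], "agonist": [-1.0], None: [1.0, -1.0]}[orientation]

    n_par = 3 if constrain_bottom_zero else 4
    best, diagnostics = None, []
    for sign in hill_signs:
        for h0 in (0.5, 1.0, 2.0):
            theta0 = [log_mid, sign * h0, top0] + ([] if constrain_bottom_zero else [bot0])
            lo = [log_mid - 6, -10, -np.inf] + ([] if constrain_bottom_zero else [-np.inf])
            hi = [log_mid + 6, 10, np.inf] + ([] if constrain_bottom_zero else [np.inf])
            try:
                sol = optimize.least_squares(
                    lambda t: _dr_model(t, c, constrain_bottom_zero) - y,
                    theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception as exc:
                diagnostics.append({"start": theta0, "error": str(exc)})
                continue
            diagnostics.append({"start": theta0, "cost": sol.cost, "success": bool(sol.success)})
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitFailureError("dose-response fit failed from all starts", {"starts": diagnostics})

    theta = best.x
    ic50 = 10.0 ** theta[0]
    hill = float(theta[1])
    top = float(theta[2])
    bottom = 0.0 if constrain_bottom_zero else float(theta[3])
    # the 4PL is invariant under (hill, top, bottom) -> (-hill, bottom, top);
    # report the canonical orientation with top >= bottom
    if not constrain_bottom_zero and top < bottom:
        top, bottom, hill = bottom, top, -hill
    dof = len(c) - n_par

    # covariance on the natural scale via a numerical Jacobian at the solution
    nat = np.array([ic50, hill, top, bottom])
    free = [0, 1, 2] if constrain_bottom_zero else [0, 1, 2, 3]

    def nat_model(p):
        return four_pl(c, p[0], p[1], p[2], p[3])

    J = np.zeros((len(c), len(free)))
    for k, i in enumerate(free):
        step = 1e-6 * max(abs(nat[i]), 1e-3)
        hi_p, lo_p = nat.copy(), nat.copy()
        hi_p[i] += step
        lo_p[i] -= step
        J[:, k] = (nat_model(hi_p) - nat_model(lo_p)) / (2 * step)
    resid = nat_model(nat) - y
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    try:
        core = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        core = s2 * np.linalg.pinv(J.T @ J)
    cov = np.zeros((4, 4))
    for k, i in enumerate(free):
        for m, j in enumerate(free):
            cov[i, j] = core[k, m]

    return DoseResponseFit(
        ic50=float(ic50), hill_slope=hill, top=top, bottom=bottom,
        covariance=cov, bottom_fixed=constrain_bottom_zero, residual_dof=dof,
        metadata={"sse": float(2 * best.cost), "orientation_forced": orientation},
    )


@dataclass
class SternVolmerFit:
    """Linear Stern-Volmer fit: F0/F = intercept + Ksv * [Q]."""

    ksv: float                      # per M
    intercept: float                # ~1 expected for pure collisional quenching
    ci95_ksv: tuple[float, float]
    r_squared: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": "stern_volmer",
            "ksv": self.ksv,
            "intercept": self.intercept,
            "ci95_ksv": list(self.ci95_ksv),
            "r_squared": self.r_squared,
            "metadata": self.metadata,
        }


def fit_stern_volmer(quench: QuenchSeries) -> SternVolmerFit:
    """OLS of F0/F on quencher concentration; Ksv is the slope.

    F0 is the fluorescence at zero quencher from the same series; if no zero
    point exists, the smallest-concentration point is used with a warning.
    The 95% CI on Ksv uses the t distribution on the slope standard error.
    The intercept is left free as a diagnostic (≈1 for pure collisional
    quenching).
    """
    c = np.asarray(quench.quencher_conc, dtype=float)
    f = np.asarray(quench.fluorescence, dtype=float)
    if len(c) < 3:
        raise InsufficientDataError(f"need >= 3 quencher concentrations, got {len(c)}")
    if np.any(f <= 0):
        raise ParameterError("fluorescence values must be positive")

    zero = c == 0
    if zero.any():
        f0 = float(f[zero].mean())
    else:
        i_min = int(np.argmin(c))
        f0 = float(f[i_min])
        warnings.warn(
            "no zero-quencher point; using the smallest-concentration point as F0",
            stacklevel=2,
        )

    y = f0 / f
    res = stats.linregress(c, y)
    dof = len(c) - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return SternVolmerFit(
        ksv=float(res.slope), intercept=float(res.intercept),
        ci95_ksv=(float(ci[0]), float(ci[1])), r_squared=float(res.rvalue**2),
        metadata={"f0": f0, "n_points": len(c), "regression": "F0/F on [Q]"},
    )
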