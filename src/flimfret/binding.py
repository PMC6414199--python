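"""FLIM-FRET binding-curve construction and fitting.

Per-ROI FRET efficiency is E% = (1 - tau_i/tau0) * 100, where tau_i is the
ROI's mean donor lifetime and tau0 the donor-only reference.  Efficiencies
are binned by acceptor:donor intensity ratio with variable bin widths (0.1
below ratio 0.5, 0.25 between 0.5 and 1.25, 0.5 above), an exact zero bin
for donor-only ROIs, and a minimum occupancy per bin.  Bin means are fitted
to a Hill-saturation curve E% = Emax * r^h / (Kd^h + r^h) for binding
conditions, or to a straight line for collision-only controls (collisional
FRET scales linearly with concentration and does not saturate).

Negative efficiencies (lifetime noise pushing tau_i above tau0) are retained
throughout; clamping them would bias low-ratio bins upward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FitFailureError, InsufficientDataError, ParameterError
from .synthgen import hill_efficiency

__all__ = [
    "QCThresholds",
    "BinnedPoint",
    "HillFit",
    "LinearFit",
    "qc_filter_rois",
    "compute_efficiency",
    "ratio_bin_edges",
    "bin_by_ratio",
    "fit_hill",
    "fit_collision_baseline",
    "predict_with_ci",
]

MIN_ROIS_PER_BIN = 20


@dataclass(frozen=True)
class QCThresholds:
    """Intensity cutoffs for discarding noisy or saturated ROIs."""

    donor_min: float
    donor_saturation: float
    acceptor_saturation: float

    def __post_init__(self):
        if not self.donor_min < self.donor_saturation:
            raise ParameterError(
                f"donor_min ({self.donor_min}) must be < donor_saturation ({self.donor_saturation})"
            )

    @classmethod
    def from_percentiles(cls, rois: pd.DataFrame, low: float = 1.0, high: float = 99.0):
        """Default thresholds: 1st/99th percentiles of the pooled dataset."""
        d = rois["donor_intensity"].to_numpy(float)
        a = rois["acceptor_intensity"].to_numpy(float)
        return cls(
            donor_min=float(np.percentile(d, low)),
            donor_saturation=float(np.percentile(d, high)),
            acceptor_saturation=float(np.percentile(a, high)),
        )


def qc_filter_rois(
    rois: pd.DataFrame, thresholds: QCThresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard ROIs whose donor signal is too low/saturated or acceptor saturated.

    Returns ``(kept, rejection_log)``; the log has the rejected rows' indices
    and one reason code each (``donor_low``, ``donor_saturated``,
    ``acceptor_saturated`` — checked in that order).
    """
    if rois.empty:
        warnings.warn("qc_filter_rois: empty ROI table", stacklevel=2)
        return rois.copy(), pd.DataFrame(columns=["roi_index", "reason"])
    d = rois["donor_intensity"].to_numpy(float)
    a = rois["acceptor_intensity"].to_numpy(float)
    reason = np.full(len(rois), "", dtype=object)
    reason[a >= thresholds.acceptor_saturation] = "acceptor_saturated"
    reason[d >= thresholds.donor_saturation] = "donor_saturated"
    reason[d < thresholds.donor_min] = "donor_low"
    bad = reason != ""
    log = pd.DataFrame({"roi_index": rois.index[bad], "reason": reason[bad]})
    return rois.loc[~bad].copy(), log


def compute_efficiency(mean_lifetime_ns, tau0: float):
    """FRET efficiency E% = (1 - tau_i/tau0) * 100; negatives are kept."""
    if tau0 <= 0:
        raise ParameterError(f"tau0 must be > 0, got {tau0}")
    tau = np.asarray(mean_lifetime_ns, dtype=float)
    e = (1.0 - tau / tau0) * 100.0
    return e if e.ndim else float(e)


def ratio_bin_edges(max_ratio: float) -> np.ndarray:
    """Variable-width ratio bin edges: 0.1 to 0.5, 0.25 to 1.25, 0.5 beyond.

    Edges are 0, 0.1, ..., 0.5, 0.75, 1.0, 1.25, 1.75, 2.25, ... continuing
    at width 0.5 until ``max_ratio`` is covered.
    """
    edges = list(np.round(np.arange(0.0, 0.5, 0.1), 10)) + [0.5, 0.75, 1.0, 1.25]
    while edges[-1] <= max_ratio:
        edges.append(round(edges[-1] + 0.5, 10))
    return np.asarray(edges)


@dataclass
class BinnedPoint:
    """One ratio bin's summary: mean efficiency ± SEM over its ROIs."""

    ratio_low: float
    ratio_high: float
    ratio_mid: float
    mean_e: float
    sem_e: float
    n_roi: int


def bin_by_ratio(
    ratio, e_percent, min_per_bin: int = MIN_ROIS_PER_BIN
) -> list[BinnedPoint]:
    """Bin per-ROI efficiencies by intensity ratio.

    The first bin holds exactly ratio == 0 (donor-only ROIs); positive ratios
    fall into half-open [low, high) intervals from :func:`ratio_bin_edges`.
    Bins with fewer than ``min_per_bin`` ROIs are dropped.  ``ratio_mid`` is
    the mean observed ratio within the bin, not the geometric midpoint: with
    wide bins and a right-skewed ratio distribution the midpoint sits above
    where the ROIs actually are, which would bias the downstream curve fit.
    """
    r = np.asarray(ratio, dtype=float)
    e = np.asarray(e_percent, dtype=float)
    if r.shape != e.shape:
        raise ParameterError("ratio and e_percent must have the same length")
    if r.size == 0:
        return []
    if np.any(r < 0):
        raise ParameterError("ratios must be nonnegative")

    out: list[BinnedPoint] = []

    def summarize(vals, rvals, lo, hi):
        n = len(vals)
        if n < min_per_bin:
            return
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        mid = float(np.mean(rvals)) if n else 0.0
        out.append(BinnedPoint(lo, hi, mid, float(np.mean(vals)), sem, n))

    zero = r == 0
    summarize(e[zero], r[zero], 0.0, 0.0)

    pos_r, pos_e = r[~zero], e[~zero]
    if pos_r.size:
        edges = ratio_bin_edges(float(pos_r.max()))
        idx = np.digitize(pos_r, edges) - 1  # half-open [low, high)
        idx = np.clip(idx, 0, len(edges) - 2)
        for i in range(len(edges) - 1):
            sel = idx == i
            if sel.any():
                summarize(pos_e[sel], pos_r[sel], float(edges[i]), float(edges[i + 1]))
    return out


@dataclass
class HillFit:
    """Hill-saturation fit (Emax %, Kd in ratio units, Hill slope h)."""

    emax: float
    kd: float
    h: float
    covariance: np.ndarray
    residual_dof: int
    fit_domain: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.emax, self.kd, self.h])

    def predict(self, ratio):
        return hill_efficiency(ratio, self.emax, self.kd, self.h)

    def predict_from(self, params, ratio):
        return hill_efficiency(ratio, *params)

    def to_dict(self) -> dict:
        return {
            "model": "hill",
            "emax": self.emax,
            "kd": self.kd,
            "h": self.h,
            "covariance": np.asarray(self.covariance).tolist(),
            "residual_dof": self.residual_dof,
            "fit_domain": list(self.fit_domain),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillFit":
        return cls(
            emax=d["emax"], kd=d["kd"], h=d["h"],
            covariance=np.asarray(d["covariance"], dtype=float),
            residual_dof=int(d["residual_dof"]),
            fit_domain=tuple(d["fit_domain"]),
            metadata=d.get("metadata", {}),
        )


@dataclass
class LinearFit:
    """Straight-line fit E% = slope * ratio + intercept (collision baseline)."""

    slope: float
    intercept: float
    covariance: np.ndarray
    residual_dof: int = 0
    fit_domain: tuple[float, float] = (0.0, np.inf)
    metadata: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.slope, self.intercept])

    def predict(self, ratio):
        r = np.asarray(ratio, dtype=float)
        out = self.slope * r + self.intercept
        return out if out.ndim else float(out)

    def predict_from(self, params, ratio):
        r = np.asarray(ratio, dtype=float)
        out = params[0] * r + params[1]
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "model": "linear",
            "slope": self.slope,
            "intercept": self.intercept,
            "covariance": np.asarray(self.covariance).tolist(),
            "residual_dof": self.residual_dof,
            "fit_domain": list(self.fit_domain),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearFit":
        return cls(
            slope=d["slope"], intercept=d["intercept"],
            covariance=np.asarray(d["covariance"], dtype=float),
            residual_dof=int(d.get("residual_dof", 0)),
            fit_domain=tuple(d.get("fit_domain", (0.0, np.inf))),
            metadata=d.get("metadata", {}),
        )


# parameter bounds for the Hill fit: Emax in (0, 100], Kd > 0, h in (0, 10]
HILL_BOUNDS = (np.array([1e-9, 1e-9, 1e-9]), np.array([100.0, np.inf, 10.0]))


def _hill_starts(r: np.ndarray, e: np.ndarray) -> list[np.ndarray]:
    emax0 = max(float(e.max()), 1.0)
    half = emax0 / 2.0
    above = e >= half
    kd0 = float(np.interp(half, np.sort(e), r[np.argsort(e)])) if above.any() else float(np.median(r))
    kd0 = min(max(kd0, 1e-3), 10 * r.max())
    return [np.array([emax0, kd0, h0]) for h0 in (0.5, 1.0, 2.0, 4.0)]


def fit_hill(binned: list[BinnedPoint], weighted: bool = False) -> HillFit:
    """Least-squares Hill fit to bin mean efficiencies.

    The zero-ratio bin is excluded (the model is identically 0 there, and the
    bin exists to anchor the donor-only reference, not the curve).  Fitting is
    unweighted by default — the bin means, not the raw ROIs, are the fitted
    observations; set ``weighted=True`` for inverse-SEM^2 weighting.
    Multistart over Hill-slope initial values guards against local minima.

    The parameter covariance accounts for the unequal precision of the bin
    means: when every bin carries a positive SEM, a heteroscedastic sandwich
    covariance (J'J)^-1 J' diag(SEM^2) J (J'J)^-1 is used, so bins averaging
    thousands of ROIs and bins near the 20-ROI floor contribute their actual
    uncertainty.  Without SEMs the homoscedastic residual-based covariance
    s^2 (J'J)^-1 is the fallback.
    """
    pts = [b for b in binned if b.ratio_mid > 0]
    if len(pts) < 4:
        raise InsufficientDataError(f"need >= 4 positive-ratio bins for a Hill fit, got {len(pts)}")
    r = np.array([b.ratio_mid for b in pts])
    e = np.array([b.mean_e for b in pts])
    w = np.ones_like(e)
    if weighted:
        sems = np.array([max(b.sem_e, 1e-6) for b in pts])
        w = 1.0 / sems

    def resid(p):
        return w * (hill_efficiency(r, *p) - e)

    best = None
    diagnostics = []
    for p0 in _hill_starts(r, e):
        try:
            sol = optimize.least_squares(resid, p0, bounds=HILL_BOUNDS, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - scipy raises rarely here
            diagnostics.append({"start": p0.tolist(), "error": str(exc)})
            continue
        diagnostics.append({"start": p0.tolist(), "cost": sol.cost, "success": bool(sol.success)})
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("Hill fit failed to converge from all starts", {"starts": diagnostics})

    dof = len(pts) - 3
    sems = np.array([b.sem_e for b in pts])
    if np.all(sems > 0) and not weighted:
        cov = _sandwich_covariance(best.jac, sems)
    else:
        cov = _covariance_from_jacobian(best.jac, best.fun, dof)
    emax, kd, h = best.x
    return HillFit(
        emax=float(emax), kd=float(kd), h=float(h), covariance=cov,
        residual_dof=dof, fit_domain=(float(r.min()), float(r.max())),
        metadata={
            "weighted": weighted,
            "n_bins": len(pts),
            "bounds": {"emax": [0, 100], "kd": [0, None], "h": [0, 10]},
            "sse": float(2 * best.cost),
        },
    )


def _sandwich_covariance(jac: np.ndarray, sems: np.ndarray) -> np.ndarray:
    """Heteroscedastic covariance for an unweighted fit with known point SEMs."""
    jtj_inv = np.linalg.pinv(jac.T @ jac)
    meat = jac.T @ (sems[:, None] ** 2 * jac)
    return jtj_inv @ meat @ jtj_inv


def _covariance_from_jacobian(jac: np.ndarray, resid: np.ndarray, dof: int) -> np.ndarray:
    """Gauss-Newton covariance: s^2 (J'J)^-1 with s^2 = SSE/dof."""
    jtj = jac.T @ jac
    try:
        inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(jtj)
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    return s2 * inv


def fit_collision_baseline(binned: list[BinnedPoint]) -> LinearFit:
    """OLS of bin mean efficiency on ratio midpoint, free intercept."""
    if len(binned) < 3:
        raise InsufficientDataError(f"need >= 3 bins for a collision baseline, got {len(binned)}")
    r = np.array([b.ratio_mid for b in binned])
    e = np.array([b.mean_e for b in binned])
    X = np.column_stack([r, np.ones_like(r)])
    beta, res_ss, *_ = np.linalg.lstsq(X, e, rcond=None)
    resid = e - X @ beta
    dof = len(r) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    return LinearFit(
        slope=float(beta[0]), intercept=float(beta[1]), covariance=cov,
        residual_dof=dof, fit_domain=(float(r.min()), float(r.max())),
        metadata={"n_bins": len(binned)},
    )


def _prediction_gradient(fit, ratio: float, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of the prediction w.r.t. the parameters."""
    p = fit.params.astype(float)
    g = np.zeros_like(p)
    for i in range(len(p)):
        step = rel_step * max(abs(p[i]), 1.0)
        hi, lo = p.copy(), p.copy()
        hi[i] += step
        lo[i] -= step
        g[i] = (fit.predict_from(hi, ratio) - fit.predict_from(lo, ratio)) / (2 * step)
    return g


def predict_with_ci(fit, ratio: float, level: float = 0.95):
    """Point prediction with a delta-method confidence interval.

    Ratios outside the fitted domain are allowed but flagged with an
    extrapolation warning.  A singular/absent covariance yields ``(nan, nan)``
    for the CI while the point estimate is still returned.
    """
    lo_d, hi_d = fit.fit_domain
    if not (lo_d <= ratio <= hi_d):
        warnings.warn(
            f"ratio {ratio} outside fitted domain [{lo_d}, {hi_d}]; extrapolating",
            stacklevel=2,
        )
    e_hat = float(fit.predict(ratio))
    cov = np.asarray(fit.covariance, dtype=float)
    if cov.size == 0 or not np.all(np.isfinite(cov)):
        return e_hat, (np.nan, np.nan)
    g = _prediction_gradient(fit, ratio)
    var = float(g @ cov @ g)
    if var < 0:
        return e_hat, (np.nan, np.nan)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return e_hat, (e_hat - half, e_hat + half)
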