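"""Lifetime estimation from TCSPC decay histograms.

The FLIM instrument records, per pixel, a histogram of photon arrival times.
Pixels are pooled until each group exceeds a photon floor (default 1000
photons, matching standard FLIM practice for reliable per-ROI lifetimes),
and the mean donor lifetime is estimated by maximum likelihood under a
single-exponential decay truncated to the acquisition window.  No instrument
response function or background term is modelled: the downstream binding
analysis consumes only a mean lifetime, for which the truncated
mono-exponential is the minimal faithful model.

The donor-only reference lifetime tau0 — the unquenched donor lifetime used
to convert per-ROI lifetimes into FRET efficiencies — is the arithmetic mean
lifetime over ROIs with no detectable acceptor signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import (
    DegenerateDecayError,
    InsufficientPhotonsError,
    ParameterError,
    ReferenceUnavailableError,
    SchemaError,
)
from .synthgen import DecayHistogram, truncated_exp_bin_probs

__all__ = [
    "LifetimeEstimate",
    "pool_to_photon_floor",
    "fit_monoexponential",
    "decay_loglik",
    "donor_reference_lifetime",
    "venus_detection_threshold",
]

PHOTON_FLOOR = 1000  # pool pixels until each group exceeds this many photons
MIN_FIT_PHOTONS = 100


@dataclass
class LifetimeEstimate:
    """Maximum-likelihood lifetime with a 95% CI from the likelihood curvature."""

    tau: float
    ci95: tuple[float, float]
    n_photons: int
    converged: bool


def pool_to_photon_floor(
    histograms: list[DecayHistogram], floor: int = PHOTON_FLOOR
) -> list[DecayHistogram]:
    """Greedily merge per-pixel histograms until each pool exceeds ``floor``.

    Pixels are consumed in input order; counts of consecutive pixels are
    summed until the running total exceeds the floor, then a new pool starts.
    A trailing remainder below the floor is folded into the last complete
    pool, so total photons are conserved.
    """
    if not histograms:
        return []
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if len(h.bin_edges) != len(edges) or not np.allclose(h.bin_edges, edges):
            raise SchemaError("all per-pixel histograms must share bin_edges")

    pooled: list[np.ndarray] = []
    acc = np.zeros(len(edges) - 1, dtype=np.int64)
    for h in histograms:
        acc = acc + h.counts
        if acc.sum() > floor:
            pooled.append(acc)
            acc = np.zeros_like(acc)
    if acc.sum() > 0:
        if pooled:
            pooled[-1] = pooled[-1] + acc
        else:
            pooled.append(acc)
    return [DecayHistogram(bin_edges=edges.copy(), counts=c, pixel_id=i) for i, c in enumerate(pooled)]


def decay_loglik(tau: float, hist: DecayHistogram) -> float:
    """Multinomial log-likelihood of a truncated mono-exponential decay."""
    p = truncated_exp_bin_probs(tau, hist.bin_edges)
    nz = hist.counts > 0
    return float(np.sum(hist.counts[nz] * np.log(p[nz])))


def fit_monoexponential(hist: DecayHistogram) -> LifetimeEstimate:
    """Estimate the mean lifetime of a decay histogram by truncated-exponential MLE.

    The 95% CI comes from the observed information (numerical second
    derivative of the log-likelihood at the maximum); it is the quadratic
    approximation a nonlinear-regression package would report.
    """
    total = hist.total
    if total < MIN_FIT_PHOTONS:
        raise InsufficientPhotonsError(
            f"need >= {MIN_FIT_PHOTONS} photons for a lifetime fit, got {total}"
        )
    if int((hist.counts > 0).sum()) < 2:
        raise DegenerateDecayError("all photons fall in a single time bin")

    window = hist.bin_edges[-1] - hist.bin_edges[0]
    lo, hi = 1e-3 * window, 50.0 * window
    res = minimize_scalar(
        lambda t: -decay_loglik(t, hist), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10 * window},
    )
    tau = float(res.x)
    converged = bool(res.success) and lo * 1.01 < tau < hi * 0.99

    # observed information via central second difference
    dt = max(1e-5 * tau, 1e-9)
    d2 = (decay_loglik(tau + dt, hist) - 2 * decay_loglik(tau, hist) + decay_loglik(tau - dt, hist)) / dt**2
    if d2 < 0:
        se = 1.0 / np.sqrt(-d2)
        ci = (max(tau - 1.96 * se, 0.0), tau + 1.96 * se)
    else:
        ci = (0.0, np.inf)
        converged = False
    return LifetimeEstimate(tau=tau, ci95=ci, n_photons=total, converged=converged)


def venus_detection_threshold(control_acceptor_intensities) -> float:
    """Acceptor-channel detectability cutoff: mean + 2 SD of a control set."""
    x = np.asarray(control_acceptor_intensities, dtype=float)
    if x.size < 2:
        raise ParameterError("need >= 2 control intensities for a detection threshold")
    return float(x.mean() + 2.0 * x.std(ddof=1))


def donor_reference_lifetime(
    rois: pd.DataFrame, venus_detect_threshold: float, min_rois: int = 5
) -> tuple[float, int]:
    """Mean donor lifetime over ROIs without detectable acceptor signal.

    Returns ``(tau0, n_used)``.  Raises if fewer than ``min_rois`` regions
    fall below the detection threshold.
    """
    if not {"acceptor_intensity", "mean_lifetime_ns"}.issubset(rois.columns):
        raise SchemaError("ROI table needs acceptor_intensity and mean_lifetime_ns columns")
    mask = rois["acceptor_intensity"].to_numpy(float) < venus_detect_threshold
    n = int(mask.sum())
    if n < min_rois:
        raise ReferenceUnavailableError(
            f"only {n} ROIs below the acceptor detection threshold; need >= {min_rois}"
        )
    tau0 = float(rois.loc[mask, "mean_lifetime_ns"].mean())
    return tau0, n
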