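"""Synthetic data generation for the FLIM-FRET analysis pipeline.

The microscope and plate reader are replaced by parametric generators whose
ground truth is known exactly, so every estimator in the pipeline can be
validated by parameter recovery.  Five kinds of input are emulated:

* per-ROI FLIM-FRET tables (donor/acceptor intensity, mean donor lifetime,
  photon count) for binding and collision-control conditions,
* TCSPC photon-arrival decay histograms,
* cell-free FRET titrations (four-parameter logistic response),
* Stern-Volmer iodide-quenching series,
* per-cell feature tables with labelled apoptotic / healthy control
  populations and a transfected population whose death probability rises
  logistically with acceptor (Venus) expression.

All randomness flows through a single integer seed per call; identical
parameters and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "LognormalSpec",
    "SynthBindingParams",
    "GroundTruth",
    "DecayHistogram",
    "TitrationSeries",
    "QuenchSeries",
    "gen_roi_dataset",
    "gen_decay_histogram",
    "gen_titration",
    "gen_quench_series",
    "gen_cell_features",
    "hill_efficiency",
]

#: Column order of the ROI table written by :func:`gen_roi_dataset`.
ROI_COLUMNS = [
    "donor_intensity",
    "acceptor_intensity",
    "mean_lifetime_ns",
    "photon_count",
    "condition",
    "replicate_id",
]

#: Morphology/intensity features used by the cell-death classifier, in order.
CELL_FEATURES = [
    "tmre_total",
    "nuclear_area",
    "nuclear_roundness",
    "cell_area",
    "cell_roundness",
]


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution specified by its median and log-space sigma."""

    median: float
    sigma: float

    def __post_init__(self):
        if self.median <= 0:
            raise ParameterError(f"LognormalSpec.median must be > 0, got {self.median}")
        if self.sigma < 0:
            raise ParameterError(f"LognormalSpec.sigma must be >= 0, got {self.sigma}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


def hill_efficiency(ratio, emax: float, kd: float, h: float):
    """Hill-saturation FRET efficiency E%(r) = Emax * r^h / (Kd^h + r^h)."""
    r = np.asarray(ratio, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = emax * r[pos] ** h / (kd**h + r[pos] ** h)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SynthBindingParams:
    """Ground-truth parameters for a synthetic FLIM-FRET ROI dataset.

    Defaults emulate a saturating anti-apoptotic:BH3 interaction measured over
    a few thousand regions of interest: donor lifetime near 3.8 ns, maximum
    efficiency ~40 %, half-saturation near an acceptor:donor intensity ratio
    of 0.3, additive Gaussian lifetime noise of 0.08 ns, and ~10 % of regions
    expressing no detectable acceptor (used for the donor-only reference).
    """

    emax: float = 40.0            # maximum FRET efficiency at saturation (%)
    kd: float = 0.3               # relative dissociation constant (ratio units)
    h: float = 1.0                # Hill slope
    tau0: float = 3.8             # unquenched donor lifetime (ns)
    sigma_tau: float = 0.08       # lifetime noise SD (ns)
    n_roi: int = 3000
    ratio_law: LognormalSpec = field(default_factory=lambda: LognormalSpec(0.4, 0.9))
    donor_law: LognormalSpec = field(default_factory=lambda: LognormalSpec(1000.0, 0.5))
    frac_donor_only: float = 0.10
    collision_slope: float = 8.0  # E% per unit ratio for collision-only FRET
    mean_photons: float = 5000.0  # mean photons pooled per ROI
    seed: int = 0

    def __post_init__(self):
        checks = [
            (0 <= self.emax <= 100, "emax", "must be in [0, 100]"),
            (self.kd > 0, "kd", "must be > 0"),
            (self.h > 0, "h", "must be > 0"),
            (self.tau0 > 0, "tau0", "must be > 0"),
            (self.sigma_tau >= 0, "sigma_tau", "must be >= 0"),
            (self.n_roi >= 1, "n_roi", "must be >= 1"),
            (0 <= self.frac_donor_only <= 1, "frac_donor_only", "must be in [0, 1]"),
            (self.mean_photons >= 1, "mean_photons", "must be >= 1"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ParameterError(f"SynthBindingParams.{name} {msg}, got {getattr(self, name)}")


@dataclass
class GroundTruth:
    """Per-ROI truth retained alongside a generated dataset."""

    params: SynthBindingParams
    kind: str                      # "binding" or "collision"
    ratio: np.ndarray              # true acceptor:donor intensity ratio
    fraction_bound: np.ndarray     # r^h/(Kd^h+r^h); NaN for collision datasets
    e_true: np.ndarray             # noiseless FRET efficiency (%)

    def to_dict(self) -> dict:
        d = asdict(self.params)
        d["ratio_law"] = asdict(self.params.ratio_law)
        d["donor_law"] = asdict(self.params.donor_law)
        return {
            "params": d,
            "kind": self.kind,
            "ratio": self.ratio.tolist(),
            "fraction_bound": self.fraction_bound.tolist(),
            "e_true": self.e_true.tolist(),
        }


def gen_roi_dataset(
    params: SynthBindingParams,
    condition_label: str,
    kind: str = "binding",
    replicate_id: str = "rep1",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one condition's ROI table plus its ground truth.

    ``kind="binding"`` produces Hill-saturating FRET; ``kind="collision"``
    produces efficiency linear in the intensity ratio, emulating the
    random-collision FRET of a non-binding control.  A ``frac_donor_only``
    fraction of ROIs carries zero acceptor signal and the unquenched donor
    lifetime, enabling downstream estimation of the reference lifetime.
    """
    if kind not in ("binding", "collision"):
        raise ParameterError(f"kind must be 'binding' or 'collision', got {kind!r}")
    rng = np.random.default_rng(params.seed)
    n = params.n_roi

    donor = params.donor_law.draw(rng, n)
    ratio = params.ratio_law.draw(rng, n)
    donor_only = rng.random(n) < params.frac_donor_only
    ratio[donor_only] = 0.0

    if kind == "binding":
        frac = np.zeros(n)
        pos = ratio > 0
        frac[pos] = ratio[pos] ** params.h / (params.kd**params.h + ratio[pos] ** params.h)
        e_true = params.emax * frac
    else:
        frac = np.full(n, np.nan)
        e_true = params.collision_slope * ratio

    tau = params.tau0 * (1.0 - e_true / 100.0)
    if params.sigma_tau > 0:
        tau = tau + params.sigma_tau * rng.standard_normal(n)
    tau = np.maximum(tau, 1e-6)  # lifetimes are physical; noise floor only

    photons = np.maximum(rng.poisson(params.mean_photons, n), 1)

    df = pd.DataFrame(
        {
            "donor_intensity": donor,
            "acceptor_intensity": ratio * donor,
            "mean_lifetime_ns": tau,
            "photon_count": photons,
            "condition": condition_label,
            "replicate_id": replicate_id,
        }
    )
    truth = GroundTruth(params=params, kind=kind, ratio=ratio, fraction_bound=frac, e_true=e_true)
    return df, truth


@dataclass
class DecayHistogram:
    """TCSPC photon-arrival histogram: monotone bin edges (ns) and counts."""

    bin_edges: np.ndarray
    counts: np.ndarray
    pixel_id: int | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ParameterError(
                f"counts length {len(self.counts)} != len(bin_edges)-1 = {len(self.bin_edges) - 1}"
            )
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_low_ns": self.bin_edges[:-1],
                "t_high_ns": self.bin_edges[1:],
                "counts": self.counts,
            }
        )
        if self.pixel_id is not None:
            df.insert(0, "pixel_id", self.pixel_id)
        return df


def truncated_exp_bin_probs(tau_ns: float, bin_edges: np.ndarray) -> np.ndarray:
    """Bin probabilities of an exponential decay truncated to the window."""
    e = np.exp(-np.asarray(bin_edges, dtype=float) / tau_ns)
    p = e[:-1] - e[1:]
    return p / (e[0] - e[-1])


def gen_decay_histogram(
    tau_ns: float,
    n_photons: int,
    window_ns: float = 50.0,
    n_bins: int = 256,
    seed: int = 0,
) -> DecayHistogram:
    """Draw a multinomial TCSPC histogram from a truncated exponential decay."""
    if tau_ns <= 0:
        raise ParameterError(f"tau_ns must be > 0, got {tau_ns}")
    if n_photons < 1:
        raise ParameterError(f"n_photons must be >= 1, got {n_photons}")
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if window_ns <= 0:
        raise ParameterError(f"window_ns must be > 0, got {window_ns}")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, window_ns, n_bins + 1)
    counts = rng.multinomial(n_photons, truncated_exp_bin_probs(tau_ns, edges))
    return DecayHistogram(bin_edges=edges, counts=counts)


@dataclass
class TitrationSeries:
    """Concentration-response pairs from a cell-free FRET titration."""

    conc: np.ndarray               # drug or protein concentration (nM)
    response: np.ndarray           # fluorescence or derived response (a.u. or %)
    replicate_id: str = "rep1"
    truth: dict | None = None      # generator parameters, when synthetic

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"conc_nM": self.conc, "response": self.response, "replicate_id": self.replicate_id}
        )


def four_pl(conc, ic50: float, hill: float, top: float, bottom: float):
    """Four-parameter logistic: bottom + (top-bottom)/(1+(c/ic50)^hill)."""
    c = np.asarray(conc, dtype=float)
    out = np.full_like(c, top)
    pos = c > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (c[pos] / ic50) ** hill)
    # c = 0 sits at the hill-sign-appropriate asymptote
    if np.any(~pos):
        out[~pos] = top if hill > 0 else bottom
    return out if out.ndim else float(out)


def gen_titration(
    kd_like: float,
    hill: float,
    top: float,
    bottom: float,
    concs,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "rep1",
) -> TitrationSeries:
    """Generate a four-parameter-logistic titration with Gaussian noise."""
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ParameterError("concs must be nonempty")
    if np.any(concs < 0):
        raise ParameterError("concs must be nonnegative")
    if kd_like <= 0:
        raise ParameterError(f"kd_like must be > 0, got {kd_like}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    resp = four_pl(concs, kd_like, hill, top, bottom)
    if noise_sd > 0:
        resp = resp + noise_sd * rng.standard_normal(concs.size)
    truth = {"kd_like": kd_like, "hill": hill, "top": top, "bottom": bottom, "noise_sd": noise_sd}
    return TitrationSeries(conc=concs, response=resp, replicate_id=replicate_id, truth=truth)


@dataclass
class QuenchSeries:
    """Fluorescence vs quencher concentration for Stern-Volmer analysis."""

    quencher_conc: np.ndarray      # quencher concentration (M)
    fluorescence: np.ndarray       # a.u.
    condition: str = ""
    truth: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quencher_M": self.quencher_conc,
                "fluorescence": self.fluorescence,
                "condition": self.condition,
            }
        )


def gen_quench_series(
    ksv: float,
    f0: float,
    quencher_concs,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "",
) -> QuenchSeries:
    """Generate collisional quenching data F(c) = F0 / (1 + Ksv*c) + noise."""
    if ksv < 0:
        raise ParameterError(f"ksv must be >= 0, got {ksv}")
    if f0 <= 0:
        raise ParameterError(f"f0 must be > 0, got {f0}")
    concs = np.asarray(quencher_concs, dtype=float)
    if concs.size == 0 or np.any(concs < 0):
        raise ParameterError("quencher_concs must be nonempty and nonnegative")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    f = f0 / (1.0 + ksv * concs)
    if noise_sd > 0:
        f = f + noise_sd * rng.standard_normal(concs.size)
    return QuenchSeries(
        quencher_conc=concs,
        fluorescence=f,
        condition=condition,
        truth={"ksv": ksv, "f0": f0, "noise_sd": noise_sd},
    )


# Healthy-cell feature baseline: (mean, SD) per feature, and the direction an
# apoptotic cell moves (TMRE collapses, nucleus condenses and rounds up, the
# whole cell shrinks and rounds up).
_CELL_BASELINE = {
    "tmre_total": (5.0e4, 1.0e4, -1.0),
    "nuclear_area": (1200.0, 200.0, -1.0),
    "nuclear_roundness": (0.75, 0.06, +1.0),
    "cell_area": (4000.0, 800.0, -1.0),
    "cell_roundness": (0.60, 0.08, +1.0),
}


def _draw_cell_features(rng, n, dead: bool, separation: np.ndarray) -> dict:
    cols = {}
    for j, name in enumerate(CELL_FEATURES):
        mu, sd, sign = _CELL_BASELINE[name]
        shift = sign * separation[j] * sd if dead else 0.0
        x = mu + shift + sd * rng.standard_normal(n)
        if name.endswith("roundness"):
            x = np.clip(x, 0.0, 1.0)
        else:
            x = np.maximum(x, 1.0)  # areas/intensities stay positive
        cols[name] = x
    return cols


def gen_cell_features(
    n_per_class: int = 500,
    class_separation=3.0,
    venus_death_ec50: float = 1000.0,
    venus_death_slope: float = 2.0,
    n_cells: int = 3000,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Generate control populations plus a transfected population.

    Two labelled control clouds (``control_label`` = ``positive`` for
    TNFa/cycloheximide-style apoptotic cells, ``negative`` for untreated)
    are Gaussian in each morphology feature, separated by ``class_separation``
    pooled SDs (scalar or one value per feature).  The unlabelled transfected
    population expresses Venus lognormally; its true death label is Bernoulli
    with a logistic probability in log10(Venus) centred at
    ``venus_death_ec50`` with slope ``venus_death_slope`` per decade.  The
    ground-truth label is kept in ``true_dead``.
    """
    if n_per_class < 2:
        raise ParameterError(f"n_per_class must be >= 2, got {n_per_class}")
    if n_cells < 0:
        raise ParameterError(f"n_cells must be >= 0, got {n_cells}")
    if venus_death_ec50 <= 0:
        raise ParameterError(f"venus_death_ec50 must be > 0, got {venus_death_ec50}")
    if n_replicates < 1:
        raise ParameterError(f"n_replicates must be >= 1, got {n_replicates}")
    sep = np.broadcast_to(np.asarray(class_separation, dtype=float), (len(CELL_FEATURES),)).copy()
    if np.any(sep < 0):
        raise ParameterError("class_separation values must be >= 0")
    for name in CELL_FEATURES:
        if _CELL_BASELINE[name][1] <= 0:
            raise ParameterError(f"zero-variance feature spec for {name}")

    rng = np.random.default_rng(seed)
    frames = []

    for label, dead in (("negative", False), ("positive", True)):
        cols = _draw_cell_features(rng, n_per_class, dead, sep)
        cols["venus_mean"] = np.maximum(50.0 + 15.0 * rng.standard_normal(n_per_class), 0.0)
        cols["venus_median"] = cols["venus_mean"] * (0.9 + 0.05 * rng.standard_normal(n_per_class))
        cols["mito_mean"] = np.maximum(800.0 + 150.0 * rng.standard_normal(n_per_class), 1.0)
        df = pd.DataFrame(cols)
        df["control_label"] = label
        df["true_dead"] = dead
        df["well_id"] = "ctrl_pos" if dead else "ctrl_neg"
        df["replicate_id"] = [f"rep{1 + i % n_replicates}" for i in range(n_per_class)]
        frames.append(df)

    if n_cells > 0:
        venus = np.exp(np.log(300.0) + 1.2 * rng.standard_normal(n_cells))
        z = venus_death_slope * (np.log10(venus) - np.log10(venus_death_ec50))
        p_dead = 1.0 / (1.0 + np.exp(-z))
        dead = rng.random(n_cells) < p_dead
        cols_a = _draw_cell_features(rng, n_cells, False, sep)
        cols_d = _draw_cell_features(rng, n_cells, True, sep)
        cols = {k: np.where(dead, cols_d[k], cols_a[k]) for k in CELL_FEATURES}
        df = pd.DataFrame(cols)
        df["venus_mean"] = venus
        df["venus_median"] = venus * (0.9 + 0.05 * rng.standard_normal(n_cells))
        df["mito_mean"] = np.maximum(800.0 + 150.0 * rng.standard_normal(n_cells), 1.0)
        df["control_label"] = "none"
        df["true_dead"] = dead
        df["well_id"] = "transfected"
        df["replicate_id"] = [f"rep{1 + i % n_replicates}" for i in range(n_cells)]
        frames.append(df)

    return pd.concat(frames, ignore_index=True)
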