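"""End-to-end FLIM-FRET runs: configuration, orchestration, reporting.

A run takes three ROI-table conditions — a reference (vehicle), a perturbed
condition (drug or mutation), and a non-binding collision control — and
produces the donor-only reference lifetime, QC attrition counts, binned
efficiencies, fitted curves, and the Resistance statistic with its 95% CI,
all written as CSV/JSON plus a binding-curve plot.  Re-running with the same
configuration and seed reproduces every number exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, FitFailureError, FlimFretError, InsufficientDataError
from .synthgen import SynthBindingParams, LognormalSpec, gen_roi_dataset
from .tcspc import donor_reference_lifetime
from .binding import (
    QCThresholds,
    bin_by_ratio,
    compute_efficiency,
    fit_collision_baseline,
    fit_hill,
    qc_filter_rois,
    HillFit,
    LinearFit,
)
from .resistance import default_interpolation_ratio, resistance_statistic
from .io import read_roi_table, write_json

__all__ = ["RunConfig", "run_flimfret_pipeline", "fit_background_curve", "analyze_condition"]

ROLES = ("reference", "perturbed", "background")


@dataclass
class RunConfig:
    """Configuration for one FLIM-FRET resistance run.

    Either ``inputs`` maps each role (reference/perturbed/background) to a
    ROI CSV path, or ``synthetic`` maps roles to generator keyword overrides
    (the demo mode).  ``venus_threshold`` is the acceptor-intensity cutoff
    below which an ROI counts as donor-only for the tau0 estimate.
    """

    out_dir: str = "flimfret_run"
    inputs: dict = field(default_factory=dict)        # role -> csv path
    synthetic: dict | None = None                      # role -> param overrides
    qc: dict | None = None                             # donor_min/donor_saturation/acceptor_saturation
    min_per_bin: int = 20
    target: str = "BclXL"
    ratio: float | None = None
    n_draws: int = 2000
    venus_threshold: float = 1.0
    seed: int = 0
    make_plot: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic is None and set(self.inputs) != set(ROLES):
            raise ConfigurationError(
                f"inputs must provide paths for all of {ROLES} (or set synthetic)"
            )
        if self.synthetic is None:
            for role, path in self.inputs.items():
                if not Path(path).exists():
                    raise ConfigurationError(f"input for {role!r} does not exist: {path}")
        if self.min_per_bin < 1:
            raise ConfigurationError("min_per_bin must be >= 1")
        # resolves or raises
        default_interpolation_ratio(self.target, self.ratio)


#: Generator settings for the built-in demo: a saturating reference, a
#: partially displaced drug condition, and a collision-only control.
DEMO_SYNTHETIC = {
    "reference": {"emax": 40.0, "kd": 0.3, "h": 1.0},
    "perturbed": {"emax": 28.0, "kd": 0.45, "h": 1.0},
    "background": {"kind": "collision", "collision_slope": 8.0},
}


def _make_synthetic(role: str, overrides: dict, seed: int) -> pd.DataFrame:
    kw = dict(overrides)
    kind = kw.pop("kind", "binding")
    for law in ("ratio_law", "donor_law"):
        if law in kw and isinstance(kw[law], dict):
            kw[law] = LognormalSpec(**kw[law])
    params = SynthBindingParams(seed=seed, **kw)
    df, _ = gen_roi_dataset(params, condition_label=role, kind=kind)
    return df


def fit_background_curve(binned) -> HillFit | LinearFit:
    """Fit the collision control: Hill first, straight line as fallback.

    A Hill fit whose Kd lies beyond the fitted ratio range is non-saturating
    — the data carry no curvature — so the linear collision model is used
    instead, consistent with collisional FRET scaling linearly with
    concentration.
    """
    try:
        hf = fit_hill(binned)
        if hf.kd <= hf.fit_domain[1]:
            return hf
    except (FitFailureError, InsufficientDataError):
        pass
    return fit_collision_baseline([b for b in binned if b.ratio_mid > 0])


def analyze_condition(
    rois: pd.DataFrame,
    tau0: float,
    thresholds: QCThresholds,
    min_per_bin: int = 20,
    background: bool = False,
):
    """QC-filter, compute efficiencies, bin, and fit one condition's ROIs.

    Returns ``(fit, binned points, stage log dict)``.
    """
    kept, rejects = qc_filter_rois(rois, thresholds)
    ratio = kept["acceptor_intensity"].to_numpy(float) / kept["donor_intensity"].to_numpy(float)
    e = compute_efficiency(kept["mean_lifetime_ns"].to_numpy(float), tau0)
    binned = bin_by_ratio(ratio, e, min_per_bin=min_per_bin)
    fit = fit_background_curve(binned) if background else fit_hill(binned)
    log = {
        "n_input": len(rois),
        "n_kept": len(kept),
        "n_rejected": len(rejects),
        "rejection_reasons": rejects["reason"].value_counts().to_dict() if len(rejects) else {},
        "n_bins": len(binned),
        "n_binned_rois": int(sum(b.n_roi for b in binned)),
    }
    return fit, binned, log


def _binned_frame(binned) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ratio_low": b.ratio_low,
                "ratio_high": b.ratio_high,
                "ratio_mid": b.ratio_mid,
                "mean_e": b.mean_e,
                "sem_e": b.sem_e,
                "n_roi": b.n_roi,
            }
            for b in binned
        ]
    )


def _plot_curves(out_path: Path, curves: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"reference": "tab:green", "perturbed": "tab:cyan", "background": "tab:red"}
    for role, (fit, binned) in curves.items():
        df = _binned_frame(binned)
        ax.errorbar(df["ratio_mid"], df["mean_e"], yerr=df["sem_e"], fmt="o",
                    color=colors[role], label=f"{role} (binned)", ms=4, capsize=2)
        if len(df):
            r = np.linspace(0, df["ratio_mid"].max(), 200)
            ax.plot(r, fit.predict(r), color=colors[role], lw=1.5)
    ax.set_xlabel("acceptor : donor intensity ratio")
    ax.set_ylabel("FRET efficiency E%")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def run_flimfret_pipeline(config: RunConfig) -> dict:
    """Execute a full resistance run and write its artifacts.

    Returns the machine-readable report (also written to
    ``<out_dir>/report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}
    for i, role in enumerate(ROLES):
        try:
            if config.synthetic is not None:
                overrides = config.synthetic.get(role, DEMO_SYNTHETIC[role])
                tables[role] = _make_synthetic(role, overrides, seed=config.seed + i)
            else:
                tables[role] = read_roi_table(config.inputs[role])
        except FlimFretError as exc:
            raise type(exc)(f"[stage=load role={role}] {exc}") from exc

    pooled = pd.concat(tables.values(), ignore_index=True)
    tau0, n_donor_only = donor_reference_lifetime(pooled, config.venus_threshold)

    if config.qc:
        thresholds = QCThresholds(**config.qc)
    else:
        thresholds = QCThresholds.from_percentiles(pooled)

    curves, logs = {}, {}
    for role in ROLES:
        try:
            fit, binned, log = analyze_condition(
                tables[role], tau0, thresholds,
                min_per_bin=config.min_per_bin, background=(role == "background"),
            )
        except FlimFretError as exc:
            raise type(exc)(f"[stage=fit role={role}] {exc}") from exc
        curves[role] = (fit, binned)
        logs[role] = log
        _binned_frame(binned).to_csv(out / f"binned_{role}.csv", index=False)
        write_json(fit.to_dict(), out / f"fit_{role}.json")

    ratio = default_interpolation_ratio(config.target, config.ratio)
    result = resistance_statistic(
        curves["reference"][0], curves["perturbed"][0], curves["background"][0],
        ratio, n_draws=config.n_draws, seed=config.seed,
    )

    report = {
        "software": {"name": "flimfret", "version": __version__},
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "tau0_ns": tau0,
        "n_donor_only_rois": n_donor_only,
        "qc_thresholds": asdict(thresholds),
        "stages": logs,
        "fits": {role: curves[role][0].to_dict() for role in ROLES},
        "resistance": result.to_dict(),
    }
    write_json(report, out / "report.json")
    if config.make_plot:
        _plot_curves(out / "binding_curves.png", curves)
    return report
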