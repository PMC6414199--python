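"""High-content apoptosis scoring and colocalization analysis.

Cells are scored dead/alive with a Fisher linear discriminant trained on two
control populations — apoptotic cells (TNFa + cycloheximide treated) and
untreated cells — using morphology and mitochondrial-potential features
(total TMRE intensity, nuclear area and roundness, cell area and roundness).
Features are standardized, the pooled within-class covariance is inverted
(pseudo-inverse, so duplicated or collinear features are handled), and the
decision threshold sits at the midpoint of the two class score means; ties
label alive (conservative death calls).

Manual-threshold flags provide an independent sanity check: a cell is "TMRE
negative" or "small nucleus" when the feature falls more than two standard
deviations below the untreated-well mean.

Death curves bin classified cells by acceptor (Venus) expression — a proxy
for how much of the transfected pro-apoptotic protein the cell makes —
computing % Dead per replicate per bin, then mean ± SEM across replicates.

Colocalization of a Venus-tagged protein with a mitochondrial stain is the
per-object Pearson correlation of background-subtracted pixel intensities,
aggregated to per-replicate means and then a grand mean ± SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .synthgen import CELL_FEATURES

__all__ = [
    "ClassifierModel",
    "DeathCurvePoint",
    "train_linear_classifier",
    "classify_cells",
    "two_sd_flags",
    "death_by_expression_bins",
    "default_venus_bins",
    "object_filters",
    "pearson_colocalization",
]

MIN_CONTROL_CELLS = 100
MIN_CELLS_PER_BIN = 30


@dataclass
class ClassifierModel:
    """Fisher linear discriminant on standardized features.

    ``score = w . (x - mean)/sd``; a cell is dead iff score > threshold
    (threshold = midpoint of class score means; ties -> alive).
    """

    weights: np.ndarray
    bias: float                      # decision threshold on the score
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_summary: dict = field(default_factory=dict)

    def scores(self, cells: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in cells.columns]
        if missing:
            raise SchemaError(f"cell table missing classifier features: {missing}")
        X = cells[self.feature_names].to_numpy(float)
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.weights

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_names": self.feature_names,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_summary": self.training_summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            feature_names=list(d["feature_names"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            training_summary=d.get("training_summary", {}),
        )


def train_linear_classifier(
    positive: pd.DataFrame,
    negative: pd.DataFrame,
    features: list[str] | None = None,
    min_per_class: int = MIN_CONTROL_CELLS,
) -> ClassifierModel:
    """Train a Fisher LDA on apoptotic (positive) vs untreated (negative) controls.

    Zero-variance features are dropped with a warning; rank deficiency in the
    pooled covariance (e.g. duplicated features) is handled by pseudo-inverse.
    """
    features = list(features or CELL_FEATURES)
    for name, df in (("positive", positive), ("negative", negative)):
        if len(df) < min_per_class:
            raise ParameterError(
                f"insufficient {name} control cells: {len(df)} < {min_per_class}"
            )
        missing = [f for f in features if f not in df.columns]
        if missing:
            raise SchemaError(f"{name} control table missing features: {missing}")

    Xp = positive[features].to_numpy(float)
    Xn = negative[features].to_numpy(float)
    pooled = np.vstack([Xp, Xn])
    sds = pooled.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        features = [f for f, k in zip(features, keep) if k]
        Xp, Xn, sds = Xp[:, keep], Xn[:, keep], sds[keep]
    means = np.vstack([Xp, Xn]).mean(axis=0)

    Zp = (Xp - means) / sds
    Zn = (Xn - means) / sds
    mu_p, mu_n = Zp.mean(axis=0), Zn.mean(axis=0)
    Sp = np.cov(Zp, rowvar=False, ddof=1)
    Sn = np.cov(Zn, rowvar=False, ddof=1)
    n_p, n_n = len(Zp), len(Zn)
    S = ((n_p - 1) * Sp + (n_n - 1) * Sn) / (n_p + n_n - 2)
    w = np.linalg.pinv(np.atleast_2d(S)) @ (mu_p - mu_n)

    thr = 0.5 * (float(np.mean(Zp @ w)) + float(np.mean(Zn @ w)))
    pred_p = (Zp @ w) > thr
    pred_n = (Zn @ w) > thr
    acc = (pred_p.sum() + (~pred_n).sum()) / (n_p + n_n)
    return ClassifierModel(
        weights=w,
        bias=thr,
        feature_names=features,
        feature_means=means,
        feature_sds=sds,
        training_summary={"n_positive": n_p, "n_negative": n_n, "training_accuracy": float(acc)},
    )


def classify_cells(model: ClassifierModel, cells: pd.DataFrame) -> pd.Series:
    """Label each cell 'dead' or 'alive'; boundary ties go to 'alive'."""
    s = model.scores(cells)
    return pd.Series(np.where(s > model.bias, "dead", "alive"), index=cells.index, name="label")


def two_sd_flags(cells: pd.DataFrame, untreated_reference: pd.DataFrame) -> pd.DataFrame:
    """Manual flags: value strictly below reference mean - 2 SD.

    Returns a boolean DataFrame with ``tmre_negative`` (total TMRE intensity)
    and ``small_nucleus`` (nuclear area) columns.
    """
    if len(untreated_reference) < 10:
        raise ParameterError(
            f"untreated reference needs >= 10 cells, got {len(untreated_reference)}"
        )
    out = {}
    for flag, feat in (("tmre_negative", "tmre_total"), ("small_nucleus", "nuclear_area")):
        if feat not in cells.columns or feat not in untreated_reference.columns:
            raise SchemaError(f"missing feature column {feat!r}")
        ref = untreated_reference[feat].to_numpy(float)
        cutoff = ref.mean() - 2.0 * ref.std(ddof=1)
        out[flag] = cells[feat].to_numpy(float) < cutoff
    return pd.DataFrame(out, index=cells.index)


@dataclass
class DeathCurvePoint:
    """% Dead (mean ± SEM across replicates) in one Venus-expression bin."""

    venus_bin: tuple[float, float]
    pct_dead_mean: float
    pct_dead_sem: float
    n_cells_total: int
    n_replicates: int


def default_venus_bins(cells: pd.DataFrame, n_bins: int = 8) -> np.ndarray:
    """Equal-count (octile by default) bin edges on the pooled Venus intensities."""
    v = cells["venus_mean"].to_numpy(float)
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max in the last bin
    return np.unique(edges)


def death_by_expression_bins(
    labels: pd.Series,
    cells: pd.DataFrame,
    bin_edges,
    min_cells: int = MIN_CELLS_PER_BIN,
) -> list[DeathCurvePoint]:
    """% Dead per Venus bin: per replicate first, then mean ± SEM across replicates.

    Bin edges are held fixed by the caller so curves are comparable across
    conditions.  Bins with fewer than ``min_cells`` total cells are dropped.
    With fewer than 2 replicates the SEM is reported as NaN.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing")
    if "replicate_id" not in cells.columns:
        raise SchemaError("cell table needs a replicate_id column")
    v = cells["venus_mean"].to_numpy(float)
    dead = labels.to_numpy() == "dead"
    reps = cells["replicate_id"].to_numpy()
    idx = np.digitize(v, edges) - 1

    out = []
    for i in range(len(edges) - 1):
        in_bin = idx == i
        n_total = int(in_bin.sum())
        if n_total < min_cells:
            continue
        pct = []
        for rep in pd.unique(reps):
            sel = in_bin & (reps == rep)
            if sel.sum() > 0:
                pct.append(100.0 * dead[sel].mean())
        n_rep = len(pct)
        mean = float(np.mean(pct))
        sem = float(np.std(pct, ddof=1) / np.sqrt(n_rep)) if n_rep >= 2 else float("nan")
        out.append(
            DeathCurvePoint(
                venus_bin=(float(edges[i]), float(edges[i + 1])),
                pct_dead_mean=mean,
                pct_dead_sem=sem,
                n_cells_total=n_total,
                n_replicates=n_rep,
            )
        )
    return out


def object_filters(
    cells: pd.DataFrame,
    venus_mean_min: float = -np.inf,
    venus_median_min: float = -np.inf,
    mito_band: tuple[float, float] = (-np.inf, np.inf),
    size_band: tuple[float, float] = (-np.inf, np.inf),
) -> tuple[pd.DataFrame, dict]:
    """Select well-segmented transfected objects for colocalization analysis.

    Keeps cells passing all of: mean Venus above threshold (expressing),
    median Venus above threshold (discards segmentation artifacts), mean
    MitoTracker within a band (properly stained), and cell area within a
    band (drops debris and fused objects).  Returns ``(kept, rejection
    counts per filter)``; rejection reasons are assessed independently, so a
    cell can count against several filters.
    """
    if mito_band[0] > mito_band[1] or size_band[0] > size_band[1]:
        raise ParameterError("filter bands must satisfy low <= high")
    venus_ok = cells["venus_mean"].to_numpy(float) >= venus_mean_min
    median_ok = cells["venus_median"].to_numpy(float) >= venus_median_min
    mito = cells["mito_mean"].to_numpy(float)
    mito_ok = (mito >= mito_band[0]) & (mito <= mito_band[1])
    size = cells["cell_area"].to_numpy(float)
    size_ok = (size >= size_band[0]) & (size <= size_band[1])
    keep = venus_ok & median_ok & mito_ok & size_ok
    counts = {
        "venus_mean": int((~venus_ok).sum()),
        "venus_median": int((~median_ok).sum()),
        "mito": int((~mito_ok).sum()),
        "size": int((~size_ok).sum()),
        "kept": int(keep.sum()),
        "total": len(cells),
    }
    return cells.loc[keep].copy(), counts


def pearson_colocalization(
    pixels: pd.DataFrame, min_pixels: int = 10
) -> tuple[pd.DataFrame, dict]:
    """Per-object Pearson r of background-subtracted channels, then replicate means.

    ``pixels`` is long-form with columns object_id, replicate_id, channel_a,
    channel_b, bg_a, bg_b (per-image scalar backgrounds).  Background is
    subtracted per channel and floored at 0.  Objects with fewer than
    ``min_pixels`` pixels or zero variance in either channel after
    subtraction are skipped with a warning.

    Returns ``(per_object table with columns object_id, replicate_id, r;
    summary dict with per-replicate means and the grand mean ± SEM)``.
    """
    required = {"object_id", "replicate_id", "channel_a", "channel_b", "bg_a", "bg_b"}
    missing = required - set(pixels.columns)
    if missing:
        raise SchemaError(f"pixel table missing columns: {sorted(missing)}")

    rows = []
    for (obj, rep), grp in pixels.groupby(["object_id", "replicate_id"], sort=False):
        if len(grp) < min_pixels:
            warnings.warn(f"object {obj!r}: only {len(grp)} pixels; skipped", stacklevel=2)
            continue
        a = np.maximum(grp["channel_a"].to_numpy(float) - grp["bg_a"].to_numpy(float), 0.0)
        b = np.maximum(grp["channel_b"].to_numpy(float) - grp["bg_b"].to_numpy(float), 0.0)
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"object {obj!r}: zero-variance channel; skipped", stacklevel=2)
            continue
        rows.append({"object_id": obj, "replicate_id": rep, "r": float(np.corrcoef(a, b)[0, 1])})
    per_object = pd.DataFrame(rows, columns=["object_id", "replicate_id", "r"])

    rep_means = per_object.groupby("replicate_id")["r"].mean() if len(per_object) else pd.Series(dtype=float)
    n_rep = len(rep_means)
    grand = float(rep_means.mean()) if n_rep else float("nan")
    sem = float(rep_means.std(ddof=1) / np.sqrt(n_rep)) if n_rep >= 2 else float("nan")
    summary = {
        "replicate_means": {str(k): float(v) for k, v in rep_means.items()},
        "mean_r": grand,
        "sem_r": sem,
        "n_objects": len(per_object),
        "n_replicates": n_rep,
    }
    return per_object, summary
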