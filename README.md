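# flimfret

Quantitative analysis of Bcl-2-family protein:protein interactions measured
by FLIM-FRET in live cells, plus the companion cell-free and high-content
assays: lifetime estimation from TCSPC decays, Hill-slope binding curves,
the drug-displacement **Resistance** statistic, inhibitor dose–response and
Stern–Volmer quenching fits, and control-trained apoptosis classification.
A synthetic-data generator stands in for the microscope, so every estimator
in the pipeline can be validated by parameter recovery against known ground
truth.

## Who this is for

Labs measuring protein interactions by donor-lifetime FRET (e.g. mCerulean3
donor / Venus acceptor fusions of Bcl-2 family proteins) and quantifying how
BH3-mimetic drugs or binding-site mutations disrupt those complexes, as well
as anyone who wants a tested, scriptable re-implementation of this analysis
chain instead of a spreadsheet/Prism workflow.

## The model

Binding shortens the donor's fluorescence lifetime. Per region of interest
(ROI) with mean donor lifetime τᵢ and donor-only reference lifetime τ₀:

```
E% = (1 − τᵢ/τ₀) × 100
```

E% is binned by the acceptor:donor intensity ratio r (bin widths 0.1 below
r = 0.5, 0.25 up to 1.25, 0.5 beyond; exact zero bin; ≥ 20 ROIs per bin) and
the bin means are fitted to a saturation curve with a Hill slope:

```
E% = Emax · r^h / (Kd^h + r^h)
```

Non-binding collision controls produce E% linear in r and are fitted with a
straight line. The Resistance of a complex to a drug or mutation is read off
three fitted curves at a fixed ratio (0.5 for Bcl-XL, 0.25 for Bcl-2):

```
R = 100 · (B − C) / (A − C)
```

with A the reference (vehicle) efficiency, B the perturbed efficiency, and C
the collision background. R ≈ 0 means the perturbation stripped the complex
down to random collisions; R ≈ 100 means it had no effect. R is unclamped
and carries a parametric-bootstrap 95% CI propagating all three fits'
parameter covariances.

Cell-free assays use E% = (1 − F_labeled/F_unlabeled)·100, fraction bound
F/F_max·100, four-parameter logistic dose–response fits (optionally with the
bottom plateau fixed at 0), and Stern–Volmer quenching F₀/F = 1 + K_SV[Q].
Apoptosis scoring trains a Fisher linear discriminant on apoptotic vs
untreated control cells and builds % Dead curves against acceptor (Venus)
expression bins.

## Worked example

The built-in demo generates three synthetic conditions (a saturating
reference, a partially displaced drug condition, and a collision-only
control), estimates τ₀ from donor-only ROIs, fits all three curves, and
computes R at ratio 0.5:

```
$ flimfret run-all --seed 1 --out demo
tau0 = 3.79958 ns
R = 51.8408%  95% CI [51.0429, 52.8468]
artifacts in demo
```

The generator's reference curve saturates at Emax = 40% with Kd = 0.3 and the
drug condition at Emax = 28% with Kd = 0.45 over a collision slope of 8%/r,
which places the true R near 51% — the fitted value and its CI recover it.
`demo/` contains the binned data, the three fit JSONs (parameters plus
covariance), `report.json` with QC attrition counts and seeds, and a
binding-curve plot.

The same stages are available piecemeal (`simulate`, `lifetimes`,
`bind-fit`, `resistance`, `dose-response`, `quench`, `classify`,
`death-curve`, `coloc`, `validate`), e.g.:

```
$ flimfret simulate --kind quench --out q.csv --seed 2
$ flimfret quench q.csv
all: Ksv=7.44245 /M  95% CI [5.98827, 8.89663]  R^2=0.9806
```

(the generating constant was 8 /M at 1% noise). Everything the CLI does is a
thin wrapper over `flimfret.*` library functions.

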