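# Methods

This note documents the statistical models, defaults, and design choices in
flimfret, in the spirit of a package methods appendix. Nothing here states a
result the test suite or `scripts/acceptance.py` does not itself compute.

## Lifetime estimation (tcspc)

TCSPC histograms are modelled as multinomial draws over the bin
probabilities of a single-exponential decay truncated to the acquisition
window (default 50 ns, 256 bins). The mean lifetime is the maximizer of the
multinomial log-likelihood (bounded scalar optimization); its 95% CI comes
from the observed information (numerical curvature at the maximum). No
instrument response function or background term is modelled: the downstream
analysis consumes only a mean lifetime per ROI, and for that purpose the
truncated mono-exponential is the minimal faithful model. Multi-exponential
decays, phasor analysis, and per-pixel image reconstruction are out of
scope.

Per-pixel histograms are pooled greedily in input order until each pool
exceeds 1000 photons — the standard floor for a stable per-ROI lifetime — 
with any trailing remainder folded into the last pool so photons are
conserved. Spatial adjacency is not available in tabular inputs, hence
input-order pooling. Fits require ≥ 100 photons; at the 1000-photon floor
the estimator's bias is a fraction of a percent (measured by Monte Carlo in
the acceptance checks).

The donor-only reference lifetime τ₀ is the arithmetic mean lifetime over
ROIs whose acceptor-channel intensity falls below a detectability threshold
(at least 5 such ROIs required). The threshold is either a configured
absolute value (default 1.0 intensity units, which isolates the generator's
acceptor-free ROIs exactly) or mean + 2 SD of acceptor intensity in a
supplied control population.

## Binding curves (binding)

QC discards ROIs with donor intensity below `donor_min` (noisy) or at/above
`donor_saturation`, and ROIs with acceptor intensity at/above
`acceptor_saturation`; defaults are the 1st/99th percentiles of the pooled
dataset when no absolute cutoffs are configured. Each rejection is logged
with one reason code.

Efficiencies are binned by intensity ratio with half-open `[low, high)`
intervals and edges 0, 0.1, …, 0.5, 0.75, 1.0, 1.25, 1.75, 2.25, …
(constant 0.5 width continuing upward); ratio = 0 forms its own exact bin
(donor-only ROIs). Bins under 20 ROIs are dropped. Negative E% values are
retained — clamping would bias low-ratio bins upward. The bin's abscissa is
the **mean observed ratio** of its ROIs rather than the interval midpoint:
with wide bins and a right-skewed ratio distribution the midpoint
overstates where the ROIs sit, which would bias the fitted Emax upward and
the Hill slope downward.

The Hill model is fitted to the bin means (the zero bin excluded),
unweighted by default since the means are the observations; inverse-SEM²
weighting is available. Bounds: Emax ∈ (0, 100], Kd > 0, h ∈ (0, 10].
Multistart initialization uses Emax₀ = max bin mean, Kd₀ = interpolated
half-max ratio, and h₀ ∈ {0.5, 1, 2, 4}. The parameter covariance uses a
heteroscedastic sandwich estimator (J'J)⁻¹ J' diag(SEM²) J (J'J)⁻¹ when
every bin carries a positive SEM — bins averaging thousands of ROIs and
bins at the 20-ROI floor then contribute their actual precision — with the
homoscedastic s²(J'J)⁻¹ as fallback. Collision controls are fitted by OLS
with a free intercept. Curve predictions carry delta-method 95% CIs;
out-of-domain ratios are allowed with an extrapolation warning.

## Resistance (resistance)

R = 100·(B − C)/(A − C) from the three fitted curves evaluated at a fixed
ratio (0.5 for Bcl-XL complexes, 0.25 for Bcl-2; custom values allowed). R
is undefined (error) when A − C ≤ 0.5 E% — the reference is then
indistinguishable from collisions. R is never clamped; values above 100
are legitimate (a perturbation can increase apparent binding).

The 95% CI is a parametric bootstrap: parameter vectors are drawn from each
fit's multivariate normal (mean = estimates, covariance = fit covariance),
draws violating the Hill bounds are discarded (10× oversampling, point
estimate padding in the rare shortfall), R is recomputed per draw, and the
2.5/97.5 percentiles reported. Uncertainty from **all three** curves is
propagated; this choice is recorded in the output metadata. Singular
covariances fall back to a delta-method interval with a warning.

The background curve is fitted as a Hill curve first; if the fit fails or
is non-saturating (Kd beyond the data's ratio range — i.e. the data carry
no curvature), the linear collision model is used instead.

## Cell-free assays (invitro)

Dose–response data are fitted to the four-parameter logistic
`bottom + (top − bottom)/(1 + (c/IC50)^h)`, optimized over log10(IC50) with
zero-concentration points handled through the asymptote rather than
log-transformed. The model is invariant under
(h, top, bottom) → (−h, bottom, top); fits are canonicalized to
top ≥ bottom, so inhibitor curves report h > 0 and agonist curves h < 0.
Orientation is inferred by multistart over both signs unless forced. The
`constrain_bottom_zero` flag fixes the bottom plateau at 0 (complete
displacement assumed at infinite inhibitor) and demonstrably shrinks IC50
variance on data generated with a true zero bottom. Covariance is reported
on the natural (IC50, h, top, bottom) scale from a numerical Jacobian.

Stern–Volmer constants use the standard collisional form F₀/F = 1 + K_SV[Q]
fitted by OLS with the intercept left free as a diagnostic (≈ 1 expected);
the regression direction (F₀/F on [Q]) is recorded in metadata. F₀ is the
zero-quencher point of the same series, or the smallest-concentration point
with a warning. The K_SV 95% CI uses the t distribution on the slope SE.

## Cell death and colocalization (celldeath)

The classifier is a Fisher linear discriminant on standardized features
(total TMRE intensity, nuclear area/roundness, cell area/roundness) with
pooled within-class covariance inverted by pseudo-inverse, so duplicated or
collinear features are harmless. The decision threshold is the midpoint of
the two class score means; boundary ties label "alive" (conservative death
calls). Training requires ≥ 100 cells per control class; zero-variance
features are dropped with a warning. This is a from-scratch implementation
because the exact threshold/tie/rank-deficiency contract above is part of
the interface; an off-the-shelf LDA serves as an independent cross-check in
the tests.

Manual 2-SD flags ("TMRE negative", "small nucleus") use a strict
`value < mean − 2·SD` cutoff against an untreated reference well. Death
curves compute % Dead per replicate per Venus-intensity bin, then mean ±
SEM across replicates; bins under 30 cells are dropped, bin edges are held
fixed across conditions by the caller (equal-count octiles of the pooled
population by default). Colocalization subtracts a per-image scalar
background per channel (floored at 0; no rolling-ball estimation —
segmentation is out of scope), computes Pearson's r per object (≥ 10
pixels, nonzero variance), and aggregates object → replicate mean → grand
mean ± SEM.

## Synthetic data (synthgen)

The generator emulates the statistical structure of the real assays, not
the optics: no images, PSF, or segmentation are simulated.

* ROI datasets: donor intensity lognormal (median 1000, σ 0.5), intensity
  ratio lognormal (median 0.4, σ 0.9 — dense low-ratio sampling spanning
  roughly 0–3), 10% donor-only ROIs with zero acceptor, photon counts
  Poisson (mean 5000, floored at 1). True E% follows the Hill model
  (defaults Emax 40%, Kd 0.3, h 1) or the collision line (8%/ratio unit);
  the measured lifetime is τ₀(1 − E/100) plus additive Gaussian noise
  (σ 0.08 ns) on the lifetime, since lifetime is the measured quantity.
  Defaults: τ₀ = 3.8 ns, 3000 ROIs per condition — the scale of a pooled
  three-replicate live-cell experiment. The real instrument's intensity
  distributions are not published; these defaults are plausible and fully
  configurable.
* Decays: multinomial draws over truncated-exponential bin probabilities.
* Titrations: 4PL plus Gaussian noise; quench series: F₀/(1 + K_SV c) plus
  noise.
* Cell tables: two Gaussian control clouds separated by a configurable
  number of pooled SDs per feature (apoptotic cells: lower TMRE, smaller
  rounder nuclei and cells), plus a transfected population with lognormal
  Venus expression and Bernoulli death labels from a logistic in
  log10(Venus) (EC50 1000 intensity units, slope 2/decade), assigned
  round-robin to 3 replicates.

Identical parameters and seed give byte-identical outputs. What passing
tests show: the estimators recover the generating parameters under the
stated noise model. What they do not show: robustness to features real
data have and the generator lacks — instrument response functions,
autofluorescence background, intensity-dependent lifetime artifacts,
segmentation errors, non-lognormal expression, or spatial correlation
between neighboring ROIs.

## Numerical choices and problem sizes

Nonlinear fits use trust-region-reflective least squares with tight
tolerances and multistart; equality with independent zooming grid-search
oracles is asserted in the tests to 0.5% per parameter. Bootstrap CIs use
2000 draws by default (1000 in the heavier Monte-Carlo tests). Monte-Carlo
checks use 100-replicate designs (500 for the lifetime bias study), sized
so the full suite runs in well under a minute while leaving the binomial
error on coverage counts small. Floating-point output is rounded to 6
significant digits in console reports and kept at full precision in JSON.

## Known limitations

* R values from the original imaging studies are not reproduced here; they
  require the study's raw microscopy data. The package reproduces the
  method and its qualitative contrasts (displaceable vs resistant
  complexes) on synthetic data.
* The Hill slope from intensity-ratio binding curves is distorted by
  expression-level coupling between donor and acceptor in real cells; it
  should be read as a curve-shape parameter, not a cooperativity constant.
* The lifetime model omits IRF convolution; absolute lifetimes from real
  hardware will differ, though E% (a ratio of lifetimes) is less affected.
* Whether the original fits constrained Emax or h is unknown; the bounds
  used here are recorded in each fit's metadata.
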