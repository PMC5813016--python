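# Methods

`tirfpharm` re-implements, as a tested pipeline over synthetic data, the
quantitative machinery used to characterize non-catechol D1 dopamine
receptor (D1R) agonists: quantification of β-arrestin-GFP membrane
puncta in TIRF microscopy, the group statistics applied to those
endpoints, the receptor-pharmacology calculations of an agonist
campaign, and a hierarchical Bayesian treatment of saturation
radioligand binding. This note documents the models, the defaults and
why, the numerical choices, and what the synthetic data do and do not
establish.

## TIRF image model (synthetic fields)

A field is rendered as

```
expected = background + gradient + cell plateaus + Σ puncta
```

followed by Poisson shot noise on the expected counts, additive Gaussian
read noise, rounding, and clipping to the 16-bit range — the standard
camera model, applied in that order.

* **Background**: constant baseline (default 500 counts) plus an optional
  low-frequency non-uniformity modeled as a large-σ Gaussian blob
  (default σ = 80 px, amplitude configurable). The blob spatial scale is
  deliberately larger than twice the large top-hat radius so that it
  exercises the background-flattening step.
* **Cells**: filled ellipses with jittered semi-axes (default 45 ± 8 px)
  carrying a constant diffuse plateau (default 12,000 counts). The
  plateau stands in for unrecruited cytosolic/membrane GFP signal, which
  in real arrestin-GFP imaging is strong relative to the extracellular
  background; it is what gives Otsu's method the bimodal
  cell-vs-background histogram the segmentation step relies on. A dim
  plateau makes Otsu latch onto the puncta-vs-everything split instead
  and collapses the cell mask — a genuine failure mode of the method,
  reproducible here by lowering `cell_plateau`.
* **Soft cell edges**: the plateau is blurred with a Gaussian
  (`cell_edge_sigma_px`, default 3 px). Hard single-pixel edges are
  unphysical for diffraction-limited optics, and their rasterization
  leaves pixel-scale protrusions that survive the radius-30 top-hat as
  ~30-unit rim artifacts — spurious "puncta" just above the detection
  threshold. With soft edges the rim residue stays below ~11 units.
* **Puncta**: isotropic Gaussians (default σ = 1.5 px) truncated at 4σ,
  peak amplitudes uniform in 15,000–45,000 counts, centers constrained
  to cell footprints, with an optional minimum separation (rejection
  sampling). These approximate sub-resolution clathrin-pit-scale spots.
* **Noise defaults**: shot noise on, read noise sd 100 counts. The source
  study does not state acquisition noise statistics or pixel size; these
  are free, realistic parameters, not instrument estimates.

Generators are bit-deterministic given `seed` (one `default_rng` drives
placement, amplitudes and noise in a fixed order).

**What the synthetic fields do not emulate:** realistic PSF/optics
(no Airy rings, no depth-dependent TIRF decay), spatially correlated
noise, autofluorescence texture inside cells, cell-to-cell brightness
variation, or time-lapse dynamics. Passing detection tests here shows
the operator chain is implemented correctly and is robust to the noise
and background structure modeled; it does not certify performance on
real micrographs.

## Detection chain

All parameters live in `PipelineConfig`; defaults are the published
operating point.

1. **sqrt → 8-bit**: `v8 = min(255, floor(sqrt(v16)))`. This maps the
   full 16-bit range onto [0, 255], compresses bright-spot dynamic range
   so dim and bright puncta are comparable, and approximately
   variance-stabilizes shot noise. Integer output; monotone.
2. **Gaussian smoothing**: normalized kernel, σ = 1 px, truncated at
   half-width 2 px (5×5). The half-width reading of "h = 2 px" is a
   design choice; the source does not define h.
3. **Double white top-hat**: image minus its grayscale opening with a
   flat disk — first radius 30 px (removes smooth background wider than
   the disk; exactly zero on constants, offset-invariant), then radius
   5 px (suppresses local intensity variation around puncta).
   Structuring elements are discrete Euclidean disks, center included.
4. **Non-maximal suppression**: a pixel is a peak iff its value
   ≥ threshold (default 20, 8-bit units) and ≥ every pixel within
   Chebyshev distance 3. Equal-valued candidates that touch
   (8-connectivity) are one plateau; only the lexicographically smallest
   (row, col) survives. The neighborhood metric and tie-break are design
   choices fixed here so that the operator has a unique, testable output.
5. **Marker-controlled watershed** on the negated enhanced image, with
   peaks as foreground markers and all sub-threshold pixels as the
   background marker. The background-marker level re-uses the NMS
   threshold (the source names only the foreground markers). Each peak
   yields exactly one region; regions touching the border are retained.
6. **Measurement** on the sqrt-transformed but otherwise unprocessed
   image: per-region pixel count, mean intensity and integrated
   intensity (mean × area ≡ pixel sum).
7. **Cell segmentation**: Otsu's threshold (exhaustive over the 256
   levels, maximizing between-class variance, ties to the lowest level),
   hole filling, largest 8-connected component. It runs on the smoothed
   8-bit image (configurable; the source does not say which image feeds
   it).
8. **Endpoints**: puncta whose centroid pixel lies outside the cell mask
   are dropped; optional area/mean-intensity gates (off by default — the
   published gating values are not stated); per-field puncta count and
   summed integrated intensity are divided by `area / median(areas)`
   with the median pooled across the whole experiment.

### Known limitation: background vs measured intensity

Detection is exactly invariant to smooth additive backgrounds (the
radius-30 top-hat removes them before peak finding): adding a blob of
scale > 60 px at 20% of a field's 16-bit dynamic range changes puncta
counts by 0. The *measured* integrated intensity, however, is read from
the unprocessed sqrt image, so an additive background b raises each
region pixel by ≈ b/(2√v); at that perturbation scale, fields where the
blob overlaps the cell shift their intensity endpoint by up to ~9%.
A sub-5% bound would require background-subtracted measurement, which
the method does not perform. The acceptance suite asserts the strict
bound and documents the failure rather than weakening the measurement.

## Group statistics

Per-cell endpoint values are square-root transformed (for count-like
endpoints the variance scales with the mean; √ stabilizes it — the
variance of √Poisson(λ) tends to 1/4 independent of λ), then averaged
within recording batch. The analysis unit is the batch mean (three or
more batches per condition, ~20 cells per batch), which avoids
pseudo-replication across cells sharing a well. Homogeneity is assessed
by Bartlett's test; treatment effects by one-way fixed-effects ANOVA;
comparisons against the control by Dunnett's procedure (two-sided,
max-|t| multivariate-t null integrated with a seeded RNG, so adjusted
p values are reproducible); other comparison families by
Benjamini–Hochberg FDR. All tests two-tailed at 5%. Degenerate inputs
are defined rather than NaN: identical constant groups give F = 0,
exactly equal variances give Bartlett p = 1, zero-variance groups raise
a dedicated error.

## Dose–response and receptor math

* **4PL**: `r = bottom + (top − bottom)/(1 + (EC50/c)^hill)`, fitted by
  least squares on log10 concentration. Initialization is deterministic
  (bottom = min, top = max, EC50 at the concentration nearest the
  half-range response, hill = 1) with hill bounded to [0.1, 10]; flat
  curves are flagged `no_response` instead of fitted; non-convergence
  returns an explicit `failed` status. The plate design is 11 points at
  half-log increments (a 10^5 concentration span) with saturating
  full-agonist control wells (5 µM dopamine in the emulated assay).
* **Percent efficacy**: 100 × fitted top / positive-control response.
* **Percent desensitization**: 100 × (vehicle − treated)/vehicle cAMP
  after an agonist challenge; negative values (sensitization) are
  preserved. Basal subtraction is off by default (the assay normalizes
  to the vehicle-pretreated challenge response only).
* **Standard curve**: monotone 4PL of HTRF ratio vs log concentration,
  inverted analytically; ratios outside the calibrated range are
  flagged, never silently extrapolated.
* **Δpotency** = EC50(mutant)/EC50(wild type); > 1 means the mutation
  impairs that agonist's potency.
* **Cheng–Prusoff**: Ki = IC50/(1 + L/Kd); **apparent Kb** =
  IC50/(1 + [A]/EC50_A); **occupancy**: RO% = 100·C/(C + Ki) at unbound
  brain concentration C = C_brain,total · fu,b.
* **PK**: one-compartment oral absorption (Bateman function), linear
  superposition over repeated doses; ka = ke raises a degenerate-kinetics
  error. This is an explicit surrogate for unpublished in vivo PK
  models. The occupancy-matching routine exploits dose-linearity to find
  the scalar that equates two compounds' time-averaged occupancy
  (Brent's method on log-scale), mirroring how a test compound's regimen
  is normalized to a reference's target engagement.

## Hierarchical Bayesian saturation binding

Specific binding (total − nonspecific, paired per concentration, floored
at 0 with a flag) follows B = Bmax·L/(L + Kd). The hierarchical model
has group-level (condition-level) Kd and Bmax, lognormal day effects on
Bmax (day-to-day tissue/counting variation; the day-effect placement is
configurable in principle, Bmax-only by default), and proportional
(lognormal) measurement error with a common scale. Priors: lognormal on
Kd and Bmax centred on per-group least-squares estimates with scale 1.5
(≈ 30-fold, weakly informative); half-normal (scale 0.5) on the
day-effect sd and the noise sd. Sampling is affine-invariant ensemble
MCMC (emcee), ≥ 2×ndim walkers, run as independent chains (defaults:
3 chains, 50,000 total iterations, 25,000 burn-in); convergence is
assessed by the split-chain potential-scale-reduction statistic with
tolerance 1.01 and non-convergence is flagged and warned, never silent.
Identical seed and data give identical summaries.

Mechanism classification reads the 95% credible intervals against the
no-inhibitor reference: Bmax CI entirely below the reference CI →
**mixed** competitive/non-competitive; Bmax CIs overlapping with the Kd
CI entirely above the reference → **competitive**; anything else →
**indeterminate**. CI overlap is the operational reading of "difference
larger than the experimental noise".

Tests and the acceptance script run the sampler at reduced iteration
counts (600–4,500 total iterations; coverage over 60–100 simulated
datasets at the 9-concentration × 3-day design) — sizes chosen so the
whole suite runs in minutes while Monte-Carlo error stays well inside
the asserted tolerances; the 3 × 50,000/25,000 defaults remain the
production setting.

## Reproducibility

Every stochastic stage takes an explicit integer seed and is
bit-reproducible; `run_experiment` writes a JSON manifest (config,
seeds, versions) sufficient to regenerate every output. The CLI
(`tirfpharm simulate|detect|stats|fit-dr|fit-binding|occupancy|run-all`)
is a thin layer over the library; data go to files, logs to stderr.
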