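# Methods note

This note records what `octavd` computes, the parameter values it
defaults to, why those choices were made, and where the synthetic data
deliberately falls short of clinical reality.

## 1. Synthetic en face angiograms

`generate_vessel_image(params, seed)` grows a vessel network by
stroke-based random walks: seeds start on the image border aimed inward,
advance in 2-px steps with Gaussian direction jitter (SD 0.22 rad),
taper (0.5% per step, floor 0.9 px radius), and branch with probability
2% per step. Each stroke stamps a disk of the current width. Growth
stops when the foreground fraction reaches `target_density`, counted
over pixels **outside** the FAZ raster — so the target refers to the
final mask after the avascular zone is cleared — with exact,
deduplicated pixel bookkeeping. A hard budget (`max_strokes`, default
6000) bounds the work; if the target is not reached within it, or the
final mask falls below 90% of the target, `GenerationError` is raised.

The FAZ is a 24-gon at the image center with ±12% radial jitter; a
guard disk of radius `1.25 * faz_radius + 2` stops strokes so vessels
terminate at the avascular zone rather than crossing it. Rendering
applies, in order: a two-level intensity map (vessel 200, background
50), radial brightness falloff (fraction 0.3 at the corners), 15%
multiplicative speckle, additive Gaussian noise (SD 8), and clipping to
8-bit. The defaults give images on which local-Otsu recovery of the
true density is within ~1 percentage point.

Default scale: 6 mm / 512 px (≈11.7 µm/px), the common macular OCTA
field of view.

**Realism limits.** Strokes are disks on straight-ish walks: there is
no capillary-scale anastomotic mesh, no flow-projection artifact, no
motion stripes, and the FAZ boundary is polygonal rather than formed by
terminal capillary loops. Noise is stationary; real OCTA noise is
signal- and depth-dependent. These limits do not affect the validation
logic, which compares measurements to the generator's own ground truth.

## 2. Image standardization

`standardize` = central crop → contrast stretch → brightness
normalization.

- Crop keeps `floor(fraction * side)` pixels per axis (default 0.5, the
  central 3×3 mm of a 6×6 mm scan); an odd margin drops the extra pixel
  at the bottom/right.
- Contrast stretch maps the [0.5, 99.5] percentile window to [0, 255];
  the inset percentiles resist isolated speckle extremes. Constant
  images pass through unchanged.
- Normalization affinely rescales to mean 128 / SD 25 before rounding
  and clipping; zero-variance inputs return a constant image flagged
  `degenerate`.

## 3. Vessel quantification

`local_otsu_binarize(image, radius=15)` thresholds each pixel against
the Otsu split of its own `(2r+1)²` window (edge-clipped). It is
implemented as an exact integral-histogram sweep over the 255 candidate
splits: per-pixel class counts and sums are window box-sums of
per-intensity indicator images, and the between-class variance
`(S0*W1 - S1*W0)² / (W0*W1)` is maximized with first-maximum tie-break
(lowest threshold wins). Zero-variance windows admit no split and are
classified background; foreground is intensity ≥ threshold. With the
window covering the whole image this reduces exactly to global Otsu,
which the tests verify against an exhaustive search. Radius 15 px spans
several capillary widths at 11.7 µm/px and keeps both classes present
in each window.

Metrics from a mask and FAZ polygon:

- whole-image VD = vessel pixels / all pixels;
- extra-FAZ VD = vessel pixels / (all pixels − FAZ pixels) — the FAZ is
  assumed avascular, so only the denominator shrinks;
- FAZ area = FAZ pixels / all pixels (and mm² via the pixel scale).

Polygon areas are **rasterized** (pixel centers inside the polygon) in
all metric denominators, for consistency with pixel-count vessel areas;
the analytic shoelace area is exposed as a cross-check. Tests verify
the raster against an independent ray-casting implementation.

## 4. Longitudinal registration

Visits are aligned by a similarity transform (uniform scale + rotation
+ translation, no reflection) fitted in closed form: writing landmarks
as complex numbers, `a = Σ(w−w̄)(z−z̄)* / Σ|z−z̄|²` gives `s·e^{iθ}`
directly. Collinear source landmarks are rejected — the algebra still
solves, but the configuration has no leverage against annotation error
orthogonal to the line. Warping uses inverse-mapped bilinear
resampling with an in-frame validity mask (tolerance 1e-9 absorbs
floating-point residue of exact rotations). Comparison is restricted
to the maximal axis-aligned rectangle inside both fields of view,
found by the histogram-stack algorithm on the validity raster — a
deterministic stand-in for cropping the overlap by hand.

## 5. Cohort simulation

For eye *j* of patient *i* in group *g*:

```
y_ij = mu_g + beta' (x_ij - x̄_g) + sigma_g (sqrt(rho) b_i + sqrt(1-rho) e_ij)
```

Defaults: `rho = 0.5`; ages/CST/duration are truncated normals (20–90
years, 150–450 µm, 0–300 months); treatment is multinomial over (none,
oral, biologics, dual) with biologics as the modelling reference
(reference probabilities 0.15/0.40/0.25/0.20). Covariates are centered
at their **realized** per-group means: under asymmetric truncation the
realized mean differs from the configured one, and realized-mean
centering keeps the configured group means exact for every draw while
leaving slopes untouched.

**Design consequence.** Reference covariate effects are layered on top
of the configured group SDs, so outcomes with a large covariate
variance share (e.g. a duration slope of −0.16 %/month against a
duration SD of ~66 months) carry substantially more total variance than
the configured SD alone. Per-draw group-comparison power is
correspondingly lower than summary statistics computed without effects
would suggest; multi-replicate significance claims in the acceptance
suite therefore use plain normal draws at the configured means/SDs.

The longitudinal arm simulates 23 eyes of 16 patients with clustered
baseline values and paired deltas (default inter-eye correlation 0.5);
the deep-plexus FAZ-area delta defaults to mean +0.31 / SD 0.60,
detectable by the clustered Wilcoxon test at this sample size roughly
half the time — matching the marginal significance typical of small
longitudinal cohorts.

## 6. Statistics

- **Mann-Whitney U**: exact enumeration of all splits for n ≤ 12 per
  group (two-sided by symmetric tail probability `P(|U−μ| ≥ |u−μ|)`),
  tie-corrected normal approximation with continuity correction
  otherwise (matching the standard asymptotic implementation).
- **Clustered Wilcoxon signed-rank** (Rosner-Glynn-Lee): T = sum of
  signed ranks, Var = Σ (within-cluster signed-rank sums)², z = T/√Var.
  For singleton clusters this reduces exactly to the ordinary Wilcoxon
  normal approximation without continuity correction (ties via average
  ranks); a sign-flip permutation oracle verifies the clustered case.
  At least 5 clusters are required.
- **Correlations**: Pearson r with a patient-level cluster bootstrap
  (2000 replicates) for the two-sided p-value when clusters are given.
- **Clustered linear models**: GEE, Gaussian family, exchangeable
  working correlation, **bias-reduced (Mancl-DeRouen) sandwich SEs**,
  and a t reference with (patients − parameters) degrees of freedom.
  Null calibration at 28 patients / 53 eyes over 2000 replicates:
  plain sandwich + t rejected 6.8% at nominal 5%; bias-reduced + t
  rejected 5.05%, hence the default. The correction is undefined when
  a cluster has leverage one (a covariate level carried by a single
  patient); the fit then falls back to the plain sandwich and records
  it in `ModelFit.se_method`. With singleton clusters the bias-reduced
  sandwich equals OLS HC3 exactly, which serves as a reduction oracle.
- **Screen → multivariable workflow**: covariates univariably
  associated with the outcome at P < 0.10 enter a joint clustered
  model; with a single retained covariate the multivariable fit equals
  the univariable one identically. End-to-end type-I error of the
  workflow at nominal 0.05 measured 4.8% over 500 null cohorts.

## 7. Problem sizes and runtime

Everything is desk-scale on one CPU: 256² image generation ~0.1 s,
local Otsu at 256² ~0.7 s, a full seeded pipeline run (`run_reproduce`)
~2 s, the complete test suite ~1 min, and the heaviest acceptance tests
(500-replicate calibration, 200-replicate coverage) ~20 s combined.

## 8. Numerical conventions

- Intensities are uint8 throughout; intermediate float computations are
  rounded (`rint`) and clipped before storage.
- Otsu ties resolve to the lowest threshold (first maximum in the
  sweep); crop ties drop the bottom/right pixel.
- All randomness flows through `numpy.random.default_rng`; pipeline
  stages draw sub-seeds from `SeedSequence.spawn`, reduced mod 2³¹.
- FAZ-area percentages are not clamped: the cohort generator can emit
  values outside a physically plausible range in extreme draws, which
  is accepted for distributional fidelity to the configured moments.
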