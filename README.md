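# octavd — OCT-angiography vessel-density analysis

`octavd` is a library for quantifying retinal capillary loss on en face
OCT-angiography (OCTA) images, built around the analysis design of
case-control uveitis studies such as birdshot chorioretinopathy (BCR)
cohorts. It covers the full desk-scale pipeline:

- **Synthetic data with ground truth** — a branching vessel-network
  generator producing 8-bit en face angiograms with a known vessel mask,
  a clear foveal avascular zone (FAZ), peripheral brightness falloff and
  speckle noise; plus an eye-level cohort generator with configurable
  group means/SDs, within-patient inter-eye correlation and linear
  covariate effects.
- **Image standardization** — central crop, percentile contrast stretch
  and brightness normalization, so scans from different sessions are
  thresholded on a common scale.
- **Vessel quantification** — local (per-pixel neighbourhood) Otsu
  binarization and three outcomes per eye and plexus: whole-image vessel
  density (VD, %), extra-FAZ VD (%) and FAZ area (% and mm²).
- **Longitudinal registration** — closed-form least-squares similarity
  transforms from matched landmarks, image warping, and a maximal
  inscribed-rectangle overlap crop so both visits are measured over the
  same retinal area.
- **Eye-clustered statistics** — exact/tie-corrected Mann-Whitney,
  the clustered Wilcoxon signed-rank test (Rosner-Glynn-Lee), cluster
  bootstrap correlations, and GEE linear models with bias-reduced
  cluster-robust standard errors for two-eyes-per-patient data, wired
  into the study's screen-then-multivariable workflow.

Because clinical OCTA images are private, the package is validated
end-to-end on simulation: every measurement has a ground truth or an
independent oracle, and the statistical machinery is calibrated against
null simulations and published summary statistics.

## Statistical model

Cohort outcomes follow a compound-symmetry model. For eye *j* of
patient *i* in group *g*:

```
y_ij = mu_g + beta' x_ij + sigma_g * (sqrt(rho) * b_i + sqrt(1-rho) * e_ij)
```

with `b_i, e_ij ~ N(0,1)`, within-patient correlation `rho` (default
0.5), and linear covariate effects `beta` applied to covariates centered
at their realized group means (so `mu_g` is preserved exactly).
Group comparisons use the Mann-Whitney U test; paired visit changes use
the clustered Wilcoxon signed-rank test with variance `sum(cluster rank
sums squared)`; adjusted associations use GEE (Gaussian, exchangeable
working correlation) with Mancl-DeRouen bias-reduced sandwich SEs and a
t reference on (patients − parameters) degrees of freedom.

## Worked example

Simulate a cohort of 53 affected eyes (28 patients) versus 110 control
eyes (59 patients) and run the case-control analysis
(`examples/04_cohort_statistics.py`):

```python
from octavd import (generate_cohort, mann_whitney_u, multivariable_fit,
                    reference_cohort_spec, reference_covariate_effects,
                    univariable_screen)

spec = reference_cohort_spec(covariate_effects=reference_covariate_effects())
cohort = generate_cohort(spec, seed=0)

dcp = cohort[cohort.plexus == "DCP"]
res = mann_whitney_u(dcp[dcp.group == "BCR"]["whole_vd"],
                     dcp[dcp.group == "control"]["whole_vd"])

sub = dcp[dcp.group == "BCR"]
retained, _ = univariable_screen(sub, "whole_vd",
                                 ["age", "sex", "cst_um", "duration_months",
                                  "treatment", "active"], alpha=0.10)
fit = multivariable_fit(sub, "whole_vd", retained)
print(fit.table.round(4))
```

Output:

```
DCP whole VD: affected 30.1% vs control 38.6%, Mann-Whitney p = 1.29e-04
screen retained (P < 0.10): ['age', 'cst_um', 'duration_months']
multivariable clustered model (53 eyes, 28 patients, bias_reduced SEs):
                 estimate      se       p  ci_low  ci_high
age               -0.3071  0.1609  0.0683 -0.6391   0.0250
cst_um             0.0328  0.0129  0.0179  0.0062   0.0595
duration_months   -0.1789  0.0302  0.0000 -0.2412  -0.1166
```

The deep-plexus vessel-density deficit in affected eyes is strongly
significant, and the clustered model recovers the generating
coefficients (age −0.31, CST +0.027, duration −0.18) within their CIs.

The image side is just as direct (`examples/02_quantify.py`):

```
noiseless image:
  true VD 33.00%  measured VD 33.00%
noisy image, standardized:
  true VD 33.00%  measured VD 34.10%
  extra-FAZ VD 34.75%  FAZ area 1.85% (0.1666 mm^2)
```

All five example scripts under `examples/` run in seconds and print
their own interpretation lines. A thin CLI mirrors the stages:

```bash
octavd simulate image --out demo --seed 42
octavd quantify manifest.csv metrics.csv --otsu-radius 15
octavd reproduce --seed 0 --out reproduction
```

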