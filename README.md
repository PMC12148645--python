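# ufiber

Short association fiber (U-fiber) tractometry and developmental
microstructure statistics.

Short association fibers (SAFs) are the 5–40 mm U-shaped streamlines of the
superficial white matter, running directly beneath the cortex and mediating
local cortico-cortical connections. Unlike the major long-range (LR)
bundles, they mature late — into the third decade of life — and their
relationship to the deep tracts they accompany is an open question in
developmental neuroimaging. `ufiber` is a desk-scale, fully testable
implementation of the analysis chain used to study that question: it
classifies SAF streamlines by proximity to LR bundle masks, extracts
bundle-wise diffusion features, models their development across age and
sex, and tests whether the microstructural coupling between an LR bundle
and *its* SAF is specific — stronger than the coupling with unrelated
bundles. Because real developmental MRI cohorts cannot ship with a
package, every stage is driven by synthetic phantoms and cohorts with
known ground truth, so each claim the pipeline makes is scored against
the generative design that produced its inputs.

## What it computes

**Classification.** Streamlines are kept if their arc length lies in
[5, 40] mm, assigned to every LR bundle whose binary mask they traverse
(exact segment–voxel marching, not point sampling), and cleaned with a
multi-scale QuickBundles filter: the bundle is re-clustered under the
minimum-average-direct-flip (MDF) metric at a geometric ladder of
thresholds, and a streamline is kept only if it lands in a cluster holding
at least 5% of the bundle in at least a fraction α = 0.6 of the levels.

**Microstructure.** Diffusion tensors are fit voxel-wise by weighted
log-linear least squares restricted to b ≤ 1500 s/mm², yielding FA, MD,
AD and RD; NODDI-style features (ICVF, ISOVF, ODI) are consumed at the
feature level. Each feature is averaged over a bundle's voxels.

**Development.** Each bundle-wise feature *y* (z-scored) is modelled as

```
y = β0 + β1·Age + β2·Sex + β3·Age·Sex + β4·zTICV + ε
```

with age in years, sex coded 0 = female / 1 = male (so β1 is the female
age slope and β1 + β3 the male one), and total intracranial volume
z-scored. Fits use iteratively reweighted least squares with Tukey's
bisquare weight (c = 4.685, MAD residual scale), which discounts gross
outliers. Raw-scale age slopes are also expressed as percent change per
year of the population mean. SAF and LR effect sizes are compared with a
two-tailed z-test on the coefficient difference. All families of tests
are controlled with Benjamini–Hochberg FDR at α = 0.05.

**Coupling specificity.** Feature values are correlated between bundles
across participants with partial Pearson correlations (controlling age,
sex, zTICV), Fisher-z transformed (z = atanh r), and each LR bundle's
associated-SAF correlation is compared to the mean of its correlations
with all other SAFs (hypothesis "saf") or all other LR bundles
(hypothesis "lr") via a one-tailed Z-test with SE = 1/√(N − k − 3),
k = 3 covariates.

## Worked example

```python
from ufiber import (SimDesign, simulate_cohort, fit_all_bundles,
                    fit_ticv_model, run_specificity)

design = SimDesign(n_participants=616, pathways=("AF", "CST", "CC"),
                   coupling_assoc=0.6, coupling_nonassoc=0.2, seed=42)
cohort, features, truth = simulate_cohort(design)

ticv = fit_ticv_model(cohort)
print(f"TICV model: beta_age={ticv.beta_age:+.3f}, "
      f"beta_agexsex={ticv.beta_agexsex:+.3f}, "
      f"male slope={ticv.male_age_slope:+.3f} SD/yr")

results = fit_all_bundles(features, cohort)
age = results[(results.term == "age") & (results.tier == "SAF")]
print(age[["pathway", "feature", "beta", "q", "significant"]].head(4))

spec = run_specificity(features, cohort)
print(spec[(spec.hypothesis == "saf") & (spec.feature == "MD")]
      [["pathway", "Z", "p_one_tailed", "significant"]])
```

prints

```
TICV model: beta_age=-0.027, beta_agexsex=+0.060, male slope=+0.033 SD/yr
pathway feature      beta            q  significant
     AF      AD -0.022155 8.136979e-02        False
     AF      FA  0.035924 4.865168e-03         True
     AF    ICVF  0.072318 3.445421e-07         True
     AF   ISOVF  0.042999 1.193356e-03         True
pathway        Z  p_one_tailed  significant
     AF 6.374640  9.169641e-11         True
     CC 4.120596  1.889466e-05         True
    CST 5.798810  3.339352e-09         True
```

The TICV sub-model recovers the generator's diverging male/female
trajectories (females' intracranial volume drifts slightly down with age,
males' slightly up); the effect matrix flags the feature–age associations
that survive FDR in standard-deviation-per-year units; and the
specificity table shows that with associated coupling 0.6 against
background 0.2, every LR bundle's own SAF stands out (Z ≫ 0).

A command-line interface mirrors the stages
(`ufiber simulate-cohort | simulate-phantom | classify-saf | fit-dti |
analyze regress|compare|specificity | run-all`); `ufiber run-all
--seed 5 --out run/` writes effect matrices, percent-change and
specificity tables, per-pathway correlation matrices and a manifest that
reproduces the run bit-for-bit.

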