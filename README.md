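# tissuefractal

Multiparametric quantification of structural complexity and disorder in
grayscale tissue micrographs.

Bright-field transmission images of tissue encode local mass density in
their pixel intensities: denser tissue changes the refractive index and,
with it, the transmitted intensity. `tissuefractal` turns that intensity
field into a suite of interpretable structural biomarkers aimed at
comparing a control cohort against a disease cohort (for example healthy
vs. neurodegenerative brain tissue), where disease progression shows up as
heterogeneous mass accumulation and growing nanoscale disorder:

1. **Threshold-dependent box-counting fractal dimension.** Each image is
   binarized at a grayscale threshold `g` (foreground = intensity ≥ g;
   expressed as a percent of full scale, `100·g/256`), tiled into regions,
   and the per-region dimension is the least-squares slope

   `Df = slope of ln N(r) vs ln(1/r)`

   where `N(r)` counts occupied boxes of side `r`. Sweeping the threshold
   grid (default 25–155 in steps of 5) yields MeanDf / STDDf trajectories;
   the *optimal threshold* maximizes the between-group difference.
2. **Multifractal spectrum (direct μ-measure method).** The intensity
   field is a mass measure with box fractions `P(ε,i)`; the Q-warped
   weights `μ_i(Q,ε) = P_i^Q / Σ P_j^Q` give the singularity strength
   `α(Q)` and spectrum `f(Q)` as regression slopes over `ln ε`, without a
   Legendre transform. Bandwidth `Δα = αmax − αmin` measures heterogeneity.
3. **Fractal functional transformation.** `Dtf = Df / (Dfmax − Df)` with
   `Dfmax = 2` for planar images; `ln Dtf` is approximately Gaussian, so
   Mean(lnDtf) and STD(lnDtf) are statistically well-behaved quantification
   parameters. Gaussianity is scored by a chi-square test (100 × p-value).
4. **Inverse participation ratio (IPR).** Relative intensity fluctuations
   `ε_i = (I_i − Ī)/Ī` in an L×L window form the site potentials of an
   Anderson tight-binding lattice (`t = 1`, open boundaries);
   `IPR_k = Σ |E_k|⁴` of each unit-normalized eigenvector lies in
   `[1/L², 1]` and its mean over all L² states, ⟨IPR⟩, grows with
   structural disorder.

A synthetic-data module provides ground-truth fixtures for every
estimator — Sierpiński-type carpets (exact monofractals), binomial
multiplicative cascades (closed-form multifractal spectra), Anderson
lattices of tunable disorder width, and pseudo-tissue textures with a
`severity` knob that reproduces the control-vs-disease contrast in every
metric.

## Worked example

```python
import numpy as np
from tissuefractal import (CarpetSpec, make_carpet, fit_dimension, percent_of,
                           make_cohort, RunConfig, run_all)

# exact monofractal oracle: level-4 Sierpinski carpet
carpet = make_carpet(CarpetSpec(base=3, retained=8, levels=4))
res = fit_dimension(carpet, box_sizes=(3, 9, 27))
print(f"Sierpinski carpet Df = {res.df:.6f}")

print(f"grayscale 110 -> {percent_of(110):.5f}% of full scale")

# seeded pseudo-tissue cohorts: severity 0 (control) vs 1 (disease)
control = make_cohort(5, severity=0.0, seed=11, size=240)
disease = make_cohort(5, severity=1.0, seed=22, size=240)
report = run_all(RunConfig(ipr_sizes=(4, 8, 16)),
                 images_a=control, images_b=disease)

mc = report["trajectory"]["contrasts"]["mean_df"]
print(f"optimal threshold (MeanDf): gray {mc['optimal_gray_level']} "
      f"({mc['optimal_percent']:.3f}%), control {mc['value_control']:.4f} "
      f"vs disease {mc['value_disease']:.4f}")
for name, value in report["percent_change_table"].items():
    print(f"{name:10s} {value:+7.2f}%")
```

prints

```
Sierpinski carpet Df = 1.892789
grayscale 110 -> 42.96875% of full scale
optimal threshold (MeanDf): gray 155 (60.547%), control 1.9292 vs disease 1.9489
MeanDf       +1.02%
STDDf       +42.18%
Mean_lnDtf  +24.19%
STD_lnDtf  +157.71%
Mean_IPR     +5.36%
```

The carpet dimension matches the analytic value ln 8 / ln 3 ≈ 1.892789 to
machine precision because the box sizes divide the construction scales.
The cohort contrast shows every headline metric higher in the "disease"
group: its masks are fuller at high thresholds (MeanDf), more variable
region-to-region (STDDf, and amplified by the functional transform in
Mean/STD lnDtf), and its windows are more disordered (⟨IPR⟩).

## Command line

```bash
tissuefractal synth tissue --size 480 --severity 0.7 --seed 3 --out img.png
tissuefractal boxcount img.png --threshold-gray 110 --region 60
tissuefractal mfa img.png --q -10:10:0.5 --eps 2,4,6,10,12 --out mfa.csv
tissuefractal ipr IMGDIR --sizes 2,4,8,16,32 --out ipr.json
tissuefractal sweep --group-a DIR_A --group-b DIR_B --sweep 25:155:5 --stat mean
tissuefractal run --group-a DIR_A --group-b DIR_B --out-dir results/
```

`tissuefractal run` executes the full pipeline and writes `report.json`,
per-curve CSVs, raw per-window IPR values and (optionally) trajectory and
IPR plots.

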