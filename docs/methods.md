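# Methods

## Scope and data model

All analyses operate on 2D grayscale intensity fields with integer values
on the 0–255 scale (`GrayImage`). 16-bit rasters are linearly rescaled
(255·v/65535, rounded) and RGB inputs converted with BT.601 luminance
weights on read. Region tiling uses 1-based `(row, col)` tile coordinates
(tile (1,1) top-left, row-major); remainder pixels that do not fill a
complete tile are dropped rather than padded, since padding would inject
artificial structure into the box counts. Pixel indexing inside arrays is
0-based.

## Threshold convention

A binarization threshold is a grayscale level `g ∈ [0, 255]`; its percent
form is `100·g/256` (percent of the number of representable levels). The
divisor 256 is the only convention consistent with every documented
level/percent pair (110 ↔ 42.968…, 95 ↔ 37.1094, 80 ↔ 31.25,
150 ↔ 58.59); it is exact in binary floating point. Pixels exactly at the
threshold are foreground (≥ rule). The default sweep grid is 25–155 in
steps of 5 — the range over which tissue masks transition, with every
commonly reported optimum on the grid.

## Box-counting dimension

`N(r)` counts occupied cells of an axis-aligned grid of side `r` anchored
at the top-left corner; ragged edge cells are included. `Df` is the
ordinary least-squares slope of `ln N(r)` against `ln(1/r)` over the full
box-size list (no size windowing), with the coefficient of determination
reported. Defaults: box sizes (2, 4, 6, 10, 12) on 60×60 regions; both are
configurable, and regions of 30/60/120/240 are the intended working range.
Grid-anchored (non-sliding) counting keeps `N(r)` exact on self-similar
fixtures whose construction scales divide the image side, which is what
lets the test suite pin the estimator to analytic dimensions at 1e-9.

Empty regions have no defined dimension (`ln 0`): they are excluded from
MeanDf/STDDf with the exclusion count surfaced, never coerced to zero.
STDDf is the sample standard deviation (ddof = 1).

## Threshold trajectories and optimal thresholds

At each grid threshold the per-region `Df` values of all images in a group
are pooled (not averaged per image first; pooling matches the pooled
region-level distributions the statistics summarize). Thresholds where
every region of every image is empty stay in the curve as gaps — zeros
would fabricate a spurious optimum.

The optimal threshold for a statistic (MeanDf, STDDf, Mean(lnDtf),
STD(lnDtf)) maximizes the absolute between-group difference over the grid;
ties break toward the lowest threshold, and percent change always uses the
control group as denominator. A **minimum-support rule** (default 10
regions per group per entry, configurable, 0 disables) excludes grid
entries whose statistic rests on a handful of surviving regions: near the
all-foreground or all-background ends of the grid a mean or standard
deviation over two or three regions is not a comparable group statistic,
and with small cohorts such entries would otherwise dominate the argmax.
With cohorts of ten 480×480 images and 60×60 regions (640 regions per
entry) the rule is inert.

## Multifractal spectrum

The intensity field of a region is treated as a mass measure: at box side
ε, `P(ε,i)` is the box's share of total intensity. For each moment order Q
(default grid −10…10, step 0.5) the normalized weights
`μ_i = P_i^Q / Σ P_j^Q` are computed in log space (|Q| = 10 on small
masses would otherwise overflow), with zero-mass boxes dropped before
exponentiation since `P^Q` diverges for negative Q. Then

* `α(Q)` = slope of `Σ μ_i ln P_i` over `ln ε`,
* `f(Q)` = slope of `Σ μ_i ln μ_i` over `ln ε`,

by least squares over the box-side list (default (2, 4, 6, 10, 12),
matching the box-counting scales for comparability; per-Q r² is reported).
For exact multiplicative cascades both sums are exactly linear in `ln ε`,
so the estimator reproduces the closed form
`τ(Q) = −log_b Σ w_i^Q`, `α = −(Σ w^Q ln w)/(ln b · Σ w^Q)`, `f = Qα − τ`
to machine precision — the independent oracle used in the tests. With a
single box side the estimator degenerates to the quotient form, with a
warning.

Spectrum parameters (αmin, αmax, Δα, fmin, fmax, Δf) are extrema over the
Q grid. Estimated `f` values above the support dimension are reported
as-is: a finite-size estimator can produce them, and clamping would hide
the bias. Group-level spectra are pointwise means of per-image spectra
over the shared Q grid.

## Fractal functional transformation

`Dtf = Df / (Dfmax − Df)` with `Dfmax = 2` for planar images; the map is
strictly increasing on (0, 2) and exactly inverted by
`Df = 2·Dtf/(1 + Dtf)`. Regions with `Df ≤ 0` or `Df ≥ 2 − δ` (pole guard
δ = 1e-9) are excluded and counted, not clipped — clipping would
manufacture outliers in `ln Dtf`. Gaussianity of a sample is scored by a
Pearson chi-square test against the fitted normal using bins of equal
expected probability (default 10 bins, dof = bins − 3); the score is
100 × p-value, so scores near 100 mean "indistinguishable from Gaussian".
The operational definition of the score is configurable in the sense that
the fit object also exposes the raw statistic and p-value.

## Tight-binding IPR

Each L×L window yields site potentials `ε_i = c·(I_i − Ī)/Ī` (window mean
as the reference intensity; `c` is an exposed `disorder_scale`, default 1,
because the physical proportionality between relative intensity and
relative refractive-index fluctuation is not calibrated). The Hamiltonian
has the potentials on the diagonal and hopping `t = 1` between 4-neighbor
sites, open boundaries by default (periodic optional). All L² eigenstates
enter `⟨IPR⟩ = (1/N) Σ_k Σ_sites |E_k(site)|⁴`; no energy filtering.

Numerical choices:

* The diagonal is centered (mean subtracted) before diagonalization.
  Eigenvectors are invariant under uniform potential shifts, so this makes
  shift invariance of every IPR exact by construction instead of relying
  on solver reproducibility inside degenerate subspaces.
* Windows are non-overlapping (overlap would correlate the lattice
  statistics); group mean/STD are over the pooled windows of all images
  (sample std, ddof = 1). Zero-mean (fully dark) windows carry no
  relative-fluctuation signal and are skipped.
* Scans batch all windows of one size into a stacked symmetric
  eigendecomposition, chunked to bound memory.

Two empirical regimes worth knowing: (i) at small L (2, 4) the ordered
lattice is highly degenerate and ⟨IPR⟩ is *non-monotonic* in weak disorder
— weak potentials select more-extended perturbative eigenvectors before
localization takes over — so only sufficiently strong disorder contrasts
are meaningful there; (ii) raw ⟨IPR⟩ falls roughly like 1/L² with window
size for weakly disordered windows. The growth of disorder with window
scale is therefore read from the participation relative to the extended
limit, `⟨IPR⟩·L²` (`IPRResult.mean_normalized`), which increases with L on
spatially correlated heterogeneity.

## Synthetic fixtures

Every generator is pure given (spec, seed).

* **Carpets** (`make_carpet`): at each level every active cell keeps m of
  its b² subcells — deterministically (cells farthest from the center
  first, reproducing the classical Sierpiński carpet at b=3, m=8) or
  uniformly at random. Each active cell has exactly m active children, so
  box counts at construction scales are exactly m^level and the analytic
  dimension is ln m / ln b.
* **Cascades** (`make_cascade`): b² non-negative weights summing to 1,
  multiplied down k levels (optionally shuffled per cell, which permutes
  box masses without changing the spectrum). Output is kept as a float
  measure; 8-bit quantization happens only on explicit export, because it
  destroys deep-level mass ratios.
* **Anderson lattices** (`make_anderson`): i.i.d. site potentials
  ~ Uniform(−W/2, W/2).
* **Pseudo-tissue** (`make_pseudo_tissue`): a 480×480 (default) image
  composed of
  - a fine-grained correlated Gaussian field (spectral synthesis,
    power-spectrum slope β = 1.5) of scale σ = 25 around background 160 —
    fine grain makes healthy regions self-average to a tight per-region Df
    distribution;
  - two much smoother patch fields (β = 4, sigmoid-squashed): accumulated
    patches brightened by ×(1 + 0.28·s·m_acc) and atrophic patches dimmed
    by ×(1 − 0.10·s·m_loss), where s ∈ [0, 1] is the severity knob. The
    accumulation/loss mixture raises both the mean and the between-region
    spread of Df at high thresholds while leaving low-threshold masks
    statistically unchanged;
  - Poisson-placed Gaussian clumps with lognormal peak intensities
    (density, amplitude and tail width all grow with severity) —
    long-tailed localized mass accumulations;
  - multiplicative pixel noise (CV 0.06, growing with severity) — keeps
    relative heterogeneity alive even in saturating bright patches;
  - severity-scaled dark "micro-pore" pixels (isolated extreme scatterers;
    rate 0.1% → ~4%). Being isolated, they barely touch box counts but
    dominate the IPR contrast at the smallest window sizes.

  The generator emulates the *statistical* signatures the analyses target
  (threshold-dependent mask structure, long-tailed region statistics,
  scale-dependent relative fluctuations), not histology: there is no
  staining model, no optics PSF, no anatomical structure. Passing
  direction tests on these cohorts shows the pipeline responds correctly
  to controlled heterogeneity; it does not validate any claim about real
  tissue.

## Demonstration scales

The package defaults mirror the reference study conditions (10 images per
group, 480×480 px, grid 25–155 step 5, 60×60 regions, boxes
(2, 4, 6, 10, 12), Q ∈ [−10, 10], IPR sizes (2, 4, 8, 16, 32)). The
end-to-end direction test in the suite runs 10 vs 10 cohorts at 240×240 px
with IPR sizes (4, 8, 16), and the all-sizes IPR severity check uses 2 + 2
images at 128×128 — the package's chosen demonstration sizes, which keep
every distributional feature of the full-scale setup while the whole suite
runs in minutes.

## Known limitations

* The box-size lists must be small relative to the region side; the OLS
  fit uses all provided sizes without windowing, so a poorly chosen ladder
  (e.g. sizes comparable to the region) biases Df.
* The multifractal estimator assumes the measure is well sampled at every
  box side; on nearly-binary sparse regions the negative-Q branch is
  noise-dominated (r² per Q is reported for exactly this reason).
* The chi-square Gaussianity score is a p-value: it is uniform under the
  null, so single-sample scores fluctuate; only systematic differences
  (e.g. log vs raw) are meaningful.
* ⟨IPR⟩ contrasts at L = 2 and 4 require strong local scatterers (see the
  degeneracy note above); smooth weak heterogeneity is invisible there.
* Dense eigendecomposition limits practical window sizes to L ≲ 64
  (L² × L² matrices).
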