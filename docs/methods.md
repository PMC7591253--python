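# Methods

curlquant re-implements, as a tested library, the quantitative analyses used
in zebrafish studies of Reissner-fiber-dependent body-axis straightening:
dual-allele RNA-seq consistency screening, calcium-trace activity
quantification in CSF-contacting neurons, relative qPCR, and body-axis
morphometrics with Mendelian rescue statistics. This note records the models,
the defaults and why, and the limits of what the synthetic benchmarks show.

## Dual-allele differential-expression consistency (`curlquant.de`)

**Procedure.** Counts are normalised to counts per million (CPM). Within each
(allele, phenotype) condition cell, the two most mutually consistent of the
three replicates are kept, ranked by mean Spearman correlation of
log2(CPM + 1) against the other members of the cell; the original analysis
made this call by eye from a PCA, and rank correlation is the reproducible
automatable proxy (a PCA-centroid-distance metric is available as
`reliability_metric="pca"`). Genes below 1 CPM in the straight-control
average are removed. Genes with a curled/straight fold change ≤ 0.75 (down)
or ≥ 1.45 (up) on the reliable-replicate averages form two shortlists. For
those genes, a per-gene linear model is fitted to log2(CPM + 0.5) of **all**
original samples with phenotype indicators (straight, curled) as regressors
of interest and allele-family indicators as confounders; the curled − straight
contrast is tested with a t-test on n − rank(X) = 9 df for the full 12-sample
design. The two-indicator-per-factor encoding is rank deficient (rank 3); the
contrast is estimable, and coefficients use the Moore–Penrose pseudo-inverse,
verified equal to a reduced full-rank parameterisation at 1e-10. Finally a
Benjamini–Hochberg rank rule with q = 0.2 is applied to each direction's
p-value-sorted shortlist: selection stops at the first rank i where
p₍ᵢ₎ > (i/N)·q, N being that shortlist's size; ties in p break by gene id.

**Numerical choices.** The log2 response (rather than raw CPM) stabilises
variance and makes β a log2 fold change; a linear-CPM response is exposed.
Thresholds are inclusive (≥ 1 CPM kept, FC ≤ 0.75 / ≥ 1.45 shortlisted).
Zero residual variance with a nonzero contrast is reported as p = 0 with a
`degenerate_fit` flag; an all-constant gene as p = 1 with `constant`. Empty
shortlists propagate as empty reports rather than errors.

**FDR is not controlled at q by this design — a documented limitation.**
The BH rule is applied to genes *pre-selected for extreme fold change*, and
the same noise that pushes a null gene past the fold-change cutoff also
deflates its consistency p-value. The p-values entering BH are therefore not
uniform under the null, and BH's guarantee does not transfer: in all-null
simulations at the default conditions, the selected set is non-empty in most
runs (mean false-discovery proportion ≈ 0.8–1.0, versus the q + margin ≈ 0.25
one would expect if the guarantee held). This is a property of the
shortlist-then-test design itself, not of its implementation here: fitting
the same GLM to *all* expressed genes in a null simulation gives exactly
uniform p-values (KS test against U(0,1), p = 0.86), and BH applied to that
unselected list controls FDR as expected. Screens built this way should
treat the selected list as candidates for independent validation (as the
original study did, by qPCR), not as an FDR-controlled discovery set.

## Calcium activity (`curlquant.calcium`)

Per-cell activity is ∫ΔF/F min⁻¹. The baseline F0 is the 10th percentile of
the full trace — robust to transients at the duty cycles seen here (a
sliding-window percentile is exposed for drifting baselines); ΔF/F =
(F − F0)/F0; the trapezoidal integral over the recording, with time in
minutes, is divided by the duration in minutes, so a constant ΔF/F of c
scores exactly c and the statistic is invariant to rescaling the raw
fluorescence and to resampling rate (up to trapezoid error). Negative
excursions subtract by default (a flat noisy trace can score slightly
negative); `rectify=True` floors at zero. Populations are compared by the
median percent change, (median_ref − median_test)/median_ref × 100 (positive
= decrease), with a two-sample Kolmogorov–Smirnov test; the asymptotic
p-value matches the hundreds-of-cells group sizes this statistic is used
with, and the exact method is available for small samples. Groups under 3
cells are refused.

## Relative qPCR (`curlquant.qpcr`)

Technical-replicate CTs (2–3 per reaction) are averaged; ΔCT is taken
against the housekeeping reference (lsm12b by default) within the same
biological replicate, and relative abundance is 2^−ΔCT — invariant to
per-plate CT offsets. Paired designs form per-replicate ratios
test/control and report their mean ± SEM; when the mean ratio is below 1 a
"fold decrease" is reported as the mean ± SEM of the per-replicate
reciprocals, the convention used when replicate experiments are summarised
as "x.x ± s fold decrease". Unpaired designs (no replicate matching) use the
ratio of group means with a delta-method SEM. Significance comes from a
Student t-test on the abundances (paired on differences, unpaired pooled
variance); zero-variance cases are flagged degenerate with p forced to 1
(no difference) or 0 (constant shift) to keep pipelines total.

## Morphometrics and rescue statistics (`curlquant.morphometry`)

Axis shape is the angle at the caudal limit of the yolk extension between
rays to the ear and to the tail tip. The convention is fixed by the image
frame (rostral toward −x, dorsal toward +y): the interior angle θ is
extended to 360 − θ when the tail lies dorsal to the vertex→ear ray, so
straight embryos read slightly above 180°, curled-down well below, and
curled-up above. Collinear landmarks give exactly 180°; the measure is
exactly invariant to translation and uniform scaling, and y-mirroring maps
θ ↦ 360 − θ. Curled/straight classification is an input label (scored by
eye in practice); the angle<150° classifier exists only to close the loop
in fully synthetic pipelines and is marked non-canonical. Clutch frequencies
are reported pooled (Σcurled/Σtotal) and as per-clutch mean ± SEM; pooled
equals the count-weighted per-clutch mean. Mendelian expectations treat
curled-down as recessive (het×het → 25%). Rescue experiments compare matched
clutches split between treatments with a paired t-test on per-clutch
frequencies.

## Synthetic data (`curlquant.synthetic`)

All generators are deterministic given their seed and return the planted
truth alongside the data.

**Counts.** Negative binomial, mean–dispersion form (variance
μ + μ²·dispersion). Defaults: 2 alleles × 2 phenotypes × 3 replicates;
baseline log2-CPM abundances uniform on (−2, 10), spanning filtered to
highly expressed genes; library sizes 20–40 M reads (typical bulk RNA-seq
depth — at 1 CPM ≈ 30 counts, so Poisson noise does not swamp biological
dispersion); dispersion 0.01, the canonical biological coefficient of
variation (~0.1) for genetically identical model organisms, appropriate
here where each library pools 30 embryos. Under these defaults ~0.3–1% of
expressed null genes cross the fold-change cutoffs, the same order as the
shortlist fractions observed in real screens of this design. Planted
classes: shared down/up effects (default log2FC −2, i.e. the ~4-fold scale
of the strongest real hit), allele-specific effects (one allele only), and
nulls. Every gene receives a per-allele-family log-normal batch offset
(default sd 0.25 log2 units) shared by all samples of that family — the
confounder the GLM must absorb. An optional "unreliable replicate" gets
extra per-gene log-normal noise of log2-sd (noise_inflation − 1),
decorrelating it so the reliability ranking can find it. Dispersion 0 gives
deterministic rounded-mean counts. Note counts are compositional (fixed
library total): planting a large down-regulated mass inflates all other
CPMs, so planted fold changes are recovered exactly only when the planted
genes are a negligible mass fraction.

**Calcium traces.** Poisson-timed transients — instantaneous rise of
amplitude ΔF/F 1.0, single-exponential decay τ = 2 s (the simplest kernel
matching GCaMP phenomenology; the event rate, amplitude, and τ are all
config fields) — on a constant baseline of 100 a.u. with Gaussian noise
(sd 2 a.u.), sampled at 4 Hz for 240 s. The published acquisition states
rate and duration but delegates trace processing to an archived script, so
kinetics and noise here are stated defaults, not reproductions. Group
labels scale event rates (e.g. mutant × 0.5). Truth stores event times and
the noise-free integral per cell.

**qPCR.** CT = intercept − log2(true abundance) + N(0, sd) per technical
replicate; defaults intercept 22 cycles, sd 0.2 cycles (a typical SYBR
plate repeatability), 3 technical replicates.

**Clutches.** Genotypes drawn per cross (het×het → ¼, ½, ¼); an embryo is
curled iff homozygous and not rescued (rescue probability per homozygote
under treatment).

**Landmarks.** Target angles drawn Normal(mean, sd) per group, clipped to
(0, 360); default sd 15°, matching the within-group spread of printed angle
distributions. The vertex sits at the origin, the ear at distance 1.0 on the
rostral side, the tail at distance 1.5 in the direction realising the target
angle — any configuration with that angle is equivalent for the quantifier.

**What the synthetic benchmarks do not show.** The generators emulate the
statistical structure of each modality, not its physics: no read mapping or
GC/length bias, no bleaching or motion in traces, no amplification-efficiency
differences between primer pairs, no imaging distortion of landmarks, and no
clutch-to-clutch penetrance variability. Passing recovery tests demonstrates
the estimators are correct for the stated noise models, not that those
models exhaust real-data failure modes.

## Problem sizes used in the automated checks

Simulation-based checks run at sizes chosen to make their Monte-Carlo error
comfortably smaller than the tolerance being asserted: 5,000-gene count
experiments (10 seeds for the null FDR property, 3 for power), 200 cells per
group for calcium recovery, 100 seeds for qPCR fold recovery, 10⁴ embryos
for the Mendelian fraction (binomial SE ≈ 0.4 points against a ±1.5-point
band), and 10⁵ for the genotype-frequency convergence property.
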