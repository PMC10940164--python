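# Methods

## TMT processing

A PSM table carries per-channel reporter intensities plus two acquisition-side
quality attributes: the reporter signal-to-noise summed across the plex
(`summed_snr`) and the MS1 isolation purity. QC keeps PSMs with
`summed_snr > 200` **and** `isolation_purity > 0.5`; both inequalities are
strict, so a PSM sitting exactly at a threshold is removed. Filtering is
applied before channel normalization: the QC attributes describe acquisition,
not relative channel loading, so normalization factors should not be computed
from unreliable PSMs.

Channel sum-normalization equalizes protein input across channels: with
`T_c` the total intensity of channel `c` over all retained PSMs, every
intensity in channel `c` is multiplied by `median(T)/T_c`, after which all
channel totals equal the median of the original totals. For an even plex
size the median is the midpoint of the two central totals (standard sample
median). The transform is idempotent — a second pass computes factors of
exactly 1. A channel with zero total is an error naming the channel; zero
intensities inside retained PSMs are kept as zeros (no imputation).

Protein quantification sums the normalized intensities of a protein's PSMs
per channel. Summing weights each PSM by its own signal, i.e. a
weighted-average quantification; a protein with no retained PSMs is absent
from the matrix rather than present as a zero row. Multi-plex bridging is
out of scope: each plex is normalized independently.

## Differential abundance

Intensities are log2-transformed and centred on the mean of the reference
(WT) replicates, protein by protein, so the reference mean of each row is
exactly zero and entries read directly as log2 fold change versus WT.
Nonpositive intensities are treated as unquantified (NaN); a protein with no
quantified reference replicate is excluded with a log entry. Group
comparisons use the pooled-variance two-sided Student's t-test (Welch is an
option); by default a protein must be fully quantified in both groups to be
tested, otherwise it is flagged `insufficient_n` and kept with NA statistics.
Zero pooled variance is reported as p = 1 for equal means, else the smallest
positive double, flagged `degenerate_variance`. Benjamini–Hochberg adjustment
is applied within each comparison across the tested proteins (the step-up
implementation is statsmodels' `fdr_bh`).

## The allelic-series model

The genotype series WT, DKO, TKO, QKO, PKO is coded with cumulative
indicators `x_k = 1` iff the sample's genotype includes the k-th sequential
deletion, and each protein's WT-centred log2 values are fit by ordinary
least squares on the staircase design. Because the design is saturated in
genotype, the coefficients have a closed form: each β_k equals the difference
of adjacent genotype sample means (β₁ = mean(DKO) − mean(WT), β₃ =
mean(QKO) − mean(TKO), ...), balanced or not — the solver is verified against
this closed form to 1e-10 on random unbalanced designs.

One numerical-inference choice deserves emphasis: **the intercept column is
retained in the solve** even though centring drives its estimate to zero.
On centred data the point estimates are identical with or without it, but
dropping the column misstates the uncertainty — it treats the subtracted WT
replicate mean as noiseless, understating Var(β₁) by a factor of two, and
overcounts residual degrees of freedom (n−4 instead of the correct n−5).
With 3 replicates per genotype the no-intercept variant rejects a true-null
step-1 coefficient 17% of the time at nominal α = 0.05; with the intercept
retained the t inference is exact (verified by the null-calibration and
CI-coverage tests). Standard errors come from s²(XᵀX)⁻¹ with s² = RSS/(n−5),
p-values from the two-sided t distribution, and BH adjustment is applied per
step across proteins (pooled adjustment is an option); significance is
adjusted p < 0.05. Degenerate fits (zero residual variance, insufficient
rank, no residual df) are flagged rather than silently dropped, and proteins
with missing samples are fit on their available rows when rank permits.

Genotypes outside the series (e.g. extra plex controls) are not part of the
allelic design; they are analyzed by the differential module.

## Compartment statistics

Annotations classify proteins by organelle and ER compartment
(ER-associated / ER-membrane / ER-lumen); transmembrane-segment counts are
parsed from `_n` name suffixes (`VAPA_1` → VAPA, 1 TM segment; no suffix → 0).
An ER compartment class on a non-ER organelle is rejected as inconsistent.
Group summaries keep counts conserving: fitted proteins without annotation
are reported as `unannotated`.

The randomized-selection null compares a compartment's distribution of
per-protein values against chance: each of 100 iterations draws the same
number of proteins uniformly without replacement from the full quantified
background (group members may be redrawn — nothing is excluded) and applies
a two-sided two-sample Kolmogorov–Smirnov test. How the 100 iteration-level
p-values collapse to one number is genuinely open, so both readings are
returned: the full p distribution with its median and significant fraction,
and a single pooled test of the group against all draws concatenated. Note
that the two-sample KS statistic is discrete: at group sizes below ~150 its
null rejection rate at α = 0.05 is visibly conservative (≈0.03–0.04), an
intrinsic property of the test rather than an implementation artefact;
calibration checks therefore use group sizes of a few hundred.

Wilcoxon signed-rank tests use the exact distribution for n ≤ 25 without
tied magnitudes and the normal approximation with continuity correction
otherwise; zeros are dropped (signed-rank convention), and an all-zero input
is degenerate with p = 1. The β-versus-zero test is one-sided (greater) with
Bonferroni adjustment `min(1, p·m)`, m being the number of compartment × step
tests in the panel; genotype-versus-genotype comparisons are paired two-sided
tests on per-protein differences.

## Keima flux

The per-condition flux ratio divides the arithmetic mean of the acidic
(561-nm-excited) channel by the arithmetic mean of the neutral
(445-nm-excited) channel over the condition's gated events — means of
channels, not the mean of per-event ratios (a deliberate contract, asserted
in tests; geometric means are available as an option since some cytometry
workflows prefer them). Flux is reported relative to an explicitly paired
bafilomycin-A1 control, making the control itself exactly 1 and cancelling
any common detector gain. Input is a post-gating event table (CSV); gating
and compensation are upstream concerns.

## The synthetic-data generator

The simulator emulates a single-plex allelic-series TMT experiment with
known ground truth. Per protein: a lognormal baseline abundance
(log2 ~ N(16, 1.5²)); sparse per-step effects — nonzero with probability
0.1 per step, magnitudes |N(0, 0.5)| log2 units; compartments drawn as 10%
ER-associated, 20% ER-membrane, 15% ER-lumen, 55% other organelles, with
ER-membrane proteins 3× enriched for step-1 effects and ER-lumen proteins
for step-4 effects, both with a 0.8 positive-sign bias (membrane-first,
lumen-late accumulation upon receptor loss). Receptor proteins are modelled
as a −2.5 log2 step effect at their deletion step and zero after — a large
negative step rather than literal zero intensity, keeping log2 finite — with
FAM134A and FAM134C removed at step 1, then FAM134B, TEX264, CCPG1.
Replicate noise is Gaussian on the log2 scale with σ = 0.25 by default, a
conventional TMT replicate spread (three biological replicates per genotype
by default). Protein intensities are split across 1 + Poisson(mean−1) PSMs
with lognormal shares identical across channels, so rollup conserves the
protein matrix exactly; configured fractions of PSMs draw failing QC
attributes (SNR ≤ 200 or purity ≤ 0.5) and have their intensities perturbed
multiplicatively by U(0.1, 10) per channel so that filtering is
consequential. Flow events are lognormal in the neutral channel with the
acidic channel a mean-one lognormal multiple of the target ratio, so the
channel-mean ratio converges to the target; a BAFA flag pins the effective
ratio at the baseline (0.25 by default).

All randomness derives from named child streams of a single root seed
(`default_rng([seed, k])`), so identical configurations are byte-identical
and each artefact is independently reproducible.

What the simulator does **not** model: co-isolation interference mechanics,
missing values beyond QC filtering, multi-plex batch effects (off by
default), raw spectra or chromatography, and cytometry gating. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to every artefact of real TMT or
flow data.

## Problem sizes and tolerances

Tests and the acceptance script use 300–1,000 simulated proteins, 20-seed
replications for calibration checks, 10,000 random designs for the
closed-form oracle, and 10⁵ flow events — sizes at which the Monte-Carlo
error of each check is far below its assertion tolerance while the full
suite runs in well under a minute of compute per module. Exactness checks
use 1e-9–1e-12 absolute tolerances (solver and rollup conservation);
statistical checks use 3–4 binomial standard errors around the nominal rate.
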