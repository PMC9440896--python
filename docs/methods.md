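# Methods

## The problem

Label-free LC-MS/MS quantification of pooled samples yields exactly one
abundance per protein per condition. With no replicates there is no
within-group variance, so ordinary per-protein tests (t, limma, DESeq-style
models) are unavailable. The alternative implemented here treats the whole
collection of per-protein log ratios as an empirical null and scores each
protein by how far into a tail of that distribution its own ratio falls.

## The outlier statistic

For each protein quantified in both conditions we form

    r = log2(abundance_treated / abundance_control).

Proteins missing in either condition are excluded (with a logged reason);
a stored abundance of exactly 0 is kept distinct from missing in the input
table but equally admits no log ratio, so it is excluded at this step with
its own reason.

The spread of the r distribution is estimated from three percentiles,

    r_{-1} = P15.87,  r_0 = P50,  r_1 = P84.13,

computed by linear interpolation between order statistics (with sorted
v[0..n-1] and h = (n-1)q, the value is v[floor(h)] interpolated toward
v[floor(h)+1]). 15.87 and 84.13 are 100·Φ(∓1) rounded to two decimals, so
on a normal sample both one-sided differences

    sd_right = r_1 - r_0,    sd_left = r_0 - r_{-1}

converge to the conventional standard deviation; on a skewed sample they
differ, and each side of the distribution gets its own scale. A protein's
standardized distance is taken against the side it falls on,

    z = (r - r_0)/sd_right   if r >= r_0,
    z = (r_0 - r)/sd_left    if r <  r_0,

and its outlier p-value is the standard normal upper-tail mass beyond z,

    p = ½·erfc(z/√2) = ∫_z^∞ φ(t) dt ∈ (0, 0.5],

valid under the null hypothesis that the log-ratio distribution has normal
upper and lower tails. The p-value is one-tailed per protein: the null is
phrased per tail and the two sides are standardized separately, so a
median protein scores exactly 0.5 and, under a symmetric null, about 10%
of proteins fall below 0.05 when both tails are counted. Differential
proteins are called with two joint strict gates: fold change
2^|r| > 1.5 and p < 0.05. The fold change is derived from the same r used
for the p-value, so the two gates cannot disagree about the ratio.

Deliberate numerical choices:

- **Log base 2.** Proteomics convention; fold change reads directly as
  2^|r|. The statistic itself is base-invariant: multiplying all r by a
  positive constant rescales the percentile triple identically and leaves
  every z and p unchanged (property-tested), provided the fold-change gate
  is re-expressed in the new base.
- **Percentile rule.** The linear-interpolation definition above (numpy's
  default) is stated explicitly and isolated in one function because the
  percentile convention is the only free choice in the estimator.
- **Minimum of 20 retained proteins** (configurable) before the percentile
  triple is estimated; tail percentiles on smaller sets are noise.
- **Degenerate spreads are errors**, not silent fallbacks: if either
  one-sided s.d. is zero the distribution carries no usable scale
  information on that side.
- **No multiple-testing correction gates the protein-level call** — the
  procedure uses raw p < 0.05 by design. A Benjamini–Hochberg q-value
  column is written alongside for the reader and never consulted.

## Enrichment and overlap

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) with the *detected* proteins (those quantified in both
conditions) as the background of size N, a category of size K within that
background, a hit list of size n, and overlap k. Hits absent from the
background are dropped with a warning. Categories with K below
`min_category_size` (default 5, a typical web-tool magnitude) are skipped,
and the Bonferroni factor m counts only the categories actually tested —
the usual practice of correcting over tested hypotheses. The reported
enrichment ratio is (k/n)/(K/N).

Set overlap is exact set arithmetic on deduplicated identifiers, reported
as a percentage of each set separately. Two denominators naturally yield a
range (e.g. "22 to 24% co-regulated"), which is why both directions are
always reported; an empty set's percentage is defined as 0 with a warning.

## Group comparisons

Every group is screened with Shapiro–Wilk. Normality is assessed per group
(not on pooled residuals) and the parametric branch requires *all* groups
to pass at alpha = 0.05 — the stricter, reproducible reading, isolated
behind one function so the policy can be swapped. Then:

- 2 groups, parametric: two-tailed Student's t, classical equal-variance
  pooled form (a Welch flag exists, off by default, since the procedure is
  named after Student's test).
- 2 groups, non-parametric: two-sided Mann–Whitney U; exact enumeration
  when the smaller group has ≤ 8 values and there are no ties, otherwise
  the tie- and continuity-corrected normal approximation.
- ≥ 3 groups, parametric: one-way ANOVA; when the omnibus is significant
  at alpha, Fisher's LSD pairwise p-values from the pooled within-group
  mean square and its error degrees of freedom (protected LSD; an
  unprotected flag exists). LSD applies no pairwise multiplicity
  adjustment — that is its definition — and reduces exactly to the pooled
  two-sample t when only two groups exist (tested).
- ≥ 3 groups, non-parametric: tie-corrected Kruskal–Wallis, omnibus only.
  No post hoc follows deliberately: the procedure names none for this
  branch, and inventing one (e.g. Dunn's) would change the inferences.

Constant groups and groups smaller than 3 are errors naming the group.

The lipidomics heatmap normalization maps each species row of group means
affinely to percentages: smallest mean 0%, largest 100%. Constant rows
become all 0% with a warning. The map is invariant to positive affine
transforms of a row, so unit changes cannot move the heatmap.

## The synthetic experiment

The generator emulates the replicate-free design: control abundances
log-uniform over `baseline_range` (default 1e5–1e9, four decades of
typical LFQ intensity), treated = control · 2^(ε + planted), with ε drawn
from the null family and the planted log2 ratio ±`effect_log2` for exactly
round(`frac_de`·n) proteins — half up, half down, the odd one up, so
fixtures are deterministic. Missingness is missing-completely-at-random
per cell (default 0, so ground-truth recovery is well defined; switch it
on to exercise the quantified-in-both exclusion rule). Abundances are
strictly positive; missing is the only absence state the generator emits.

The null family is an **equal-mass split normal about the median**: the
ratio falls on either side of the centre with probability ½ and its
magnitude is half-normal with that side's scale. `null_skew` is
log2(scale_left/scale_right); 0 recovers exactly N(0, `null_sd`), and 1
makes the left tail twice as wide as the right. This family was chosen
over the continuous-density two-piece normal deliberately: each side is
then *exactly* a normal tail about the median — precisely the null the
outlier statistic assumes — so per-tail p-values are uniform in the
large-n limit and calibration tests measure estimator error, not model
mismatch. The cost is a density step at the median, which is irrelevant
to a tail statistic. Defaults (n = 10,000 proteins, 5% differential at
|log2| = 2, null s.d. 0.3) describe a clean, well-powered experiment.

What the simulation does *not* emulate: peptide-level noise, intensity
normalization, informative (abundance-dependent) missingness, correlated
proteins, or pooling noise distinct from the single spread parameter.
Passing tests therefore certify the statistic and the pipeline machinery,
not robustness to those real-data features.

The grouped-measurement generator draws N(mean_i, sd) or
exp(N(log mean_i, sd)) per group ("lognormal" interprets `means` as the
median on the original scale and `sd` as the log-scale spread); the
gene-set generator plants one category equal to a chosen member list and
fills the rest with uniform draws from the universe.

## Problem sizes

Calibration checks use 10,000 proteins (KS distance to uniform < 0.02 is
then well above the ~0.009 sampling floor), asymmetry checks 20,000 so
each tail holds ~10,000 points, power checks 10 seeds of 10,000, the
normal-recovery Monte-Carlo 10^6 draws (percentile s.e. ~0.0012, so the
1% band is ~8 s.e. wide), the hypergeometric enumeration every
(k, K, n) with N ≤ 30 in exact rational arithmetic, and the group-test
null calibration 1,000 seeded three-group experiments. These sizes make
every stochastic bound a many-sigma event rather than a coin flip.

## Known limitations

- The outlier p-value is a population statement about the tail of the
  ratio distribution, not a replicate-based test; at raw p < 0.05 the
  false-positive fraction among true nulls is ~5% per tail by
  construction, which on thousands of proteins is hundreds of calls. That
  is inherent to the published procedure (and why downstream conclusions
  rest on pathway-level enrichment, not single proteins).
- With ~5% planted effects the percentile triple is mildly contaminated;
  at the default effect size the bias is negligible, but a large
  differential fraction would inflate the robust s.d. and cost power.
- Whether the upstream quantifications were normalized before ratio
  formation is outside this package's scope; it takes the table as given.
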