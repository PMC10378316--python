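# Methods

This note documents the statistical procedures, the synthetic-data
model, and the design choices made where the underlying analysis recipe
was genuinely open.

## Detection filtering

Each array gets its own detection threshold: five times the standard
deviation of the background probes plus the 10% trimmed mean of the
negative-control probes. "10% trimmed" means symmetric trimming — the
lowest and highest 10% of negative-control values are discarded before
averaging (`scipy.stats.trim_mean`). A measurement probe is removed when
its signal is below threshold on at least `low_fraction` of arrays;
"consistently low" is read as *all* arrays by default (`low_fraction =
1.0`) and is configurable, since the recipe does not quantify
"consistently". Control probes never propagate downstream.

## SAM

For feature *i*, the moderated statistic is `d_i = r_i / (s_i + s0)`
where `r_i` is the tumor−normal mean difference (or the mean of
within-pair log2 differences in paired mode) and `s_i` the pooled
standard error (or the paired-difference standard error). `s0` is chosen
among percentiles (0, 5, …, 100) of the `s_i` distribution by minimizing
the coefficient of variation of the median absolute deviation of `d`
computed within quantile windows of `s` (the original SAM tuning); with
fewer than 10 features the tuning degenerates and the median of `s` is
used. All-constant features keep a finite `d` through `s0` and are
flagged.

Significance is by label permutation (sign flips of within-pair
differences in paired mode), using the same `s0`. When the number of
distinct permutations is at most `n_perm`, all of them are enumerated;
p-values are then `k / B` with the observed labelling one of the `B`
arrangements, otherwise the add-one convention `(1 + k)/(1 + B)` avoids
zero p-values. The per-feature p counts permutations with
`|d_i^b| ≥ |d_i|`. The FDR is the SAM pooled estimate: at threshold
`t = |d_i|`, `E[#{|d^perm| ≥ t}] / #{|d^obs| ≥ t}`, and
`q_i = min` of that ratio over all attainable thresholds `≤ |d_i|`. No
π₀ estimate is applied (π₀ = 1), which keeps the estimate conservative
and the exhaustive oracle in the tests exact. Both the permutation p
(primary) and a plain Welch / paired t-test p (`t_p`) are reported,
since either reading of "p-value" is defensible; marker selection uses
the permutation p.

Marker selection is strict: fold change `> 2` **or** `< 0.5`, `p <
0.05`, `q < 0.05`; boundary values are excluded. Fold changes are
computed from log2 data as `2^(Δmean)` (unpaired) or `2^mean(Δ_pair)`
(paired).

## Clustering

Samples are clustered on the marker subset with average-linkage
agglomerative clustering on `1 − Pearson` correlation distance between
sample profiles — the analysis never states its clustering recipe, so
the most common microarray-heatmap convention is used and both distance
and linkage are knobs. The tree is cut at the root split into exactly
two groups. Samples are processed in lexicographic id order so
equal-distance merges are deterministic; fully degenerate inputs (all
samples identical) fall back to a single cluster without crashing.
Accuracy against known labels is the better of the two cluster→label
mappings, hence always ≥ 0.5.

## Families and roles

miRBase-style ids are grouped into families by stripping, in order, a
trailing star marker (`*`), a trailing arm suffix (`-3p`/`-5p`), and a
trailing single-digit genomic-copy suffix (`-1`, `-2`, …) when the
remainder still names a family stem. This reproduces groupings such as
{`hsa-miR-101-1`, `hsa-miR-101-2`} → `hsa-miR-101` and {`hsa-miR-30a`,
`hsa-miR-30a*`} → `hsa-miR-30a` while leaving `hsa-miR-720` and
`hsa-miR-7` intact; other corner cases are this package's convention.

Role rule per family: oncomiR iff fold change > 1 and HR > 1 with
p < 0.05; tumor suppressor iff fold change < 1 and HR < 1 with p < 0.05;
otherwise discordant. Fold change is compared against 1 (not the 2/0.5
selection bounds) because candidates have already passed marker
selection. With several survival isoforms, only significant isoforms
vote and all must agree in HR direction; conflicting significant
isoforms make the family discordant, as does a family with no
significant isoform.

## Survival

Kaplan–Meier curves and two-group log-rank tests use lifelines. The
univariate Cox fit uses the Breslow partial likelihood (statsmodels
PHReg, Newton iterations, tolerance 1e−8, ≤ 50 iterations) with Wald 95%
intervals. Monotone likelihoods (perfect separation) are detected by an
exploding coefficient or standard error (|β| > 10 or SE > 10, or a
singular Hessian) and returned flagged rather than raised. The
per-feature screen dichotomizes expression at the cohort median with
ties assigned to the low group — the field-default split; quartile or
optimal-cutpoint splitting is deliberately out of scope — and reports
the high-vs-low HR with the log-rank p. A continuous-covariate mode is
also available.

## Drug sensitivity and pan status

Responses are analyzed on the ln scale (linear IC50/EC50 values are
log-transformed; ln measures used as-is), so line classification is
rank-invariant. Per drug/source/measure, lines at or below the lower
tertile boundary (linear-interpolation quantiles) are sensitive, at or
above the upper tertile resistant, the rest intermediate — a symmetric,
parameter-free stand-in for the original classification, with the split
quantiles exposed as knobs. Gene–drug calls are Welch two-sample t-tests
(pooled variance available as a knob) between the sensitive and
resistant groups, intermediates excluded: sensitive if p < 0.05 with the
higher mean in the sensitive group, resistant symmetric, otherwise
`ns`. Every (source, measure) combination contributes calls and the pan
logic runs over their union: pan-sensitive requires at least one
sensitive call and zero resistant calls across all drugs with coverage
of the full drug list enforced (all-`ns` features are `neither`, since a
pan gene is expected to show at least one significant association).
Essentiality: fraction of lines with dependency score < −0.5, flagged
essential when that fraction exceeds 0.5 in either screen ("either" by
default with a "both" switch, since the source material uses both
readings in different places).

## Signature and connectivity

The up list collects miRNA-target genes with HR < 1 (log-rank p < 0.05),
pan-sensitive at both the mRNA and protein levels, and not essential;
the down list needs HR > 1 and pan-resistance at both levels. The
essentiality filter applies only to the up list. No size cap is imposed
— the reference 28+28 was an outcome, not a parameter — but a top-k
truncation by log-rank p exists for parity experiments. Lists are sorted
by gene id, so the signature is a deterministic function of its inputs.

The connectivity engine ranks a profile's genes by descending score
(ties by gene id) and computes a weighted-KS enrichment for each tag
set: tag positions add `|score|^w` normalized over tags (w = 1 by
default; w = 0 gives the rank-only statistic), non-tag positions
subtract `1/(N − n_tags)`; the ES is the signed maximum deviation. The
bidirectional score is `(ES_up − ES_down)/2` when the enrichments have
opposite signs and 0 otherwise, lying in [−1, 1] with 1 meaning maximal
expression similarity. Significance is by tag permutation — random
disjoint up/down sets of matching sizes, equivalently random rank
positions — enumerated exhaustively when the number of ordered disjoint
pairs is ≤ `n_perm`. This engine is a local, validated stand-in for a
hosted connectivity service whose exact scoring build is unspecified;
it is not expected to reproduce that service's numbers, and the tests
validate it against brute-force running-sum and enumeration oracles and
on planted data. Hits require score > 0.9 and p < 0.05.

## Potency filter and responder profiles

Response values are converted to linear µM (ln measures exponentiated;
when a line reports both scales the linear value wins), pooled per
measure family, and trimmed by Tukey fences (outside Q1 − 1.5·IQR,
Q3 + 1.5·IQR, linear-interpolation quartiles) — the outlier rule is this
package's choice, exposed as the quartile convention is. A hit passes
when every available measure's post-trim mean is below 7 µM; with
multiple sources each source is judged separately and any passing source
suffices (permissive by design). Fewer than 3 values leave potency
undetermined rather than guessed. Responder genes per drug require the
same significant direction at mRNA and protein level; genes without
protein data are not candidates. Top mutated/fused genes per line are
ranked by count with alphabetical tie-breaks.

## Synthetic data

The generator's defaults mirror the emulated study: 45 tumor + 7 normal
tissue arrays (four matched pairs sharing an additive patient effect,
SD 0.3), 3 + 6 blood samples, 1087 probes with 86 planted markers
(log2 shift ±2, i.e. 4-fold, alternating direction; Gaussian noise
SD 0.5 on the log2 scale so fold-change ground truth is exact), 40
negative-control and 40 background probes near intensity 4.0, and 50
consistently-low probes that the detection filter should remove; 12
planted prognostic features at log-hazard ±ln 2; a 500-subject survival
cohort (exponential event times, baseline hazard 0.02/month, censoring
times Uniform(0, b) with b solved so the expected censored fraction
under the baseline hazard equals the configured rate — 20% by default);
a 31-line cell panel (the size of the emulated proteome panel) against
19 drugs × 3 sources × 4 measures; and a 100-perturbagen library with
one planted reversal compound and one high-IC50 potency decoy.

Panel structure: a single latent per-line sensitivity drives every
drug's ln-response (slope 1.5 per SD) with small per-combination noise
(SD 0.05) and tight EC50–IC50 coupling (SD 0.02), so tertile splits
across drugs, sources and measures largely coincide while still able to
disagree at boundaries. Planted sensitive genes are expressed higher in
sensitive lines (log2 effect 2 per latent SD; resistant genes mirror
this), protein is mRNA plus independent noise (SD 0.7, giving gene-level
mRNA–protein correlations around 0.4, in the range reported for
proteogenomic panels) and is mean-centered; discordant genes carry the
mRNA signal with an independent protein profile. These panel noise
scales are a deliberate calibration: the pan definition gives every null
gene ~114 chances at a lucky significant call, so recovering planted pan
genes at high precision requires (a) near-coincident splits, which
collapse those chances to essentially one 5% event per gene, and (b) an
informative protein level that rarely confirms an mRNA fluke. With that
calibration the both-level pan sets recover the planted sets with mean
precision ≈ 0.92 and recall 1.0 over 20 seeds. Dependency matrices
plant essential genes at −0.8 ± 0.1 (null genes at 0 ± 0.15); mutation
and fusion records default to sparse Poisson draws and accept explicit
per-line count overrides.

Planted library hits place the signature's up genes on the top ranks
and down genes on the bottom ranks of a linear score vector (score
exactly 1.0 at the default zero profile jitter); non-hits are
permutations of the same vector. Hits carry potent in-panel responses
(~1.5 µM, with one injected extreme outlier per perturbagen so the Tukey
trim is exercised), decoys the same profile at ~50 µM.

What the generator does *not* emulate: miRNA co-expression structure,
batch effects, probe-level physics, non-proportional hazards,
drug-specific mechanism heterogeneity, and realistic mutation spectra.
Passing tests therefore demonstrate that the machinery recovers known
planted structure under the stated noise model — not that the
biological conclusions of any particular real dataset are reproduced.

All randomness flows from `numpy.random.default_rng((seed, stream))`
with one fixed stream constant per generator, so identical configs give
byte-identical outputs while generators remain independently callable.

## Problem sizes in the test suite

Module tests run on scaled-down instances (tens of features/subjects)
chosen to keep oracle enumeration exact: SAM oracles use 3-vs-3 designs
(20 exhaustive label assignments), the Cox grid-search oracle uses ≤ 8
subjects, connectivity enumeration ≤ ~10⁴ tag-set pairs. The behavioral
suite runs the full default study once end-to-end, the Cox recovery at
n = 500 over 100 replicates, pan recovery over 20 seeds, and null
controls over 50 seeds.

## Known limitations

* The per-feature SAM permutation p uses each feature's own permutation
  distribution; pooling across features (as some SAM variants do) would
  give finer granularity at small sample sizes.
* The connectivity engine scores each library column independently; no
  compound-set aggregation or cell-line summarization is performed —
  consensus entries must be supplied as their own profiles.
* Tertile line classification discards the intermediate third; with
  small panels this limits t-test power per drug.
* The survival screen fits one feature at a time; no multivariate
  adjustment or multiple-testing correction is applied, matching the
  screening character of the original analysis.
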