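# Methods

## Pipeline overview

The package implements a temporal coexpression analysis for a two-group
(CTRL/HS), four-time-point (P12/P30/P60/P120) expression study. Per time
point it runs: variance filtering, SAM-style permutation differential
expression, paired CTRL/HS network construction with CTRL-derived module
labels, connectivity rank-change analysis, and permutation module
preservation. Over all samples it builds a single joint network and relates
module eigengenes to the group indicator and one-vs-rest time-point
indicators. Every stage is driven by one `RunConfig` whose defaults are the
study's procedural constants: soft threshold 10 (with an automatic check
that the scale-free fit reaches 0.8, or `beta="auto"` to select the power),
top 5000 most-variable genes, minimum module size 50, FDR target 10%,
gold-module size 1000, 10 hubs per module, gene/module significance
cutoffs 0.05/0.1.

## Input formats

Expression: TSV, gene rows x sample columns, first column gene ids, header
sample ids, log2-scale values. Sample table: TSV with `sample_id`, `group`
(CTRL/HS), `timepoint`, optional `sex`. Probe map: two-column TSV
(probe, gene). qPCR: long TSV with `sample_id`, `group`, `gene`, `ct`.
Gene sets: standard GMT.

## Preprocessing

`log2_transform` requires strictly positive intensities and fails naming
the offending gene/sample rather than emitting -inf. `quantile_normalize`
is the classic algorithm: each column's rank-r value is replaced by the
cross-column mean of the rank-r order statistics; ties within a column
receive the mean of their tied rank-means (dialects differ here, so the
choice is documented and tested, including idempotence). Probes collapse to
genes by the arithmetic mean of probe rows. "Most variable" means largest
sample variance on the normalised log2 matrix, with lexicographic gene-id
tie-breaks for determinism; the filter is applied per analysis (per time
point and once for the joint network).

## Network construction

Biweight midcorrelation uses the standard Tukey weights
`w = (1 - u^2)^2, |u| < 1` with `u = (x - median) / (9 * MAD)` and no
outlier-proportion cap. A zero-MAD vector cannot be biweighted: the scalar
`bicor` drops the pair to Pearson (with a warning) so the result remains a
recognised correlation, while the matrix routine applies the fallback per
gene (only the offending gene is mean-centred), the "individual fallback"
dialect. Constant genes get correlation 0 and a warning.

Adjacency is unsigned, `a_ij = |cor|^beta`, with the diagonal stored as 0
so connectivities are plain row sums. The scale-free fit index bins
connectivity into 10 equal-width bins, regresses log10(bin frequency) on
log10(mean bin connectivity) over non-empty bins, and returns the R^2 only
when the slope is negative (a rising "power law" is no power law; the index
is 0 then). `pick_soft_threshold` returns the smallest power on the grid
(default 1..20) reaching fit 0.8, or the maximising power with a flag.

Topological overlap is the standard unsigned form with `TOM_ii = 1`;
module detection clusters `1 - TOM` by average linkage
(`scipy.cluster.hierarchy`; exact O(n^2) algorithm, adequate at the 5000
gene scale).

### Tree cut

WGCNA's dynamic hybrid cut is replaced by a fully specified static cut.
A fixed cut height cannot work across regimes: at high powers the merge
heights of a realistic dataset bunch within ~1e-4 of the maximum, while a
near-noiseless dataset produces a few discrete height plateaus. The
implemented rule therefore scans candidate cut heights drawn from two
complementary scales — quantiles of the merge-height distribution (covers
dense merge regions) and midpoints of the 50 widest inter-merge gaps
(covers sparse regions) — and counts, at each candidate, the clusters with
at least `min_module_size` members. The winning cluster count is the one
that persists most, scored as an equal blend of its share of quantile
candidates and its share of the height range covered by the widest gaps;
the cut is then placed in the widest height gap where that count holds (the
most stable single location). A fixed-fraction cut of the height range
remains available via `cut_height_fraction`. On planted-module data this
rule recovers noiseless blocks exactly and reaches adjusted Rand index
0.97-1.0 against planted truth on the default generator at powers 6 and 10.

Clusters below the minimum size become "grey"; surviving modules take the
WGCNA colour sequence by decreasing size. Tests compare partitions, never
colour names.

## Module statistics

The module eigengene is the first right-singular vector of the
standardised (per-gene z-scored) module submatrix, unit-norm, sign-oriented
so the mean correlation with member genes is positive; variance explained
is the share of the first squared singular value. kME and GS use Pearson
correlation (bicor is reserved for the network step), with GS p-values
from the t distribution on n-2 degrees of freedom. Trait encoding: HS = 1,
CTRL = 0; time points as one-vs-rest indicators. Hubs are the 10 largest
kWithin per module, ties broken by gene id; modules smaller than the hub
count return all members flagged `short_module`.

## Differential expression (SAM)

`d_i = (mean_HS - mean_CTRL) / (s_i + s0)` with `s_i` the pooled two-sample
standard error. `s0` is selected from the 0,5,...,100 percentiles of
`{s_i}` by minimising the coefficient of variation of the median absolute
deviation of `d` across 10 quantile windows of `s`. A caveat found while
validating: on exactly homoscedastic data this criterion is minimised at
the largest candidate (conditional on `s` in a window, the plain
t-statistic spread is proportional to 1/s, so only a large `s0` flattens
it); this is harmless — the permutation machinery uses the same `s0`, so
FDR calibration is unaffected — but worth knowing when inspecting selected
values.

Significance: for each of B (default 200) group-label permutations the
sorted d statistics are recomputed; their column means give the expected
order statistics. At threshold delta, the ordered genes departing from the
expected statistic by more than delta define asymmetric calling cut-offs
(the smallest called positive d and largest called negative d); estimated
FDR = pi0 x median permuted exceedance count / observed call count, with
pi0 = min(1, #{d in the interquartile range of permuted d} / (0.5 n)). The
delta grid is 50 values spanning the observed departures; estimates are
monotonised conservatively (each delta is charged the worst raw estimate
among itself and all stricter deltas) and the smallest delta meeting the
target is selected. Empty call sets have undefined FDR and are never
selected. Direction is the sign of d. Under a global null the procedure
calls a handful of genes in 500 at the 10% target (tested over seeds);
realised FDR on planted-effect data is approximate, as expected for SAM's
plug-in estimator.

qPCR: `dCt = Ct_target - Ct_reference` (default reference Gapdh),
`ddCt = dCt - mean(dCt over CTRL)`, fold change `2^-ddCt`, two-sample
t-test on dCt with significance at P < 0.1.

## Paired comparison and preservation

Both networks are built at the same power on the gene intersection; module
labels come from the reference (CTRL) network, or from a supplied
assignment (e.g. planted truth in simulations). Ranks are dense ranks of
kWithin over all non-grey genes (global, so gains are comparable between
modules), ties by gene id; `delta_rank = rank_ref - rank_test` with
positive = gain in the test condition. Modules are ordered by median member
delta, the sign of the median classifies gain/loss, and the count of
gaining genes is reported alongside.

Preservation uses two statistics per module: density (mean off-diagonal
within-module test adjacency) and connectivity (Pearson correlation of
member kWithin between reference and test). Their null distributions come
from random gene sets of matched size drawn from the *entire* gene
universe — drawing from non-grey genes only, as one might first try,
degenerates when few genes are non-grey and biases the null toward
module-like sets; random sets from the whole network are also what the
established preservation framework uses. `Z = (obs - null mean)/null SD`,
`Zsummary = (Zdensity + Zconnectivity)/2`, classified as none (< 2),
weak/moderate (2-10), strong (> 10). The gold module (default 1000 random
genes, necessarily a strict subset of the universe) calibrates the scale:
its Zsummary sits near 0. This two-statistic construction is a deliberate
reduction of the full multi-statistic composite in the established
framework; it keeps the same permutation-Z form and thresholds while being
fully specifiable and testable.

## Enrichment

One-sided hypergeometric over-representation against GMT collections. The
universe defaults to the union of all collection members (a hypergeometric
test cannot run without one; web tools that advertise "no background" make
an equivalent internal choice). Reporting requires p <= 0.05 AND at least
3 overlapping genes; no multiple-testing correction, matching the raw-p
reporting convention. Function-group summaries count the union of overlap
genes per group — a gene in two groups counts once per group — with
percentages over the total.

## Synthetic data generator

Each planted module m has one latent factor per sample, `u_ms ~ N(0,1)`;
member gene i observes `l_i u_ms + N(0, noise_sd^2)` with loading `l_i ~
U(loading_range)`, plus a baseline of 8 so values resemble log2
intensities. Perturbations act on HS samples only, keeping CTRL as the
shared reference: `gain`/`loss` multiply/divide loadings by `gain_factor`,
`destroy` replaces the module with independent noise, `shift` adds a
`de_effect` mean shift to every member (the planted construct for
trait-linked modules — loading scaling alone changes eigengene variance,
not its mean, so it cannot produce an eigengene-trait correlation).
Differential genes are drawn from the background and shifted by
+/- `de_effect` in HS. All randomness flows from one integer seed.

Defaults emulate the study scale: 6 modules of 300/250/200/150/100/80
genes, 1000 background genes, 8 samples per group per time point
(64 total), loadings U(0.4, 0.9), noise SD 1.0, gain factor 2.0 — sized so
the full pipeline runs in minutes on one CPU. The per-time-point sample
count is a parameter (attrition in real designs varies it).

What the generator does not emulate: probe-level artefacts (dye bias,
spatial effects), batch effects, non-Gaussian noise, correlated background
genes, overlapping module membership. Passing tests therefore demonstrate
that the algorithms recover the structure they assume, not that real
microarray data satisfies those assumptions.

## Problem sizes and numerical choices in the tests

Recovery tests that loop over 20 seeds use scaled designs (three modules
of 120/90/70 genes plus 320 background, or two 60-gene modules for the
rank-change recovery) so the suite stays fast; single-shot checks and the
calibration script use the full default design. Exchangeability of
unperturbed CTRL/HS blocks is checked across seeds (sign balance and mean
difference of group-mean |r|) rather than by a within-seed two-sample test:
all pairs in a module share one latent-factor realisation, so within a
seed their correlations shift coherently with the realised factor variance
and any iid-sample test over pairs rejects spuriously. Degenerate inputs
are handled explicitly: constant genes (flagged, correlation 0), zero null
SD in preservation (Z = 0 or +/-inf with a flag), all-equal standard
errors in SAM (s0 = 0), fewer genes than the filter size (kept, warned).

## Known limitations

- The static tree cut, while robust across the regimes tested, is not the
  dynamic hybrid algorithm; highly nested module structure may resolve
  differently.
- Zconnectivity based on kWithin correlation is noisy at high powers with
  weak modules (the adjacency then amplifies sampling noise); Zsummary is
  carried mostly by the density statistic in that regime.
- SAM's estimated FDR is a plug-in estimate; realised FDR on strongly
  shifted planted genes can exceed the estimate at small sample sizes.
- Blockwise construction for very large gene sets (> 20k) is out of scope;
  the dense TOM is O(n^2) memory.
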