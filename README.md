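# coexnet

Temporal weighted gene-coexpression network analysis for paired
control-vs-case expression studies, built around the design of hyperthermic
seizure experiments in rat hippocampal CA3: two groups (CTRL and HS) sampled
at four postnatal time points (P12/P30/P60/P120), with the questions being
which gene modules exist, how their wiring changes between conditions, and
which genes respond.

The package is aimed at computational biologists who want the full pipeline
as importable, tested functions rather than a collection of notebook
snippets: preprocessing, SAM-style permutation differential expression,
unsigned WGCNA-style network construction and module detection,
module/gene-trait statistics, paired-network comparison by
intramodular-connectivity rank change, and permutation module preservation.
A latent-factor simulator with planted ground truth makes every stage
verifiable without any external download.

## The model

Expression profiles are correlated with the biweight midcorrelation
(bicor) and turned into an unsigned weighted network

    a_ij = |bicor(x_i, x_j)|^beta

with the soft threshold beta chosen as the smallest power whose
connectivity distribution reaches a scale-free topology fit R^2 >= 0.8
(beta = 10 in the original study design). Modules are clusters of the
topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

under average-linkage clustering of 1 - TOM; genes outside any module of at
least 50 members are "grey". Each module is summarised by its eigengene
(first principal component of the standardised member expression); gene
significance GS = cor(x_i, trait) and module significance = cor(ME, trait)
are reported at the P <= 0.05 (genes) and P <= 0.1 (modules) thresholds,
with the 10 top-ranked genes per module by intramodular connectivity
(kWithin) as hubs.

For the paired comparison, modules are identified in the CTRL network and
the labels transferred onto the same genes in the HS network. Connectivity
change is measured by the rank shift delta = rank_CTRL - rank_HS (positive
= gain in HS). Module preservation uses permutation Z scores for module
density (mean within-module test adjacency) and connectivity (correlation
of member kWithin between networks) against random gene sets of matched
size, with Zsummary = (Zdensity + Zconnectivity)/2 and the conventional
bands: < 2 no preservation, 2-10 weak/moderate, > 10 strong. A "gold"
module of 1000 random genes is carried along as a calibration baseline.

Differential expression uses the SAM moderated statistic
d_i = (mean_HS - mean_CTRL) / (s_i + s0) with the fudge factor s0 chosen by
Tusher's coefficient-of-variation criterion and the false discovery rate
estimated from group-label permutations, calling genes at a 10% FDR target.
A 2^-ddCt module handles qPCR validation against a housekeeping reference.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted truth (all outputs under `results/`):

```sh
python analysis/01_simulate.py --seed 1      # generate the three datasets
python analysis/02_preprocess.py             # log2 + quantile + variance filter
python analysis/03_differential_expression.py
python analysis/04_network_modules.py
python analysis/05_compare_networks.py
python analysis/06_enrichment.py
```

Selected output from a run with seed 1:

```
s0=0.8868 pi0=0.977 selected delta=0.2784 estimated FDR=7.52% called=26
recall of planted DE genes: 20/20; 6 extra calls
```

— the SAM stage picks the smallest delta whose estimated FDR is at or below
10% (here 7.5%), recovering all 20 planted mean-shift genes with 6 extra
calls, consistent with the target rate.

```
selected beta=2 (scale-free fit index 0.825)
detected 6 modules, sizes {'turquoise': 317, 'blue': 229, ...}
agreement with planted modules (ARI over non-grey genes): 0.929
```

— the automatic power selection reaches the 0.8 scale-free fit criterion
and module detection recovers the six planted modules almost exactly.

```
           size  Zdensity  Zconnectivity  Zsummary   class
blue         51     22.91           0.63     11.77  strong
turquoise    73     -0.96          -1.05     -1.01    none
gold        400     -0.45          -0.93     -0.69    none
```

— in the paired comparison the intact planted module (detected as `blue`)
is strongly preserved in HS (Zsummary > 10), the module destroyed in HS
(`turquoise`) shows no preservation (< 2), and the random gold baseline
sits near zero.

The same pipeline runs from the shell via the `coexnet` command
(`simulate`, `preprocess`, `de`, `network`, `compare`, `enrich`, `run`),
and accepts a user-supplied expression matrix / sample table in the TSV
formats described in `docs/methods.md` (e.g. a processed GEO series
matrix).

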