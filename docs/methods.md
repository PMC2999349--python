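# Methods

## Overview

`pcnkit` turns a multi-dose expression experiment (vehicle control plus a
ladder of doses, a few biological replicates each) into, per dose, a set of
differentially expressed genes (DEGs), a pathway × dose frequency count
matrix, and a network connecting the top-ranked pathways through their
membership overlaps. The method is deliberately counting-based: no
enrichment p-values are computed anywhere, and pathway topology is never
used — only membership sets.

## Preprocessing

Stages, in the default order, with the `scale_state` each one produces:

| stage | default | post-condition | state |
|---|---|---|---|
| intensity floor | 5.0 | all values ≥ 5.0 | `floored` |
| sample QC | mean Pearson r ≥ 0.80 | failing samples removed | `floored` |
| present-flag filter | ≥ 50% P flags (inclusive) | failing probes removed | `floored` |
| per-chip normalization | — | each column's 50th percentile = 1 | `chip_normalized` |
| per-gene normalization | — | each row's median = 1 | `gene_normalized` |
| log2 | — | monotone transform | `log2` |

Choices made where the procedure left room:

- **Normalization semantics.** "Normalize by the 50th percentile" is
  implemented as division by the per-array median (and per-gene by the
  across-sample median); subtraction is meaningless on an intensity scale.
  Percentiles use linear interpolation on sorted values (numpy's default),
  pinned so results are bit-reproducible.
- **QC scale and order.** Sample-sample Pearson correlations are computed
  on log2 of floored intensities: the log scale stabilises variance across
  the intensity range, and flooring first guarantees positivity. For this
  reason the floor runs before QC even though QC is conceptually the first
  filter; `preprocess(..., qc_before_floor=True)` restores the other order.
- **Threshold senses.** "At least 50% present" is inclusive (4 of 8
  passes); "less than 80% correlation" is strict (a sample at exactly 0.80
  is retained).
- Each transformer refuses matrices in the wrong `scale_state`, so the
  chain cannot be applied out of order silently.

## Differential expression

Per gene, for one dose vs control on log2 data:

    d = (x̄_T − x̄_C) / (s + s0),
    s = sqrt[ (1/n_T + 1/n_C) · (SS_T + SS_C) / (n_T + n_C − 2) ]

- **Fudge factor s0.** Candidates are the percentiles 0, 5, …, 100 of the
  per-gene `s` distribution. For each candidate, genes are windowed into up
  to 100 equal-occupancy groups by `s`; the spread of `d` in each window is
  a scaled median absolute deviation (MAD/0.64), and the candidate with the
  smallest coefficient of variation of those spreads wins, ties toward the
  smaller percentile. If all `s` are identical, s0 = 0 with a warning. The
  chosen s0 scales linearly with the data, as it must.
- **Permutations.** Balanced label reassignments (group sizes preserved).
  A 4 vs 4 design has C(8,4) = 70 distinct assignments and is enumerated
  exhaustively (the observed labeling is one of them); designs with more
  than 1000 assignments are sampled without replacement with a fixed seed,
  observed labeling included. Null `d` values are computed with the same
  s0 as the observed statistic.
- **Delta scan.** Genes are ordered by `d` and compared with the
  permutation expectation of each order statistic. Starting at the origin
  of that quantile–quantile comparison and moving outward, the calling
  cutoff in each direction sits at the first gene whose displacement from
  expectation reaches Δ; all genes beyond it are called. (Taking *any*
  displaced gene as a cutoff candidate, rather than the first crossing
  from the origin, lets a single noisy tail gene drag the opposite cutoff
  across the whole distribution and destroys null calibration — the
  origin-outward scan is load-bearing.) The median over permutations of
  the null statistics beyond the cutoffs estimates false positives;
  FDR(Δ) = median false positives / genes called, 0 by convention when
  nothing is called. No null-proportion (π0) correction is applied by
  default; `pi0` is exposed.
- **Delta selection.** `choose_delta(max_fdr)` returns the smallest Δ on
  the grid with estimated FDR strictly below the cap — the most permissive
  Δ that keeps predicted false positives under it.
- **q-values.** q(gene) = the lowest FDR among grid deltas at which the
  gene is called (1 if never called), then made monotone non-increasing in
  the gene's |displacement| by a running minimum, so a more extreme gene
  never has a larger q.
- **DEG filter.** Fold change is computed on the unlogged normalized
  intensities as the ratio of group arithmetic means, two-sided
  (max of ratio and inverse, direction recorded). A DEG needs fold change
  ≥ 2 **and** q < 0.05. The q threshold default is 0.05; 0.01 is a
  one-flag change and, by construction, selects a subset.

## Pathway counting and ranking

`counts[p, d] = |map(DEGs_d) ∩ members(p)|`, where `map` sends DEG
identifiers into the pathway namespace through an optional many-to-many
mapping table (policy `expand` = union of all targets, default, or
`drop_ambiguous` = 1:1 ids only). Member symbols are uppercased at ingest
so cross-namespace comparison is case-insensitive.

The ALL column defaults to the **sum of per-dose counts** (a gene hit at
two doses counts twice); `union_count` (distinct genes across doses) is
available, never exceeds the sum, and is exposed because the aggregation is
a genuine modelling choice. Rows are ranked by descending ALL, ties broken
lexicographically by pathway id; all-zero rows are kept (they rank last) so
the matrix always has the ingested database's dimension. The top 20 rows
feed the network stage.

## Network

For each unordered pair of top pathways, similarity defaults to the
**overlap coefficient** |∩|/min(|Pi|,|Pj|); Jaccard |∩|/|∪| is a flag. The
edge rule is S ≥ 0.2 AND ≥ 2 shared members (both constants configurable).
Similarity uses full pathway membership — DEGs affect only the node
attributes (`deg_count`, which equals the PPFCM cell for that pathway and
dose; `pathway_size`). Raising either threshold can only remove edges, so
threshold settings form a monotone filtration. Exports: GraphML (typed
attributes, round-trips through re-import), SIF (relation `overlaps`,
isolates listed alone), and a tab-separated edge table.

## Synthetic data

The generator emulates a single-channel array study: per-probe baseline
log2 intensity ~ Uniform(6, 12), Gaussian log2 noise (default sd 0.3),
exponentiated to the intensity scale. Defaults mirror the study design the
pipeline targets: 4 replicates, a vehicle control plus three active doses,
planted DEG fractions (0.01, 0.05, 0.15) of 2000 genes, log2 effect size
2.0 (a 4-fold shift, sign random per gene), with monotone designs nesting
the planted sets so the dose–response trend is built in. Present/absent
flags are independent Bernoulli (default 5% absent) — real detection flags
correlate with intensity; this independence is the simplest testable
assumption and is a stated simplification. Pathway databases realise every
*requested* pairwise overlap exactly by giving each pair its own private
block of shared members; as a consequence triple intersections are always
empty, and overlap requests must fit within each pathway's size (violations
raise an error naming the offending pair).

What passing tests on these data do **not** show: robustness to correlated
noise between genes, intensity-dependent variance, structured missingness,
or partially overlapping pathway hierarchies as found in curated databases.

## Problem sizes and numerical choices

The statistical checks run at 2000 genes, 4 vs 4 replicates with the full
70-permutation enumeration: large enough that s0 selection and the FDR
machinery operate in their intended regime, small enough to iterate
quickly. Null calibration uses 10–25 seeded draws; the dose-response
trend 20–40. Degenerate inputs are defended explicitly: fewer than 2
replicates per group, empty delta grids, non-positive medians after
flooring (impossible by construction, checked anyway), empty pathway
member sets, and infeasible overlap requests all raise informative errors
rather than propagating NaNs.

## Known limitations

- Only the two-class unpaired design is supported (no paired, multiclass
  or time-course modes, no local-FDR estimation).
- The counting method inherits its sensitivity to pathway database
  composition: large pathways accumulate counts faster, and the ranking
  does not correct for set size — by design, since the method is a raw
  frequency count.
- The ortholog mapping is an input; no mapping is ever inferred, and
  mapping quality directly bounds pathway-count fidelity.
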