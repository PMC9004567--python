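# Methods

This note documents the models, conventions and design choices behind
`dualtarget`, in the order the pipeline runs them.

## Inputs and vocabularies

All inputs are delimited text: long-format TSV for ranked lists (`disease`,
`novelty`, `gene`, `rank`), comparison tables (`gene`, `comparison_id`,
`disease`, `logfc`, optionally `category`, `disease_class`), and hallmark
annotations; one-symbol-per-line text for gene pools. Gene symbols are
whitespace-stripped and upper-cased on ingest so that set operations across
sources with mixed symbol styles are deterministic. Closed vocabularies:
disease category {AAD, NAAD}; disease class {neurological, metabolic,
inflammatory, fibrotic, infectious} (infectious occurs only among NAADs, so
the consistency stage never encounters it); novelty {high_confidence,
medium_novel, highly_novel}; and twelve hallmark-of-aging terms (the nine
classic hallmarks plus extracellular matrix stiffness, inflammation and
retrotranspositions).

logFC is treated as an opaque signed magnitude: no assumption is made about
its base (log2 vs natural log), because every statistic downstream is either
sign-based (consistency) or location-based within one dataset (t-test), and
neither depends on the base. Rows with missing-value tokens (`NA`, empty,
`.` …) or non-finite logFC are dropped and counted in the load summary;
any other non-numeric cell is a row-level schema error.

## Aggregation

Within one category and novelty setting, each disease's list is truncated to
ranks ≤ `rank_cap` (default 100) — entries beyond the cap are excluded, not
clamped — and the truncated lists are unioned. Each gene gets
`occurrence` = number of diseases whose truncated list contains it, and
`mean_rank` = the average of its ranks over those diseases only. A gene's
absence from a disease affects occurrence, not mean rank: occurrence is the
dominant sort key, so adding a penalty rank for absences would double-count
the same signal. Ordering is (occurrence desc, mean_rank asc, gene symbol
asc); the lexicographic final tie-break is arbitrary but makes the output a
total order, hence byte-reproducible. Aggregation is a fold over a set
union, so it is invariant to the input order of the lists, and raising
`rank_cap` can only grow occurrences.

The top-k (default 100) genes of the AAD and NAAD aggregates are
intersected: `aad_specific = AAD \ NAAD`, `common = AAD ∩ NAAD`,
`naad_specific = NAAD \ AAD`. Novelty settings are processed independently;
no cross-novelty merging.

## Expression consistency

For a gene and an AAD disease class, `frac_up` and `frac_down` are the
fractions of that gene's case-control comparisons in the class with
logFC > 0 and < 0. A comparison with logFC exactly 0 counts toward neither
direction — a sign statistic should not credit absent change — so
`frac_up + frac_down ≤ 1`. The call is `up` when `frac_up ≥ threshold`,
`down` when `frac_down ≥ threshold`, else `inconsistent`; the threshold
(default 0.60) is inclusive and restricted to (0.5, 1], which guarantees at
most one direction can qualify. Consistency uses AAD-category records only;
NAAD records feed only the group comparison. Missing (gene, comparison)
records are simply absent from denominators.

The dual-purpose filter counts, per gene, the classes called `up` and the
classes called `down`; a direction with ≥ `min_classes` (default 2) classes
produces one call. A gene qualifying in both directions is emitted once per
direction with an `ambiguous` flag rather than silently dropped, so the
downstream rule engine can surface it.

The AAD-vs-NAAD comparison of a gene's logFC values is a two-tailed
two-sample t-test, Welch (unequal variance) by default since the two groups
pool heterogeneous datasets with no reason to share a variance; a pooled
Student variant is exposed for exact-replication attempts. At least two
observations per group are required. A Benjamini–Hochberg column is emitted
for reference but no filtering uses it, keeping the per-gene tests
presentational, as in the analysis the pipeline reimplements.

## Hypergeometric enrichment

Enrichment of n targets against a pool of K genes in a background of N
druggable genes, with observed overlap r, reports the expected overlap
E = n·K/N, the fold enrichment r/E, and the upper tail
p = P(X ≥ r) = 1 − Σ_{i<r} C(K,i)·C(N−K,n−i)/C(N,n). The tail convention is
`≥ r` (one minus the sum to r−1), not `> r`; the off-by-one is the classic
enrichment bug and is pinned by tests against exact rational arithmetic and
draw enumeration. Binomial coefficients are evaluated through log-gamma and
the tail summed in log space (`logsumexp`): N in the thousands overflows
naive factorials. r = 0 short-circuits to p = 1 exactly; the result is
clamped to [0, 1] against round-off. The background N is a property of the
pool (default 5,626, the druggable-gene universe), never hard-coded.

## Hallmark summaries and candidate selection

Hallmark assignment, pro/anti-aging role, cancer-driver status and safety
evidence are curated *inputs*; the module is a deterministic rule engine
over them. Summaries count, over a target list, genes per hallmark, genes
with ≥ 2 hallmarks, genes carrying all 12, and unannotated targets. The
candidate rule is a conjunction — ≥ 1 hallmark, a dual-purpose call, no
safety flag, and the cancer-driver exclusion (a flagged driver or suppressor
whose therapeutic direction would be antagonism, i.e. a pro-aging role, is
dropped; an agonist direction passes). Each criterion is an independent
toggle, and disabling any toggle can only enlarge the output (verified as a
property test). The role column maps directly to the therapy rationale:
pro-aging → antagonize, anti-aging → agonize.

## Synthetic data generator

The generator emulates the input layer of the study — not upstream omics
(no count matrices, batch effects or age covariates). Defaults are the
study conditions: 33 diseases with the published class assignments and
per-disease comparison counts (14 AADs / 87 comparisons, 19 NAADs / 126),
a 5,626-gene universe matching the druggable background, top-100 lists, and
a planted-sign probability of 0.9.

Planted structure: `n_planted_aad` genes (default 30) are boosted in AAD
diseases only; `n_planted_common` genes (default 20) in all diseases; the
remainder are null. The planted counts were chosen so planted genes fill
roughly half of a top-100 aggregate, leaving room for null genes to compete
— a regime where both sensitivity and false positives are measurable.
Ranks come from a score-and-sort pipeline rather than direct rank
permutation, preserving a realistic score→rank mechanism: null genes draw
scores uniformly on (1, n_genes); a planted gene draws G + U(0,1) with
G ~ Geometric(p) failures (default p = 0.05, mean 19, putting planted genes
mostly but not deterministically inside the top 100). As p → 1 planted genes
occupy the top ranks outright, a limit used as a generator test.

logFC: null genes draw Normal(0, σ) with σ = 1 (a typical spread for
moderated log2 fold changes across heterogeneous cohorts); planted genes
draw sign · |Normal(1.5, σ)|, where the sign equals the planted direction
with probability exactly `planted_sign_prob`. This makes the
per-comparison correct-sign probability equal to the parameter by
construction, so the generator's own distributional claims (binomial null
sign counts, degenerate limits) are exactly testable. All randomness flows
from one root seed through named CRC32-keyed substreams per disease and
purpose: identical configs are byte-reproducible and single diseases can be
regenerated in isolation.

What passing recovery tests show — and what they do not: the pipeline
correctly recovers genes whose ranks and logFC signs carry the planted
cross-disease signal under independent noise. Real transcriptomic
comparisons are not independent (shared platforms, overlapping cohorts,
correlated genes), real ranked lists come from a multi-score AI engine with
its own biases, and real effect sizes vary per gene; none of that is
emulated, so recovery rates here are generator-design targets, not claims
about performance on real data.

Recovery scoring (in `benchmark.py`): sensitivity is the fraction of
planted AAD genes present in `aad_specific ∩ dual-purpose`; the null
false-positive rate is the fraction of all null genes appearing in that
recovered set; the evaluation pool for enrichment is every planted gene
plus 50 seed-drawn null fillers over the simulated universe.

## Pipeline and determinism

Stages communicate through TSV files, each prefixed with a `#` provenance
line (tool version, config hash — never a timestamp), so any stage can be
rerun or swapped and every report number is recomputable from the emitted
intermediates. `report.json` carries parameters, SHA-256 hashes of all
inputs, per-stage row counts and a hash of the report itself; identical
inputs and config reproduce the hash bit-for-bit. Stage failures abort with
the stage name.

## Problem sizes in the test suite

Unit and property tests run on compact layouts (a 7-disease, 300-gene
configuration spanning all four AAD classes); the end-to-end recovery check
runs the full default study geometry over 20 seeds, and the acceptance
script does the same. Exhaustive hypergeometric oracles cover all instances
with N ≤ 25 (rational arithmetic) and N ≤ 10 plus one N = 20 case (draw
enumeration).

## Known limitations

* Headline counts of the original analysis that depend on its proprietary
  upstream scoring (sizes of the combined lists, the 42/58 split, the
  145-gene hallmark set, the 9-candidate shortlist) are not reproducible
  from printed data; the pipeline reproduces the *procedure* and is
  validated by parameter recovery on synthetic data instead.
* The consistency statistic ignores comparison weights (sample sizes per
  comparison are not part of the input schema).
* The candidate rule engine exposes the selection criteria as toggles; it
  does not attempt to reproduce any particular manual shortlist, whose
  curation involved unpublished judgment.
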