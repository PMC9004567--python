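"""Parameter-recovery evaluation of the pipeline on simulated data.

Runs the full analysis chain — aggregate, classify, per-class consistency,
dual-purpose filter, enrichment — on one simulated dataset and scores it
against the planted ground truth:

* sensitivity: fraction of planted AAD genes recovered in the
  AAD-specific ∩ dual-purpose set;
* null false-positive rate: fraction of null (unplanted) genes appearing
  in that recovered set;
* enrichment of the recovered set against a pool built as the planted
  genes plus random null fillers, over the simulated druggable background.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aggregation import classify_targets, combine_lists, select_top
from .consistency import consistency_table, dual_purpose_filter
from .enrichment import EnrichmentResult, overlap_and_test
from .simulate import SimConfig, _rng, gene_universe, simulate
from .types import Category, GenePool


@dataclass(frozen=True)
class RecoveryResult:
    """Scores of one simulated end-to-end run against planted truth."""

    seed: int
    n_recovered: int
    sensitivity: float
    false_positive_rate: float
    enrichment: EnrichmentResult | None


def run_recovery(
    config: SimConfig,
    rank_cap: int = 100,
    top_k: int = 100,
    threshold: float = 0.60,
    min_classes: int = 2,
    n_pool_fillers: int = 50,
) -> RecoveryResult:
    """Simulate, run the pipeline stages in memory, and score recovery.

    The evaluation pool contains every planted gene plus ``n_pool_fillers``
    null genes drawn from a seed-derived substream, with the simulated
    universe as the enrichment background.
    """
    lists, comparisons, truth = simulate(config)
    aad_names = {d.name for d in config.diseases if d.category is Category.AAD}
    aad_lists = [rl for rl in lists if rl.disease in aad_names]
    naad_lists = [rl for rl in lists if rl.disease not in aad_names]
    aad_top = select_top(combine_lists(aad_lists, rank_cap=rank_cap), top_k)
    naad_top = select_top(combine_lists(naad_lists, rank_cap=rank_cap), top_k)
    classification = classify_targets(aad_top, naad_top)

    profiles = consistency_table(comparisons, aad_top, threshold=threshold)
    calls = dual_purpose_filter(profiles, min_classes=min_classes)
    dual_genes = {c.gene for c in calls}
    recovered = sorted(classification.aad_specific & dual_genes)

    planted_aad = set(truth.planted_aad)
    planted_all = set(truth.planted)
    sensitivity = (
        len(planted_aad & set(recovered)) / len(planted_aad) if planted_aad else 0.0
    )
    fpr = (
        len(set(recovered) - planted_all) / len(truth.null_genes)
        if truth.null_genes
        else 0.0
    )

    enrichment = None
    if recovered and planted_all:
        rng = _rng(config.seed, "pool-fillers")
        nulls = sorted(truth.null_genes)
        fillers = (
            rng.choice(nulls, size=min(n_pool_fillers, len(nulls)), replace=False)
            if nulls
            else []
        )
        pool = GenePool(
            name="planted-plus-fillers",
            genes=frozenset(planted_all) | frozenset(fillers),
            background_size=len(gene_universe(config.n_genes)),
        )
        enrichment = overlap_and_test(recovered, pool)

    return RecoveryResult(
        seed=config.seed,
        n_recovered=len(recovered),
        sensitivity=sensitivity,
        false_positive_rate=fpr,
        enrichment=enrichment,
    )
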