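"""Cross-disease aggregation of ranked target lists.

Each disease contributes a top-``rank_cap`` ranked gene list.  Aggregation
unions the lists within one disease category (AAD or NAAD) and one novelty
setting, scoring every gene by (1) occurrence — the number of diseases whose
top list contains it — and (2) mean rank over the diseases where it occurs.
Genes are ordered by descending occurrence, then ascending mean rank, then
gene symbol (deterministic final tie-break).  The top-k slice of the AAD and
NAAD aggregates are then intersected to classify targets as AAD-specific,
common, or NAAD-specific.

A gene absent from a disease's top list contributes nothing to its mean
rank: occurrence, not a penalty rank, carries the cross-disease signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .types import Category, Novelty, RankedTargetList, ValidationError


@dataclass
class AggregatedTargets:
    """Combined cross-disease target table for one category + novelty.

    ``frame`` has columns gene, occurrence, mean_rank and is ordered by
    (occurrence desc, mean_rank asc, gene asc).
    """

    novelty: Novelty
    frame: pd.DataFrame
    category: Category | None = None
    n_diseases: int = 0

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class TargetClassification:
    """Partition of the union of two top lists into three disjoint sets."""

    aad_specific: frozenset[str]
    common: frozenset[str]
    naad_specific: frozenset[str]
    novelty: Novelty | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "aad_specific") for g in sorted(self.aad_specific)]
            + [(g, "common") for g in sorted(self.common)]
            + [(g, "naad_specific") for g in sorted(self.naad_specific)]
        )
        return pd.DataFrame(rows, columns=["gene", "membership"])


def combine_lists(
    lists: Iterable[RankedTargetList],
    rank_cap: int = 100,
    category: Category | str | None = None,
) -> AggregatedTargets:
    """Union per-disease top lists into one occurrence/mean-rank table.

    Each list is truncated to entries with rank <= ``rank_cap`` before the
    union; occurrence and mean rank are computed only over the diseases where
    a gene appears.  All lists must share one novelty setting; the input
    order of the lists does not affect the result.
    """
    lists = list(lists)
    if not lists:
        raise ValidationError("combine_lists: empty input collection")
    if rank_cap < 1:
        raise ValidationError(f"rank_cap must be >= 1, got {rank_cap}")
    novelties = {rl.novelty for rl in lists}
    if len(novelties) > 1:
        raise ValidationError(
            f"combine_lists: mixed novelty settings: {sorted(n.value for n in novelties)}"
        )
    diseases = [rl.disease for rl in lists]
    if len(set(diseases)) != len(diseases):
        raise ValidationError("combine_lists: duplicate disease lists")

    occurrence: dict[str, int] = {}
    rank_sum: dict[str, float] = {}
    for rl in lists:
        for gene, rank in rl.top(rank_cap).items():
            occurrence[gene] = occurrence.get(gene, 0) + 1
            rank_sum[gene] = rank_sum.get(gene, 0.0) + rank

    frame = pd.DataFrame(
        {
            "gene": list(occurrence),
            "occurrence": list(occurrence.values()),
            "mean_rank": [rank_sum[g] / occurrence[g] for g in occurrence],
        }
    )
    frame = frame.sort_values(
        ["occurrence", "mean_rank", "gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
    cat = Category(category) if category is not None else None
    return AggregatedTargets(
        novelty=lists[0].novelty, frame=frame, category=cat, n_diseases=len(lists)
    )


def select_top(agg: AggregatedTargets, k: int = 100) -> list[str]:
    """First ``k`` genes of an aggregate, in its canonical order."""
    if k <= 0:
        raise ValidationError(f"select_top: k must be positive, got {k}")
    return agg.frame["gene"].head(k).tolist()


def classify_targets(
    aad_top: Sequence[str],
    naad_top: Sequence[str],
    novelty: Novelty | str | None = None,
) -> TargetClassification:
    """Intersect AAD and NAAD top lists into specific/common/specific sets."""
    aad = [str(g) for g in aad_top]
    naad = [str(g) for g in naad_top]
    if len(set(aad)) != len(aad) or len(set(naad)) != len(naad):
        raise ValidationError("classify_targets: input lists must be deduplicated")
    aad_set, naad_set = set(aad), set(naad)
    return TargetClassification(
        aad_specific=frozenset(aad_set - naad_set),
        common=frozenset(aad_set & naad_set),
        naad_specific=frozenset(naad_set - aad_set),
        novelty=Novelty(novelty) if novelty is not None else None,
    )
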