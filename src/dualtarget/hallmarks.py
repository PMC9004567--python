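"""Hallmark-of-aging summaries and the candidate-selection rule engine.

The mapping from gene to hallmarks of aging is a curated literature input
(see :func:`dualtarget.io.read_hallmark_annotations`), as are the pro/anti-
aging role, cancer-driver status and safety evidence; nothing here mines
literature.  This module joins those annotations with target lists and
dual-purpose expression calls, producing (a) summary counts per hallmark and
(b) a deterministic conjunctive shortlist of dual-purpose candidates.

Candidate rule: a gene survives iff it has at least one hallmark AND a
dual-purpose consistency call AND no safety flag AND passes the
cancer-driver exclusion (a flagged driver/suppressor whose therapeutic
direction would be antagonism is dropped).  Every criterion is an
independent toggle; disabling a toggle can only enlarge the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consistency import DualPurposeCall
from .types import HALLMARKS, Novelty, ValidationError, normalize_gene

ROLE_TO_RATIONALE = {
    "pro_aging": "pro_aging_antagonize",
    "anti_aging": "anti_aging_agonize",
}


@dataclass(frozen=True)
class HallmarkSummary:
    """Counts of hallmark annotations over one target list."""

    per_hallmark_counts: Mapping[str, int]
    multi_hallmark_genes: frozenset[str]
    all_hallmark_genes: frozenset[str]
    annotated_total: int
    unannotated_targets: frozenset[str]


@dataclass(frozen=True)
class CandidateRecord:
    """One gene's pass through the candidate-selection rule engine."""

    gene: str
    novelty: Novelty
    hallmarks: frozenset[str]
    dual_purpose: DualPurposeCall | None
    direction_rationale: str
    cancer_driver_flag: bool
    safety_flag: bool
    ambiguous: bool = False


def _check_vocab(hallmarks: frozenset[str], gene: str) -> frozenset[str]:
    unknown = hallmarks - HALLMARKS
    if unknown:
        raise ValidationError(f"{gene}: unknown hallmark term(s): {sorted(unknown)}")
    return hallmarks


def summarize_hallmarks(
    annotations: pd.DataFrame, targets: Iterable[str]
) -> HallmarkSummary:
    """Summarize hallmark annotations over ``targets``.

    ``annotations`` is the table returned by
    :func:`~dualtarget.io.read_hallmark_annotations` (columns ``gene`` and
    ``hallmarks`` holding sets).  Counts cover the intersection of targets
    and annotated genes only; targets with no hallmark are reported
    separately in ``unannotated_targets``.
    """
    target_list = [normalize_gene(g) for g in targets]
    target_set = set(target_list)
    hallmark_of = {
        row.gene: _check_vocab(frozenset(row.hallmarks), row.gene)
        for row in annotations.itertuples()
    }
    counts = {h: 0 for h in sorted(HALLMARKS)}
    multi, full, annotated = set(), set(), set()
    for gene in target_set:
        terms = hallmark_of.get(gene, frozenset())
        if not terms:
            continue
        annotated.add(gene)
        for h in terms:
            counts[h] += 1
        if len(terms) >= 2:
            multi.add(gene)
        if len(terms) == len(HALLMARKS):
            full.add(gene)
    return HallmarkSummary(
        per_hallmark_counts=counts,
        multi_hallmark_genes=frozenset(multi),
        all_hallmark_genes=frozenset(full),
        annotated_total=len(annotated),
        unannotated_targets=frozenset(target_set - annotated),
    )


def summary_frame(summary: HallmarkSummary) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(summary.per_hallmark_counts.items()),
        columns=["hallmark", "n_genes"],
    )


def select_candidates(
    annotations: pd.DataFrame,
    dual_calls: Sequence[DualPurposeCall],
    targets: Iterable[str] | None = None,
    require_hallmark: bool = True,
    require_dual_purpose: bool = True,
    require_safe: bool = True,
    exclude_cancer_drivers: bool = True,
) -> list[CandidateRecord]:
    """Apply the conjunctive candidate rule over annotated genes.

    The candidate universe is the annotated genes, optionally restricted to
    ``targets``.  A gene with dual-purpose calls in both directions is
    emitted once per direction with ``ambiguous=True``, never silently
    dropped.  Output is sorted by (gene, direction rationale).
    """
    calls_by_gene: dict[str, list[DualPurposeCall]] = {}
    for call in dual_calls:
        calls_by_gene.setdefault(call.gene, []).append(call)
    restrict = {normalize_gene(g) for g in targets} if targets is not None else None

    out: list[CandidateRecord] = []
    for row in annotations.sort_values("gene").itertuples():
        gene = row.gene
        if restrict is not None and gene not in restrict:
            continue
        hallmarks = _check_vocab(frozenset(row.hallmarks), gene)
        rationale = ROLE_TO_RATIONALE[row.role]
        if require_hallmark and not hallmarks:
            continue
        if require_safe and bool(row.safety_flag):
            continue
        if (
            exclude_cancer_drivers
            and bool(row.cancer_driver)
            and rationale == "pro_aging_antagonize"
        ):
            continue
        gene_calls = calls_by_gene.get(gene, [])
        if require_dual_purpose and not gene_calls:
            continue
        ambiguous = any(c.ambiguous for c in gene_calls)
        for call in sorted(gene_calls, key=lambda c: c.direction) or [None]:
            out.append(
                CandidateRecord(
                    gene=gene,
                    novelty=Novelty(row.novelty),
                    hallmarks=hallmarks,
                    dual_purpose=call,
                    direction_rationale=rationale,
                    cancer_driver_flag=bool(row.cancer_driver),
                    safety_flag=bool(row.safety_flag),
                    ambiguous=ambiguous,
                )
            )
    return out


def candidates_frame(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene,
                c.novelty.value,
                ";".join(sorted(c.hallmarks)),
                c.dual_purpose.direction if c.dual_purpose else "",
                c.dual_purpose.n_classes_consistent if c.dual_purpose else 0,
                c.direction_rationale,
                int(c.cancer_driver_flag),
                int(c.safety_flag),
                int(c.ambiguous),
            )
            for c in candidates
        ],
        columns=[
            "gene",
            "novelty",
            "hallmarks",
            "direction",
            "n_classes_consistent",
            "direction_rationale",
            "cancer_driver",
            "safety_flag",
            "ambiguous",
        ],
    )
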