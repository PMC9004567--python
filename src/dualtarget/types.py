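"""Shared domain types, closed vocabularies and validation errors.

The pipeline manipulates a small set of tabular objects: per-disease ranked
target lists, per-comparison log fold-change (logFC) records, curated gene
pools, and gene-to-hallmark annotations.  On disk everything is plain text
(TSV, or one symbol per line for pools); in memory each object is either a
small dataclass or a pandas DataFrame whose columns follow the schemas
defined here.

Gene symbols are upper-cased and whitespace-stripped on ingest so that set
operations across sources with mixed symbol styles are deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class SchemaError(ValueError):
    """An input table is missing a required column or has an unparseable cell."""


class ValidationError(ValueError):
    """An input parsed cleanly but violates a domain invariant."""


class Category(str, enum.Enum):
    """Disease category: age-associated (AAD) or non-age-associated (NAAD)."""

    AAD = "AAD"
    NAAD = "NAAD"


class DiseaseClass(str, enum.Enum):
    """Broad mechanistic disease class used for per-class consistency calls."""

    NEUROLOGICAL = "neurological"
    METABOLIC = "metabolic"
    INFLAMMATORY = "inflammatory"
    FIBROTIC = "fibrotic"
    INFECTIOUS = "infectious"


class Novelty(str, enum.Enum):
    """Novelty setting of a ranked target list.

    Trades literature evidence for novelty: ``high_confidence`` lists favour
    well-published targets, ``highly_novel`` lists favour sparsely published
    ones.
    """

    HIGH_CONFIDENCE = "high_confidence"
    MEDIUM_NOVEL = "medium_novel"
    HIGHLY_NOVEL = "highly_novel"


#: The twelve hallmark-of-aging terms accepted in annotation tables: the nine
#: classic hallmarks plus extracellular matrix stiffness, inflammation and
#: retrotranspositions.
HALLMARKS: frozenset[str] = frozenset(
    {
        "altered intercellular communications",
        "cellular senescence",
        "deregulated nutrient signaling",
        "epigenetic shift",
        "genomic instability",
        "impaired proteostasis",
        "mitochondrial dysfunction",
        "stem cell exhaustion",
        "telomere attrition",
        "extracellular matrix stiffness",
        "inflammation",
        "retrotranspositions",
    }
)

N_HALLMARKS = len(HALLMARKS)


def normalize_gene(symbol: str) -> str:
    """Canonicalize a gene symbol: strip whitespace, upper-case.

    Raises :class:`ValidationError` on an empty symbol.
    """
    sym = str(symbol).strip().upper()
    if not sym:
        raise ValidationError("empty gene symbol")
    return sym


def _coerce(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError as exc:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"{value!r} is not a valid {enum_cls.__name__} (allowed: {allowed})"
        ) from exc


@dataclass(frozen=True)
class DiseaseMeta:
    """One disease: its name, AAD/NAAD category, class, and comparison count."""

    name: str
    category: Category
    disease_class: DiseaseClass
    n_comparisons: int

    def __post_init__(self):
        object.__setattr__(self, "category", _coerce(self.category, Category))
        object.__setattr__(
            self, "disease_class", _coerce(self.disease_class, DiseaseClass)
        )
        if self.n_comparisons < 1:
            raise ValidationError(
                f"{self.name}: n_comparisons must be >= 1, got {self.n_comparisons}"
            )


def build_registry(diseases: Iterable[DiseaseMeta]) -> dict[str, DiseaseMeta]:
    """Index diseases by name, rejecting duplicates."""
    registry: dict[str, DiseaseMeta] = {}
    for meta in diseases:
        if meta.name in registry:
            raise ValidationError(f"duplicate disease name: {meta.name}")
        registry[meta.name] = meta
    return registry


@dataclass
class RankedTargetList:
    """One disease's prioritized genes under one novelty setting.

    ``entries`` maps gene symbol to rank (1 = strongest association); the
    mapping preserves insertion order, which downstream code treats as the
    file's row order.
    """

    disease: str
    novelty: Novelty
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.novelty = _coerce(self.novelty, Novelty)
        seen_ranks: dict[int, str] = {}
        clean: dict[str, int] = {}
        for gene, rank in self.entries.items():
            sym = normalize_gene(gene)
            rank = int(rank)
            if rank < 1:
                raise ValidationError(f"{self.disease}/{sym}: rank must be >= 1")
            if sym in clean:
                raise ValidationError(f"{self.disease}: duplicate gene {sym}")
            if rank in seen_ranks:
                raise ValidationError(
                    f"{self.disease}: rank {rank} assigned to both "
                    f"{seen_ranks[rank]} and {sym}"
                )
            seen_ranks[rank] = sym
            clean[sym] = rank
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, rank_cap: int) -> dict[str, int]:
        """Entries with rank <= ``rank_cap``, ordered by rank."""
        return {
            g: r
            for g, r in sorted(self.entries.items(), key=lambda kv: kv[1])
            if r <= rank_cap
        }


@dataclass(frozen=True)
class GenePool:
    """A curated gene set together with the druggable background it lives in.

    ``background_size`` is the size N of the druggable universe used as the
    hypergeometric background for enrichment against this pool.
    """

    name: str
    genes: frozenset[str]
    background_size: int

    def __post_init__(self):
        object.__setattr__(
            self, "genes", frozenset(normalize_gene(g) for g in self.genes)
        )
        if self.background_size < 1:
            raise ValidationError(f"{self.name}: background_size must be positive")
        if len(self.genes) > self.background_size:
            raise ValidationError(
                f"{self.name}: pool of {len(self.genes)} genes exceeds "
                f"background_size {self.background_size}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class HallmarkAnnotation:
    """Literature-derived annotation of one gene.

    ``hallmarks`` must be drawn from the 12-term :data:`HALLMARKS` vocabulary.
    The pro/anti-aging role, cancer-driver status and safety evidence are
    curated inputs, not computed quantities.
    """

    gene: str
    hallmarks: frozenset[str]
    is_cancer_driver: bool = False
    novelty: Novelty = Novelty.HIGH_CONFIDENCE
    role: str = "pro_aging"  # {pro_aging, anti_aging}
    safety_flag: bool = False

    def __post_init__(self):
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        object.__setattr__(self, "hallmarks", frozenset(self.hallmarks))
        object.__setattr__(self, "novelty", _coerce(self.novelty, Novelty))
        unknown = self.hallmarks - HALLMARKS
        if unknown:
            raise ValidationError(
                f"{self.gene}: unknown hallmark term(s): {sorted(unknown)}"
            )
        if self.role not in ("pro_aging", "anti_aging"):
            raise ValidationError(
                f"{self.gene}: role must be pro_aging or anti_aging, got {self.role!r}"
            )


def validate_vocab(value: str, vocabulary: Mapping | frozenset, what: str) -> str:
    """Check membership of ``value`` in a closed vocabulary."""
    if value not in vocabulary:
        raise ValidationError(f"unknown {what}: {value!r}")
    return value
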