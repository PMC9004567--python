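"""Synthetic ranked lists and logFC tables with planted ground truth.

The generator emulates the input layer of the cross-disease target-discovery
study: 33 diseases (14 age-associated, 19 non-age-associated, with the
study's class assignments and per-disease case-control comparison counts of
87 and 126), a druggable universe of 5,626 genes, per-disease top-100 ranked
target lists, and one logFC value per (gene, comparison).

Planted structure:

* *planted AAD genes* receive stochastically better ranks in AAD diseases
  only, and a directional logFC shift in AAD comparisons;
* *planted common genes* are boosted and shifted in every disease;
* *null genes* have uniformly random rank scores and zero-centred logFC.

Ranks come from sampling a score per gene and sorting: null scores are
uniform on (1, n_genes), a planted gene's score is G + U(0,1) with
G ~ Geometric(planted_rank_geometric_p) failures — the larger the geometric
parameter, the closer planted genes sit to the top, and in the limit of the
parameter at 1 they occupy the top ranks outright.  A planted gene's logFC
is sign * |Normal(planted_logfc_mean, noise_logfc_sd)| where the sign equals
the planted direction with probability ``planted_sign_prob``, so the
per-comparison probability of the correct sign is exactly that parameter.

All randomness flows from one root seed through named substreams (one per
disease and purpose), so identical configurations reproduce byte-identical
outputs and individual diseases can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import COMPARISON_COLUMNS
from .types import (
    Category,
    DiseaseClass,
    DiseaseMeta,
    Novelty,
    RankedTargetList,
    ValidationError,
)

#: The 33-disease study layout: 14 age-associated diseases spanning 87
#: case-control comparisons and 19 non-age-associated diseases spanning 126.
STUDY_DISEASES: tuple[DiseaseMeta, ...] = (
    DiseaseMeta("Alzheimer's disease", Category.AAD, DiseaseClass.NEUROLOGICAL, 12),
    DiseaseMeta("Amyotrophic lateral sclerosis", Category.AAD, DiseaseClass.NEUROLOGICAL, 10),
    DiseaseMeta("Chronic kidney disease", Category.AAD, DiseaseClass.METABOLIC, 7),
    DiseaseMeta("Chronic obstructive pulmonary disease", Category.AAD, DiseaseClass.INFLAMMATORY, 6),
    DiseaseMeta("Cirrhosis of liver", Category.AAD, DiseaseClass.FIBROTIC, 5),
    DiseaseMeta("Idiopathic Pulmonary Fibrosis", Category.AAD, DiseaseClass.FIBROTIC, 11),
    DiseaseMeta("Obesity", Category.AAD, DiseaseClass.METABOLIC, 10),
    DiseaseMeta("Osteoarthritis", Category.AAD, DiseaseClass.INFLAMMATORY, 5),
    DiseaseMeta("Osteoporosis", Category.AAD, DiseaseClass.METABOLIC, 2),
    DiseaseMeta("Parkinson's disease", Category.AAD, DiseaseClass.NEUROLOGICAL, 4),
    DiseaseMeta("Primary myelofibrosis", Category.AAD, DiseaseClass.FIBROTIC, 2),
    DiseaseMeta("Pulmonary arterial hypertension", Category.AAD, DiseaseClass.METABOLIC, 5),
    DiseaseMeta("Rheumatoid Arthritis", Category.AAD, DiseaseClass.INFLAMMATORY, 4),
    DiseaseMeta("Type II diabetes mellitus", Category.AAD, DiseaseClass.METABOLIC, 4),
    DiseaseMeta("Acromegaly", Category.NAAD, DiseaseClass.METABOLIC, 2),
    DiseaseMeta("Asthma", Category.NAAD, DiseaseClass.INFLAMMATORY, 13),
    DiseaseMeta("Bipolar disorder", Category.NAAD, DiseaseClass.NEUROLOGICAL, 4),
    DiseaseMeta("Celiac disease", Category.NAAD, DiseaseClass.INFLAMMATORY, 3),
    DiseaseMeta("Crohn's disease", Category.NAAD, DiseaseClass.INFLAMMATORY, 8),
    DiseaseMeta("Cystic fibrosis", Category.NAAD, DiseaseClass.FIBROTIC, 5),
    DiseaseMeta("Hepatitis, alcoholic", Category.NAAD, DiseaseClass.METABOLIC, 3),
    DiseaseMeta("Hepatitis C virus infection", Category.NAAD, DiseaseClass.INFECTIOUS, 2),
    DiseaseMeta("Huntington's disease", Category.NAAD, DiseaseClass.NEUROLOGICAL, 5),
    DiseaseMeta("Infectious meningitis", Category.NAAD, DiseaseClass.INFECTIOUS, 3),
    DiseaseMeta("Influenza", Category.NAAD, DiseaseClass.INFECTIOUS, 5),
    DiseaseMeta("Multiple sclerosis", Category.NAAD, DiseaseClass.INFLAMMATORY, 11),
    DiseaseMeta("Psoriasis", Category.NAAD, DiseaseClass.INFLAMMATORY, 11),
    DiseaseMeta("Pulmonary tuberculosis", Category.NAAD, DiseaseClass.INFECTIOUS, 7),
    DiseaseMeta("Schizophrenia", Category.NAAD, DiseaseClass.NEUROLOGICAL, 4),
    DiseaseMeta("Systemic lupus erythematosus", Category.NAAD, DiseaseClass.INFLAMMATORY, 9),
    DiseaseMeta("Systemic scleroderma", Category.NAAD, DiseaseClass.FIBROTIC, 6),
    DiseaseMeta("Type I diabetes mellitus", Category.NAAD, DiseaseClass.METABOLIC, 12),
    DiseaseMeta("Ulcerative colitis", Category.NAAD, DiseaseClass.INFLAMMATORY, 13),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation.

    Defaults mirror the study conditions: a 5,626-gene druggable universe,
    the 33-disease layout above, top-100 lists, and a 0.9 per-comparison
    probability that a planted gene's logFC carries its planted sign.
    """

    seed: int = 0
    n_genes: int = 5626
    diseases: tuple[DiseaseMeta, ...] = STUDY_DISEASES
    n_planted_aad: int = 30
    n_planted_common: int = 20
    planted_sign_prob: float = 0.9
    planted_rank_geometric_p: float = 0.05
    noise_logfc_sd: float = 1.0
    planted_logfc_mean: float = 1.5
    list_length: int = 100
    novelty: Novelty = Novelty.HIGH_CONFIDENCE

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_planted_aad < 0 or self.n_planted_common < 0:
            raise ValidationError("planted counts must be non-negative")
        if self.n_planted_aad + self.n_planted_common > self.n_genes:
            raise ValidationError("planted counts exceed gene universe")
        if not (0.5 < self.planted_sign_prob <= 1.0):
            raise ValidationError("planted_sign_prob must be in (0.5, 1]")
        if not (0.0 < self.planted_rank_geometric_p <= 1.0):
            raise ValidationError("planted_rank_geometric_p must be in (0, 1]")
        if self.noise_logfc_sd <= 0:
            raise ValidationError("noise_logfc_sd must be positive")
        if self.list_length < 1:
            raise ValidationError("list_length must be positive")
        object.__setattr__(self, "novelty", Novelty(self.novelty))
        object.__setattr__(self, "diseases", tuple(self.diseases))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Planted gene assignments: gene -> direction (+1 up, -1 down)."""

    planted_aad: dict[str, int] = field(default_factory=dict)
    planted_common: dict[str, int] = field(default_factory=dict)
    null_genes: frozenset[str] = frozenset()

    @property
    def planted(self) -> dict[str, int]:
        return {**self.planted_aad, **self.planted_common}

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "planted_aad", d) for g, d in sorted(self.planted_aad.items())]
            + [(g, "planted_common", d) for g, d in sorted(self.planted_common.items())]
        )
        return pd.DataFrame(rows, columns=["gene", "role", "direction"])


def gene_universe(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Named substream: root seed extended with CRC32 keys per name."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng([seed, *keys])


def make_truth(config: SimConfig) -> GroundTruth:
    genes = gene_universe(config.n_genes)
    rng = _rng(config.seed, "truth")
    n_planted = config.n_planted_aad + config.n_planted_common
    picked = rng.choice(config.n_genes, size=n_planted, replace=False)
    directions = rng.choice([1, -1], size=n_planted)
    planted_aad = {
        genes[i]: int(d)
        for i, d in zip(picked[: config.n_planted_aad], directions[: config.n_planted_aad])
    }
    planted_common = {
        genes[i]: int(d)
        for i, d in zip(picked[config.n_planted_aad :], directions[config.n_planted_aad :])
    }
    null = frozenset(genes) - set(planted_aad) - set(planted_common)
    return GroundTruth(
        planted_aad=planted_aad, planted_common=planted_common, null_genes=null
    )


def _relevant_planted(truth: GroundTruth, meta: DiseaseMeta) -> dict[str, int]:
    if meta.category is Category.AAD:
        return truth.planted
    return dict(truth.planted_common)


def gen_ranked_lists(
    config: SimConfig, truth: GroundTruth | None = None
) -> tuple[list[RankedTargetList], GroundTruth]:
    """Simulate one top-``list_length`` ranked list per disease.

    Planted genes relevant to a disease draw geometric rank scores near the
    top; null genes draw uniform scores.  Identical config (seed included)
    yields identical output.
    """
    if truth is None:
        truth = make_truth(config)
    genes = np.array(gene_universe(config.n_genes))
    index = {g: i for i, g in enumerate(genes)}
    lists: list[RankedTargetList] = []
    for meta in config.diseases:
        relevant = _relevant_planted(truth, meta)
        if len(relevant) > config.list_length:
            raise ValidationError(
                f"{meta.name}: {len(relevant)} planted genes exceed list length "
                f"{config.list_length}"
            )
        rng = _rng(config.seed, "ranks", meta.name)
        scores = rng.uniform(1.0, float(config.n_genes), size=config.n_genes)
        if relevant:
            idx = np.array([index[g] for g in relevant])
            failures = rng.geometric(config.planted_rank_geometric_p, size=idx.size) - 1
            scores[idx] = failures + rng.uniform(0.0, 1.0, size=idx.size)
        top = np.argsort(scores, kind="stable")[: config.list_length]
        entries = {genes[i]: rank for rank, i in enumerate(top, start=1)}
        lists.append(
            RankedTargetList(disease=meta.name, novelty=config.novelty, entries=entries)
        )
    return lists, truth


def gen_comparisons(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate one logFC per (gene, case-control comparison).

    Null genes draw Normal(0, noise_logfc_sd); planted genes relevant to the
    disease draw sign * |Normal(planted_logfc_mean, noise_logfc_sd)| with
    the planted sign kept at probability ``planted_sign_prob``.
    """
    genes = np.array(gene_universe(config.n_genes))
    index = {g: i for i, g in enumerate(genes)}
    chunks: list[pd.DataFrame] = []
    for meta in config.diseases:
        rng = _rng(config.seed, "logfc", meta.name)
        k = meta.n_comparisons
        values = rng.normal(0.0, config.noise_logfc_sd, size=(config.n_genes, k))
        relevant = _relevant_planted(truth, meta)
        if relevant:
            idx = np.array([index[g] for g in relevant])
            direction = np.array([relevant[g] for g in genes[idx]])[:, None]
            magnitude = np.abs(
                rng.normal(config.planted_logfc_mean, config.noise_logfc_sd, size=(idx.size, k))
            )
            keep = rng.random(size=(idx.size, k)) < config.planted_sign_prob
            signs = direction * np.where(keep, 1, -1)
            values[idx, :] = signs * magnitude
        comp_ids = [f"{meta.name}|c{j+1}" for j in range(k)]
        chunk = pd.DataFrame(
            {
                "gene": np.repeat(genes, k),
                "comparison_id": np.tile(comp_ids, config.n_genes),
                "disease": meta.name,
                "logfc": values.ravel(),
                "category": meta.category.value,
                "disease_class": meta.disease_class.value,
            }
        )
        chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)[COMPARISON_COLUMNS]


def simulate(config: SimConfig) -> tuple[list[RankedTargetList], pd.DataFrame, GroundTruth]:
    """Generate ranked lists and the comparison table from one config."""
    lists, truth = gen_ranked_lists(config)
    comparisons = gen_comparisons(config, truth)
    return lists, comparisons, truth


def study_registry() -> dict[str, DiseaseMeta]:
    from .types import build_registry

    return build_registry(STUDY_DISEASES)
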