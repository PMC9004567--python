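"""Readers and writers for the pipeline's delimited-text formats.

All tabular inputs and outputs are header-ed TSV (comma configurable via
``sep``); gene pools are plain text, one symbol per line.  Output files start
with a provenance comment line prefixed by ``#`` carrying the tool version
and, where relevant, a configuration hash; all readers skip ``#`` lines.

Readers are total on their declared schemas: any failure raises a typed
error (:class:`~dualtarget.types.SchemaError` or
:class:`~dualtarget.types.ValidationError`) and never returns a partially
loaded object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .types import (
    Category,
    DiseaseClass,
    DiseaseMeta,
    GenePool,
    HALLMARKS,
    Novelty,
    RankedTargetList,
    SchemaError,
    ValidationError,
    normalize_gene,
)

#: Canonical column order for comparison tables.
COMPARISON_COLUMNS = [
    "gene",
    "comparison_id",
    "disease",
    "logfc",
    "category",
    "disease_class",
]

_MISSING_LOGFC = {"", "NA", "N/A", "NAN", "NONE", "NULL", "."}


def provenance_line(**extra: object) -> str:
    parts = [f"# dualtarget {__version__}"]
    parts.extend(f"{k}={v}" for k, v in sorted(extra.items()))
    return " ".join(parts)


def write_table(frame: pd.DataFrame, path: str | Path, sep: str = "\t", **meta) -> None:
    """Write a DataFrame as delimited text with a provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(**meta) + "\n")
        frame.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")


def read_ranked_lists(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[RankedTargetList]:
    """Load per-disease ranked target lists from a long-format table.

    Required columns (renameable through ``schema``, a mapping from the
    canonical name to the column name actually present): ``disease``,
    ``novelty``, ``gene``, ``rank``.  One :class:`RankedTargetList` is built
    per (disease, novelty) pair; within each list the file's row order is
    preserved.
    """
    frame = read_table(path, sep=sep)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in frame.columns}
    for canonical, actual in schema.items():
        if actual not in frame.columns:
            raise SchemaError(
                f"{path}: schema maps {canonical!r} to missing column {actual!r}"
            )
    frame = frame.rename(columns=rename)
    _require_columns(frame, ["disease", "novelty", "gene", "rank"], path)

    frame = frame.assign(gene=frame["gene"].map(normalize_gene))
    dup = frame.duplicated(subset=["disease", "novelty", "gene"], keep=False)
    if dup.any():
        offenders = (
            frame.loc[dup, ["disease", "novelty", "gene"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValidationError(f"{path}: duplicate (disease, novelty, gene): {offenders}")

    lists = []
    for (disease, novelty), grp in frame.groupby(["disease", "novelty"], sort=False):
        entries = dict(zip(grp["gene"], grp["rank"].astype(int)))
        lists.append(RankedTargetList(disease=disease, novelty=novelty, entries=entries))
    return lists


def write_ranked_lists(
    lists: Iterable[RankedTargetList], path: str | Path, sep: str = "\t", **meta
) -> None:
    rows = [
        (rl.disease, rl.novelty.value, gene, rank)
        for rl in lists
        for gene, rank in rl.entries.items()
    ]
    frame = pd.DataFrame(rows, columns=["disease", "novelty", "gene", "rank"])
    write_table(frame, path, sep=sep, **meta)


@dataclass
class ComparisonLoad:
    """Validated comparison records plus a summary of rejected rows."""

    frame: pd.DataFrame
    n_rejected: int = 0
    rejected_rows: list[int] = field(default_factory=list)  # 0-based data rows


def read_comparisons(
    path: str | Path,
    registry: Mapping[str, DiseaseMeta] | None = None,
    sep: str = "\t",
) -> ComparisonLoad:
    """Load per-comparison logFC records.

    Required columns: ``gene``, ``comparison_id``, ``disease``, ``logfc``.
    ``category`` and ``disease_class`` are taken from the file when present,
    otherwise resolved through ``registry``; a disease absent from the
    registry is an error.  Rows whose logfc is a missing-value token or
    non-finite are dropped and counted in the returned summary; any other
    non-numeric logfc raises a row-level :class:`SchemaError`.
    """
    frame = read_table(path, sep=sep)
    _require_columns(frame, ["gene", "comparison_id", "disease", "logfc"], path)
    frame = frame.reset_index(drop=True)

    raw = frame["logfc"]
    values = pd.Series(math.nan, index=frame.index, dtype=float)
    missing_mask = pd.Series(False, index=frame.index)
    for i, cell in raw.items():
        if isinstance(cell, str):
            token = cell.strip()
            if token.upper() in _MISSING_LOGFC:
                missing_mask[i] = True
                continue
            try:
                values[i] = float(token)
            except ValueError as exc:
                raise SchemaError(
                    f"{path}: non-numeric logfc {cell!r} at data row {i}"
                ) from exc
        else:
            values[i] = float(cell)
    nonfinite = ~missing_mask & ~values.map(math.isfinite)
    drop_mask = missing_mask | nonfinite
    rejected_rows = list(frame.index[drop_mask])
    frame = frame.loc[~drop_mask].assign(logfc=values[~drop_mask])

    frame = frame.assign(
        gene=frame["gene"].map(normalize_gene),
        comparison_id=frame["comparison_id"].astype(str),
    )
    dup = frame.duplicated(subset=["gene", "comparison_id"], keep=False)
    if dup.any():
        offenders = (
            frame.loc[dup, ["gene", "comparison_id"]]
            .drop_duplicates()
            .head(10)
            .to_records(index=False)
            .tolist()
        )
        raise ValidationError(f"{path}: duplicate (gene, comparison_id): {offenders}")

    if "category" in frame.columns and "disease_class" in frame.columns:
        bad_cat = set(frame["category"]) - {c.value for c in Category}
        bad_cls = set(frame["disease_class"]) - {c.value for c in DiseaseClass}
        if bad_cat or bad_cls:
            raise ValidationError(
                f"{path}: unknown category/disease_class values: "
                f"{sorted(bad_cat | bad_cls)}"
            )
    else:
        if registry is None:
            raise SchemaError(
                f"{path}: no category/disease_class columns and no disease "
                "registry supplied to resolve them"
            )
        unknown = sorted(set(frame["disease"]) - set(registry))
        if unknown:
            raise ValidationError(f"{path}: unknown disease(s): {unknown}")
        frame = frame.assign(
            category=frame["disease"].map(lambda d: registry[d].category.value),
            disease_class=frame["disease"].map(
                lambda d: registry[d].disease_class.value
            ),
        )
    frame = frame[COMPARISON_COLUMNS].reset_index(drop=True)
    return ComparisonLoad(
        frame=frame, n_rejected=len(rejected_rows), rejected_rows=rejected_rows
    )


def write_comparisons(frame: pd.DataFrame, path: str | Path, sep: str = "\t", **meta):
    write_table(frame[COMPARISON_COLUMNS], path, sep=sep, **meta)


def read_gene_pool(
    path: str | Path, name: str, background_size: int
) -> GenePool:
    """Load a curated gene pool (one symbol per line, ``#`` comments allowed).

    Symbols are case-normalized and deduplicated; an empty file or a
    background smaller than the pool is an error.
    """
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(normalize_gene(line))
    if not symbols:
        raise ValidationError(f"{path}: gene pool file is empty")
    return GenePool(name=name, genes=frozenset(symbols), background_size=background_size)


def write_gene_pool(pool: GenePool, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(sorted(pool.genes)) + "\n")


_TRUTHY = {"1", "TRUE", "YES", "T"}


def _as_bool(cell) -> bool:
    if isinstance(cell, bool):
        return cell
    if pd.isna(cell):
        return False
    return str(cell).strip().upper() in _TRUTHY


def read_hallmark_annotations(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Load the gene-to-hallmark annotation table.

    Required columns: ``gene``, ``hallmarks`` (semicolon-separated terms from
    the 12-term vocabulary; empty allowed).  Optional: ``role``
    ({pro_aging, anti_aging}; default pro_aging), ``cancer_driver``,
    ``safety_flag`` (0/1 booleans), ``novelty``.  Returns a DataFrame with
    one row per gene and the ``hallmarks`` column holding frozensets.
    """
    frame = read_table(path, sep=sep)
    _require_columns(frame, ["gene", "hallmarks"], path)
    frame = frame.assign(gene=frame["gene"].map(normalize_gene))
    if frame["gene"].duplicated().any():
        dupes = sorted(frame.loc[frame["gene"].duplicated(), "gene"])
        raise ValidationError(f"{path}: duplicate annotation rows for {dupes}")

    def parse_hallmarks(cell) -> frozenset[str]:
        if pd.isna(cell) or not str(cell).strip():
            return frozenset()
        terms = frozenset(t.strip().lower() for t in str(cell).split(";") if t.strip())
        unknown = terms - HALLMARKS
        if unknown:
            raise ValidationError(f"{path}: unknown hallmark term(s): {sorted(unknown)}")
        return terms

    out = pd.DataFrame(
        {
            "gene": frame["gene"],
            "hallmarks": frame["hallmarks"].map(parse_hallmarks),
            "role": frame.get("role", pd.Series("pro_aging", index=frame.index)).fillna(
                "pro_aging"
            ),
            "cancer_driver": frame.get(
                "cancer_driver", pd.Series(False, index=frame.index)
            ).map(_as_bool),
            "safety_flag": frame.get(
                "safety_flag", pd.Series(False, index=frame.index)
            ).map(_as_bool),
            "novelty": frame.get(
                "novelty", pd.Series(Novelty.HIGH_CONFIDENCE.value, index=frame.index)
            ),
        }
    )
    bad_role = set(out["role"]) - {"pro_aging", "anti_aging"}
    if bad_role:
        raise ValidationError(f"{path}: unknown role value(s): {sorted(bad_role)}")
    bad_nov = set(out["novelty"]) - {n.value for n in Novelty}
    if bad_nov:
        raise ValidationError(f"{path}: unknown novelty value(s): {sorted(bad_nov)}")
    return out.reset_index(drop=True)


def write_hallmark_annotations(frame: pd.DataFrame, path: str | Path, sep: str = "\t"):
    out = frame.assign(hallmarks=frame["hallmarks"].map(lambda s: ";".join(sorted(s))))
    write_table(out, path, sep=sep)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line, normalized, order preserved, deduplicated."""
    genes: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym = normalize_gene(line)
        if sym not in seen:
            seen.add(sym)
            genes.append(sym)
    return genes
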