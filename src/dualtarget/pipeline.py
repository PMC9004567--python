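"""End-to-end orchestration: aggregate -> classify -> consistency ->
dual-purpose -> enrichment -> hallmark summary -> candidates.

Stages communicate through TSV files in the output directory rather than
in-memory handoff, so any stage can be rerun or audited in isolation.  A
machine-readable ``report.json`` records the parameters, SHA-256 hashes of
every input, row counts at each stage, and a hash of the report itself;
identical inputs and configuration reproduce an identical report hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .aggregation import classify_targets, combine_lists, select_top
from .consistency import consistency_table, dual_purpose_filter, dual_purpose_frame, group_comparison_table
from .enrichment import overlap_and_test
from .hallmarks import candidates_frame, select_candidates, summarize_hallmarks, summary_frame
from .io import (
    read_comparisons,
    read_gene_pool,
    read_hallmark_annotations,
    read_ranked_lists,
    write_table,
)
from .types import Category, Novelty, ValidationError

log = logging.getLogger("dualtarget")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and parameters of one full pipeline run."""

    ranked_lists: str
    comparisons: str
    out_dir: str
    pools: dict[str, str] = field(default_factory=dict)  # name -> path
    annotations: str | None = None
    rank_cap: int = 100
    top_k: int = 100
    threshold: float = 0.60
    min_classes: int = 2
    test_variant: str = "welch"
    background_n: int = 5626
    novelties: list[str] | None = None  # default: all present in the input
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValidationError, OSError, KeyError) as exc:
            raise StageError(name, str(exc)) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as
    ``report.json`` in the output directory)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"config_hash": chash}
    report: dict = {
        "tool": {"name": "dualtarget", "version": __version__},
        "parameters": asdict(config),
        "inputs": {},
        "stages": {},
    }
    input_paths = {"ranked_lists": config.ranked_lists, "comparisons": config.comparisons}
    for name, path in config.pools.items():
        input_paths[f"pool:{name}"] = path
    if config.annotations:
        input_paths["annotations"] = config.annotations
    for name, path in input_paths.items():
        report["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    lists = _stage("read_ranked_lists")(read_ranked_lists, config.ranked_lists)
    load = _stage("read_comparisons")(read_comparisons, config.comparisons)
    comparisons = load.frame
    report["stages"]["load"] = {
        "ranked_lists": len(lists),
        "comparison_rows": int(len(comparisons)),
        "comparison_rows_rejected": load.n_rejected,
    }
    log.info("loaded %d ranked lists, %d comparison rows (%d rejected)",
             len(lists), len(comparisons), load.n_rejected)

    aad_names = set(comparisons.loc[comparisons["category"] == Category.AAD.value, "disease"])
    novelties = config.novelties or sorted({rl.novelty.value for rl in lists})

    pools = {
        name: _stage("read_gene_pool")(read_gene_pool, path, name, config.background_n)
        for name, path in config.pools.items()
    }
    annotations = (
        _stage("read_annotations")(read_hallmark_annotations, config.annotations)
        if config.annotations
        else None
    )

    for nov in novelties:
        nov_enum = Novelty(nov)
        nov_lists = [rl for rl in lists if rl.novelty is nov_enum]
        by_cat = {
            Category.AAD: [rl for rl in nov_lists if rl.disease in aad_names],
            Category.NAAD: [rl for rl in nov_lists if rl.disease not in aad_names],
        }
        tops: dict[Category, list[str]] = {}
        for cat, cat_lists in by_cat.items():
            if not cat_lists:
                raise StageError("aggregate", f"no {cat.value} lists at novelty {nov}")
            agg = _stage("aggregate")(
                combine_lists, cat_lists, rank_cap=config.rank_cap, category=cat
            )
            write_table(
                agg.frame, out_dir / f"aggregated_{cat.value}_{nov}.tsv", **meta
            )
            tops[cat] = select_top(agg, config.top_k)
            report["stages"][f"aggregate_{cat.value}_{nov}"] = {
                "n_lists": len(cat_lists),
                "n_genes": len(agg),
                "top_k": len(tops[cat]),
            }
        classification = _stage("classify")(
            classify_targets, tops[Category.AAD], tops[Category.NAAD], novelty=nov
        )
        write_table(
            classification.to_frame(), out_dir / f"classification_{nov}.tsv", **meta
        )
        report["stages"][f"classify_{nov}"] = {
            "aad_specific": len(classification.aad_specific),
            "common": len(classification.common),
            "naad_specific": len(classification.naad_specific),
        }
        log.info("novelty %s: %d AAD-specific, %d common, %d NAAD-specific",
                 nov, len(classification.aad_specific), len(classification.common),
                 len(classification.naad_specific))

        aad_top = tops[Category.AAD]
        profiles = _stage("consistency")(
            consistency_table, comparisons, aad_top, threshold=config.threshold
        )
        write_table(profiles, out_dir / f"consistency_{nov}.tsv", **meta)
        calls = _stage("dual_purpose")(
            dual_purpose_filter, profiles, min_classes=config.min_classes
        )
        write_table(dual_purpose_frame(calls), out_dir / f"dual_purpose_{nov}.tsv", **meta)
        report["stages"][f"consistency_{nov}"] = {
            "profiles": int(len(profiles)),
            "dual_purpose_calls": len(calls),
        }

        counts = (
            comparisons[comparisons["gene"].isin(aad_top)]
            .groupby(["gene", "category"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        testable = [
            g
            for g in aad_top
            if g in counts.index
            and counts.loc[g].get("AAD", 0) >= 2
            and counts.loc[g].get("NAAD", 0) >= 2
        ]
        ttests = _stage("group_comparison")(
            group_comparison_table,
            comparisons[comparisons["gene"].isin(aad_top)],
            testable,
            variant=config.test_variant,
        )
        write_table(ttests, out_dir / f"group_comparison_{nov}.tsv", **meta)
        report["stages"][f"group_comparison_{nov}"] = {"genes_tested": int(len(ttests))}

        if pools:
            rows = []
            for pname, pool in pools.items():
                res = _stage("enrichment")(overlap_and_test, aad_top, pool)
                rows.append(
                    (
                        pname,
                        res.input.N,
                        res.input.K,
                        res.input.n,
                        res.input.r,
                        res.expected,
                        res.fold,
                        res.p_value,
                        ";".join(res.overlap_genes),
                    )
                )
            enr = pd.DataFrame(
                rows,
                columns=["name", "N", "K", "n", "r", "expected", "fold", "p_value", "overlap_genes"],
            )
            write_table(enr, out_dir / f"enrichment_{nov}.tsv", **meta)
            report["stages"][f"enrichment_{nov}"] = {
                row[0]: {"r": row[4], "fold": round(row[6], 2), "p_value": row[7]}
                for row in rows
            }

        if annotations is not None:
            summary = _stage("hallmark_summary")(summarize_hallmarks, annotations, aad_top)
            write_table(summary_frame(summary), out_dir / f"hallmark_summary_{nov}.tsv", **meta)
            cands = _stage("candidates")(
                select_candidates, annotations, calls, targets=aad_top
            )
            write_table(candidates_frame(cands), out_dir / f"candidates_{nov}.tsv", **meta)
            report["stages"][f"hallmarks_{nov}"] = {
                "annotated_total": summary.annotated_total,
                "candidates": len(cands),
            }

    payload = json.dumps(report, sort_keys=True, default=str)
    report["report_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    (out_dir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=str) + "\n"
    )
    return report
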