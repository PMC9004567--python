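"""Per-class expression-consistency calls and AAD-vs-NAAD logFC comparison.

A gene is *consistently dysregulated* in a disease class when at least a
threshold fraction (default 0.60, inclusive) of its case-control comparisons
in that class share a sign of logFC.  Consistency is a sign-only statistic:
a comparison with logfc exactly 0 counts toward neither direction, and
scaling all logFC by a positive constant leaves every call unchanged.
Consistency is evaluated on age-associated-disease (AAD) comparisons only;
non-AAD records feed only the AAD-vs-NAAD group comparison.

A *dual-purpose* gene is one consistently dysregulated in the same direction
in at least ``min_classes`` (default 2) disease classes.  A gene reaching
the class quota in both directions is reported once per direction with an
``ambiguous`` flag rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Category, DiseaseClass, ValidationError

CALL_UP = "up"
CALL_DOWN = "down"
CALL_INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class ConsistencyProfile:
    """Direction consistency of one gene within one disease class."""

    gene: str
    disease_class: str
    n_comparisons: int
    frac_up: float
    frac_down: float
    call: str


@dataclass(frozen=True)
class DualPurposeCall:
    """A gene consistently dysregulated the same way in >= min_classes classes."""

    gene: str
    direction: str
    n_classes_consistent: int
    classes: frozenset[str]
    ambiguous: bool = False


def _validate_threshold(threshold: float) -> None:
    if not (0.5 < threshold <= 1.0):
        raise ValidationError(
            f"consistency threshold must be in (0.5, 1], got {threshold}"
        )


def _make_call(frac_up: float, frac_down: float, threshold: float) -> str:
    # threshold > 0.5 guarantees at most one direction can reach it
    if frac_up >= threshold:
        return CALL_UP
    if frac_down >= threshold:
        return CALL_DOWN
    return CALL_INCONSISTENT


def consistency_profile(
    records: pd.DataFrame,
    gene: str,
    disease_class: DiseaseClass | str,
    threshold: float = 0.60,
) -> ConsistencyProfile:
    """Consistency call for one (gene, disease class) over AAD comparisons."""
    _validate_threshold(threshold)
    cls = DiseaseClass(disease_class).value
    mask = (
        (records["category"] == Category.AAD.value)
        & (records["gene"] == gene)
        & (records["disease_class"] == cls)
    )
    logfc = records.loc[mask, "logfc"].to_numpy(dtype=float)
    if logfc.size == 0:
        raise ValidationError(
            f"no AAD comparison records for gene {gene!r} in class {cls!r}"
        )
    frac_up = float(np.mean(logfc > 0))
    frac_down = float(np.mean(logfc < 0))
    return ConsistencyProfile(
        gene=gene,
        disease_class=cls,
        n_comparisons=int(logfc.size),
        frac_up=frac_up,
        frac_down=frac_down,
        call=_make_call(frac_up, frac_down, threshold),
    )


def consistency_table(
    records: pd.DataFrame,
    genes: Iterable[str] | None = None,
    threshold: float = 0.60,
) -> pd.DataFrame:
    """Long-format consistency table (gene x disease class) over AAD records.

    Returns columns gene, disease_class, n_comparisons, frac_up, frac_down,
    call — one row per (gene, class) pair with at least one AAD comparison.
    """
    _validate_threshold(threshold)
    sub = records[records["category"] == Category.AAD.value]
    if genes is not None:
        genes = set(genes)
        sub = sub[sub["gene"].isin(genes)]
    if sub.empty:
        return pd.DataFrame(
            columns=["gene", "disease_class", "n_comparisons", "frac_up", "frac_down", "call"]
        )
    grouped = (
        sub.assign(up=sub["logfc"] > 0, down=sub["logfc"] < 0)
        .groupby(["gene", "disease_class"], observed=True)
        .agg(n_comparisons=("logfc", "size"), frac_up=("up", "mean"), frac_down=("down", "mean"))
        .reset_index()
    )
    grouped["call"] = np.select(
        [grouped["frac_up"] >= threshold, grouped["frac_down"] >= threshold],
        [CALL_UP, CALL_DOWN],
        default=CALL_INCONSISTENT,
    )
    return grouped.sort_values(["gene", "disease_class"]).reset_index(drop=True)


def _profiles_frame(
    profiles: pd.DataFrame | Iterable[ConsistencyProfile],
) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame(
        [
            (p.gene, p.disease_class, p.n_comparisons, p.frac_up, p.frac_down, p.call)
            for p in profiles
        ],
        columns=["gene", "disease_class", "n_comparisons", "frac_up", "frac_down", "call"],
    )


def dual_purpose_filter(
    profiles: pd.DataFrame | Iterable[ConsistencyProfile],
    min_classes: int = 2,
) -> list[DualPurposeCall]:
    """Select genes consistently dysregulated in >= ``min_classes`` classes.

    For each gene the classes called ``up`` and the classes called ``down``
    are counted separately; a direction with at least ``min_classes`` classes
    yields one call.  Genes qualifying in both directions are emitted for
    both, flagged ``ambiguous``.  Output is sorted by (gene, direction).
    """
    if min_classes < 1:
        raise ValidationError(f"min_classes must be >= 1, got {min_classes}")
    frame = _profiles_frame(profiles)
    calls: list[DualPurposeCall] = []
    for gene, grp in frame.groupby("gene", sort=True):
        up = frozenset(grp.loc[grp["call"] == CALL_UP, "disease_class"])
        down = frozenset(grp.loc[grp["call"] == CALL_DOWN, "disease_class"])
        qualifying = []
        if len(up) >= min_classes:
            qualifying.append((CALL_UP, up))
        if len(down) >= min_classes:
            qualifying.append((CALL_DOWN, down))
        ambiguous = len(qualifying) == 2
        for direction, classes in qualifying:
            calls.append(
                DualPurposeCall(
                    gene=gene,
                    direction=direction,
                    n_classes_consistent=len(classes),
                    classes=classes,
                    ambiguous=ambiguous,
                )
            )
    return calls


def dual_purpose_frame(calls: Sequence[DualPurposeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene,
                c.direction,
                c.n_classes_consistent,
                ";".join(sorted(c.classes)),
                int(c.ambiguous),
            )
            for c in calls
        ],
        columns=["gene", "direction", "n_classes_consistent", "classes", "ambiguous"],
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test of one gene's logFC between AAD and NAAD comparisons."""

    gene: str
    t_statistic: float
    p_value: float
    n_aad: int
    n_naad: int
    mean_logfc_aad: float
    mean_logfc_naad: float
    variant: str = "welch"


def compare_logfc_groups(
    records: pd.DataFrame, gene: str, variant: str = "welch"
) -> GroupComparison:
    """Two-tailed t-test of a gene's logFC values, AAD vs NAAD.

    ``variant`` selects Welch (unequal variance, default) or ``student``
    (pooled variance).  Requires at least two observations per group.
    """
    if variant not in ("welch", "student"):
        raise ValidationError(f"unknown t-test variant: {variant!r}")
    sub = records[records["gene"] == gene]
    aad = sub.loc[sub["category"] == Category.AAD.value, "logfc"].to_numpy(dtype=float)
    naad = sub.loc[sub["category"] == Category.NAAD.value, "logfc"].to_numpy(dtype=float)
    if aad.size < 2 or naad.size < 2:
        raise ValidationError(
            f"gene {gene!r}: need >= 2 logfc values per group "
            f"(got {aad.size} AAD, {naad.size} NAAD)"
        )
    t_stat, p_val = stats.ttest_ind(aad, naad, equal_var=(variant == "student"))
    return GroupComparison(
        gene=gene,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_aad=int(aad.size),
        n_naad=int(naad.size),
        mean_logfc_aad=float(aad.mean()),
        mean_logfc_naad=float(naad.mean()),
        variant=variant,
    )


def group_comparison_table(
    records: pd.DataFrame,
    genes: Iterable[str],
    variant: str = "welch",
) -> pd.DataFrame:
    """Per-gene AAD-vs-NAAD t-tests with a Benjamini-Hochberg column.

    The BH-adjusted p-value is reported for reference only; no filtering in
    this package uses it.
    """
    from statsmodels.stats.multitest import multipletests

    rows = [compare_logfc_groups(records, g, variant=variant) for g in genes]
    frame = pd.DataFrame(
        [
            (
                c.gene,
                c.t_statistic,
                c.p_value,
                c.n_aad,
                c.n_naad,
                c.mean_logfc_aad,
                c.mean_logfc_naad,
            )
            for c in rows
        ],
        columns=[
            "gene",
            "t_statistic",
            "p_value",
            "n_aad",
            "n_naad",
            "mean_logfc_aad",
            "mean_logfc_naad",
        ],
    )
    if len(frame):
        frame["p_adj_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["p_adj_bh"] = []
    return frame
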