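"""Sign-consistency calls, the dual-purpose filter, and group t-tests."""

import itertools
import random

import numpy as np
import pytest
from scipy import stats

from dualtarget import ValidationError, compare_logfc_groups, consistency_profile
from dualtarget.consistency import (
    CALL_DOWN,
    CALL_INCONSISTENT,
    CALL_UP,
    ConsistencyProfile,
    consistency_table,
    dual_purpose_filter,
    group_comparison_table,
)

from conftest import aad_records, make_records

CLASSES = ["neurological", "metabolic", "inflammatory", "fibrotic"]


def records_for(logfcs, disease_class="neurological", gene="A"):
    return make_records(aad_records(gene, logfcs, disease_class))


class TestConsistencyProfile:
    def test_all_up_is_up(self):
        p = consistency_profile(records_for([0.1, 2.0, 0.5, 1.1, 3.0]), "A", "neurological")
        assert (p.frac_up, p.call) == (1.0, CALL_UP)

    def test_sixty_percent_boundary_is_inclusive(self):
        p = consistency_profile(records_for([1, 1, 1, -1, -1]), "A", "neurological")
        assert p.frac_up == pytest.approx(0.6)
        assert p.call == CALL_UP

    def test_zero_logfc_counts_toward_neither_direction(self):
        p = consistency_profile(records_for([1, 1, -1, -1, 0]), "A", "neurological")
        assert p.frac_up == pytest.approx(0.4)
        assert p.frac_down == pytest.approx(0.4)
        assert p.call == CALL_INCONSISTENT

    def test_non_aad_records_are_ignored(self):
        rows = aad_records("A", [1.0, 1.0]) + [
            ("A", "n1", "naad_d", -5.0, "NAAD", "neurological"),
        ]
        p = consistency_profile(make_records(rows), "A", "neurological")
        assert p.n_comparisons == 2
        assert p.call == CALL_UP

    def test_missing_gene_class_is_error(self):
        with pytest.raises(ValidationError, match="B.*metabolic"):
            consistency_profile(records_for([1.0]), "B", "metabolic")

    def test_threshold_outside_half_one_rejected(self):
        for bad in (0.5, 0.3, 1.2):
            with pytest.raises(ValidationError):
                consistency_profile(records_for([1.0]), "A", "neurological", threshold=bad)

    def test_matches_sign_counting_oracle(self, rng):
        """Vectorized profiles equal naive per-row sign counting."""
        for _ in range(50):
            n = int(rng.integers(1, 15))
            logfcs = np.round(rng.normal(0, 1, n), 3)
            logfcs[rng.random(n) < 0.15] = 0.0
            cls = CLASSES[int(rng.integers(4))]
            p = consistency_profile(records_for(list(logfcs), cls), "A", cls)
            up = sum(1 for x in logfcs if x > 0)
            down = sum(1 for x in logfcs if x < 0)
            assert p.frac_up == pytest.approx(up / n)
            assert p.frac_down == pytest.approx(down / n)
            expected = (
                CALL_UP if up / n >= 0.6 else CALL_DOWN if down / n >= 0.6 else CALL_INCONSISTENT
            )
            assert p.call == expected

    def test_raising_threshold_never_creates_a_direction_call(self, rng):
        for _ in range(30):
            logfcs = list(rng.normal(0, 1, int(rng.integers(2, 12))))
            lo = consistency_profile(records_for(logfcs), "A", "neurological", threshold=0.55)
            hi = consistency_profile(records_for(logfcs), "A", "neurological", threshold=0.85)
            if lo.call == CALL_INCONSISTENT:
                assert hi.call == CALL_INCONSISTENT

    def test_invariant_to_order_and_positive_scaling(self, rng):
        logfcs = list(rng.normal(0, 1, 9))
        base = consistency_profile(records_for(logfcs), "A", "neurological")
        shuffled = consistency_profile(records_for(logfcs[::-1]), "A", "neurological")
        scaled = consistency_profile(records_for([7.3 * x for x in logfcs]), "A", "neurological")
        for other in (shuffled, scaled):
            assert (other.frac_up, other.frac_down, other.call) == (
                base.frac_up,
                base.frac_down,
                base.call,
            )

    def test_table_agrees_with_single_profiles(self, rng):
        rows = []
        for g in ["A", "B", "C"]:
            for cls in CLASSES[:3]:
                rows += aad_records(g, list(rng.normal(0, 1, 5)), cls)
        frame = make_records(rows)
        table = consistency_table(frame)
        for row in table.itertuples():
            single = consistency_profile(frame, row.gene, row.disease_class)
            assert row.frac_up == pytest.approx(single.frac_up)
            assert row.call == single.call


def profile(gene, cls, call):
    return ConsistencyProfile(gene, cls, 5, 1.0 if call == CALL_UP else 0.0,
                              1.0 if call == CALL_DOWN else 0.0, call)


class TestDualPurposeFilter:
    def test_four_class_upregulation(self):
        profiles = [profile("CX", c, CALL_UP) for c in CLASSES]
        calls = dual_purpose_filter(profiles)
        assert len(calls) == 1
        assert calls[0].direction == CALL_UP
        assert calls[0].n_classes_consistent == 4
        assert not calls[0].ambiguous

    def test_single_class_excluded(self):
        profiles = [profile("A", "neurological", CALL_UP)] + [
            profile("A", c, CALL_INCONSISTENT) for c in CLASSES[1:]
        ]
        assert dual_purpose_filter(profiles) == []

    def test_both_directions_emitted_as_ambiguous(self):
        profiles = [
            profile("A", "neurological", CALL_UP),
            profile("A", "metabolic", CALL_UP),
            profile("A", "inflammatory", CALL_DOWN),
            profile("A", "fibrotic", CALL_DOWN),
        ]
        calls = dual_purpose_filter(profiles)
        assert [c.direction for c in calls] == [CALL_UP, CALL_DOWN]
        assert all(c.ambiguous for c in calls)

    def test_min_classes_validation(self):
        with pytest.raises(ValidationError):
            dual_purpose_filter([], min_classes=0)

    def test_matches_exhaustive_enumeration(self):
        """Filter output equals enumeration over all (gene, direction,
        class-subset) triples on random small instances."""
        rng = random.Random(99)
        for _ in range(100):
            n_genes = rng.randint(1, 6)
            min_classes = rng.randint(1, 4)
            profiles = [
                profile(f"g{i}", c, rng.choice([CALL_UP, CALL_DOWN, CALL_INCONSISTENT]))
                for i in range(n_genes)
                for c in CLASSES
            ]
            expected = set()
            for gene in {p.gene for p in profiles}:
                for direction in (CALL_UP, CALL_DOWN):
                    best = set()
                    for k in range(1, 5):
                        for subset in itertools.combinations(CLASSES, k):
                            if all(
                                any(p.gene == gene and p.disease_class == c and p.call == direction
                                    for p in profiles)
                                for c in subset
                            ) and len(subset) > len(best):
                                best = set(subset)
                    if len(best) >= min_classes:
                        expected.add((gene, direction, frozenset(best)))
            got = {
                (c.gene, c.direction, c.classes)
                for c in dual_purpose_filter(profiles, min_classes=min_classes)
            }
            assert got == expected


class TestGroupComparison:
    def base_records(self, aad, naad, gene="A"):
        rows = aad_records(gene, aad)
        rows += [
            (gene, f"n{i}", "naad_d", x, "NAAD", "inflammatory")
            for i, x in enumerate(naad)
        ]
        return make_records(rows)

    def test_identical_groups_give_t0_p1(self):
        vec = [0.3, -0.5, 1.2]
        c = compare_logfc_groups(self.base_records(vec, vec), "A")
        assert c.t_statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self, rng):
        aad = list(1 + 0.01 * rng.normal(size=6))
        naad = list(-1 + 0.01 * rng.normal(size=6))
        c = compare_logfc_groups(self.base_records(aad, naad), "A")
        assert c.p_value < 1e-10
        assert c.t_statistic > 0

    def test_welch_matches_closed_form_t_cdf(self):
        """p equals a by-hand Welch statistic pushed through the t CDF."""
        aad = np.array([0.8, 1.4, 0.2, 1.9, 0.6])
        naad = np.array([-0.1, 0.5, 0.3, -0.7])
        va, vn = aad.var(ddof=1) / len(aad), naad.var(ddof=1) / len(naad)
        t_hand = (aad.mean() - naad.mean()) / np.sqrt(va + vn)
        df = (va + vn) ** 2 / (va**2 / (len(aad) - 1) + vn**2 / (len(naad) - 1))
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        c = compare_logfc_groups(self.base_records(list(aad), list(naad)), "A")
        assert c.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert c.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_student_variant_matches_pooled_test(self):
        aad, naad = [0.8, 1.4, 0.2], [-0.1, 0.5, 0.3, -0.7]
        c = compare_logfc_groups(self.base_records(aad, naad), "A", variant="student")
        t_ref, p_ref = stats.ttest_ind(aad, naad, equal_var=True)
        assert c.t_statistic == pytest.approx(float(t_ref))
        assert c.p_value == pytest.approx(float(p_ref))

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            compare_logfc_groups(self.base_records([1.0], [0.1, 0.2]), "A")

    def test_table_carries_bh_column_without_filtering(self, rng):
        rows = []
        for g in ["A", "B", "C"]:
            rows.extend(self.base_records(
                list(rng.normal(size=4)), list(rng.normal(size=4)), gene=g
            ).itertuples(index=False))
        frame = make_records([tuple(r) for r in rows])
        table = group_comparison_table(frame, ["A", "B", "C"])
        assert "p_adj_bh" in table.columns
        assert (table["p_adj_bh"] >= table["p_value"] - 1e-12).all()
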