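"""Synthetic generator: determinism, planted structure, distributional nulls."""

import numpy as np
import pytest

from dualtarget import Category, SimConfig, ValidationError
from dualtarget.consistency import consistency_table
from dualtarget.io import read_comparisons, read_ranked_lists, write_comparisons, write_ranked_lists
from dualtarget.simulate import (
    STUDY_DISEASES,
    gen_comparisons,
    gen_ranked_lists,
    make_truth,
    study_registry,
)

from dataclasses import replace


class TestConfig:
    def test_study_layout_totals(self):
        aad = [d for d in STUDY_DISEASES if d.category is Category.AAD]
        naad = [d for d in STUDY_DISEASES if d.category is Category.NAAD]
        assert (len(aad), sum(d.n_comparisons for d in aad)) == (14, 87)
        assert (len(naad), sum(d.n_comparisons for d in naad)) == (19, 126)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(planted_sign_prob=0.4)
        with pytest.raises(ValidationError):
            SimConfig(n_genes=10, n_planted_aad=8, n_planted_common=8)
        with pytest.raises(ValidationError):
            SimConfig(noise_logfc_sd=0.0)


class TestRankedListGeneration:
    def test_identical_seed_gives_byte_identical_files(self, small_config, tmp_path):
        for run in ("a", "b"):
            lists, truth = gen_ranked_lists(small_config)
            comps = gen_comparisons(small_config, truth)
            write_ranked_lists(lists, tmp_path / f"lists_{run}.tsv")
            write_comparisons(comps, tmp_path / f"comps_{run}.tsv")
        assert (tmp_path / "lists_a.tsv").read_bytes() == (tmp_path / "lists_b.tsv").read_bytes()
        assert (tmp_path / "comps_a.tsv").read_bytes() == (tmp_path / "comps_b.tsv").read_bytes()

    def test_different_seed_changes_output(self, small_config):
        lists1, _ = gen_ranked_lists(small_config)
        lists2, _ = gen_ranked_lists(replace(small_config, seed=small_config.seed + 1))
        assert any(a.entries != b.entries for a, b in zip(lists1, lists2))

    def test_geometric_limit_puts_planted_on_top(self, small_config):
        config = replace(small_config, planted_rank_geometric_p=1.0)
        lists, truth = gen_ranked_lists(config)
        for rl in lists:
            meta = {d.name: d for d in config.diseases}[rl.disease]
            relevant = set(truth.planted) if meta.category is Category.AAD else set(
                truth.planted_common
            )
            top = [g for g, r in sorted(rl.entries.items(), key=lambda kv: kv[1])]
            assert set(top[: len(relevant)]) == relevant

    def test_planted_exceeding_list_capacity_rejected(self, small_config):
        config = replace(small_config, list_length=5)
        with pytest.raises(ValidationError, match="exceed"):
            gen_ranked_lists(config)

    def test_planted_aad_boosted_only_in_aad_diseases(self, small_config):
        """Across seeds, planted AAD genes occur far more often in AAD lists
        than null genes do, and show no advantage in NAAD lists."""
        occ_planted, occ_null, naad_occ_planted = [], [], []
        for seed in range(50):
            config = replace(small_config, seed=seed)
            lists, truth = gen_ranked_lists(config)
            aad_names = {d.name for d in config.diseases if d.category is Category.AAD}
            planted = set(truth.planted_aad)
            nulls = truth.null_genes
            for rl in lists:
                members = set(rl.entries)
                if rl.disease in aad_names:
                    occ_planted.append(len(members & planted) / len(planted))
                    occ_null.append(len(members & nulls) / len(nulls))
                else:
                    naad_occ_planted.append(len(members & planted) / len(planted))
        assert np.mean(occ_planted) > np.mean(occ_null)
        assert np.mean(occ_planted) > 0.5
        assert np.mean(naad_occ_planted) == pytest.approx(np.mean(occ_null), abs=0.05)


class TestComparisonGeneration:
    def test_study_layout_comparison_counts(self):
        config = SimConfig(seed=0, n_genes=50, n_planted_aad=3, n_planted_common=2)
        truth = make_truth(config)
        comps = gen_comparisons(config, truth)
        per_cat = comps.groupby("category")["comparison_id"].nunique()
        assert per_cat["AAD"] == 87
        assert per_cat["NAAD"] == 126
        assert len(comps) == 50 * 213

    def test_pure_sign_prob_gives_full_consistency(self, small_config):
        config = replace(small_config, planted_sign_prob=1.0)
        lists, truth = gen_ranked_lists(config)
        comps = gen_comparisons(config, truth)
        table = consistency_table(comps, genes=set(truth.planted))
        up_genes = {g for g, d in truth.planted.items() if d > 0}
        for row in table.itertuples():
            expected = 1.0 if row.gene in up_genes else 0.0
            assert row.frac_up == pytest.approx(expected)

    def test_null_sign_fractions_follow_binomial(self, small_config):
        """Empirical distribution of null genes' up-counts in one class
        matches Binomial(n_comparisons, 1/2)."""
        from scipy.stats import binom

        config = replace(small_config, n_genes=2000, seed=5)
        truth = make_truth(config)
        comps = gen_comparisons(config, truth)
        cls = comps[
            (comps["disease_class"] == "neurological")
            & (comps["category"] == "AAD")
            & comps["gene"].isin(truth.null_genes)
        ]
        counts = cls.groupby("gene")["logfc"].apply(lambda x: (x > 0).sum())
        n = cls.groupby("gene")["logfc"].size().iloc[0]
        grid = np.arange(n + 1)
        ecdf = np.searchsorted(np.sort(counts.to_numpy()), grid, side="right") / len(counts)
        ks = np.max(np.abs(ecdf - binom.cdf(grid, n, 0.5)))
        assert ks < 0.05

    def test_generator_output_round_trips_with_zero_rejections(
        self, small_config, tmp_path
    ):
        lists, truth = gen_ranked_lists(small_config)
        comps = gen_comparisons(small_config, truth)
        write_ranked_lists(lists, tmp_path / "lists.tsv")
        write_comparisons(comps, tmp_path / "comps.tsv")
        back = read_ranked_lists(tmp_path / "lists.tsv")
        assert [(l.disease, l.entries) for l in back] == [
            (l.disease, l.entries) for l in lists
        ]
        load = read_comparisons(tmp_path / "comps.tsv")
        assert load.n_rejected == 0
        assert len(load.frame) == len(comps)

    def test_registry_matches_study_diseases(self):
        registry = study_registry()
        assert len(registry) == 33
        assert registry["Obesity"].disease_class.value == "metabolic"
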