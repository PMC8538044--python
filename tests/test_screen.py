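"""Count normalization, binning, Z-scoring, selection, gene assignment,
and the overlap/quartile/GO statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dictytox import screen, synthetic
from tests.conftest import make_screen_matrix


def _long(rows):
    return pd.DataFrame(
        rows, columns=["insertion_id", "screen", "replicate", "round", "count"]
    )


class TestNormalizeCounts:
    def test_proportional_scaling_to_rpm(self):
        raw = _long([("i1", "drug", 1, 2, 75), ("i2", "drug", 1, 2, 25)])
        out = screen.normalize_counts(raw)
        assert out.loc["i1", ("drug", 1, 2)] == pytest.approx(750_000)
        assert out.loc["i2", ("drug", 1, 2)] == pytest.approx(250_000)

    def test_tags_of_one_insertion_summed(self):
        raw = _long(
            [("i1", "drug", 1, 2, 40), ("i1", "drug", 1, 2, 60), ("i2", "drug", 1, 2, 100)]
        )
        raw["tag"] = ["t1", "t2", "t3"]
        out = screen.normalize_counts(raw)
        assert out.loc["i1", ("drug", 1, 2)] == pytest.approx(500_000)

    def test_depth_invariance(self):
        raw = _long([("i1", "drug", 1, 2, 30), ("i2", "drug", 1, 2, 70)])
        deeper = raw.assign(count=raw["count"] * 10)
        pd.testing.assert_frame_equal(
            screen.normalize_counts(raw), screen.normalize_counts(deeper)
        )

    def test_duplicate_sample_rows_without_tags_rejected(self):
        raw = _long([("i1", "drug", 1, 2, 40), ("i1", "drug", 1, 2, 60)])
        with pytest.raises(ValueError, match="duplicate"):
            screen.normalize_counts(raw)

    def test_nonunique_insertions_dropped_before_scaling(self):
        raw = _long([("i1", "drug", 1, 2, 50), ("i2", "drug", 1, 2, 50)])
        raw["unique"] = [True, False]
        out = screen.normalize_counts(raw)
        assert list(out.index) == ["i1"]
        assert out.loc["i1", ("drug", 1, 2)] == pytest.approx(1e6)


class TestBinning:
    def test_boundaries(self):
        matrix = make_screen_matrix(
            {
                ("DMSO", 1, 2): {"a": 99.9, "b": 100.0, "c": 1000.0, "d": 1000.1},
                ("DMSO", 2, 2): {"a": 99.9, "b": 100.0, "c": 1000.0, "d": 1000.1},
            }
        )
        bins = screen.bin_mutants(matrix, 2)
        assert bins["a"] == "bin100"
        assert bins["b"] == "bin1000"
        assert bins["c"] == "bin1000"
        assert bins["d"] == "bin10000"

    def test_bin_uses_replicate_mean(self):
        matrix = make_screen_matrix(
            {("DMSO", 1, 2): {"a": 50.0}, ("DMSO", 2, 2): {"a": 250.0}}
        )
        assert screen.bin_mutants(matrix, 2)["a"] == "bin1000"  # mean 150


class TestLfcZ:
    def _matrix(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        dmso = rng.uniform(120, 900, n)
        drug = dmso * rng.lognormal(0, 0.4, n)
        ids = [f"m{i:03d}" for i in range(n)]
        return make_screen_matrix(
            {
                ("DMSO", 1, 2): dict(zip(ids, dmso)),
                ("DMSO", 2, 2): dict(zip(ids, dmso * rng.lognormal(0, 0.05, n))),
                ("drug", 1, 2): dict(zip(ids, drug)),
                ("drug", 2, 2): dict(zip(ids, drug * rng.lognormal(0, 0.05, n))),
            }
        )

    def test_count_equal_to_dmso_mean_gives_zero_lfc(self):
        matrix = make_screen_matrix(
            {
                ("DMSO", 1, 2): {"a": 400.0, "b": 150.0, "c": 600.0},
                ("DMSO", 2, 2): {"a": 400.0, "b": 150.0, "c": 600.0},
                ("drug", 1, 2): {"a": 400.0, "b": 300.0, "c": 900.0},
                ("drug", 2, 2): {"a": 400.0, "b": 300.0, "c": 900.0},
            }
        )
        calls = screen.compute_lfc_z(matrix, "drug", 2)
        assert calls.loc["a", "lfc_1"] == pytest.approx(0.0)

    def test_z_standardization_identity_per_bin_and_replicate(self):
        calls = screen.compute_lfc_z(self._matrix(), "drug", 2)
        for rep in (1, 2):
            grouped = calls.groupby("bin")[f"z_{rep}"]
            for _, z in grouped:
                if len(z) >= 3:
                    assert abs(z.mean()) < 1e-9
                    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_planted_eightfold_enrichment_lfc_near_three(self):
        matrix = make_screen_matrix(
            {
                ("DMSO", 1, 2): {"a": 500.0, "b": 500.0, "c": 500.0},
                ("DMSO", 2, 2): {"a": 500.0, "b": 500.0, "c": 500.0},
                ("drug", 1, 2): {"a": 4000.0, "b": 500.0, "c": 500.0},
                ("drug", 2, 2): {"a": 4000.0, "b": 500.0, "c": 500.0},
            }
        )
        calls = screen.compute_lfc_z(matrix, "drug", 2)
        assert calls.loc["a", "lfc_1"] == pytest.approx(3.0, abs=0.01)

    def test_small_bin_gets_nan_z_with_warning(self):
        matrix = make_screen_matrix(
            {
                ("DMSO", 1, 2): {"a": 50.0, "b": 500.0, "c": 500.0, "d": 500.0},
                ("DMSO", 2, 2): {"a": 50.0, "b": 500.0, "c": 500.0, "d": 500.0},
                ("drug", 1, 2): {"a": 50.0, "b": 400.0, "c": 600.0, "d": 500.0},
                ("drug", 2, 2): {"a": 50.0, "b": 400.0, "c": 600.0, "d": 500.0},
            }
        )
        with pytest.warns(UserWarning, match="bin100"):
            calls = screen.compute_lfc_z(matrix, "drug", 2)
        assert np.isnan(calls.loc["a", "z_1"])


class TestSelectMutants:
    def _calls(self, rows, rnd):
        df = pd.DataFrame(rows).set_index("mutant")
        df.index.name = None
        return df

    def test_both_replicates_required_for_advantage(self):
        r5 = pd.DataFrame(
            {"bin": ["bin1000"] * 2, "z_1": [1.6, 2.0], "z_2": [1.4, 1.8]},
            index=["m1", "m2"],
        )
        r2 = pd.DataFrame(
            {"bin": ["bin1000"] * 2, "z_1": [0.0, 0.0], "z_2": [0.0, 0.0]},
            index=["m1", "m2"],
        )
        adv, dis = screen.select_mutants(r2, r5)
        assert adv == {"m2"}

    def test_disadvantage_excludes_low_count_bin(self):
        r2 = pd.DataFrame(
            {
                "bin": ["bin1000", "bin100"],
                "z_1": [-1.2, -2.0],
                "z_2": [-1.5, -2.5],
            },
            index=["m1", "m2"],
        )
        r5 = pd.DataFrame(
            {"bin": ["bin1000", "bin100"], "z_1": [0.0, 0.0], "z_2": [0.0, 0.0]},
            index=["m1", "m2"],
        )
        adv, dis = screen.select_mutants(r2, r5)
        assert dis == {"m1"}
        assert not adv

    def test_nan_z_treated_neutral(self):
        r2 = pd.DataFrame(
            {"bin": ["bin1000"], "z_1": [np.nan], "z_2": [-3.0]}, index=["m1"]
        )
        r5 = pd.DataFrame(
            {"bin": ["bin1000"], "z_1": [np.nan], "z_2": [3.0]}, index=["m1"]
        )
        adv, dis = screen.select_mutants(r2, r5)
        assert not adv and not dis

    def test_planted_selection_recovered_small_screen(self):
        for seed in range(3):
            s = np.zeros(300)
            s[:10] = 0.5
            s[10:20] = -0.5
            cfg = synthetic.ScreenSimConfig(
                seed=seed, n_mutants=300, read_depth=300_000, selection_coefficients=s
            )
            matrix = screen.normalize_counts(synthetic.gen_screen_counts(cfg))
            c2 = screen.compute_lfc_z(matrix, "drug", 2)
            c5 = screen.compute_lfc_z(matrix, "drug", 5)
            adv, dis = screen.select_mutants(c2, c5)
            planted_adv = {f"M{i:05d}" for i in range(10)}
            planted_dis = {f"M{i:05d}" for i in range(10, 20)}
            neutral = {f"M{i:05d}" for i in range(20, 300)}
            assert len(adv & planted_adv) >= 8
            assert len(dis & planted_dis) >= 6
            assert len((adv | dis) & neutral) <= 0.05 * len(neutral)


class TestGeneAssignment:
    @pytest.fixture
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC", "gPseudo"],
                "chromosome": ["1", "1", "1", "2"],
                "start": [1000, 5000, 6300, 100],
                "end": [2000, 6000, 7000, 400],
                "strand": ["+", "-", "+", "+"],
                "gene_type": ["gene", "gene", "gene", "pseudogene"],
            }
        )

    def _annotate(self, genes, positions):
        ins = pd.DataFrame(
            {
                "insertion_id": [f"i{k}" for k in range(len(positions))],
                "chromosome": [c for c, _ in positions],
                "position": [p for _, p in positions],
            }
        )
        return screen.annotate_insertions(ins, genes)

    def test_intragenic_assignment(self, genes):
        ann = self._annotate(genes, [("1", 1500)])
        assert ann.loc["i0", "category"] == "intragenic"
        assert ann.loc["i0", "assigned_gene"] == "gA"

    def test_upstream_300bp_promoter_assignment(self, genes):
        ann = self._annotate(genes, [("1", 700)])  # 300 bp upstream of gA (+)
        assert ann.loc["i0", "category"] == "promoter_within_500bp"
        assert ann.loc["i0", "assigned_gene"] == "gA"

    def test_upstream_600bp_not_assigned(self, genes):
        ann = self._annotate(genes, [("1", 400)])
        assert ann.loc["i0", "category"] == "intergenic"
        assert pd.isna(ann.loc["i0", "assigned_gene"])

    def test_minus_strand_upstream_is_rightward(self, genes):
        # gB is on -, so its upstream window is (6000, 6500]; but gC starts
        # at 6300, so 6100 is upstream of gB only
        ann = self._annotate(genes, [("1", 6100)])
        assert ann.loc["i0", "assigned_gene"] == "gB"

    def test_divergent_promoters_take_nearer_start(self, genes):
        # 6250 is 250 bp upstream of gB(-, TSS 6000) and 50 bp upstream of gC(+, TSS 6300)
        ann = self._annotate(genes, [("1", 6250)])
        assert ann.loc["i0", "assigned_gene"] == "gC"

    def test_pseudogene_insertion_excluded_from_gene_lists(self, genes):
        ann = self._annotate(genes, [("2", 200), ("1", 1500)])
        assert ann.loc["i0", "excluded_class"] == "pseudogene"
        assert screen.assign_genes(["i0", "i1"], ann) == ["gA"]

    def test_blacklist_and_intergenic_removed(self, genes):
        ann = self._annotate(genes, [("1", 1500), ("1", 5500), ("1", 3000)])
        out = screen.assign_genes(["i0", "i1", "i2"], ann, blacklist=["gA"])
        assert out == ["gB"]

    def test_unknown_mutant_rejected(self, genes):
        ann = self._annotate(genes, [("1", 1500)])
        with pytest.raises(KeyError):
            screen.assign_genes(["nope"], ann)


def _brute_force_overlap_p(n_universe, size_a, size_b, k_obs):
    """P(|A ∩ B| >= k) by enumeration over all draws of A, B fixed."""
    universe = list(range(n_universe))
    b = set(universe[:size_b])
    total = 0
    hits = 0
    for a in itertools.combinations(universe, size_a):
        total += 1
        hits += len(b & set(a)) >= k_obs
    return hits / total


class TestOverlapTest:
    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            size_a = int(rng.integers(1, n + 1))
            size_b = int(rng.integers(1, n + 1))
            universe = [f"g{i}" for i in range(n)]
            a = list(rng.choice(universe, size_a, replace=False))
            b = universe[:size_b]
            res = screen.overlap_test(a, b, universe)
            expected = _brute_force_overlap_p(n, size_a, size_b, res.k)
            assert res.p == pytest.approx(expected, rel=1e-9)

    def test_full_overlap_of_everything_certain(self):
        u = ["a", "b", "c"]
        assert screen.overlap_test(u, u, u).p == pytest.approx(1.0)

    def test_five_of_five_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        a = universe[:5]
        res = screen.overlap_test(a, a, universe)
        assert res.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            screen.overlap_test(["x"], ["a"], ["a", "b"])


class TestRankQuartile:
    def test_uniform_spread_not_significant(self):
        scores = pd.Series(np.arange(100.0), index=[f"m{i:03d}" for i in range(100)])
        listed = [f"m{i:03d}" for i in (5, 30, 55, 80)]
        counts, chi2, p = screen.rank_quartile_test(scores, listed)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_forty_listed_all_in_top_quartile(self):
        scores = pd.Series(np.arange(400.0), index=[f"m{i:03d}" for i in range(400)])
        listed = [f"m{i:03d}" for i in range(360, 400)]
        counts, chi2, p = screen.rank_quartile_test(scores, listed)
        assert counts == {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 40}
        assert chi2 == pytest.approx(120.0)
        assert p < 1e-20

    def test_chi_squared_matches_hand_formula(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=41), index=[f"m{i:02d}" for i in range(41)])
        listed = list(scores.index[:8])
        counts, chi2, _ = screen.rank_quartile_test(scores, listed)
        expected = len(listed) / 4
        hand = sum((counts[q] - expected) ** 2 / expected for q in counts)
        assert chi2 == pytest.approx(hand, rel=1e-12)

    @pytest.mark.parametrize("n", [7, 40, 41, 42, 43, 100])
    def test_quartile_sizes_differ_by_at_most_one(self, n):
        scores = pd.Series(np.arange(float(n)), index=[f"m{i:03d}" for i in range(n)])
        counts, _, _ = screen.rank_quartile_test(scores, list(scores.index))
        sizes = sorted(counts.values())
        assert sizes[-1] - sizes[0] <= 1
        assert sum(sizes) == n

    def test_unscored_listed_mutant_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            screen.rank_quartile_test(scores, ["c"])


class TestGoEnrichment:
    def test_term_identical_to_list_is_most_enriched(self):
        universe = [f"g{i}" for i in range(30)]
        genes = universe[:5]
        terms = {
            "match": set(genes),
            "same_size_other": set(universe[10:15]),
            "half": set(universe[:2]) | set(universe[20:23]),
        }
        out = screen.go_enrichment(genes, universe, terms, alpha=1.0)
        assert out[0].label == "match"
        assert out[0].k == 5

    def test_matches_enumeration_on_ten_gene_universe(self):
        universe = [f"g{i}" for i in range(10)]
        genes = universe[:4]
        term_genes = universe[2:7]
        out = screen.go_enrichment(genes, universe, {"t": term_genes}, alpha=1.0)
        res = out[0]
        expected = _brute_force_overlap_p(10, 4, 5, res.k)
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_null_calibration_about_five_percent(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        n_sig = n_terms = 0
        for _ in range(40):
            genes = list(rng.choice(universe, 20, replace=False))
            terms = {
                f"t{j}": set(rng.choice(universe, 15, replace=False))
                for j in range(25)
            }
            sig = screen.go_enrichment(genes, universe, terms, alpha=0.05)
            n_sig += len(sig)
            n_terms += len(terms)
        # hypergeometric p-values are discrete and conservative, so the
        # realized rate sits at or below the nominal 5%
        assert 0.005 <= n_sig / n_terms <= 0.08

    def test_term_without_universe_genes_skipped(self):
        universe = ["a", "b"]
        out = screen.go_enrichment(["a"], universe, {"t": {"zzz"}}, alpha=1.0)
        assert out == []

    def test_bh_flag_filters_on_adjusted_p(self):
        universe = [f"g{i}" for i in range(50)]
        genes = universe[:5]
        terms = {"hit": set(genes)}
        terms.update(
            {f"noise{j}": {universe[10 + j]} for j in range(20)}
        )
        out = screen.go_enrichment(genes, universe, terms, alpha=0.05, bh_correct=True)
        assert [r.label for r in out] == ["hit"]
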