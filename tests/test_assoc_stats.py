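"""Fisher/BH/Z statistics, TE association, windows, PAV and population bins."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from methyldup import assoc_stats as ast
from methyldup.core_io import GeneModel, TEFeature


# --- independent oracles ----------------------------------------------------


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, n = a + b, a + b + c + d
    c1 = a + c

    def prob(x):
        return (
            math.comb(c1, x)
            * math.comb(n - c1, r1 - x)
            / math.comb(n, r1)
        )

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def bh_oracle(p):
    """Textbook step-up: q_(i) = min_{k >= i} p_(k) * m / k, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        q[order[i]] = min(running, 1.0)
    return q


class TestFisher:
    def test_balanced_table(self):
        r = ast.fisher_exact(10, 10, 10, 10)
        assert r.odds_ratio == 1.0
        assert r.p == pytest.approx(1.0)
        assert r.direction == "none"

    def test_perfect_association(self):
        r = ast.fisher_exact(5, 0, 0, 5)
        assert math.isinf(r.odds_ratio)
        assert r.p == pytest.approx(2 / 252)
        assert r.direction == "enriched"

    def test_depletion_direction(self):
        r = ast.fisher_exact(1, 10, 10, 1)
        assert r.odds_ratio < 1
        assert r.direction == "depleted"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ast.fisher_exact(0, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            r = ast.fisher_exact(a, b, c, d)
            assert r.p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12)

    def test_haldane_odds_ratio_finite(self):
        r = ast.fisher_exact(5, 0, 0, 5)
        assert r.odds_ratio_haldane == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))


class TestBH:
    def test_step_up_hand_example(self):
        q = ast.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert ast.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_nan_excluded_from_family(self):
        q = ast.bh_adjust([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # family size 2, rank 1

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_textbook_step_up_and_dominates_p(self, p):
        q = ast.bh_adjust(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()


class TestEnrichmentScan:
    def test_counts_arithmetic(self):
        labels = pd.Series(
            ["L"] * 40 + ["other"] * 60, index=[f"g{i}" for i in range(100)]
        )
        cat = pd.Series(
            ["C" if (i < 20 or 40 <= i < 60) else "rest" for i in range(100)],
            index=[f"g{i}" for i in range(100)],
        )
        out = ast.enrichment_scan(labels, cat, exclude_labels=())
        row = out.set_index(["label", "category"]).loc[("L", "C")]
        assert (row["a"], row["b"], row["c"], row["d"]) == (20, 20, 20, 40)
        assert row["odds_ratio"] == pytest.approx(2.0)

    def test_missing_and_unclassified_excluded_by_default(self):
        labels = pd.Series({"g1": "gbM", "g2": "missing", "g3": "unclassified", "g4": "teM"})
        cat = pd.Series({"g1": "A", "g2": "A", "g3": "A", "g4": "B"})
        out = ast.enrichment_scan(labels, cat)
        assert set(out["label"]) == {"gbM", "teM"}
        assert out[["a", "b", "c", "d"]].to_numpy().sum(axis=1).max() == 2

    def test_perfect_enrichment(self):
        labels = pd.Series({f"g{i}": ("L" if i < 10 else "M") for i in range(30)})
        cat = pd.Series({f"g{i}": ("C" if i < 10 else "D") for i in range(30)})
        out = ast.enrichment_scan(labels, cat, exclude_labels=())
        row = out.set_index(["label", "category"]).loc[("L", "C")]
        assert math.isinf(row["odds_ratio"])
        assert row["direction"] == "enriched"


class TestTwoProportionZ:
    def test_equal_proportions(self):
        assert ast.two_proportion_z(5, 10, 5, 10) == (0.0, 1.0)

    def test_strong_difference_and_chi2_equivalence(self):
        z, p = ast.two_proportion_z(9, 10, 1, 10)
        assert p < 0.01
        chi2 = sps.chi2.sf(z**2, df=1)
        assert p == pytest.approx(chi2, rel=1e-9)

    def test_antisymmetric_under_group_swap(self):
        z1, p1 = ast.two_proportion_z(7, 10, 2, 12)
        z2, p2 = ast.two_proportion_z(2, 12, 7, 10)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion(self):
        assert ast.two_proportion_z(0, 10, 0, 10) == (0.0, 1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ast.two_proportion_z(11, 10, 0, 10)


class TestTEAssociation:
    GENE = GeneModel("g", "chr1", 10_000, 12_000)

    def _flag(self, te):
        return ast.te_association([self.GENE], [te])["g"]

    def test_te_999_bp_upstream_is_associated(self):
        assert self._flag(TEFeature("chr1", 8_500, 10_000 - 999))

    def test_te_1001_bp_downstream_is_not(self):
        assert not self._flag(TEFeature("chr1", 12_000 + 1_001, 14_000))

    def test_te_inside_gene_body_is_associated(self):
        assert self._flag(TEFeature("chr1", 10_500, 10_600))

    def test_other_chromosome_ignored(self):
        assert not self._flag(TEFeature("chr2", 10_500, 10_600))


class TestSlidingWindows:
    def _run(self, genes, tes, lengths, **kw):
        labels = {g.gene_id: "gbM" for g in genes}
        return ast.sliding_windows(genes, labels, tes, lengths, **kw)

    def test_250kb_chromosome_tiles_five_windows(self):
        prof, _ = self._run([], [], {"chr1": 250_000})
        coords = list(zip(prof["start"], prof["end"]))
        assert coords == [
            (0, 100_000),
            (50_000, 150_000),
            (100_000, 200_000),
            (150_000, 250_000),
            (200_000, 250_000),
        ]

    def test_gene_midpoint_counted_in_two_overlapping_windows(self):
        g = GeneModel("g", "chr1", 74_000, 76_000)  # midpoint 75 kb
        prof, _ = self._run([g], [], {"chr1": 250_000})
        counted = prof.loc[prof["n_genes"] > 0, ["start", "end"]]
        assert counted.values.tolist() == [[0, 100_000], [50_000, 150_000]]

    def test_short_chromosome_single_window(self):
        prof, _ = self._run([], [], {"chr1": 30_000})
        assert len(prof) == 1
        assert (prof.loc[0, "start"], prof.loc[0, "end"]) == (0, 30_000)

    def test_even_windows_partition_genes(self):
        rng = np.random.default_rng(0)
        genes = [
            GeneModel(f"g{i}", "chr1", int(s), int(s) + 500)
            for i, s in enumerate(rng.integers(0, 990_000, size=200))
        ]
        prof, _ = self._run(genes, [], {"chr1": 1_000_000})
        even = prof.iloc[::2]
        assert even["n_genes"].sum() == 200

    def test_te_bp_is_clipped_overlap(self):
        te = TEFeature("chr1", 90_000, 110_000)
        prof, _ = self._run([], [te], {"chr1": 250_000})
        assert prof.loc[0, "te_bp"] == 10_000  # window [0, 100k)
        assert prof.loc[1, "te_bp"] == 20_000  # window [50k, 150k) contains all


class TestPAV:
    def test_low_coverage_in_one_accession(self):
        cov = pd.DataFrame([[1.0, 0.1, 0.9]], index=["g"])
        assert list(ast.call_pav(cov)) == ["g"]

    def test_all_covered_not_pav(self):
        cov = pd.DataFrame([[0.5, 0.8, 0.2]], index=["g"])
        assert list(ast.call_pav(cov)) == []  # 0.2 boundary is strict

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            ast.call_pav(pd.DataFrame([[-0.1]], index=["g"]))


class TestPopulationFrequency:
    def test_bin_boundaries(self):
        assert ast.bin_frequency(0.0) == "0%"
        assert ast.bin_frequency(0.249) == "<25%"
        assert ast.bin_frequency(0.25) == "25-50%"
        assert ast.bin_frequency(0.50) == "50-75%"
        assert ast.bin_frequency(0.75) == ">75%"
        assert ast.bin_frequency(1.0) == ">75%"

    def test_232_of_928_lands_in_25_to_50(self):
        labels = ["teM"] * 232 + ["unM"] * 696
        m = pd.DataFrame([labels], index=["g"])
        out = ast.population_frequency(m)
        assert out.loc["g", "freq_teM"] == pytest.approx(0.25)
        assert out.loc["g", "bin_teM"] == "25-50%"

    def test_frequencies_sum_to_one_over_informative(self):
        m = pd.DataFrame(
            [["gbM", "teM", "missing", "unM", "gbM"]], index=["g"]
        )
        out = ast.population_frequency(m)
        total = sum(out.loc["g", f"freq_{c}"] for c in ("gbM", "teM", "unM", "unclassified"))
        assert total == pytest.approx(1.0)
        assert out.loc["g", "n_accessions_with_data"] == 4

    def test_all_missing_gene_excluded(self):
        m = pd.DataFrame([["missing", "missing"]], index=["g"])
        assert ast.population_frequency(m).empty


class TestSummarizeByGroup:
    def test_median_and_ranking(self):
        vals = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        groups = pd.Series(["lo"] * 3 + ["hi"] * 3)
        out = ast.summarize_by_group(vals, groups)
        assert out.loc[0, "group"] == "lo"
        assert out.loc[0, "median"] == 2.0
        assert out.loc[1, "median"] == 20.0

    def test_undefined_values_counted(self):
        vals = pd.Series([1.0, np.nan, 3.0])
        out = ast.summarize_by_group(vals, pd.Series(["a", "a", "a"]))
        assert out.loc[0, "n"] == 2
        assert out.loc[0, "n_undefined"] == 1
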