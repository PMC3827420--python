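"""Gene-set derivation, 2x2 tests and expected-overlap statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tflink.integrate import (
    GeneSets,
    contingency_association,
    contingency_from_table,
    derive_gene_sets,
    direction_concordance,
    category_fraction_test,
    expected_overlap,
    fisher_exact_grid,
    overlap_p_monte_carlo,
    summarize_ratios,
)


def de_frame(status_by_gene):
    return pd.DataFrame(
        {"status": list(status_by_gene.values()),
         "linear_fc": 2.0, "log2fc": 1.0, "p_value": 0.01,
         "above_background": True},
        index=list(status_by_gene.keys()),
    )


class Assignment:
    def __init__(self, peak_id, gene_id):
        self.peak_id, self.gene_id = peak_id, gene_id


class TestDeriveGeneSets:
    def test_rule_application(self):
        from tflink.motifs import MotifHit

        assignments = [Assignment("p1", "gA"), Assignment("p2", "gB")]
        hits = {"p1": [MotifHit("p1", "RUNX", 0, "+", "TGTGGT")],
                "p2": []}
        de = de_frame({"gA": "up", "gB": "down", "gC": "ns"})
        sets = derive_gene_sets(assignments, hits, de,
                                {"gA", "gB", "gC"})
        assert sets.regulated == {"gA"}          # bound + motif + DE
        assert "gB" in sets.responsive            # bound, no motif
        assert "gB" not in sets.regulated
        assert sets.provenance["gA"]["peaks"] == ["p1"]

    def test_invariant_chain_enforced(self):
        with pytest.raises(ValueError):
            GeneSets(universe={"a"}, bound={"a", "b"},
                     bound_with_motif=set(), responsive=set())
        with pytest.raises(ValueError):
            GeneSets(universe={"a", "b"}, bound={"a"},
                     bound_with_motif={"a", "b"}, responsive=set())

    def test_de_gene_outside_universe_errors(self):
        de = de_frame({"gX": "up"})
        with pytest.raises(ValueError, match="gX"):
            derive_gene_sets([], {}, de, {"gA"})


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher by integer-exact enumeration of the support."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    masses = [math.comb(r1, x) * math.comb(n - r1, c1 - x)
              for x in range(lo, hi + 1)]
    obs = masses[a - lo]
    total = sum(masses)
    return sum(m for m in masses if m <= obs) / total


class TestContingency:
    def test_fisher_matches_enumeration_on_example_table(self):
        result = contingency_from_table(((1, 9), (11, 3)))
        assert result.fisher_p == pytest.approx(
            exact_fisher_oracle(1, 9, 11, 3), rel=1e-10)

    def test_fisher_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            ours = contingency_from_table(
                ((int(a), int(b)), (int(c), int(d)))).fisher_p
            _, scipy_p = stats.fisher_exact([[a, b], [c, d]])
            assert ours == pytest.approx(scipy_p, rel=1e-7)

    def test_chi_square_definition(self):
        table = ((30, 10), (10, 30))
        result = contingency_from_table(table)
        arr = np.array(table, float)
        expected = arr.sum(1, keepdims=True) @ arr.sum(0, keepdims=True) \
            / arr.sum()
        chi2 = ((arr - expected) ** 2 / expected).sum()
        assert result.chi_square == pytest.approx(chi2)
        assert result.chi_square_p == pytest.approx(
            stats.chi2.sf(chi2, 1))

    def test_extreme_dependence_tiny_p(self):
        universe = {f"g{i}" for i in range(400)}
        half = {f"g{i}" for i in range(200)}
        result = contingency_association(half, half, universe)
        assert result.fisher_p < 1e-10
        assert result.chi_square_p < 1e-10

    def test_haldane_correction_on_zero_cell(self):
        result = contingency_from_table(((0, 10), (10, 10)))
        assert result.odds_ratio == pytest.approx(
            (0.5 * 10.5) / (10.5 * 10.5))

    def test_null_p_valid_at_all_levels(self, rng):
        # independent random sets: the exact test's discrete p is
        # sub-uniform, so rejection rates must not exceed alpha (+CI)
        universe = [f"g{i}" for i in range(300)]
        pvals = []
        for _ in range(500):
            a = set(rng.choice(universe, 60, replace=False))
            b = set(rng.choice(universe, 60, replace=False))
            pvals.append(
                contingency_association(a, b, set(universe)).fisher_p)
        pvals = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            ci = 2.58 * math.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals <= alpha).mean() <= alpha + ci
        # and not wildly conservative either at the median
        assert (pvals <= 0.5).mean() >= 0.25


class TestExpectedOverlap:
    def test_expected_formula(self):
        stat = expected_overlap(10, 10, 100, observed=1)
        assert stat.expected == pytest.approx(1.0)

    def test_lists_equal_universe_degenerate(self):
        u = {f"g{i}" for i in range(50)}
        stat = expected_overlap(u, u, u)
        assert stat.observed == 50 and stat.p_value == pytest.approx(1.0)

    def test_paper_scale_expected_eleven(self):
        # 231- and 818-member lists in a ~17.2k universe share 38 genes:
        # expectation is ~11 and the tail p is far below 1e-10
        stat = expected_overlap(231, 818, 17_178, observed=38)
        assert stat.expected == pytest.approx(11.0, abs=0.05)
        assert stat.p_value < 1e-10

    def test_symmetry_in_lists(self):
        a = expected_overlap(30, 70, 500, observed=12)
        b = expected_overlap(70, 30, 500, observed=12)
        assert a.expected == b.expected and a.p_value == b.p_value

    def test_inconsistent_observed_errors(self):
        with pytest.raises(ValueError):
            expected_overlap(5, 10, 100, observed=6)

    def test_tail_matches_monte_carlo(self):
        stat = expected_overlap(20, 30, 100, observed=10)
        mc = overlap_p_monte_carlo(20, 30, 100, 10, n_draws=100_000, seed=3)
        sigma = math.sqrt(stat.p_value * (1 - stat.p_value) / 100_000)
        assert abs(stat.p_value - mc) <= 3 * sigma + 1e-9

    def test_hypergeom_tail_is_exact_sum(self):
        stat = expected_overlap(12, 15, 60, observed=7)
        direct = sum(
            math.comb(12, k) * math.comb(48, 15 - k) / math.comb(60, 15)
            for k in range(7, 13))
        assert stat.p_value == pytest.approx(direct, rel=1e-10)


class TestDirectionConcordance:
    def test_printed_example_fraction(self):
        genes = [f"g{i}" for i in range(118)]
        de_a = de_frame({g: "up" for g in genes})
        statuses = {g: ("up" if i < 92 else "down")
                    for i, g in enumerate(genes)}
        de_b = de_frame(statuses)
        result = direction_concordance(genes, de_a, de_b)
        assert result["n_same_direction"] == 92
        assert result["percent"] == 78

    def test_all_matching(self):
        de = de_frame({"g1": "down", "g2": "up"})
        assert direction_concordance(["g1", "g2"], de, de)["percent"] == 100

    def test_ns_status_errors(self):
        de_a = de_frame({"g1": "up"})
        de_b = de_frame({"g1": "ns"})
        with pytest.raises(ValueError):
            direction_concordance(["g1"], de_a, de_b)


class TestCategoryFraction:
    def test_null_fraction_gives_no_signal(self):
        # set fraction == genome fraction -> p near 1
        result = category_fraction_test(34, 500, 0.068, 22_000)
        assert result.fisher_p > 0.5

    def test_tf_enrichment_detected(self):
        result = category_fraction_test(20, 118, 0.068, 22_000)
        assert result.fisher_p < 0.05
        assert result.chi_square_p < 0.05

    def test_doubling_counts_sharpens_p(self):
        small = category_fraction_test(20, 118, 0.068, 22_000)
        big = category_fraction_test(40, 236, 0.068, 44_000)
        assert big.fisher_p < small.fisher_p


class TestSummarizeRatios:
    def test_printed_ratio_examples(self):
        counts = {
            "regulated_cd8_act": 341, "regulated_cd8_rest": 231,
            "common_act": 118, "common_rest": 38,
            "responsive_cd8_rest": 609,
        }
        out = summarize_ratios(counts, [
            ("regulated_cd8_act", "regulated_cd8_rest"),
            ("common_act", "common_rest"),
            ("regulated_cd8_rest", "responsive_cd8_rest"),
        ])
        assert out["regulated_cd8_act/regulated_cd8_rest"]["ratio_1dp"] == 1.5
        assert out["common_act/common_rest"]["ratio"] >= 3
        assert out["regulated_cd8_rest/responsive_cd8_rest"]["percent"] == 38

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            summarize_ratios({"a": 1, "b": 0}, [("a", "b")])


class TestFisherGrid:
    def test_grid_agrees_with_scipy_sample(self, rng):
        n = rng.integers(10, 50, 100)
        r1 = np.array([int(rng.integers(1, x)) for x in n])
        c1 = np.array([int(rng.integers(1, x)) for x in n])
        lo = np.maximum(0, r1 + c1 - n)
        hi = np.minimum(r1, c1)
        a = np.array([int(rng.integers(l, h + 1))
                      for l, h in zip(lo, hi)])
        ours = fisher_exact_grid(a, r1, c1, n)
        for i in range(len(n)):
            table = [[a[i], r1[i] - a[i]],
                     [c1[i] - a[i], n[i] - r1[i] - c1[i] + a[i]]]
            _, sp = stats.fisher_exact(table)
            assert ours[i] == pytest.approx(sp, rel=1e-7)
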