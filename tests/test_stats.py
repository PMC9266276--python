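from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sweetreview.corpus_io import Product, Review, SweetenerRecord
from sweetreview.stats import (
    bh_adjust,
    bonferroni_adjust,
    compare_product_ratings,
    customer_dispersion,
    enrichment_by_caloric_class,
    enrichment_by_sweetener,
    prop_test_two_sided,
    wilcoxon_one_sided,
)

from .oracles import oracle_prop_test, oracle_wilcoxon_less


class TestPropTest:
    def test_identical_proportions(self):
        assert prop_test_two_sided(50, 100, 50, 100) == pytest.approx(1.0)

    def test_frozen_r_reference_value(self):
        # verified against R prop.test(c(9,1), c(10,10)) and the closed form
        assert prop_test_two_sided(9, 10, 1, 10) == pytest.approx(
            0.001745118700, abs=1e-10
        )

    def test_degenerate_all_failures(self):
        assert prop_test_two_sided(0, 10, 0, 10) == 1.0

    def test_degenerate_all_successes(self):
        assert prop_test_two_sided(10, 10, 5, 5) == 1.0

    def test_matches_closed_form_oracle_on_grid(self):
        for k1, n1, k2, n2 in itertools.product([0, 1, 5, 9], [10], [0, 3, 10], [10, 25]):
            if (k1 == 0 and k2 == 0) or (k1 == n1 and k2 == n2):
                continue
            assert prop_test_two_sided(k1, n1, k2, n2) == pytest.approx(
                oracle_prop_test(k1, n1, k2, n2), abs=1e-12
            )

    def test_symmetric_in_groups(self):
        for k1, n1, k2, n2 in [(3, 12, 7, 20), (1, 5, 4, 9), (0, 8, 2, 6)]:
            assert prop_test_two_sided(k1, n1, k2, n2) == pytest.approx(
                prop_test_two_sided(k2, n2, k1, n1)
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prop_test_two_sided(1, 0, 1, 2)
        with pytest.raises(ValueError):
            prop_test_two_sided(3, 2, 1, 2)

    def test_type_one_error_calibration(self):
        # spec invariant: rejection rate at alpha=0.05 within [0.03, 0.07]
        rng = np.random.default_rng(7)
        n1, n2, p = 120, 150, 0.3
        rejections = 0
        trials = 2000
        k1s = rng.binomial(n1, p, size=trials)
        k2s = rng.binomial(n2, p, size=trials)
        for k1, k2 in zip(k1s, k2s):
            if prop_test_two_sided(int(k1), n1, int(k2), n2) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / trials <= 0.07


class TestWilcoxon:
    def test_exact_extreme_split(self):
        assert wilcoxon_one_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.05)

    def test_all_ties_no_evidence(self):
        assert wilcoxon_one_sided([3, 3, 3], [3, 3, 3]) >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1, 2])

    def test_exact_branch_matches_enumeration_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            nx = int(rng.integers(1, n))
            values = rng.permutation(np.arange(1, n + 1)).astype(float)
            x, y = list(values[:nx]), list(values[nx:])
            assert wilcoxon_one_sided(x, y) == pytest.approx(
                oracle_wilcoxon_less(x, y), abs=1e-12
            )

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        detected = 0
        for _ in range(20):
            x = np.clip(np.round(rng.normal(3.1, 0.9, size=100)), 1, 5)
            y = np.clip(np.round(rng.normal(4.0, 0.9, size=100)), 1, 5)
            if wilcoxon_one_sided(x, y) < 0.001:
                detected += 1
        assert detected >= 20 * 0.99


class TestAdjustments:
    def test_bh_spec_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_single_value_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_bh_ones(self):
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_bh_empty(self):
        assert bh_adjust([]) == []

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_bonferroni(self):
        assert bonferroni_adjust([0.01, 0.4], m=3) == pytest.approx([0.03, 1.0])
        assert bonferroni_adjust([0.3]) == [pytest.approx(0.3)]

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    def test_adjusted_dominates_raw(self, ps):
        for raw, adj in zip(ps, bh_adjust(ps)):
            assert raw <= adj + 1e-12
            assert adj <= 1.0
        for raw, adj in zip(ps, bonferroni_adjust(ps)):
            assert raw <= adj + 1e-12
            assert adj <= 1.0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_bh_matches_defining_formula(self, ps):
        from .oracles import oracle_bh

        assert bh_adjust(ps) == pytest.approx(oracle_bh(ps), abs=1e-12)


def _mini_catalog():
    return [
        SweetenerRecord("sucrose", frozenset({"sucrose"}), "caloric"),
        SweetenerRecord("sucralose", frozenset({"sucralose"}), "non-caloric"),
    ]


def _corpus(rng, rates, n_per_product=400, penalty=0.0):
    """Products keyed by sweetener mix with planted per-product oversweet rates."""
    catalog = _mini_catalog()
    products, reviews, oversweet = [], [], set()
    i = 0
    for pid, (sweeteners, rate) in enumerate(rates):
        raw = ", ".join(["water"] + list(sweeteners))
        products.append(
            Product(f"P{pid}", f"item {pid}", "snacks", raw,
                    ["water"] + list(sweeteners), set(sweeteners))
        )
        for _ in range(n_per_product):
            is_over = rng.random() < rate
            base = int(rng.choice([3, 4, 5], p=[0.2, 0.3, 0.5]))
            rating = max(1, round(base - penalty)) if is_over else base
            rid = f"R{i}"
            reviews.append(
                Review(rid, f"P{pid}", f"C{i % 97}", "", "text", rating)
            )
            if is_over:
                oversweet.add(rid)
            i += 1
    return reviews, oversweet, products, catalog


class TestEnrichment:
    def test_single_sweetener_no_correction(self, rng):
        reviews, over, products, catalog = _corpus(
            rng, [(("sucrose",), 0.2)], n_per_product=50
        )
        records = enrichment_by_sweetener(reviews, over, products, catalog)
        assert len(records) == 1
        assert records[0].p_adjusted == pytest.approx(records[0].p_raw)

    def test_orphan_review_rejected(self, rng):
        reviews, over, products, catalog = _corpus(rng, [(("sucrose",), 0.2)], 10)
        reviews.append(Review("RX", "GHOST", "C0", "", "t", 5))
        with pytest.raises(ValueError, match="GHOST"):
            enrichment_by_sweetener(reviews, over, products, catalog)

    def test_planted_excess_detected(self, rng):
        reviews, over, products, catalog = _corpus(
            rng,
            [(("sucrose",), 0.1), (("sucrose",), 0.1), (("sucralose",), 0.3)],
            n_per_product=600,
        )
        records = {r.sweetener: r for r in
                   enrichment_by_sweetener(reviews, over, products, catalog)}
        suc = records["sucralose"]
        assert suc.proportion > suc.baseline_proportion
        assert suc.p_adjusted < 0.05

    def test_sorted_by_review_count(self, rng):
        reviews, over, products, catalog = _corpus(
            rng, [(("sucrose",), 0.1), (("sucralose",), 0.1)], n_per_product=30
        )
        reviews = reviews + [Review("RY", "P0", "C1", "", "t", 4)]
        records = enrichment_by_sweetener(reviews, over, products, catalog)
        assert [r.sweetener for r in records] == ["sucrose", "sucralose"]

    def test_invariants(self, rng):
        reviews, over, products, catalog = _corpus(
            rng, [(("sucrose",), 0.15), (("sucralose",), 0.15)], 100
        )
        for rec in enrichment_by_sweetener(reviews, over, products, catalog):
            assert 0 <= rec.n_oversweet <= rec.n_reviews
            assert rec.p_adjusted == pytest.approx(min(1.0, rec.p_raw * 2))


class TestCaloricClass:
    def test_multi_class_product_counts_once_per_class(self, rng):
        reviews, over, products, catalog = _corpus(
            rng, [(("sucrose", "sucralose"), 0.2)], n_per_product=40
        )
        records = enrichment_by_caloric_class(reviews, over, products, catalog)
        assert {r.sweetener for r in records} == {"caloric", "non-caloric"}
        assert all(r.n_reviews == 40 for r in records)

    def test_planted_class_excess(self, rng):
        reviews, over, products, catalog = _corpus(
            rng,
            [(("sucrose",), 0.1), (("sucrose",), 0.1), (("sucralose",), 0.35)],
            n_per_product=500,
        )
        records = {r.sweetener: r for r in
                   enrichment_by_caloric_class(reviews, over, products, catalog)}
        assert records["non-caloric"].p_adjusted < 0.05
        assert records["non-caloric"].proportion > records["non-caloric"].baseline_proportion


class TestCompareProductRatings:
    def test_threshold_arithmetic(self, rng):
        # 51 reviews, 6 oversweet (11.8%) -> passes both filters
        reviews = []
        over = set()
        for i in range(51):
            rid = f"R{i}"
            reviews.append(Review(rid, "P0", f"C{i}", "", "t", 5 if i >= 6 else 4))
            if i < 6:
                over.add(rid)
        out = compare_product_ratings(reviews, over)
        assert len(out) == 1
        assert (out[0].n_oversweet, out[0].n_other) == (6, 45)

    def test_exactly_fifty_reviews_excluded(self):
        reviews = [Review(f"R{i}", "P0", "c", "", "t", 4) for i in range(50)]
        over = {f"R{i}" for i in range(6)}
        assert compare_product_ratings(reviews, over) == []

    def test_below_oversweet_fraction_excluded(self):
        reviews = [Review(f"R{i}", "P0", "c", "", "t", 4) for i in range(60)]
        over = {"R0", "R1"}  # 3.3% < 10%
        assert compare_product_ratings(reviews, over) == []

    def test_planted_penalty_significant(self, rng):
        reviews, over, products, _ = _corpus(
            rng, [(("sucrose",), 0.25)] * 4, n_per_product=120, penalty=1.0
        )
        out = compare_product_ratings(reviews, over)
        assert len(out) == 4
        assert all(c.significant for c in out)
        assert all(c.mean_oversweet < c.mean_other for c in out)
        assert all(1.0 <= c.mean_oversweet <= 5.0 for c in out)

    def test_missing_ratings_excluded(self):
        reviews = []
        over = set()
        for i in range(80):
            rating = None if i % 10 == 0 else 4
            reviews.append(Review(f"R{i}", "P0", "c", "", "t", rating))
            if i < 20:
                over.add(f"R{i}")
        out = compare_product_ratings(reviews, over)
        assert out[0].n_oversweet + out[0].n_other == 72

    def test_counts_partition_product_reviews(self, rng):
        reviews, over, products, _ = _corpus(rng, [(("sucrose",), 0.3)], 90)
        out = compare_product_ratings(reviews, over)
        assert out[0].n_oversweet + out[0].n_other == 90


class TestCustomerDispersion:
    def test_strict_threshold(self):
        reviews = [Review(f"R{i}", "P0", "C_heavy", "", "t", 4) for i in range(31)]
        reviews += [Review(f"S{i}", "P0", "C_light", "", "t", 4) for i in range(30)]
        records, summary = customer_dispersion(reviews, set(), min_reviews=30)
        assert [r.customer_id for r in records] == ["C_heavy"]
        assert summary["n_customers"] == 1

    def test_no_heavy_reviewers(self):
        reviews = [Review("R0", "P0", "C0", "", "t", 4)]
        records, summary = customer_dispersion(reviews, set())
        assert records == []
        assert summary is None

    def test_product_driven_labels_rarely_concentrate(self, rng):
        # oversweet status depends on product only; heavy reviewers spread
        # across products should rarely exceed 10% oversweet
        reviews, over = [], set()
        i = 0
        for cust in range(40):
            for _ in range(60):
                pid = int(rng.integers(0, 50))
                rid = f"R{i}"
                reviews.append(Review(rid, f"P{pid}", f"C{cust}", "", "t", 4))
                if pid < 2 and rng.random() < 0.5:  # 2 oversweet-prone products
                    over.add(rid)
                i += 1
        records, summary = customer_dispersion(reviews, over)
        frac_above = summary["n_above_10pct"] / summary["n_customers"]
        assert frac_above <= 0.05

    def test_percentages_in_range(self, rng):
        reviews = [Review(f"R{i}", "P0", "C0", "", "t", 4) for i in range(40)]
        over = {f"R{i}" for i in range(8)}
        records, summary = customer_dispersion(reviews, over)
        assert records[0].oversweet_pct == pytest.approx(20.0)
        assert 0 <= records[0].oversweet_pct <= 100
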