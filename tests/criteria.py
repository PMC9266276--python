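"""Acceptance-criterion computations, shared by the test suite and the
standalone acceptance report script.

Each function recomputes its quantity from scratch by running the package on
freshly generated synthetic data (or closed-form oracles) and returns plain
numbers; the assertions live in ``test_acceptance.py``.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np

from sweetreview.classify import split_labeled, train_classifier
from sweetreview.cli import run_pipeline
from sweetreview.lexicon import default_lexicon
from sweetreview.stats import (
    bh_adjust,
    bonferroni_adjust,
    compare_product_ratings,
    enrichment_by_sweetener,
    prop_test_two_sided,
    wilcoxon_one_sided,
)
from sweetreview.sweetmatch import SWEET_FAMILY, iter_mentions, review_levels, tally, tokenize
from sweetreview.synthetic_data import SimulationConfig, generate_corpus

from .oracles import (
    oracle_bh,
    oracle_prop_test,
    oracle_tally_counts,
    oracle_wilcoxon_less,
    random_fuzz_corpus,
)

NO_DECOY_MIXTURE = {
    "under-sweet": 0.05,
    "neutral": 0.20,
    "sweet-only": 0.20,
    "none": 0.55,
    "decoy": 0.0,
}


def _oversweet_ids(reviews, lexicon):
    return {r.review_id for r in reviews if "oversweet" in review_levels(r, lexicon)}


# 1 ------------------------------------------------------------------------
def matcher_oracle_agreement(seed: int, n_corpora: int = 100) -> dict:
    """Exact tally equality against the brute-force n-gram oracle."""
    rng = np.random.default_rng(seed)
    lexicon = default_lexicon()
    n_agree = 0
    for _ in range(n_corpora):
        corpus = random_fuzz_corpus(rng, max_reviews=200)
        if tally(corpus, lexicon).counts == oracle_tally_counts(corpus, lexicon):
            n_agree += 1
    return {"n_corpora": n_corpora, "n_agree": n_agree}


# 2 ------------------------------------------------------------------------
def mention_partition(seed: int, n_corpora: int = 100) -> dict:
    """Level + sweet-only + excluded mention counts vs sweet-family tokens."""
    rng = np.random.default_rng(seed)
    lexicon = default_lexicon()
    n_ok = 0
    for _ in range(n_corpora):
        corpus = random_fuzz_corpus(rng, max_reviews=200)
        n_tokens = sum(
            1 for r in corpus
            for t in tokenize(f"{r.title} {r.text}") if t in SWEET_FAMILY
        )
        if len(list(iter_mentions(corpus, lexicon))) == n_tokens:
            n_ok += 1
    return {"n_corpora": n_corpora, "n_ok": n_ok}


# 3 ------------------------------------------------------------------------
def prevalence_recovery(seed: int, n_seeds: int = 10, n_reviews: int = 50000) -> dict:
    """Planted prevalence 0.10 vs pipeline (matcher) estimate, decoy-free."""
    lexicon = default_lexicon()
    errors = []
    estimates = []
    for offset in range(n_seeds):
        config = SimulationConfig(
            n_products=100, n_customers=200, n_reviews=n_reviews,
            base_oversweet_rate=0.10, per_sweetener_log_odds={},
            non_oversweet_mixture=dict(NO_DECOY_MIXTURE), seed=seed + offset,
        )
        bundle = generate_corpus(config)
        estimate = len(_oversweet_ids(bundle.reviews, lexicon)) / n_reviews
        estimates.append(estimate)
        errors.append(abs(estimate - 0.10))
    return {
        "n_seeds": n_seeds,
        "n_reviews": n_reviews,
        "planted": 0.10,
        "mean_estimate": float(np.mean(estimates)),
        "max_abs_error": float(np.max(errors)),
    }


# 4 ------------------------------------------------------------------------
def _gap_config(seed: int, penalty: float) -> SimulationConfig:
    return SimulationConfig(
        n_products=26, n_customers=150, n_reviews=3120,
        base_oversweet_rate=0.30, per_sweetener_log_odds={},
        oversweet_rating_penalty=penalty,
        non_oversweet_mixture=dict(NO_DECOY_MIXTURE), seed=seed,
    )


def rating_gap_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Planted 0.9-star penalty: share of qualifying products significant
    after BH, and the mean estimated gap."""
    lexicon = default_lexicon()
    n_products = 0
    n_significant = 0
    gaps = []
    for rep in range(n_replicates):
        bundle = generate_corpus(_gap_config(seed + rep, penalty=0.9))
        over = _oversweet_ids(bundle.reviews, lexicon)
        for comp in compare_product_ratings(bundle.reviews, over):
            n_products += 1
            n_significant += int(comp.significant)
            gaps.append(comp.mean_other - comp.mean_oversweet)
    return {
        "n_replicates": n_replicates,
        "n_products": n_products,
        "frac_significant": n_significant / n_products,
        "mean_gap": float(np.mean(gaps)),
        "planted_gap": 0.9,
    }


# 5 ------------------------------------------------------------------------
def null_calibration(seed: int, n_replicates: int = 50) -> dict:
    """Zero penalty, uniform sweetener rates: flagged fractions under
    BH (products) and Bonferroni (sweeteners)."""
    lexicon = default_lexicon()
    n_products = n_products_flagged = 0
    n_sweeteners = n_sweeteners_flagged = 0
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_products=20, n_customers=100, n_reviews=2400,
            base_oversweet_rate=0.30, per_sweetener_log_odds={},
            oversweet_rating_penalty=0.0,
            non_oversweet_mixture=dict(NO_DECOY_MIXTURE), seed=seed + rep,
        )
        bundle = generate_corpus(config)
        over = _oversweet_ids(bundle.reviews, lexicon)
        for comp in compare_product_ratings(bundle.reviews, over):
            n_products += 1
            n_products_flagged += int(comp.significant)
        for rec in enrichment_by_sweetener(
            bundle.reviews, over, bundle.products, config.sweetener_catalog
        ):
            n_sweeteners += 1
            n_sweeteners_flagged += int(rec.p_adjusted < 0.05)
    return {
        "n_replicates": n_replicates,
        "n_products": n_products,
        "frac_products_flagged": n_products_flagged / n_products,
        "n_sweeteners": n_sweeteners,
        "frac_sweeteners_flagged": n_sweeteners_flagged / n_sweeteners,
    }


# 6 ------------------------------------------------------------------------
def test_function_correctness(seed: int) -> dict:
    """Max deviations from the defining formulas / exhaustive enumeration."""
    # prop.test vs closed-form Yates chi-square on a grid of 2x2 tables
    prop_err = 0.0
    for k1, n1, k2, n2 in itertools.product(
        [0, 1, 4, 7, 10], [10, 15], [0, 2, 8], [10, 40]
    ):
        if (k1 == 0 and k2 == 0) or (k1 == n1 and k2 == n2):
            continue
        prop_err = max(
            prop_err,
            abs(prop_test_two_sided(k1, n1, k2, n2) - oracle_prop_test(k1, n1, k2, n2)),
        )
    # exact wilcoxon vs full enumeration for every split of <= 10 observations
    wilcoxon_err = 0.0
    for n in range(2, 11):
        values = [float(v) for v in range(1, n + 1)]
        for nx in range(1, n):
            for subset in itertools.combinations(range(n), nx):
                x = [values[i] for i in subset]
                y = [values[i] for i in range(n) if i not in subset]
                wilcoxon_err = max(
                    wilcoxon_err,
                    abs(wilcoxon_one_sided(x, y) - oracle_wilcoxon_less(x, y)),
                )
    # BH / Bonferroni vs defining formulas on random p-vectors
    rng = np.random.default_rng(seed)
    bh_err = bonf_err = 0.0
    for _ in range(200):
        ps = rng.random(int(rng.integers(1, 30))).tolist()
        bh_err = max(bh_err, float(np.max(np.abs(
            np.array(bh_adjust(ps)) - np.array(oracle_bh(ps))))))
        expected = np.minimum(np.array(ps) * len(ps), 1.0)
        bonf_err = max(bonf_err, float(np.max(np.abs(
            np.array(bonferroni_adjust(ps)) - expected))))
    return {
        "prop_test_max_abs_err": prop_err,
        "wilcoxon_exact_max_abs_err": wilcoxon_err,
        "bh_max_abs_err": bh_err,
        "bonferroni_max_abs_err": bonf_err,
    }


# 7 ------------------------------------------------------------------------
def classifier_sanity(seed: int) -> dict:
    """Planted decoy/real distinction: 10-fold CV accuracy and exact split sizes."""
    lexicon = default_lexicon()
    config = SimulationConfig(
        n_products=20, n_customers=80, n_reviews=1500,
        base_oversweet_rate=0.20,
        non_oversweet_mixture={"under-sweet": 0.05, "neutral": 0.20,
                               "sweet-only": 0.20, "none": 0.40, "decoy": 0.15},
        seed=seed,
    )
    bundle = generate_corpus(config)
    eligible = [r for r in bundle.reviews
                if "oversweet" in review_levels(r, lexicon)]
    texts = [f"{r.title} {r.text}" for r in eligible]
    labels = [bundle.ground_truth.classifier_label[r.review_id] for r in eligible]
    clf = train_classifier(
        texts, labels,
        grid={"max_depth": [3], "learning_rate": [0.1], "n_estimators": [100]},
        k_folds=10, seed=seed,
    )
    train, test = split_labeled(list(range(5590)), 0.75, seed=seed)
    return {
        "n_labeled": len(eligible),
        "cv_accuracy_mean": clf.metrics["cv_accuracy_mean"],
        "split_train": len(train),
        "split_test": len(test),
    }


# 8 ------------------------------------------------------------------------
def pipeline_determinism(seed: int, out_root: Path) -> dict:
    """Byte-compare two full pipeline runs under the same seed."""
    def _run(name: str) -> Path:
        config = SimulationConfig(
            n_products=26, n_customers=120, n_reviews=2500,
            base_oversweet_rate=0.30, seed=seed,
        )
        return run_pipeline(config, out_dir=out_root / name, seed=seed)

    a, b = _run("a"), _run("b")
    compared = []
    identical = True
    for path in sorted(a.rglob("*")):
        if not path.is_file():
            continue
        rel = path.relative_to(a)
        if rel.name == "manifest.json" or rel.suffix == ".joblib":
            continue  # manifests carry timing; the model pickle is compared via its manifest
        compared.append(str(rel))
        if path.read_bytes() != (b / rel).read_bytes():
            identical = False
    # manifests must agree on everything except timing
    def _stripped(p: Path) -> dict:
        m = json.loads((p / "manifest.json").read_text())
        m.pop("timing", None)
        m.pop("total_seconds", None)
        return m

    manifests_equal = _stripped(a) == _stripped(b)
    return {
        "n_files_compared": len(compared),
        "byte_identical": bool(identical),
        "manifests_equal_modulo_timing": bool(manifests_equal),
    }
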