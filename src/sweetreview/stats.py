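"""Enrichment, rating-comparison and dispersion statistics.

The two-sample proportion test reproduces the default behaviour of R's
``prop.test`` (chi-square with Yates continuity correction, correction
capped at ``|p1-p2| / (1/n1 + 1/n2)``).  The rank-sum comparison is
one-sided (oversweet ratings stochastically smaller), exact for small
tie-free samples.  Sweetener enrichment uses Bonferroni control across the
sweeteners tested in the run; product rating comparisons use
Benjamini-Hochberg.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .corpus_io import Product, Review, SweetenerRecord

__all__ = [
    "SweetenerEnrichment",
    "ProductRatingComparison",
    "CustomerDispersion",
    "prop_test_two_sided",
    "wilcoxon_one_sided",
    "bh_adjust",
    "bonferroni_adjust",
    "enrichment_by_sweetener",
    "enrichment_by_caloric_class",
    "compare_product_ratings",
    "customer_dispersion",
    "write_enrichment",
    "write_rating_comparisons",
    "write_dispersion",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class SweetenerEnrichment:
    sweetener: str
    n_reviews: int
    n_oversweet: int
    proportion: float
    baseline_proportion: float
    p_raw: float
    p_adjusted: float  # Bonferroni


@dataclass
class ProductRatingComparison:
    product_id: str
    n_oversweet: int
    n_other: int
    mean_oversweet: float
    mean_other: float
    p_raw: float
    p_adjusted: float  # Benjamini-Hochberg
    significant: bool


@dataclass
class CustomerDispersion:
    customer_id: str
    n_reviews: int
    n_oversweet: int
    oversweet_pct: float


def prop_test_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test of equal proportions, matching R ``prop.test`` defaults.

    Chi-square on the 2x2 table with Yates continuity correction; the
    correction is capped so the statistic is 0 for identical proportions.
    Degenerate tables (both groups all successes or all failures) return
    p = 1 by convention.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"success count {k} outside [0, {n}]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col = table.sum(axis=0)
    if col[0] == 0 or col[1] == 0:
        logger.warning(
            "degenerate 2x2 table (%d/%d vs %d/%d): p = 1 by convention",
            k1, n1, k2, n2,
        )
        return 1.0
    row = table.sum(axis=1)
    total = table.sum()
    expected = np.outer(row, col) / total
    delta = k1 / n1 - k2 / n2
    yates = min(0.5, abs(delta) / (1 / n1 + 1 / n2))
    statistic = (((np.abs(table - expected) - yates) ** 2) / expected).sum()
    return float(sps.chi2.sf(statistic, df=1))


def wilcoxon_one_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided rank-sum p-value for x stochastically smaller than y.

    Exact enumeration when the pooled sample has <= 12 tie-free values;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    result = sps.mannwhitneyu(
        x, y, alternative="less", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(result.pvalue)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, position-aligned with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def bonferroni_adjust(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """min(1, p * m); m defaults to the number of tests supplied."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    return np.minimum(p * m, 1.0).tolist()


def _join_products(
    reviews: Sequence[Review], products: Sequence[Product]
) -> dict[str, Product]:
    by_id = {p.product_id: p for p in products}
    orphans = sorted({r.product_id for r in reviews} - by_id.keys())
    if orphans:
        raise ValueError(f"reviews reference unknown product ids: {orphans}")
    return by_id


def _enrichment(
    reviews: Sequence[Review],
    oversweet_ids: set[str],
    group_of_product: dict[str, set[str]],
) -> list[SweetenerEnrichment]:
    n_total = len(reviews)
    k_total = sum(1 for r in reviews if r.review_id in oversweet_ids)
    baseline = k_total / n_total
    per_group: dict[str, list[int]] = {}
    for r in reviews:
        for g in group_of_product.get(r.product_id, ()):
            n_k = per_group.setdefault(g, [0, 0])
            n_k[0] += 1
            n_k[1] += int(r.review_id in oversweet_ids)
    tested = {g: nk for g, nk in per_group.items() if nk[0] > 0}
    m = len(tested)
    records = []
    for g, (n, k) in tested.items():
        p_raw = prop_test_two_sided(k, n, k_total, n_total)
        records.append(
            SweetenerEnrichment(
                sweetener=g,
                n_reviews=n,
                n_oversweet=k,
                proportion=k / n,
                baseline_proportion=baseline,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
            )
        )
    records.sort(key=lambda rec: (-rec.n_reviews, rec.sweetener))
    return records


def enrichment_by_sweetener(
    reviews: Sequence[Review],
    oversweet_ids: set[str],
    products: Sequence[Product],
    catalog: Sequence[SweetenerRecord],
) -> list[SweetenerEnrichment]:
    """Per-sweetener oversweet proportion vs. the dataset-wide baseline.

    Reviews of multi-sweetener products count toward every sweetener;
    Bonferroni ``m`` is the number of sweeteners actually tested.
    Sorted by review count, descending.
    """
    by_id = _join_products(reviews, products)
    known = {rec.canonical_name for rec in catalog}
    groups = {pid: (p.sweeteners & known) for pid, p in by_id.items()}
    return _enrichment(reviews, oversweet_ids, groups)


def enrichment_by_caloric_class(
    reviews: Sequence[Review],
    oversweet_ids: set[str],
    products: Sequence[Product],
    catalog: Sequence[SweetenerRecord],
) -> list[SweetenerEnrichment]:
    """Same machinery with sweeteners pooled by caloric class.

    A product whose sweeteners span two classes contributes its reviews once
    per class; Bonferroni ``m`` is the number of classes tested.
    """
    by_id = _join_products(reviews, products)
    class_of = {rec.canonical_name: rec.caloric_class for rec in catalog}
    groups = {
        pid: {class_of[s] for s in p.sweeteners if s in class_of}
        for pid, p in by_id.items()
    }
    return _enrichment(reviews, oversweet_ids, groups)


def compare_product_ratings(
    reviews: Sequence[Review],
    oversweet_ids: set[str],
    min_reviews: int = 50,
    min_oversweet_frac: float = 0.10,
) -> list[ProductRatingComparison]:
    """One-sided rating comparison (oversweet < other) per qualifying product.

    Products qualify with strictly more than ``min_reviews`` reviews and an
    oversweet share of at least ``min_oversweet_frac``.  Reviews lacking a
    rating are excluded from the comparison (counted in a log message).  BH
    adjustment runs across exactly the retained products.
    """
    by_product: dict[str, list[Review]] = {}
    for r in reviews:
        by_product.setdefault(r.product_id, []).append(r)
    comparisons: list[ProductRatingComparison] = []
    raw_ps: list[float] = []
    n_unrated = 0
    for pid in sorted(by_product):
        group = by_product[pid]
        n = len(group)
        n_over = sum(1 for r in group if r.review_id in oversweet_ids)
        if n <= min_reviews or n_over / n < min_oversweet_frac:
            continue
        x = [r.rating for r in group if r.review_id in oversweet_ids and r.rating is not None]
        y = [r.rating for r in group if r.review_id not in oversweet_ids and r.rating is not None]
        n_unrated += sum(1 for r in group if r.rating is None)
        if not x or not y:
            logger.warning("product %s skipped: a rating group is empty after "
                           "excluding unrated reviews", pid)
            continue
        raw_ps.append(wilcoxon_one_sided(x, y))
        comparisons.append(
            ProductRatingComparison(
                product_id=pid,
                n_oversweet=len(x),
                n_other=len(y),
                mean_oversweet=float(np.mean(x)),
                mean_other=float(np.mean(y)),
                p_raw=raw_ps[-1],
                p_adjusted=math.nan,  # filled below
                significant=False,
            )
        )
    if not comparisons:
        logger.warning("no product passed the rating-comparison filters")
        return []
    if n_unrated:
        logger.info("excluded %d unrated reviews from rating comparisons", n_unrated)
    for comp, p_adj in zip(comparisons, bh_adjust(raw_ps)):
        comp.p_adjusted = p_adj
        comp.significant = p_adj < ALPHA
    return comparisons


def customer_dispersion(
    reviews: Sequence[Review],
    oversweet_ids: set[str],
    min_reviews: int = 30,
) -> tuple[list[CustomerDispersion], Optional[dict[str, float]]]:
    """Oversweet share per heavy reviewer (strictly more than ``min_reviews``).

    Returns the per-customer records plus a summary (mean/sd of the
    oversweet percentage and the count of customers above 10%), or ``None``
    for the summary when no customer qualifies.
    """
    per_customer: dict[str, list[int]] = {}
    for r in reviews:
        n_k = per_customer.setdefault(r.customer_id, [0, 0])
        n_k[0] += 1
        n_k[1] += int(r.review_id in oversweet_ids)
    records = [
        CustomerDispersion(
            customer_id=cid,
            n_reviews=n,
            n_oversweet=k,
            oversweet_pct=100.0 * k / n,
        )
        for cid, (n, k) in sorted(per_customer.items())
        if n > min_reviews
    ]
    if not records:
        return [], None
    pcts = np.array([rec.oversweet_pct for rec in records])
    summary = {
        "n_customers": float(len(records)),
        "mean_oversweet_pct": float(pcts.mean()),
        "sd_oversweet_pct": float(pcts.std(ddof=1)) if len(records) > 1 else 0.0,
        "n_above_10pct": float((pcts > 10.0).sum()),
    }
    return records, summary


def write_enrichment(records: Iterable[SweetenerEnrichment], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sweetener", "n_reviews", "n_oversweet", "proportion",
                         "baseline_proportion", "p_raw", "p_adjusted"])
        for r in records:
            writer.writerow([r.sweetener, r.n_reviews, r.n_oversweet,
                             f"{r.proportion:.6f}", f"{r.baseline_proportion:.6f}",
                             f"{r.p_raw:.6g}", f"{r.p_adjusted:.6g}"])


def write_rating_comparisons(
    records: Iterable[ProductRatingComparison], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["product_id", "n_oversweet", "n_other", "mean_oversweet",
                         "mean_other", "p_raw", "p_adjusted", "significant"])
        for r in records:
            writer.writerow([r.product_id, r.n_oversweet, r.n_other,
                             f"{r.mean_oversweet:.4f}", f"{r.mean_other:.4f}",
                             f"{r.p_raw:.6g}", f"{r.p_adjusted:.6g}",
                             int(r.significant)])


def write_dispersion(
    records: Iterable[CustomerDispersion],
    summary: Optional[dict[str, float]],
    path: str | Path,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["customer_id", "n_reviews", "n_oversweet", "oversweet_pct"])
        for r in records:
            writer.writerow([r.customer_id, r.n_reviews, r.n_oversweet,
                             f"{r.oversweet_pct:.2f}"])
        if summary is not None:
            writer.writerow(["#summary",
                             f"mean={summary['mean_oversweet_pct']:.2f}",
                             f"sd={summary['sd_oversweet_pct']:.2f}",
                             f"above10pct={int(summary['n_above_10pct'])}"])
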