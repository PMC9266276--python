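"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results from definitions (full n-gram scans,
closed-form chi-square, exhaustive rank enumeration, the literal BH formula)
without touching the package's optimized code paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2

from sweetreview.corpus_io import Review
from sweetreview.lexicon import Lexicon
from sweetreview.sweetmatch import SWEET_FAMILY, tokenize

_LEVEL_RANK = {"oversweet": 0, "under-sweet": 1, "neutral": 2}


def oracle_resolve(tokens: list[str], index: int, lexicon: Lexicon) -> str:
    """Resolve one sweet-family token by scanning every lexicon surface
    against every n-gram position (quadratic, definition-level)."""
    matches = []
    for entry in lexicon.entries:
        surface_tokens = entry.surface.split()
        L = len(surface_tokens)
        for start in range(0, len(tokens) - L + 1):
            if tokens[start : start + L] == surface_tokens and start <= index < start + L:
                matches.append(entry)
    excluded = [e for e in matches if e.level == "excluded"]
    if excluded:
        return "excluded"
    if matches:
        best = min(
            matches,
            key=lambda e: (-len(e.surface.split()), _LEVEL_RANK[e.level], e.surface),
        )
        return best.level
    return "sweet-only"


def oracle_review_levels(review: Review, lexicon: Lexicon) -> set[str]:
    tokens = tokenize(f"{review.title} {review.text}")
    levels = set()
    for i, tok in enumerate(tokens):
        if tok in SWEET_FAMILY:
            resolved = oracle_resolve(tokens, i, lexicon)
            if resolved != "excluded":
                levels.add(resolved)
    return levels


def oracle_tally_counts(reviews: list[Review], lexicon: Lexicon) -> dict[str, int]:
    counts = {"oversweet": 0, "under-sweet": 0, "neutral": 0, "sweet-only": 0}
    for review in reviews:
        for level in oracle_review_levels(review, lexicon):
            counts[level] += 1
    return counts


def oracle_prop_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Closed-form continuity-corrected chi-square on the 2x2 table."""
    N = n1 + n2
    successes = k1 + k2
    failures = N - successes
    observed = [[k1, n1 - k1], [k2, n2 - k2]]
    expected = [
        [n1 * successes / N, n1 * failures / N],
        [n2 * successes / N, n2 * failures / N],
    ]
    yates = min(0.5, abs(k1 / n1 - k2 / n2) / (1 / n1 + 1 / n2))
    stat = sum(
        (abs(observed[i][j] - expected[i][j]) - yates) ** 2 / expected[i][j]
        for i in range(2)
        for j in range(2)
    )
    return float(chi2.sf(stat, 1))


def oracle_wilcoxon_less(x: list[float], y: list[float]) -> float:
    """Exact one-sided (x smaller) rank-sum p by exhaustive enumeration.

    Assumes no ties across the pooled sample.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank[v] for v in x)
    n, nx = len(pooled), len(x)
    hits = sum(
        1 for subset in combinations(range(1, n + 1), nx) if sum(subset) <= w_obs
    )
    return hits / comb(n, nx)


def oracle_bh(p_values: list[float]) -> list[float]:
    """BH step-up: p(i) * m / i, cumulative min from the largest rank."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p_values[i] * m / (pos + 1))
        adjusted[i] = min(running, 1.0)
    return adjusted


_FUZZ_WORDS = [
    "too", "not", "very", "way", "so", "much", "sweet", "sweetness", "sweeter",
    "sweetest", "sweets", "sweetener", "sweeteners", "sweetened", "enough",
    "tooth", "leaf", "potato", "cream", "spot", "overload", "of", "a", "bit",
    "the", "and", "i", "love", "it", "this", "tea", "sugar", "isnt", "isn't",
    "never", "barely", "hardly", "perfectly", "lightly", "for", "me", "flavor",
    "at", "all", "overly", "sickly", "just", "right",
]


def random_fuzz_review(rng: np.random.Generator, review_id: str) -> Review:
    n_tokens = int(rng.integers(0, 25))
    words = [str(rng.choice(_FUZZ_WORDS)) for _ in range(n_tokens)]
    title_words = [str(rng.choice(_FUZZ_WORDS)) for _ in range(int(rng.integers(0, 4)))]
    return Review(
        review_id=review_id,
        product_id=f"P{rng.integers(0, 5)}",
        customer_id=f"C{rng.integers(0, 5)}",
        title=" ".join(title_words),
        text=" ".join(words),
        rating=int(rng.integers(1, 6)),
    )


def random_fuzz_corpus(rng: np.random.Generator, max_reviews: int = 200) -> list[Review]:
    n = int(rng.integers(1, max_reviews + 1))
    return [random_fuzz_review(rng, f"R{i}") for i in range(n)]
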