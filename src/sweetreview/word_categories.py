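"""Percentage of reviews mentioning each word category (taste, texture, ...)."""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus_io import Review
from .sweetmatch import SWEET_FAMILY, tokenize

__all__ = [
    "CategoryLexicon",
    "CategoryFrequencies",
    "load_category_lexicons",
    "default_category_lexicons",
    "category_frequencies",
    "write_category_frequencies",
]


@dataclass(frozen=True)
class CategoryLexicon:
    category_name: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"category {self.category_name!r} has an empty word set")


@dataclass
class CategoryFrequencies:
    n_total_reviews: int
    n_reviews: dict[str, int]          # category -> reviews with >=1 hit
    percent: dict[str, float]          # category -> 100 * n_reviews / total
    sweet_subset_percent: float        # share of reviews with a sweet-family word


def load_category_lexicons(path: str | Path | None = None) -> list[CategoryLexicon]:
    """Load category word lists from a TSV (category, word)."""
    if path is None:
        text = resources.files("sweetreview.data").joinpath("category_words.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    words: dict[str, set[str]] = {}
    order: list[str] = []
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        category, word = line.split("\t")
        if category not in words:
            words[category] = set()
            order.append(category)
        words[category].add(word.lower())
    lexicons = [CategoryLexicon(c, frozenset(words[c])) for c in order]
    _warn_on_overlap(lexicons)
    return lexicons


def default_category_lexicons() -> list[CategoryLexicon]:
    return load_category_lexicons(None)


def _warn_on_overlap(lexicons: Sequence[CategoryLexicon]) -> None:
    for i, a in enumerate(lexicons):
        for b in lexicons[i + 1 :]:
            shared = a.words & b.words
            if shared:
                warnings.warn(
                    f"categories {a.category_name!r} and {b.category_name!r} "
                    f"share words: {sorted(shared)}",
                    stacklevel=3,
                )


def category_frequencies(
    reviews: Iterable[Review],
    category_lexicons: Optional[Sequence[CategoryLexicon]] = None,
) -> CategoryFrequencies:
    """Fraction of reviews containing >= 1 word from each category.

    A review counts once per category regardless of how many of its words
    hit.  Also reports the share of reviews containing a sweet-family word
    (the darker-bar subset of the taste category).  Raises on an empty
    review collection rather than dividing by zero.
    """
    if category_lexicons is None:
        category_lexicons = default_category_lexicons()
    reviews = list(reviews)
    if not reviews:
        raise ValueError("category_frequencies requires a non-empty review set")
    n_reviews = {lex.category_name: 0 for lex in category_lexicons}
    n_sweet = 0
    for review in reviews:
        tokens = set(tokenize(f"{review.title} {review.text}"))
        for lex in category_lexicons:
            if tokens & lex.words:
                n_reviews[lex.category_name] += 1
        if tokens & SWEET_FAMILY:
            n_sweet += 1
    total = len(reviews)
    percent = {c: 100.0 * n / total for c, n in n_reviews.items()}
    return CategoryFrequencies(
        n_total_reviews=total,
        n_reviews=n_reviews,
        percent=percent,
        sweet_subset_percent=100.0 * n_sweet / total,
    )


def write_category_frequencies(freqs: CategoryFrequencies, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "n_reviews", "percent"])
        for category, n in freqs.n_reviews.items():
            writer.writerow([category, n, f"{freqs.percent[category]:.2f}"])
        writer.writerow(["taste:sweet-family",
                         round(freqs.sweet_subset_percent * freqs.n_total_reviews / 100),
                         f"{freqs.sweet_subset_percent:.2f}"])
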