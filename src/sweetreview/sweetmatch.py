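"""Sweetness-mention extraction and per-level review tallies.

Review text (title + body) is tokenized; every sweet-family token yields one
mention, resolved against the lexicon with the precedence

    excluded  >  longest level surface  >  shorter surfaces  >  sweet-only

Equal-length ties break by level order (oversweet > under-sweet > neutral),
then lexicographically, so resolution is a total order and deterministic.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .corpus_io import Review
from .lexicon import Lexicon

__all__ = [
    "SWEET_FAMILY",
    "SweetMention",
    "TallyTable",
    "tokenize",
    "extract_environments",
    "resolve_mention",
    "iter_mentions",
    "tally",
    "write_tally",
    "write_mention_log",
]

# Fixed sweet-family stems anchoring mention extraction.
SWEET_FAMILY = frozenset(
    ["sweet", "sweetness", "sweeter", "sweetest", "sweetened",
     "sweetener", "sweeteners", "sweets"]
)

LEVEL_OUTCOMES = ("oversweet", "under-sweet", "neutral")
TALLY_CATEGORIES = ("oversweet", "under-sweet", "neutral", "sweet-only")

_LEVEL_RANK = {"oversweet": 0, "under-sweet": 1, "neutral": 2}

_TOKEN_RE = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class SweetMention:
    review_id: Optional[str]
    token_index: int
    window: tuple[Optional[str], str, Optional[str]]
    resolved: str  # oversweet | under-sweet | neutral | sweet-only | excluded
    matched_surface: Optional[str]


@dataclass
class TallyTable:
    counts: dict[str, int]
    percentages: dict[str, float]
    total_reviews_with_sweetness: int

    def two_row(self) -> dict[str, float]:
        """Collapsed oversweet vs everything-else percentages."""
        total = sum(self.counts[c] for c in TALLY_CATEGORIES)
        if total == 0:
            return {"oversweet": 0.0, "other": 0.0}
        over = self.counts["oversweet"]
        return {
            "oversweet": 100.0 * over / total,
            "other": 100.0 * (total - over) / total,
        }


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; punctuation stripped except in-word apostrophes."""
    tokens = _TOKEN_RE.findall(text.lower().replace("’", "'"))
    return [t for t in (tok.strip("'") for tok in tokens) if t]


def extract_environments(text: str) -> list[tuple[Optional[str], str, Optional[str]]]:
    """One (previous, matched, next) window per sweet-family token."""
    tokens = tokenize(text)
    windows = []
    for i, tok in enumerate(tokens):
        if tok in SWEET_FAMILY:
            prev = tokens[i - 1] if i > 0 else None
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            windows.append((prev, tok, nxt))
    return windows


class _SurfaceIndex:
    """Lexicon surfaces keyed by token tuple for O(1) n-gram lookup."""

    def __init__(self, lexicon: Lexicon):
        self.by_tokens: dict[tuple[str, ...], str] = {}
        self.max_len = 1
        for entry in lexicon.entries:
            toks = tuple(entry.surface.split())
            self.by_tokens[toks] = entry.level
            self.max_len = max(self.max_len, len(toks))


def _surface_index(lexicon: Lexicon) -> _SurfaceIndex:
    # cached on the lexicon object; rebuilt if entries were edited
    idx = getattr(lexicon, "_surface_index", None)
    if idx is None or len(idx.by_tokens) != len({e.surface for e in lexicon.entries}):
        idx = _SurfaceIndex(lexicon)
        lexicon._surface_index = idx  # type: ignore[attr-defined]
    return idx


def resolve_mention(
    tokens: Sequence[str],
    token_index: int,
    lexicon: Lexicon,
    review_id: Optional[str] = None,
) -> SweetMention:
    """Resolve the sweet-family token at ``token_index`` to a sweetness outcome.

    All lexicon surfaces covering the token are considered; an excluded match
    suppresses level matches outright; otherwise the longest surface wins.
    With no match at all the mention is "sweet-only".
    """
    tok = tokens[token_index]
    if tok not in SWEET_FAMILY:
        raise ValueError(f"token {tok!r} at index {token_index} is not a sweet-family token")
    idx = _surface_index(lexicon)
    n = len(tokens)
    candidates: list[tuple[int, int, str, str]] = []  # (-len, rank, surface, level)
    excluded: list[str] = []
    for L in range(1, idx.max_len + 1):
        for start in range(max(0, token_index - L + 1), min(token_index, n - L) + 1):
            gram = tuple(tokens[start : start + L])
            level = idx.by_tokens.get(gram)
            if level is None:
                continue
            surface = " ".join(gram)
            if level == "excluded":
                excluded.append(surface)
            else:
                candidates.append((-L, _LEVEL_RANK[level], surface, level))
    window = (
        tokens[token_index - 1] if token_index > 0 else None,
        tok,
        tokens[token_index + 1] if token_index + 1 < n else None,
    )
    if excluded:
        surface = min(excluded, key=lambda s: (-len(s.split()), s))
        return SweetMention(review_id, token_index, window, "excluded", surface)
    if candidates:
        _, _, surface, level = min(candidates)
        return SweetMention(review_id, token_index, window, level, surface)
    return SweetMention(review_id, token_index, window, "sweet-only", None)


def _review_tokens(review: Review) -> list[str]:
    return tokenize(f"{review.title} {review.text}")


def iter_mentions(reviews: Iterable[Review], lexicon: Lexicon) -> Iterator[SweetMention]:
    """All resolved mentions over title+text of each review, in order."""
    for review in reviews:
        tokens = _review_tokens(review)
        for i, tok in enumerate(tokens):
            if tok in SWEET_FAMILY:
                yield resolve_mention(tokens, i, lexicon, review_id=review.review_id)


def review_levels(review: Review, lexicon: Lexicon) -> set[str]:
    """The set of tally categories this review contributes to (excluded dropped)."""
    tokens = _review_tokens(review)
    levels: set[str] = set()
    for i, tok in enumerate(tokens):
        if tok in SWEET_FAMILY:
            resolved = resolve_mention(tokens, i, lexicon).resolved
            if resolved != "excluded":
                levels.add(resolved)
    return levels


def tally(
    reviews: Iterable[Review],
    lexicon: Lexicon,
    collapse_dominant: bool = False,
) -> TallyTable:
    """Count reviews per sweetness level (multi-membership by default).

    A review contributes to every category with >= 1 resolved mention; with
    ``collapse_dominant`` it counts only under its highest-precedence level
    (oversweet > under-sweet > neutral > sweet-only).  Percentages are over
    the sum of the four category counts; an empty tally reports 0s.
    """
    counts = {c: 0 for c in TALLY_CATEGORIES}
    n_with = 0
    for review in reviews:
        levels = review_levels(review, lexicon)
        if not levels:
            continue
        n_with += 1
        if collapse_dominant:
            for c in TALLY_CATEGORIES:
                if c in levels:
                    counts[c] += 1
                    break
        else:
            for c in levels:
                counts[c] += 1
    total = sum(counts.values())
    percentages = {
        c: (100.0 * counts[c] / total if total else 0.0) for c in TALLY_CATEGORIES
    }
    return TallyTable(counts=counts, percentages=percentages,
                      total_reviews_with_sweetness=n_with)


def write_tally(table: TallyTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["level", "count", "percent"])
        for c in TALLY_CATEGORIES:
            writer.writerow([c, table.counts[c], f"{table.percentages[c]:.2f}"])
        writer.writerow(["total_reviews_with_sweetness",
                         table.total_reviews_with_sweetness, ""])


def write_mention_log(
    reviews: Iterable[Review], lexicon: Lexicon, path: str | Path
) -> None:
    """Per-mention audit log for manual curation parity."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["review_id", "prev", "word", "next", "matched_surface", "level"])
        for m in iter_mentions(reviews, lexicon):
            writer.writerow([
                m.review_id, m.window[0] or "", m.window[1], m.window[2] or "",
                m.matched_surface or "", m.resolved,
            ])
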