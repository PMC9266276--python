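"""Sweetness-phrase lexicon: construction, validation and TSV round-trip.

A lexicon starts from base phrases mapped to sweetness levels and is expanded
with negated forms (level flipped through an editable flip table), common
misspellings, and exclusion suffixes that void a sweetness-level reading
("sweet tooth", "sweet leaf").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "LEVELS",
    "PROVENANCES",
    "DEFAULT_FLIP_TABLE",
    "PhraseEntry",
    "Lexicon",
    "LexiconError",
    "LexiconParseError",
    "build_lexicon",
    "validate_lexicon",
    "save_lexicon",
    "load_lexicon",
    "default_lexicon",
]

LEVELS = ("oversweet", "under-sweet", "neutral", "excluded")
PROVENANCES = ("base", "negated", "misspelling", "suffix-variant")

# Level a phrase lands on once negated.  "not too sweet" is praise, not a
# complaint; negating a plain or neutral sweetness assertion denies sweetness.
DEFAULT_FLIP_TABLE: dict[str, str] = {
    "oversweet": "neutral",
    "under-sweet": "neutral",
    "neutral": "under-sweet",
}

DEFAULT_NEGATION_PREFIXES = ["not", "isn't", "wasn't", "never"]
DEFAULT_MISSPELLINGS = {
    "isn't": ["isnt"],
    "wasn't": ["wasnt"],
    "doesn't": ["doesnt"],
    "too": ["to"],
}
DEFAULT_EXCLUSION_SUFFIXES = [
    "tooth", "leaf", "potato", "potatoes", "corn",
    "pea", "peas", "cream", "spot", "onion", "chili",
]


class LexiconError(ValueError):
    pass


class LexiconParseError(LexiconError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class PhraseEntry:
    surface: str  # lowercase, single-space separated, 1-6 words
    level: str
    provenance: str = "base"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise LexiconError(f"invalid level {self.level!r}")
        if self.provenance not in PROVENANCES:
            raise LexiconError(f"invalid provenance {self.provenance!r}")


@dataclass
class Lexicon:
    entries: list[PhraseEntry] = field(default_factory=list)
    negation_prefixes: list[str] = field(default_factory=list)
    exclusion_suffixes: list[str] = field(default_factory=list)
    version: str = "0"

    def surface_map(self) -> dict[str, PhraseEntry]:
        return {e.surface: e for e in self.entries}

    def summary_counts(self) -> dict[str, int]:
        """Phrase counts per level plus the single 'sweet-only' fallback row."""
        counts = {"oversweet": 0, "under-sweet": 0, "neutral": 0}
        for e in self.entries:
            if e.level in counts:
                counts[e.level] += 1
        counts["sweet-only"] = 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


def _flip(level: str, flip_table: Mapping[str, str]) -> str:
    try:
        return flip_table[level]
    except KeyError:
        raise LexiconError(f"flip table has no target for level {level!r}") from None


def build_lexicon(
    base_phrases: Mapping[str, str],
    negation_prefixes: Sequence[str] = (),
    misspellings: Optional[Mapping[str, Sequence[str]]] = None,
    exclusion_suffixes: Sequence[str] = (),
    flip_table: Optional[Mapping[str, str]] = None,
    version: str = "0",
) -> Lexicon:
    """Expand base phrases into a full lexicon.

    Per base phrase this emits: the base entry; one negated entry per prefix
    with the level flipped (skipped for excluded bases and for phrases that
    already begin with a negation prefix); one excluded entry per exclusion
    suffix; and, transitively, misspelling variants of every emitted entry.

    Raises :class:`LexiconError` when a base phrase lacks "sweet" or when two
    parents generate the same surface at different levels.
    """
    misspellings = misspellings or {}
    flip_table = flip_table or DEFAULT_FLIP_TABLE

    for phrase, level in base_phrases.items():
        if "sweet" not in phrase:
            raise LexiconError(f"base phrase {phrase!r} does not contain 'sweet'")
        if level not in LEVELS:
            raise LexiconError(f"base phrase {phrase!r} has invalid level {level!r}")

    entries: list[PhraseEntry] = []
    by_surface: dict[str, PhraseEntry] = {}
    parents: dict[str, str] = {}

    def add(surface: str, level: str, provenance: str, parent: str) -> None:
        surface = " ".join(surface.split())
        prior = by_surface.get(surface)
        if prior is not None:
            if prior.level != level:
                raise LexiconError(
                    f"surface {surface!r} generated at levels {prior.level!r} "
                    f"(from {parents[surface]!r}) and {level!r} (from {parent!r})"
                )
            return  # same level: first generation wins
        entry = PhraseEntry(surface, level, provenance)
        by_surface[surface] = entry
        parents[surface] = parent
        entries.append(entry)

    neg_set = set(negation_prefixes)
    for phrase, level in base_phrases.items():
        add(phrase, level, "base", phrase)
        first_word = phrase.split()[0]
        if level != "excluded" and first_word not in neg_set:
            for prefix in negation_prefixes:
                add(f"{prefix} {phrase}", _flip(level, flip_table), "negated", phrase)
        if level != "excluded":
            for suffix in exclusion_suffixes:
                add(f"{phrase} {suffix}", "excluded", "suffix-variant", phrase)

    # misspelling closure: keep substituting until no new surface appears
    frontier = list(entries)
    while frontier:
        next_frontier: list[PhraseEntry] = []
        for entry in frontier:
            words = entry.surface.split()
            for word, variants in sorted(misspellings.items()):
                if word not in words:
                    continue
                for variant in variants:
                    surface = " ".join(variant if w == word else w for w in words)
                    if surface not in by_surface:
                        add(surface, entry.level, "misspelling", entry.surface)
                        next_frontier.append(by_surface[surface])
        frontier = next_frontier

    return Lexicon(
        entries=entries,
        negation_prefixes=list(negation_prefixes),
        exclusion_suffixes=list(exclusion_suffixes),
        version=version,
    )


def validate_lexicon(lexicon: Lexicon) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    violations = []
    seen: dict[str, str] = {}
    for e in lexicon.entries:
        if not e.surface:
            violations.append("empty surface")
            continue
        if e.surface != " ".join(e.surface.lower().split()):
            violations.append(f"surface {e.surface!r} not normalized lowercase")
        n_words = len(e.surface.split())
        if not 1 <= n_words <= 6:
            violations.append(f"surface {e.surface!r} has {n_words} words (1-6 allowed)")
        if "sweet" not in e.surface:
            violations.append(f"surface {e.surface!r} does not contain 'sweet'")
        prior = seen.get(e.surface)
        if prior is None:
            seen[e.surface] = e.level
        elif prior != e.level:
            violations.append(
                f"surface {e.surface!r} appears at levels {prior!r} and {e.level!r}"
            )
        else:
            violations.append(f"surface {e.surface!r} duplicated")
    return violations


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    lines = [
        f"#% version={lexicon.version}",
        "#% negation_prefixes=" + "|".join(lexicon.negation_prefixes),
        "#% exclusion_suffixes=" + "|".join(lexicon.exclusion_suffixes),
        "surface\tlevel\tprovenance",
    ]
    lines += [f"{e.surface}\t{e.level}\t{e.provenance}" for e in lexicon.entries]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon TSV written by :func:`save_lexicon` (round-trip identity)."""
    lex = Lexicon()
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if line.startswith("#%"):
            try:
                key, value = line[2:].strip().split("=", 1)
            except ValueError:
                raise LexiconParseError(f"malformed directive {line!r}", lineno)
            if key == "version":
                lex.version = value
            elif key == "negation_prefixes":
                lex.negation_prefixes = [v for v in value.split("|") if v]
            elif key == "exclusion_suffixes":
                lex.exclusion_suffixes = [v for v in value.split("|") if v]
            else:
                raise LexiconParseError(f"unknown directive key {key!r}", lineno)
            continue
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t") != ["surface", "level", "provenance"]:
                raise LexiconParseError(f"unexpected header {line!r}", lineno)
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LexiconParseError(f"expected 3 columns, got {len(parts)}", lineno)
        surface, level, provenance = parts
        if level not in LEVELS:
            raise LexiconParseError(f"unknown level token {level!r}", lineno)
        if provenance not in PROVENANCES:
            raise LexiconParseError(f"unknown provenance token {provenance!r}", lineno)
        lex.entries.append(PhraseEntry(surface, level, provenance))
    return lex


def _load_base_phrases() -> dict[str, str]:
    text = resources.files("sweetreview.data").joinpath("base_phrases.tsv").read_text("utf-8")
    phrases: dict[str, str] = {}
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        surface, level = line.split("\t")
        phrases[surface] = level
    return phrases


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The packaged lexicon: curated seeds expanded with default rules."""
    return build_lexicon(
        _load_base_phrases(),
        negation_prefixes=DEFAULT_NEGATION_PREFIXES,
        misspellings=DEFAULT_MISSPELLINGS,
        exclusion_suffixes=DEFAULT_EXCLUSION_SUFFIXES,
        version="default-1",
    )
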