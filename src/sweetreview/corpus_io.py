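"""Reading, writing and normalizing review and product tables.

Review/product tables are plain CSV or TSV files with a header row; the
dialect is picked from the file extension (``.tsv`` -> tab, anything else
-> comma).  Ingredient strings are normalized into lowercase token lists and
scanned for sweeteners from a packaged catalog.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Review",
    "Product",
    "SweetenerRecord",
    "SchemaError",
    "RowError",
    "read_reviews",
    "write_reviews",
    "read_products",
    "write_products",
    "deduplicate_reviews",
    "normalize_ingredients",
    "detect_sweeteners",
    "load_sweetener_catalog",
    "default_sweetener_catalog",
    "load_filler_lexicon",
    "write_sweetener_table",
]

CALORIC_CLASSES = ("caloric", "non-caloric", "sugar alcohol", "sugar fiber")

REVIEW_COLUMNS = ("review_id", "product_id", "customer_id", "title", "text", "rating", "date")
PRODUCT_COLUMNS = ("product_id", "name", "category", "ingredients")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A data row violates a field contract; carries the 0-based row index."""

    def __init__(self, message: str, row_index: int):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


@dataclass(frozen=True)
class Review:
    review_id: str
    product_id: str
    customer_id: str
    title: str
    text: str
    rating: Optional[int] = None  # 1..5 when present
    date: Optional[_dt.date] = None


@dataclass
class Product:
    product_id: str
    name: str
    category: str
    raw_ingredients: str
    ingredients: list[str] = field(default_factory=list)
    sweeteners: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class SweetenerRecord:
    canonical_name: str
    synonyms: frozenset[str]
    caloric_class: str

    def __post_init__(self) -> None:
        if self.caloric_class not in CALORIC_CLASSES:
            raise ValueError(
                f"caloric_class {self.caloric_class!r} not in {CALORIC_CLASSES}"
            )
        if self.canonical_name not in self.synonyms:
            # canonical name must always resolve to itself
            object.__setattr__(
                self, "synonyms", frozenset(self.synonyms) | {self.canonical_name}
            )


def _dialect_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


_DATE_FORMATS = ("%Y-%m-%d", "%m/%d/%Y", "%m/%d/%y", "%B %d, %Y", "%d %B %Y")


def parse_date(value: str) -> Optional[_dt.date]:
    """Parse ISO and common US date forms; unparseable values become None."""
    value = value.strip()
    if not value:
        return None
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(value, fmt).date()
        except ValueError:
            continue
    # epoch seconds show up in the Kaggle dump
    if value.isdigit() and len(value) >= 9:
        try:
            return _dt.datetime.fromtimestamp(int(value), _dt.timezone.utc).date()
        except (ValueError, OverflowError):
            return None
    return None


def _parse_rating(value: str, row_index: int) -> Optional[int]:
    value = value.strip()
    if not value:
        return None
    try:
        rating = int(value)
    except ValueError:
        raise RowError(f"unparseable rating {value!r}", row_index) from None
    if rating not in (1, 2, 3, 4, 5):
        raise RowError(f"rating {rating} outside 1..5", row_index)
    return rating


def read_reviews(path: str | Path) -> list[Review]:
    """Read a review table; one :class:`Review` per data row.

    Missing ratings are preserved as ``None``.  A missing required column
    raises :class:`SchemaError`; a bad rating raises :class:`RowError` with
    the offending 0-based data-row index.
    """
    delim = _dialect_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in REVIEW_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        reviews = []
        for i, row in enumerate(reader):
            reviews.append(
                Review(
                    review_id=row["review_id"],
                    product_id=row["product_id"],
                    customer_id=row["customer_id"],
                    title=row["title"] or "",
                    text=row["text"] or "",
                    rating=_parse_rating(row["rating"] or "", i),
                    date=parse_date(row["date"] or ""),
                )
            )
    return reviews


def write_reviews(reviews: Iterable[Review], path: str | Path) -> None:
    delim = _dialect_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(REVIEW_COLUMNS)
        for r in reviews:
            writer.writerow(
                [
                    r.review_id,
                    r.product_id,
                    r.customer_id,
                    r.title,
                    r.text,
                    "" if r.rating is None else r.rating,
                    "" if r.date is None else r.date.isoformat(),
                ]
            )


def read_products(
    path: str | Path,
    catalog: Optional[Sequence[SweetenerRecord]] = None,
    filler_lexicon: Optional[frozenset[str]] = None,
) -> list[Product]:
    """Read a product table and annotate ingredients/sweeteners."""
    if catalog is None:
        catalog = default_sweetener_catalog()
    if filler_lexicon is None:
        filler_lexicon = load_filler_lexicon()
    delim = _dialect_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in PRODUCT_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        products = []
        for row in reader:
            raw = row["ingredients"] or ""
            tokens = normalize_ingredients(raw, filler_lexicon)
            products.append(
                Product(
                    product_id=row["product_id"],
                    name=row["name"] or "",
                    category=row["category"] or "",
                    raw_ingredients=raw,
                    ingredients=tokens,
                    sweeteners=detect_sweeteners(tokens, catalog),
                )
            )
    return products


def write_products(products: Iterable[Product], path: str | Path) -> None:
    delim = _dialect_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(PRODUCT_COLUMNS)
        for p in products:
            writer.writerow([p.product_id, p.name, p.category, p.raw_ingredients])


_DEDUP_KEYS = {
    # default: duplicates within a product; cross-posted variants survive
    "default": lambda r: (r.product_id, r.customer_id, r.title, r.text),
    "customer_title_text": lambda r: (r.customer_id, r.title, r.text),
    "text": lambda r: (r.text,),
}


def deduplicate_reviews(
    reviews: Iterable[Review], key: str = "default"
) -> list[Review]:
    """Drop duplicate reviews, keeping the first occurrence.

    ``key`` selects the duplicate-group definition: ``"default"`` (same
    product, customer, title and text), ``"customer_title_text"`` (collapses
    cross-product copies), or ``"text"``.
    """
    if key not in _DEDUP_KEYS:
        raise ValueError(f"unknown dedup key {key!r}; choose from {sorted(_DEDUP_KEYS)}")
    key_fn = _DEDUP_KEYS[key]
    seen: set = set()
    out = []
    for r in reviews:
        k = key_fn(r)
        if k not in seen:
            seen.add(k)
            out.append(r)
    return out


_INGREDIENT_SPLIT = re.compile(r"[^a-z0-9%]+")


def normalize_ingredients(
    raw_ingredients: str, filler_lexicon: frozenset[str]
) -> list[str]:
    """Normalize a raw ingredient string into lowercase tokens.

    Lowercases, strips punctuation (commas, parentheses, asterisks, ...),
    splits on whitespace and drops filler words and empty tokens.
    """
    tokens = _INGREDIENT_SPLIT.split(raw_ingredients.lower())
    return [t for t in tokens if t and t not in filler_lexicon]


def detect_sweeteners(
    ingredients: Sequence[str], catalog: Sequence[SweetenerRecord]
) -> set[str]:
    """Report every catalog sweetener whose synonym matches the token list.

    Synonyms are matched against runs of consecutive tokens, longest synonym
    first; tokens consumed by a longer match are not re-used, so "high
    fructose corn syrup" does not additionally count as "corn syrup", and a
    bare "sugar" immediately followed by "free" is not a sweetener hit.
    """
    if not catalog:
        raise ValueError("sweetener catalog is empty")
    synonym_map: list[tuple[tuple[str, ...], str]] = []
    for rec in catalog:
        for syn in rec.synonyms:
            synonym_map.append((tuple(syn.split()), rec.canonical_name))
    # longest first so multi-word names shadow their sub-phrases
    synonym_map.sort(key=lambda it: (-len(it[0]), it[0]))
    consumed = [False] * len(ingredients)
    found: set[str] = set()
    for syn_tokens, canonical in synonym_map:
        L = len(syn_tokens)
        for start in range(0, len(ingredients) - L + 1):
            if any(consumed[start : start + L]):
                continue
            if tuple(ingredients[start : start + L]) != syn_tokens:
                continue
            nxt = ingredients[start + L] if start + L < len(ingredients) else ""
            if nxt == "free":  # "sugar free" is not a sugar hit
                continue
            for j in range(start, start + L):
                consumed[j] = True
            found.add(canonical)
    return found


def load_filler_lexicon(path: str | Path | None = None) -> frozenset[str]:
    """Load filler words (one per line, '#' comments) from path or the package default."""
    if path is None:
        text = resources.files("sweetreview.data").joinpath("filler_words.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def load_sweetener_catalog(path: str | Path | None = None) -> list[SweetenerRecord]:
    """Load a sweetener catalog TSV (canonical_name, synonyms '|'-joined, caloric_class)."""
    if path is None:
        text = resources.files("sweetreview.data").joinpath("sweetener_catalog.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    records = []
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    expected = ["canonical_name", "synonyms", "caloric_class"]
    if header != expected:
        raise SchemaError(f"sweetener catalog header {header} != {expected}")
    for line in lines[1:]:
        name, syns, cls = line.split("\t")
        records.append(
            SweetenerRecord(
                canonical_name=name,
                synonyms=frozenset(s.strip() for s in syns.split("|") if s.strip()),
                caloric_class=cls,
            )
        )
    return records


def default_sweetener_catalog() -> list[SweetenerRecord]:
    return load_sweetener_catalog(None)


def write_sweetener_table(
    products: Iterable[Product],
    catalog: Sequence[SweetenerRecord],
    path: str | Path,
) -> None:
    """Write the normalized product table with one boolean column per sweetener."""
    names = [rec.canonical_name for rec in catalog]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["product_id", "name", "category"] + names)
        for p in products:
            writer.writerow(
                [p.product_id, p.name, p.category]
                + [int(n in p.sweeteners) for n in names]
            )
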