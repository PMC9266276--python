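"""Synthetic review corpora with planted, fully-known structure.

Every review's oversweet status is drawn from a per-product probability
(logistic in the product's sweetener effects), its text is assembled from a
level-matched template, and its star rating optionally carries a planted
penalty when the reviewer perceives the product as oversweet.  The emitted
tables use exactly the schemas :mod:`sweetreview.corpus_io` reads, and the
planted truth is returned row-for-row for recovery tests.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus_io import (
    Product,
    Review,
    SweetenerRecord,
    default_sweetener_catalog,
    load_filler_lexicon,
    normalize_ingredients,
    detect_sweeteners,
    write_products,
    write_reviews,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CorpusBundle",
    "load_templates",
    "generate_corpus",
    "default_paper_like_config",
    "write_ground_truth",
]

NON_OVERSWEET_LEVELS = ("under-sweet", "neutral", "sweet-only", "none", "decoy")

_TITLES = ["quick review", "my thoughts", "honest opinion", "bought again", "first try"]
_CATEGORIES = ["snacks", "beverages", "breakfast", "baking", "condiments"]


def load_templates(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load level -> template lists from a TSV (level, template)."""
    if path is None:
        text = resources.files("sweetreview.data").joinpath("templates.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    templates: dict[str, list[str]] = {}
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        level, template = line.split("\t")
        templates.setdefault(level, []).append(template)
    return templates


@dataclass
class SimulationConfig:
    n_products: int = 50
    n_customers: int = 300
    n_reviews: int = 5000
    sweetener_catalog: list[SweetenerRecord] = field(default_factory=default_sweetener_catalog)
    # per-product distribution over sweetener sets: [(names tuple, probability)]
    sweetener_assignment: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: [
            ((), 0.20),
            (("sucrose",), 0.35),
            (("sucrose", "corn syrup"), 0.10),
            (("sucralose",), 0.10),
            (("steviol glycosides",), 0.10),
            (("honey",), 0.05),
            (("erythritol",), 0.05),
            (("inulin",), 0.05),
        ]
    )
    base_oversweet_rate: float = 0.10
    per_sweetener_log_odds: dict[str, float] = field(default_factory=dict)
    rating_base_distribution: tuple[float, ...] = (0.02, 0.03, 0.10, 0.35, 0.50)
    oversweet_rating_penalty: float = 0.9
    heavy_reviewer_fraction: float = 0.05
    heavy_reviewer_weight: float = 25.0
    # mixture over NON_OVERSWEET_LEVELS for reviews not planted oversweet
    non_oversweet_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "under-sweet": 0.05,
            "neutral": 0.20,
            "sweet-only": 0.20,
            "none": 0.47,
            "decoy": 0.08,
        }
    )
    missing_rating_rate: float = 0.0
    phrase_templates: dict[str, list[str]] = field(default_factory=load_templates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_products < 1 or self.n_customers < 1:
            raise ValueError("n_products and n_customers must be >= 1")
        if self.n_reviews < self.n_products:
            raise ValueError("n_reviews must be >= n_products")
        if not 0.0 <= self.base_oversweet_rate <= 1.0:
            raise ValueError("base_oversweet_rate must be in [0, 1]")
        if not 0.0 <= self.heavy_reviewer_fraction <= 1.0:
            raise ValueError("heavy_reviewer_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rating_rate <= 1.0:
            raise ValueError("missing_rating_rate must be in [0, 1]")
        if self.oversweet_rating_penalty < 0:
            raise ValueError("oversweet_rating_penalty must be >= 0")
        if len(self.rating_base_distribution) != 5 or not math.isclose(
            sum(self.rating_base_distribution), 1.0, abs_tol=1e-9
        ):
            raise ValueError("rating_base_distribution must be 5 probabilities summing to 1")
        if not math.isclose(sum(p for _, p in self.sweetener_assignment), 1.0, abs_tol=1e-9):
            raise ValueError("sweetener_assignment probabilities must sum to 1")
        catalog_names = {rec.canonical_name for rec in self.sweetener_catalog}
        for names, _ in self.sweetener_assignment:
            unknown = set(names) - catalog_names
            if unknown:
                raise ValueError(f"sweetener_assignment references unknown sweeteners {sorted(unknown)}")
        unknown = set(self.per_sweetener_log_odds) - catalog_names
        if unknown:
            raise ValueError(f"per_sweetener_log_odds references unknown sweeteners {sorted(unknown)}")
        if set(self.non_oversweet_mixture) - set(NON_OVERSWEET_LEVELS):
            raise ValueError(f"non_oversweet_mixture keys must be among {NON_OVERSWEET_LEVELS}")
        if not math.isclose(sum(self.non_oversweet_mixture.values()), 1.0, abs_tol=1e-9):
            raise ValueError("non_oversweet_mixture must sum to 1")
        if not self.phrase_templates.get("oversweet"):
            raise ValueError("phrase_templates must provide oversweet templates")
        for level, weight in self.non_oversweet_mixture.items():
            if weight > 0 and not self.phrase_templates.get(level):
                raise ValueError(f"non-empty mixture weight for {level!r} but no templates")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["sweetener_catalog"] = [
            {"canonical_name": r.canonical_name,
             "synonyms": sorted(r.synonyms),
             "caloric_class": r.caloric_class}
            for r in self.sweetener_catalog
        ]
        payload["sweetener_assignment"] = [
            {"sweeteners": list(names), "probability": p}
            for names, p in self.sweetener_assignment
        ]
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        payload = json.loads(text)
        payload["sweetener_catalog"] = [
            SweetenerRecord(d["canonical_name"], frozenset(d["synonyms"]), d["caloric_class"])
            for d in payload["sweetener_catalog"]
        ]
        payload["sweetener_assignment"] = [
            (tuple(d["sweeteners"]), d["probability"])
            for d in payload["sweetener_assignment"]
        ]
        payload["rating_base_distribution"] = tuple(payload["rating_base_distribution"])
        return cls(**payload)


@dataclass
class GroundTruth:
    review_oversweet: dict[str, bool]           # review_id -> planted indicator
    review_template_level: dict[str, str]       # review_id -> template level drawn
    classifier_label: dict[str, str]            # only reviews with an oversweet phrase
    product_probability: dict[str, float]       # product_id -> true oversweet prob
    product_sweeteners: dict[str, tuple[str, ...]]
    planted_penalty: float
    planted_effects: dict[str, float]


@dataclass
class CorpusBundle:
    reviews: list[Review]
    products: list[Product]
    ground_truth: GroundTruth
    config: SimulationConfig


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_corpus(config: SimulationConfig) -> CorpusBundle:
    """Generate a corpus; fully reproducible under ``config.seed``.

    Ratings apply the planted penalty before stochastic integer rounding
    (floor plus a Bernoulli on the fractional part), which preserves the
    penalty in expectation, then clamp to [1, 5].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    base_logit = (
        math.log(config.base_oversweet_rate / (1 - config.base_oversweet_rate))
        if 0 < config.base_oversweet_rate < 1
        else (-math.inf if config.base_oversweet_rate == 0 else math.inf)
    )

    # --- products -----------------------------------------------------------
    assign_probs = np.array([p for _, p in config.sweetener_assignment])
    assign_idx = rng.choice(len(assign_probs), size=config.n_products, p=assign_probs)
    filler = load_filler_lexicon()
    products: list[Product] = []
    product_prob = np.empty(config.n_products)
    truth_sweeteners: dict[str, tuple[str, ...]] = {}
    for i in range(config.n_products):
        names = config.sweetener_assignment[assign_idx[i]][0]
        pid = f"P{i:05d}"
        raw = ", ".join(["water", "salt"] + list(names))
        tokens = normalize_ingredients(raw, filler)
        products.append(
            Product(
                product_id=pid,
                name=f"{_CATEGORIES[i % len(_CATEGORIES)]} item {i}",
                category=_CATEGORIES[i % len(_CATEGORIES)],
                raw_ingredients=raw,
                ingredients=tokens,
                sweeteners=detect_sweeteners(tokens, config.sweetener_catalog),
            )
        )
        logit = base_logit + sum(config.per_sweetener_log_odds.get(s, 0.0) for s in names)
        product_prob[i] = _logistic(logit) if math.isfinite(logit) else (0.0 if logit < 0 else 1.0)
        truth_sweeteners[pid] = tuple(names)

    # --- customers ----------------------------------------------------------
    n_heavy = int(round(config.heavy_reviewer_fraction * config.n_customers))
    weights = np.ones(config.n_customers)
    weights[:n_heavy] = config.heavy_reviewer_weight
    customer_probs = weights / weights.sum()

    # --- reviews ------------------------------------------------------------
    n = config.n_reviews
    product_idx = rng.integers(0, config.n_products, size=n)
    customer_idx = rng.choice(config.n_customers, size=n, p=customer_probs)
    oversweet = rng.random(n) < product_prob[product_idx]

    levels = list(config.non_oversweet_mixture.keys())
    level_probs = np.array([config.non_oversweet_mixture[l] for l in levels])
    level_draw = rng.choice(len(levels), size=n, p=level_probs)

    base_rating = rng.choice(5, size=n, p=np.asarray(config.rating_base_distribution)) + 1
    latent = base_rating.astype(float) - config.oversweet_rating_penalty * oversweet
    floor = np.floor(latent)
    rating = floor + (rng.random(n) < (latent - floor))
    rating = np.clip(rating, 1, 5).astype(int)
    missing = rng.random(n) < config.missing_rating_rate

    title_idx = rng.integers(0, len(_TITLES), size=n)
    day_offset = rng.integers(0, 1500, size=n)
    base_date = _dt.date(2018, 1, 1)

    # per-review template pick (index drawn lazily per level for determinism)
    template_pick = rng.random(n)

    reviews: list[Review] = []
    review_oversweet: dict[str, bool] = {}
    review_level: dict[str, str] = {}
    classifier_label: dict[str, str] = {}
    for i in range(n):
        rid = f"R{i:07d}"
        if oversweet[i]:
            level = "oversweet"
        else:
            level = levels[level_draw[i]]
        pool = config.phrase_templates[level]
        text = pool[int(template_pick[i] * len(pool))]
        reviews.append(
            Review(
                review_id=rid,
                product_id=f"P{product_idx[i]:05d}",
                customer_id=f"C{customer_idx[i]:05d}",
                # unique title keeps legitimate distinct reviews from
                # colliding under the duplicate key (customer, title, text)
                title=f"{_TITLES[title_idx[i]]} {i}",
                text=text,
                rating=None if missing[i] else int(rating[i]),
                date=base_date + _dt.timedelta(days=int(day_offset[i])),
            )
        )
        review_oversweet[rid] = bool(oversweet[i])
        review_level[rid] = level
        if level == "oversweet":
            classifier_label[rid] = "oversweet-product"
        elif level == "decoy":
            classifier_label[rid] = "not-oversweet-product"

    truth = GroundTruth(
        review_oversweet=review_oversweet,
        review_template_level=review_level,
        classifier_label=classifier_label,
        product_probability={f"P{i:05d}": float(product_prob[i]) for i in range(config.n_products)},
        product_sweeteners=truth_sweeteners,
        planted_penalty=config.oversweet_rating_penalty,
        planted_effects=dict(config.per_sweetener_log_odds),
    )
    return CorpusBundle(reviews=reviews, products=products, ground_truth=truth, config=config)


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    directory = Path(directory)
    lines = ["review_id\toversweet\ttemplate_level\tclassifier_label"]
    for rid in truth.review_oversweet:
        lines.append(
            f"{rid}\t{int(truth.review_oversweet[rid])}\t"
            f"{truth.review_template_level[rid]}\t{truth.classifier_label.get(rid, '')}"
        )
    (directory / "ground_truth.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    lines = ["product_id\ttrue_probability\tsweeteners"]
    for pid, prob in truth.product_probability.items():
        lines.append(f"{pid}\t{prob:.8f}\t" + "|".join(truth.product_sweeteners[pid]))
    (directory / "product_truth.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_corpus(bundle: CorpusBundle, directory: str | Path) -> None:
    """Write reviews.csv, products.csv, ground-truth TSVs and the echoed config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_reviews(bundle.reviews, directory / "reviews.csv")
    write_products(bundle.products, directory / "products.csv")
    write_ground_truth(bundle.ground_truth, directory)
    (directory / "config.json").write_text(bundle.config.to_json() + "\n", encoding="utf-8")


def default_paper_like_config(seed: int = 0) -> SimulationConfig:
    """A config whose planted parameters echo the reported headline magnitudes:
    a 0.9-star oversweet rating penalty, roughly one sweetness-mention review
    in ten being an oversweet complaint, and a positive sucralose effect.
    """
    return SimulationConfig(
        n_products=60,
        n_customers=400,
        n_reviews=12000,
        base_oversweet_rate=0.10,
        per_sweetener_log_odds={"sucralose": 0.8, "corn syrup": 0.4,
                                "steviol glycosides": 0.0},
        oversweet_rating_penalty=0.9,
        heavy_reviewer_fraction=0.05,
        seed=seed,
    )
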