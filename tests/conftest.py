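from __future__ import annotations

import numpy as np
import pytest

from sweetreview.corpus_io import Review, SweetenerRecord, default_sweetener_catalog
from sweetreview.lexicon import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def catalog():
    return default_sweetener_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def tiny_catalog():
    return [
        SweetenerRecord("sucrose", frozenset({"sucrose", "sugar", "cane sugar"}), "caloric"),
        SweetenerRecord("sucralose", frozenset({"sucralose"}), "non-caloric"),
    ]


def make_review(i, text, title="", product="P0", customer="C0", rating=5):
    return Review(
        review_id=f"R{i}",
        product_id=product,
        customer_id=customer,
        title=title,
        text=text,
        rating=rating,
    )


@pytest.fixture()
def review_factory():
    return make_review
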