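import pytest

from splintstore import workflows
from splintstore.seqcore import random_address_book

SENTENCE_WORDS = ["DNAdata", "Stores", "Apple"]


@pytest.fixture(scope="session")
def book4():
    """A small synthetic address book: 2 forward, 1 internal, 2 reverse."""
    return random_address_book(
        ["forward", "forward", "internal", "reverse", "reverse"], seed=11
    )


@pytest.fixture(scope="session")
def sentence_build():
    """Serial three-word sentence pool assembled in expectation mode."""
    return workflows.build_sentence_pool(SENTENCE_WORDS, seed=1)


@pytest.fixture(scope="session")
def sentence_products(sentence_build):
    return workflows.products_only(sentence_build.pool, min_length=150)


@pytest.fixture(scope="session")
def movie_build():
    """Three random 16x16 frames assembled into eight 270-nt products."""
    return workflows.build_movie_pool(seed=2)


@pytest.fixture(scope="session")
def movie_products(movie_build):
    return workflows.products_only(movie_build.pool, min_length=270)
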