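import random

import pytest
from hypothesis import HealthCheck, settings

import fxtag as fx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def patterns():
    return fx.load_category_patterns()


@pytest.fixture(scope="session")
def modifiers():
    return fx.load_modifier_patterns()


@pytest.fixture(scope="session")
def matcher(patterns, modifiers):
    return fx.RuleMatcher(patterns, modifiers)


def make_sentence(text, patient_id="p", note_id="n", index=0):
    return fx.Sentence(
        patient_id=patient_id,
        note_id=note_id,
        index=index,
        start=0,
        end=len(text),
        text=text,
    )


@pytest.fixture(scope="session")
def oracle_tables(patterns, modifiers):
    """Precomputed expansion tables for the brute-force oracle."""
    from oracle_utils import build_expansions

    site_expansions = {
        c: build_expansions(patterns.branches[c]) for c in patterns.categories
    }
    modifier_expansions = build_expansions(modifiers.branches)
    return site_expansions, modifier_expansions


def random_sentences(patterns, modifiers, n, seed):
    """Radiology-flavored random sentences (<=200 chars) for oracle tests.

    Tokens mix concrete site-term expansions, modifier expansions, filler
    words, and near-miss distractors so both hits and misses occur.
    """
    rng = random.Random(seed)
    site_terms = []
    for c in patterns.categories:
        for branch in patterns.branches[c]:
            site_terms.append(fx.expand_branch(branch, rng.randrange(2**30)))
    mod_terms = [
        fx.expand_branch(b, rng.randrange(2**30)) for b in modifiers.branches
    ]
    fillers = [
        "the", "of", "left", "right", "acute", "no", "with", "seen", "at",
        "and", "mild", "chronic", "region", "noted", "unremarkable",
        "maxillofacial", "irregularity", "degenerative", "alignment",
        "negative", "rule", "out",
    ]
    pools = [site_terms, mod_terms, fillers]
    weights = [3, 2, 5]
    sentences = []
    for _ in range(n):
        k = rng.randint(2, 14)
        tokens = []
        for _ in range(k):
            pool = rng.choices(pools, weights)[0]
            tokens.append(rng.choice(pool))
        text = " ".join(tokens)
        if rng.random() < 0.5:
            text += "."
        sentences.append(text[:200])
    return sentences
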