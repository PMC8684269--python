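"""Shared fixtures: a hand-built mini thesaurus and a session-scoped synthetic cohort."""

import pytest

from edlos.config import DEFAULT_CUES, GeneratorConfig
from edlos.extraction import extract_stay_concepts
from edlos.features import derive_stay_features
from edlos.synthetic import generate_cohort, generate_thesaurus, stays_to_frame
from edlos.thesaurus import Concept, ConceptThesaurus


@pytest.fixture
def mini_thesaurus() -> ConceptThesaurus:
    """root -> {pain -> abdominal pain, fever}; pain/abdominal-pain share a substring."""
    return ConceptThesaurus(
        [
            Concept("root", None, "clinical finding"),
            Concept("pain", "root", "pain", frozenset({"dolor"})),
            Concept("abdominal-pain", "pain", "abdominal pain"),
            Concept("fever", "root", "fever", frozenset({"pyrexia"})),
        ]
    )


@pytest.fixture
def cues():
    return DEFAULT_CUES["en"]


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(n_stays=400, seed=11)


@pytest.fixture(scope="session")
def thesaurus(gen_config):
    return generate_thesaurus(gen_config)


@pytest.fixture(scope="session")
def cohort(gen_config, thesaurus):
    return generate_cohort(gen_config, thesaurus)


@pytest.fixture(scope="session")
def stays_df(cohort):
    stays, _ = cohort
    return derive_stay_features(stays_to_frame(stays))


@pytest.fixture(scope="session")
def concepts_by_stay(cohort, thesaurus):
    _, notes = cohort
    cues = DEFAULT_CUES["en"]
    return {
        n.stay_id: extract_stay_concepts([{"sentences": list(n.sentences)}], thesaurus, cues)
        for n in notes
    }
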