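import pytest

from menagerie.corpus_io import Abstract, detect_sections, segment_sentences
from menagerie.fixtures import FixtureConfig, generate_corpus
from menagerie.pipeline import Resources
from menagerie.species_model import load_hierarchy


@pytest.fixture(scope="session")
def resources():
    return Resources.packaged()


@pytest.fixture(scope="session")
def hierarchy():
    return load_hierarchy()


@pytest.fixture(scope="session")
def clean_bundle():
    """Distractor-free fixture corpus: extraction should be lossless."""
    return generate_corpus(
        FixtureConfig(n_abstracts=40, seed=101, distractor_rate=0.0)
    )


@pytest.fixture(scope="session")
def noisy_bundle():
    """Corpus with excluded-region distractors planted at rate 0.5."""
    return generate_corpus(
        FixtureConfig(n_abstracts=40, seed=202, distractor_rate=0.5)
    )


def make_abstract(pmid: str, title: str, body: str, structured=False,
                  year=2017, pub_types=None) -> Abstract:
    ab = Abstract(pmid, title, body, segment_sentences(body), year=year,
                  pub_types=pub_types or ["Journal Article"])
    if structured:
        ab = detect_sections(ab)
    ab.validate()
    return ab
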