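import math

import pytest
from hypothesis import HealthCheck, settings

from p2pwatch.document_model import ExtractedDoc, RawFile, segment
from p2pwatch.fixtures import CorpusSpec, generate_corpus
from p2pwatch.health_detector import default_stopwords, load_health_lexicon
from p2pwatch.pii_detector import Gazetteer, NameLexicon, OrgPatterns, TriggerPatterns
from p2pwatch.pipeline import run_pipeline
from p2pwatch.shallow_filters import default_profiles

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_doc(text: str, extension: str = "txt", path: str = "doc.txt") -> ExtractedDoc:
    """Build an ExtractedDoc directly from text, bypassing file I/O."""
    raw = text.encode("utf-8")
    rf = RawFile(path, raw, math.ceil(len(raw) / 1024), extension, path.rsplit(".", 1)[0])
    tokens, sentences = segment(text)
    return ExtractedDoc(rf, text, tuple(tokens), tuple(sentences))


@pytest.fixture(scope="session")
def doc_factory():
    return make_doc


@pytest.fixture(scope="session")
def name_lexicon():
    return NameLexicon.from_files()


@pytest.fixture(scope="session")
def triggers():
    return TriggerPatterns.from_file()


@pytest.fixture(scope="session")
def gazetteer():
    return Gazetteer.from_file()


@pytest.fixture(scope="session")
def org_patterns():
    return OrgPatterns.from_file()


@pytest.fixture(scope="session")
def health_lexicon():
    return load_health_lexicon()


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


@pytest.fixture(scope="session")
def language_profiles():
    return default_profiles()


#: the study-conditions corpus: every document class, fixed seed, >= 500 files
CORPUS_COUNTS = dict(
    true_phi=80,
    pseudo_phi=60,
    published=100,
    non_english=60,
    duplicates=60,
    binary_junk=60,
    benign_personal=60,
    health_only=60,
)
CORPUS_SEED = 1234


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Generated corpus (manifest, directory) shared across the session."""
    root = tmp_path_factory.mktemp("corpus") / "files"
    spec = CorpusSpec(out_dir=str(root), seed=CORPUS_SEED, **CORPUS_COUNTS)
    manifest = generate_corpus(spec)
    return manifest, root


@pytest.fixture(scope="session")
def corpus_report(corpus):
    manifest, root = corpus
    return run_pipeline(root)
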