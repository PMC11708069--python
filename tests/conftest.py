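import pytest

from clinanno.core import RuleTokenizer, make_document, segment
from clinanno.fixtures import toy_lexicon
from clinanno.pipeline import Resources


@pytest.fixture(scope="session")
def lexicon():
    return toy_lexicon()


@pytest.fixture(scope="session")
def resources(lexicon):
    return Resources(lexicon=lexicon)


@pytest.fixture
def make_doc():
    def _make(text, doc_id="doc"):
        doc = make_document(doc_id, text)
        return segment(doc, RuleTokenizer())

    return _make
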