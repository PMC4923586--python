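import pytest

from demotext.lexicon import load_emotion_lexicon, load_sentiment_lexicon
from demotext.synthetic import write_fixture_lexicons


@pytest.fixture(scope="session")
def fixture_lexicon_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("lexicons")
    return write_fixture_lexicons(outdir)


@pytest.fixture(scope="session")
def sentiment_lexicon(fixture_lexicon_paths):
    return load_sentiment_lexicon(fixture_lexicon_paths["sentiment"])


@pytest.fixture(scope="session")
def emotion_lexicon(fixture_lexicon_paths):
    return load_emotion_lexicon(fixture_lexicon_paths["emotion"])
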