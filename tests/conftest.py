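import numpy as np
import pytest

from healthtopics.corpus import LabeledCorpus, Message
from healthtopics.lexicons import (
    DomainLexicon,
    SentimentLexicon,
    Sense,
    default_domain_lexicon,
    default_sentiment_lexicon,
)


@pytest.fixture(scope="session")
def domain_lexicon() -> DomainLexicon:
    return default_domain_lexicon()


@pytest.fixture(scope="session")
def sentiment_lexicon() -> SentimentLexicon:
    return default_sentiment_lexicon()


@pytest.fixture
def tiny_corpus() -> LabeledCorpus:
    """Three labeled messages covering the three topic flavours."""
    return LabeledCorpus.from_messages(
        [
            Message("m1", "I had chemo then surgery for breast cancer.", "treatment"),
            Message("m2", "Sending you love and hugs, stay strong!", "emotional"),
            Message("m3", "Five years out and back to a new routine.", "survivorship"),
        ]
    )


@pytest.fixture
def mixed_corpus() -> LabeledCorpus:
    """20 messages, 3 labels, with repeated vocabulary for count tests."""
    msgs = []
    texts = {
        "treatment": "chemo and tamoxifen after my mastectomy surgery",
        "emotional": "so happy and grateful for the support here",
        "survivorship": "walking daily and feeling strong five years out",
    }
    labels = ["treatment"] * 8 + ["emotional"] * 5 + ["survivorship"] * 7
    for i, lab in enumerate(labels):
        msgs.append(Message(f"d{i:02d}", texts[lab] + f" note{i}", lab))
    return LabeledCorpus.from_messages(msgs)


@pytest.fixture
def toy_sentiment_lexicon() -> SentimentLexicon:
    return SentimentLexicon(
        entries={
            "happy": [Sense(0.625, 0.25, 1)],
            "mixed": [Sense(0.5, 0.25, 1), Sense(0.0, 0.25, 2)],
            "plain": [Sense(0.0, 0.0, 1)],
            "borderline": [Sense(0.25, 0.25, 1)],
            "sad": [Sense(0.0, 0.875, 1)],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
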