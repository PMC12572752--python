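import logging

import numpy as np
import pytest

from speechmark.io_preprocess import AlignedTranscript, AudioSignal, Token
from speechmark.synthetic_data import bundled_toy_lexicon

logging.getLogger("speechmark").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_lexicon():
    return bundled_toy_lexicon()


@pytest.fixture(scope="session")
def toy_graph(toy_lexicon):
    return toy_lexicon[0]


@pytest.fixture(scope="session")
def toy_embeddings(toy_lexicon):
    return toy_lexicon[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_token(text="word", onset=0.0, offset=0.3, pos="noun", syllables=1, stop=False):
    return Token(text=text, onset=onset, offset=offset, pos=pos,
                 n_syllables=syllables, is_stop=stop)


@pytest.fixture
def simple_transcript():
    tokens = [
        make_token("the", 0.0, 0.2, pos="other", stop=True),
        make_token("boy", 0.25, 0.55, pos="noun"),
        make_token("is", 0.6, 0.7, pos="other", stop=True),
        make_token("falling", 0.75, 1.15, pos="verb", syllables=2),
        make_token("quickly", 1.2, 1.6, pos="adverb", syllables=2),
        make_token("uh", 1.7, 1.8, pos="other"),
    ]
    return AlignedTranscript(tokens, recording_id="rec0")


def tone(freq=440.0, duration=1.0, sr=16000, amp=0.5):
    t = np.arange(int(duration * sr)) / sr
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t), sr)
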