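from pathlib import Path

import pandas as pd
import pytest

from ppaspeech import packaged_lexicon, read_transcript

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def lexicon():
    return packaged_lexicon()


@pytest.fixture(scope="session")
def worked_example():
    """Two-utterance, 12-word annotated sample with one instance of every
    error category, one self-corrected sequence and one embedding."""
    return read_transcript(DATA / "worked_example.json")


@pytest.fixture(scope="session")
def worked_example_oracle():
    """Hand-computed parameter sheet for the worked example (frozen)."""
    df = pd.read_csv(DATA / "worked_example_features.csv")
    return dict(zip(df["feature"], df["value"]))
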