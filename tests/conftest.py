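import numpy as np
import pytest

from voxnat.synth_speech import SpeechSpec, synth_utterance


@pytest.fixture(scope="session")
def vowel_word():
    """A 3-syllable synthetic word with stressed middle syllable."""
    spec = SpeechSpec(
        durations=(0.20, 0.26, 0.18),
        f0s=(200.0, 240.0, 205.0),
        intensities_db=(0.0, 3.0, 0.0),
        stressed_index=1,
        word="test",
        seed=1,
    )
    return synth_utterance(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def pulse_vowel(f0=200.0, dur=0.5, fs=48000, formants=((500, 80), (1500, 120), (2500, 160))):
    """Deterministic pulse-train vowel through two-pole resonators."""
    from scipy import signal as sps

    n = int(dur * fs)
    x = np.zeros(n)
    idx = np.round(np.arange(0, n - 1, fs / f0)).astype(int)
    x[idx] = 1.0
    a1 = np.exp(-2 * np.pi * f0 / fs)
    for _ in range(2):
        x = sps.lfilter([1 - a1], [1, -a1], x)
    for f, bw in formants:
        r = np.exp(-np.pi * bw / fs)
        th = 2 * np.pi * f / fs
        x = sps.lfilter([1 - 2 * r * np.cos(th) + r * r], [1, -2 * r * np.cos(th), r * r], x)
    return np.diff(x, prepend=0.0)
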