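"""Source-filter generator for single-word emotional utterances.

Produces vowel-only 2-3 syllable words with known per-syllable F0,
duration, intensity, formants, and exactly one stressed syllable, so the
feature extractors and the editing chain can be validated against ground
truth.  The source is a pulse train with a -12 dB/octave glottal slope, a
+6 dB/octave lip-radiation term, cascaded two-pole formant resonators and
a -40 dB noise floor.  Emotion profiles set distinct F0/rate/intensity
regimes; the disgust profile gives unstressed syllables the *higher*
pitch, so its pitch stress contrast is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .audio import Waveform, rescale
from .editing import EMOTIONS
from .errors import ConfigurationError
from .textgrid import Interval, UtteranceAnnotation

__all__ = ["SpeechSpec", "EMOTION_PROFILES", "synth_utterance", "synth_corpus"]

RATE = 48000

#: per-emotion synthesis regime (an adult female voice):
#: base F0 (Hz), stressed-vs-unstressed F0 delta (Hz; negative for
#: disgust), base syllable duration (s), stressed duration delta (s),
#: stressed intensity delta (dB)
EMOTION_PROFILES = {
    "anger": dict(f0=220.0, f0_delta=45.0, dur=0.16, dur_delta=0.08, int_delta=4.0),
    "disgust": dict(f0=185.0, f0_delta=-30.0, dur=0.20, dur_delta=0.07, int_delta=3.0),
    "fear": dict(f0=255.0, f0_delta=35.0, dur=0.15, dur_delta=0.06, int_delta=3.0),
    "happiness": dict(f0=240.0, f0_delta=40.0, dur=0.17, dur_delta=0.07, int_delta=3.5),
    "neutral": dict(f0=190.0, f0_delta=30.0, dur=0.18, dur_delta=0.07, int_delta=3.0),
    "sadness": dict(f0=170.0, f0_delta=25.0, dur=0.22, dur_delta=0.08, int_delta=2.5),
}

_DEFAULT_FORMANTS = ((550.0, 90.0), (1550.0, 120.0), (2650.0, 160.0))


@dataclass
class SpeechSpec:
    """Generating parameters for one utterance."""

    durations: tuple  # per-syllable, s
    f0s: tuple  # per-syllable, Hz
    intensities_db: tuple  # per-syllable level, dB relative
    stressed_index: int
    formants: tuple = _DEFAULT_FORMANTS  # ((F, bandwidth), ...) Hz
    emotion: str = "neutral"
    word: str = "word"
    rate: int = RATE
    noise_floor_db: float = -40.0
    jitter_sd: float = 0.0  # relative period perturbation
    shimmer_sd: float = 0.0  # relative pulse-amplitude perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.durations)
        if not (len(self.f0s) == len(self.intensities_db) == k):
            raise ConfigurationError("per-syllable fields must have equal length")
        if not 0 <= self.stressed_index < k:
            raise ConfigurationError("stressed_index out of range")
        if any(d <= 0.06 for d in self.durations):
            raise ConfigurationError("syllable durations must exceed 60 ms")
        fvals = [f for f, _ in self.formants]
        if sorted(fvals) != list(fvals):
            raise ConfigurationError("formants must be ascending")
        if max(self.f0s) >= fvals[0]:
            raise ConfigurationError("F0 must stay below F1")


def _pulse_train(n: int, f0: float, fs: float, rng, jitter_sd, shimmer_sd):
    """Unit pulses with optionally perturbed periods/amplitudes."""
    x = np.zeros(n)
    pos = 0.0
    while pos < n:
        amp = 1.0
        if shimmer_sd > 0:
            amp = max(0.1, 1.0 + shimmer_sd * rng.standard_normal())
        x[int(pos)] += amp
        period = fs / f0
        if jitter_sd > 0:
            period *= max(0.5, 1.0 + jitter_sd * rng.standard_normal())
        pos += period
    return x


def _resonator_ba(f: float, bw: float, fs: float):
    r = np.exp(-np.pi * bw / fs)
    th = 2 * np.pi * f / fs
    a = np.array([1.0, -2 * r * np.cos(th), r * r])
    return np.array([a.sum()]), a  # unity gain at DC


def synth_utterance(spec: SpeechSpec):
    """Render a spec to (Waveform, UtteranceAnnotation, ground truth dict)."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.rate
    segments = []
    for dur, f0, level_db in zip(spec.durations, spec.f0s, spec.intensities_db):
        n = int(round(dur * fs))
        x = _pulse_train(n, f0, fs, rng, spec.jitter_sd, spec.shimmer_sd)
        # glottal slope: two one-pole lowpasses cornered at F0 (-12 dB/oct)
        a1 = np.exp(-2 * np.pi * f0 / fs)
        for _ in range(2):
            x = sps.lfilter([1 - a1], [1, -a1], x)
        for f, bw in spec.formants:
            b, a = _resonator_ba(f, bw, fs)
            x = sps.lfilter(b, a, x)
        x = np.diff(x, prepend=0.0)  # lip radiation (+6 dB/oct)
        rms = np.sqrt(np.mean(x**2))
        x *= 10.0 ** (level_db / 20.0) / max(rms, 1e-12)
        # short raised-cosine edges to avoid junction clicks
        edge = min(int(0.008 * fs), n // 4)
        env = np.ones(n)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        env[:edge] = ramp
        env[-edge:] = ramp[::-1]
        segments.append(x * env)
    y = np.concatenate(segments)
    if spec.noise_floor_db is not None:
        rms = np.sqrt(np.mean(y**2))
        y = y + rng.standard_normal(y.size) * rms * 10 ** (spec.noise_floor_db / 20.0)
    w = Waveform(rescale(y, "peak"), rate=fs, bit_depth=24)

    starts = np.concatenate(([0.0], np.cumsum(spec.durations)))
    syls = []
    for i in range(len(spec.durations)):
        label = f"s{i + 1}" + ("*" if i == spec.stressed_index else "")
        syls.append(Interval(starts[i], starts[i + 1], label))
    ann = UtteranceAnnotation(
        word=spec.word,
        tiers={
            "phone": list(syls),
            "syllable": syls,
            "word": [Interval(0.0, starts[-1], spec.word)],
        },
    )
    truth = asdict(spec)
    return w, ann, truth


def _spec_for(emotion: str, word_id: int, rng) -> SpeechSpec:
    prof = EMOTION_PROFILES[emotion]
    n_syl = int(rng.integers(2, 4))
    stressed = int(rng.integers(0, n_syl))
    durs, f0s, ints = [], [], []
    for i in range(n_syl):
        d = prof["dur"] * float(rng.uniform(0.9, 1.1))
        f = prof["f0"] + float(rng.normal(0, 8.0))
        lv = float(rng.normal(0, 1.0))
        if i == stressed:
            d += prof["dur_delta"]
            f += prof["f0_delta"]
            lv += prof["int_delta"]
        durs.append(d)
        f0s.append(max(f, 110.0))
        ints.append(lv)
    formants = tuple(
        (f * float(rng.uniform(0.96, 1.04)), bw) for f, bw in _DEFAULT_FORMANTS
    )
    return SpeechSpec(
        durations=tuple(durs),
        f0s=tuple(f0s),
        intensities_db=tuple(ints),
        stressed_index=stressed,
        formants=formants,
        emotion=emotion,
        word=f"{emotion}_{word_id:02d}",
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def synth_corpus(n_per_emotion: int = 24, emotions=EMOTIONS, seed: int = 0):
    """Generate the full stimulus set: n utterances for each emotion.

    Returns a list of (Waveform, UtteranceAnnotation, truth) triples,
    deterministic in `seed`.
    """
    if n_per_emotion < 2:
        raise ConfigurationError("need at least 2 utterances per emotion")
    rng = np.random.default_rng(seed)
    corpus = []
    for emotion in emotions:
        if emotion not in EMOTION_PROFILES:
            raise ConfigurationError(f"unknown emotion {emotion!r}")
        for i in range(n_per_emotion):
            corpus.append(synth_utterance(_spec_for(emotion, i, rng)))
    return corpus
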