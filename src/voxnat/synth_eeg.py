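"""Multi-subject EEG simulator with coupled block ratings.

Epochs are built as pattern x amplitude x canonical component waveform
plus 1/f noise mixed through smooth random topographies.  The three ERP
components (P200, early LPP, late LPP) carry condition-dependent
amplitudes (per-emotion offsets, naturalness-level gains); per-trial and
per-subject latency jitter controls phase locking, so across-word
coherence is high while across-subject coherence is only partial.
Ratings are drawn once per 24-trial block, as in the task; the spectral
slope of the trial noise is coupled to the block's valence (steeper,
lower fractal dimension) and arousal (flatter, higher), giving the
configured HFD-rating correlation signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .editing import EMOTIONS, LEVELS
from .eeg import EEGEpochs, RATE, EPOCH_WINDOW
from .errors import ConfigurationError
from .montage import CHANNELS_32, channel_positions

__all__ = ["SimConfig", "simulate_subject", "simulate_experiment"]


def _topography(center_ch: str, width: float) -> np.ndarray:
    """Gaussian spatial pattern on the template, peak 1 at `center_ch`."""
    pos = channel_positions()
    c = pos[CHANNELS_32.index(center_ch)]
    d = np.linalg.norm(pos - c, axis=1)
    return np.exp(-(d**2) / (2 * width**2))


@dataclass
class ComponentSpec:
    """One canonical ERP component."""

    name: str
    center_s: float  # latency of the Gaussian bump
    sigma_s: float  # bump width
    base_uv: float  # baseline amplitude, microvolts
    center_ch: str  # topography peak
    topo_width: float = 0.06  # meters
    emotion_offsets_uv: dict = field(default_factory=dict)
    level_gains: dict = field(
        default_factory=lambda: {"human": 1.0, "level1": 0.85, "level2": 0.7}
    )

    def amplitude(self, emotion: str, level: str) -> float:
        return (
            self.base_uv + self.emotion_offsets_uv.get(emotion, 0.0)
        ) * self.level_gains.get(level, 1.0)


def _default_components() -> list:
    emo_p200 = {"anger": 1.6, "disgust": -0.6, "fear": 0.8, "happiness": 1.2,
                "neutral": -1.2, "sadness": 0.0}
    emo_lpp = {"anger": 1.0, "disgust": 0.4, "fear": 0.8, "happiness": 1.2,
               "neutral": -1.0, "sadness": -0.4}
    return [
        ComponentSpec("P200", 0.200, 0.035, 4.0, "FC1",
                      emotion_offsets_uv=emo_p200),
        ComponentSpec("earlyLPP", 0.550, 0.110, 3.0, "CP1",
                      emotion_offsets_uv=emo_lpp),
        ComponentSpec("lateLPP", 0.850, 0.110, 2.5, "Pz",
                      emotion_offsets_uv=emo_lpp),
    ]


#: per-emotion rating means: valence and arousal on the 1-9 SAM scales
RATING_MEANS = {
    "anger": (2.0, 7.0),
    "disgust": (2.5, 5.0),
    "fear": (2.0, 6.0),
    "happiness": (8.0, 7.0),
    "neutral": (5.0, 3.0),
    "sadness": (2.0, 3.0),
}
#: per-level mean opinion scores (naturalness, intelligibility, 1-5)
MOS_MEANS = {"human": (4.5, 4.6), "level1": (3.4, 3.9), "level2": (2.4, 3.3)}
#: per-level probability of choosing the correct discrete emotion
RECOGNITION_ACCURACY = {"human": 0.851, "level1": 0.748, "level2": 0.68}


@dataclass
class SimConfig:
    """Study-design and signal parameters of the simulated experiment."""

    n_subjects: int = 37
    n_words: int = 24  # trials (words) per emotion x level block
    emotions: tuple = EMOTIONS
    levels: tuple = LEVELS
    components: list = field(default_factory=_default_components)
    noise_sd_uv: float = 9.0  # total noise SD per channel
    noise_exponent: float = 1.0  # 1/f^beta power exponent
    n_noise_sources: int = 6
    subject_latency_sd_s: float = 0.045  # across-subject phase jitter
    trial_latency_sd_s: float = 0.025  # across-word phase jitter
    subject_gain_sd: float = 0.15
    #: amplitude of the idiosyncratic per-subject response signature: a
    #: band-limited waveform fixed across a subject's trials (keeping
    #: across-word coherence high) but independent between subjects
    #: (keeping across-subject coherence partial)
    subject_signature_uv: float = 7.0
    rating_sd: float = 0.8
    # HFD-rating coupling: d(noise exponent)/d(rating z-score); valence
    # steepens the spectrum (lower HFD), arousal flattens it (higher HFD)
    valence_slope_coupling: float = 0.35
    arousal_slope_coupling: float = 0.35
    rate: float = RATE
    window: tuple = EPOCH_WINDOW

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_words < 1:
            raise ConfigurationError("need at least one subject and word")
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ConfigurationError(f"unknown levels {unknown}")
        unknown = set(self.emotions) - set(EMOTIONS)
        if unknown:
            raise ConfigurationError(f"unknown emotions {unknown}")

    @property
    def n_trials_per_subject(self) -> int:
        return self.n_words * len(self.emotions) * len(self.levels)


def _pink_noise(rng, n_samples: int, exponent: float, n_series: int) -> np.ndarray:
    """1/f^exponent (power) Gaussian noise, unit variance per row."""
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((n_series, freqs.size))
            + 1j * rng.standard_normal((n_series, freqs.size))) * scale
    x = np.fft.irfft(spec, n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def _noise_topographies(rng, n_sources: int) -> np.ndarray:
    """Smooth random spatial mixing patterns (sources x channels)."""
    pos = channel_positions()
    centers = pos[rng.integers(0, len(pos), n_sources)]
    widths = rng.uniform(0.04, 0.1, n_sources)
    topo = np.exp(
        -np.linalg.norm(pos[None, :, :] - centers[:, None, :], axis=2) ** 2
        / (2 * widths[:, None] ** 2)
    )
    return topo * rng.choice([-1.0, 1.0], size=(n_sources, 1))


def simulate_subject(cfg: SimConfig, subject: int, seed: int):
    """Simulate all blocks of one subject.

    Returns (EEGEpochs, ratings DataFrame, truth dict).
    """
    rng = np.random.default_rng(seed)
    n_t = int(round((cfg.window[1] - cfg.window[0]) * cfg.rate))
    times = cfg.window[0] + np.arange(n_t) / cfg.rate
    topo = {c.name: _topography(c.center_ch, c.topo_width) for c in cfg.components}
    subj_latency = rng.normal(0.0, cfg.subject_latency_sd_s)
    subj_gain = max(0.2, rng.normal(1.0, cfg.subject_gain_sd))
    mix = _noise_topographies(rng, cfg.n_noise_sources)
    # idiosyncratic evoked signature: 2-15 Hz waveform, post-stimulus
    # envelope, fixed for all of this subject's trials
    sig = _pink_noise(rng, n_t, 1.0, 1)[0]
    from scipy.signal import butter, filtfilt

    b_f, a_f = butter(2, [2.0 / (cfg.rate / 2), 15.0 / (cfg.rate / 2)], "bandpass")
    sig = filtfilt(b_f, a_f, sig)
    env = np.clip((times - 0.0) / 0.15, 0, 1) * np.clip((1.0 - times) / 0.15, 0, 1)
    signature = cfg.subject_signature_uv * (sig / max(sig.std(), 1e-12)) * env
    sig_topo = _topography(["FC1", "Cz", "CP1", "Pz"][rng.integers(0, 4)], 0.08)

    blocks = [(e, l) for l in cfg.levels for e in cfg.emotions]
    rng.shuffle(blocks)
    data = np.empty((len(blocks) * cfg.n_words, len(CHANNELS_32), n_t))
    rows, ratings = [], []
    trial = 0
    for block_id, (emotion, level) in enumerate(blocks):
        v_mean, a_mean = RATING_MEANS[emotion]
        valence = float(np.clip(round(rng.normal(v_mean, cfg.rating_sd)), 1, 9))
        arousal = float(np.clip(round(rng.normal(a_mean, cfg.rating_sd)), 1, 9))
        nat_m, int_m = MOS_MEANS[level]
        naturalness = float(np.clip(round(rng.normal(nat_m, 0.6)), 1, 5))
        intelligibility = float(np.clip(round(rng.normal(int_m, 0.6)), 1, 5))
        acc = RECOGNITION_ACCURACY[level]
        if rng.uniform() < acc:
            chosen = emotion
        else:
            others = [e for e in EMOTIONS if e != emotion]
            chosen = others[rng.integers(0, len(others))]
        ratings.append(
            dict(subject=subject, block=block_id, emotion=emotion, level=level,
                 naturalness=naturalness, intelligibility=intelligibility,
                 valence=valence, arousal=arousal, chosen_emotion=chosen)
        )
        # rating-coupled spectral slope for this block's noise
        v_z = (valence - 5.0) / 2.0
        a_z = (arousal - 5.0) / 2.0
        beta = np.clip(
            cfg.noise_exponent
            + cfg.valence_slope_coupling * v_z
            - cfg.arousal_slope_coupling * a_z,
            0.1,
            2.5,
        )
        for word in range(cfg.n_words):
            trial_latency = rng.normal(0.0, cfg.trial_latency_sd_s)
            latency = subj_latency + trial_latency
            epoch = np.zeros((len(CHANNELS_32), n_t))
            for comp in cfg.components:
                amp = comp.amplitude(emotion, level) * subj_gain
                bump = np.exp(-((times - comp.center_s - latency) ** 2)
                              / (2 * comp.sigma_s**2))
                epoch += amp * topo[comp.name][:, None] * bump[None, :]
            shift = int(round(trial_latency * cfg.rate))
            epoch += sig_topo[:, None] * np.roll(signature, shift)[None, :]
            src = _pink_noise(rng, n_t, float(beta), cfg.n_noise_sources)
            noise = mix.T @ src
            noise += 0.3 * rng.standard_normal(epoch.shape)
            noise *= cfg.noise_sd_uv / noise.std()
            data[trial] = epoch + noise
            rows.append(
                dict(subject=subject, emotion=emotion, level=level,
                     word=f"{emotion}_{word:02d}", block=block_id)
            )
            trial += 1
    labels = pd.DataFrame(rows)
    epochs = EEGEpochs(data, times, labels, list(CHANNELS_32), cfg.rate)
    truth = dict(
        subject=subject,
        seed=seed,
        subject_latency_s=subj_latency,
        subject_gain=subj_gain,
        amplitudes={
            f"{c.name}:{e}:{l}": c.amplitude(e, l)
            for c in cfg.components
            for e in cfg.emotions
            for l in cfg.levels
        },
    )
    return epochs, pd.DataFrame(ratings), truth


def simulate_experiment(cfg: SimConfig, seed: int = 0):
    """Simulate every subject of the experiment.

    Returns (list of per-subject EEGEpochs, ratings table over all
    subjects and blocks, ground-truth dict).  Deterministic in `seed`.
    """
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(0, 2**31 - 1, cfg.n_subjects)
    all_epochs, all_ratings, truths = [], [], []
    for s in range(cfg.n_subjects):
        ep, rt, tr = simulate_subject(cfg, s, int(subject_seeds[s]))
        all_epochs.append(ep)
        all_ratings.append(rt)
        truths.append(tr)
    ratings = pd.concat(all_ratings, ignore_index=True)
    truth = dict(seed=seed, config=asdict(cfg), subjects=truths)
    return all_epochs, ratings, truth
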