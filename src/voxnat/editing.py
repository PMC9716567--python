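"""Naturalness reduction by prosodic and spectral editing.

The edit chain mirrors how commercial concatenative voices deviate from
human speech: lexical-stress contrasts (duration, median pitch) are
flattened with TD-PSOLA on the stressed syllable, syllables are re-joined
with 10 ms linear cross-fades, F2/F3 are shifted down toward F1 by
linear-prediction pole relocation, and harmonics 1 and 4 are attenuated
with parametric EQ.  Every edit is verified against its target and the
comparison collected in an :class:`EditReport`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg

from .audio import Waveform, rescale
from .errors import (
    ConfigurationError,
    ConstraintError,
    EstimationError,
    LengthError,
    UnvoicedError,
)
from .features import (
    _glottal_cycle_marks,
    _resample_to,
    estimate_formants,
    harmonic_spectrum,
    pitch_track_median,
    stress_contrast,
)
from .textgrid import Interval, UtteranceAnnotation

__all__ = [
    "LEVELS",
    "EMOTIONS",
    "EditPlan",
    "EditReport",
    "make_edit_plan",
    "psola_modify",
    "crossfade_concat",
    "shift_formants",
    "attenuate_harmonics",
    "reduce_naturalness",
]

EMOTIONS = ("anger", "disgust", "fear", "happiness", "neutral", "sadness")
LEVELS = ("human", "level1", "level2")
#: emotions whose stressed/unstressed median pitch does not differ; pitch
#: is therefore left unedited for them
PITCH_EDIT_DISABLED = ("fear", "sadness")

#: per-level stress-contrast reduction draws: mean, SD of a normal
#: truncated to [0, 1]
STRESS_REDUCTION = {"human": (0.0, 0.0), "level1": (0.38, 0.15), "level2": (0.74, 0.18)}
#: per-level F2/F3 frequency reduction draws
FORMANT_REDUCTION = {"human": (0.0, 0.0), "level1": (0.12, 0.07), "level2": (0.41, 0.07)}
#: per-level harmonic attenuation (dB) applied to H1 and H4; the editing
#: direction is fixed (softer harmonics at lower naturalness), the
#: magnitude is a package default
HARMONIC_GAIN_DB = {"human": 0.0, "level1": -6.0, "level2": -12.0}


@dataclass
class EditPlan:
    """Targeted edits for one utterance at one naturalness level."""

    level: str
    emotion: str
    r_duration: float  # stress-contrast reduction fraction for duration
    r_pitch: float  # ... for median pitch (ignored if pitch edit disabled)
    ratio_f2_f1: float  # target F2/F1
    ratio_f3_f1: float  # target F3/F1
    gain_h1_db: float
    gain_h4_db: float
    pitch_edit_enabled: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ConfigurationError(f"unknown level {self.level!r}")
        if self.emotion not in EMOTIONS:
            raise ConfigurationError(f"unknown emotion {self.emotion!r}")
        if not (1.0 < self.ratio_f2_f1 < self.ratio_f3_f1):
            raise ConstraintError("formant ratio targets must keep F1 < F2 < F3")

    @property
    def is_identity(self) -> bool:
        return (
            self.r_duration == 0
            and self.r_pitch == 0
            and self.gain_h1_db == 0
            and self.gain_h4_db == 0
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            open(path, "w").write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "EditPlan":
        return cls(**json.load(open(path)))


def make_edit_plan(level: str, profile, emotion: str, seed: int) -> EditPlan:
    """Draw a per-utterance edit plan.

    Reduction fractions are independent truncated-normal draws (per
    feature), so naturalness varies within a level and the reduction is
    non-equidistant across levels.  `profile` supplies the utterance's
    F1..F3 used to anchor the formant-ratio targets.
    """
    if level not in LEVELS:
        raise ConfigurationError(f"unknown level {level!r}")
    if emotion not in EMOTIONS:
        raise ConfigurationError(f"unknown emotion {emotion!r}")
    rng = np.random.default_rng(seed)
    mu_s, sd_s = STRESS_REDUCTION[level]
    mu_f, sd_f = FORMANT_REDUCTION[level]

    def draw(mu, sd, hi=1.0):
        if sd == 0:
            return float(mu)
        return float(np.clip(rng.normal(mu, sd), 0.0, hi))

    r_dur = draw(mu_s, sd_s)
    r_pit = draw(mu_s, sd_s)
    frac2 = draw(mu_f, sd_f, hi=0.9)
    frac3 = draw(mu_f, sd_f, hi=0.9)
    ratio2 = profile.F2 * (1 - frac2) / profile.F1
    ratio3 = profile.F3 * (1 - frac3) / profile.F1
    # preserve the resonance hierarchy F1 < F2 < F3
    ratio2 = max(ratio2, 1.15)
    # keep the F2/F3 targets at least ~1.1*F1 apart so both resonances
    # stay resolvable (the printed per-level ratio means are >= 1.3 apart)
    ratio3 = max(ratio3, ratio2 + 1.1)
    gain = HARMONIC_GAIN_DB[level]
    return EditPlan(
        level=level,
        emotion=emotion,
        r_duration=r_dur,
        r_pitch=r_pit,
        ratio_f2_f1=ratio2,
        ratio_f3_f1=ratio3,
        gain_h1_db=gain,
        gain_h4_db=gain,
        pitch_edit_enabled=emotion not in PITCH_EDIT_DISABLED,
        seed=seed,
    )


# --------------------------------------------------------------------------
# TD-PSOLA
# --------------------------------------------------------------------------

def psola_modify(
    syllable: Waveform, pitch_factor: float = 1.0, duration_factor: float = 1.0
) -> Waveform:
    """Time-domain pitch-synchronous overlap-add modification.

    Hann windows of two local periods are centered at glottal cycle marks;
    synthesis marks are spaced period/pitch_factor apart and mapped back to
    the analysis time axis compressed/stretched by duration_factor, so
    segments are duplicated or dropped as needed.  The windows carry the
    original spectral envelope, leaving formants unchanged.
    """
    if not (0.25 <= pitch_factor <= 4 and 0.25 <= duration_factor <= 4):
        raise ValueError("factors must lie in [0.25, 4]")
    x = syllable.samples
    fs = syllable.rate
    _, f0 = pitch_track_median(syllable)  # raises UnvoicedError when unvoiced
    t_marks, _ = _glottal_cycle_marks(x, fs, f0)
    marks = np.round(t_marks * fs).astype(int)
    if marks.size < 3:
        raise UnvoicedError("too few pitch marks for PSOLA")
    # extrapolate marks beyond the detected range so OLA covers the edges
    d0 = marks[1] - marks[0]
    dn = marks[-1] - marks[-2]
    pre = np.arange(marks[0] - d0, -d0, -d0)[::-1]
    post = np.arange(marks[-1] + dn, x.size + dn, dn)
    marks = np.concatenate((pre, marks, post))
    d = np.diff(marks)
    # forward diff drives the synthesis advance (keeps identity factors
    # phase-locked to the mark grid even when early periods are irregular);
    # the centered average sets the window length
    advance = np.append(d, d[-1]).astype(float)
    periods = np.empty(marks.size)
    periods[0] = d[0]
    periods[-1] = d[-1]
    periods[1:-1] = 0.5 * (d[:-1] + d[1:])

    n_out = int(round(x.size * duration_factor))
    num = np.zeros(n_out)
    den = np.zeros(n_out)
    # start on the (extended) mark grid so identity factors reproduce the
    # input with no sub-period phase offset
    s = float(marks[0]) * duration_factor
    while s < n_out:
        u = s / duration_factor  # position on the analysis axis
        j = int(np.argmin(np.abs(marks - u)))
        half = int(round(periods[j]))
        win = np.hanning(2 * half + 1)
        seg_lo = marks[j] - half
        seg_hi = marks[j] + half + 1
        lo_clip = max(0, -seg_lo)
        hi_clip = max(0, seg_hi - x.size)
        seg = x[seg_lo + lo_clip : seg_hi - hi_clip]
        w = win[lo_clip : win.size - hi_clip]
        out_lo = int(round(s)) - half + lo_clip
        out_hi = out_lo + seg.size
        a = max(0, -out_lo)
        b = max(0, out_hi - n_out)
        if seg.size - a - b > 0:
            num[out_lo + a : out_hi - b] += (seg * w)[a : seg.size - b]
            den[out_lo + a : out_hi - b] += w[a : seg.size - b]
        s += advance[j] / pitch_factor
    out = num / np.maximum(den, 1e-3)
    return replace(syllable, samples=out)


# --------------------------------------------------------------------------
# cross-fade concatenation
# --------------------------------------------------------------------------

def fade_curve(n: int, direction: str) -> np.ndarray:
    """Linear fade gains over n points, spacing (x2 - x1)/(n - 1)."""
    if direction == "in":
        return np.linspace(0.0, 1.0, n)
    if direction == "out":
        return np.linspace(1.0, 0.0, n)
    raise ValueError(direction)


def crossfade_concat(segments, fade_ms: float = 10.0) -> Waveform:
    """Concatenate segments with linear cross-fades at the junctions.

    The fade window spans `fade_ms`: the last fade_ms/2 of the left
    segment is faded out and the first fade_ms/2 of the right segment is
    faded in; segments abut, so the output length is the sum of the
    segment lengths.
    """
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    rate = segments[0].rate
    if any(s.rate != rate for s in segments):
        raise ValueError("segments must share a sample rate")
    n_half = int(round(fade_ms / 2 / 1000 * rate))
    for s in segments:
        if s.samples.size < 2 * n_half:
            raise LengthError(
                f"segment of {s.duration * 1000:.1f} ms shorter than fade window"
            )
    parts = []
    last = len(segments) - 1
    for i, s in enumerate(segments):
        y = s.samples.copy()
        if i > 0:
            y[:n_half] *= fade_curve(n_half, "in")
        if i < last:
            y[-n_half:] *= fade_curve(n_half, "out")
        parts.append(y)
    return replace(segments[0], samples=np.concatenate(parts))


# --------------------------------------------------------------------------
# formant shifting
# --------------------------------------------------------------------------

_SHIFT_RATE = 10000.0
_SHIFT_ORDER = 10


def shift_formants(
    w: Waveform, target_F2: float, target_F3: float, max_iter: int = 20
) -> Waveform:
    """Move F2/F3 to targets by relocating linear-prediction pole angles.

    The signal is decomposed at 10 kHz into a Burg all-pole envelope and
    its excitation residual; the pole pairs closest to the measured F2 and
    F3 are rotated by the requested frequency change (bandwidths kept) and
    the residual is re-filtered, leaving F0 and F1 untouched.  Because
    pole angles and measured formant peaks do not map one-to-one for
    large shifts, the edit is applied as a fixed-point iteration:
    re-measure, correct the residual error, stop when within 1%.
    """
    try:
        F1, F2, F3 = estimate_formants(w)
    except EstimationError:
        # closely spaced resonances: anchor on envelope peaks instead
        pk, _ = _envelope_peaks(w)
        F1 = float(pk[0])
        F2 = float(pk[1]) if pk.size > 1 else target_F2
        F3 = float(pk[2]) if pk.size > 2 else target_F3
    if not (F1 < target_F2 < target_F3 < _SHIFT_RATE / 2):
        raise ConstraintError(
            f"targets must satisfy F1({F1:.0f}) < F2 < F3 < {_SHIFT_RATE / 2:.0f} Hz"
        )
    if abs(target_F2 - F2) < 1e-9 and abs(target_F3 - F3) < 1e-9:
        return replace(w, samples=w.samples.copy())  # identity edit
    try:
        m2_0, m3_0 = formants_near(w, (F2, F3))
    except EstimationError:
        m2_0, m3_0 = F2, F3
    # each trial re-edits the *original* signal with a corrected request,
    # so filtering artifacts never accumulate across iterations
    req2, req3 = target_F2, target_F3
    best_out, best_err = None, np.inf
    for _ in range(max_iter):
        out = _shift_formants_once(w, m2_0, m3_0, req2, req3)
        try:
            m2, m3 = formants_near(out, (target_F2, target_F3))
        except EstimationError:
            if best_out is None:
                best_out = out  # cannot verify further; keep the edit
            break
        err = max(abs(m2 - target_F2) / target_F2, abs(m3 - target_F3) / target_F3)
        if err < best_err:
            best_out, best_err = out, err
        if err < 0.0001:
            break
        # damped request correction: the request->measured map has gain
        # near 2, so a full-step update diverges; 0.7 lightly overshoots,
        # which keeps the terminal residuals centered on zero
        req2 = float(np.clip(req2 + 0.7 * (target_F2 - m2), F1 * 1.1, _SHIFT_RATE / 2 - 300))
        req3 = float(np.clip(req3 + 0.7 * (target_F3 - m3), req2 + 150, _SHIFT_RATE / 2 - 100))
    return best_out


def _envelope_peaks(w: Waveform):
    """Peaks of the order-12 Burg spectral envelope (freqs Hz, heights dB)."""
    fs = 10000.0
    x = _resample_to(w.samples, w.rate, fs)
    alpha = np.exp(-2 * np.pi * 50.0 / fs)
    x = np.append(x[0], x[1:] - alpha * x[:-1])
    x = x * np.hamming(x.size)
    rho, _ = burg(x, order=12, demean=True)
    a = np.concatenate(([1.0], -rho))
    grid, h = sps.freqz([1.0], a, worN=2048, fs=fs)
    env_db = 20.0 * np.log10(np.abs(h) + 1e-12)
    peaks, _ = sps.find_peaks(env_db)
    peaks = peaks[(grid[peaks] > 90) & (grid[peaks] < fs / 2 - 100)]
    if peaks.size == 0:
        raise EstimationError("no spectral-envelope peaks")
    # parabolic refinement of the peak positions
    out = []
    for p in peaks:
        ym1, y0, yp1 = env_db[p - 1], env_db[p], env_db[p + 1]
        denom = ym1 - 2 * y0 + yp1
        delta = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
        out.append(float(grid[p] + np.clip(delta, -1, 1) * (grid[1] - grid[0])))
    return np.array(out), env_db[peaks]


def _root_candidates(w: Waveform) -> np.ndarray:
    """Resonance candidates from order-10 Burg roots (loose bandwidth cut)."""
    try:
        f = estimate_formants(w, n_formants=1, max_bandwidth=600.0,
                              return_all=True)
        return np.asarray(f)
    except EstimationError:
        return np.array([])


def measure_formants(w: Waveform):
    """Formant measurement with fallbacks for heavily edited signals.

    Order-10 Burg roots are the most faithful on clean and
    PSOLA-processed words; order-12 with a looser bandwidth cut resolves
    closely spaced resonances; the order-12 spectral-envelope peaks are
    the last resort when pole pairs merge entirely.
    """
    try:
        return estimate_formants(w)
    except EstimationError:
        pass
    try:
        return estimate_formants(w, order=12, max_bandwidth=600.0)
    except EstimationError:
        freqs, _ = _envelope_peaks(w)
        if freqs.size < 3:
            raise
        return tuple(freqs[:3])


def formants_near(w: Waveform, expected) -> tuple:
    """Measured resonance nearest each expected frequency.

    Candidates come from the order-10 root set (robust against the
    harmonic-induced spurious envelope peaks of high-F0 words); when no
    root candidate lands within 25% of an expected value -- e.g. merged
    resonances after a heavy shift -- the spectral-envelope peaks serve
    as a rescue set.
    """
    roots = _root_candidates(w)
    try:
        env, _ = _envelope_peaks(w)
    except EstimationError:
        env = np.array([])
    out = []
    for e in expected:
        best = np.nan
        if roots.size:
            best = float(roots[np.argmin(np.abs(roots - e))])
        if env.size and (not np.isfinite(best) or abs(best - e) / e > 0.25):
            cand = float(env[np.argmin(np.abs(env - e))])
            if not np.isfinite(best) or abs(cand - e) < abs(best - e):
                best = cand
        if not np.isfinite(best):
            raise EstimationError("no resonance candidates found")
        out.append(best)
    return tuple(out)


def _shift_formants_once(
    w: Waveform, F2: float, F3: float, target_F2: float, target_F3: float
) -> Waveform:
    fs = _SHIFT_RATE
    x = _resample_to(w.samples, w.rate, fs)
    # analyze the pre-emphasized signal so every formant owns a pole pair
    alpha = np.exp(-2 * np.pi * 50.0 / fs)
    xe = np.append(x[0], x[1:] - alpha * x[:-1])
    rho, _ = burg(xe, order=_SHIFT_ORDER, demean=True)
    a_orig = np.concatenate(([1.0], -rho))
    roots = np.roots(a_orig)
    upper = np.where(np.imag(roots) > 0)[0]
    freqs = np.angle(roots[upper]) * fs / (2 * np.pi)
    new_roots = roots.copy()
    for measured, target in ((F2, target_F2), (F3, target_F3)):
        if abs(target - measured) < 1e-9:
            continue
        k = upper[np.argmin(np.abs(freqs - measured))]
        # rotate the pole by the requested frequency change so any small
        # angle-vs-formant bias cancels between analysis and resynthesis;
        # cap the pole bandwidth at 150 Hz so a deep downshift still
        # produces a resonance peak at the pole angle instead of being
        # dragged by the neighboring formant's skirt
        dtheta = 2 * np.pi * (target - measured) / fs
        mag = max(np.abs(roots[k]), np.exp(-np.pi * 150.0 / fs))
        new_roots[k] = mag * np.exp(1j * (np.angle(roots[k]) + dtheta))
        conj = np.argmin(np.abs(roots - np.conj(roots[k])))
        new_roots[conj] = np.conj(new_roots[k])
    a_new = np.real(np.poly(new_roots))
    residual = sps.lfilter(a_orig, [1.0], xe)
    y = sps.lfilter([1.0], a_new, residual)
    y = sps.lfilter([1.0], [1.0, -alpha], y)  # undo pre-emphasis
    out = _resample_to(y, fs, w.rate)
    out = out[: w.samples.size]
    if out.size < w.samples.size:
        out = np.pad(out, (0, w.samples.size - out.size))
    return replace(w, samples=out)


# --------------------------------------------------------------------------
# harmonic attenuation (parametric EQ)
# --------------------------------------------------------------------------

def _peaking_biquad(fc: float, gain_db: float, bw: float, fs: float):
    """RBJ peaking-EQ biquad coefficients (cut for negative gain)."""
    A = 10.0 ** (gain_db / 40.0)
    w0 = 2 * np.pi * fc / fs
    q = fc / bw
    alpha = np.sin(w0) / (2 * q)
    b = np.array([1 + alpha * A, -2 * np.cos(w0), 1 - alpha * A])
    a = np.array([1 + alpha / A, -2 * np.cos(w0), 1 - alpha / A])
    return b / a[0], a / a[0]


def attenuate_harmonics(w: Waveform, gains: dict, f0: float) -> Waveform:
    """Reduce harmonic intensities with narrow peaking-EQ bands.

    `gains` maps harmonic index (1-based) to a non-positive dB gain.  Band
    centers and bandwidths come from the measured harmonic spectrum (width
    at half prominence, clamped to f0/2 so neighboring harmonics stay
    unaffected).  The EQ is applied in the frequency domain (steady-state
    biquad response), so the nominal dB cut is exact at the band center.
    """
    if any(g > 0 for g in gains.values()):
        raise ValueError("gains must be <= 0 dB")
    if all(g == 0 for g in gains.values()):
        return replace(w, samples=w.samples.copy())
    spec = harmonic_spectrum(w, f0, n_harmonics=max(gains))
    n = w.samples.size
    freqs = np.fft.rfftfreq(n, d=1.0 / w.rate)
    # deepest cut wins where bands overlap, so stacked skirts cannot
    # over-attenuate a line that several bands cover
    dip_db = np.zeros(freqs.size)
    peaks, _ = sps.find_peaks(spec.psd_db)
    prom = sps.peak_prominences(spec.psd_db, peaks)[0]
    widths = sps.peak_widths(spec.psd_db, peaks, rel_height=0.5)[0]
    df = spec.freqs[1] - spec.freqs[0]
    for k, gain in gains.items():
        if gain == 0:
            continue
        h = spec.harmonic(k)  # raises MissingHarmonicError when absent
        # a harmonic of an utterance with moving F0 is a band of lines:
        # cut every prominent line within +-f0/2 that is within 20 dB of
        # the strongest one, each with its own half-prominence band
        sel = np.where(
            (np.abs(spec.freqs[peaks] - k * f0) <= f0 / 2)
            & (prom > 3.0)
            & (spec.psd_db[peaks] > h.intensity - 20.0)
        )[0]
        for i in sel:
            fc = float(spec.freqs[peaks[i]])
            bw = float(np.clip(widths[i] * df, 2.0 * w.rate / n, f0 / 2))
            b, a = _peaking_biquad(fc, gain, bw, w.rate)
            _, hz = sps.freqz(b, a, worN=2 * np.pi * freqs / w.rate)
            band_db = np.minimum(20.0 * np.log10(np.abs(hz) + 1e-12), 0.0)
            # flat bottom across the analysis-grid spacing: the nominal
            # cut applies over the line's frequency-measurement
            # uncertainty, not only at the biquad center sample
            band_db[np.abs(freqs - fc) <= df] = gain
            dip_db = np.minimum(dip_db, band_db)
    response = 10.0 ** (dip_db / 20.0)
    y = np.fft.irfft(np.fft.rfft(w.samples) * response, n)

    # one measured touch-up per band: cutting neighboring lines also
    # lowers the leakage pedestal under the main line by a few
    # hundredths of a dB; correct the band so the achieved change at the
    # main line equals the nominal gain
    post = sps.periodogram(
        y[: spec.n_dft] if spec.n_dft < n else y,
        fs=w.rate, window="hamming", nfft=spec.n_dft,
    )[1]
    post_db = 10.0 * np.log10(np.maximum(post, 1e-30))
    touch_db = np.zeros(freqs.size)
    for k, gain in gains.items():
        if gain == 0:
            continue
        h = spec.harmonic(k)
        idx = int(np.argmin(np.abs(spec.freqs - h.frequency)))
        residual = (post_db[idx] - h.intensity) - gain
        if abs(residual) > 1e-6:
            touch_db[np.abs(freqs - k * f0) <= f0 / 2] = -residual
    if np.any(touch_db):
        y = np.fft.irfft(np.fft.rfft(y) * 10.0 ** (touch_db / 20.0), n)
    return replace(w, samples=y)


# --------------------------------------------------------------------------
# full reduction pipeline
# --------------------------------------------------------------------------

@dataclass
class EditReport:
    """Expected vs observed value for every edited feature of one utterance."""

    level: str
    emotion: str
    rows: list = field(default_factory=list)  # dicts: feature, expected, observed

    def add(self, feature: str, expected: float, observed: float) -> None:
        if any(r["feature"] == feature for r in self.rows):
            raise ValueError(f"feature {feature!r} reported twice")
        self.rows.append(
            {"feature": feature, "expected": float(expected), "observed": float(observed)}
        )

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows).assign(level=self.level, emotion=self.emotion)

    def __getitem__(self, feature: str) -> dict:
        for r in self.rows:
            if r["feature"] == feature:
                return r
        raise KeyError(feature)


def _shift_annotation(ann: UtteranceAnnotation, new_durations) -> UtteranceAnnotation:
    """Rebuild syllable/word tiers after the stressed syllable changed length."""
    starts = np.concatenate(([0.0], np.cumsum(new_durations)))
    syl = [
        Interval(starts[i], starts[i + 1], iv.label)
        for i, iv in enumerate(ann.syllables)
    ]
    tiers = {"syllable": syl, "word": [Interval(0.0, starts[-1], ann.word)]}
    if "phone" in ann.tiers:
        tiers["phone"] = list(syl)
    return UtteranceAnnotation(word=ann.word, tiers=tiers)


def reduce_naturalness(
    w: Waveform, ann: UtteranceAnnotation, plan: EditPlan
) -> tuple[Waveform, UtteranceAnnotation, EditReport]:
    """Run the full edit chain for one utterance.

    Order: TD-PSOLA on the stressed syllable -> cross-fade concatenation ->
    F2/F3 shift -> H1/H4 attenuation -> peak normalization.  The report
    compares each edited feature with its target: the post-edit stress
    contrast should equal (1 - r) times the original.
    """
    report = EditReport(level=plan.level, emotion=plan.emotion)

    # --- stress edits on the stressed syllable
    c_dur = stress_contrast(w, ann, "duration").value
    stressed = ann.stressed_interval()
    syl_waves = [w.slice(iv.start, iv.end) for iv in ann.syllables]
    s_idx = ann.stressed_index
    dur_factor = 1.0
    if plan.r_duration > 0:
        new_dur = stressed.duration - plan.r_duration * c_dur
        dur_factor = float(np.clip(new_dur / stressed.duration, 0.25, 4.0))
    pitch_factor = 1.0
    c_pitch = None
    if plan.pitch_edit_enabled and plan.r_pitch > 0:
        c_pitch = stress_contrast(w, ann, "median_pitch").value
        s_med = pitch_track_median(syl_waves[s_idx])[1]
        target_med = s_med - plan.r_pitch * c_pitch
        pitch_factor = float(np.clip(target_med / s_med, 0.25, 4.0))
    if dur_factor != 1.0 or pitch_factor != 1.0:
        syl_waves[s_idx] = psola_modify(syl_waves[s_idx], pitch_factor, dur_factor)

    # --- concatenate with cross-fades
    word = crossfade_concat(syl_waves)
    new_ann = _shift_annotation(ann, [s.duration for s in syl_waves])
    report.add("duration_contrast", (1 - plan.r_duration) * c_dur,
               stress_contrast(word, new_ann, "duration").value)
    if c_pitch is not None:
        report.add("pitch_contrast", (1 - plan.r_pitch) * c_pitch,
                   stress_contrast(word, new_ann, "median_pitch").value)

    # --- spectral edits
    try:
        F1, _, _ = measure_formants(word)
    except EstimationError:
        F1 = float(_envelope_peaks(word)[0][0])  # anchor on the first peak
    target_F2 = plan.ratio_f2_f1 * F1
    target_F3 = plan.ratio_f3_f1 * F1
    word = shift_formants(word, target_F2, target_F3)
    try:
        obs_F2, obs_F3 = formants_near(word, (target_F2, target_F3))
    except EstimationError:
        obs_F2 = obs_F3 = float("nan")
    report.add("F2", target_F2, obs_F2)
    report.add("F3", target_F3, obs_F3)

    _, f0 = pitch_track_median(word)
    gains = {1: plan.gain_h1_db, 4: plan.gain_h4_db}
    pre = harmonic_spectrum(word, f0)
    word = attenuate_harmonics(word, gains, f0)
    post = harmonic_spectrum(word, f0)
    # paired measurement: read the post-edit intensity at the very line
    # measured before the edit, so re-picking a different line cannot
    # masquerade as an edit error
    for k, gain in ((1, plan.gain_h1_db), (4, plan.gain_h4_db)):
        pre_h = pre.harmonic(k)
        idx = int(np.argmin(np.abs(post.freqs - pre_h.frequency)))
        report.add(f"H{k}", pre_h.intensity + gain, float(post.psd_db[idx]))

    word = word.peak_normalized()
    return word, new_ann, report
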