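"""Acoustic feature extraction for single-word emotional utterances.

Implements the measurement battery used to characterize voice naturalness:
autocorrelation pitch tracking (floor 100 Hz, ceiling 600 Hz, 100 frames/s),
cycle-to-cycle perturbation measures (jitter, shimmer), harmonics-to-noise
ratio, Burg-LPC formant estimation, harmonic intensities H1..H4 from a
modified periodogram, their correction for the spectral bias of the first
two formants (H1*..H4*), and stressed-minus-unstressed syllable contrasts.

Conventions: all intensities are 10*log10 of power with reference 1.0 on
peak-normalized amplitude; DFT size is 2**round(log2(N)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from statsmodels.regression.linear_model import burg

from .audio import Waveform, rescale
from .errors import (
    EstimationError,
    InsufficientSyllablesError,
    MissingHarmonicError,
    UnvoicedError,
    VoxnatError,
)
from .textgrid import UtteranceAnnotation

__all__ = [
    "PitchTrack",
    "Harmonic",
    "HarmonicSpectrum",
    "AcousticProfile",
    "StressContrast",
    "pitch_track",
    "pitch_track_median",
    "perturbation_and_hnr",
    "estimate_formants",
    "harmonic_spectrum",
    "correct_harmonic_bias",
    "resonator_gain_db",
    "mean_intensity_db",
    "stress_contrast",
    "acoustic_profile",
    "dft_size",
]

PITCH_FLOOR = 100.0
PITCH_CEILING = 600.0
FRAMES_PER_SECOND = 100
VOICING_THRESHOLD = 0.45
HNR_CAP_DB = 40.0


# --------------------------------------------------------------------------
# pitch
# --------------------------------------------------------------------------

@dataclass
class PitchTrack:
    """Frame-wise fundamental frequency; unvoiced frames hold NaN."""

    times: np.ndarray
    f0: np.ndarray
    strength: np.ndarray  # normalized autocorrelation at the chosen lag
    floor: float = PITCH_FLOOR
    ceiling: float = PITCH_CEILING
    frames_per_second: int = FRAMES_PER_SECOND

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    def median(self) -> float:
        """Median (50% quantile) over voiced frames."""
        v = self.f0[self.voiced]
        if v.size == 0:
            raise UnvoicedError("no voiced frame")
        return float(np.median(v))


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if x.size < frame_len:
        return np.empty((0, frame_len))
    return sliding_window_view(x, frame_len)[::hop]


def pitch_track(
    w: Waveform,
    floor: float = PITCH_FLOOR,
    ceiling: float = PITCH_CEILING,
    frames_per_second: int = FRAMES_PER_SECOND,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> PitchTrack:
    """Autocorrelation pitch tracker.

    Frames of length 3/floor s are Hann-windowed; the normalized
    autocorrelation is divided by the window's own autocorrelation
    (lag-window correction) and its highest peak in the [floor, ceiling]
    lag range, refined by parabolic interpolation, gives the frame F0.
    A frame is voiced when that peak exceeds `voicing_threshold`.
    """
    fs = w.rate
    frame_len = int(round(3.0 / floor * fs))
    if w.samples.size < frame_len:
        raise UnvoicedError(
            f"waveform shorter than one analysis frame ({frame_len / fs:.3f} s)"
        )
    hop = int(round(fs / frames_per_second))
    frames = _frame_signal(w.samples, frame_len, hop)
    frames = frames - frames.mean(axis=1, keepdims=True)
    win = np.hanning(frame_len)
    nfft = int(2 ** np.ceil(np.log2(2 * frame_len)))
    spec = np.fft.rfft(frames * win, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, :frame_len]
    # lag-window correction: divide by the window's own autocorrelation
    wac = np.fft.irfft(np.abs(np.fft.rfft(win, nfft)) ** 2, nfft)[:frame_len]
    wac /= wac[0]
    power = ac[:, 0].copy()
    power[power <= 0] = np.inf
    r = ac / power[:, None] / np.maximum(wac, 1e-6)[None, :]

    lag_min = max(2, int(np.floor(fs / ceiling)))
    lag_max = min(frame_len - 2, int(np.ceil(fs / floor)))
    f0 = np.full(frames.shape[0], np.nan)
    strength = np.zeros(frames.shape[0])
    seg = r[:, lag_min : lag_max + 1]
    # restrict to local maxima so the global ramp near lag 0 cannot win
    interior = (seg[:, 1:-1] >= seg[:, :-2]) & (seg[:, 1:-1] >= seg[:, 2:])
    cand = np.where(interior, seg[:, 1:-1], -np.inf)
    # octave cost: penalize longer lags so the lag-window correction's
    # slight inflation at long lags cannot promote subharmonics
    lags_all = np.arange(lag_min + 1, lag_max)
    octave_penalty = 0.02 * np.log2(lags_all / lag_min)
    best = np.argmax(cand - octave_penalty[None, :], axis=1)
    for i in range(frames.shape[0]):
        j = best[i] + 1 + lag_min
        rv = r[i, j]
        if not np.isfinite(cand[i, best[i]]):
            continue
        strength[i] = rv
        if rv < voicing_threshold:
            continue
        ym1, y0, yp1 = r[i, j - 1], r[i, j], r[i, j + 1]
        denom = ym1 - 2 * y0 + yp1
        delta = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
        lag = j + np.clip(delta, -1, 1)
        cand_f0 = fs / lag
        if floor <= cand_f0 <= ceiling:
            f0[i] = cand_f0
    times = (np.arange(frames.shape[0]) * hop + frame_len / 2) / fs
    return PitchTrack(times, f0, strength, floor, ceiling, frames_per_second)


def pitch_track_median(w: Waveform, **kwargs) -> tuple[PitchTrack, float]:
    """Pitch track plus its median over voiced frames.

    Raises UnvoicedError when no frame is voiced.
    """
    pt = pitch_track(w, **kwargs)
    return pt, pt.median()


# --------------------------------------------------------------------------
# perturbation (jitter/shimmer) and HNR
# --------------------------------------------------------------------------

def _glottal_cycle_marks(x: np.ndarray, fs: float, f0: float):
    """Locate per-cycle peaks with sub-sample refinement.

    Returns (times s, amplitudes); picks the waveform polarity whose cycle
    peaks are larger on average.
    """
    period = fs / f0
    best = None
    for sgn in (1.0, -1.0):
        y = sgn * x
        peaks, _ = sps.find_peaks(y, distance=max(2, int(0.7 * period)))
        if peaks.size < 3:
            continue
        amps = y[peaks]
        if best is None or np.median(amps) > best[2]:
            best = (peaks, amps, float(np.median(amps)), y)
    if best is None:
        raise UnvoicedError("no glottal cycles detected")
    peaks, amps, _, y = best
    # parabolic refinement of peak positions and heights
    p = peaks[(peaks > 0) & (peaks < x.size - 1)]
    ym1, y0, yp1 = y[p - 1], y[p], y[p + 1]
    denom = ym1 - 2 * y0 + yp1
    delta = np.where(denom != 0, 0.5 * (ym1 - yp1) / denom, 0.0)
    delta = np.clip(delta, -1, 1)
    t = (p + delta) / fs
    a = y0 - 0.25 * (ym1 - yp1) * delta
    return t, a


def perturbation_and_hnr(w: Waveform) -> dict:
    """Jitter (local, ppq5), shimmer (local, apq5), mean HNR in dB.

    Periods come from consecutive cycle peaks; jitter_local is the mean
    absolute period difference over the mean period, ppq5 the 5-point
    period quotient, shimmer the same statistics on cycle peak amplitudes
    ("shimmer ppq5" is the 5-point amplitude quotient, apq5).  HNR per
    voiced frame is 10*log10(r / (1 - r)) from the normalized
    autocorrelation peak r, averaged over frames and capped at 40 dB.
    """
    pt = pitch_track(w)
    f0 = pt.median()  # raises UnvoicedError when unvoiced
    t, a = _glottal_cycle_marks(w.samples, w.rate, f0)
    periods = np.diff(t)
    keep = (periods > 0.5 / pt.ceiling) & (periods < 1.5 / pt.floor)
    periods = periods[keep]
    amps = a[1:][keep]
    if periods.size < 5:
        raise UnvoicedError("fewer than 5 detectable periods")

    def local(v: np.ndarray) -> float:
        return float(np.mean(np.abs(np.diff(v))) / np.mean(v))

    def ppq5(v: np.ndarray) -> float:
        if v.size < 5:
            return np.nan
        windows = sliding_window_view(v, 5)
        dev = np.abs(windows[:, 2] - windows.mean(axis=1))
        return float(np.mean(dev) / np.mean(v))

    # frame-wise HNR over voiced frames
    voiced = pt.voiced
    r = np.clip(pt.strength[voiced], 1e-6, None)
    hnr_frames = 10.0 * np.log10(r / np.maximum(1.0 - r, 1e-12))
    hnr = float(np.clip(np.mean(np.clip(hnr_frames, None, HNR_CAP_DB)), None, HNR_CAP_DB))
    return {
        "jitter_local": local(periods),
        "jitter_ppq5": ppq5(periods),
        "shimmer_local": local(amps),
        "shimmer_ppq5": ppq5(amps),
        "hnr": hnr,
    }


# --------------------------------------------------------------------------
# formants
# --------------------------------------------------------------------------

_FORMANT_RATE = 10000.0
_LPC_ORDER = 10
_MAX_BANDWIDTH = 400.0


def _resample_to(x: np.ndarray, fs: float, target: float) -> np.ndarray:
    from fractions import Fraction

    frac = Fraction(int(target), int(fs)).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def estimate_formants(
    w: Waveform,
    n_formants: int = 3,
    return_bandwidths: bool = False,
    order: int = _LPC_ORDER,
    max_bandwidth: float = _MAX_BANDWIDTH,
    return_all: bool = False,
):
    """First three vocal-tract resonances by Burg linear prediction.

    Pre-emphasis from 50 Hz, resampling to 10 kHz, Burg order 10; poles
    with bandwidth < 400 Hz are taken in ascending frequency order.
    Closely spaced formants may need a higher `order` / looser
    `max_bandwidth` to resolve.
    """
    x = _resample_to(w.samples, w.rate, _FORMANT_RATE)
    fs = _FORMANT_RATE
    alpha = np.exp(-2 * np.pi * 50.0 / fs)
    x = np.append(x[0], x[1:] - alpha * x[:-1])
    x = x * np.hamming(x.size)
    if np.allclose(x, 0):
        raise EstimationError("silent input")
    rho, _ = burg(x, order=order, demean=True)
    roots = np.roots(np.concatenate(([1.0], -rho)))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2 * np.pi)
    bws = -fs / np.pi * np.log(np.abs(roots))
    ok = (freqs > 90) & (freqs < fs / 2 - 50) & (bws < max_bandwidth) & (bws > 0)
    freqs, bws = freqs[ok], bws[ok]
    if return_all:
        if freqs.size == 0:
            raise EstimationError("no resonances found")
        return tuple(np.sort(freqs))
    if freqs.size < n_formants:
        raise EstimationError(
            f"only {freqs.size} resonances found (need {n_formants})"
        )
    order = np.argsort(freqs)[:n_formants]
    f = freqs[order]
    b = bws[order]
    if return_bandwidths:
        return tuple(f), tuple(b)
    return tuple(f)


# --------------------------------------------------------------------------
# harmonic spectrum
# --------------------------------------------------------------------------

def dft_size(n_samples: int) -> int:
    """DFT length 2**n with n the nearest integer to log2(N)."""
    return int(2 ** round(np.log2(n_samples)))


@dataclass(frozen=True)
class Harmonic:
    index: int
    frequency: float  # Hz, measured peak position
    intensity: float  # dB
    bandwidth: float  # Hz, width at half prominence
    prominence: float  # dB


@dataclass
class HarmonicSpectrum:
    """Modified-periodogram PSD with the first four harmonic peaks."""

    freqs: np.ndarray
    psd_db: np.ndarray
    n_dft: int
    f0: float
    harmonics: list  # list[Harmonic], indices 1..4
    corrected: dict = field(default_factory=dict)  # {1: H1*, ...} dB

    def harmonic(self, k: int) -> Harmonic:
        for h in self.harmonics:
            if h.index == k:
                return h
        raise MissingHarmonicError(f"harmonic {k} not present")

    def raw(self, k: int) -> float:
        return self.harmonic(k).intensity


def harmonic_spectrum(
    w: Waveform, f0: float, n_harmonics: int = 4
) -> HarmonicSpectrum:
    """Harmonic intensities H1..Hn from a Hamming-window modified periodogram.

    The PSD (dB) peak nearest k*f0 (within +-f0/2) gives Hk; the bandwidth
    is the width where the descending PSD crosses peak - prominence/2.
    """
    x = w.samples
    nfft = dft_size(x.size)
    if nfft < x.size:  # DFT shorter than the signal: analyze the first nfft samples
        x = x[:nfft]
    freqs, pxx = sps.periodogram(x, fs=w.rate, window="hamming", nfft=nfft)
    psd_db = 10.0 * np.log10(np.maximum(pxx, 1e-30))
    peaks, _ = sps.find_peaks(psd_db)
    prominences = sps.peak_prominences(psd_db, peaks)[0]
    widths = sps.peak_widths(psd_db, peaks, rel_height=0.5)[0]
    df = freqs[1] - freqs[0]
    harmonics = []
    top = psd_db[peaks].max() if peaks.size else -np.inf
    for k in range(1, n_harmonics + 1):
        target = k * f0
        in_win = np.abs(freqs[peaks] - target) <= f0 / 2
        # a harmonic must be prominent and within 55 dB of the strongest
        # peak: genuine lines sitting in a spectral valley stay well
        # inside that band, while far window-leakage sidelobes of a
        # strong line fall below it
        cand = np.where(
            in_win & (prominences > 3.0) & (psd_db[peaks] > top - 55.0)
        )[0]
        if cand.size == 0:
            raise MissingHarmonicError(
                f"no peak within +-{f0 / 2:.0f} Hz of harmonic {k} ({target:.0f} Hz)"
            )
        best = cand[np.argmax(psd_db[peaks[cand]])]
        harmonics.append(
            Harmonic(
                index=k,
                frequency=float(freqs[peaks[best]]),
                intensity=float(psd_db[peaks[best]]),
                bandwidth=float(widths[best] * df),
                prominence=float(prominences[best]),
            )
        )
    return HarmonicSpectrum(freqs, psd_db, nfft, f0, harmonics)


def resonator_gain_db(f, formant: float, bandwidth: float, rate: float) -> np.ndarray:
    """Gain (dB, relative to DC) of a two-pole resonance at frequency f."""
    f = np.asarray(f, dtype=float)
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2 * np.pi * formant / rate
    omega = 2 * np.pi * f / rate
    pole1 = r * np.exp(1j * theta)
    pole2 = r * np.exp(-1j * theta)
    z = np.exp(-1j * omega)
    denom = np.abs(1 - pole1 * z) * np.abs(1 - pole2 * z)
    dc = np.abs(1 - pole1) * np.abs(1 - pole2)
    return 20.0 * np.log10(dc / denom)


def correct_harmonic_bias(
    h: HarmonicSpectrum,
    F1: float,
    F2: float,
    B1: float,
    B2: float,
    rate: float,
) -> dict:
    """Remove the spectral boost of formants 1-2 from the harmonic intensities.

    Hk* = Hk - sum_i gain_dB(fk; Fi, Bi), the gain being that of a
    two-pole resonance normalized at DC, so the corrected values estimate
    the source spectrum independent of where the harmonics sit relative
    to the formant peaks.
    """
    if B1 <= 0 or B2 <= 0:
        raise ValueError("formant bandwidths must be positive")
    corrected = {}
    for harm in h.harmonics:
        if harm.frequency >= rate / 2:
            raise VoxnatError(
                f"harmonic at {harm.frequency:.0f} Hz is above Nyquist"
            )
        gain = resonator_gain_db(harm.frequency, F1, B1, rate) + resonator_gain_db(
            harm.frequency, F2, B2, rate
        )
        corrected[harm.index] = float(harm.intensity - gain)
    h.corrected = corrected
    return corrected


# --------------------------------------------------------------------------
# profiles and stress contrasts
# --------------------------------------------------------------------------

def mean_intensity_db(x: np.ndarray) -> float:
    """Mean intensity: 10*log10 of mean power, reference 1.0."""
    p = float(np.mean(np.asarray(x, dtype=float) ** 2))
    if p <= 0:
        raise UnvoicedError("silent segment has no intensity")
    return 10.0 * np.log10(p)


@dataclass
class AcousticProfile:
    """Per-utterance feature vector."""

    median_pitch: float
    duration: float
    mean_intensity: float
    jitter_local: float
    jitter_ppq5: float
    shimmer_local: float
    shimmer_ppq5: float
    hnr: float
    F1: float
    F2: float
    F3: float
    H1c: float  # H1* .. H4*: harmonic intensities corrected for formant bias
    H2c: float
    H3c: float
    H4c: float

    COLUMNS = (
        "median_pitch duration mean_intensity jitter_local jitter_ppq5 "
        "shimmer_local shimmer_ppq5 hnr F1 F2 F3 H1c H2c H3c H4c"
    ).split()

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


def profiles_to_csv(profiles, path, names=None) -> None:
    """Write one profile row per utterance in fixed column order."""
    import pandas as pd

    df = pd.DataFrame([p.as_dict() for p in profiles], columns=AcousticProfile.COLUMNS)
    if names is not None:
        df.insert(0, "utterance", list(names))
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class StressContrast:
    feature: str  # duration | median_pitch | mean_intensity
    value: float  # stressed minus unstressed


def stress_contrast(
    w: Waveform, ann: UtteranceAnnotation, feature: str
) -> StressContrast:
    """Stressed-minus-unstressed syllable contrast.

    Duration: stressed duration minus the mean unstressed duration.
    Pitch / intensity: measured on the stressed syllable minus on the
    concatenation of all unstressed syllables.
    """
    if len(ann.syllables) < 2:
        raise InsufficientSyllablesError("monosyllabic word has no contrast")
    stressed = ann.stressed_interval()
    unstressed = ann.unstressed_intervals()
    if not unstressed:
        raise InsufficientSyllablesError("no unstressed syllable")
    if feature == "duration":
        value = stressed.duration - float(np.mean([iv.duration for iv in unstressed]))
        return StressContrast(feature, value)
    s_seg = w.slice(stressed.start, stressed.end)
    u_samples = np.concatenate(
        [w.slice(iv.start, iv.end).samples for iv in unstressed]
    )
    u_seg = Waveform(u_samples, rate=w.rate, bit_depth=w.bit_depth)
    if feature == "median_pitch":
        value = pitch_track_median(s_seg)[1] - pitch_track_median(u_seg)[1]
    elif feature == "mean_intensity":
        value = mean_intensity_db(s_seg.samples) - mean_intensity_db(u_seg.samples)
    else:
        raise ValueError(f"unknown feature {feature!r}")
    return StressContrast(feature, value)


def acoustic_profile(w: Waveform, f0: float | None = None) -> AcousticProfile:
    """Full feature battery on one peak-normalized utterance."""
    wn = w.peak_normalized()
    pt, median_pitch = pitch_track_median(wn)
    if f0 is None:
        f0 = median_pitch
    pert = perturbation_and_hnr(wn)
    (F1, F2, F3), (B1, B2, _) = estimate_formants(wn, return_bandwidths=True)
    spec = harmonic_spectrum(wn, f0)
    corr = correct_harmonic_bias(spec, F1, F2, B1, B2, wn.rate)
    return AcousticProfile(
        median_pitch=median_pitch,
        duration=wn.duration,
        mean_intensity=mean_intensity_db(wn.samples),
        F1=F1,
        F2=F2,
        F3=F3,
        H1c=corr[1],
        H2c=corr[2],
        H3c=corr[3],
        H4c=corr[4],
        **pert,
    )
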