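import numpy as np
import pytest

from conftest import pulse_vowel
from voxnat.audio import Waveform
from voxnat.errors import (
    EstimationError,
    InsufficientSyllablesError,
    MissingHarmonicError,
    UnvoicedError,
)
from voxnat.features import (
    correct_harmonic_bias,
    dft_size,
    estimate_formants,
    harmonic_spectrum,
    perturbation_and_hnr,
    pitch_track_median,
    resonator_gain_db,
    stress_contrast,
)
from voxnat.synth_speech import SpeechSpec, synth_utterance


# --------------------------------------------------------------------------
# pitch
# --------------------------------------------------------------------------

def test_median_pitch_on_pulse_vowel():
    w = Waveform(pulse_vowel(f0=200.0, dur=0.5))
    _, med = pitch_track_median(w)
    assert abs(med - 200.0) <= 2.0


def test_median_pitch_majority_of_frames():
    # 0.3 s at 150 Hz followed by 0.2 s at 300 Hz: the median sits with
    # the more numerous 150 Hz frames
    x = np.concatenate([pulse_vowel(150.0, 0.3), pulse_vowel(300.0, 0.2)])
    _, med = pitch_track_median(Waveform(x))
    assert abs(med - 150.0) <= 3.0


def test_white_noise_is_unvoiced(rng):
    with pytest.raises(UnvoicedError):
        pitch_track_median(Waveform(rng.standard_normal(24000)))


def test_median_pitch_amplitude_invariance():
    w = Waveform(pulse_vowel(220.0, 0.4))
    _, med1 = pitch_track_median(w)
    _, med2 = pitch_track_median(Waveform(w.samples * 0.05))
    assert med1 == pytest.approx(med2, abs=1e-9)


# --------------------------------------------------------------------------
# perturbation and HNR
# --------------------------------------------------------------------------

def test_perturbation_zero_on_strictly_periodic():
    period = np.zeros(240)  # 200 Hz at 48 kHz
    period[:40] = np.hanning(40)
    x = np.tile(period, 100)
    res = perturbation_and_hnr(Waveform(x))
    assert res["jitter_local"] <= 1e-12  # zero up to float interpolation noise
    assert res["shimmer_local"] <= 1e-12
    assert res["hnr"] >= 39.0  # capped at 40 dB for numerically periodic input


def test_jitter_local_hand_formula():
    # alternating short/long periods (10% apart, like 10 vs 11 ms but
    # inside the tracker's 100-600 Hz range): jitter_local must equal
    # mean |T_i - T_{i-1}| / mean T of the realized period sequence
    fs = 48000
    periods = np.array([int(8.0 * fs / 1000), int(8.8 * fs / 1000)] * 30)
    pos = np.concatenate(([0], np.cumsum(periods)))
    x = np.zeros(pos[-1] + 1)
    x[pos] = 1.0
    expected = np.mean(np.abs(np.diff(periods))) / np.mean(periods)
    res = perturbation_and_hnr(Waveform(x, rate=fs))
    assert res["jitter_local"] == pytest.approx(expected, rel=0.02)


def test_hnr_zero_at_equal_signal_and_noise_power(rng):
    t = np.arange(48000) / 48000
    h = sum(np.sin(2 * np.pi * 200 * (k + 1) * t) / (k + 1) for k in range(6))
    h /= h.std()
    x = h + rng.standard_normal(48000)
    res = perturbation_and_hnr(Waveform(x))
    assert abs(res["hnr"]) <= 1.0


def test_jitter_shimmer_monotone_in_noise():
    jits, shims = [], []
    for sd in (0.0, 0.01, 0.03):
        vals = []
        for seed in range(3):
            spec = SpeechSpec(
                durations=(0.4, 0.2), f0s=(200.0, 200.0), intensities_db=(0.0, 0.0),
                stressed_index=0, jitter_sd=sd, shimmer_sd=sd, seed=seed,
                noise_floor_db=None,
            )
            w, _, _ = synth_utterance(spec)
            res = perturbation_and_hnr(w)
            vals.append((res["jitter_local"], res["shimmer_local"]))
        jits.append(np.mean([v[0] for v in vals]))
        shims.append(np.mean([v[1] for v in vals]))
    assert jits[0] < jits[1] < jits[2]
    assert shims[0] < shims[1] < shims[2]


def test_perturbation_unvoiced_error(rng):
    with pytest.raises(UnvoicedError):
        perturbation_and_hnr(Waveform(rng.standard_normal(24000)))


# --------------------------------------------------------------------------
# formants
# --------------------------------------------------------------------------

@pytest.mark.parametrize("formants", [(500, 1500, 2500), (700, 1200, 2600)])
def test_formant_recovery(formants):
    bws = (80, 120, 160)
    w = Waveform(pulse_vowel(120.0, 0.5, formants=tuple(zip(formants, bws))))
    est = estimate_formants(w)
    assert est[0] < est[1] < est[2]
    for got, want in zip(est, formants):
        assert abs(got - want) / want < 0.05


def test_pure_sine_has_no_formant_structure():
    t = np.arange(24000) / 48000.0
    with pytest.raises(EstimationError):
        estimate_formants(Waveform(np.sin(2 * np.pi * 500 * t)))


# --------------------------------------------------------------------------
# harmonic spectrum
# --------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(48000, 65536), (1000, 1024), (1500, 2048)])
def test_dft_size_examples(n, expected):
    assert dft_size(n) == expected


def test_dft_size_rounding_rule():
    for n in np.unique(np.logspace(1, 6, 300).astype(int)):
        assert abs(np.log2(dft_size(int(n))) - np.log2(n)) <= 0.5 + 1e-12


def four_harmonic_complex(powers=(1.0, 0.25, 0.1, 0.05), f0=200.0, dur=0.5, fs=48000):
    t = np.arange(int(dur * fs)) / fs
    amps = np.sqrt(np.asarray(powers))
    y = sum(a * np.sin(2 * np.pi * f0 * (k + 1) * t) for k, a in enumerate(amps))
    return Waveform(y / np.max(np.abs(y)), rate=fs)


def test_harmonic_intensities():
    w = four_harmonic_complex()
    spec = harmonic_spectrum(w, 200.0)
    assert spec.n_dft == dft_size(w.samples.size)
    assert spec.raw(2) - spec.raw(1) == pytest.approx(-6.0, abs=1.0)
    for h in spec.harmonics:
        assert abs(h.frequency - h.index * 200.0) <= 100.0
        assert h.bandwidth > 0


def test_missing_harmonic_error():
    w = four_harmonic_complex(powers=(1.0, 0.0, 0.1, 0.05))
    with pytest.raises(MissingHarmonicError):
        harmonic_spectrum(w, 200.0)


# --------------------------------------------------------------------------
# formant-bias correction
# --------------------------------------------------------------------------

def test_bias_correction_far_formants_is_identity():
    w = four_harmonic_complex()
    spec = harmonic_spectrum(w, 200.0)
    corrected = correct_harmonic_bias(spec, 20000.0, 22000.0, 200.0, 200.0, w.rate)
    for h in spec.harmonics:
        assert corrected[h.index] == pytest.approx(h.intensity, abs=0.1)


def test_bias_correction_recovers_source_tilt():
    # flat source through two known resonators: corrected harmonics
    # should be flat again (within 1 dB)
    from scipy import signal as sps

    fs = 48000
    t = np.arange(int(0.5 * fs)) / fs
    y = sum(np.sin(2 * np.pi * 150 * (k + 1) * t) for k in range(4))
    for f, bw in ((500.0, 80.0), (1500.0, 120.0)):
        r = np.exp(-np.pi * bw / fs)
        th = 2 * np.pi * f / fs
        b = [1 - 2 * r * np.cos(th) + r * r]
        a = [1, -2 * r * np.cos(th), r * r]
        y = sps.lfilter(b, a, y)
    w = Waveform(y / np.max(np.abs(y)), rate=fs)
    spec = harmonic_spectrum(w, 150.0)
    corrected = correct_harmonic_bias(spec, 500.0, 1500.0, 80.0, 120.0, fs)
    assert abs(corrected[1] - corrected[2]) <= 1.0
    assert abs(corrected[1] - corrected[4]) <= 1.5


def test_bias_correction_stable_when_formant_moves_onto_harmonic():
    # analytic oracle: raw intensities = source + resonator gains; moving
    # F1 onto H2 changes the raw H2 but the corrected H2* must not move
    f0 = 200.0
    fs = 48000.0
    source_db = np.array([0.0, -6.0, -10.0, -13.0])
    h_freqs = f0 * np.arange(1, 5)

    def corrected_for(F1):
        from voxnat.features import Harmonic, HarmonicSpectrum

        gains = resonator_gain_db(h_freqs, F1, 90.0, fs) + resonator_gain_db(
            h_freqs, 1500.0, 120.0, fs
        )
        harms = [
            Harmonic(k + 1, h_freqs[k], source_db[k] + gains[k], 10.0, 30.0)
            for k in range(4)
        ]
        spec = HarmonicSpectrum(
            np.linspace(0, fs / 2, 100), np.zeros(100), 65536, f0, harms
        )
        return correct_harmonic_bias(spec, F1, 1500.0, 90.0, 120.0, fs)

    far = corrected_for(700.0)
    on_h2 = corrected_for(400.0)  # F1 right on the 2nd harmonic
    assert on_h2[2] == pytest.approx(far[2], abs=1.0)


def test_resonator_gain_at_peak_positive():
    g = resonator_gain_db(500.0, 500.0, 80.0, 48000.0)
    assert g > 10.0


# --------------------------------------------------------------------------
# stress contrasts
# --------------------------------------------------------------------------

def test_duration_contrast_arithmetic():
    from voxnat.textgrid import Interval, UtteranceAnnotation

    syl = [
        Interval(0.0, 0.15, "a"),
        Interval(0.15, 0.45, "b*"),
        Interval(0.45, 0.70, "c"),
    ]
    ann = UtteranceAnnotation(word="x", tiers={"syllable": syl})
    w = Waveform(np.ones(int(0.7 * 48000)))
    c = stress_contrast(w, ann, "duration")
    assert c.value == pytest.approx(0.30 - 0.20, abs=1e-9)


def test_pitch_contrast_from_synthesis(vowel_word):
    w, ann, _ = vowel_word
    c = stress_contrast(w, ann, "median_pitch")
    assert c.value == pytest.approx(40.0, abs=4.0)


def test_intensity_contrast_sign(vowel_word):
    w, ann, _ = vowel_word
    c = stress_contrast(w, ann, "mean_intensity")
    assert c.value > 0  # stressed syllable synthesized 3 dB louder


def test_monosyllable_rejected():
    from voxnat.textgrid import Interval, UtteranceAnnotation

    ann = UtteranceAnnotation(
        word="x", tiers={"syllable": [Interval(0.0, 0.3, "a*")]}
    )
    w = Waveform(np.ones(48000))
    with pytest.raises(InsufficientSyllablesError):
        stress_contrast(w, ann, "duration")
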