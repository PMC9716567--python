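import numpy as np
import pytest

from conftest import pulse_vowel
from voxnat.audio import Waveform
from voxnat.editing import (
    EditPlan,
    attenuate_harmonics,
    crossfade_concat,
    fade_curve,
    formants_near,
    make_edit_plan,
    measure_formants,
    psola_modify,
    reduce_naturalness,
    shift_formants,
)
from voxnat.errors import (
    ConfigurationError,
    ConstraintError,
    LengthError,
    UnvoicedError,
)
from voxnat.features import (
    acoustic_profile,
    harmonic_spectrum,
    pitch_track_median,
    stress_contrast,
)


# --------------------------------------------------------------------------
# edit plans
# --------------------------------------------------------------------------

def test_level1_draw_moments(vowel_word):
    profile = acoustic_profile(vowel_word[0])
    rs = [
        make_edit_plan("level1", profile, "anger", seed=s).r_duration
        for s in range(1000)
    ]
    assert np.mean(rs) == pytest.approx(0.38, abs=0.02)
    assert np.std(rs) == pytest.approx(0.15, abs=0.02)


def test_level2_draw_moments(vowel_word):
    profile = acoustic_profile(vowel_word[0])
    rs = [
        make_edit_plan("level2", profile, "anger", seed=s).r_duration
        for s in range(1000)
    ]
    # truncation to [0, 1] pulls the level-2 moments slightly inward
    assert np.mean(rs) == pytest.approx(0.74, abs=0.03)
    assert np.std(rs) == pytest.approx(0.18, abs=0.03)


@pytest.mark.parametrize("emotion,enabled", [("fear", False), ("sadness", False),
                                             ("anger", True), ("neutral", True)])
def test_pitch_edit_gating(vowel_word, emotion, enabled):
    profile = acoustic_profile(vowel_word[0])
    plan = make_edit_plan("level1", profile, emotion, seed=0)
    assert plan.pitch_edit_enabled is enabled


def test_human_plan_is_identity(vowel_word):
    profile = acoustic_profile(vowel_word[0])
    plan = make_edit_plan("human", profile, "neutral", seed=0)
    assert plan.is_identity
    assert plan.ratio_f2_f1 == pytest.approx(profile.F2 / profile.F1)


def test_unknown_level_and_emotion_rejected(vowel_word):
    profile = acoustic_profile(vowel_word[0])
    with pytest.raises(ConfigurationError):
        make_edit_plan("level3", profile, "anger", seed=0)
    with pytest.raises(ConfigurationError):
        make_edit_plan("level1", profile, "boredom", seed=0)


def test_plan_json_roundtrip(tmp_path, vowel_word):
    profile = acoustic_profile(vowel_word[0])
    plan = make_edit_plan("level2", profile, "disgust", seed=5)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    assert EditPlan.from_json(path) == plan


# --------------------------------------------------------------------------
# TD-PSOLA
# --------------------------------------------------------------------------

def syllable(vowel_word):
    w, ann, _ = vowel_word
    iv = ann.stressed_interval()
    return w.slice(iv.start, iv.end)


def test_psola_pitch_shift(vowel_word):
    syl = syllable(vowel_word)  # 240 Hz stressed syllable
    out = psola_modify(syl, pitch_factor=0.8)
    _, med = pitch_track_median(out)
    assert med == pytest.approx(0.8 * 240.0, rel=0.03)


def test_psola_duration_stretch(vowel_word):
    syl = syllable(vowel_word)
    out = psola_modify(syl, duration_factor=1.5)
    period = syl.rate / 240.0
    assert abs(out.samples.size - 1.5 * syl.samples.size) <= period


def test_psola_identity(vowel_word):
    syl = syllable(vowel_word)
    out = psola_modify(syl, 1.0, 1.0)
    n = min(out.samples.size, syl.samples.size)
    r = np.corrcoef(out.samples[:n], syl.samples[:n])[0, 1]
    assert r > 0.99


def test_psola_composition(vowel_word):
    syl = syllable(vowel_word)
    once = psola_modify(psola_modify(syl, 0.8, 1.0), 1.5, 1.0)
    _, med = pitch_track_median(once)
    assert med == pytest.approx(240.0 * 0.8 * 1.5, rel=0.05)


def test_psola_preserves_formants(vowel_word):
    from voxnat.features import estimate_formants

    syl = syllable(vowel_word)
    before = estimate_formants(syl)
    after = estimate_formants(psola_modify(syl, 0.8, 1.3))
    # F2/F3 stay within 5%; F1 gets a wider band because the LPC
    # estimator's low-formant bias moves with F0, not because the
    # envelope changed
    assert abs(after[0] - before[0]) / before[0] < 0.10
    for b, a in zip(before[1:], after[1:]):
        assert abs(a - b) / b < 0.05


def test_psola_unvoiced_error(rng):
    with pytest.raises(UnvoicedError):
        psola_modify(Waveform(rng.standard_normal(24000)), 0.8)


def test_psola_factor_bounds(vowel_word):
    with pytest.raises(ValueError):
        psola_modify(syllable(vowel_word), pitch_factor=0.1)


# --------------------------------------------------------------------------
# cross-fade concatenation
# --------------------------------------------------------------------------

def test_fade_curve_five_points():
    np.testing.assert_allclose(fade_curve(5, "in"), [0, 0.25, 0.5, 0.75, 1])
    np.testing.assert_allclose(
        fade_curve(5, "in") + fade_curve(5, "out"), np.ones(5)
    )


def test_crossfade_lengths_and_junction(vowel_word):
    w = vowel_word[0]
    segs = [w.slice(0.0, 0.2), w.slice(0.2, 0.46), w.slice(0.46, 0.64)]
    out = crossfade_concat(segs)
    assert out.samples.size == sum(s.samples.size for s in segs)

    # junction smoothness on DC segments: the first difference is bounded
    # by the linear ramp slope
    dc = [Waveform(np.ones(4800)), Waveform(np.ones(4800))]
    joined = crossfade_concat(dc)
    bound = 1.0 / (0.005 * 48000) * 1.01
    assert np.max(np.abs(np.diff(joined.samples))) < bound


def test_crossfade_short_segment_rejected():
    with pytest.raises(LengthError):
        crossfade_concat([Waveform(np.ones(100)), Waveform(np.ones(4800))])


# --------------------------------------------------------------------------
# formant shifting
# --------------------------------------------------------------------------

def test_shift_formants_to_level2_ratios():
    # a vowel near the printed human means (F1 500, F2 1400, F3 2550)
    # shifted to the level-2 ratio targets F2/F1 = 1.7, F3/F1 = 3.0
    w = Waveform(pulse_vowel(120.0, 0.5, formants=((500, 80), (1400, 120), (2550, 160))))
    F1 = measure_formants(w)[0]
    t2, t3 = 1.7 * F1, 3.0 * F1
    out = shift_formants(w, t2, t3)
    m2, m3 = formants_near(out, (t2, t3))
    assert abs(m2 - t2) / t2 < 0.05
    assert abs(m3 - t3) / t3 < 0.05
    # F1 and F0 untouched
    assert formants_near(out, (F1,))[0] == pytest.approx(F1, rel=0.05)
    assert pitch_track_median(out)[1] == pytest.approx(120.0, rel=0.05)


def test_shift_formants_identity(vowel_word):
    w = vowel_word[0]
    from voxnat.features import estimate_formants

    _, F2, F3 = estimate_formants(w)
    out = shift_formants(w, F2, F3)
    np.testing.assert_array_equal(out.samples, w.samples)


def test_shift_formants_hierarchy_guard(vowel_word):
    with pytest.raises(ConstraintError):
        shift_formants(vowel_word[0], 300.0, 2000.0)  # F2 below F1


# --------------------------------------------------------------------------
# harmonic attenuation
# --------------------------------------------------------------------------

def test_attenuate_h1(vowel_word):
    w = vowel_word[0].peak_normalized()
    _, f0 = pitch_track_median(w)
    pre = harmonic_spectrum(w, f0)
    out = attenuate_harmonics(w, {1: -6.0, 4: 0.0}, f0)
    post = harmonic_spectrum(out, f0)
    assert post.raw(1) - pre.raw(1) == pytest.approx(-6.0, abs=1.0)
    assert abs(post.raw(2) - pre.raw(2)) < 1.0
    assert abs(post.raw(3) - pre.raw(3)) < 1.0


def test_attenuate_h4_after_bias_correction(vowel_word):
    from voxnat.features import correct_harmonic_bias, estimate_formants

    w = vowel_word[0].peak_normalized()
    _, f0 = pitch_track_median(w)
    (F1, F2, _), (B1, B2, _) = estimate_formants(w, return_bandwidths=True)
    pre = harmonic_spectrum(w, f0)
    pre_c = correct_harmonic_bias(pre, F1, F2, B1, B2, w.rate)
    out = attenuate_harmonics(w, {1: 0.0, 4: -12.0}, f0)
    post = harmonic_spectrum(out, f0)
    post_c = correct_harmonic_bias(post, F1, F2, B1, B2, w.rate)
    assert post_c[4] - pre_c[4] == pytest.approx(-12.0, abs=1.0)


def test_attenuate_zero_gain_is_identity(vowel_word):
    w = vowel_word[0]
    _, f0 = pitch_track_median(w)
    out = attenuate_harmonics(w, {1: 0.0, 4: 0.0}, f0)
    np.testing.assert_array_equal(out.samples, w.samples)


def test_attenuate_positive_gain_rejected(vowel_word):
    with pytest.raises(ValueError):
        attenuate_harmonics(vowel_word[0], {1: 3.0}, 200.0)


# --------------------------------------------------------------------------
# full reduction
# --------------------------------------------------------------------------

def test_reduce_level2_duration_contrast(vowel_word):
    w, ann, _ = vowel_word
    profile = acoustic_profile(w)
    plan = make_edit_plan("level2", profile, "anger", seed=3)
    plan.r_duration = 0.74
    orig = stress_contrast(w, ann, "duration").value
    out, new_ann, report = reduce_naturalness(w, ann, plan)
    got = stress_contrast(out, new_ann, "duration").value
    assert got == pytest.approx((1 - 0.74) * orig, rel=0.10)
    assert np.max(np.abs(out.samples)) == pytest.approx(1.0)


def test_reduce_identity_plan(vowel_word):
    w, ann, _ = vowel_word
    profile = acoustic_profile(w)
    plan = make_edit_plan("human", profile, "neutral", seed=0)
    out, new_ann, report = reduce_naturalness(w, ann, plan)
    dur = report["duration_contrast"]
    assert dur["expected"] == pytest.approx(dur["observed"], abs=1e-6)
    h1 = report["H1"]
    assert h1["expected"] == pytest.approx(h1["observed"], abs=0.5)


def test_report_features_unique(vowel_word):
    w, ann, _ = vowel_word
    plan = make_edit_plan("level1", acoustic_profile(w), "happiness", seed=2)
    _, _, report = reduce_naturalness(w, ann, plan)
    feats = [r["feature"] for r in report.rows]
    assert len(feats) == len(set(feats))
    assert {"duration_contrast", "pitch_contrast", "F2", "F3", "H1", "H4"} <= set(feats)
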