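# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `voxnat`. It describes what the code computes;
every number quoted as a behavior of the package is produced by the
test suite or by `scripts/acceptance.py`, not asserted from memory.

## 1. Acoustic measurement battery

**Pitch.** Autocorrelation tracking on 30 ms (3/floor) Hann-windowed
frames at 100 frames/s, floor 100 Hz, ceiling 600 Hz. The frame
autocorrelation is divided by the window's own autocorrelation
(lag-window correction), the highest interior peak in the lag band is
refined by parabolic interpolation, and a frame is voiced when the
corrected peak exceeds 0.45. An octave cost of 0.02·log₂(lag/lag_min)
penalizes longer lags: without it, the lag-window correction's slight
inflation at long lags (≈ +0.001) can promote subharmonics; a larger
cost (0.1) was found to cause octave-up errors on harmonically thinned
signals (e.g. after H1 attenuation), so the penalty is deliberately
small. Median pitch is the 50 % quantile over voiced frames only;
unvoiced gaps are not interpolated.

**Jitter, shimmer, HNR.** Glottal cycle marks are waveform peaks
(polarity chosen by the larger median peak, sub-sample parabolic
refinement). jitter_local = mean |Tᵢ−Tᵢ₋₁| / mean T; ppq5 is the
five-point period quotient; shimmer analogues act on cycle peak
amplitudes, and "shimmer ppq5" is read as the five-point amplitude
quotient (apq5 in Praat nomenclature). HNR per voiced frame is
10·log₁₀(r/(1−r)) from the corrected autocorrelation peak r, averaged
over frames and capped at 40 dB for numerically periodic signals.

**Formants.** Pre-emphasis from 50 Hz, resampling to 10 kHz, Burg
linear prediction of order 10; roots with bandwidth < 400 Hz are taken
in ascending frequency. The estimator recovers synthetic resonators
within ≈ 5 % for F0 up to ≈ 250 Hz; the known LPC low-formant bias
moves with F0, which matters when comparing measurements across a pitch
edit (the PSOLA test therefore holds F1 to 10 % and F2/F3 to 5 %).
Heavily edited words get fallbacks: order 12 with a 600 Hz bandwidth
cut, then the peaks of the order-12 spectral envelope. For verifying
edits, candidates are matched *nearest to the expected frequency*
(order-10 roots first, envelope peaks as a rescue when poles merge);
anchoring at the target prevents harmonic-induced spurious envelope
peaks of high-F0 words from being mislabeled as formants.

**Harmonics and formant-bias correction.** The PSD is one modified
periodogram of the whole utterance (Hamming window, no averaging), with
DFT length 2ⁿ, n the nearest integer to log₂(N); if 2ⁿ < N the first 2ⁿ
samples are analyzed. Hk is the PSD peak nearest k·F0 within ±F0/2; a
candidate peak must be prominent (> 3 dB) and within 55 dB of the
strongest peak, which admits genuine lines sitting in spectral valleys
while rejecting window-leakage sidelobes. The bandwidth is the width
where the descending PSD crosses peak − prominence/2. Corrected
intensities subtract the gain (dB, relative to DC) of the two-pole
resonances (F1, B1) and (F2, B2) evaluated at the harmonic frequency:
Hk\* = Hk − Σᵢ gain(fk; Fᵢ, Bᵢ). Bandwidths default to the LPC-derived
values; constants may be passed instead. All intensities are
10·log₁₀(power), reference 1.0, on peak-normalized signals.

**Stress contrasts** are stressed-minus-unstressed: duration uses the
mean unstressed duration; pitch and intensity are measured on the
stressed syllable vs the concatenation of the unstressed syllables.

## 2. Naturalness reduction

The chain runs in fixed order: TD-PSOLA on the stressed syllable →
cross-fade concatenation → F2/F3 shift → H1/H4 attenuation → peak
normalization. Intermediate stages stay in floating range; only the
final rescale touches amplitude.

**Edit plans.** Stress-contrast reduction fractions are independent
truncated-normal draws per feature — N(0.38, 0.15) for level 1,
N(0.74, 0.18) for level 2, clipped to [0, 1] — so naturalness varies
within a level and the reduction is non-equidistant across levels.
F2/F3 frequency reductions draw from N(0.12, 0.07) / N(0.41, 0.07) and
map to F2/F1, F3/F1 ratio targets anchored at the utterance's measured
F1. Targets keep the hierarchy F1 < F2 < F3 and at least 1.1·F1 between
F2 and F3 (the per-level ratio means are ≥ 1.3 apart): closer targets
are physically unresolvable as separate resonances. Median pitch is not
edited for fear and sadness (their stressed/unstressed pitch does not
differ). Harmonic cuts default to −6 dB (level 1) and −12 dB (level 2)
for both H1 and H4: the editing direction is fixed by the naturalness
gradient, the magnitude is a package constant. Intensity-based stress
is measured but never edited.

**TD-PSOLA.** Two-period Hann windows centered at cycle marks;
synthesis positions advance by the local period divided by the pitch
factor and map back to the analysis axis scaled by the duration factor;
overlap-add is normalized by the accumulated window envelope. Marks are
extrapolated past the detected range so the edges are covered, and the
synthesis advance uses the forward mark difference so identity factors
reproduce the input with no sub-period phase offset (identity
correlation > 0.99 by test).

**Cross-fades** are abutting fade-out/fade-in ramps (no overlap-add):
the 10 ms window spans the last 5 ms of the left segment and the first
5 ms of the right one, with linearly spaced gains (spacing
(x₂−x₁)/(n−1)); output length is exactly the sum of the segment
lengths. An overlap-add variant is intentionally not provided.

**Formant shifting** decomposes the 10 kHz pre-emphasized signal into a
Burg order-10 all-pole envelope and its residual, rotates the pole
pairs nearest the measured F2/F3 by the requested frequency change, and
re-filters. The rotated pole's bandwidth is capped at 150 Hz so a deep
downshift still produces a resonance peak at the pole angle instead of
being dragged by the neighboring formant's skirt. Because pole angles
and measured peaks do not map one-to-one, the edit iterates: each trial
re-edits the *original* signal (filter artifacts never accumulate) with
a request corrected by 0.7 of the measured error (the request→measured
map has gain near 2; a full step diverges, light overshoot keeps the
terminal residuals centered), keeping the best iterate, up to 20
iterations or 0.01 % error. Median target error on a full synthetic
corpus is ≲ 0.01 %, 90th percentile ≲ 1 % at level 2.

**Harmonic attenuation** builds RBJ peaking-EQ magnitude responses —
one per prominent line within ±F0/2 of k·F0, width from the
half-prominence rule clamped to [2 bins, F0/2] — and applies them in
the frequency domain (steady-state response; no filter transient).
Where bands overlap, the deepest cut wins, so stacked skirts cannot
over-attenuate; a flat bottom across the analysis-grid spacing makes
the nominal cut exact over the line's frequency-measurement
uncertainty; and one measured touch-up per band corrects the few
hundredths of a dB by which cutting neighboring lines lowers the
leakage pedestal under the main line. Achieved cuts match the nominal
gain to < 0.01 dB in the median.

**Verification.** Each edited feature is recorded as expected vs
observed; post-EQ intensities are read at the very line measured before
the edit (a paired design — re-picking a different line cannot
masquerade as an edit error). Corpus-level checks compare expected and
observed at instrument precision (formants 1 Hz, intensities 0.1 dB,
durations 1 ms, pitch 0.1 Hz): the chain is otherwise deterministic to
≈ 10⁻³ Hz/dB, and a rank test on raw float residue would measure
nothing but rounding direction.

## 3. Synthetic speech

Source-filter synthesis: a pulse train with a −12 dB/octave glottal
slope (two one-pole low-passes cornered at F0), cascaded two-pole
resonators (defaults 550/1550/2650 Hz, bandwidths 90/120/160 Hz,
jittered ±4–5 % per utterance), a +6 dB/octave lip-radiation
difference, and a −40 dB noise floor. Words are 2–3 vowel-only
syllables (60 ms minimum; consonants are out of scope — the features
under test are vocalic) with exactly one stressed syllable. The
per-emotion regimes encode an adult female voice with distinct F0,
rate, and intensity (e.g. anger 220 Hz ± a +45 Hz stressed excursion,
sadness 170 Hz, fear 255 Hz); disgust gives the *unstressed* syllables
the higher pitch, so its pitch stress contrast is negative. Optional
relative period/amplitude noise drives jitter/shimmer for perturbation
tests. F0 is constant within a syllable, so the generating medians are
exact ground truth; F0 must stay below F1.

What the generator does not emulate: consonants and naturalistic
spectra, coarticulation, continuous F0 movement, room acoustics.
Passing tests show the measurement and editing chains are correct on
vocalic signals with known structure, not that they are robust to
conversational recordings.

## 4. EEG containers and preprocessing

Epochs are trials × 32 channels × 384 samples (256 Hz, −0.5..1.0 s)
with a pandas label table (subject, emotion, level, word, block) and
the 10–20 template positions (from the standard montage shipped with
the MNE ecosystem). Baseline correction subtracts the per-trial,
per-channel mean over −500..200 ms — the recording protocol's printed
range, kept as the default with a configurable override (the +200 ms
tail is unusual; it matters only for analyses that assume a
signal-free baseline). Bad channels are flagged by (1) flatline > 5 s,
(2) high-band noise ratio > 4 robust SDs of the channel population,
(3) amplitude-distribution log-probability > 5 robust SDs. Published
artifact-removal algorithms (subspace reconstruction, wavelet-ICA,
spline interpolation, reference standardization) are out of scope;
synthetic epochs enter clean, and an average reference can be applied
in their place.

## 5. Single-trial ERPs and cluster statistics

**LDA beamformer.** Pattern p = trial-and-time average amplitude per
channel over the component window (P200 150–250 ms, early LPP
400–700 ms, late LPP 700–1000 ms); covariance pooled over every sample
of every trial, conditions included; shrinkage
C_γ = (1−γ)C + γ(tr C/d)I with γ = 0.5; w = C_γ⁻¹p/(pᵀC_γ⁻¹p), so
wᵀp = 1 to machine precision. A conditioning check rejects singular
C_γ with the advice to raise γ. Known limitation: when the filter is
fit and applied on the *same* trials, variance minimization partially
cancels the realized between-condition difference (at the simulator's
default SNR the measured 2 µV difference shrinks to ≈ half); unbiased
amplitude readout therefore uses split-half cross-fitting (fit on one
half, measure the held-out half), which the acceptance suite does with
150 trials per condition.

**Cluster-based permutation.** Conditions are compared at every
(channel, sample) by a one-way F across trials (or a two-sample t for
pairs); points beyond the parametric cluster-forming threshold
(p < 0.05) are clustered over temporal adjacency and sensor
neighborhoods (neighbors = distance < 0.7 × head radius on the
template, 4–6 per sensor; serialized with results); clusters need two
or more distinct sensors; the cluster statistic is the sum of F (or t)
values; the null is the maximum cluster statistic over label shuffles
(default 1,000), and p = (1 + #{null ≥ observed})/(nperm + 1). The t
mode is two-sided with α = 0.025 per side. Analyses are per subject:
trials are the observations, and tests run on channel-space epochs.
The familywise type-I rate sits inside the 95 % binomial interval of
0.05 over 200 null simulations (acceptance suite).

**Amplitude dispersion** rescales the data once onto [0, 1] (min-max)
and takes the SD along the chosen axis (each subject over trials, or
each trial over subjects). A single global rescale keeps the two
directions comparable; rescaling every slice along the analysis axis
(available as an option) makes the SD scale-invariant by construction
and cannot express which direction varies more. Constant input
short-circuits to SD 0.

## 6. ITPC and fractal dimension

**ITPC.** Morlet wavelets on 52 linear frequencies 2.2–30 Hz with a
cycle count linear in frequency from 1 to 2.8 (endpoints fixed, the
schedule between them is the package's choice), FFT convolution padded
×4, phases sampled at 200 bins spanning −200..1000 ms. Bins whose
wavelet support (±2.5 σ_t) leaves the epoch are marked invalid, never
extrapolated. ITPC(f,t) = |mean over the axis of e^{iφ}|; the axis is
trials (across-word coherence) or subjects (across-subject coherence).
The scalar `summary()` of a map is the mean over valid post-stimulus
bins at ≤ 10 Hz — the band that carries the evoked response; including
the signal-free 10–30 Hz half of the grid would only average in the
Rayleigh floor (≈ √(π/4N)). Significance: the per-frequency null
resamples baseline-bin ITPC values (−500..200 ms grid, 200 draws,
seeded), per-bin p-values are Benjamini–Hochberg corrected across the
grid at 0.01.

**Higuchi fractal dimension.** Curve lengths
L_m(k) = Σ|x(m+ik) − x(m+(i−1)k)| · (N−1)/(⌊(N−m)/k⌋·k)/k averaged
over offsets m; the dimension is the OLS slope of ln L(k) against
ln(1/k), k = 1..kmax. Calibration: a ramp gives 1.00 ± 0.02, white
noise 2.0 ± 0.1, and the estimate is exactly invariant to affine
transforms. kmax selection walks k upward until three consecutive
increments fall below 0.01, capped at N/2 with a warning. The
rise-to-plateau premise holds for 1/f-type signals (EEG-like); for
white noise the curve starts at ≈ 2 and fluctuates, and for
sine-plus-noise mixtures it can decrease — the property tests
therefore exercise the plateau shape on 1/f noise.

## 7. Synthetic EEG

Each trial is Σ components (Gaussian-topography pattern × per-condition
amplitude × Gaussian-bump waveform) + 1/f noise mixed through smooth
random topographies + an *idiosyncratic subject signature*: a 2–15 Hz
band-limited waveform, fixed across a subject's trials, independent
between subjects, 7 µV by default. The signature is what makes
across-subject phase coherence only partial while across-word coherence
stays high — latency jitter alone cannot do this, because 1–2.8-cycle
wavelets assign near-identical low-frequency phases to any positive
deflection regardless of tens-of-milliseconds shifts. With the default
jitters (subject latency SD 45 ms, trial latency SD 25 ms, noise
9 µV/channel), the simulated across-word summary coherence is ≈ 0.60
and across-subject ≈ 0.25 (37 subjects), reproducing the partial
between-participant synchrony regime alongside stereotyped
between-word locking; these two couplings were calibrated once to that
regime and then frozen. Component amplitudes: P200 base 4 µV
(fronto-central), early LPP 3 µV and late LPP 2.5 µV
(centro-parietal), per-emotion offsets of ±1–1.6 µV, level gains
1/0.85/0.7 (human/level 1/level 2 — amplitudes fade with
synthetization).

Ratings are drawn once per 24-trial block, as in the task: valence and
arousal from per-emotion SAM means, naturalness/intelligibility MOS
means falling with level (4.5/3.4/2.4 and 4.6/3.9/3.3), and the chosen
emotion correct with probability 0.851/0.748/0.68 per level, errors
uniform over the remaining five. The spectral exponent of a block's
noise is coupled to its ratings — valence steepens the spectrum (lower
fractal dimension), arousal flattens it — so trial-level HFD correlates
negatively with valence and positively with arousal; block ratings pair
with trial HFD by duplication within the block.

Not emulated: biophysical forward models, blinks and muscle artifacts,
volume-conduction asymmetries, electrode drift.

## 8. Behavioral statistics

Confusion matrices count predicted × target emotions per level;
precision + false-discovery = 100 % per predicted class, recall +
false-negative = 100 % per target class, accuracy = trace/total. The
within-subject omnibus test follows the decision path exactly:
Shapiro–Wilk on additive-model residuals chooses RM-ANOVA vs Friedman;
under RM-ANOVA, Mauchly's test decides whether the Greenhouse–Geisser
correction applies; post-hocs are Tukey (studentized range on the RM
error term) after ANOVA and Conover with Holm adjustment after
Friedman. The RM-ANOVA/Friedman engines are cross-checked against
independent implementations to 10⁻⁸. Paired contrasts branch to
Wilcoxon on non-normal differences; the all-equal edge case is reported
as t = 0, p = 1. Spearman correlations pool trials across subjects
with block-expanded ratings. Smoothing splines are cubic with the
penalty weight chosen by exact leave-one-out CV over a log grid (13
points spanning 10 decades in natural units of the roughness penalty);
duplicate abscissae collapse to weighted group means, which is
equivalent for the penalized criterion; λ → ∞ recovers the
least-squares line.

**A-priori power analysis.** Subjects are simulated from a
multivariate normal with the printed condition means (4, 2, 3, 4, 1, 3),
common SD 3, compound-symmetry correlation 0.5; the decision rule is
the within-subject omnibus F at α = 0.05 (a tractable proxy for the
cluster-permutation decision — under compound symmetry sphericity holds
and no correction is needed); power is the rejection fraction over
2,000 replicates per candidate n and the smallest n reaching 0.9 is
found by binary search. The analytic noncentral-F power of this design
crosses 0.90 between n = 12 (0.9004) and n = 13 (0.927), so the
Monte-Carlo minimum is 12 or 13 depending on the seed — the reported
value should be read with that ±1 seed sensitivity. (The same
machinery applied to the synthetization design, means (6, 4, 3), is
available through the same function.)

## 9. Problem sizes in the checked runs

The test suite validates edit recovery and the naturalness gradient on
the full stimulus-scale corpus (24 utterances × 6 emotions, both
levels); ITPC regimes on 37 simulated subjects × 24 words of one
condition; beamformer recovery over 50 simulations; cluster type-I
calibration over 200 null simulations at 500 permutations on
16-trial × 32-channel × 0.25 s epochs; and the end-to-end rehearsal on
3-subject × 8-word simulations, twice from identical seeds and across
12 independent seeds for the coupling signs.
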