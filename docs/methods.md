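# Methods

This package simulates an interactive synchronous-speech task between a human
participant and an adaptive virtual partner (VP), generates synthetic
intracranial (sEEG) recordings with known ground truth, and implements the
behavioural and electrophysiological analysis chain that operates on such
data. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not establish.

## The dyad model

Both speakers are phase oscillators on the syllabic cycle with natural
frequency ω = 2π·3 rad/s (the task's ~3 Hz syllable rate). Per 4 ms tick
(250 Hz control rate, explicit Euler):

    φ_vp ← φ_vp + Δt·[ω + |k|·ω·sin(φ_p + ψ − φ_vp)]
    φ_p  ← φ_p  + Δt·[ω + k_p·ω·sin(φ_vp − φ_p)] + ξ,   ξ ~ N(0, σ²Δt)

The coupling terms are scaled by ω so `k` is dimensionless per cycle. The
VP's preferred offset ψ is selected by the sign of its coupling strength:
`k = −0.09` targets synchrony (ψ = 0), `k = +0.09` targets anti-phase
(ψ = π, "speaking between the participant's syllables"), `k = ±0.01` is the
neutral condition. The anti-phase target is the only choice in the
attractive-Kuramoto family that *destabilises* coordination relative to the
neutral condition: with the participant pulling toward synchrony at
`k_p = 0.15`, a π/2 target would still add net restoring force at the mixed
fixed point and *increase* phase locking, inverting the observed condition
ordering. With ψ = π the linearised restoring rates are 0.24ω (sync), ~0.15ω
(neutral) and 0.06ω (shifted), which produces the intended ordering of
coordination quality. ψ remains a free parameter everywhere; the agent
module is routinely exercised at ψ = π/2 as well.

The human is not modelled beyond this symmetric coupling plus Wiener phase
noise. The participant noise default, **σ = 2.25 rad/√s**, was calibrated
once against the task's reported verbal-coordination statistics (trial VCI
mean ≈ 0.5, 5–95 % range ≈ 0.17–0.83, with a clear sync > neutral > shifted
ordering) and is not adjusted elsewhere. Note the noise absorbs all sources
of real-world variability (articulation, tracking error, attention), which
is why it is much larger than pure motor timing jitter.

Phases map to envelopes via `((1 + cos φ)/2)²`: one syllable-like pulse per
cycle, values in [0, 1]. The quadratic sharpening keeps the fundamental
dominant after band-passing, so envelope phase ≈ oscillator phase.

Sessions are 24 trials × 14 s (one third per condition, order shuffled by
the session seed; neutral trials alternate k = ±0.01), ~1000 syllables per
session. Trials are bit-reproducible from their seeds.

## The virtual-partner control loop

The agent re-implements the adaptive loop offline in the envelope domain:
per 4 ms tick it (1) extracts a 3-component feature vector (mean, mean first
difference, RMS) from the trailing 25 ms chunk of the participant envelope;
(2) estimates the participant's syllabic phase by aligning the last 250 ms
of feature vectors to stimulus-aligned model utterances with open-begin
subsequence DTW (free start along the model, best end column, ties to the
earliest model; the model is tiled twice so alignments may wrap the cyclic
stimulus); (3) converts the phase error into a playback-rate multiplier
`rate = 1 + |k|·sin(φ_p − φ_vp − ψ)` clamped to [0.5, 2]; (4) advances its
stimulus read position at that rate and emits the linearly interpolated
envelope sample (cyclic repetition). Silent input (chunk RMS < 1e-4) falls
back to dead-reckoning the phase at ω, so a silent participant hears the
unwarped stimulus.

The real system worked on audio with WSOLA resynthesis and unspecified
(likely spectral) features; the envelope-domain loop with interpolated
read-out is sufficient for every downstream envelope analysis, and the
feature vector is an explicit swap point. The subsequence-DTW formulation
replaces a fixed alignment band: the history may match any model span, and
its per-tick cost is bounded by history × (2·stimulus) cells (numba-compiled).

Closed-loop behaviour: with |k| = 0.09 and a cooperative (non-adaptive)
input, the loop settles within ~1 s at a steady-state lag equal to ψ (tested
at ψ = 0 and π/2, tolerance 0.2 rad); with |k| = 0.01 total warping stays
below 2 % of the trial.

## Behavioural metrics

The speech envelope is band-passed at 2.25–5 Hz (4th-order Butterworth,
zero-phase forward–backward; raw audio is first brought to 16 kHz, rectified
via the analytic-signal magnitude, low-passed and decimated to 250 Hz). The
instantaneous phase is the Hilbert angle. The verbal coordination index
(VCI) of a trial is the phase-locking value |⟨e^{i(φ_a−φ_b)}⟩| of the two
envelope phases.

Chance level: 500 surrogates by circular time-shift of one phase series
(uniform shift ≥ 0.5 s from zero; shift of the phase series, not phase
randomisation, preserving both marginals), p = (1+#{null ≥ obs})/(1+500).
All shifts are evaluated in one FFT pass (the PLV at shift s is a circular
cross-correlation of the unit phasors), identical to direct recomputation
to 1e-12. A degenerate case worth knowing: if one phase series is a
*perfect* linear ramp, every circular shift leaves the PLV unchanged and the
test becomes maximally conservative (p = 1). Realistic phases — warped VP
speech, noisy participants — are irregular and unaffected; calibration nulls
must therefore pair two independently variable speakers.

Under the calibrated noise the per-trial surrogate test has moderate power
(~70 % of sync-coupled trials at α = 0.05 — the dyad's mean phase diffuses,
which widens the null), while every simulated participant is above chance at
the session level; the condition contrast (difference of condition means,
1000 label permutations, two-sided, +1-corrected) rejects in essentially
every session.

The participant–VP delay is the cross-correlation maximum within ±300 ms,
negative = participant leads. Trials at or below the participant's median
delay are "anticipatory", strictly above "compensatory" (ties go to
anticipatory; fixed convention).

## Synthetic sEEG

Recordings are 1 kHz, built at the level of *virtual* (bipolar) channels —
the carriers of the injected effects — and then integrated into contact
potentials along each shaft (`contact_{i+1} = contact_i − virtual_i`, plus a
strong per-shaft common mode carrying pink noise and 50 Hz line with
harmonics), so bipolar re-referencing has real geometry to consume and
recovers the virtual signals exactly.

The spectrum is partitioned into contiguous 1/f-profile band-limited
components (0.5–1, the six canonical bands, the 50–70 Hz gap, 125–300 Hz).
Because the analysis bands are partition members, a task-window gain applied
to a component is exactly the band effect the spectral stage should measure.
Gains are *percent power change* (amplitudes scale by √(1+gain/100)).

Per-channel injections (defaults, by region of interest):

| ROI | HFa gain | other bands | ρ(HFa, VCI) | PAC source (depth 0.5) |
|---|---|---|---|---|
| STG BA41/42 (primary auditory) | +100 % | δ+20, θ−30, α−35, β−30, lγ+40 | 0 | VP speech phase |
| STG BA22 (secondary auditory) | +60 % | θ−25, α−30, β−25, lγ+25 | −0.6 | VP speech phase |
| IPL BA40 | +30 % | α−25, β−20 | −0.3 | none |
| IFG BA44 | +50 % | β−20 | −0.6 | phase difference |
| NULL_REGION | 0 | — | 0 | none |

This mirrors the qualitative dissociation the analysis chain is meant to
resolve: primary auditory cortex responds strongly but is behaviour-blind;
secondary auditory cortex carries the behaviour correlation with
speech-phase coupling; the IFG couples to the coordination dynamics (the
VP−participant phase difference).

The behaviour correlation is injected by a monotone lognormal per-trial HFa
amplitude multiplier built from the normal scores of the VCI ranks mixed at
the Pearson equivalent of the target Spearman ρ (r = 2 sin(πρ/6)), spread
0.35, normalised to unit mean power; the attained sample ρ is recorded in
the ground truth. PAC is injected as `(1 + d·cos φ_behav)/√(1+d²/2)` on the
HFa component within trials (unit mean power). Two interactions are worth
noting: (1) the per-trial multiplier widens the across-epoch power
distribution, so the task-vs-rest permutation test loses power on
ρ-injected channels; (2) on phase-difference-coupled channels the realised
per-trial PAC power covaries with the trial's phase-difference
concentration, which attenuates the recovered ρ there (≈ −0.45 for a −0.6
target). Recovery checks therefore target the clean channels (BA41/42 for
gain, BA22 for ρ).

Default layout: 5 ROI shafts of 7 contacts (6 virtual channels each) plus
one 5-contact artifact shaft (4 virtual channels, 20× amplitude over ~30 %
of the task) — 34 virtual channels. ROI centres are placed with ≥ ~37 mm
pairwise separation so the five regional clouds form an unambiguous spatial
cluster structure (idealised relative to real anatomy, where STG subfields
adjoin; the clustering stage is validated on geometry, not on anatomical
realism).

## sEEG analysis chain

* Preprocessing: bipolar montage (midpoint coordinates); zero-phase notch at
  50…300 Hz (Q = 30) plus 0.5–300 Hz band-pass applied as a single SOS
  cascade (exact for zero-phase filtering); channel rejection by broadband
  variance > median + 2·IQR on the raw task recording (the fence's reference
  point is configurable: median/Q3/zero); task epochs −0.2…14 s with
  baseline −0.1…0 s subtracted and the first 500 ms masked from analysis;
  rest cut into seventeen 14 s epochs.
* PSD: multitaper (DPSS, time-bandwidth 4, 7 tapers) per epoch on the
  analysis window, interpolated onto 125 log-spaced frequencies 0.5–125 Hz.
  Band power averages grid points with half-open [lo, hi) edges; the
  50–70 Hz gap is preserved.
* Global effect: 100·(mean_task − mean_rest)/mean_rest per channel × band;
  two-sided epoch-label permutation (N = 1000, +1 correction).
* Brain–behaviour: Spearman ρ across trials between band power and VCI
  (ranks then Pearson, exact to 1e-12 against scipy), trial-label
  permutation (N = 1000). ROI statistics: one-sample t vs 0,
  Benjamini–Hochberg across ROIs.
* PAC: HFa amplitude = 70–125 Hz zero-phase band-pass → analytic magnitude →
  40 Hz low-pass → 250 Hz. Metric: normalised mean vector length
  |Σ a·e^{iφ}| / Σ a (Tort modulation index available); the `1 + cos`
  benchmark equals 1/2 analytically. Channel-level values average per-trial
  PAC; surrogates circularly shift the amplitude per trial (500, ≥ 0.5 s),
  reported as % increase over the surrogate mean. The paired ROI comparison
  (Wilcoxon) uses the surrogate-normalised values, because the raw MVL also
  reflects the phase marginal — the phase *difference* is concentrated, not
  uniform, on well-coordinated trials — which only cancels after surrogate
  correction.
* Clustering: k-means (Euclidean, mm) over k = 2…10, 50 restarts, fixed
  seed; best k by mean silhouette. Set comparison: silhouette difference
  with size-preserving re-assignment permutations (N = 1000); observed and
  permuted statistics run through the same internal k-means path (5
  restarts) so the test is exchangeable, while reported silhouettes use the
  full estimator.

## Problem sizes and determinism

The standard synthetic study uses 48 behavioural trials (two sessions'
worth) for the across-trial correlation, 34 channels, 500 surrogates and
1000 permutations; calibration checks use 1000 null instances. Every stage
seed derives from a master seed via a CRC-hash SeedSequence, so stages rerun
independently and a manifest reproduces any run.

## What passing tests show — and what they don't

The synthetic generator realises exactly the effect classes the analyses
target, with known amplitudes, plus the main nuisance structure (1/f
background, line noise, common mode, artifact channels, condition structure,
behaviour-yoked modulations). Recovery at stated tolerances demonstrates
the chain is correct and calibrated *on data of this structure*. It does not
establish performance on real sEEG: no epileptiform activity, no volume
conduction beyond the shared common mode, no non-stationary background, no
articulation artifacts, stationary Gaussian band components, and idealised
ROI geometry. Real-data entry points (WAV audio, EDF + channel-table CSV)
reuse the identical analysis code paths.

## Known limitations

* The participant model is a single noisy oscillator: no sentence
  micro-structure (the task's sentences imply within-sentence rate below
  3 Hz; the simulator uses the stated ~3 Hz task rate throughout), no
  fatigue or learning across trials.
* The DTW feature set, history length and rate limits of the original
  real-time system are unpublished; values here are engineering choices.
* Circular-shift surrogates are degenerate for strictly periodic phases
  (documented above); tests and calibrations use realistic, variable phases.
* The artifact-channel fence's reference point ("2·IQR") is a convention;
  median-centred by default, configurable.
* Per-trial band power is used raw (no per-trial baseline normalisation)
  in the correlation stage; a normalisation option exists.
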