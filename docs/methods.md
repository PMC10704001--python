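# Methods

This note documents the models implemented in `hearlab`, the parameter
choices that matter, what the synthetic-data generators emulate, and the
numerical decisions behind the fits.

## Stimulus synthesis

All stimuli are float waveforms at 48 kHz by default, with levels expressed
as RMS dB re full scale (dBFS). The default stimulus level of −26 dBFS
leaves crest-factor headroom for noise maskers. Each task has a calibration
sound built by concatenating representative task stimuli (at least 3 s);
its overall RMS anchors a `CalibrationReference`, and no task stimulus may
exceed it by more than 6 dB — the convention used when remote participants
set their own comfortable volume against the calibration sound.

Task-specific conventions, chosen once where the underlying designs leave
them open:

* **Antiphase triad** (headphone check 1): three 200-Hz, 1-s tones with
  20-ms Hann ramps; the target is 6 dB softer than both foils; the first
  foil (in position order) has its right channel polarity-inverted. In
  either channel alone the target is still the softest tone — the mono
  blind spot that motivates the second check.
* **N0Sπ chirp** (headphone check 2): masker noise band 100–500 Hz,
  identical in both channels; a 150–400 Hz linear sweep (flat trials at the
  geometric mean, ≈245 Hz) added antiphase across channels at a default
  per-channel SNR of −16 dB. The SNR default was chosen so that monaural
  detection sits near chance while the binaural masking level difference
  makes dichotic detection easy; it is configurable.
* **F0 discrimination**: four 200-ms harmonic complexes (equal-amplitude
  harmonics 1–10, sine phase, F0 = 110 Hz), 20-ms Hann ramps, 250 ms
  between tones. A listed shift Δ is the total excursion split
  symmetrically: tone 1 at +Δ/2, tone 3 at −Δ/2.
* **Gap detection**: two 125-ms 4-kHz markers with 1-ms Hann ramps
  flanking the gap (the 0-ms foil is the two ramped markers abutted);
  noise a half-octave either side of 4 kHz at tone level −10 dB runs from
  50 ms before the first marker to 50 ms after the second (mirroring the
  lead), with 10-ms edge tapers; the gap interrupts the tone only.
* **ITD**: realized as an interaural carrier phase shift φ = 2πfτ, split
  ±φ/2 across ears — exact for pure tones; 500 Hz, 300 ms, 20-ms ramps.
  ITDs implying φ > π are rejected.
* **ILD**: ±ILD/2 dB applied to the two ears so the across-ear mean level
  is preserved; 4 kHz tones; the louder ear swaps between intervals.
* **CMR**: 1-ERB-wide bands (ERB = 24.7·(4.37·F_kHz + 1) Hz; 456.5 Hz at
  4 kHz) synthesized in the frequency domain from seeded random phases and
  amplitude-modulated by a 100%-depth 10-Hz raised-sine envelope. Flanker
  bands are 1 ERB wide with near edges 2 ERB from the on-band edges; CORR
  shares the on-band modulator, ACORR uses the π-shifted (inverted) one.
  Noise carriers of different bands are independent.

Synthesis is deterministic: identical seeds and parameters give
bit-identical samples. WAV I/O uses float32 RIFF via `scipy.io.wavfile`.

## Screening rules and the two-Gaussian ROC

The headphone rule is conjunctive: at least 5 of 6 correct in *each* of the
two checks (4 of 6 for cohorts recruited for diagnosed hearing loss). The
hearing screen gates on word-recognition scores with ≥ comparisons at each
SNR (default cutoffs 100 / 83 / 75 at 10 / 5 / 0 dB; the −5 dB block is
recorded but never gates), on engagement (more than two browser focus-loss
events fail), and on survey denials of hearing loss, neurological disorder,
and persistent tinnitus. Flow gates between tasks use a strict "more than"
comparison, so a score exactly at a flow threshold does not open the gate;
screening cutoffs, by contrast, pass at the boundary.

Cutoff derivation starts at the cohort's 65th percentile at each SNR
(linear-interpolation percentiles) and relaxes all cutoffs simultaneously
in 2-percentile-point steps, stopping at the first step where the joint
exclusion (failing any gate) reaches the target. Per-SNR independent
relaxation schedules would also meet the stated endpoint; the simultaneous
schedule was chosen as the simplest rule consistent with it.

The ROC model treats NH scores as Normal(μ, σ) and HL scores as
Normal(μ − g·s_p, r·σ) with the equal-weight pooled SD
s_p = σ·√((1+r²)/2). Pooled-SD weighting is configurable in the effects
module, but the population model uses equal weights because the
meta-analytic group sizes behind g are not part of the model's inputs. The
analytic curve is computed on the untruncated Gaussians; simulated cohorts
clip scores to [0, 100], which leaves below-cutoff indicators unchanged for
any cutoff inside the score range. With g = 2.05 and r = 3, placing the
cutoff at the NH 35th percentile excludes 91.9% of the HL population; the
value stays between 85% and 95% for NH exclusions of 20–40%.

## Psychometric fitting

The observer model is ψ(x) = γ + (1−γ−λ)·S((x−m)/s) on the log-stimulus
axis, with a logistic S and width w defined as the 5→95% rise interval
(s = w/(2·ln 19)). γ is fixed at the design chance rate (1/6, 1/3, 1/2)
and never estimated. Block-to-block variability enters through a
beta-binomial likelihood parameterised by η ∈ [0, 1), with beta variance
η²·p(1−p) (ν = 1/η² − 1); η = 0 is handled exactly as a pure binomial.

The posterior over (m, w, λ, η) is integrated on a 40×40×20×10 grid.
Priors: uniform in m over the data range padded by half a span on each
side; log-uniform in w from the smallest level spacing to 3× the data
span; a Beta(1, 24) scaled to [0, 0.1] on λ; a Beta(1, 9) on η (grid
truncated at 0.6, where the prior mass is already negligible). These are
deliberate approximations of "default" fitting-software priors, not a
bit-exact reproduction. After a first pass, the m and w grids are re-laid
over the posterior mean ± 5 marginal SDs and the integration repeated;
this refinement removes most grid-coarseness bias (a guard test checks
agreement with a much finer unrefined grid).

Thresholds at a target proportion correct invert ψ at every grid point and
propagate the posterior: the point estimate is the posterior geometric
mean, the interval the central 95%. Degenerate data (all correct, or at
chance throughout) return a fit with boundary-diagnostic flags rather than
raising. CMR effects are reported with the field's sign convention —
CORR−REF = REF_threshold − CORR_threshold, positive when co-modulated
flankers lower the threshold — with interval half-widths combined in
quadrature.

## Effect sizes

Hedges' g = J·(μ_a − μ_b)/s_p with J = 1 − 3/(4·df − 1), df = n_a+n_b−2.
When a source reports an SEM, σ = SEM·√n. When any group size is unknown
(common when digitising printed tables), the equal-weight pooled SD
√((σ_a²+σ_b²)/2) is used with J = 1 and no sampling variance is reported;
this is recorded in the output. Inverse-variance pooling uses fixed-effect
weights 1/varᵢ and a 1.96 CI multiplier with no small-sample t adjustment.

## Confusion clustering

Pairwise similarity between consonants is the symmetrized off-diagonal
confusion probability (p(i→j)+p(j→i))/2 (the underlying tallies are
asymmetric and no symmetrization convention is standard, so the arithmetic
mean was chosen); distance is 1 − s/max(s). Linkage is average by default
(single and complete selectable; for single linkage the topology depends
only on the similarity ordering, for the others the monotone conversion
matters and is documented as a caveat). The agglomeration threshold is
swept to the largest value yielding exactly the requested number of
clusters, singletons included; tied merge heights can make a count
unattainable, in which case the attainable counts are reported.

## Synthetic observers and cohorts

The simulators emulate the *response statistics* the analysis modules
assume, not auditory processing: psychometric observers are stationary
binomial responders on the generating curve; cohort members carry one
latent word-recognition score from the two-Gaussian population
(NH ~ Normal(85, 8) percent at 0 dB SNR by default — a realistic
suprathreshold word-in-babble level for normal hearing) mapped to SNRs by
fixed monotone offsets (+8, +4, 0, −18 points at 10, 5, 0, −5 dB) and
clipped to [0, 100]; the offsets keep the 10-dB gate off the 100% ceiling
so percentile cutoffs remain well defined. Headphone-check sessions draw
Bernoulli outcomes from per-mode accuracies: stereo (0.98, 0.95), mono
earphone (0.98, 1/3), free-field (0.40, 1/3) for (triad, chirp). Under
these accuracies both tasks usually fail in a free-field session; the triad
fails in over 95% of failing sessions.

Because observers are parametric, passing tests demonstrates that the
pipeline recovers what it assumes — synthesis invariants, estimator
calibration, rule logic — not that human CMR or BMLD magnitudes are
predicted; those magnitudes are inputs, not outputs. Real response data
add non-stationarity (learning, fatigue), level-dependent lapses, and
hardware variability that the beta-binomial overdispersion only partially
absorbs.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁶ draws for the ROC operating point, 10⁵
participants for the empirical-vs-analytic curve comparison, 10⁴
participants for cutoff derivation, and 200 replicate fits (7 levels × 25
trials, reduced 24×24×12×8 grid) for credible-interval coverage; the
10,000-trial recovery fit uses the default grid with refinement. Envelope
correlations in the CMR checks are measured on Hilbert envelopes band-passed
5–15 Hz around the 10-Hz modulation rate, which isolates the modulator from
intrinsic noise-envelope fluctuations. Cross-correlation lags for ITD
checks use parabolic peak interpolation at 48 kHz.

## Known limitations

* Speech corpora (rhyme-test words, C/a/ syllables) are represented by
  manifest placeholders; speech tasks are exercised at the score level.
* The fit approximates, but does not clone, the reference fitting
  software's priors and sigmoid defaults.
* The meta-analytic inputs (the 15 studies) are consumed as the two
  parameters g and r; the pooling arithmetic is implemented, the studies'
  data are not bundled.
* No auditory-periphery modeling: simulated observers cannot predict
  masking-release magnitudes, only reproduce assumed ones.
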