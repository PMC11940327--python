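# Methods

## The estimator

The transient hypoxia test measures peripheral chemoreflex sensitivity
as a regression slope. For each nitrogen administration the pipeline
constructs one pre-hypoxic and one post-hypoxic point per response
channel and pools the points across episodes:

1. **Episode segmentation.** The SpO₂ nadir of an administration
   `[a, b)` is the minimum of the SpO₂ channel over the half-open
   window `(b, b + 60 s]`; ties break toward the earlier sample.
   Episodes are flagged invalid (with a recorded reason, never silently
   dropped) when the gap to the previous administration is under 180 s
   or when the nadir sits less than 2 % below the pre-window SpO₂ mean
   ("no desaturation"). Both thresholds are configurable; the 2 % QC
   floor is this package's choice — episode-level quality control has
   no published rule.
2. **Pre-hypoxic point.** Means of SpO₂ and of the response events
   (per-breath V̇, or per-beat smoothed HR) over `[a − 60 s, a)`. The
   window anchors at the administration start: desaturation begins only
   after the administration plus the circulation delay, so this window
   is uncontaminated by the stimulus.
3. **Post-hypoxic point.** The window runs from the 5th heartbeat
   before the nadir to the 20th heartbeat after it, counted on the
   cleaned (post-ectopic-removal) beat series; near recording edges the
   window truncates to the available beats and the point is flagged.
   The ventilatory response is the mean of the three largest
   *consecutive* per-breath V̇ values whose onsets fall in the window;
   the cardiac response is the single highest 3-beat-smoothed HR. The
   abscissa is the nadir SpO₂.
4. **Fit.** Ordinary least squares of response on SpO₂ over all points
   (2 × episodes used). Because the response rises as SpO₂ falls, the
   raw slope is negative; the reported sensitivity is its positive
   magnitude (HVR in L/min/SpO₂ %, HR slope in bpm/SpO₂ %). A
   paradoxical positive raw slope is reported as a negative magnitude
   with a warning — never clamped. A fit requires at least 3 valid
   episodes (warning below 4).

### Preprocessing

- **Breaths.** A breath is a maximal run of expiratory flow above
  0.05 L/s lasting ≥ 0.3 s (both configurable; the delineation rule of
  the acquisition software is proprietary, these defaults reject sensor
  noise while keeping shallow breaths). The integration support widens
  to the enclosing run of positive flow so threshold clipping does not
  bite into tidal volume. BR uses the forward breath-to-breath period
  (last breath inherits the previous one); V̇ = V_T × BR by
  construction. The period convention is not published; forward is the
  package default and the delineation parameters are exposed.
- **Beats.** RR is the backward interval; HR_raw = 60/RR. Ectopic
  (premature) beats are flagged automatically when RR falls below 0.8 ×
  the median of the 11 surrounding RR intervals (manual annotation
  flags take precedence when requested). Removal deletes the beat and
  merges the two disturbed intervals; the merged interval is recorded
  as the RR of the closing beat but is *not* treated as a physiological
  cardiac cycle — its HR is set to NaN and excluded from smoothing and
  window statistics. Treating the merged 2·RR interval as a real cycle
  would inject a spurious half-rate HR spike into every cleaned
  analysis window.
- **Smoothing.** HR_smooth is the 3-beat centred moving average;
  boundary beats use the available 2-beat mean so nadir windows near
  recording edges stay usable.
- **Irregular rhythm.** If more than 20 % of beats are flagged, the HR
  pipeline refuses the recording (mirroring the exclusion of atrial
  fibrillation from HR analysis); the ventilatory pipeline still runs,
  since it uses beats only to delimit windows.
- **Baseline.** Resting values are the averages over the 10 min
  immediately preceding the first administration (per-breath V̇,
  per-beat HR, per-sample SpO₂/etCO₂); a shorter pre-test segment is an
  error.

## The synthetic recording generator

No public recordings of this protocol exist, so the generator *is* the
test bed. It emulates:

- the administration staircase: first bout 5 s, +5 s steps until the
  predicted nadir reaches the ~70 % target or the 40 s cap, then
  remaining bouts drawn uniformly from the identified range; gaps of
  ≥ 180 s (plus 0–30 s jitter); 4–12 bouts;
- first-order SpO₂ kinetics: decay toward a 60 % physiological floor
  with τ_fall = 30 s during administration, recovery toward baseline
  with τ_recover = 20 s afterwards, shifted by a 6 s lung-to-earlobe
  circulation delay (the nadir-anchored windows tolerate this delay, so
  its exact value is not critical);
- linear response gains: per-breath V̇ = 11 + Gv·D + ε,
  per-beat HR = 62 + Gh·D + ε, with D the *peak-hold* desaturation
  (maximum of `baseline SpO₂ − SpO₂(t)` over the trailing 15 s) and
  Gaussian noise (σ_V̇ = 0.5 L/min ≈ 5 % breath-to-breath CV for quiet
  supine breathing; σ_HR = 1 bpm);
- co-modulated rate and depth (BR scales with the square root of the
  ventilation ratio) so V̇ = V_T × BR holds exactly;
- half-sine expiratory lobes whose integral equals the breath's tidal
  volume (amplitude π·V_T / (2·T_exp), expiration 40 % of the cycle;
  inspiration is silence because the one-way valve circuit measures
  expiration only);
- optional ectopics: a Poisson-drawn subset of beats is advanced to
  60 % of the preceding RR with a compensatory pause (total beat-train
  duration preserved), flagged in the ground truth;
- a 600 s pre-test baseline and a 120 s tail; etCO₂ is a constant with
  slow noise (a placeholder — the channel feeds no computation).

**The sustained-response (peak-hold) choice.** A strictly instantaneous
linear response to first-order SpO₂ kinetics would make the published
max-type point construction systematically under-recover the gain: the
desaturation peaks at a single instant (a kink, not a plateau), so the
mean of three breaths straddling the nadir sits below Gv·D_max. A
transient hypoxic stimulus in fact produces a ventilatory/cardiac
response that outlasts it by tens of seconds; holding the drive at the
trailing 15 s peak is the simplest model of that after-discharge, and
it makes the estimator exact in the noiseless case — which is what
turns parameter recovery into a meaningful acceptance surface.

**Randomness.** One root seed; independent named substreams in a fixed
documented order (schedule, breaths, beats, ectopics, etco2). Identical
configurations produce bit-identical recordings.

**What the generator does not emulate** (so passing tests do not speak
to these): pulse-oximeter averaging and motion artifacts beyond the
additive delay, breathing-pattern irregularity (sighs, apnoeas,
swallows), baseline drift and autocorrelated physiological variability,
ECG morphology (beat times are generated directly), etCO₂ dynamics, and
any nonlinearity or saturation of the chemoreflex gain itself.

## Known estimator bias under noise

The post-hypoxic points are maxima (best consecutive V̇ triple; single
highest smoothed HR). Under measurement noise a maximum is upward
biased by roughly E[max of k noisy candidates], which shifts every
post-point up by a constant while the pre-points (plain means) stay
unbiased — tilting the pooled slope upward by ≈ bias / (SpO₂ range).
With zero true gain the estimated slopes therefore do *not* average to
zero under default noise (the acceptance suite computes the magnitude;
the zero-noise null is exact to 1e-9). This is a property of the
published point-construction rule, not of this implementation; it is
visible in the worked example as the small upward shift of the HR
slope, whose single-beat maximum is taken over more effective draws
than the ventilatory best-of-triples.

## Carotid flow

Mean diameter = systolic/3 + 2·diastolic/3 (mm; the artery spends about
two thirds of the cycle near its diastolic calibre); per-artery values
from multiple B-mode videos are averaged; CABF = π(d/2)²·TAMEAN·60 in
mL/min with inputs fixed as mm and m/s. The per-patient aggregation
over left/right carotids is not published; the default is the mean of
the available sides, configurable to `{left, right, sum, mean}`, and
the choice is stamped into the output.

## Cohort statistics

- **Normality gate.** One-sample KS against a normal with the sample's
  own mean/SD. Because the parameters are estimated, the plain KS table
  is anticonservative; the p-value comes from a seeded Monte-Carlo null
  table (2000 replicates per sample size, cached). The gate (α = 0.05
  on the paired differences) selects paired t vs Wilcoxon; the rule for
  that choice is not published, so the gate is deterministic, logged,
  and overridable per variable.
- **Wilcoxon signed-rank.** Zeros dropped, mid-ranks for ties; exact
  two-sided p from the full sign-flip distribution (computed by a
  convolution recurrence over doubled ranks) up to n = 25, tie-corrected
  normal approximation beyond.
- **Spearman Δ-correlations.** Pearson correlation of mid-ranks of the
  per-subject pre→post changes; exact permutation p (all n! orderings)
  for n < 10, t approximation otherwise.
- **Literature comparison.** A Welch two-sample t-test from summary
  statistics (mean ± SD, n). Published descriptions of such comparisons
  sometimes label them "paired", which is not computable across
  independent cohorts; the two-sample summary-statistics test is the
  defensible interpretation and is what this package implements.
- **Multiplicity.** None by default (p < 0.05 convention); Holm
  adjustment behind a flag.
- Degenerate inputs: all-zero differences report p = 1; constant
  samples/Δ-vectors raise explicit errors rather than returning NaN.

## Demo cohort

`make_demo_cohort` draws per-subject pre/post gains from truncated
normals matching the cohort distributions (HVR 0.42 ± 0.29 pre with a
small non-significant shift after the intervention; HR slope
0.26 ± 0.23 pre with a +0.11 shift) with a 0.02 floor, and an aortic
valve area covariate whose pre→post change shares a latent factor with
the HR-gain change, reproducing the study's headline Δ-correlation
structure. Only a seeded subset of ≈ 10/26 of subjects is
HR-analysable, mirroring the published split between ventilatory and
cardiac sample sizes.

## Problem sizes and numerical choices

Acceptance-scale runs use 200 subjects for parameter recovery, 100–200
seeds for the null, 50 paired seeds for ectopic robustness, 20 gains
for the noiseless sweep, and the 26-subject demo cohort — all at the
protocol's native 1 kHz; one subject simulates and analyses in well
under a second. Unit tests use reduced rates (50–125 Hz) and 4
administrations. Other numerical choices: half-open time intervals
`[start, end)` with 0-based indexing throughout; trapezoidal
integration for tidal volumes; nadir and HR-maximum ties break to the
earliest event; recording CSVs are written with shortest-round-trip
floats and read with round-trip parsing so write → read is exact.

## Limitations

Real recordings will violate the generator's clean-signal assumptions
(see the non-emulated list above); the breath-delineation thresholds
and the ectopic prematurity threshold will need adjustment per
acquisition setup; the estimator's max-selection bias means small true
gains are overestimated under noise, an inherent property of the
protocol's point construction; and the EDF reader is not implemented —
recordings enter via the documented CSV dialect.
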