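# chemoreflex

Quantification of peripheral chemoreceptor (carotid/aortic body)
sensitivity from transient-hypoxia test recordings, with carotid blood
flow computation and the paired pre/post cohort statistics used in
clinical chemoreflex studies.

The package is aimed at cardiorespiratory physiologists who run the
*transient hypoxia test*: a supine subject breathes through a circuit
into which brief (5–40 s) boluses of pure nitrogen are administered
4–12 times, at least 3 minutes apart, producing stepwise SpO₂
desaturations with nadirs down to ~70 %. Chemoreflex sensitivity is the
slope of the response against SpO₂ across the resulting pre-/post-
hypoxic point pairs:

- **HVR** (hypoxic ventilatory response, L/min per % SpO₂) — from
  breath-by-breath instantaneous minute ventilation V̇ = V_T × BR
  computed off the expiratory flow channel;
- **HR slope** (bpm per % SpO₂) — from ectopic-cleaned,
  3-beat-smoothed beat-to-beat heart rate.

For each N₂ episode the estimator builds two points per channel: the
pre-hypoxic point (60 s window means immediately before the
administration) and the post-hypoxic point (SpO₂ nadir within 1 min of
the administration end, paired with the mean of the three largest
consecutive V̇ values — or the single highest smoothed HR — inside a
window from 5 heartbeats before to 20 heartbeats after the nadir).
Points are pooled across episodes and fit by ordinary least squares;
the sensitivity is reported as the positive slope magnitude.

Also included:

- a **synthetic recording generator** with known ground-truth gains
  (first-order SpO₂ kinetics, linear chemoreflex gains, half-sine
  expiratory flow rendering, optional ectopic beats), so the whole
  pipeline is testable end to end without patient data;
- **carotid artery blood flow**: mean diameter = sys/3 + 2·dia/3 (mm),
  CABF = π(d/2)² · TAMEAN · 60 (mL/min);
- **cohort statistics**: Monte-Carlo–calibrated KS normality gate,
  paired t / exact Wilcoxon signed-rank comparisons, Spearman
  correlations of pre→post changes (exact permutation p for small n),
  and a summary-statistics Welch t-test against literature values.

## Worked example

```python
from chemoreflex import SynthConfig, simulate_subject, run_hvr, run_hr_slope

cfg = SynthConfig(seed=7)           # defaults: 1 kHz, 8 admins, Gv=0.42, Gh=0.26
rec, truth = simulate_subject(cfg)  # ~37 min recording + ground truth
hvr = run_hvr(rec)
hr = run_hr_slope(rec)
print(f"HVR      = {hvr.slope_magnitude:.3f} {hvr.units}")
print(f"HR slope = {hr.slope_magnitude:.3f} {hr.units}")
```

prints

```
HVR      = 0.426 L/min/SpO2%
HR slope = 0.296 bpm/SpO2%
```

i.e. the pipeline recovers the configured ventilatory gain 0.42 within
measurement noise (R² of the pooled fit is 0.999 over 8 episodes / 16
points; the episode nadirs span 69.5–90.5 %). The HR slope sits
slightly above its true 0.26 because the protocol's "single highest
smoothed HR" post-point is a maximum over noisy beats — see
`docs/methods.md` for the bias analysis. Carotid flow arithmetic:

```python
from chemoreflex import mean_diameter, cabf
mean_diameter(6.30, 5.85)   # -> 6.00 mm
cabf(6.00, 0.34)            # -> 576.8 mL/min
```

The same operations are available from the shell:

```bash
chemoreflex simulate --seed 7 --out rec/
chemoreflex analyze --recording rec/ --channel both --out results.json
chemoreflex cabf --in carotid.csv --out cabf.csv
chemoreflex demo --n 26 --seed 0 --out demo/
```

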