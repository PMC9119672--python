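# pstnkit

Quantification toolkit for appetite-circuit experiments in freely
behaving mice: event-aligned **fiber-photometry dF/F** processing with
control-channel quality screening, **meal-microstructure** detection
from continuous bottle-weight recordings, and **cell co-expression**
quantification with Abercrombie double-counting correction — plus
seeded synthetic-data generators so every stage is testable against
known ground truth.

It is written for labs that record bulk GCaMP signals around a
stimulus (food exposure, hormone infusion), measure liquid-diet intake
on scales, and count marker-labeled neurons (e.g. *Tac1*- and
*Crh*-expressing subpopulations) in sectioned tissue.

## The quantities it computes

**Photometry.** Each trial carries a 465 nm signal channel F and a
405 nm calcium-independent control, with the event at t = 0. Both
channels are independently averaged into 1 s bins aligned at t = 0,
then

ΔF/F(t) = (F(t) − F_baseline) / F_baseline,
F_baseline = median of F over the 30 s before the event.

Trials in which the 405 nm control deviates more than 20% from its
baseline median are excluded (motion/bleaching artifacts); no
isosbestic regression is applied. Per trial the pipeline reports
max ΔF/F over t ∈ [0, 75] s and the trapezoidal area under ΔF/F from
t = 0 to its first return to zero; per group, mean ± SEM traces and
the trial × time heat-map matrix.

**Meals.** A meal is any net weight decrease strictly greater than
0.02 g; decreases separated by less than 15 s count as a single meal.
Detection reads the trace through a dead band (default 0.005 g) so
scale jitter registers no movement, merges nearby bouts, then applies
the size threshold. Outputs: per-meal size/duration, meal frequency,
cumulative-intake curves, per-epoch totals (pre/stimulation/post), and
per-animal session means.

**Cells.** From per-section counts of exclusive classes
(`tac1_only`, `crh_only`, `both`), sections are pooled within animal
and percentages are reported in both conventions (exclusive classes
summing to 100%, and inclusive marker totals). Raw profile counts are
corrected for double counting with Abercrombie's factor
N = n · T/(T + h) (T = section thickness, default 30 µm; h = mean
nuclear height, user-measured). Group dispersion is across animals.

## Worked example

Simulate five feeding sessions and detect meals:

```bash
pstnkit simulate feeding --seed 7 --out sim
pstnkit meals --input sim/manifest.csv --out out
```

`out/meal_stats.csv` then contains, per session, the microstructure
over the first 3 h:

```
subject_id session_id  n_meals  mean_size_g  mean_duration_s  frequency_per_h  total_intake_g
       m01       s000        5       0.3221             24.0           1.6667          1.6104
       m01       s001        5       0.1369             31.0           1.6667          0.6846
       m01       s002        5       0.2731             25.4           1.6667          1.3653
```

All five simulated meals per session are recovered; 1.6667 meals/h is
5 meals over the 3 h window, and `total_intake_g` is the summed bottle
weight lost to detected meals (compare `sim/ground_truth.json`).

The same from Python, for one photometry trial:

```python
from pstnkit import photometry as phot
from pstnkit.simulate import PhotometrySimConfig, gen_photometry_session

session, truth = gen_photometry_session(PhotometrySimConfig(seed=7))
trace = phot.process_session(session)           # 1 Hz, normalized, screened
metrics = phot.trace_metrics(trace)
print(trace.f_baseline, metrics.max_dff, metrics.auc, metrics.t_return_s)
# 99.762  0.2896  5.539  76.0
```

The simulated transient has amplitude 0.3 ΔF/F and a 20 s decay; the
recovered peak is 0.2896 (1 s bin averaging plus 1% noise), the area
under the curve 5.539 ΔF/F·s against the A·τ = 6 of an infinite
noiseless decay, and the noisy trace first touches zero 76 s after the
event.

Other entry points: `pstnkit photometry --input DIR --out DIR`,
`pstnkit cells --input counts.csv --particle-um H --out DIR`, and
`pstnkit run --config cfg.yaml --out DIR` for a full
simulate → analyze → report run (deterministic given the seed; every
file written is listed in `run_report.json`).

## Layout

```
src/pstnkit/
  photometry.py   # downsample, dF/F, QC screen, metrics, group summary
  meals.py        # meal detection, statistics, curves, epoch totals
  cells.py        # co-expression percentages, Abercrombie correction
  simulate.py     # seeded generators + ground truth
  reference.py    # enumeration-based meal-detector oracle (validation)
  io.py           # CSV readers/writers (fixed float format)
  pipeline.py     # config validation, orchestration, run report
  cli.py          # pstnkit simulate|photometry|meals|cells|run
docs/methods.md   # models, parameters, design choices, limitations
```
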