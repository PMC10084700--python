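# broodetect

Detection of parental **brooding** — a parent bird warming its chick under
its body — from miniature multisensor dataloggers glued to the backs of
precocial shorebird chicks (lapwings, *Vanellus* spp.). A logger records
tri-axial acceleration at 25 Hz plus on-body temperature and light level at
1 Hz; `broodetect` turns those raw channels into labeled brooding bouts and
the summary tables that feed downstream mixed models of brooding rate and
brooding efficiency.

The package is aimed at behavioral ecologists working with accelerometry /
biologging data who need a reproducible, testable implementation of this
kind of rule-assisted unsupervised segmentation — including a synthetic
datalogger simulator with ground-truth behavioral states, so every stage of
the pipeline can be validated without any field data.

## The method

1. **Preprocessing** (`broodetect.accel`). Per-axis offset/gain are
   estimated from static windows by an iterative closest-point sphere fit
   (calibrated static vectors are driven toward unit norm). Each axis
   *x(t)* is split into a gravitational component — a centered moving
   median with 0.2 Hz cut-off — and a dynamic residual, which is smoothed
   by a 2 Hz moving median. Overall dynamic body acceleration is
   ODBA(t) = |d_x(t)| + |d_y(t)| + |d_z(t)|.
   All channels are averaged into 5-s bins; ambient temperature and sun
   elevation are joined; the first and last 30 min are trimmed.

2. **Segmentation** (`broodetect.hmm`). For each chick separately, a
   two-state Gaussian hidden Markov model is fitted on
   y_t = log(ODBA_t + ε) by Baum–Welch (EM), and the most probable
   active / non-active path is decoded by the Viterbi algorithm. The
   lower-mean state is "non-active"; its maximal runs become candidate
   brooding bouts.

3. **Rule-based post-processing** (`broodetect.postprocess`). A candidate
   bout overlapping daylight (sun above −6°) is brooding only if its light
   level drops below **50 lx** for part of the bout — plant shade reads
   200–2,000 lx, a chick pressed under its parent reads ≈ 0. Bout
   boundaries are refined with the chick's on-body temperature
   differences (warming onset starts a bout, cooling onset after the
   low-activity period ends it). Brooding bouts and within-brooding breaks
   of up to **20 s** are pruned as positioning artifacts. Chicks above
   **65 g** are flagged: their feathers cover the light sensor.

4. **Summaries** (`broodetect.summaries`). Model-ready tables: brooded vs
   non-brooded minutes per local clock hour (with previous-hour brooding,
   civil-dark night flag, diel sine/cosine, √minutes weights) and brooding
   efficiency — the median on-body temperature of each bout longer than
   5 min after its first 5 min, when the temperature has stabilized at the
   parent-chick equilibrium.

5. **Simulation & evaluation** (`broodetect.synth`, `broodetect.evaluate`).
   The simulator generates diel ambient temperature, an alternating
   semi-Markov behavior sequence whose brooding probability follows
   logistic(intercept + slope·z(T_amb) + night effect), first-order
   on-body thermal relaxation dT/dt = (T_target − T)/τ toward a
   species-specific equilibrium, sun-driven light with shade confounders,
   and state-dependent acceleration with sensor miscalibration. The
   evaluator scores detections against the simulated truth (per-bin
   balanced accuracy, bout-level F1, boundary errors, rate error).

## Worked example

```python
from datetime import timedelta
from broodetect import synth, accel, pipeline, evaluate, summaries
from broodetect.io import ChickRecord

cfg = synth.nl_preset(duration_h=24.0, seed=3)        # temperate-site preset
raw, ambient, truth = synth.simulate_chick(cfg, "nl01")
chick = ChickRecord("nl01", "f01", "NL", 30.0, 25.0, 30.0,
                    raw.start_utc, raw.start_utc + timedelta(hours=24),
                    cfg.lat, cfg.lon)

trace, cal = accel.preprocess_chick(raw, ambient, chick)
bouts = pipeline.detect_chick(trace, chick, seed=1)
report = evaluate.evaluate_chick(bouts, truth, trace)
eff = summaries.efficiency_table(bouts, trace, chick)

print(f"brooding bouts detected: {len(bouts.select('brooding'))}")
print(f"true brooding proportion: {truth.brooding_prop:.3f}")
print(f"balanced accuracy: {report.balanced_accuracy:.3f}")
print(f"bout-level F1 (IoU >= 0.5): {report.bout_f1:.3f}")
print(f"rate error: {report.rate_error:+.4f}")
print(f"median stabilized bout temperature: {eff['median_temp'].median():.1f} C")
```

prints

```
brooding bouts detected: 38
true brooding proportion: 0.460
balanced accuracy: 0.998
bout-level F1 (IoU >= 0.5): 1.000
rate error: -0.0018
median stabilized bout temperature: 37.0 C
```

i.e. on a 24-h synthetic chick the pipeline recovers 38 brooding bouts,
misestimates the brooding proportion by 0.2 percentage points, and the
stabilized bout temperature sits at the preset brood-patch equilibrium
(37.2 °C) to within sensor noise and relaxation error.

The same steps are available as a CLI:

```sh
broodetect simulate --species NL --n 10 --duration-h 48 --seed 42 --out data/
broodetect preprocess --raw-dir data/ --ambient data/ambient.csv \
    --chicks data/chicks.csv --out trace5/
broodetect detect --trace5 trace5/ --chicks data/chicks.csv --out bouts/ --seed 1
broodetect summarize --bouts bouts/ --trace5 trace5/ --chicks data/chicks.csv \
    --out summaries/
broodetect evaluate --pred bouts/ --truth data/truth.csv --trace5 trace5/ \
    --out eval.json
broodetect actogram --trace5 trace5/nl01_trace5.csv --bouts bouts/nl01_bouts.csv \
    --out fig/nl01.png
```

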