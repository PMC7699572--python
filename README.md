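# aircine

Dynamic cine-MRI upper-airway morphometry: phantom simulation,
region-growing lumen segmentation, respiratory-cycle summarization, and
repeated-measures statistics.

## The problem

Sedatives relax pharyngeal dilator muscles and can narrow a child's
upper airway. One way to quantify this is dynamic (CINE) MRI: a single
axial slice — at the nasopharynx (NP) or the retroglossal level (RG) —
is imaged every 300–400 ms for about 72 frames while the patient
breathes, and the airway lumen is measured in every frame. Comparing the
airway's size across anesthetic conditions (e.g., a sedative alone at
baseline "00", then 5/10/15 min after an adjunct drug) is then a
within-subject, repeated-measures problem.

`aircine` implements that whole analysis chain as a tested Python
library with a CLI:

1. **Synthetic phantoms** (`aircine.phantom`) — breathing-modulated dark
   elliptical lumina on noisy gray tissue with exact analytic ground
   truth, at single-sequence or cohort scale. Since real patient images
   from such studies are rarely shareable, the phantoms are the
   validation substrate for everything downstream.
2. **I/O** (`aircine.io`) — DICOM series, NIfTI-1 and multi-page TIFF
   (+ JSON sidecar) readers/writers with pixel-spacing (mm) and
   frame-interval (ms) metadata.
3. **Segmentation** (`aircine.segmentation`) — the semi-automatic
   workflow: a user seed in the lumen on frame 1; 1-D intensity profiles
   through the seed along the transverse (TX, image columns) and
   anterior–posterior (AP, rows) axes; the nearest prominent bright peak
   on each side of the seed marks the tissue flank and sets rectangular
   limits; 4-connected region growing below an automatic (Otsu)
   threshold inside those limits; automatic seed propagation by mask
   centroid across the remaining frames.
4. **Metrics** (`aircine.metrics`) — per-frame cross-sectional area
   (mm²) and AP/TX diameters (mm).
5. **Temporal summary** (`aircine.temporal`) — each metric trace is
   reduced to a "true" minimum (average of all respiratory valleys),
   mean, and "true" maximum (average of all peaks).
6. **Statistics** (`aircine.stats`) — paired t / Wilcoxon signed-rank
   baseline-vs-follow-up comparisons with 95% CIs, percent change and
   paired Cohen's *d* (mean(diff)/SD(diff)); linear mixed-effects
   dose–response models of the change from baseline (fixed effects:
   time level, age, baseline value; random intercept per subject;
   REML) reported as least-squares mean changes; Bonferroni/Holm
   multiplicity adjustment; Dunnett-type many-to-one comparisons
   against baseline via the multivariate-t distribution of the paired
   t statistics.
7. **Power** (`aircine.power`) — exact noncentral-t power and sample
   size for the two-sided paired t-test.

## Worked example

```python
import numpy as np
from aircine import (PhantomSpec, make_phantom_sequence, segment_sequence,
                     sequence_metrics, summarize, paired_t_power, PowerQuery)
from aircine.segmentation import SeedPoint

# a breathing phantom: 5 x 4 mm semi-axes, 20% respiratory modulation,
# 3 s period sampled every 350 ms, noise sd 12, 0.8 px blur
spec = PhantomSpec(ap_semiaxis=5.0, tx_semiaxis=4.0, modulation_fraction=0.2,
                   respiratory_period=3000.0, noise_sd=12.0, psf_sigma=0.8, seed=7)
seq, truth = make_phantom_sequence(spec, identifier="demo")

masks = segment_sequence(seq, SeedPoint(64, 64))     # seed once, on frame 0
metrics = sequence_metrics(masks, seq)
print(metrics.head(3).to_string(index=False))
summ = summarize(metrics)["area"]
print(f"area: t_min={summ.t_min:.1f}  t_mean={summ.t_mean:.1f}  t_max={summ.t_max:.1f}")
print(f"power = {paired_t_power(PowerQuery(22, 0.7, 0.025)):.4f}")
```

prints

```
 frame  time_ms  area_mm2  ap_mm  tx_mm
     0      0.0     60.75   10.5    7.5
     1    350.0     82.25   11.5    9.5
     2    700.0     89.75   11.5    9.5
area: t_min=41.8  t_mean=65.1  t_max=90.0
power = 0.8002
```

The per-frame table gives the lumen area and diameters in physical
units (here 0.5 mm pixels). The summary line says: averaging the eight
detected end-expiratory valleys gives a "true" minimum area of
41.8 mm², the overall mean is 65.1 mm², and the eight inspiratory peaks
average 90.0 mm² — against analytic ground truth of 40.2 / 64.8 /
90.5 mm² for this phantom. The power line reproduces the planning
calculation for a 22-pair paired t-test at a two-sided per-comparison
level of 0.025 and an effect of 0.7 SD of the change: 80% power.

A full cohort run (simulate → segment → metrics → summarize → stats)
is one command:

```bash
aircine run --config run.yaml     # see aircine.pipeline.RunConfig
aircine power --n 22 --d 0.7 --alpha 0.025
aircine segment --in seq.tif --seed 64,64 --out segdir
```

Every stage communicates through files (TIFF/NIfTI stacks, CSV tables),
so stages can be re-run and inspected independently; identical config +
seed reproduces byte-identical outputs.

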