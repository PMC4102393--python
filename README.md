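# nemaswim

Quantitative analysis of *C. elegans* swimming locomotion from video.

Swimming is a richer behavior than crawling — deeper bends, occasional
reversals, curling bouts, vigor that changes second to second — and manual
scoring (counting head bends by eye) misses most of it.  `nemaswim` tracks
multiple swimmers in grayscale video, reduces each animal to its centerline
(the mid-body line of lateral symmetry, tail `s = 0` to head `s = 1`), and
scores ten behavioral measures per frame with robust per-trial summaries and
grouped statistics.  It is aimed at labs doing behavioral phenotyping:
mutant comparisons, aging studies, drug screens.

## The analysis in brief

Every frame's posture is encoded as dimensionless curvature
`k_hat(s, t) = kappa(s, t) * L` sampled on 12 equally long body segments —
the *curvature kymograph*.  Normalizing by body length `L` makes all
curvature measures independent of animal size, image resolution, and frame
rate.  Undulatory swimming is a traveling wave

    k_hat(s, t) ≈ A sin(2π(f_s s + f_t t))

so the kymograph's 2D Fourier magnitude has a single dominant mode
`(f_s*, f_t*)`.  Because swimmers change behavior within seconds, the
transform is *short-time*: computed at every frame over five windows (32,
40, 48, 56, 64 frames), resampled onto a shared zero-padded frequency
raster, and averaged.  The per-frame mode drives most measures:

| measure | meaning | units |
|---|---|---|
| Wave initiation rate | `60\|f_t*\|` — strokes per minute | waves/min |
| Body wave number | `\|f_s*\|` — wave cycles on the body | cycles/body |
| Asymmetry | mean signed curvature over two strokes (side bias) | curvature |
| Stretch | largest curvature range of any body part in two strokes | curvature |
| Attenuation | % deficit of tail-quarter vs head-quarter range | % |
| Reverse swimming | % of time with `f_t* < 0` (tail-initiated waves) | % |
| Curling | % of time an extremity touches the far body ("O"/"6") | % |
| Travel speed | directed motion of the stroke-averaged body center | body lengths/s |
| Brush stroke | area painted in two strokes, in body areas, minus one | body areas |
| Activity index | brush stroke per unit time | body areas/s |

Continuous measures are summarized by the temporal median and the 10–90
percentile range (medians resist the skew of dynamic behavior changes);
reverse swimming and curling are binary states summarized as percentages.

## Worked example

Generate a synthetic swimmer (1.5 Hz stroke frequency, 1.5 waves on the
body, drifting at 0.1 body lengths/s, reversing for 20% of the trial) and
fit the model:

```python
from nemaswim import SwimScenario, SwimTrial

scn = SwimScenario(seed=1, drift_v=0.1, reverse_episodes=((216, 324),))
res = SwimTrial.from_scenario(scn).fit()
print(res.summary())
```

```
Swim trial summary
==================
animal id:        0
frame rate:       18 fps
valid frames:     540/540
head-tail swap:   no

measure                   median       p10       p90  units
------------------------------------------------------------------
wave_initiation_rate      89.990    89.453    89.991  waves/min
body_wave_number           1.500     1.492     1.500  cycles/body
asymmetry                 -0.000    -0.023     0.023  curvature
stretch                    5.949     5.949     5.958  curvature
attenuation                0.000    -0.004     0.004  %
travel_speed               0.100     0.100     0.100  body lengths/s
brush_stroke               3.231     3.222     3.235  body areas
activity_index             2.423     2.376     2.426  body areas/s
reverse swimming            20.0  % of time
curling                      0.0  % of time
```

The generator's ground truth is recovered: 90 waves/min (`60 × 1.5 Hz`),
wave number 1.5, zero side bias, stretch `2A = 6`, 20% time in reverse,
travel speed 0.1 body lengths/s.  `res.plot_kymograph()` draws the
curvature heat map; `res.plot_measure("wave_initiation_rate")` draws one
measure with its median and 10–90 band.

For real data, build the trial from a tracked video or an exchange table
(`frame, point_index, x, y, half_width, valid` — any external tracker that
provides body coordinates and widths can feed the measures):

```python
import pandas as pd
trial = SwimTrial.from_dataframe(pd.read_csv("centerlines.csv"), frame_rate=18.0)
results = trial.fit()
```

From the shell:

```bash
nemaswim track video.tiff --fps 18 --out trackdir/   # segment + track swimmers
nemaswim measure trackdir/ --out results/            # ten measures per animal
nemaswim report results/results_wide.csv --group-by strain --plots plots/
nemaswim simulate --config scenario.yaml --out sim/  # synthetic benchmark data
```

Group statistics (`nemaswim.session.compare_groups`) use the two-sided
Mann–Whitney U test with Holm correction and report mean ± SEM, medians,
and significance tiers; asymmetry is aggregated as |median| per animal so
left- and right-biased animals do not cancel.

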