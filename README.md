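# avprosody

Tools for studying **audiovisual prosody**: how eyebrow raises — a prominent
facial gesture — align in time with voice pitch (F0) during speech.  The
package takes frame-level measurement tables (30 fps: eyebrow height from
68-point 3D facial landmarks, head angles, pitch with gaps at voiceless
frames) plus SubRip subtitles for segmentation, and asks whether the *shape*
of the pitch contour around a brow-raise peak predicts how high the brows go.

It is aimed at researchers in gesture/speech coordination who want a
reproducible, scriptable version of this analysis, together with a synthetic
data generator for power analysis and method validation.

## The model

Each subtitle segment contributes one analysis unit: the frame of maximal
standardized eyebrow height (the *eyebrow peak*), with a window of 121
positions (−60 … +60 frames, ±2 s) of eyebrow and pitch values around it.
Pitch contours immediately before and after the peak are treated as locally
sinusoidal and fitted with a four-parameter baseline-shifted sine,

    y(t) = I + A · sin(2π f t + φπ)

where *I* is the baseline shift, *A* ≥ 0 the amplitude, *f* the ordinary
frequency (cycles/s), and φ ∈ [0, 2) the phase in units of π radians
(categorized as high-rising [0, 0.5), high-falling [0.5, 1), low-falling
[1, 1.5), low-rising [1.5, 2)).  *A* and *f* quantify the contour's
**dynamicity** — how far and how fast pitch moves — while φ captures its
shape at the window's start.

The magnitude of each brow-raise peak is then modeled from the fitted sine
parameters of the pre-peak region (19 frames ≈ 630 ms, peak included) and the
post-peak region (17 frames ≈ 570 ms) with a linear mixed model,

    peak_height ~ A_pre + f_pre + φ_pre + A_post + f_post + (1 | speaker)

estimated by REML with Satterthwaite degrees of freedom.  Supporting
machinery includes a per-position Mann-Whitney "raise scope" test (which
window positions carry significantly elevated eyebrow heights), smoothed
positional summary curves with 95% bands, a 1.5-SD split into low/high
raises, and ML-AIC selection of the best-fitting window size (10–20 frames).

## Worked example

Generate a 5-speaker synthetic corpus (200 segments) whose brow-peak heights
are coupled to the pitch-contour parameters, run the full pipeline, and print
the report:

```python
from avprosody import SyntheticConfig, PipelineConfig, make_report
from avprosody.pipeline import run_synthetic_pipeline

cfg = SyntheticConfig(seed=7, n_speakers=5, segments_per_speaker=40)
bundle, truth = run_synthetic_pipeline(cfg, PipelineConfig(sweep_sizes=(17, 19)))
print(make_report(bundle))
```

Excerpt of the output:

```
windows: 200
pre window: 19 frames (~633 ms); post window: 17 frames (~567 ms)

raise scope (elevated positions): -11 .. 11

model combined (n=102, speakers=5):
            estimate  std_error         df          t          p
Intercept      0.518      0.293     95.997      1.768      0.080
A_pre         -0.036      0.057     95.999     -0.633      0.528
f_pre          0.023      0.208     95.999      0.109      0.913
phi_pre        0.075      0.096     95.998      0.785      0.434
A_post         0.175      0.055     95.998      3.190      0.002
f_post         0.335      0.182     95.999      1.839      0.069
  random-intercept var 0.0000, residual var 0.3260

mean r2 (post): size 17: 0.996, size 19: 0.966
```

Reading this: eyebrow heights are significantly elevated from about 11 frames
before to 11 frames after the peak (the raise scope); the post-peak
amplitude coefficient 0.175 (p = 0.002) says that segments whose post-peak
pitch excursions are larger carry higher brow raises, in z-units of eyebrow
height per z-unit of amplitude.  At this small n the pre-peak phase effect
(generative value 0.238) is present but not individually significant —
estimates stabilize at the generator's default 750 segments.

The same stages are available from a shell:

```sh
avprosody simulate --seed 7 --out sim/
avprosody run --frames sim/frames.tsv --out results/ --sizes 10:20
avprosody report --bundle-dir results/
```

plus stagewise verbs (`windows`, `fit`, `model`, `geometry`, `io validate`)
and `reproduce`, which recomputes the headline quantities from previously
serialized per-segment window tables.

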