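# mitoflow

Deep, multi-feature analysis of mitochondria in fluorescence time-lapse
microscopy: segmentation with watershed declumping, a 22-slot feature
extractor spanning morphology, intensity, texture and motion, a pixel-based
**intensity-flow** motion estimator with a Lucas–Kanade optical-flow
baseline, and supervised classification of mitochondrial morphology
(punctate / networked / swollen) and of cell health (control / stressed).

It is aimed at cell biologists and toxicologists quantifying mitochondrial
phenotype from single- or dual-channel TIFF stacks — including regimes where
mitochondria fuse into networks and cannot be tracked as objects.

## The core method

Mitochondrial motion is estimated from the change in fluorescence intensity
between adjacent frames rather than from brightness-constant feature
tracking. For frames *I<sub>t</sub>*, *I<sub>t+1</sub>*:

1. difference image  *D* = *I<sub>t+1</sub>* − *I<sub>t</sub>*
2. rescale  *D′* = (*D* + *G*) / 2*G* with *G* = 2<sup>bit&nbsp;depth</sup> − 1,
   so *D′* ∈ [0, 1] and "no change" maps to 0.5 (for 8-bit data:
   *D′* = (*D* + 255)/510)
3. region of interest  ROI = *S<sub>t</sub>* ∪ *S<sub>t+1</sub>*, the union of
   the per-frame Otsu segmentations
4. per-pixel motion vectors  ∇*D′* = *u* x̂ + *v* ŷ by central differences,
   restricted to the ROI
5. vector addition over a mitochondrion, class, or cell gives a summed
   vector with magnitude *M* = √(*u*² + *v*²) and angle θ = atan2(*v*, *u*)

Because the estimator reads the gradient of intensity *change*, it makes no
brightness-constancy assumption: signal that fades or redistributes (fusion,
swelling, reporter maturation) still yields meaningful vectors, where
optical flow degrades.

Texture is summarised by the differential box-counting fractal dimension of
the intensity surface (2 = flat, → 3 with roughness) and gliding-box
lacunarity of the binary segmentation (1 = uniform, larger = gappy/clumped).
Morphology classification uses KNN / naive Bayes on per-object features;
health classification uses per-video mean features with KNN, linear
discriminant analysis or an error-correcting output-code classifier, plus an
exhaustive feature-subset search.

All generators needed to validate the pipeline end-to-end (two-frame motion
scenes with known translation, morphology fields with per-object class
ground truth, morphogenesis videos, control/stressed video pairs) ship in
`mitoflow.synth`.

## Worked example

Regenerate the six canonical motion-validation scenes (dot / disc /
rectangle; uniform or uneven intensity; constant or fading to half
brightness; translated 4 px at 30°) and compare intensity flow against
Lucas–Kanade:

```bash
$ mitoflow validate-motion --displacement 4 --angle 30 --seed 1
       case  if_angle_acc  if_mag_acc  lk_angle_acc  lk_mag_acc
  solid_dot         99.80      100.00         99.37      100.00
 uneven_dot         98.71      100.00         99.97      100.00
fading_disc         98.89       71.70         82.53        0.00
 solid_rect         97.50      100.00         93.20      100.00
uneven_rect         89.14      100.00         97.23      100.00
fading_rect         87.14       69.46         86.41        0.00
intensity-flow mean: angle 95.20% magnitude 90.19% | lucas-kanade mean: angle 93.12% magnitude 66.67%
```

Angle accuracy is 100·(1 − |wrapped error|/180); magnitude accuracy
compares each estimator with its own output on the non-fading version of
the scene. On the two fading scenes — where brightness constancy is
violated — the intensity-flow estimator keeps both direction (98.9 / 87.1)
and magnitude (71.7 / 69.5) while the optical-flow magnitude collapses to
zero.

A still image can be pushed through segmentation, feature extraction and
morphology classification from the shell:

```bash
mitoflow synth --kind morphology --counts 5,3,2 --seed 3 --out field.tif
mitoflow segment field.tif --no-declump --out labels.tif
mitoflow features field.tif --masks labels.tif --out features.csv
mitoflow classify-morph features.csv --library training.csv --algo knn --out predicted.csv
# class area fractions: {"networked": 0.386, "punctate": 0.110, "swollen": 0.504}
```

or from Python via `mitoflow.run_pipeline(RunConfig(...), "field.tif", "out/")`.

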