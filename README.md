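# mitocal

Quantitative analysis of **free mitochondrial Ca²⁺ concentration in neurons**
from two-channel ratiometric FRET multiphoton z-stacks.

Genetically encoded cameleon sensors (such as mitochondria-targeted Yellow
Cameleon 3.6) report Ca²⁺ through the ratio *R* of their YFP and CFP emission
intensities. `mitocal` implements the full measurement pipeline around such a
sensor: indicator calibration, mitochondria segmentation, per-organelle
ratio and concentration measurement, Ca²⁺-overload classification, treatment
responses (ΔR/R₀), amyloid-plaque proximity analysis, particle morphology,
longitudinal cell tracking, and hierarchy-aware cohort statistics — together
with a synthetic-data generator that produces every input with known ground
truth, so each stage is testable without microscope data.

It is written for imaging labs quantifying organelle Ca²⁺ in vivo (e.g. in
mouse models of cerebral β-amyloidosis) and for anyone needing a reference
implementation of ratiometric indicator quantification.

## The model

The sensor's titration curve is a Hill sigmoid in free Ca²⁺ concentration *C*:

```
R(C) = Rmin + (Rmax − Rmin) · Cⁿ / (K′dⁿ + Cⁿ)
```

and a measured ratio is converted back with the standard ratiometric
(inverse Hill) equation

```
[Ca²⁺]mit = K′d · ((R − Rmin) / (Rmax − R))^(1/n)
```

The package ships a default curve with the in-situ constants of the
mitochondria-targeted YC3.6 sensor (Rmin = 0.606, Rmax = 2.6921,
K′d = 4.21 µM, n = 1.57). Ca²⁺ **overload** is defined against a control
cohort as *R* > mean + 2·SD of all pooled control mitochondria; a volume is
a treatment **responder** when its mean ratio rises by ΔR/R₀ ≥ 5%.

Image processing follows the fixed chain: per-slice background subtraction
(mean of the bottom 5% of each slice) → per-slice mean filtering (radius 2)
→ local-mean adaptive thresholding of the CFP+YFP sum → 3D connected
components with a physical size constraint. Ratios are ratio-of-sums over
each object's voxels, taken from the unsmoothed background-subtracted
channels.

## Worked example

```python
from mitocal import (subtract_background, smooth, segment_mitochondria,
                     measure_objects, overload_threshold, overload_fraction,
                     volume_summary)
from mitocal.synthetic import generate_stack, generate_cohort, StackSpec

stack, truth = generate_stack(StackSpec(), seed=7)     # 50 objects + noise
bsub, qc = subtract_background(stack)
labels = segment_mitochondria(smooth(bsub))
objects = measure_objects(labels, bsub)

wt = generate_cohort("wt_like", seed=1)                # control object pool
thr = overload_threshold(wt)
print(f"threshold {thr.threshold:.4f}")
print(volume_summary(objects, thr=thr))
```

prints

```
threshold 0.9880
volume_id mouse_id  mean_ratio  n_objects  n_missing_ratio  overload_pct
     vol0   mouse0      0.7476         50                0           4.0
```

The threshold 0.988 is the control pool's mean + 2 SD (the generator's
control preset is N(0.67, 0.16²), whose population value is 0.99); the
segmented stack's 50 mitochondria average *R* = 0.748 and 4% of them exceed
the overload cut. Individual objects carry calibrated concentrations, e.g.
*R* = 0.670 → 469 nM and *R* = 0.807 → 1011 nM.

A `mitocal` command-line tool wraps the same functions
(`mitocal calibrate / convert / segment / quantify / overload / response /
distance / track / compare / simulate`).

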