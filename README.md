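# platepick

Colony detection, screening and robot-frame picklist generation for
Petri-dish photographs.

Small labs increasingly automate clone screening on open liquid handlers:
a camera photographs an agar plate, software finds the colonies, scores
them against user criteria (size, color, fluorescence) and emits the
millimetre coordinates the robot needs to pick each one into a multiwell
plate. `platepick` implements that software half end to end, hardware
free: classical image segmentation, touching-group splitting,
multicriteria screening, pixel-to-robot coordinate mapping, COCO-panoptic
dataset export for training learned detectors, and a detection benchmark
driven by a built-in synthetic plate generator with exhaustive ground
truth — so every stage is testable without a camera, a robot, or any
download.

## Method

**Detection.** The dish wall is located by a circular Hough transform
over a Canny edge map (coarse pass on a 4x-downsampled image, refined by
a least-squares circle fit to the outer-wall edge pixels and a radial
intensity profile that snaps the radius to the outer edge). The dish
bounding box is cropped, and the inner agar disc is binarized with
Gaussian blurring plus adaptive Gaussian thresholding (foreground where
blurred intensity exceeds the local Gaussian-weighted mean by an offset);
each connected component is regularized to its convex hull (Sklansky).
The wall annulus is treated separately — speckle noise, Canny edges with
the known wall circles suppressed, sealing/hole-filling/erosion/top-hat —
so colonies straddling the margin are still found. Touching groups merged
into one segment are split by a local-maximum search: regional maxima of
the smoothed grayscale (minimum separation 0.8 mm, prominence-filtered)
seed a marker-controlled watershed.

**Screening.** Every colony footprint gets three marks in [0, 1] —
min-max-normalized area, HSV-cone distance to a target color (similar or
dissimilar mode), and mean fluorescence / 255 — combined as a weighted
sum `w_size·m_size + w_color·m_color + w_fluor·m_fluor` into a normalized
unitary score. Top-k colonies are picked in descending score order and
assigned destination wells column-wise (A1, B1, ..., H1, A2, ...).

**Coordinate mapping.** A colony centroid c_i in crop pixels maps to the
robot frame by vector addition and rotation: the offset from the labware
centre O_lab is `(O_Pet − O_lab) + (c_i − O_Pet′)` (dish-to-labware plus
colony-to-dish-centre), scaled to mm, converted to a right-handed frame
(y negated) and rotated 90° anticlockwise, with configurable per-axis
sign flags for the physical mount.

**Evaluation.** Detections are greedily matched to ground-truth colonies
within 1 mm (the picking tolerance). Reported metrics: raw performance
(matched fraction, over all and over pickable colonies), accuracy
TP/(TP+FP+FN), misclassification rate, sensitivity TP/(TP+FN) and
precision TP/(TP+FP), where a colony is *pickable* if it sits clear of a
2 mm security margin at the wall and is at least 1 mm in diameter.

## Worked example

`examples/03_screen_and_pick.py` simulates a 50/50 white/blue plate and
screens it for dissimilarity to a blue target color:

```
detected 60 colonies, 59 pickable, picked 10
picklist written to example_output/pick/picklist.csv:
colony_id,dx_mm,dy_mm,score,pick_order,dest_well
49,24.100000,-25.500000,1.000000,1,A1
47,21.926316,30.450000,0.961669,2,B1
51,26.350000,21.850000,0.954311,3,C1
...
```

`dx_mm`/`dy_mm` are robot-frame offsets from the labware centre where the
tip must descend; the highest-scoring (whitest, i.e. most dissimilar to
blue) colonies are picked first into wells filled column-wise. The other
examples cover simulation (`01`), stagewise detection and counting
(`02`), augmented COCO-panoptic dataset building with a leakage-free
75/25 split (`04`), and benchmark evaluation (`05`).

The same pipeline is available as a thin CLI:

```sh
platepick simulate --seed 42 --n 100 --out-dir run/
platepick pick --config config.yml
platepick evaluate --ground-truth run/ground_truth.csv \
    --footprints run/footprints.csv --report run/report.json
```

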