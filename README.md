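# cervtrack

Cervical-spine motion analysis from per-frame vertebra label masks of
dynamic X-ray recordings.

Given a stack of integer label images (one frame per time point, labels
C0–C7), cervtrack

* builds a rigid **mean shape** per vertebra per recording,
* tracks each vertebra's per-frame rotation by translating the mean shape
  to the mask centroid and rotating it for maximal overlap (search window
  ±90° around the previous frame's angle, coarse grid + golden-section
  refinement),
* derives inter-vertebral **relative rotations**, Gaussian-smoothed traces
  (σ = 3 frames), segmental ranges of motion (sROM) and **motion-pattern
  curves** against the cumulative C4–C7 rotation, including the sequence of
  segmental contribution (SSC),
* evaluates segmentations against ground truth with **DSC, IoU and HD95**
  (thresholds 0.8 / 0.7 / 16 mm),
* quantifies agreement between predicted and reference rotation traces with
  **ICC(3,1)** (two-way mixed effects, consistency) including sensitivity
  filters for low sROM (< 4°) and low-quality segments, and Pearson
  correlations of segmentation metrics vs. ICC,
* provides contrast preprocessing (histogram equalization within a patient
  mask; histogram matching to a reference frame), and
* generates **synthetic phantom recordings** — an articulated chain of
  vertebra shapes with programmed segmental kinematics and controllable
  degradation — with analytic ground truth for validation.

## CLI

One entry point with stage-composable subcommands:

```sh
cervtrack simulate --n-frames 150 --size 1024 --seed 1 -o phantom/
cervtrack preprocess --stack gray.tiff --mode equalize -o eq.tiff
cervtrack metrics --pred pred.tiff --gt gt.tiff --spacing-mm 0.2 -o metrics.tsv
cervtrack meanshape --masks masks.tiff --vertebra C4 -o template.tiff
cervtrack track --masks masks.tiff -o traces.tsv
cervtrack pattern --traces traces_segments.tsv -o pattern.tsv --plot pattern.png
cervtrack reliability --pred-traces p.tsv --gt-traces g.tsv -o icc.tsv
cervtrack pipeline --pred pred.tiff --gt gt.tiff -o out/
```

Exit codes: 0 success, 2 configuration error, 3 data error.

Label stacks are multi-page TIFF (uint16) or directories of PNGs, with a
YAML metadata sidecar (`<stack>.meta.yaml`) holding frame rate, pixel
spacing and quality flags. All tables are TSV; missing values are empty
cells.

## Conventions

Images are row-major with origin top-left; x = column, y = row. Angles are
in degrees, positive = counter-clockwise in image coordinates. Label 0 is
background. HD95 is reported in mm when a pixel spacing is known, else in
pixels (flagged).

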