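# vmadapt

A tested, reusable pipeline for analyzing **multi-context visuomotor
adaptation** with fMRI multivariate pattern analysis (MVPA), driven by its
own synthetic-data generator.

## The scientific problem

When people adapt to several visuomotor mappings — here a −90° cursor
rotation, a +90° rotation, and a horizontal mirror reversal — the brain must
represent three distinct levels of task information:

* the **visual direction** of the stimulus on screen,
* the **movement direction** of the hand, and
* the **task context** (which mapping is in force).

Because the context couples visual input to motor output (e.g. under the
−90° rotation a rightward hand movement produces upward cursor motion),
naive decoding confounds the three levels. The pipeline implements
**conjunctional cross-classification**: a linear SVM is trained on one set
of condition cells and tested on another, chosen so that only the targeted
level can support generalization. Training up-vs-down visual directions in
one context and testing them in another context — where the same visual
labels require *different* hand movements — isolates visual coding; the
same construction with roles swapped isolates movement coding; and context
decoding trains on cells matched for visual direction while testing on
cells matched for movement direction, so neither direction level can carry
the label.

The headline question is about **structural learning**: if a subject
extracts the structure shared by two contexts (e.g. "rotation"), their
neural context representations become similar — high *representation
commonality* — which *lowers* context-decoding accuracy. A benefit of
structural learning therefore predicts a **negative correlation between
context-decoding accuracy and behavioral performance**, and the package's
generator plants exactly this mechanism: a monotone link from a subject's
erasing speed (dots/s) to the correlation ρ between their context pattern
vectors.

## What the package contains

| module | contents |
| --- | --- |
| `vmadapt.task_design` | contexts and their 2×2 transforms, type-1 index-1 continuous-carryover trial sequences (every ordered direction pair occurs exactly once per block), 15-block sessions, event timelines |
| `vmadapt.behavior` | erasing-trial simulation, the erasing-speed metric (dots erased / trial duration), the 168-px outlier-trial rule |
| `vmadapt.synthetic` | multi-subject beta-series or 4-D BOLD generation with plantable visual / movement / context patterns, the performance→commonality link, AR(1) noise, motion and global-signal artifacts |
| `vmadapt.first_level` | double-gamma HRF convolution, mass-univariate and per-block MVPA design matrices, OLS beta fits, FD / global-signal scan flagging, Gaussian smoothing |
| `vmadapt.decoding` | train/test pair enumeration (12 / 12 / 8 / 16 pairs), leave-two-block-out CV, 9-mm searchlight, linear SVM (libsvm), accuracy-minus-chance maps |
| `vmadapt.group_stats` | group GLM t-maps, TFCE, max-statistic permutation FWE (sign-flip and Freedman–Lane), Benjamini–Hochberg FDR, ROI tests with uncentered confounds |
| `vmadapt.cli` / `vmadapt.io` | `vmadapt` command-line pipeline, NIfTI and TSV I/O, config and run manifests |

## Worked example

```python
import numpy as np
from vmadapt import synthetic as syn, decoding as dec, group_stats as gs

grid = syn.VolumeGrid((24, 24, 18))           # 3-mm voxels
model = syn.PatternModel(grid=grid)
cohort = syn.sample_cohort(8, model, rng=np.random.default_rng(7))

s = cohort[0]
print(round(s.performance.mean_rotation_speed, 2),
      round(s.performance.mean_mirror_speed, 2), round(s.rho_rotation, 2))
# 1.55 2.22 0.55      erasing speeds (dots/s) and the planted commonality

amap = dec.run_searchlight_decoding(s, "context_rot_rot")
roi = model.region_masks["context_region"] & grid.brain_mask
print(round(float(np.nanmean(amap.values[roi])), 1))
# 37.6               accuracy minus chance (percentage points) in the
#                    region carrying context signal

maps = [dec.run_searchlight_decoding(c, "context_rot_rot",
                                     subdivide_folds=False).values
        for c in cohort]
perf = [c.performance.mean_rotation_speed for c in cohort]
design = gs.GroupDesign(regressors={"performance": np.array(perf)},
                        tested="performance")
t, p = gs.roi_test(maps, roi, design)
print(round(t, 2), round(p, 4))
# -6.01 0.0005       better performers decode worse: the negative
#                    accuracy-performance slope the generator plants
```

The same flow runs from the shell:

```bash
vmadapt run --seed 7 --n-subjects 8 --out-dir results/demo
```

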