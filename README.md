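# echolandmarks

Few-shot anatomical landmark detection in multi-view echocardiograms, for
researchers studying annotation-efficient cardiac image analysis.
Quantifying left-ventricular mass (LVM) needs four landmarks in each of
the standard echo views (A2C, A4C, PLAX, PSAX), but labelled data per
view are scarce. This package treats each view as a task in a
model-agnostic meta-learning (MAML) problem: a Gaussian-heatmap
segmentation network is meta-trained on three views and adapted to the
held-out view from only k labelled frames.

The core pieces:

- **Heatmap codec** — a landmark at x becomes a channel with target
  exp(−‖p − x‖² / 2σ²), σ = 7 px; prediction decodes by per-channel
  argmax (optional matched-filter and subpixel refinement).
- **Meta-learners** — four first-order update rules over a
  backbone-agnostic parameter contract:
  FOMAML (θ_k = θ_{k−1} − α∇L; outer θ_meta ← θ_meta − β∇L_query(θ_K)),
  Meta-SGD (learnable per-parameter α), Meta-Curvature
  (Kronecker-factored gradient preconditioning
  M̂_o M̂_i M̂_f applied as mode-wise contractions) and ANIL (inner loop
  on the head φ only).
- **Backbone** — a miniature encoder–decoder with skip connections
  implemented in pure NumPy with explicit backward passes, so the whole
  protocol runs on one CPU.
- **Phantom views** — a parametric generator of sector-masked,
  speckled chamber images with known 4-point ground truth per view,
  sampled into k-shot episodes.
- **Metrics** — MDE (px), SDR (fraction within threshold), MAE (degrees,
  folded to [0, 90]) and SAS = 100(α|cos θ| + (1−α)e^(−βd)), plus Dice
  and mean pixel accuracy on binarised heatmaps.
- **LVM** — Devereux (0.8·1.04·((IVS+LVID+LVPW)³ − LVID³) + 0.6 g) and
  area-length (1.05·((5/6)A1(a+d+t) − (5/6)A2(a+d)) g) conversions with
  explicit pixel-to-cm calibration.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from echolandmarks import MetaLandmarkDetector, sample_episode, default_view_specs

det = MetaLandmarkDetector(learner="fomaml", heldout_view="PSAX",
                           k_shot=5, meta_iterations=200, random_state=4)
det.fit()                                   # meta-train on A2C/A4C/PLAX

spec = det.view_specs_["PSAX"]              # the unseen view
episode = sample_episode(spec, k=30, n_query=10, rng_seed=20004)
det.adapt(episode)                          # 100 inner steps at rate 0.05
report = det.evaluate(episode.query)
print(f"MDE  {report.mean('mde'):.2f} ± {report.sd('mde'):.2f} px")
print(f"SAS  {report.mean('sas'):.1f}")
```

Output on this seed:

```
MDE  11.80 ± 1.17 px
SAS  38.1
```

meaning the adapted detector localises the four PSAX landmarks of unseen
phantoms to about 12 px on the 64-pixel frames — the same adaptation from
a random initialisation gives about 20 px — while the combined
parallelism/separation similarity of the predicted measurement lines is
38/100 (residual misplacement of ~10 px costs most of the separation
term at the default decay of 0.1 per pixel). PLAX landmarks feed the LVM
formulas once a pixel-to-cm calibration is supplied:

```python
from echolandmarks import (devereux_lvm, segments_to_measurements,
                           default_view_specs, render_phantom)
s = render_phantom(default_view_specs()["PLAX"], 7)
m = segments_to_measurements(s.landmarks, pixel_spacing=0.25)
print(f"IVS {m.ivs:.2f}  LVID {m.lvid:.2f}  LVPW {m.lvpw:.2f} cm;  "
      f"LVM {devereux_lvm(m):.1f} g")
```

```
IVS 1.28  LVID 4.27  LVPW 1.28 cm;  LVM 201.2 g
```

A command-line surface mirrors the library:
`echolandmarks generate | meta-train | fine-tune | evaluate | baseline |
metrics` (see `--help` of each subcommand).

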