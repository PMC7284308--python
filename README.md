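# mtphen

Quantitative phenotyping of 3D cardiac microtissues (MTs) — scaffold-free
spheroids of hiPSC-derived cardiomyocytes (CM), endothelial cells (EC) and
cardiac fibroblasts (CF). The package re-implements, as a tested library,
the image- and signal-analysis pipelines such experiments need:

* **Nuclei reconstruction** — confocal z-stacks are segmented slice by
  slice with a kernel-radius (KR) scaled operator chain (lighting
  homogenization → local-median background subtraction → median/Gaussian/
  maximum enhancement → EDT-seeded flood fill → KR² size filter), sections
  are fitted with equal-area ellipses and linked across z by maximal
  ellipse overlap up to a condition-specific axial cap KZ, and each nucleus
  is summarised by an ellipsoid with volume `V = (4/3)·π·a·b·c`.
* **Cell classification** — nuclei are typed from TNNI / COL1A1 / CD31
  marker intensity inside their ellipse sections (per-section vote, mode
  over the chain); proliferative (Ki67⁺) cells are called by a
  presence/absence pipeline with a 135° line opening that removes fibrous
  structures.
* **Spatial packing** — per-nucleus median distance to the 12 nearest
  neighbours and its tissue-level mean ± SD.
* **Sarcomere organization** — the FFT alignment index (fraction of
  spectral power under the first-order Z-band peak) and sarcomere length
  (Z-band spacing, sub-pixel).
* **Contractility** — Horn–Schunck optical flow on bright-field movies,
  15×15 μm vector binning over a 300×300 μm selection, contraction/
  relaxation profiles of the maximum-velocity bin, five per-beat kinematic
  parameters, contraction direction maps, normalized contraction duration
  `CD/√IBI`, and the pacing-following classifier (rate within ±15% of the
  stimulus and amplitude CV < 28%).
* **Electrophysiology and calcium** — AP features (RMP, APA, APD90, Vmax),
  I_to-notch detection via a −3 mV/ms derivative cutoff after the peak,
  dF/F with mean+SD tissue masking, transient kinetics and the caffeine
  amplitude ratio (SR calcium content proxy).

Every pipeline is verifiable without microscope data: `mtphen.synthgen`
renders stacks, striation images, movies and traces with exact analytic
ground truth (poses, identities, velocities, AP/calcium kinetics).

## Worked example

```python
from mtphen import classification, reconstruction, segmentation, spatial
from mtphen.synthgen import StackRecipe, generate_stack

stack, truth = generate_stack(StackRecipe(seed=1))   # 200 nuclei, 70/15/15
sections = segmentation.segment_stack(stack, "dapi")
nuclei = reconstruction.reconstruct(
    sections, reconstruction.ReconstructionParams(kz=12),
    stack.um_per_px, stack.z_step_um, inplane_correction_px=6,
)
labels = classification.classify_all(nuclei, stack)
print(len(nuclei), classification.composition(labels))
import numpy as np
med = spatial.knn_median_distance(np.array([n.centroid_um for n in nuclei]))
print(spatial.mt_average_distance(med))
```

prints (seed 1):

```
199 {'CM': 67.74, 'EC': 16.67, 'CF': 15.59, 'unclassified': 6.53}
(25.52, 5.00)
```

199 of the 200 rendered nuclei are recovered; the classified composition
is within ~2 percentage points of the generated 70/15/15 mixture; nuclei
sit a median ~25.5 μm from their 12 nearest neighbours in this packing.

The same steps are available from a shell:

```bash
mtphen reconstruct stack.tif --kz 12 --classify --out nuclei.csv
mtphen metrics nuclei.csv
mtphen contraction movie.tif --fps 100 --pixel-size 0.65 --pace 2.0
mtphen traces ap recording.csv
```

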