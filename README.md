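# osteolcn

Automated segmentation and connectomics of the osteocyte
lacunar-canalicular network (LCN) in 2D confocal scans of bone.

Osteocytes — the mechanosensitive cells embedded in bone matrix — sit in
lacunae and talk to each other through dendritic processes running in
canaliculi. The integrity of this network degrades with age (fewer cells,
fewer and shorter connections, more blunted "dead-end" canaliculi), and
quantifying it normally requires slow, expert manual segmentation. This
package automates the measurement chain for researchers in bone biology
and biomedical image analysis:

* **Thresholding segmentation** of somas and dendrites, two pipelines
  sharing pre/post-processing (Gaussian σ=2, binary split at 70, 3×3
  closing, subtraction) around either an Otsu core (histogram restricted
  to [80, 255]) or a Canny core (hysteresis 70/220);
* **Evaluation metrics**: DSC = 2|P∩G|/(|P|+|G|), IoU = |P∩G|/|P∪G|,
  per-class IoU and mIoU;
* **Connectomics**: label mask → dilation (4×4 ellipsoid / 2×2) →
  connected components → graph with osteocytes as nodes V and dendrite
  segments as edges E, plus per-image metrics — |V|, dead ends per node,
  connections per node 2|E|/|V|, connection length and diameter (µm),
  mean shortest path;
* **Training machinery** for pluggable per-pixel classifiers: masked
  DiceCE loss for partial labels, dendrite-label dilation, a
  dendrite-fragmentation penalty (each predicted component of size s
  contributes s^(−λ), discouraging short, disconnected dendrites), AdamW
  with cosine annealing, and a numpy test backbone;
* **Group statistics**: per-image reports compared by two-sided Student's
  t-test (α = 1e-4), mean ± SD per group;
* **Synthetic scene generator** with exact ground truth (image, 3-class
  mask, planted graph) and a parametric young → aged phenotype transform,
  so the whole chain is verifiable without proprietary imaging data.

## Worked example

```python
import osteolcn as o

scene = o.generate_scene(o.SceneConfig(seed=42))      # image + truth
label = o.segment(scene.image, "canny")               # 3-class label
rep   = o.evaluate_label(label, scene.mask)           # vs planted mask
graph, net = o.extract_graph(label, um_per_px=0.284)  # graph + metrics
```

With this seed the scene plants 7 osteocytes, 5 connections and 11
dead-end stubs. The printed results:

```
DSC 0.825  mIoU 0.597  osteocyte IoU 0.703  dendrite IoU 0.490
recovered: 7 nodes, 1 connections, 16 dead ends
connections/node 0.29  dead ends/node 2.29
mean connection length 30.5 um  mean dendrite length 4.4 um  mean diameter 0.66 um
```

Reading this: all 7 somas are found (osteocyte IoU 0.70 — boundaries are
inflated by smoothing, which costs IoU but not detection); the thin
dendrites are recovered only partially (IoU 0.49), so most planted
connections fragment into dead-end pieces — exactly the failure mode that
makes automated LCN connectomics hard, and the reason segmentation-level
scores must be read alongside graph-level recovery. On noise-free scenes
the same graph extraction applied to the *ground-truth* mask recovers
planted node and edge counts exactly.

Run on ground truth instead (`o.extract_graph(scene.mask, ...)`) or
compare groups end-to-end:

```python
aged_cfg = o.degrade_to_aged(o.SceneConfig(), severity=1.0)
# generate 30 scenes per group, segment, extract_graph, then:
comparisons = o.compare_groups(young_reports, aged_reports, alpha=1e-4)
```

The aged group shows fewer osteocytes, lower connectivity, shorter
dendrites and more dead ends per cell, each at p < 1e-4 under the default
study conditions.

The same stages are available from the shell:

```sh
lcn generate --out-dir scenes/ --n-scenes 5 --seed 1
lcn segment  --method otsu --in scenes/scene_00001.tif --out pred.png
lcn evaluate --pred pred.png --truth scenes/scene_00001_mask.png
lcn connectome --label pred.png --um-per-px 0.284 --out-report report.csv
lcn compare  --group-a young/ --group-b aged/ --method canny
```

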