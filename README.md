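# prism

Quantitative analysis of multiplexed neuronal imaging with exchangeable
nucleic-acid probes: single-synapse profiling from sequential confocal
imaging, and DNA-PAINT super-resolution post-processing, plus the design
of locked-nucleic-acid (LNA) imaging probes.

## Who this is for

Labs doing multiplexed immunofluorescence of neuronal cultures in which a
dozen or more protein targets are imaged sequentially with diffusible,
fluorophore-conjugated oligonucleotide probes bound to antibody-conjugated
docking strands. One probe is imaged per round, washed out, and replaced;
the analysis must therefore correct per-round illumination and lateral
drift before any cross-channel quantity is meaningful. The same docking
strands support single-molecule PAINT imaging, whose localization tables
need fiducial-based drift correction, rendering, and colocalization-scale
readouts.

No raw dataset from such experiments is publicly deposited, so the package
ships a first-class synthetic-data module that generates confocal image
sets and PAINT localization streams with full ground truth; every analysis
stage is validated against planted truth.

## What it computes

**Confocal profiling** (`prism.preprocess`, `prism.segmentation`,
`prism.features`, `prism.pipeline`):

- Flat-field correction: per-channel background by morphological opening
  (disk radius 100 px), averaged per plate, normalized to mean 1, divided
  out.
- Round registration: integer (dx, dy) maximizing the normalized spatial
  cross-correlation of the reference channel (MAP2), applied to all
  channels of the round.
- Punctae segmentation: 1% contrast saturation → 5×5 adaptive Wiener
  denoising → white top-hat (disk radius 8) → the binarization threshold
  that maximizes the object count over 100 quantile-spaced candidates →
  watershed splitting of touching punctae. Areas, integrated intensities
  and intensity-weighted centroids are measured on the corrected (not
  enhanced) image.
- Synapse identification: synapsin-I punctae with area strictly greater
  than 0.42 µm², centroids outside the DAPI nuclear mask. Other channels
  attach to a synapse when their weighted centroid lies within 1 µm;
  a synapse with no colocalized punctum in a channel gets intensity 0 and
  area 0 there.
- Statistics: per-image → per-well two-stage averaging; two-tailed
  Student's t-tests of treated vs untreated wells relative to the
  untreated mean; per-group Pearson correlation networks (edge shown when
  mean r > 0.35); replicate-centered tests of correlation differences;
  log / sd-1 / min-0 normalization; exact-method t-SNE (perplexity 40,
  5000 iterations, PCA initialization); kernel-density sub-type maps;
  Ward hierarchical clustering.

**PAINT post-processing** (`prism.paint`): greedy fiducial track linking,
per-track LOESS smoothing of x(t), y(t) averaged into a drift trajectory,
drift correction, 2D-histogram rendering at 5.4 nm bins with Gaussian
smoothing, angle-averaged radial cross-correlation C(r) normalized to a
unit baseline with a 1/e decay-length readout of structure size, and 1D
trans-synaptic profiles (median and Gaussian-fit FWHM = 2√(2 ln 2)·σ̂).

**Probe design** (`prism.probes`): append the two-adenine 3′ anchor,
enumerate maximal complementary stretches between each probe and every
docking strand, score every C(L, 3) LNA substitution scheme with an
empirical cross-hybridization cost (per strand, Σ length^β · n_LNA^α,
assigned cost = max over strands), and return the global minimum-cost
scheme.

## Worked example

Simulate a default field (200 synapses, five synaptic channels, drift,
vignette, noise), profile it end to end, and compare with ground truth:

```python
import numpy as np
from scipy.spatial import cKDTree
from prism.pipeline import run_simulated_pipeline
from prism.simulate import SimConfig

res = run_simulated_pipeline(SimConfig(seed=1))
feats = res["features"]          # one row per detected synapse
gt = res["ground_truth"]

print(len(feats), "synapses detected of", len(gt.synapses), "planted")
px_um = 0.187
d, _ = cKDTree(gt.synapses[["x", "y"]].to_numpy() * px_um).query(
    feats[["x", "y"]].to_numpy() * px_um
)
print("precision at 1 um:", np.mean(d < 1.0).round(3))
print(res["shifts"])
```

prints

```
192 synapses detected of 200 planted
precision at 1 um: 1.0
  round  dx  dy
0     0   0   0
1     1   2   2
2     2   2   3
3     3   0   0
4     4  -3  -1
```

i.e. 96% of planted synapses recovered with no false detections, and the
planted inter-round drift recovered exactly (round 0 is the reference).
The feature table has one `<channel>_intensity`, `<channel>_area_um2` and
`<channel>_mean_intensity` column per synaptic channel, ready for the
statistics in `prism.features`.

The command-line interface exposes the same stages
(`prism simulate-confocal`, `prism flatfield`, `prism register`,
`prism segment`, `prism run`, `prism simulate-paint`, `prism paint-drift`,
`prism paint-render`, `prism paint-radial`, `prism probe-design`); run
`prism --help` for options.

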