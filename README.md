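# graftquant

Quantitative pipelines for studying how cytotoxic T cells distribute
between the vascular and tubular compartments of a rejecting kidney
allograft. During T cell–mediated rejection (TCMR), CD8⁺ lymphocytes
accumulate around tubules while the graft microvasculature is relatively
spared; this package implements the computational side of that question
for researchers working with IHC sections, whole-slide scans, intravital
two-photon movies, and single-cell/bulk transcriptomics:

- **`insilico`** — an agent-based model of T cells wandering a canvas and
  freezing on contact with two compartments ("red" and "blue") of
  predefined areas. Snapshot densities (immobilized cells per mm², scaled
  to an 8 μm cell diameter) let you ask which variable — cell number,
  compartment area, or contact duration — can produce an area-normalized
  density asymmetry. Conditions are compared by one-way ANOVA on the
  red − blue density difference.
- **`ihc`** — CD8⁺ T cell density inside vascular (CD34) or tubular
  (COL-IV) regions of interest: H/E/DAB color deconvolution
  (OD = −log₁₀((I+1)/I₀), Ruifrok–Johnston stain basis), Otsu + binary
  morphology ROI segmentation with manual mask edits, scale-normalized
  Laplacian-of-Gaussian blob detection, and the density readout
  count / ROI area (cells/mm²).
- **`wsi`** — whole-slide CXCL12 chemokine-gradient quantification:
  2048×2048 tiling, empty-tile filtering (>50% background), adaptive
  tissue segmentation on the hematoxylin channel, DAB positivity at
  OD > 0.035, and pixel-sum aggregation into a positive-area fraction and
  a tissue-normalized staining intensity; groups are compared by exact
  Mann–Whitney U tests.
- **`tracks`** — intravital track kinetics: greedy nearest-neighbor
  linking, mean velocity (path length / elapsed time), traveled distance,
  and the arrest coefficient — the time fraction of a track spent below
  2 μm/min, a surrogate for stable immunological synapse formation —
  with Welch t-tests between intravascular and extravascular tracks.
- **`sclineage`** — the single-cell QC rules (genes expressed in >10
  cells; cells with ≤0.3% mitochondrial UMIs and 300–4000 detected genes),
  ln(1 + count/total·10⁴) normalization, and the differentially expressed
  lineage gene (DELG) partition: lineage genes with |logFC| > 0.2 and
  adjusted P < 10⁻⁸, split into endothelial vs tubular-epithelial
  fractions and compared across contrasts by a 2×2 χ² test.
- **`synth`** — seeded, ground-truthed generators for all of the above:
  forward Beer–Lambert IHC tiles with known masks and cell centers,
  gradient slides with exact positive-area fractions, stop-and-go
  persistent-random-walk tracks with known stop structure, and count
  matrices with planted QC violations.

## Worked example

```python
import numpy as np
from graftquant import ihc, insilico, synth

# 1. synthesize an IHC tile with 30 CD8+ cells in a vascular ROI
image, truth = synth.synth_ihc(30, seed=7)
od = ihc.deconvolve(ihc.StainedImage(image, pixel_size=0.5))
roi = ihc.segment_compartment(od.channel("eosin"), "vascular", pixel_size=0.5)
smin, smax = ihc.sigma_range_for_cell(pixel_size=0.5)
blobs = ihc.detect_blobs(od.channel("dab"), smin, smax)
result = ihc.density(blobs, roi)
print(f"detected {result.count} cells in {result.area_mm2:.4f} mm^2 "
      f"-> {result.density_cells_per_mm2:.0f} cells/mm^2 "
      f"(truth: {truth.density_cells_per_mm2:.0f})")

# 2. contact-duration asymmetry in the in silico model
res = insilico.reference_experiment("duration", master_seed=1)
print({k: round(v, 1) for k, v in res["mean_diff"].items()})
print(f"one-way ANOVA p = {res['anova_p']:.2e}")
```

prints

```
detected 30 cells in 0.0294 mm^2 -> 1020 cells/mm^2 (truth: 1020)
{'1:1': -41.0, '2:1': 1082.7, '4:1': 2201.8}
one-way ANOVA p = 1.04e-29
```

The first line shows the IHC pipeline recovering the planted density
exactly. The second shows the in silico model: as the red compartment's
contact duration rises from 1× to 4× the blue one, the red − blue
density difference (cells/mm²) grows from ≈0 to >2000, and the ANOVA
across conditions is decisive. The equivalent experiments varying only
cell number or only compartment area leave the normalized difference
centered on zero.

Every pipeline is also exposed as a CLI subcommand
(`graftquant simulate|ihc-density|wsi-gradient|tracks|scqc|delg|synth`);
see `graftquant --help`.

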