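# endoquant

Quantification of endothelial junction remodelling, YAP localization and
cell motility from fluorescence and brightfield microscopy.

Endothelial monolayers respond to mechanical stimuli (such as hydrostatic
pressure) by remodelling their adherens junctions (AJ): VE-Cadherin
junctions become jagged, N-Cadherin is recruited to junctions ("cadherin
switching"), actin fibers reorient from parallel to perpendicular to the
junction axis, the paracellular barrier opens, YAP shifts into the nucleus,
and cells become more proliferative and motile.  Studies of this biology
rest on a family of bespoke image- and trajectory-quantification steps that
are usually implemented ad hoc in Fiji/MATLAB macros.  `endoquant`
implements them as a tested, reusable Python library with a CLI, plus
synthetic-data generators with attached ground truth so every measurement
can be validated against known answers.

## What it computes

* **AJ mask** from the VE-Cadherin channel: average z-projection →
  rolling-ball background subtraction (radius 300 px by default) →
  automatic "Default" (isodata/intermeans) threshold.
* **Junctional intensity ratio** of a co-stained channel (e.g.
  N-Cadherin): mean processed intensity inside the AJ mask divided by the
  mean outside it.
* **Junctional YAP area fraction**: area(thresholded YAP ∩ AJ mask) /
  area(AJ mask), with a batch-constant threshold.
* **Junction shape descriptors** of manually outlined junctions:
  perimeter P, area A, Feret's diameter F (maximum caliper distance), and
  the normalized descriptors P/F and A/F².
* **AJ–actin orientation mismatch**: per junction ROI (enlarged by 3 µm),
  the actin channel is sharpened and the VE-Cadherin channel blurred
  (σ = 2 px); each is run through structure-tensor orientation analysis
  (cubic-spline gradients, Gaussian window σ = 4 px),

      θ = ½·atan2(2·J_xy, J_yy − J_xx) ∈ [−90°, 90°),

  binned into normalized ten-degree histograms h_actin, h_VE, and scored as
  the L1 distance  Σ_bins |h_actin − h_VE| ∈ [0, 2].
* **YAP nuclear/perinuclear ratio**: mean signal inside each DAPI-derived
  nucleus over the mean in a 2-µm expansion ring (contested ring pixels
  excluded).
* **Marker-positive fraction** (Ki-67/EdU style) and **leak-area
  fraction** (biotin–streptavidin barrier assay).
* **Directionality index** of cell tracks: DI = path length / net
  displacement (1 = straight, larger = meandering), with signed x/y
  displacement decomposition relative to the wound edge.
* **Wound-closure dynamics** from brightfield time-lapse: temporal-median
  background removal → local-variance texture segmentation → per-frame
  wound area and fitted linear closure rate.

Synthetic generators (`endoquant.synthetic_data`) emulate all inputs —
Voronoi-tessellated monolayers with controllable junction jaggedness,
cadherin enrichment, YAP partitioning, marker positivity and leak
patches; von Mises fiber fields; persistent random walks; linearly closing
wounds — and record the *realized* ground-truth values for every field.

## Worked example

```python
import numpy as np
from endoquant import (MonolayerParams, generate_monolayer, build_aj_mask,
                       junctional_intensity_ratio, segment_nuclei,
                       nuclear_perinuclear_ratio, leak_area_fraction)

params = MonolayerParams(seed=7, ncad_enrichment=2.0, yap_nc_ratio=2.0,
                         leak_fraction=0.05)
sample = generate_monolayer(params)

aj = build_aj_mask(sample["VE-Cadherin"], rolling_ball_radius_px=50)
ratio = junctional_intensity_ratio(sample["N-Cadherin"], aj,
                                   rolling_ball_radius_px=50)

nuclei = segment_nuclei(sample["DAPI"])
records = nuclear_perinuclear_ratio(sample["YAP"], nuclei)
nc = np.median([r.nc_ratio for r in records if np.isfinite(r.nc_ratio)])

leak = leak_area_fraction(sample["streptavidin"], "fixed", 60.0)
```

prints (via the accompanying `print` statements):

```
AJ mask area:            2988.0 um^2
N-Cadherin enrichment:   1.98  (generated 2.00)
nuclei segmented:        59
median YAP N/C ratio:    2.00  (generated 2.00)
leak area fraction:      0.0500  (generated 0.0500)
```

The measured junctional enrichment (1.98) and nuclear/cytoplasmic YAP
ratio (2.00) recover the values the field was generated with, and the leak
fraction matches the realized patch area exactly — the synthetic fields
make each quantification auditable against known truth.  (The rolling-ball
radius is 50 px here because the synthetic fields are 256 px across; on
full-resolution micrographs the defaults of 300/80/25 px apply.)

## Command line

```bash
endoquant simulate monolayer --seed 17 --out sim/
endoquant junction-intensity --vecad sim/ve_cadherin.tif \
    --channel sim/n_cadherin.tif --config config.yaml --out quant/
endoquant mismatch --actin a.tif --vecad v.tif --rois rois.csv \
    --pixel-size 0.27 --out scores/
endoquant tracks --input tracks.csv --pixel-size 0.65 \
    --frame-interval 10 --out metrics/
```

Every run writes its outputs as CSV plus a `provenance.json` with the
resolved configuration, so any result can be reproduced byte-for-byte from
its config and seed.  `pixel_size_um` is always an explicit input (pixel
sizes are acquisition-dependent and never assumed).

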