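"""Verify that a tracer construct is secreted from cultured cells.

Simulates a cell-culture field where the extracellular medium is twice
as bright as the cytosol (the signature of a secreted fluorescent
protein), detects the cells with an adaptive local-mean threshold, and
reports the extracellular/cytosolic intensity ratio.
"""

import numpy as np

import microcirc as mc

image, truth = mc.make_cell_field(cytosolic_intensity=40.0,
                                  extracellular_intensity=80.0,
                                  n_cells=12, cell_radius=8,
                                  noise_sd=2.0, size=256, seed=2)

detected = mc.adaptive_mask(image, window=51, sensitivity=0.25, polarity="dark")
overlap = np.logical_and(detected.pixels, truth.arrays["cell_mask"]).sum()
union = np.logical_or(detected.pixels, truth.arrays["cell_mask"]).sum()

print(f"cells placed       : {truth.params['n_cells']}")
print(f"detection overlap  : Jaccard {overlap / union:.3f} vs ground truth")
print(f"secretion ratio    : {mc.secretion_ratio(image, detected):.3f} (detected mask)")
print(f"secretion ratio    : {mc.secretion_ratio(image, truth.arrays['cell_mask']):.3f} "
      f"(truth mask; configured 80/40 = 2.0)")
# A ratio well above 1 means the fluorescence accumulates outside the cells,
# i.e. the construct is secreted; a cytosolically retained construct would
# give a ratio below 1.
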