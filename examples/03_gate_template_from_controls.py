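"""Derive a coccosphere gate template from control samples.

A positive control (cultured coccolithophores, visually confirmed
coccospheres) fixes the diameter and circularity bounds of the
coccosphere region; a negative control (sediment with the calcite
dissolved out) measures how much non-coccolithophore material would
leak into that region.
"""

import numpy as np

from coccogate import (
    GateConfig,
    SampleSpec,
    derive_template,
    make_sample,
)
from coccogate.features import extract_feature_table

# positive control: cultured coccospheres only
pos_images, _ = make_sample(SampleSpec({"coccosphere": 150}, seed=1))
pos = extract_feature_table(pos_images)
pos = pos[pos["detected"]]

# negative control: sediment with calcite removed (no coccospheres left)
neg_images, _ = make_sample(
    SampleSpec(
        {"birefringent_sediment": 400, "nonbirefringent_sediment": 1600},
        seed=2,
    )
)
neg = extract_feature_table(neg_images)
neg = neg[neg["detected"] & np.isfinite(neg["circularity"])]

template = derive_template(pos, neg)
print(f"coccosphere region: diameter {template.diam_range[0]:.3f}-"
      f"{template.diam_range[1]:.3f} um, circularity >= {template.circ_min:.3f}")
print(f"negative-control contamination: "
      f"{100 * template.contamination_fraction:.2f}%")

config = template.apply_to(GateConfig())
print("field gate config now uses:", config.diam_range, config.circ_min)
# The contamination fraction estimates how often non-coccolithophore
# birefringent material would be mistaken for a coccosphere by R1 alone;
# the spot-count gate (R2) then removes coccoliths that share R1.
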