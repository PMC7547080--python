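"""Render a phantom as a noisy confocal stack and detect its nuclei.

Uses the imaging benchmark configuration: a geometrically scaled-down
lens (detection quality only depends on local blob geometry) imaged
with 1.5152 x 1.5152 x 2.992 um voxels and 4 um nuclei.  Detection is
LoG blob likelihood -> dilation maxima -> watershed splitting ->
intensity/circularity filters.
"""

from lensmap3d import DetectionParams, detect_nuclei, match_to_truth, mature_config
from lensmap3d import render_stack, sample_epithelium
from lensmap3d.synthetic import imaging_config

config = imaging_config(mature_config(seed=1))
truth = sample_epithelium(config)
grid, offset = render_stack(truth)
print(f"{len(truth.points)} planted cells rendered into a {grid.shape} stack")

detected = detect_nuclei(grid, DetectionParams(radius_um=3.5))
match = match_to_truth(
    detected[["x_um", "y_um", "z_um"]].to_numpy(),
    truth.true_xyz() - offset,  # truth expressed in the stack frame
    radius=3.5,
)
print(f"detected {len(detected)} nuclei")
print(f"precision {match['precision']:.3f}, recall {match['recall']:.3f}")
# Precision/recall are scored by one-to-one matching of detections to
# planted centres within one detection radius.
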