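"""Generate a synthetic tissue scene with paired imaging-like and
sequencing-like expression readouts, and report what each looks like.

The scene places four spatially clustered cell types, renders them into an
RGB histology-like image, and samples two technology regimes from the same
ground truth: per-cell counts at high capture (imaging-like) and spot-grid
counts at low capture with lateral diffusion and dropout (sequencing-like).
"""

import numpy as np

from stablate.degrade import sparsity_fraction
from stablate.synthetic import (
    SceneConfig,
    generate_scene,
    render_image,
    sample_imaging_counts,
    sample_sequencing_spots,
)

config = SceneConfig(seed=11)
scene = generate_scene(config)
image = render_image(scene)
imaging = sample_imaging_counts(scene, capture_efficiency=0.8, seed=11)
sequencing = sample_sequencing_spots(
    scene, spot_pitch=16.0, capture_efficiency=0.2,
    diffusion_mix=0.2, dropout_prob=0.5, seed=11,
)

print(f"scene: {scene.n_cells} cells, {config.n_cell_types} types, {config.n_genes} genes")
print(f"image: {image.shape} uint8")
print(f"imaging readout: {imaging.cell_counts.shape} counts, "
      f"mean {imaging.cell_counts.mean():.2f}, "
      f"zero fraction {(imaging.cell_counts == 0).mean():.2f}")
print(f"sequencing readout: {sequencing.spot_counts.shape} counts, "
      f"mean {sequencing.spot_counts.mean():.2f}, "
      f"zero fraction {(sequencing.spot_counts == 0).mean():.2f}")
print(f"mean per-gene sparsity, sequencing: "
      f"{sparsity_fraction(sequencing.spot_counts).mean():.2f}")
# The sequencing readout is far sparser at the same ground truth: that gap in
# molecular data quality is what the downstream experiments quantify.
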