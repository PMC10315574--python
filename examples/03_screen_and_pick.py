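"""Full pipeline: screen a white/blue plate and write a robot picklist.

A 50/50 white/blue plate is screened for dissimilarity to a blue target
color (weights 0/1/0): white colonies score highest and are picked
first, blue colonies last.  Selected centroids are mapped from crop
pixels to millimetre offsets from the labware centre in the robot frame
(scale, y-flip to a right-handed frame, 90 degrees anticlockwise).
"""

from pathlib import Path

from PIL import Image
import yaml

import platepick as pp

out = Path("example_output/pick")
out.mkdir(parents=True, exist_ok=True)

params = pp.PlateParams(n_colonies=60, group_fraction=0.0,
                        border_fraction=0.0, artifact_count=0,
                        illumination_gradient=0.05, noise_sigma=2.0,
                        seed=33)
image, gt = pp.generate_plate(params)
Image.fromarray(image.rgb).save(out / "plate.png")

cfg_path = out / "config.yml"
cfg_path.write_text(yaml.safe_dump({
    "image": str(out / "plate.png"),
    "labware_center_px": [500, 500],
    "scale_mm_per_px": params.scale_mm_per_px,
    "out_dir": str(out),
    "screening": {"weights": [0, 1, 0],
                  "target_color": [120, 150, 215],   # the blue phenotype
                  "color_mode": "dissimilar",
                  "k": 10},
}))

result = pp.run_pipeline(pp.load_config(cfg_path))
print(f"detected {result.counts['footprints']} colonies, "
      f"{result.counts['pickable']} pickable, picked "
      f"{result.counts['selected']}")
print(f"picklist written to {result.picklist_path}:")
print(result.picklist_path.read_text().strip())
# dx_mm/dy_mm are the robot-frame offsets from the labware centre the
# liquid handler needs to position its tip over each colony; wells fill
# column-wise (A1, B1, ...).
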