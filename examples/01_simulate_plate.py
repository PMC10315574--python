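"""Generate one synthetic Petri-dish image with exhaustive ground truth.

The generator renders an 87 mm dish with touching colony groups, border
colonies inside the unpickable margin, bright specks, uneven illumination
and sensor noise, plus a co-registered fluorescence channel.  Every
colony's position, size, phenotype and fluorescence level is recorded in
a CSV that the evaluation module can match detections against.
"""

from pathlib import Path

from PIL import Image

import platepick as pp

out = Path("example_output/simulate")
out.mkdir(parents=True, exist_ok=True)

params = pp.PlateParams(n_colonies=120, group_fraction=0.10,
                        border_fraction=0.05, artifact_count=3,
                        illumination_gradient=0.10, noise_sigma=3.0,
                        seed=7)
image, gt = pp.generate_plate(params)

Image.fromarray(image.rgb).save(out / "plate.png")
Image.fromarray(image.fluorescence).save(out / "plate_fluor.png")
pp.write_ground_truth(gt, out / "ground_truth.csv")

n_grouped = int((gt.colonies["group_id"] >= 0).sum())
print(f"rendered {gt.n_colonies} colonies ({n_grouped} in touching groups, "
      f"{gt.n_pickable} pickable) on an "
      f"{params.dish_outer_diameter_mm:.0f} mm dish")
print(f"wrote plate.png, plate_fluor.png and ground_truth.csv to {out}/")
# 'pickable' means: far enough from the dish wall for the robot tip, and
# at least 1 mm in diameter.
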