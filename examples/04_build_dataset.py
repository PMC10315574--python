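"""Build an augmented panoptic training dataset from synthetic plates.

Each segmented plate is expanded into 15 rotation/mirror derivatives and
exported as COCO-panoptic pairs (a JSON record plus a PNG whose pixels
encode segment ids as R + 256 G + 256^2 B).  The train/validation split
keeps all derivatives of one source plate together so augmented copies
never leak across subsets.
"""

from pathlib import Path

import platepick as pp

out = Path("example_output/dataset")
sources = []
for i in range(4):
    params = pp.PlateParams(image_size_px=500, scale_mm_per_px=0.2,
                            n_colonies=30, noise_sigma=2.0, seed=100 + i)
    image, _ = pp.generate_plate(params)
    geom = pp.detect_dish(image, (250.0, 250.0), 0.2)
    crop = pp.crop_dish(image, geom)
    inner = pp.segment_inner(crop, geom, pp.InnerParams(scale_mm_per_px=0.2))
    border = pp.segment_border(crop, geom,
                               pp.BorderParams(scale_mm_per_px=0.2))
    segmap = pp.build_segment_map(inner, border, geom,
                                  crop.dish_center_local)
    sources.append((f"plate{i:03d}", crop.rgb, segmap))

manifest = pp.build_dataset(sources, out)
train, val = pp.split_dataset(manifest, train_frac=0.75, seed=0)
print(f"{len(sources)} source plates -> {len(manifest)} dataset items "
      f"(15 derivatives each)")
print(f"split: {len(train)} train / {len(val)} validation; "
      f"train sources {sorted({i.source_id for i in train.items})}")
print(f"panoptic JSON+PNG pairs written under {out}/")
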