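"""Detect and count colonies on a synthetic plate, stage by stage.

Shows the classical segmentation chain: circular-Hough dish detection,
bounding-box crop, adaptive-threshold binarization of the inner agar
disc with convex-hull regularization, border-annulus treatment, and
local-maximum watershed splitting of touching groups.
"""

import platepick as pp

params = pp.PlateParams(n_colonies=150, group_fraction=0.10,
                        border_fraction=0.05, artifact_count=3,
                        illumination_gradient=0.10, noise_sigma=3.0,
                        seed=55)
image, gt = pp.generate_plate(params)
scale = params.scale_mm_per_px

geom = pp.detect_dish(image, (500.0, 500.0), scale)
print(f"dish: centre ({geom.center_px[0]:.1f}, {geom.center_px[1]:.1f}) px, "
      f"outer diameter {geom.radius_px * scale * 2:.1f} mm "
      f"(true {params.dish_outer_diameter_mm:.1f} mm)")

crop = pp.crop_dish(image, geom)
inner = pp.segment_inner(crop, geom, pp.InnerParams(scale_mm_per_px=scale))
border = pp.segment_border(crop, geom, pp.BorderParams(scale_mm_per_px=scale))
segmap = pp.build_segment_map(inner, border, geom, crop.dish_center_local)
fps = pp.split_groups(segmap, crop.rgb, pp.SplitParams(scale_mm_per_px=scale))

n_multi = sum(1 for r in segmap.records.values()
              if r.supercategory == "colonies" and r.n_colonies > 1)
print(f"segments: {len(segmap.colony_ids())} colony segments "
      f"({n_multi} split as multi-colony groups)")
print(f"counted {len(fps)} colonies; ground truth {gt.n_colonies} "
      f"(error {100 * abs(len(fps) - gt.n_colonies) / gt.n_colonies:.1f}%)")
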