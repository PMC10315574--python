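"""Evaluate detection on a small synthetic benchmark.

Runs the full detection chain on five benchmark-profile plates, matches
detections to ground truth at 1 mm (the robotic picking tolerance) and
prints the pooled metrics: raw performance (matched fraction), accuracy
TP/(TP+FP+FN), misclassification rate, sensitivity and precision.
The canonical 20-plate run lives in scripts/acceptance.py.
"""

import platepick as pp

profile = pp.BenchmarkParams(n_plates=5, master_seed=42)
plates = pp.generate_benchmark(profile)

matches = []
for image, gt in plates:
    scale = gt.params.scale_mm_per_px
    geom = pp.detect_dish(image, (500.0, 500.0), scale)
    crop = pp.crop_dish(image, geom)
    inner = pp.segment_inner(crop, geom, pp.InnerParams(scale_mm_per_px=scale))
    border = pp.segment_border(crop, geom,
                               pp.BorderParams(scale_mm_per_px=scale))
    segmap = pp.build_segment_map(inner, border, geom,
                                  crop.dish_center_local)
    fps = pp.split_groups(segmap, crop.rgb,
                          pp.SplitParams(scale_mm_per_px=scale))
    pp.measure_footprints(fps, crop.rgb, crop.fluorescence, scale)
    pp.flag_pickable(fps, geom, gt.params.margin_mm, scale,
                     gt.params.min_pick_diameter_mm, crop.dish_center_local)
    m = pp.match_detections(fps, gt, crop.dish_center_local, scale,
                            tol_mm=1.0)
    matches.append(m)
    print(f"plate: {gt.n_colonies:3d} colonies, detected {len(fps):3d}, "
          f"TP {m.TP:3d}  FP {m.FP}  FN {m.FN}")

pooled = pp.aggregate_matches(matches)
print(f"\npooled over {len(plates)} plates "
      f"({pooled.total_truths} colonies, {pooled.pickable_truths} pickable):")
print(pp.compute_metrics(pooled).to_table())
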