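# stemfit

Extraction of **diameter at breast height (DBH)** for individual trees from
mobile-laser-scanning (MLS) point clouds of forest plots.

A handheld or backpack LiDAR walked through a plot yields a gravity-aligned
3D map in which ground, stems, low vegetation and survey clutter are mixed.
`stemfit` turns such a map into a per-tree stem table:

1. **Crop** the map to the surveyed plot with a 2D polygon (boundary points
   kept).
2. **Ground removal** — the dominant near-horizontal plane is found with
   RANSAC (3-point hypotheses, a tilt gate against walls/stems, consensus
   maximisation, one total-least-squares refinement); points within a removal
   band around it are classified ground. A grid DTM (per-cell minimum ground
   elevation, bilinearly interpolated) converts z into height above *local*
   ground.
3. **Tree instance segmentation** — Euclidean cluster extraction: connected
   components of the graph linking points within a distance tolerance
   (default 0.5 m), size-filtered.
4. **DBH fitting** — each tree is sliced at three height bands above ground,
   1.0–1.1 m, 1.1–1.2 m and 1.2–1.4 m (half-open, so they tile 1.0–1.4 m),
   projected to the horizontal plane, and fitted with a RANSAC circle
   (circumscribed circles of random triples, radius limits 0.04–0.25 m,
   inlier threshold 1 cm) refined by geometric least squares. The diameter,
   in cm, is the DBH; each fit carries a **credibility**
   `C = inliers / slice points` in [0, 1].
5. **Evaluation** against a reference stem table: mean absolute error
   `(1/n) Σ|d̂ᵢ − dᵢ|`, mean relative error `(1/n) Σ|d̂ᵢ − dᵢ|/dᵢ` (in %),
   their sample variances, `RMSE = √((1/n) Σ(d̂ᵢ − dᵢ)²)`, the Pearson
   correlation between credibility and absolute error, and selection of the
   interval with the smallest mean absolute error.

Because no public benchmark provides a forest map with exhaustively measured
stems, the package ships a **synthetic forest simulator**: ~71 tapered-
cylinder stems on a 35 m × 30 m plot (DBH 11.75–32.78 cm, mean ≈ 20.93 cm),
undulating ground, Gaussian radial sensor noise, a warning-line clutter loop
at 2 m height, plus occlusion and density-jitter operators that mimic
one-sided scanning and platform shake. Every point is labelled, so each
pipeline stage can be validated against exact ground truth.

## Worked example

```python
import stemfit

scene = stemfit.generate_forest(stemfit.ForestConfig(seed=1))
print(f"scene: {len(scene.cloud):,} points, {len(scene.truth)} stems")
result = stemfit.run_pipeline(scene.cloud, truth=scene.truth,
                              config=stemfit.PipelineConfig(seed=1))
print(f"instances: {len(result.instances)}, matched: {len(result.matches.pairs)}")
cols = ["interval", "n", "mean_abs_error_cm", "mean_rel_error_pct",
        "rmse_cm", "credibility_sd"]
print(result.report.per_interval[cols].round(3).to_string(index=False))
print("selected interval:", result.report.selected_interval)
```

prints

```
scene: 2,598,431 points, 71 stems
instances: 71, matched: 71
interval  n  mean_abs_error_cm  mean_rel_error_pct  rmse_cm  credibility_sd
1.0-1.1m 71              0.255               1.341    0.324           0.026
1.1-1.2m 71              0.224               1.170    0.269           0.026
1.2-1.4m 71              0.162               0.831    0.200           0.020
selected interval: 1.2-1.4m
```

All 71 stems are segmented and matched; DBH is recovered with a mean
absolute error of ~0.2–0.3 cm (relative error ~1 %). On this clean synthetic
plot the widest slice (1.2–1.4 m, most points) wins the interval selection;
on real scans the lowest interval tends to win because upper slices collect
more branch clutter.

The same run from a shell:

```sh
stemfit simulate --out scene.ply --truth truth.csv --seed 1
stemfit pipeline --in scene.ply --truth truth.csv --out report/
```

which writes `report/instances.csv`, `report/per_tree.csv`,
`report/summary.csv` and diagnostic plots.

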