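# treeclass

Tree-component classification for hyperspectral LiDAR (HSL) point
clouds. An HSL scanner records, for every scan point, 3D coordinates
plus a 101-channel spectrum of laser-echo intensities (550–1050 nm,
5 nm steps). `treeclass` turns such scans of fruit trees into per-point
component labels — **unripe fruit, ripe fruit, wood, leaf** — and a
colored 3D reconstruction, for people doing orchard phenotyping,
fruit-load estimation or wood–leaf separation.

The core method, per point *t* and channel λ_i:

1. **Calibration** against a white reference panel of reflectivity ρ_b:
   ρ_t(λ_i) = V_t(λ_i)/V_b(λ_i) · ρ_b(λ_i).
2. **Spectral features** (9): R700, R730, R780, R850, R900,
   AVG R760–R930, CI_red_edge = R780/R710 − 1,
   NDVI = (R800 − R670)/(R800 + R670),
   NDRE = (R790 − R720)/(R790 + R720).
3. **Preliminary classification** with a random forest (8 trees),
   RBF-SVM (γ = 0.1, C = 10) or a 9–5–4 sigmoid network, trained on a
   7:3 split of labeled points.
4. **Spatial reprogramming**: every point is reassigned the plurality
   class of its N = 12 nearest neighbors by Euclidean distance
   S(i,j) = √((i_x−j_x)² + (i_y−j_y)² + (i_z−j_z)²). Spectra are
   degraded where the laser footprint straddles a component's
   silhouette, so spectral-only classification fails exactly where
   geometry is most informative; this pass repairs those edge points.
5. **Evaluation** by coordinate-matched comparison with an annotated
   truth set: per-class accuracy K_j = T_j/H_j and overall
   K_Overall = ΣT_j/ΣH_j.

Because public HSL tree scans are scarce, the package includes a
synthetic scene generator (trunk/branch cylinders, fruit spheres, leaf
discs; class-typical spectra; attenuated and flattened edge spectra)
used by the test-suite and the example below.

## Worked example

```python
import treeclass as tc

# a 5,000-point synthetic tree: 1,500 wood, 2,000 leaf, 750+750 fruit,
# 15% edge points with attenuated, flattened spectra
scene = tc.generate_scene(tc.SceneConfig(seed=0))
truth = scene.cloud.labels

table = tc.extract_features(scene.cloud)
tr, va = tc.split_dataset(table, truth, train_fraction=0.7, seed=0)
model = tc.train(tc.FeatureTable(table.values[tr]), truth[tr],
                 tc.ClassifierConfig(method="rf", seed=0))
preliminary = tc.predict(model, table)

enhanced, changed = tc.reprogram_labels(
    scene.cloud.coords, preliminary, tc.ReprogramConfig(n_neighbors=12))

print("preliminary K_Overall:", round(tc.score(preliminary, truth).overall_accuracy, 4))
print("enhanced    K_Overall:", round(tc.score(enhanced, truth).overall_accuracy, 4))
print("changed points:", changed.sum(),
      "| at edges:", round(scene.edge_flags[changed].mean(), 2))

tc.export_reconstruction(scene.cloud, enhanced, tc.DEFAULT_COLORMAP,
                         "reconstruction.ply")
```

Output:

```
preliminary K_Overall: 0.979
enhanced    K_Overall: 0.9998
changed points: 106 | at edges: 0.81
```

Spectral-only classification misses ~2% of points, almost all at
component edges; one reprogramming pass recovers nearly all of them,
and 81% of the labels it rewrites sit on edge-flagged points — the
changes concentrate where the spectra were degraded. `reconstruction.ply`
is a standard colored point cloud viewable in CloudCompare or MeshLab.

The same flow is available from the shell:

```sh
treeclass simulate --seed 0 --n-points 5000 --out scene.csv --truth truth.csv
treeclass run --config run.yaml          # full pipeline, all artifacts
treeclass sweep-n scene.csv              # K_Overall for N = 9..15
```

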