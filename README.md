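# morphaline

Toolkit for placing recordings of developing tissue on a common
**morphological timeline** and analysing tissue-flow kinematics:

- **Timeline registration** — pairwise frame-similarity matrices (Pearson on
  images, vorticity correlation, vector-angle correlation, stripe-curve
  correlation) are turned into monotone *correspondence curves* by a
  weighted shortest path restricted to down/right moves, so the mapping is
  order preserving. Multiple recordings fuse into a consensus timeline
  (medoid initialisation + one averaging refinement pass).
- **Timestamping** — static (fixed/stained) snapshots are placed on the
  consensus timeline by χ² minimisation; the 1-σ uncertainty follows from
  the curvature of a parabola fit to χ²(t) (σ_t² = 2/χ²″).
- **Kinematics** — minimal block-matching PIV, RK4 pathline integration
  (bilinear/linear interpolation, 0.2 min steps), displacement fields,
  velocity autocorrelation matrices and dynamic-programming segmentation of
  stationary flow *modules*.
- **Temperature scaling** — speed-curve collapse (v → v/max v, t → t·max v),
  temperature-rescaled integration endpoints, displacement-field comparison
  against in-condition variance (Welch t + Benjamini–Hochberg), mitotic
  division-time ratios, and pattern-decorrelation timescales (two-term
  Gaussian fit t_obs; t_est = c·w/v with threshold e^{−1/2} ≈ 0.61).
- **Deforming surfaces** — ICP rigid registration (principal-axes
  initialisation, Kabsch/SVD fit), shape-based similarity matrices feeding
  the same monotone-path alignment, cotangent mean curvature with mixed
  Voronoi areas, out-of-plane deformation 2·H·v_n, and Lagrangian
  (material-frame) correlation matrices.
- **Synthetic data** — ground-truthed generators for piecewise-stationary
  flows, advected stripe videos, monotone time warps, temperature-proxy
  ensembles, fixed samples at hidden times, and constricting-tube mesh
  sequences; every analysis stage is tested against these generators.

## Command-line interface

```bash
# synthetic data with ground truth
morphaline simgen embryo   --seed 0 --out data/embryo
morphaline simgen ensemble --seed 0 --n 3 --out data/ensemble
morphaline simgen tube     --seed 0 --out data/tube

# similarity matrix and pairwise timeline alignment
morphaline simmat -a data/embryo/stripe.tif -b data/embryo/stripe.tif \
    --measure pearson -o m.csv
morphaline align pairwise -m m.csv -o curve.csv
morphaline align consensus -c 0:1:c01.csv -c 1:2:c12.csv -o timeline.json
morphaline align timestamp --sample fixed.tif --timeline consensus.tif -o ts.json

# stationary flow modules from the velocity autocorrelation
morphaline modules -i data/embryo/flow.csv --measure vorticity \
    --threshold 0.6 --min-len 3 -o modules.json

# temperature-scaling analyses
morphaline scale collapse -i flow17.csv -i flow22.csv -i flow27.csv -o collapse.json
morphaline scale mitotic --cold cold.csv --hot hot.csv -o ratio.json
morphaline scale decorrelation --width 19.0 --speed 3.13

# deforming-surface pipeline
morphaline midgut register -a data/tubeA -b data/tubeB -o shape_sim.csv
morphaline midgut deform -i data/tube -o deform/
morphaline midgut autocorr -i data/tube -o lagrangian.csv
```

File formats are plain text wherever possible: velocity fields and curves as
CSV, matrices as CSV with JSON sidecars, meshes as ASCII PLY with a JSON
manifest; image sequences as multi-page float32 TIFF with a JSON sidecar.

## Conventions

Arrays are indexed `[i1, i2]`: axis 0 is the longitudinal chart coordinate
x1, axis 1 the circumferential (periodic) coordinate x2. All times are in
minutes, positions in μm, velocities in μm/min. Frame k of a sequence sits
at `start_time + k·dt`. Missing data travels as explicit boolean masks and
all statistics are pairwise-complete. Grid conventions (x1 truncation at
the poles, x2 periodicity by index wrapping) are applied by
`apply_grid_conventions` and honoured by PIV, finite differences and
interpolation.
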