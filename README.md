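# peddrs

Iterative probabilistic region-scaling reconstruction for Cerenkov
luminescence tomography (CLT).

CLT infers the 3-D distribution of an internal Cerenkov-emitting source
(for example an ¹⁸F-FDG-avid tumour) from the faint optical signal on
the animal's surface. With a diffusion-approximation finite-element
forward model, the measurement is linear, `A x = B`, but severely
ill-posed: one-step regularised inversions (Tikhonov, damped SVD, L1,
OMP) smear or misplace deep sources. This package implements a
multilevel probabilistic *energy-distribution density region scaling*
framework that wraps any of those solvers: each iteration's solution is
scored by residual norm and cosine similarity, converted to a
probability weight, and treated as a spatial probability mass whose
weighted covariance defines an oriented cuboid region of interest for
the next, smaller solve. A geometric node-budget schedule
`β = (Cut_Num/Num_f)^(1/(L_max−1))` controls the shrink rate, and the
final field is the probability-weighted fusion of the iterations whose
scores lie within one standard deviation of the mean.

The package contains, as first-class tested code:

- `peddrs.phantom_mesh` — structured tetrahedral phantoms, tissue optics
  (630 nm mouse-organ table), embedded sphere/cube/cylinder/ellipsoid
  sources with ground-truth node sets;
- `peddrs.forward_model` — P1 FEM assembly of the diffusion operator
  with Robin boundary conditions, Green-operator system matrix, noisy
  measurement synthesis;
- `peddrs.inverse_solvers` — Tikhonov, damped SVD, soft-thresholded
  LSQR (L1), and orthogonal matching pursuit;
- `peddrs.peddrs_core` — the iterative framework;
- `peddrs.metrics` — location error E_L, Dice, volume ratio R_V,
  relative residual R_R;
- `peddrs.cli` / `peddrs.fileio` — `simulate → reconstruct → evaluate`
  commands over legacy VTK, Matrix Market, CSV and JSON.

See `docs/methods.md` for the model, parameter defaults, and what the
synthetic studies do and do not demonstrate.

## Worked example

```sh
cat > config.yaml <<'EOF'
extent: [13, 13, 15]
spacing: 1.0
source: {shape: sphere, center: [6, 7, 8], radius: 1.25}
noise_level: 0.05
seed: 1
EOF
peddrs simulate --config config.yaml --outdir out
peddrs reconstruct --mesh out/mesh.vtk --matrix out/A.mtx \
    --measurements out/B.csv --solver tikhonov \
    --out out/result.vtk --audit out/audit.csv
peddrs evaluate --result out/result.vtk --truth out/truth.json \
    --matrix out/A.mtx --measurements out/B.csv
```

which prints

```
center_x,center_y,center_z,e_l,dice,r_v,r_r
6.022302234243307,6.97850065355915,8.004147780801452,0.03,0.23728813559322035,0.1346153846153846,0.8536472296545895
```

The reconstruction ran 50 iterations (about 8 s) on the 3,136-node
phantom and localised the 1.25 mm sphere at (6, 7, 8) mm to within
**E_L = 0.03 mm**; the one-step Tikhonov solve on the same data is ten
times less accurate (E_L = 0.30 mm) and smears intensity through the
whole volume (Dice 0.016, R_V 0.008 versus 0.24 and 0.13 here).
`dice` and `r_v` score the region of nodes above
10 % of the peak intensity against the true source nodes: the fused
field's top-ranked nodes are exactly the true set, but the fusion keeps
a halo above that threshold, so the region is larger than the source
(see the limitations section of `docs/methods.md`). `r_r` is the
relative residual of the (sum-normalised) final field. `out/audit.csv`
holds the per-iteration trail: active-set size, budget, scores, weight.

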