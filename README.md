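# flowvasc

Quantification of endothelial flow responses for vascular-biology
image analysis: how endothelial cells polarize and migrate under fluid
shear stress, how labelled cell populations redistribute along the
vein–artery axis of the postnatal mouse retina, and how much of the
capillary plexus regresses during remodelling.  The package is aimed
at groups studying flow-migration coupling and its failure modes in
vascular malformations (e.g. BMP-pathway loss-of-function models of
hereditary hemorrhagic telangiectasia); it consumes segmentation
outputs — label images, binary masks and track tables — not raw
microscopy.

## What it computes

* **Polarity & morphology** — per-cell nucleus→Golgi polarity angles
  from label images; polarity index `PI = |mean e^{iθ}|` ∈ [0, 1] and
  signed polarity index (V-score) `V = mean cos(θ − ref)` ∈ [−1, 1]
  relative to the flow direction; axial (doubled-angle) orientation
  statistics per image; cell area, elongation (major/minor axis) and
  nuclear/cytosolic marker ratios.
* **Migration under flow** — forward-difference step velocities
  decomposed into flow-parallel and orthogonal components
  (`v_par = v·û`, positive = with flow); per-condition velocity
  curves with replicate-level bootstrap CIs; start-normalized
  bootstrapped trajectory ensembles (100 tracks/replicate × 4
  replicates = 400); two-population mosaic contrasts.
* **Retina vein–artery axis** — per-pixel distances to the nearest
  vein (d_v), artery (d_a) and the optic nerve (d_r) via Euclidean
  distance transforms; the arteriovenous coordinate
  `φ = d_v/(d_v + d_a)` (0 = vein, 1 = artery); boundary-corrected 2D
  KDE over (φ, d_r); axis histograms for whole mount and remodelling
  plexus; per-retina arterial 90th-percentile statistics.
* **Vessel regression** — empty-sleeve detection from paired
  CD31/ColIV masks (ColIV present, CD31 absent), staged as
  intermediate / final / long-regressed; branching points from 3D- or
  2D-skeletons; regression frequency per 100 CD31 branching points;
  CD31/ColIV density ratios normalized to the ROI volume ratio.
* **Estimation statistics** — seeded bootstrap mean-difference
  distributions with percentile 95% CIs (difference = mean(A) −
  mean(B)), plus Welch/t/Mann-Whitney wrappers.
* **Synthetic data** — fully seeded generators for all four assays
  (von Mises polarity, drift-diffusion tracks, radial retinas with a
  target (φ, r) mixture, lattice vessel networks with planted
  regression events), each emitting its ground truth.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

```python
import numpy as np
import flowvasc as fv

# a monolayer of 1000 cells polarized against flow (flow along +x)
params = fv.MonolayerParams(n_cells=1000, kappa=2.0, mu=np.pi, seed=42)
sample = fv.gen_monolayer(params)

records = fv.extract_cells(sample.cells, sample.nuclei, sample.golgi,
                           sample.markers)
summary = fv.circular_summary([r.angle for r in records], reference=0.0)
print(f"n = {summary.n}")
print(f"PI = {summary.pi_:.3f}")
print(f"V  = {summary.v:.3f}")
print(f"mean direction = {np.degrees(summary.mean_direction):.1f} deg")
print(f"mean NUC/Cyt ratio = "
      f"{np.mean([r.ratios['psmad159'] for r in records]):.3f}")
```

prints

```
n = 1000
PI = 0.689
V  = -0.688
mean direction = 177.6 deg
mean NUC/Cyt ratio = 2.000
```

The monolayer is moderately aligned (PI ≈ 0.69, the expected mean
resultant length of a von Mises population with κ = 2) and the
alignment points against the flow direction: the mean direction is
~180° and the V-score relative to flow is negative, i.e. the
nucleus→Golgi axes face upstream.  The marker channel was generated
with a nuclear enrichment of 2×, and the recovered nuclear/cytosolic
ratio is 2.000.

The same analyses are available from the shell:

```sh
flowvasc simulate monolayer --out sim/mono --seed 1
flowvasc polarity --cells sim/mono/cells.tif --nuclei sim/mono/nuclei.tif \
    --golgi sim/mono/golgi.tif --flow-angle 0 --out out/pol --seed 1
flowvasc simulate tracks --out sim/tracks --seed 1
flowvasc migrate --tracks sim/tracks/tracks.csv --out out/mig --seed 1
```

Each command writes CSV reports (and figures) into `--out`; the
`retina`, `regression`, `estimate` and remaining `simulate`
subcommands follow the same pattern (`flowvasc --help`).

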