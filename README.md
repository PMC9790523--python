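# lgedixon

Simultaneous quantification of **left-atrial (LA) wall fibrosis** and
**epicardial adipose tissue (EAT)** from dual-echo late-gadolinium-enhanced
Dixon (LGE-Dixon) cardiac MRI — implemented end-to-end on synthetic data,
from the complex echoes to the agreement statistics.

Atrial fibrosis and the fat pad around the left atrium are both risk
factors for atrial fibrillation, and a water–fat separated LGE acquisition
can measure both in a single scan: the water image carries the enhancement
contrast for scar, the fat image delineates the EAT, and the two are
intrinsically co-registered. This package re-implements that analysis chain
as testable code:

- **`phantom`** — a seeded digital LA phantom (ellipsoidal blood pool, thin
  intramural wall shell with bright scar patches, epicardial fat cap,
  mitral-valve / pulmonary-vein / appendage exclusion structures) plus a
  forward simulator for the dual-echo inversion-recovery spoiled-GRE
  acquisition (TR/TE1/TE2 = 7.1/2.2/4.8 ms, 1.25 × 1.25 × 2.5 mm³ voxels,
  single-peak fat at −3.4 ppm, B0 field map, complex Gaussian noise).
- **`dixon`** — flexible-TE two-point water–fat separation: per-voxel
  phasor-ambiguity candidates, region-growing field-map estimation
  (magnitude-ordered, neighbor-consistency selection), linear
  least-squares water/fat solve, and a water–fat swap-rate diagnostic.
- **`quantify`** — the wall-only mask by structure subtraction, the
  patient-specific scar threshold at the midpoint of the mean blood-pool
  and mean mitral-valve signal intensity on the water image,

      threshold = SI_blood + (SI_MV − SI_blood) / 2,

  fibrosis as `100 · #{wall voxels with SI > threshold} / #wall voxels`,
  and EAT volumetry (voxel count × voxel volume, optionally indexed to
  Mosteller or Du Bois body surface area).
- **`agreement`** — ICC(A,1): the two-way, absolute-agreement,
  single-measurement intraclass correlation with its F-based 95% CI,

      ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

  Bland–Altman bias / SD / limits of agreement (bias ± 1.96·SD), and a
  seeded rater simulator for parameter-recovery experiments.
- **`pipeline` / `lgedixon` CLI** — orchestration of
  simulate → separate → quantify → agree over a (seed × noise) grid, with
  JSON config validation, tidy CSV/JSON outputs, and three canonical test
  scenes.

## Worked example

```python
from lgedixon import AcquisitionParams, PhantomSpec, run_cell

cell = run_cell(PhantomSpec(scar_fraction=0.30), AcquisitionParams(),
                noise_sigma=0.0, seed=0)
print(f"blood SI      {cell['mean_blood_si']:.4f}")
print(f"MV SI         {cell['mean_mv_si']:.4f}")
print(f"threshold     {cell['threshold']:.4f}")
print(f"fibrosis      {cell['fibrosis_pct']:.2f} % "
      f"({cell['scar_voxels']}/{cell['wall_voxels']} wall voxels)")
print(f"EAT           {cell['eat_volume_ml']:.2f} mL")
print(f"swap rate     {cell['swap_rate']:.3f}")
```

prints

```
blood SI      0.3343
MV SI         0.4657
threshold     0.4000
fibrosis      30.00 % (2647/8824 wall voxels)
EAT           15.61 mL
swap rate     0.000
```

The scene was designed with 30% of wall voxels fibrotic: the blood pool and
enhancing mitral valve set the threshold at 0.400 signal units, scar voxels
(0.466) sit above it and the inversion-nulled healthy wall (≈0) below, so
the pipeline recovers the designed fraction exactly; the EAT cap of the
default scene measures 15.6 mL, a typical clinical magnitude. The same
stages are available from the shell:

```bash
lgedixon simulate --out scene/ --scar-fraction 0.3 --seed 1
lgedixon quantify --scene scene/ --out report.json --height-m 1.80 --weight-kg 80
lgedixon agree icc --table ratings.csv
```

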