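# Methods

## Scope and data flow

The package quantifies left-atrial (LA) wall fibrosis and epicardial
adipose tissue (EAT) from a dual-echo LGE-Dixon acquisition. Because
patient scans are not available, a digital phantom supplies every input:
scene geometry and tissue maps, the complex echo pair, and the structure
masks a reader would trace. The stages are phantom → two-point Dixon
separation → wall derivation and thresholding → volumetry → agreement
statistics, each usable independently.

## Phantom and forward model

**Geometry.** The scene is analytic, not anatomical: an ellipsoidal blood
pool (default semi-axes 34 × 30 × 26 mm), a wall shell of constant 3 mm
thickness around it, an epicardial fat cap (6 mm thick, half-angle 50°
about +z) outside the wall, and exclusion structures intersecting the wall
(mitral-valve disc at the inferior pole, two pulmonary-vein antra at the
±x poles, an appendage stub at +y). Shells are defined by the first-order
signed distance to the ellipsoid surface, d = (ρ − 1)/|∇ρ| with
ρ the normalized ellipsoidal radius — exact for spheres and free of the
half-voxel bias a mask-based distance transform would introduce, so
voxel-count volumes of spherical shells match their continuous volumes to
well under 1% at the default 1.25 × 1.25 × 2.5 mm³ voxels. The default
grid is 96 × 96 × 48 (120 mm field of view per axis), which runs every
stage in seconds. Scar is placed as the `round(f · N_wall)` wall voxels
nearest to a few seeded patch centers, so the realized fraction matches
the requested `f` to within rounding (the generator rejects specs it
cannot realize within 2 percentage points).

**Signal.** Each voxel has water density W, fat density F and one T1. The
complex signal at echo time TE is

    S(TE) = A(T1, TI) · (W + F·e^{i·2π·f_fat·TE}) · e^{i·2π·ψ·TE} + η,

with a single-peak fat resonance at −3.4 ppm (f_fat ≈ −217 Hz at 1.5 T), a
smooth B0 field ψ (constant, linear ramp, or Gaussian bump; amplitude in
Hz), and i.i.d. complex Gaussian noise η whose per-component SD is given
as a fraction of the noiseless blood-pool signal (derived magnitude images
are therefore Rician). The inversion weighting is the idealized
magnitude-restored form A = |1 − 2·e^{−TI/T1}|; readout-train effects on
contrast are deliberately ignored. A multi-peak fat spectrum would make
the two-point inverse ill-posed, so the single-peak model is used on both
the forward and inverse sides; equivalence is claimed only against this
model, never against vendor scanner output.

**Tissues.** Default TI is 330 ms (inside the 220–340 ms window such
protocols use). Healthy wall T1 is tied to TI/ln 2 ≈ 476 ms so the
inversion nulls it exactly — the operating point of LGE, where healthy
myocardium has a post-contrast T1 near 500 ms. Scar and the enhancing
mitral valve use T1 = 250 ms (bright, signal 0.466), blood 300 ms (0.334),
fat keeps its contrast-agent-independent 280 ms, and a body tissue
(T1 = 800 ms) fills the rest of the grid so the field map is defined
everywhere. These choices give the contrast ordering the method needs —
healthy wall ≈ 0 < blood < threshold < scar — with wide margins: at 5%
noise the per-voxel misclassification probability is negligible, which is
why recovered fibrosis percentages are stable to hundredths of a point
across noise seeds.

## Two-point water–fat separation

With real non-negative W, F and fat phases θ_n = 2π·f_fat·TE_n, the two
echo magnitudes determine the pair {W, F} up to exchange: m₁² − m₂² fixes
the product W·F, and m₁² then fixes W² + F². Each of the two assignments
implies a field-map phasor e^{i·2π·ψ·ΔTE} = S₂(W + F·e^{iθ₁}) /
(S₁(W + F·e^{iθ₂})), giving two ψ candidates per voxel separated by the
fat–water frequency (aliasing period 1/ΔTE ≈ 385 Hz at ΔTE = 2.6 ms).
The spatial resolution of this ambiguity is a quality-guided region
growth: starting from the highest-magnitude voxel (which takes the
candidate of smaller |ψ| — the assumption that the strongest voxel is
within half the fat–water shift of resonance), voxels are decided in
decreasing-magnitude order, each taking the candidate (modulo the aliasing
period) closest to the running mean of its already-decided 6-neighbors.
Voxels below a magnitude floor (default 5% of the scene maximum) carry no
usable phase and inherit the field of their nearest decided neighbor;
field-map accuracy is therefore specified over foreground voxels.

Given ψ, each echo is demodulated and (W, F) solved by linear least
squares on the stacked real/imaginary parts — the general flexible-TE
formulation, since TE1/TE2 = 2.2/4.8 ms is near- but not exactly
out/in-phase at 1.5 T. The classic (IP ± OP)/2 shortcut is retained only
as a cross-check for exactly in/opposed echoes (where it returns
max/min(W, F), its inherent dominance ambiguity). A TE pair whose fat
phases coincide (mod 2π) within 10° is rejected as a configuration error
before any voxel work. Ties W = F are assigned to water and flagged in
`swap_mask`. The swap-rate diagnostic compares recovered vs true dominant
species over foreground voxels (true total signal above 10% of the
blood-pool signal) with unequal true water/fat signal; it requires ground
truth and is meaningful for simulated data only.

## Fibrosis and EAT quantification

The wall-only mask is the intramural tracing minus the union of mitral
valve, pulmonary-vein antra, appendage and blood pool (removed counts are
logged). The scar threshold is the midpoint of the mean blood-pool and
mean mitral-valve signal on the **water** image; an inverted contrast
(valve darker than blood) warns but still applies the formula. Wall
voxels strictly above the threshold are fibrotic — ties classify as
healthy — and fibrosis is reported as a voxel-count percentage
(`definition: voxel_fraction`); no surface meshing is performed. EAT
volume counts every voxel of the EAT segmentation (no intensity gate
inside the traced border) times the voxel volume, exactly
3.90625 mm³ at the default spacing; BSA indexing defaults to Mosteller
(√(height_cm · weight_kg / 3600)), with Du Bois available by flag, and
the formula name is carried in the output.

## Agreement statistics

ICC(A,1) — two-way model, absolute agreement, single measurement — is
computed from the ANOVA mean squares, with the F-based 95% CI
(Satterthwaite denominator df). A table with identical columns returns
ICC = 1 with CI (1, 1). Bland–Altman uses the n−1 sample SD and the 1.96
multiplier for the 95% limits of agreement. The Monte-Carlo validity
check generates n = 28, k = 2 tables from subject variance 9 plus residual
variance 1 (true ICC = 0.90) with no rater offsets; under that design the
estimator is nearly unbiased and CI coverage sits near 95%. With random
per-table rater effects at k = 2 the rater variance is estimated from a
single degree of freedom and the F-interval is known to undercover; rater
offsets are therefore exercised separately (a systematic offset strictly
lowers absolute agreement).

## Pipeline, configuration and fixtures

The pipeline runs each (seed, noise) cell through the full stack,
estimating the field map rather than using the true one, and logs every
threshold, mean, seed and count needed to re-derive its numbers. A
repeatability experiment emulates a second reader by shifting the
tracings one voxel and eroding/dilating the EAT border (seeded), then
feeds the paired quantifications to the agreement layer. Configuration is
a JSON file validated against a strict schema (unknown keys rejected
before any compute); cell failures are logged and remaining cells
continue. Three canonical scenes (no-scar, 30%-scar, and a spherical
fat-heavy scene whose full EAT shell has a closed-form volume) regenerate
byte-identically from their recorded seeds. Scene I/O uses NIfTI volumes
(echoes as real/imaginary float64 pairs, masks as uint8 labels) with a
JSON sidecar carrying spacing, acquisition parameters and seed; loading
validates shape and spacing against the sidecar.

## Numerical choices and limitations

- All phases derive from `fat_shift_hz` and TE at run time; no hard-coded
  phase constants.
- Noiseless forward–inverse consistency is exact to machine precision;
  "relative error" is normalized by the scene maximum signal because
  nulled tissue makes per-voxel denominators degenerate.
- Field maps beyond ±1/(2ΔTE) ≈ ±192 Hz alias; the simulated fields stay
  within ±60 Hz. Region growth assumes a connected foreground; disjoint
  foreground components inherit the seed component's branch via
  nearest-neighbor fill.
- The phantom has crisp single-tissue voxels: no partial volume, motion,
  coil profiles, or k-space undersampling. Passing tests demonstrate the
  correctness of the separation, masking, thresholding and statistics
  under the stated signal model — not robustness to the segmentation
  variability, partial-volume blur or artifacts of patient data.
- Cohort-level clinical values (patient fibrosis burden, image-quality
  scores, scan times) require real scans and are out of scope.
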