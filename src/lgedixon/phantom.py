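"""Digital left-atrial phantom and dual-echo LGE-Dixon acquisition simulator.

The phantom is an analytically defined ellipsoidal-shell scene, not an
anatomical model: a blood-pool ellipsoid surrounded by a thin intramural
wall shell, bright fibrotic patches on the wall, an epicardial fat cap
outside the wall, and the exclusion structures (mitral-valve disc,
pulmonary-vein antra, appendage stub) that a reader would subtract from the
wall tracing.  It exists to exercise every mask-handling, water-fat
separation and thresholding rule downstream with a known ground truth.

Signal model
------------
Each voxel carries a water proton density W, a fat proton density F and a
single longitudinal relaxation time T1.  An inversion-recovery weighting

    A(T1, TI) = |1 - 2 exp(-TI / T1)|

scales both species (magnitude-restored, as in clinical LGE magnitude
images).  The complex signal at echo time TE is

    S(TE) = A * (W + F * exp(i 2 pi f_fat TE)) * exp(i 2 pi psi TE) + eta

with f_fat the fat chemical-shift frequency (single spectral peak at
-3.4 ppm), psi the B0 off-resonance field in Hz, and eta i.i.d. complex
Gaussian noise whose standard deviation per real component is expressed as
a fraction of the noiseless blood-pool signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .quantify import StructureMasks

GYROMAGNETIC_MHZ_PER_T = 42.576
FAT_CHEMICAL_SHIFT_PPM = -3.4

# Label codes used in the combined label map (documented in the sidecar).
LABEL_BODY = 0
LABEL_BLOOD = 1
LABEL_WALL = 2
LABEL_SCAR = 3
LABEL_MITRAL_VALVE = 4
LABEL_PV_LEFT = 5
LABEL_PV_RIGHT = 6
LABEL_APPENDAGE = 7
LABEL_EAT = 8

LABEL_NAMES = {
    LABEL_BODY: "body",
    LABEL_BLOOD: "blood_pool",
    LABEL_WALL: "wall_healthy",
    LABEL_SCAR: "wall_scar",
    LABEL_MITRAL_VALVE: "mitral_valve",
    LABEL_PV_LEFT: "pv_antrum_left",
    LABEL_PV_RIGHT: "pv_antrum_right",
    LABEL_APPENDAGE: "appendage",
    LABEL_EAT: "eat",
}


class GeometryError(ValueError):
    """Raised when a phantom specification describes infeasible geometry."""


def fat_shift_hz(field_strength_t: float, ppm: float = FAT_CHEMICAL_SHIFT_PPM) -> float:
    """Fat-water chemical-shift frequency in Hz (negative: fat below water)."""
    return ppm * GYROMAGNETIC_MHZ_PER_T * field_strength_t


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-echo spoiled-gradient-echo acquisition parameters.

    Defaults follow a 1.5 T inversion-recovery dual-echo protocol:
    TR/TE1/TE2 = 7.1/2.2/4.8 ms, flip 20 deg, with the inversion time
    chosen inside the 220-340 ms window used to null healthy myocardium
    after contrast.
    """

    te1_ms: float = 2.2
    te2_ms: float = 4.8
    tr_ms: float = 7.1
    flip_deg: float = 20.0
    ti_ms: float = 330.0
    field_strength_t: float = 1.5
    fat_shift_hz: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.te1_ms < self.te2_ms < self.tr_ms):
            raise ValueError(
                f"echo times must satisfy 0 < te1 < te2 < tr, got "
                f"te1={self.te1_ms}, te2={self.te2_ms}, tr={self.tr_ms}"
            )
        if self.ti_ms <= 0:
            raise ValueError("inversion time must be positive")
        if self.field_strength_t <= 0:
            raise ValueError("field strength must be positive")
        if self.fat_shift_hz is None:
            object.__setattr__(
                self, "fat_shift_hz", fat_shift_hz(self.field_strength_t)
            )

    @property
    def delta_te_ms(self) -> float:
        return self.te2_ms - self.te1_ms

    def fat_phase_rad(self, te_ms: float) -> float:
        """Phase accrued by fat relative to water at echo time ``te_ms``."""
        return 2.0 * math.pi * self.fat_shift_hz * te_ms * 1e-3

    def to_dict(self) -> dict:
        return {
            "te1_ms": self.te1_ms,
            "te2_ms": self.te2_ms,
            "tr_ms": self.tr_ms,
            "flip_deg": self.flip_deg,
            "ti_ms": self.ti_ms,
            "field_T": self.field_strength_t,
            "fat_shift_hz": self.fat_shift_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(
            te1_ms=d["te1_ms"],
            te2_ms=d["te2_ms"],
            tr_ms=d["tr_ms"],
            flip_deg=d.get("flip_deg", 20.0),
            ti_ms=d["ti_ms"],
            field_strength_t=d["field_T"],
            fat_shift_hz=d.get("fat_shift_hz"),
        )


@dataclass(frozen=True)
class TissueProps:
    """Per-tissue water/fat proton densities (a.u.) and post-contrast T1."""

    water_density: float
    fat_density: float
    t1_ms: float

    def __post_init__(self) -> None:
        for name in ("water_density", "fat_density"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.t1_ms <= 0:
            raise ValueError(f"t1_ms must be positive, got {self.t1_ms}")


def default_tissues(ti_ms: float = 330.0) -> dict[int, TissueProps]:
    """Tissue table for the default scene.

    Healthy wall T1 is tied to the inversion time (T1 = TI / ln 2, about
    476 ms at TI = 330 ms, close to the ~500 ms post-contrast value of
    healthy myocardium) so the inversion pulse nulls it, which is the
    operating point of LGE.  Scar and the enhancing mitral valve have a
    short post-contrast T1 and appear bright; fat keeps T1 = 280 ms,
    unaffected by the contrast agent.
    """
    wall_t1 = ti_ms / math.log(2.0)
    return {
        LABEL_BODY: TissueProps(1.0, 0.0, 800.0),
        LABEL_BLOOD: TissueProps(1.0, 0.0, 300.0),
        LABEL_WALL: TissueProps(1.0, 0.0, wall_t1),
        LABEL_SCAR: TissueProps(1.0, 0.0, 250.0),
        LABEL_MITRAL_VALVE: TissueProps(1.0, 0.0, 250.0),
        LABEL_PV_LEFT: TissueProps(1.0, 0.0, 300.0),
        LABEL_PV_RIGHT: TissueProps(1.0, 0.0, 300.0),
        LABEL_APPENDAGE: TissueProps(1.0, 0.0, 300.0),
        LABEL_EAT: TissueProps(0.0, 1.0, 280.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and field-map description of one synthetic scene."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 2.5)
    blood_semiaxes_mm: tuple[float, float, float] = (34.0, 30.0, 26.0)
    wall_thickness_mm: float = 3.0
    scar_fraction: float = 0.30
    n_scar_patches: int = 3
    eat_thickness_mm: float = 6.0
    eat_cap_half_angle_deg: float = 50.0
    mv_radius_mm: float = 12.0
    mv_height_mm: float = 8.0
    pv_radius_mm: float = 8.0
    appendage_radius_mm: float = 6.0
    tissues: dict[int, TissueProps] | None = None
    field_model: str = "constant"  # constant | linear | bump
    field_amplitude_hz: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise GeometryError(f"grid shape must be 3 axes of >= 8 voxels, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing_mm}")
        in_plane = max(self.spacing_mm[0], self.spacing_mm[1])
        if self.wall_thickness_mm < in_plane:
            raise GeometryError(
                f"wall thickness {self.wall_thickness_mm} mm is thinner than one "
                f"in-plane voxel ({in_plane} mm)"
            )
        if not 0.0 <= self.scar_fraction <= 1.0:
            raise GeometryError(f"scar fraction must lie in [0, 1], got {self.scar_fraction}")
        if self.scar_fraction > 0 and self.n_scar_patches < 1:
            raise GeometryError("at least one scar patch is required when scar fraction > 0")
        if self.eat_thickness_mm < 0:
            raise GeometryError("EAT thickness must be non-negative")
        if self.field_model not in ("constant", "linear", "bump"):
            raise GeometryError(f"unknown field model {self.field_model!r}")
        if self.noise_sigma < 0:
            raise GeometryError("noise sigma must be non-negative")
        fov = [n * s for n, s in zip(self.shape, self.spacing_mm)]
        reach = [
            a + self.wall_thickness_mm + self.eat_thickness_mm
            for a in self.blood_semiaxes_mm
        ]
        for ax, (r, f) in enumerate(zip(reach, fov)):
            if 2 * r >= f:
                raise GeometryError(
                    f"scene (blood pool + wall + fat, {2 * r:.1f} mm) exceeds the "
                    f"field of view ({f:.1f} mm) along axis {ax}"
                )

    def tissue_table(self, ti_ms: float = 330.0) -> dict[int, TissueProps]:
        return self.tissues if self.tissues is not None else default_tissues(ti_ms)


@dataclass
class GroundTruth:
    """Everything the simulator knows about one scene.

    ``masks`` holds the reader-style structure masks (the full intramural
    tracing, before subtraction); ``wall_mask`` is the true post-subtraction
    wall label constructed independently, so the wall-derivation rule can be
    checked against it.
    """

    spec: PhantomSpec
    water_density: np.ndarray
    fat_density: np.ndarray
    t1_map: np.ndarray
    field_map_hz: np.ndarray
    label_map: np.ndarray
    masks: StructureMasks
    wall_mask: np.ndarray
    scar_mask: np.ndarray

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.spec.spacing_mm

    def inversion_weight(self, ti_ms: float) -> np.ndarray:
        return np.abs(1.0 - 2.0 * np.exp(-ti_ms / self.t1_map))

    def effective_signal(self, acq: AcquisitionParams) -> tuple[np.ndarray, np.ndarray]:
        """Inversion-weighted water and fat signal maps (what the echoes encode)."""
        a = self.inversion_weight(acq.ti_ms)
        return a * self.water_density, a * self.fat_density


def inversion_weight(t1_ms: float | np.ndarray, ti_ms: float) -> float | np.ndarray:
    """Magnitude-restored inversion-recovery weighting |1 - 2 exp(-TI/T1)|."""
    return np.abs(1.0 - 2.0 * np.exp(-ti_ms / np.asarray(t1_ms, dtype=float)))


def blood_reference_signal(
    spec: PhantomSpec, acq: AcquisitionParams
) -> float:
    """Noiseless blood-pool water signal; the unit for noise sigma."""
    blood = spec.tissue_table(acq.ti_ms)[LABEL_BLOOD]
    return blood.water_density * float(inversion_weight(blood.t1_ms, acq.ti_ms))


def _coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates in mm, origin at the grid center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _build_field_map(spec: PhantomSpec, grids) -> np.ndarray:
    x, y, z = grids
    amp = spec.field_amplitude_hz
    if spec.field_model == "constant":
        return np.full(spec.shape, amp, dtype=float)
    extent = [g.max() if g.max() > 0 else 1.0 for g in (x, y, z)]
    if spec.field_model == "linear":
        # Linear ramp along the diagonal spanning [-amp, +amp] across the grid.
        u = (x / extent[0] + y / extent[1] + z / extent[2]) / 3.0
        return amp * u
    # Smooth Gaussian bump centered off-middle, width ~ quarter grid.
    sx, sy, sz = (e / 2.0 for e in extent)
    r2 = ((x - sx / 2) / sx) ** 2 + ((y + sy / 2) / sy) ** 2 + (z / sz) ** 2
    return amp * np.exp(-r2)


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the scene: labels, density/T1/field maps, masks and true scar set.

    Deterministic for a fixed spec (including its seed).  Scar voxels are the
    ``round(fraction * wall_count)`` wall voxels nearest (in mm) to
    ``n_scar_patches`` seed voxels drawn on the wall, giving connected patches
    whose realized fraction matches the request to within rounding.
    """
    spec.validate()
    x, y, z = _coordinate_grids(spec)
    a, b, c = spec.blood_semiaxes_mm
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    blood = rho <= 1.0
    if not blood.any():
        raise GeometryError("blood pool contains no voxels")

    # Signed distance (mm) to the blood-pool surface, first order in the
    # level-set rho: d = (rho - 1) / |grad rho|.  Exact for a sphere and
    # accurate to second order in shell thickness / curvature radius for the
    # mild ellipticity used here; evaluated at voxel centers so the shells
    # carry no systematic half-voxel offset.
    grad = np.sqrt(x**2 / a**4 + y**2 / b**4 + z**2 / c**4) / np.maximum(rho, 1e-12)
    dist = np.where(blood, 0.0, (rho - 1.0) / np.maximum(grad, 1e-12))
    wall_full = (dist > 0) & (dist <= spec.wall_thickness_mm)
    if not wall_full.any():
        raise GeometryError("wall shell contains no voxels")
    eat_band = (dist > spec.wall_thickness_mm) & (
        dist <= spec.wall_thickness_mm + spec.eat_thickness_mm
    )
    # Epicardial fat cap: directions within the half-angle of the +z axis.
    r = np.sqrt(x**2 + y**2 + z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_polar = np.where(r > 0, z / np.maximum(r, 1e-12), 1.0)
    eat = eat_band & (cos_polar >= math.cos(math.radians(spec.eat_cap_half_angle_deg)))

    # Exclusion structures positioned on the wall.
    mv = (x**2 + y**2 <= spec.mv_radius_mm**2) & (
        np.abs(z + c) <= spec.mv_height_mm / 2.0
    )
    pv_left = (x + a) ** 2 + y**2 + z**2 <= spec.pv_radius_mm**2
    pv_right = (x - a) ** 2 + y**2 + z**2 <= spec.pv_radius_mm**2
    appendage = x**2 + (y - b) ** 2 + z**2 <= spec.appendage_radius_mm**2

    exclusion_union = mv | pv_left | pv_right | appendage
    wall_true = wall_full & ~exclusion_union & ~blood
    if not wall_true.any():
        raise GeometryError("exclusion structures cover the entire wall")

    # Scar patches on the true wall.
    rng = np.random.default_rng(spec.seed)
    scar = np.zeros(spec.shape, dtype=bool)
    if spec.scar_fraction > 0:
        wall_idx = np.flatnonzero(wall_true)
        n_wall = wall_idx.size
        k = int(round(spec.scar_fraction * n_wall))
        if k > 0:
            n_seeds = min(spec.n_scar_patches, n_wall)
            seeds = rng.choice(wall_idx, size=n_seeds, replace=False)
            coords = np.stack(
                [g.ravel()[wall_idx] for g in (x, y, z)], axis=1
            )  # (n_wall, 3) mm
            seed_coords = np.stack([g.ravel()[seeds] for g in (x, y, z)], axis=1)
            d2 = ((coords[:, None, :] - seed_coords[None, :, :]) ** 2).sum(axis=2)
            nearest = d2.min(axis=1)
            order = np.lexsort((wall_idx, nearest))  # deterministic ties
            chosen = wall_idx[order[:k]]
            scar.ravel()[chosen] = True
        realized = scar.sum() / wall_true.sum()
        if abs(realized - spec.scar_fraction) > 0.02:
            raise GeometryError(
                f"requested scar fraction {spec.scar_fraction:.3f} not realizable "
                f"on this wall (got {realized:.3f})"
            )

    # Label map with explicit precedence: structures override wall/blood/body.
    label = np.full(spec.shape, LABEL_BODY, dtype=np.uint8)
    label[blood] = LABEL_BLOOD
    label[wall_full] = LABEL_WALL
    label[scar] = LABEL_SCAR
    label[mv] = LABEL_MITRAL_VALVE
    label[pv_left] = LABEL_PV_LEFT
    label[pv_right] = LABEL_PV_RIGHT
    label[appendage] = LABEL_APPENDAGE
    label[eat] = LABEL_EAT

    tissues = spec.tissue_table()
    water = np.zeros(spec.shape, dtype=float)
    fat = np.zeros(spec.shape, dtype=float)
    t1 = np.ones(spec.shape, dtype=float)
    for code, props in tissues.items():
        sel = label == code
        water[sel] = props.water_density
        fat[sel] = props.fat_density
        t1[sel] = props.t1_ms

    masks = StructureMasks(
        la_intramural=wall_full,
        blood_pool=blood & ~mv,
        mitral_valve=mv,
        exclusions={
            "pv_antrum_left": pv_left,
            "pv_antrum_right": pv_right,
            "appendage": appendage,
        },
        eat=eat,
        spacing_mm=spec.spacing_mm,
    )
    return GroundTruth(
        spec=spec,
        water_density=water,
        fat_density=fat,
        t1_map=t1,
        field_map_hz=_build_field_map(spec, (x, y, z)),
        label_map=label,
        masks=masks,
        wall_mask=wall_true,
        scar_mask=scar,
    )


def simulate_echoes(
    gt: GroundTruth,
    acq: AcquisitionParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate the two complex gradient-echo volumes.

    ``noise_sigma`` is the standard deviation of the additive complex
    Gaussian noise per real component, as a fraction of the noiseless
    blood-pool signal.  Magnitude images derived from these echoes are
    therefore Rician.
    """
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be non-negative, got {noise_sigma}")
    w_sig, f_sig = gt.effective_signal(acq)
    psi = gt.field_map_hz
    rng = np.random.default_rng(seed)
    sigma_abs = noise_sigma * blood_reference_signal(gt.spec, acq)
    echoes = []
    for te_ms in (acq.te1_ms, acq.te2_ms):
        te_s = te_ms * 1e-3
        fat_ph = np.exp(1j * 2 * np.pi * acq.fat_shift_hz * te_s)
        s = (w_sig + f_sig * fat_ph) * np.exp(1j * 2 * np.pi * psi * te_s)
        if sigma_abs > 0:
            s = s + sigma_abs * (
                rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
            )
        echoes.append(s.astype(np.complex128))
    return echoes[0], echoes[1]


# ---------------------------------------------------------------------------
# Scene I/O: NIfTI volumes + JSON sidecar
# ---------------------------------------------------------------------------

_MASK_FILES = {
    "la_intramural": "mask_la_intramural.nii.gz",
    "blood_pool": "mask_blood_pool.nii.gz",
    "mitral_valve": "mask_mitral_valve.nii.gz",
    "eat": "mask_eat.nii.gz",
}
SIDECAR_NAME = "scene.json"


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def _save_nifti(path: Path, data: np.ndarray, spacing_mm) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing_mm))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def export_scene(
    gt: GroundTruth,
    echoes: tuple[np.ndarray, np.ndarray],
    directory: str | Path,
    acq: AcquisitionParams,
    seed: int = 0,
) -> list[Path]:
    """Write echoes (real+imag float64), masks, label map and JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spacing = gt.spacing_mm
    shape = tuple(gt.label_map.shape)
    written: list[Path] = []

    for i, echo in enumerate(echoes, start=1):
        if tuple(echo.shape) != shape:
            raise ValueError(
                f"echo{i} shape {tuple(echo.shape)} does not match scene shape {shape}"
            )
        for part, arr in (("real", echo.real), ("imag", echo.imag)):
            p = directory / f"echo{i}_{part}.nii.gz"
            _save_nifti(p, arr.astype(np.float64), spacing)
            written.append(p)

    mask_arrays = {
        "la_intramural": gt.masks.la_intramural,
        "blood_pool": gt.masks.blood_pool,
        "mitral_valve": gt.masks.mitral_valve,
        "eat": gt.masks.eat,
    }
    for name, mask in gt.masks.exclusions.items():
        mask_arrays[name] = mask
    for name, mask in mask_arrays.items():
        if tuple(mask.shape) != shape:
            raise ValueError(
                f"mask {name!r} shape {tuple(mask.shape)} does not match scene "
                f"shape {shape}"
            )
        p = directory / _MASK_FILES.get(name, f"mask_{name}.nii.gz")
        _save_nifti(p, mask.astype(np.uint8), spacing)
        written.append(p)

    p = directory / "labels.nii.gz"
    _save_nifti(p, gt.label_map.astype(np.uint8), spacing)
    written.append(p)
    p = directory / "scar_truth.nii.gz"
    _save_nifti(p, gt.scar_mask.astype(np.uint8), spacing)
    written.append(p)
    p = directory / "field_map_true.nii.gz"
    _save_nifti(p, gt.field_map_hz.astype(np.float64), spacing)
    written.append(p)

    sidecar = {
        "spacing_mm": list(spacing),
        **acq.to_dict(),
        "seed": seed,
        "shape": list(shape),
        "label_codes": {str(k): v for k, v in LABEL_NAMES.items()},
        "exclusion_masks": sorted(gt.masks.exclusions),
    }
    sc = directory / SIDECAR_NAME
    sc.write_text(json.dumps(sidecar, indent=2))
    written.append(sc)
    return written


def load_scene(directory: str | Path):
    """Read back an exported scene: (masks, (echo1, echo2), acq, sidecar dict).

    Validates that every volume matches the sidecar's shape and spacing.
    """
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR_NAME).read_text())
    spacing = tuple(sidecar["spacing_mm"])
    shape = tuple(sidecar["shape"])

    def _load(name: str, dtype=None) -> np.ndarray:
        path = directory / name
        img = nib.load(str(path))
        zooms = tuple(round(float(v), 6) for v in img.header.get_zooms()[:3])
        if tuple(img.shape) != shape:
            raise ValueError(
                f"{path.name}: shape {tuple(img.shape)} does not match sidecar "
                f"shape {shape}"
            )
        if zooms != tuple(round(float(v), 6) for v in spacing):
            raise ValueError(
                f"{path.name}: voxel spacing {zooms} does not match sidecar "
                f"spacing {spacing}"
            )
        data = np.asarray(img.dataobj)
        return data.astype(dtype) if dtype is not None else data

    echoes = tuple(
        _load(f"echo{i}_real.nii.gz", np.float64)
        + 1j * _load(f"echo{i}_imag.nii.gz", np.float64)
        for i in (1, 2)
    )
    exclusions = {
        name: _load(f"mask_{name}.nii.gz", bool)
        for name in sidecar.get("exclusion_masks", [])
    }
    masks = StructureMasks(
        la_intramural=_load(_MASK_FILES["la_intramural"], bool),
        blood_pool=_load(_MASK_FILES["blood_pool"], bool),
        mitral_valve=_load(_MASK_FILES["mitral_valve"], bool),
        exclusions=exclusions,
        eat=_load(_MASK_FILES["eat"], bool),
        spacing_mm=spacing,
    )
    acq = AcquisitionParams.from_dict(sidecar)
    return masks, echoes, acq, sidecar


def spherical_spec(**overrides) -> PhantomSpec:
    """A spherical variant of the default scene (exact analytic shell volumes)."""
    base = PhantomSpec(blood_semiaxes_mm=(25.0, 25.0, 25.0))
    return replace(base, **overrides)
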