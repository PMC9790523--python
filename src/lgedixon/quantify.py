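"""Left-atrial fibrosis and epicardial adipose tissue quantification.

The analysis follows the clinical reading workflow on water-fat separated
LGE images: the intramural LA tracing minus the mitral valve, pulmonary-vein
antra, appendage and blood pool yields the wall-only mask; a patient-specific
scar threshold is set at the midpoint between the mean blood-pool and mean
mitral-valve signal intensity on the water image; wall voxels strictly above
the threshold count as fibrotic, reported as a percentage of wall voxels.
EAT is quantified directly from its segmentation as voxel count times voxel
volume, optionally indexed to body surface area.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MM3_PER_ML = 1000.0


@dataclass
class StructureMasks:
    """Co-registered binary label volumes for one subject/scene."""

    la_intramural: np.ndarray
    blood_pool: np.ndarray
    mitral_valve: np.ndarray
    exclusions: dict[str, np.ndarray]
    eat: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(np.asarray(self.la_intramural).shape)
        for name, arr in self._named():
            if tuple(np.asarray(arr).shape) != shape:
                raise ValueError(
                    f"mask {name!r} shape {tuple(np.asarray(arr).shape)} does not "
                    f"match la_intramural shape {shape}"
                )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"invalid voxel spacing {self.spacing_mm}")
        if not np.any(self.la_intramural):
            raise ValueError("la_intramural mask is empty")

    def _named(self):
        yield "la_intramural", self.la_intramural
        yield "blood_pool", self.blood_pool
        yield "mitral_valve", self.mitral_valve
        for name, arr in self.exclusions.items():
            yield name, arr
        yield "eat", self.eat

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(np.asarray(self.la_intramural).shape)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz


@dataclass
class FibrosisResult:
    mean_blood_si: float
    mean_mv_si: float
    threshold: float
    scar_voxels: int
    wall_voxels: int
    fibrosis_pct: float
    definition: str = "voxel_fraction"

    def to_dict(self) -> dict:
        return {
            "mean_blood_si": self.mean_blood_si,
            "mean_mv_si": self.mean_mv_si,
            "threshold": self.threshold,
            "scar_voxels": self.scar_voxels,
            "wall_voxels": self.wall_voxels,
            "fibrosis_pct": self.fibrosis_pct,
            "definition": self.definition,
        }


@dataclass
class EatResult:
    eat_voxels: int
    volume_ml: float
    bsa_m2: float | None = None
    volume_indexed: float | None = None
    bsa_formula: str | None = None

    def to_dict(self) -> dict:
        return {
            "eat_voxels": self.eat_voxels,
            "volume_ml": self.volume_ml,
            "bsa_m2": self.bsa_m2,
            "volume_indexed_ml_per_m2": self.volume_indexed,
            "bsa_formula": self.bsa_formula,
        }


def derive_wall_mask(masks: StructureMasks) -> np.ndarray:
    """LA wall = intramural tracing minus valve, exclusions and blood pool.

    Logs the voxel count removed per structure; raises if nothing survives.
    """
    wall = np.asarray(masks.la_intramural, dtype=bool).copy()
    removers = {
        "mitral_valve": masks.mitral_valve,
        **masks.exclusions,
        "blood_pool": masks.blood_pool,
    }
    for name, struct in removers.items():
        struct = np.asarray(struct, dtype=bool)
        removed = int(np.count_nonzero(wall & struct))
        wall &= ~struct
        logger.info("derive_wall_mask: removed %d voxels overlapping %s", removed, name)
    if not wall.any():
        raise ValueError("wall fully excluded: no LA wall voxels remain after subtraction")
    logger.info("derive_wall_mask: %d wall voxels remain", int(wall.sum()))
    return wall


def mean_si(image: np.ndarray, mask: np.ndarray, name: str = "mask") -> float:
    """Arithmetic mean signal intensity of ``image`` inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"cannot compute mean signal intensity: {name} mask is empty")
    return float(np.mean(np.asarray(image, dtype=float)[mask]))


def scar_threshold(mean_blood_si: float, mean_mv_si: float) -> float:
    """Patient-specific scar threshold.

    Half the blood-to-valve signal difference added to the blood mean, i.e.
    the midpoint (blood + valve) / 2.  An inverted contrast (valve darker
    than blood) is suspicious and triggers a warning, but the formula is
    still applied.
    """
    for v, n in ((mean_blood_si, "mean_blood_si"), (mean_mv_si, "mean_mv_si")):
        if not math.isfinite(v):
            raise ValueError(f"{n} must be finite, got {v}")
    if mean_mv_si < mean_blood_si:
        warnings.warn(
            "mitral valve mean SI below blood-pool mean SI (inverted contrast); "
            "threshold formula applied regardless",
            stacklevel=2,
        )
    return mean_blood_si + (mean_mv_si - mean_blood_si) / 2.0


def fibrosis_percentage(
    water: np.ndarray,
    wall: np.ndarray,
    threshold: float,
    mean_blood_si: float = float("nan"),
    mean_mv_si: float = float("nan"),
) -> FibrosisResult:
    """Classify wall voxels and report the fibrotic fraction.

    A voxel is fibrotic when its water-image SI is strictly greater than the
    threshold (ties count as healthy).
    """
    wall = np.asarray(wall, dtype=bool)
    if not wall.any():
        raise ValueError("wall mask is empty")
    vals = np.asarray(water, dtype=float)[wall]
    scar_voxels = int(np.count_nonzero(vals > threshold))
    wall_voxels = int(wall.sum())
    pct = 100.0 * scar_voxels / wall_voxels
    logger.info(
        "fibrosis_percentage: threshold=%.6g scar=%d wall=%d pct=%.3f",
        threshold, scar_voxels, wall_voxels, pct,
    )
    return FibrosisResult(
        mean_blood_si=mean_blood_si,
        mean_mv_si=mean_mv_si,
        threshold=float(threshold),
        scar_voxels=scar_voxels,
        wall_voxels=wall_voxels,
        fibrosis_pct=pct,
    )


def quantify_fibrosis(water: np.ndarray, masks: StructureMasks) -> FibrosisResult:
    """Full fibrosis analysis: wall derivation, threshold, classification."""
    wall = derive_wall_mask(masks)
    blood = mean_si(water, masks.blood_pool, "blood_pool")
    mv = mean_si(water, masks.mitral_valve, "mitral_valve")
    thr = scar_threshold(blood, mv)
    return fibrosis_percentage(water, wall, thr, mean_blood_si=blood, mean_mv_si=mv)


def bsa(height_m: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m^2 (Mosteller by default, Du Bois optional)."""
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError(
            f"height and weight must be positive, got {height_m} m, {weight_kg} kg"
        )
    height_cm = height_m * 100.0
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


def eat_volume(
    masks: StructureMasks,
    height_m: float | None = None,
    weight_kg: float | None = None,
    bsa_formula: str = "mosteller",
) -> EatResult:
    """EAT volumetry: voxel count times voxel volume, optionally BSA-indexed.

    Every voxel of the EAT segmentation counts; no intensity gate is applied
    inside the traced border.  The EAT mask may not intersect the blood pool
    (its inner border is the outer wall surface).
    """
    eat = np.asarray(masks.eat, dtype=bool)
    if np.any(eat & np.asarray(masks.blood_pool, dtype=bool)):
        raise ValueError(
            "EAT mask overlaps the blood pool, which is topologically impossible"
        )
    n = int(eat.sum())
    volume_ml = n * masks.voxel_volume_mm3 / MM3_PER_ML
    result = EatResult(eat_voxels=n, volume_ml=volume_ml)
    if (height_m is None) != (weight_kg is None):
        raise ValueError("height and weight must be supplied together")
    if height_m is not None and weight_kg is not None:
        result.bsa_m2 = bsa(height_m, weight_kg, bsa_formula)
        result.volume_indexed = volume_ml / result.bsa_m2
        result.bsa_formula = bsa_formula
    logger.info(
        "eat_volume: %d voxels, %.3f mL (indexed: %s)",
        n, volume_ml, result.volume_indexed,
    )
    return result
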