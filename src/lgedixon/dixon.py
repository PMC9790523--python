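"""Two-point Dixon water-fat separation with region-growing field mapping.

Given two complex gradient echoes at flexible echo times, each voxel's
signal is modelled as

    S_n = (W + F * exp(i theta_n)) * exp(i 2 pi psi TE_n),   n = 1, 2

with real non-negative water (W) and fat (F) amplitudes, theta_n the fat
chemical-shift phase at echo n, and psi the B0 off-resonance field in Hz.
Eliminating W and F from the two echo magnitudes leaves, per voxel, two
candidate (W, F) assignments (water-dominant vs fat-dominant) and hence two
candidate field-map values separated by the fat-water frequency.  The
ambiguity is resolved spatially: a region grows outward from the
highest-magnitude voxel in decreasing-magnitude order, and each voxel takes
the candidate closest to the mean field of its already-decided neighbors.
With the field map fixed, water and fat follow from a per-voxel linear
least-squares solve of the demodulated echoes.

Since the echo times are near- but not exactly out/in-phase, the general
flexible-TE solver is used throughout; the classic (IP +/- OP)/2 shortcut is
kept only as a cross-check for exactly in/opposed-phase echo pairs.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import AcquisitionParams, GroundTruth


class TEConfigurationError(ValueError):
    """The echo-time pair gives near-identical fat phases: system singular."""


@dataclass
class WaterFatResult:
    """Separated magnitude images plus the field map and diagnostics."""

    water: np.ndarray
    fat: np.ndarray
    field_map_hz: np.ndarray
    in_phase: np.ndarray
    out_phase: np.ndarray
    swap_mask: np.ndarray


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def check_te_conditioning(acq: AcquisitionParams, min_separation_deg: float = 10.0) -> None:
    """Reject echo-time pairs whose fat phases nearly coincide (mod 2 pi)."""
    sep = abs(_wrap_angle(acq.fat_phase_rad(acq.te2_ms) - acq.fat_phase_rad(acq.te1_ms)))
    if math.degrees(sep) < min_separation_deg:
        raise TEConfigurationError(
            f"fat phase separation across echoes is {math.degrees(sep):.2f} deg "
            f"(< {min_separation_deg} deg): TE pair cannot separate water and fat"
        )


def _candidate_fields(
    echo1: np.ndarray,
    echo2: np.ndarray,
    acq: AcquisitionParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel field-map candidates (Hz) and a reliability magnitude.

    Returns (psi_a, psi_b, quality): psi_a assumes the water-dominant root,
    psi_b the fat-dominant root; quality = min(|S1|, |S2|) orders the region
    growth so low-signal voxels are decided last.
    """
    theta1 = acq.fat_phase_rad(acq.te1_ms)
    theta2 = acq.fat_phase_rad(acq.te2_ms)
    c1, c2 = math.cos(theta1), math.cos(theta2)
    denom = 2.0 * (c1 - c2)
    if abs(denom) < 1e-9:
        raise TEConfigurationError(
            "echo magnitudes carry no water-fat contrast for this TE pair "
            "(cos(theta1) == cos(theta2))"
        )
    m1sq = np.abs(echo1) ** 2
    m2sq = np.abs(echo2) ** 2
    p = (m1sq - m2sq) / denom          # p = W * F
    p = np.maximum(p, 0.0)
    s = np.maximum(m1sq - 2.0 * p * c1, 0.0)  # s = W^2 + F^2
    p = np.minimum(p, s / 2.0)
    u = np.sqrt(s + 2.0 * p)           # W + F
    v = np.sqrt(np.maximum(s - 2.0 * p, 0.0))  # |W - F|

    dte_s = acq.delta_te_ms * 1e-3
    e1 = np.exp(1j * theta1)
    e2 = np.exp(1j * theta2)
    eps = 1e-30

    def psi_for(w: np.ndarray, f: np.ndarray) -> np.ndarray:
        num = echo2 * (w + f * e1)
        den = echo1 * (w + f * e2)
        ratio = num / np.where(np.abs(den) < eps, eps, den)
        return np.angle(ratio) / (2.0 * np.pi * dte_s)

    w_a, f_a = (u + v) / 2.0, (u - v) / 2.0
    psi_a = psi_for(w_a, f_a)
    psi_b = psi_for(f_a, w_a)
    quality = np.minimum(np.sqrt(m1sq), np.sqrt(m2sq))
    return psi_a, psi_b, quality


def estimate_field_map(
    echo1: np.ndarray,
    echo2: np.ndarray,
    acq: AcquisitionParams,
    magnitude_floor: float = 0.05,
) -> np.ndarray:
    """Estimate the B0 off-resonance field map (Hz) by region growing.

    Only voxels whose magnitude exceeds ``magnitude_floor`` times the scene
    maximum carry usable phase; the remaining voxels are filled from their
    nearest decided neighbor.  Candidates are compared modulo the aliasing
    period 1/(2 pi dTE); the seed (global magnitude maximum) takes the
    candidate of smallest absolute field, so the convention is that the
    off-resonance at the strongest voxel is within half the fat-water shift.
    """
    check_te_conditioning(acq)
    echo1 = np.asarray(echo1, dtype=np.complex128)
    echo2 = np.asarray(echo2, dtype=np.complex128)
    if echo1.shape != echo2.shape:
        raise ValueError("echoes must share a shape")
    psi_a, psi_b, quality = _candidate_fields(echo1, echo2, acq)
    qmax = float(quality.max())
    if qmax <= 0:
        raise ValueError("all-zero input: no seed voxel for field-map estimation")

    period_hz = 1.0 / (acq.delta_te_ms * 1e-3)
    shape = echo1.shape
    fg = quality > magnitude_floor * qmax

    flat_a = psi_a.ravel()
    flat_b = psi_b.ravel()
    flat_q = quality.ravel()
    fg_flat = fg.ravel()
    n = flat_a.size

    # Flat-index neighbor offsets for the 6-connected grid.
    strides = (shape[1] * shape[2], shape[2], 1)
    decided = np.zeros(n, dtype=bool)
    queued = np.zeros(n, dtype=bool)
    psi_out = np.zeros(n, dtype=float)
    nb_sum = np.zeros(n, dtype=float)
    nb_cnt = np.zeros(n, dtype=np.int32)

    def neighbors(idx: int):
        i, rem = divmod(idx, strides[0])
        j, k = divmod(rem, strides[1])
        if i > 0:
            yield idx - strides[0]
        if i < shape[0] - 1:
            yield idx + strides[0]
        if j > 0:
            yield idx - strides[1]
        if j < shape[1] - 1:
            yield idx + strides[1]
        if k > 0:
            yield idx - 1
        if k < shape[2] - 1:
            yield idx + 1

    def pick(idx: int, ref: float) -> float:
        best, best_err = 0.0, math.inf
        for cand in (flat_a[idx], flat_b[idx]):
            adj = cand + period_hz * round((ref - cand) / period_hz)
            err = abs(adj - ref)
            if err < best_err:
                best, best_err = adj, err
        return best

    seed = int(np.argmax(flat_q))
    cand_seed = (flat_a[seed], flat_b[seed])
    psi_out[seed] = min(cand_seed, key=abs)
    decided[seed] = True
    heap: list[tuple[float, int]] = []
    for nb in neighbors(seed):
        nb_sum[nb] += psi_out[seed]
        nb_cnt[nb] += 1
        if fg_flat[nb]:
            heapq.heappush(heap, (-flat_q[nb], nb))
            queued[nb] = True

    while heap:
        _, idx = heapq.heappop(heap)
        if decided[idx]:
            continue
        ref = nb_sum[idx] / nb_cnt[idx]
        psi_out[idx] = pick(idx, ref)
        decided[idx] = True
        for nb in neighbors(idx):
            if not decided[nb]:
                nb_sum[nb] += psi_out[idx]
                nb_cnt[nb] += 1
                if fg_flat[nb] and not queued[nb]:
                    heapq.heappush(heap, (-flat_q[nb], nb))
                    queued[nb] = True

    # Foreground voxels disconnected from the seed region (if any) and all
    # background voxels inherit the field of the nearest decided voxel.
    decided_vol = decided.reshape(shape)
    psi_vol = psi_out.reshape(shape)
    if not decided_vol.all():
        _, nearest = ndimage.distance_transform_edt(
            ~decided_vol, return_indices=True
        )
        psi_vol = psi_vol[tuple(nearest)]
    return psi_vol


def separate_water_fat(
    echo1: np.ndarray,
    echo2: np.ndarray,
    field_map_hz: np.ndarray,
    acq: AcquisitionParams,
    tie_rtol: float = 1e-6,
    min_separation_deg: float = 10.0,
) -> WaterFatResult:
    """Solve for water and fat magnitudes given the field map.

    Each echo is demodulated by exp(-i 2 pi psi TE); the real non-negative
    (W, F) pair then follows from linear least squares on the stacked
    real/imaginary parts.  ``swap_mask`` flags voxels whose two roots were
    indistinguishable (W == F up to ``tie_rtol``); by convention such signal
    is assigned to water.
    """
    check_te_conditioning(acq, min_separation_deg)
    echo1 = np.asarray(echo1, dtype=np.complex128)
    echo2 = np.asarray(echo2, dtype=np.complex128)
    psi = np.asarray(field_map_hz, dtype=float)
    if not (echo1.shape == echo2.shape == psi.shape):
        raise ValueError("echoes and field map must share a shape")

    theta = [acq.fat_phase_rad(te) for te in (acq.te1_ms, acq.te2_ms)]
    design = np.array(
        [
            [1.0, math.cos(theta[0])],
            [0.0, math.sin(theta[0])],
            [1.0, math.cos(theta[1])],
            [0.0, math.sin(theta[1])],
        ]
    )
    pinv = np.linalg.pinv(design)  # (2, 4)

    d = []
    for echo, te in ((echo1, acq.te1_ms), (echo2, acq.te2_ms)):
        demod = echo * np.exp(-1j * 2 * np.pi * psi * te * 1e-3)
        d.extend([demod.real.ravel(), demod.imag.ravel()])
    b = np.stack(d, axis=0)  # (4, N)
    wf = pinv @ b            # (2, N)
    water = np.maximum(wf[0], 0.0).reshape(echo1.shape)
    fat = np.maximum(wf[1], 0.0).reshape(echo1.shape)

    in_phase = water + fat
    out_phase = np.abs(water - fat)
    swap_mask = (out_phase <= tie_rtol * np.maximum(in_phase, 1e-300)) & (in_phase > 0)
    return WaterFatResult(
        water=water,
        fat=fat,
        field_map_hz=psi,
        in_phase=in_phase,
        out_phase=out_phase,
        swap_mask=swap_mask,
    )


def separate_in_opposed_shortcut(
    echo_in: np.ndarray, echo_opposed: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Classic two-point shortcut for exactly in/opposed-phase magnitudes:
    W = (IP + OP) / 2, F = (IP - OP) / 2.  Cross-check path only."""
    ip = np.abs(np.asarray(echo_in))
    op = np.abs(np.asarray(echo_opposed))
    return (ip + op) / 2.0, np.abs(ip - op) / 2.0


def swap_rate(
    result: WaterFatResult,
    gt: GroundTruth,
    acq: AcquisitionParams,
    signal_floor: float = 0.1,
) -> float:
    """Fraction of foreground voxels whose dominant species is wrong.

    Foreground: voxels whose true (noiseless) total signal exceeds
    ``signal_floor`` times the blood-pool signal.  Voxels with equal true
    water and fat signal carry no dominance and are excluded.  Diagnostic
    for simulated data only (requires the ground truth).
    """
    from .phantom import blood_reference_signal

    w_true, f_true = gt.effective_signal(acq)
    total = w_true + f_true
    floor = signal_floor * blood_reference_signal(gt.spec, acq)
    fg = (total > floor) & (w_true != f_true)
    if not fg.any():
        raise ValueError("empty foreground: no voxels above the signal floor")
    true_water_dom = w_true[fg] > f_true[fg]
    recon_water_dom = result.water[fg] > result.fat[fg]
    return float(np.mean(true_water_dom != recon_water_dom))
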