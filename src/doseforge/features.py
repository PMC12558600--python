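"""Geometric feature maps driving the position-dependent convolution.

A feature map λ is a scalar field in [0, 1] on the dose grid: λ = 0 marks
voxels where degradation should act at full strength, λ = 1 voxels that must
be left untouched (everything outside the body is fixed at 1). The maps are
assembled from Euclidean distance transforms (in physical mm, anisotropic
voxels), slice-wise angular distances from an OAR-to-target ray, min-max
normalization over the body, and a sigmoid-like remap that concentrates the
active region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import SigmoidParams, logger

__all__ = [
    "outside_distance",
    "inside_distance",
    "slicewise_com",
    "angular_feature",
    "normalize_feature",
    "sigmoid_remap",
    "combine_oar_feature",
    "merge_oars",
]


def _check_mask(mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"{what} must be a 3D mask")
    if not mask.any():
        raise ValueError(f"{what} is empty")
    return mask


def outside_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from each outside voxel to the mask; 0 inside."""
    mask = _check_mask(mask, "mask")
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def inside_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) to the mask boundary for inside voxels; 0 outside."""
    mask = _check_mask(mask, "mask")
    return ndimage.distance_transform_edt(mask, sampling=spacing)


def slicewise_com(mask: np.ndarray) -> np.ndarray:
    """Per-axial-slice (y, x) centroid of the mask, NaN where a slice is empty.

    Slice-wise centroids track structures whose cross-section drifts with z
    (e.g. a curved esophagus) better than a single 3D centre of mass.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.full((mask.shape[0], 2), np.nan)
    for z in range(mask.shape[0]):
        sl = mask[z]
        if sl.any():
            ys, xs = np.nonzero(sl)
            out[z] = (ys.mean(), xs.mean())
    return out


def _fill_nearest(com: np.ndarray) -> np.ndarray:
    """Replace NaN rows by the nearest populated slice's centroid."""
    filled = com.copy()
    valid = np.flatnonzero(~np.isnan(com[:, 0]))
    if valid.size == 0:
        raise ValueError("mask has no populated slices")
    for z in range(com.shape[0]):
        if np.isnan(filled[z, 0]):
            filled[z] = com[valid[np.argmin(np.abs(valid - z))]]
    return filled


def angular_feature(
    oar_mask: np.ndarray,
    target_mask: np.ndarray,
    spacing,
    margin_slices: int = 3,
    z_mode: str = "union",
) -> np.ndarray:
    """Slice-wise angular distance from the OAR→target ray, normalized by π.

    On each axial slice, a ray runs from the target centroid through the OAR
    centroid; each voxel's value is the planar angle at the target centroid
    between the voxel direction and that ray, divided by π (so 0 on the ray
    beyond the OAR, 1 diametrically opposite). Slices outside the structures'
    z-extent (``z_mode='union'``: slices holding either structure;
    ``'intersection'``: slices holding both) plus ``margin_slices`` are set
    to 1, i.e. no angular effect there. Within the extent, slices missing a
    structure inherit the nearest populated slice's centroid.
    """
    oar_mask = _check_mask(oar_mask, "OAR mask")
    target_mask = _check_mask(target_mask, "target mask")
    if oar_mask.shape != target_mask.shape:
        raise ValueError("OAR and target masks are not congruent")
    if z_mode not in ("union", "intersection"):
        raise ValueError(f"unknown z_mode {z_mode!r}")

    oar_com = slicewise_com(oar_mask)
    tgt_com = slicewise_com(target_mask)
    oar_slices = ~np.isnan(oar_com[:, 0])
    tgt_slices = ~np.isnan(tgt_com[:, 0])
    present = (oar_slices | tgt_slices) if z_mode == "union" else (oar_slices & tgt_slices)
    if not present.any():
        raise ValueError("no axial slice satisfies the z-extent rule")
    zs = np.flatnonzero(present)
    z_lo = max(0, zs.min() - margin_slices)
    z_hi = min(oar_mask.shape[0] - 1, zs.max() + margin_slices)

    oar_com = _fill_nearest(oar_com)
    tgt_com = _fill_nearest(tgt_com)

    _, sy, sx = (float(s) for s in spacing)
    ny, nx = oar_mask.shape[1:]
    yy = np.arange(ny, dtype=float)[:, None] * sy
    xx = np.arange(nx, dtype=float)[None, :] * sx

    out = np.ones(oar_mask.shape, dtype=float)
    for z in range(z_lo, z_hi + 1):
        ty, tx = tgt_com[z] * (sy, sx)
        oy, ox = oar_com[z] * (sy, sx)
        ray = np.array([oy - ty, ox - tx])
        norm_ray = np.hypot(*ray)
        if norm_ray == 0:
            logger.warning("coincident OAR/target centroids on slice %d; angle set to 0", z)
            out[z] = 0.0
            continue
        vy, vx = yy - ty, xx - tx
        norm_v = np.hypot(vy, vx)
        cos = (vy * ray[0] + vx * ray[1]) / (norm_v * norm_ray + np.finfo(float).tiny)
        ang = np.arccos(np.clip(cos, -1.0, 1.0)) / np.pi
        ang[norm_v == 0] = 0.0  # the target centroid voxel lies on the ray
        out[z] = ang
    return out


def normalize_feature(raw: np.ndarray, body: np.ndarray) -> np.ndarray:
    """Min-max normalize over body voxels to [0, 1]; everything outside → 1."""
    raw = np.asarray(raw, dtype=float)
    body = _check_mask(body, "body mask")
    if raw.shape != body.shape:
        raise ValueError("raw array and body mask are not congruent")
    inside = raw[body]
    if not np.all(np.isfinite(inside)):
        raise ValueError("raw feature values must be finite inside the body")
    lo, hi = inside.min(), inside.max()
    out = np.empty_like(raw)
    if hi == lo:
        logger.warning("degenerate feature: constant value %.4g inside body", lo)
        out.fill(0.0)
    else:
        np.clip((raw - lo) / (hi - lo), 0.0, 1.0, out=out)
    out[~body] = 1.0
    return out


def sigmoid_remap(values: np.ndarray, params: SigmoidParams) -> np.ndarray:
    """Sigmoid-like remap fixing 0 and 1 with half-max at ``params.fwhm``.

    The input is first passed through the gain u = λ^(−ln 2 / ln fwhm), which
    maps fwhm to 0.5, then through the rational sigmoid
    u^β / (u^β + (1 − u)^β) whose steepness is β. Monotone for β > 0.
    """
    if not isinstance(params, SigmoidParams):
        params = SigmoidParams(*params)
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("sigmoid_remap expects values in [0, 1]")
    exponent = -np.log(2.0) / np.log(params.fwhm)
    u = values**exponent
    ub = u**params.beta
    return ub / (ub + (1.0 - u) ** params.beta)


def combine_oar_feature(
    rho: np.ndarray, phi: np.ndarray, angular_weight: float = 0.3
) -> np.ndarray:
    """Weighted sum of distance and angular components, clipped to [0, 1]."""
    rho = np.asarray(rho, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if rho.shape != phi.shape:
        raise ValueError("distance and angular components are not congruent")
    return np.clip(rho + angular_weight * phi, 0.0, 1.0)


def merge_oars(features: list[np.ndarray]) -> np.ndarray:
    """Voxel-wise minimum across individual OAR features (union of influence)."""
    if not features:
        raise ValueError("merge_oars needs at least one feature map")
    shapes = {np.asarray(f).shape for f in features}
    if len(shapes) != 1:
        raise ValueError("feature maps are not congruent")
    return np.minimum.reduce([np.asarray(f, dtype=float) for f in features])
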