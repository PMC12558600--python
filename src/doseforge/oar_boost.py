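"""Technique 1: degrade OAR sparing by boosting dose toward a chosen group.

The feature map opens (λ → 0) in and around the group's OARs, preferentially
along the ray connecting each OAR to the target, while the target interior is
held at λ ≥ 0.98 so prescription coverage barely moves. The convolution then
raises dose by up to the scaling factor ``a`` where the map is open, an
element-wise maximum against the original forbids any decrease, and the
hotspot threshold keeps the result visually plausible.
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_PARAMS, DegradeParams, DoseGrid, OarGroup, StructureSet, logger
from .features import (
    angular_feature,
    combine_oar_feature,
    inside_distance,
    merge_oars,
    normalize_feature,
    outside_distance,
    sigmoid_remap,
)
from .gac import T1_5X5, apply_gac, clamp_direction, suppress_hotspots

__all__ = ["build_t1_feature", "degrade_oar_sparing"]


def build_t1_feature(
    structures: StructureSet,
    group: OarGroup,
    spacing,
    params: DegradeParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Final feature map for the OAR-dose boost.

    Per group member: a distance component ρ (distance outside the OAR,
    normalized over the body, sigmoid-remapped) plus a weighted angular
    component φ (OAR→target ray, remapped likewise), clipped to [0, 1];
    members merge by voxel-wise minimum. The target union contributes a
    protection term: its interior depth, remapped and rescaled to
    [0, 0.98], zero outside the targets. The final map is the voxel-wise
    maximum of the two, so the strongest constraint wins everywhere.
    """
    structures.require(group.members)
    body = structures.body
    target_union = structures.target_union()

    member_maps = []
    for name in group.members:
        oar = structures.oars[name]
        rho = sigmoid_remap(
            normalize_feature(outside_distance(oar, spacing), body),
            params.t1_distance_sigmoid,
        )
        phi_raw = angular_feature(
            oar, target_union, spacing, params.angular_margin_slices, z_mode="union"
        )
        phi = sigmoid_remap(normalize_feature(phi_raw, body), params.t1_angular_sigmoid)
        member_maps.append(combine_oar_feature(rho, phi, params.angular_weight))
    lam_oar = merge_oars(member_maps)

    rho_ptv = params.t1_target_ceiling * sigmoid_remap(
        normalize_feature(inside_distance(target_union, spacing), body),
        params.t1_target_sigmoid,
    )
    rho_ptv[~target_union] = 0.0  # no target protection outside the targets

    lam = np.maximum(lam_oar, rho_ptv)
    lam[~body] = 1.0
    return lam


def degrade_oar_sparing(
    dose: DoseGrid,
    structures: StructureSet,
    group: OarGroup,
    a: float,
    params: DegradeParams = DEFAULT_PARAMS,
) -> DoseGrid:
    """Boost dose to ``group`` by up to factor ``a`` > 1; never decreases dose."""
    if a <= 1.0:
        raise ValueError(f"Technique 1 requires a > 1, got {a}")
    if a > max(params.t1_scale_range_hn):
        logger.warning("scaling a=%.3g exceeds the validated range (max %.3g)",
                       a, max(params.t1_scale_range_hn))
    lam = build_t1_feature(structures, group, dose.spacing, params)
    out = apply_gac(dose.values, lam, a, T1_5X5)
    out = clamp_direction(out, dose.values, "increase")
    out = suppress_hotspots(
        out, dose.max_prescription, params.hotspot_threshold, params.hotspot_rescale
    )
    return dose.with_values(out)
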