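"""Technique 2: erode high-dose conformality around the high-risk target.

Three components shape the feature map: a narrow band hugging the target
border (uniform conformality loss), a wider outside-distance component, and
an angular component oriented at a chosen OAR group — together they pull the
prescription isodose off the target, most strongly on the side facing the
over-spared OARs. The convolution lowers dose by up to the factor ``a`` < 1
where the map is open; an element-wise minimum against the original forbids
any increase.
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_PARAMS, DegradeParams, DoseGrid, OarGroup, StructureSet
from .features import (
    angular_feature,
    combine_oar_feature,
    inside_distance,
    merge_oars,
    normalize_feature,
    outside_distance,
    sigmoid_remap,
)
from .gac import T2_3X3, apply_gac, clamp_direction

__all__ = ["build_t2_feature", "degrade_conformality"]


def build_t2_feature(
    structures: StructureSet,
    group: OarGroup,
    spacing,
    prescriptions,
    params: DegradeParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Final feature map for conformality erosion around the high-risk target.

    Component 1 is the unsigned distance to the target border evaluated on
    both sides, remapped through a very narrow sigmoid so only a thin shell
    around the border stays open. Component 2 is the outside-only distance
    with a wider sigmoid; component 3 the OAR-ray angular distance restricted
    to slices containing both structures (±margin). Components 2 and 3
    combine per member as ρ + w·φ and merge by minimum; the final map is
    clip(0.4·component1 + merged, 0, 1).
    """
    structures.require(group.members)
    body = structures.body
    _, target = structures.high_risk_target(prescriptions)

    d_out = outside_distance(target, spacing)
    d_border = d_out + inside_distance(target, spacing)
    c1 = sigmoid_remap(normalize_feature(d_border, body), params.t2_band_sigmoid)
    c2 = sigmoid_remap(normalize_feature(d_out, body), params.t2_outside_sigmoid)

    member_maps = []
    for name in group.members:
        oar = structures.oars[name]
        phi_raw = angular_feature(
            oar, target, spacing, params.angular_margin_slices, z_mode="intersection"
        )
        c3 = sigmoid_remap(normalize_feature(phi_raw, body), params.t2_angular_sigmoid)
        member_maps.append(combine_oar_feature(c2, c3, params.angular_weight))
    lam_ptv_oar = merge_oars(member_maps)

    lam = np.clip(params.t2_band_weight * c1 + lam_ptv_oar, 0.0, 1.0)
    lam[~body] = 1.0
    return lam


def degrade_conformality(
    dose: DoseGrid,
    structures: StructureSet,
    group: OarGroup,
    a: float,
    params: DegradeParams = DEFAULT_PARAMS,
) -> DoseGrid:
    """Reduce target coverage by up to factor ``a`` < 1; never increases dose."""
    if not 0.0 < a < 1.0:
        raise ValueError(f"Technique 2 requires 0 < a < 1, got {a}")
    lam = build_t2_feature(structures, group, dose.spacing, dose.prescriptions, params)
    out = apply_gac(dose.values, lam, a, T2_3X3)
    out = clamp_direction(out, dose.values, "decrease")
    return dose.with_values(out)
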