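"""Synthetic dose phantoms emulating high-quality VMAT dose distributions.

Clinical dose grids are not shipped with the package, so every pipeline stage
is exercised on phantoms built here: an ellipsoidal body, one or more
spherical/shell targets receiving their prescription, exponential dose
falloff outside the targets over a low-dose bath, and ellipsoidal organs at
risk (OARs) placed at varying distances and angles from the target.

The generated plans satisfy the quality contract of a good VMAT plan: each
target's V95% coverage is essentially complete, the global maximum stays
below 104% of the highest prescription, and (noise aside) dose decreases
monotonically with distance from the target surface.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DoseGrid, OarGroup, StructureSet, axis_coordinates, logger

__all__ = [
    "TargetSpec",
    "OarSpec",
    "PhantomSpec",
    "make_phantom",
    "make_cohort",
    "hn_spec",
    "gyn_spec",
    "OAR_GROUPS",
]


@dataclass(frozen=True)
class TargetSpec:
    """A spherical target (or, with ``inner_radius > 0``, a concentric shell)."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    prescription_cgy: float
    inner_radius_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= self.inner_radius_mm or self.inner_radius_mm < 0:
            raise ValueError(f"target {self.name!r}: need 0 <= inner_radius < radius")
        if self.prescription_cgy <= 0:
            raise ValueError(f"target {self.name!r}: prescription must be positive")


@dataclass(frozen=True)
class OarSpec:
    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Geometry and dose model of one synthetic plan.

    ``falloff_scale`` is the exponential decay length (mm) of dose outside the
    targets; ``bath_fraction`` the low-dose plateau inside the body as a
    fraction of prescription; ``noise_sd`` the standard deviation of the
    multiplicative Gaussian dose noise as a fraction of prescription.
    """

    grid_shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)
    body_semi_axes_mm: tuple[float, float, float] = (70.0, 85.0, 85.0)
    targets: list[TargetSpec] = field(default_factory=list)
    oars: list[OarSpec] = field(default_factory=list)
    falloff_scale: float = 15.0
    bath_fraction: float = 0.15
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.falloff_scale <= 0:
            raise ValueError("falloff_scale must be positive")
        if not 0.0 <= self.bath_fraction < 0.5:
            raise ValueError("bath_fraction must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.targets:
            raise ValueError("phantom needs at least one target")


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    z, y, x = axis_coordinates(shape, spacing)
    zz = ((z - center_mm[0]) / semi_axes_mm[0]) ** 2
    yy = ((y - center_mm[1]) / semi_axes_mm[1]) ** 2
    xx = ((x - center_mm[2]) / semi_axes_mm[2]) ** 2
    return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0


def _radial_distance(shape, spacing, center_mm) -> np.ndarray:
    z, y, x = axis_coordinates(shape, spacing)
    zz = (z - center_mm[0]) ** 2
    yy = (y - center_mm[1]) ** 2
    xx = (x - center_mm[2]) ** 2
    return np.sqrt(zz[:, None, None] + yy[None, :, None] + xx[None, None, :])


def make_phantom(spec: PhantomSpec) -> tuple[DoseGrid, StructureSet]:
    """Realize a phantom: dose grid plus congruent structure masks.

    Inside each target the dose is ``Rx * (1 + noise)``. Outside, each
    target contributes ``Rx * max(bath, exp(-d / falloff) * (1 + noise))``
    with ``d`` the Euclidean distance (mm) to the target surface, and the
    voxel takes the maximum contribution. Dose is clipped to 104% of the
    highest prescription and zeroed outside the body. Deterministic per seed.
    """
    shape, spacing = spec.grid_shape, spec.spacing
    body = _ellipsoid_mask(shape, spacing, (0.0, 0.0, 0.0), spec.body_semi_axes_mm)

    target_masks: dict[str, np.ndarray] = {}
    for t in spec.targets:
        r = _radial_distance(shape, spacing, t.center_mm)
        mask = r <= t.radius_mm
        if t.inner_radius_mm > 0:
            mask &= r > t.inner_radius_mm
        if not mask.any():
            raise ValueError(f"target {t.name!r} contains no voxels on this grid")
        target_masks[t.name] = mask

    names = list(target_masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(target_masks[a] & target_masks[b]):
                raise ValueError(f"targets {a!r} and {b!r} overlap")

    oar_masks: dict[str, np.ndarray] = {}
    for o in spec.oars:
        mask = _ellipsoid_mask(shape, spacing, o.center_mm, o.semi_axes_mm)
        if not mask.any():
            raise ValueError(f"OAR {o.name!r} contains no voxels on this grid")
        oar_masks[o.name] = mask

    for name, mask in {**target_masks, **oar_masks}.items():
        if np.any(mask & ~body):
            raise ValueError(f"structure {name!r} extends outside the body")

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else np.zeros(shape)

    dose = np.zeros(shape, dtype=float)
    for t in spec.targets:
        mask = target_masks[t.name]
        d = ndimage.distance_transform_edt(~mask, sampling=spacing)
        outside = np.maximum(spec.bath_fraction, np.exp(-d / spec.falloff_scale) * (1.0 + noise))
        contribution = t.prescription_cgy * np.where(mask, 1.0 + noise, outside)
        np.maximum(dose, contribution, out=dose)

    rx_max = max(t.prescription_cgy for t in spec.targets)
    np.clip(dose, 0.0, 1.04 * rx_max, out=dose)
    dose[~body] = 0.0

    grid = DoseGrid(dose, spacing, {t.name: t.prescription_cgy for t in spec.targets})
    structures = StructureSet(body, target_masks, oar_masks)
    return grid, structures


def make_cohort(
    n: int, base_spec: PhantomSpec, seed: int
) -> list[tuple[DoseGrid, StructureSet]]:
    """``n`` phantoms with jittered geometry and independent noise.

    Per case, target radii are scaled by a common factor in [0.92, 1.08],
    target centres are shifted jointly by up to ±2 mm per axis, and OAR
    centres by up to ±3 mm with semi-axes scaled in [0.92, 1.08]. A pure
    function of ``(n, base_spec, seed)``.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        spec = copy.deepcopy(base_spec)
        radial = rng.uniform(0.92, 1.08)
        shift = rng.uniform(-2.0, 2.0, size=3)
        spec.targets = [
            dataclasses.replace(
                t,
                radius_mm=t.radius_mm * radial,
                inner_radius_mm=t.inner_radius_mm * radial,
                center_mm=tuple(np.asarray(t.center_mm) + shift),
            )
            for t in spec.targets
        ]
        spec.oars = [
            dataclasses.replace(
                o,
                center_mm=tuple(np.asarray(o.center_mm) + rng.uniform(-3.0, 3.0, size=3)),
                semi_axes_mm=tuple(np.asarray(o.semi_axes_mm) * rng.uniform(0.92, 1.08)),
            )
            for o in spec.oars
        ]
        spec.seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(make_phantom(spec))
    logger.info("generated cohort of %d phantoms (seed=%d)", n, seed)
    return cohort


def hn_spec(seed: int = 0) -> PhantomSpec:
    """Head-and-neck-like phantom: three nested targets with distinct
    prescriptions (high/mid/low risk) and the five classic HN OAR sites."""
    return PhantomSpec(
        targets=[
            TargetSpec("ptv_high", (0.0, 0.0, 0.0), 20.0, 7000.0),
            TargetSpec("ptv_mid", (0.0, 0.0, 0.0), 28.0, 6300.0, inner_radius_mm=20.0),
            TargetSpec("ptv_low", (0.0, 0.0, 0.0), 34.0, 5600.0, inner_radius_mm=28.0),
        ],
        oars=[
            OarSpec("esophagus", (-40.0, 22.0, 0.0), (18.0, 8.0, 8.0)),
            OarSpec("larynx", (-18.0, 30.0, 0.0), (8.0, 9.0, 9.0)),
            OarSpec("brainstem", (32.0, 28.0, 0.0), (22.0, 8.0, 8.0)),
            OarSpec("optic_nerves", (38.0, -25.0, 0.0), (4.0, 5.0, 20.0)),
            OarSpec("parotid_l", (0.0, 0.0, 55.0), (15.0, 10.0, 10.0)),
            OarSpec("parotid_r", (0.0, 0.0, -55.0), (15.0, 10.0, 10.0)),
            OarSpec("cochlea_l", (24.0, -12.0, 52.0), (4.0, 4.0, 4.0)),
            OarSpec("cochlea_r", (24.0, -12.0, -52.0), (4.0, 4.0, 4.0)),
        ],
        seed=seed,
    )


def gyn_spec(seed: int = 0) -> PhantomSpec:
    """Gynecologic-like phantom: a single target prescribed 4500 cGy with
    bladder, rectum and femoral heads around it."""
    return PhantomSpec(
        targets=[TargetSpec("ptv_4500", (0.0, 0.0, 0.0), 30.0, 4500.0)],
        oars=[
            OarSpec("bladder", (0.0, -48.0, 0.0), (18.0, 14.0, 14.0)),
            OarSpec("rectum", (0.0, 48.0, 0.0), (24.0, 11.0, 11.0)),
            OarSpec("femoral_head_l", (0.0, 10.0, 60.0), (20.0, 13.0, 13.0)),
            OarSpec("femoral_head_r", (0.0, 10.0, -60.0), (20.0, 13.0, 13.0)),
        ],
        seed=seed,
    )


OAR_GROUPS: dict[str, dict[str, OarGroup]] = {
    "hn": {
        "esophagus_larynx": OarGroup("esophagus_larynx", ("esophagus", "larynx")),
        "brainstem": OarGroup("brainstem", ("brainstem",)),
        "optics": OarGroup("optics", ("optic_nerves",)),
        "parotids": OarGroup("parotids", ("parotid_l", "parotid_r")),
        "cochleae": OarGroup("cochleae", ("cochlea_l", "cochlea_r")),
    },
    "gyn": {
        "bladder": OarGroup("bladder", ("bladder",)),
        "rectum": OarGroup("rectum", ("rectum",)),
        "femoral_heads": OarGroup("femoral_heads", ("femoral_head_l", "femoral_head_r")),
    },
}
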