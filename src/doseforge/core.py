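"""Shared domain objects: dose grids, structure sets, configuration.

Conventions used throughout the package:

* All volumetric arrays are indexed ``(z, y, x)`` with 0-based voxel indices.
* ``spacing`` is millimetres per voxel along ``(z, y, x)``.
* Dose is stored in centigray (cGy) as floating point; masks are boolean
  arrays congruent with the dose grid.
* Physical coordinates place the origin at the grid centre: the coordinate of
  voxel ``i`` along an axis of length ``n`` is ``(i - (n - 1) / 2) * spacing``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("doseforge")

Spacing = tuple[float, float, float]


def _as_spacing(spacing: Sequence[float]) -> Spacing:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be three positive mm values, got {spacing!r}")
    return s  # type: ignore[return-value]


def axis_coordinates(shape: Sequence[int], spacing: Sequence[float]) -> tuple[np.ndarray, ...]:
    """Physical (mm) coordinates of voxel centres along each axis, origin at grid centre."""
    return tuple(
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    )


@dataclass
class DoseGrid:
    """A 3D dose distribution in cGy with voxel spacing and target prescriptions."""

    values: np.ndarray
    spacing: Spacing
    prescriptions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing = _as_spacing(self.spacing)
        self.prescriptions = {str(k): float(v) for k, v in self.prescriptions.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def max_prescription(self) -> float:
        if not self.prescriptions:
            raise ValueError("DoseGrid carries no prescriptions")
        return max(self.prescriptions.values())

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """A copy of this grid carrying new dose values (same spacing/prescriptions)."""
        return DoseGrid(np.asarray(values, dtype=float), self.spacing, dict(self.prescriptions))


@dataclass
class StructureSet:
    """Binary masks congruent with a DoseGrid: body, targets and organs at risk."""

    body: np.ndarray
    targets: dict[str, np.ndarray] = field(default_factory=dict)
    oars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.body = np.asarray(self.body, dtype=bool)
        self.targets = {k: np.asarray(v, dtype=bool) for k, v in self.targets.items()}
        self.oars = {k: np.asarray(v, dtype=bool) for k, v in self.oars.items()}
        for name, mask in self.iter_structures():
            if mask.shape != self.body.shape:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} does not match body {self.body.shape}"
                )
            if np.any(mask & ~self.body):
                raise ValueError(f"structure {name!r} extends outside the body mask")

    def iter_structures(self) -> Iterable[tuple[str, np.ndarray]]:
        yield from self.targets.items()
        yield from self.oars.items()

    def target_union(self) -> np.ndarray:
        if not self.targets:
            raise ValueError("structure set has no targets")
        out = np.zeros_like(self.body)
        for mask in self.targets.values():
            out |= mask
        return out

    def high_risk_target(self, prescriptions: Mapping[str, float]) -> tuple[str, np.ndarray]:
        """The target with the highest prescription."""
        if not self.targets:
            raise ValueError("structure set has no targets")
        name = max(self.targets, key=lambda t: prescriptions.get(t, -np.inf))
        if name not in prescriptions:
            raise ValueError(f"no prescription recorded for target {name!r}")
        return name, self.targets[name]

    def require(self, names: Iterable[str]) -> None:
        known = set(self.targets) | set(self.oars)
        missing = [n for n in names if n not in known]
        if missing:
            raise KeyError(f"structures not found in structure set: {missing}")


@dataclass(frozen=True)
class OarGroup:
    """A named group of organs at risk degraded together (e.g. both parotids)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("OAR group must have at least one member")


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoid-like feature remap: half-max point and steepness."""

    fwhm: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fwhm < 1.0:
            raise ValueError(f"fwhm must lie strictly inside (0, 1), got {self.fwhm}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass
class DegradeParams:
    """Every tunable of the degradation techniques, with its published default.

    ``t1_*`` drive the OAR-dose boost, ``t2_*`` the conformality erosion.
    Sigmoid pairs are (fwhm, beta); weights are unitless.
    """

    t1_distance_sigmoid: SigmoidParams = field(default_factory=lambda: SigmoidParams(0.05, 5.0))
    t1_angular_sigmoid: SigmoidParams = field(default_factory=lambda: SigmoidParams(0.05, 5.0))
    t1_target_sigmoid: SigmoidParams = field(default_factory=lambda: SigmoidParams(0.09, 5.0))
    t1_target_ceiling: float = 0.98
    angular_weight: float = 0.3
    angular_margin_slices: int = 3
    t2_band_sigmoid: SigmoidParams = field(default_factory=lambda: SigmoidParams(0.01, 15.0))
    t2_outside_sigmoid: SigmoidParams = field(default_factory=lambda: SigmoidParams(0.05, 10.0))
    t2_angular_sigmoid: SigmoidParams = field(default_factory=lambda: SigmoidParams(0.2, 10.0))
    t2_band_weight: float = 0.4
    hotspot_threshold: float = 1.04
    hotspot_rescale: float = 0.98
    t1_scale_range_hn: tuple[float, ...] = (1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7)
    t1_scale_range_gyn: tuple[float, ...] = (1.1, 1.2, 1.3, 1.4, 1.5, 1.6)
    t2_scale_range: tuple[float, ...] = (0.99, 0.98, 0.97, 0.96, 0.95)

    @classmethod
    def from_yaml(cls, path: str) -> "DegradeParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            if f.name.endswith("_sigmoid"):
                value = SigmoidParams(**value)
            elif isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)


DEFAULT_PARAMS = DegradeParams()
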