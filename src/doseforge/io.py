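"""Case I/O: NIfTI volumes with a JSON sidecar, plus run manifests.

A "case" on disk is a directory holding ``dose.nii.gz``, one
``mask_<name>.nii.gz`` per structure, and ``case.json`` recording spacing
(mm, z/y/x), prescriptions, and which masks are body/targets/OARs. Arrays
are kept in (z, y, x) order in memory and transposed to NIfTI's (x, y, z)
on disk with a diagonal affine built from the spacing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DoseGrid, StructureSet

__all__ = ["RunManifest", "read_case", "write_case", "write_volume"]

try:
    _VERSION = version("doseforge")
except PackageNotFoundError:  # pragma: no cover - editable-install edge
    _VERSION = "unknown"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly given the inputs."""

    technique: str
    parameters: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    library_version: str = _VERSION
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _affine(spacing) -> np.ndarray:
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def write_volume(values: np.ndarray, spacing, path: str | Path) -> None:
    """Write one (z, y, x) array as NIfTI (transposed to x, y, z on disk)."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.T), _affine(spacing)), str(path))


def _read_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).T
    sx, sy, sz = img.header.get_zooms()[:3]
    return arr, (float(sz), float(sy), float(sx))


def write_case(
    dose: DoseGrid,
    structures: StructureSet,
    path: str | Path,
    manifest: RunManifest | None = None,
    feature_map: np.ndarray | None = None,
) -> Path:
    """Write a case directory; optionally include a feature-map volume."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_volume(dose.values, dose.spacing, path / "dose.nii.gz")
    write_volume(structures.body, dose.spacing, path / "mask_body.nii.gz")
    for name, mask in structures.iter_structures():
        write_volume(mask, dose.spacing, path / f"mask_{name}.nii.gz")
    if feature_map is not None:
        write_volume(feature_map, dose.spacing, path / "feature.nii.gz")
    sidecar = {
        "spacing_mm_zyx": list(dose.spacing),
        "prescriptions_cgy": dose.prescriptions,
        "targets": sorted(structures.targets),
        "oars": sorted(structures.oars),
    }
    (path / "case.json").write_text(json.dumps(sidecar, indent=2))
    if manifest is not None:
        manifest.write(path / "manifest.json")
    return path


def read_case(path: str | Path) -> tuple[DoseGrid, StructureSet]:
    """Load a case directory written by :func:`write_case`."""
    path = Path(path)
    sidecar_path = path / "case.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no case.json sidecar in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    spacing = tuple(sidecar["spacing_mm_zyx"])
    prescriptions = {k: float(v) for k, v in sidecar["prescriptions_cgy"].items()}
    for t in sidecar["targets"]:
        if t not in prescriptions:
            raise ValueError(f"target {t!r} has no prescription in the sidecar")

    dose_values, dose_spacing = _read_volume(path / "dose.nii.gz")
    if not np.allclose(dose_spacing, spacing):
        raise ValueError(f"dose spacing {dose_spacing} disagrees with sidecar {spacing}")

    body_path = path / "mask_body.nii.gz"
    if not body_path.exists():
        raise FileNotFoundError(f"missing body mask in {path}")
    body, _ = _read_volume(body_path)

    def load_masks(names):
        out = {}
        for name in names:
            arr, sp = _read_volume(path / f"mask_{name}.nii.gz")
            if arr.shape != dose_values.shape:
                raise ValueError(
                    f"mask {name!r} shape {arr.shape} does not match dose {dose_values.shape}"
                )
            if not np.allclose(sp, spacing):
                raise ValueError(f"mask {name!r} spacing {sp} disagrees with sidecar")
            out[name] = arr.astype(bool)
        return out

    if not sidecar["targets"]:
        raise ValueError(f"case in {path} declares no targets")
    targets = load_masks(sidecar["targets"])
    oars = load_masks(sidecar["oars"])
    dose = DoseGrid(dose_values, spacing, prescriptions)
    structures = StructureSet(body.astype(bool), targets, oars)
    if dose.shape != structures.body.shape:
        raise ValueError("dose and body mask are not congruent")
    return dose, structures
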