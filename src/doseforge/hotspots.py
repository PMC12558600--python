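"""Technique 3: inject hotspots into the high-risk target via random walks.

One to four random walks are launched inside the target mask, each biased to
move in the axial plane (hotspots in real plans are wider than they are
tall). Each walk's visited voxels get a per-hotspot scale factor above 1;
grey dilation and box smoothing then spread and feather the region, and
voxel-wise multiplication with the dose plants the hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DoseGrid, StructureSet, logger

__all__ = ["HotspotConfig", "random_walk", "build_multiplier", "inject_hotspots"]

_INPLANE_STEPS = np.array([[0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
_AXIAL_STEPS = np.array([[1, 0, 0], [-1, 0, 0]])


@dataclass(frozen=True)
class HotspotConfig:
    """Hotspot generation settings.

    ``n_hotspots=None`` draws uniformly from 1–4; each walk gets
    ``walk_budget // n_hotspots`` steps. Scales are drawn per hotspot from
    ``scale_range``; ``xy_bias`` is the probability of an in-plane step.
    """

    n_hotspots: int | None = None
    walk_budget: int = 75
    scale_range: tuple[float, float] = (1.07, 1.13)
    xy_bias: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hotspots is not None and not 1 <= self.n_hotspots <= 4:
            raise ValueError("n_hotspots must lie in 1..4 (or None for random)")
        if self.walk_budget < 1:
            raise ValueError("walk_budget must be positive")
        lo, hi = self.scale_range
        if lo <= 1.0 or hi < lo:
            raise ValueError("scale_range must satisfy 1 < low <= high")
        if not 0.0 <= self.xy_bias <= 1.0:
            raise ValueError("xy_bias must be a probability")


def random_walk(
    target_mask: np.ndarray,
    n_steps: int,
    xy_bias: float,
    rng: np.random.Generator,
    max_resample: int = 50,
    return_path: bool = False,
    start: tuple[int, int, int] | None = None,
):
    """Voxels visited by one biased random walk confined to the mask.

    The start voxel is uniform over the mask unless ``start`` is given. Each step moves one voxel in
    ±y/±x with probability ``xy_bias`` (split evenly over the four in-plane
    moves) or ±z otherwise; moves that would leave the mask are resampled.
    If no admissible move is found after ``max_resample`` draws the walker
    stays put for that step. With ``return_path`` the ordered positions
    (one per step, plus the start) are returned instead of the visited set.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if not target_mask.any():
        raise ValueError("target mask is empty")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")

    if start is None:
        voxels = np.argwhere(target_mask)
        pos = voxels[rng.integers(len(voxels))]
    else:
        if not target_mask[tuple(start)]:
            raise ValueError("start voxel lies outside the mask")
        pos = np.asarray(start)
    path = [tuple(int(c) for c in pos)]
    stuck = False
    for _ in range(n_steps):
        for _ in range(max_resample):
            if rng.random() < xy_bias:
                step = _INPLANE_STEPS[rng.integers(4)]
            else:
                step = _AXIAL_STEPS[rng.integers(2)]
            cand = pos + step
            if np.all(cand >= 0) and np.all(cand < target_mask.shape) and target_mask[tuple(cand)]:
                pos = cand
                break
        else:
            stuck = True
        path.append(tuple(int(c) for c in pos))
    if stuck:
        logger.warning("random walk could not move inside the mask; walker stayed put")
    return path if return_path else set(path)


def build_multiplier(
    target_mask: np.ndarray, config: HotspotConfig, rng: np.random.Generator
) -> np.ndarray:
    """The voxel-wise dose multiplier: ≥ 1 everywhere, > 1 near the walks.

    Each hotspot's visited voxels are set to its scale (overlaps keep the
    larger scale); grey dilation with a (1, 3, 3) footprint widens the
    region, and a (1, 5, 5) box mean feathers its edge. Averaging values
    ≥ 1 can never undershoot 1, so the floor is exact.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    n = config.n_hotspots or int(rng.integers(1, 5))
    n_steps = config.walk_budget // n
    mult = np.ones(target_mask.shape, dtype=float)
    for _ in range(n):
        scale = rng.uniform(*config.scale_range)
        walk = random_walk(target_mask, n_steps, config.xy_bias, rng)
        idx = tuple(np.array(sorted(walk)).T)
        mult[idx] = np.maximum(mult[idx], scale)
    mult = ndimage.grey_dilation(mult, size=(1, 3, 3))
    # smooth the excess over 1 rather than the multiplier itself: the box
    # filter's cumulative sums then stay exactly zero away from the walks,
    # keeping the multiplier exactly 1 there and never below 1 anywhere
    excess = ndimage.uniform_filter(mult - 1.0, size=(1, 5, 5), mode="nearest")
    return 1.0 + np.maximum(excess, 0.0)


def inject_hotspots(
    dose: DoseGrid, structures: StructureSet, config: HotspotConfig
) -> DoseGrid:
    """Multiply the dose by a hotspot field planted in the high-risk target."""
    _, target = structures.high_risk_target(dose.prescriptions)
    rng = np.random.default_rng(config.seed)
    mult = build_multiplier(target, config, rng)
    return dose.with_values(dose.values * mult)
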