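"""Cohort-level reproduction experiments.

Convenience drivers that run a degradation technique over a synthetic cohort
and collect the per-case DVH deltas — the same loop the significance claims
are checked with, shared by the test suite, the acceptance script and the
``cohort-stats`` CLI path.
"""

from __future__ import annotations

import numpy as np

from .conformality import degrade_conformality
from .core import DEFAULT_PARAMS, DegradeParams, OarGroup
from .hotspots import HotspotConfig, inject_hotspots
from .metrics import DeltaReport, delta_metrics
from .oar_boost import degrade_oar_sparing
from .phantoms import OAR_GROUPS, PhantomSpec, gyn_spec, make_cohort

__all__ = ["run_technique_over_cohort", "collect", "default_cohort"]


def default_cohort(n: int = 20, seed: int = 0, base_spec: PhantomSpec | None = None):
    """The standard experiment cohort: GYN-like single-target phantoms."""
    return make_cohort(n, base_spec or gyn_spec(), seed)


def run_technique_over_cohort(
    cohort,
    technique: str,
    group: OarGroup | str | None = None,
    a: float | None = None,
    hotspot_config: HotspotConfig | None = None,
    params: DegradeParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> list[DeltaReport]:
    """Degrade every case and return its DVH delta report.

    ``technique`` is one of ``"oar_boost"``, ``"conformality"``,
    ``"hotspots"``. For the first two, ``group`` (an :class:`OarGroup` or a
    known group name) and ``a`` are required; for hotspots, each case gets an
    independent sub-seed derived from ``seed``.
    """
    if isinstance(group, str):
        for site_groups in OAR_GROUPS.values():
            if group in site_groups:
                group = site_groups[group]
                break
        else:
            raise KeyError(f"unknown OAR group {group!r}")

    rng = np.random.default_rng(seed)
    reports = []
    for i, (dose, structures) in enumerate(cohort):
        if technique == "oar_boost":
            degraded = degrade_oar_sparing(dose, structures, group, a, params)
            meta = {"technique": technique, "a": a, "group": group.name, "case": i}
        elif technique == "conformality":
            degraded = degrade_conformality(dose, structures, group, a, params)
            meta = {"technique": technique, "a": a, "group": group.name, "case": i}
        elif technique == "hotspots":
            cfg = hotspot_config or HotspotConfig()
            cfg = HotspotConfig(
                cfg.n_hotspots, cfg.walk_budget, cfg.scale_range, cfg.xy_bias,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            degraded = inject_hotspots(dose, structures, cfg)
            meta = {"technique": technique, "case": i, "seed": cfg.seed}
        else:
            raise ValueError(f"unknown technique {technique!r}")
        reports.append(delta_metrics(dose, degraded, structures, metadata=meta))
    return reports


def collect(reports: list[DeltaReport], metric: str, structure: str) -> list[float]:
    """Pull one metric for one structure out of a list of delta reports."""
    return [getattr(r, metric)[structure] for r in reports]
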