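"""End-to-end behavior of the three degradation techniques on phantoms."""

import numpy as np
import pytest

import doseforge as df


class TestOarBoost:
    def test_feature_map_contract(self, gyn_case):
        """λ lies in [0,1], equals 1 outside the body, is ~0.98 at the target's
        deepest voxel (protection ceiling) and low inside the boosted OAR."""
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        lam = df.build_t1_feature(structures, group, dose.spacing)
        assert lam.min() >= 0.0 and lam.max() <= 1.0
        assert np.all(lam[~structures.body] == 1.0)
        target = structures.targets["ptv_4500"]
        depth = df.inside_distance(target, dose.spacing)
        deepest = np.unravel_index(np.argmax(depth), depth.shape)
        assert lam[deepest] >= 0.98 - 1e-9
        # somewhere inside the OAR the map is nearly fully open
        assert lam[structures.oars["bladder"]].min() < 0.05

    def test_missing_structure_rejected(self, gyn_case):
        dose, structures = gyn_case
        with pytest.raises(KeyError, match="ghost"):
            df.build_t1_feature(structures, df.OarGroup("g", ("ghost",)), dose.spacing)

    def test_dose_never_decreases_and_targets_held(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        degraded = df.degrade_oar_sparing(dose, structures, group, 1.3)
        assert np.all(degraded.values >= dose.values - 1e-9)
        mean0, _ = df.dose_metrics(dose, structures.targets["ptv_4500"])
        mean1, _ = df.dose_metrics(degraded, structures.targets["ptv_4500"])
        assert (mean1 - mean0) / mean0 < 0.02

    def test_boost_is_localized_to_group(self, gyn_case):
        """The selected group's Dmean rises more than the opposite-side OAR's."""
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        degraded = df.degrade_oar_sparing(dose, structures, group, 1.1)
        d_group = df.delta_metrics(dose, degraded, structures).delta_dmean
        assert d_group["bladder"] > 0
        assert d_group["bladder"] > d_group["rectum"]

    def test_hotspot_ceiling_respected(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        degraded = df.degrade_oar_sparing(dose, structures, group, 1.7)
        rx = dose.max_prescription
        over = degraded.values[degraded.values > 1.04 * rx]
        # any voxel above the ceiling is the single-pass residual 0.98·d of an
        # input just over it, so it stays below 0.98 · (max possible input)
        assert np.all(over <= 0.98 * 1.7 * dose.values.max())

    def test_delta_dmax_monotone_in_a(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        dmaxes = []
        for a in (1.1, 1.3, 1.5, 1.7):
            degraded = df.degrade_oar_sparing(dose, structures, group, a)
            dmaxes.append(df.dose_metrics(degraded, structures.oars["bladder"])[1])
        assert np.all(np.diff(dmaxes) >= -1e-9)

    def test_rejects_a_at_most_one(self, gyn_case):
        dose, structures = gyn_case
        with pytest.raises(ValueError):
            df.degrade_oar_sparing(dose, structures, df.OAR_GROUPS["gyn"]["bladder"], 1.0)


class TestConformality:
    def test_feature_map_band_and_far_field(self, gyn_case):
        """The map opens in a thin band at the target border and saturates to
        1 far from both the target and the OAR group."""
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        lam = df.build_t2_feature(structures, group, dose.spacing, dose.prescriptions)
        assert lam.min() >= 0.0 and lam.max() <= 1.0
        assert np.all(lam[~structures.body] == 1.0)
        target = structures.targets["ptv_4500"]
        border = df.outside_distance(target, dose.spacing) + df.inside_distance(
            target, dose.spacing
        )
        on_border = (border <= 2.5) & structures.body
        assert lam[on_border].min() < 0.45  # narrow-band opening
        far = (border > 40.0) & structures.body & ~structures.oars["bladder"]
        # away from target and OAR ray the map must fully close on some voxels
        assert np.median(lam[far]) == 1.0

    def test_dose_never_increases_and_far_dose_unchanged(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        degraded = df.degrade_conformality(dose, structures, group, 0.95)
        assert np.all(degraded.values <= dose.values + 1e-12)
        lam = df.build_t2_feature(structures, group, dose.spacing, dose.prescriptions)
        untouched = lam == 1.0
        np.testing.assert_allclose(
            degraded.values[untouched], dose.values[untouched], atol=1e-10
        )

    def test_relative_decrease_bounded_by_scale(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        for a in (0.99, 0.95):
            degraded = df.degrade_conformality(dose, structures, group, a)
            pos = dose.values > 0
            rel = degraded.values[pos] / dose.values[pos]
            # smoothing can only average neighbours, so the worst-case factor
            # is bounded below by a times the worst neighbourhood ratio; on the
            # phantom's smooth dose this stays very close to the scaling bound
            assert rel.min() >= a * 0.9

    def test_coverage_drops_and_monotone_in_a(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        target = structures.targets["ptv_4500"]
        v99_orig = df.coverage(dose, target, 4500.0, 0.99)
        v99s, v95s = [], []
        for a in (0.99, 0.98, 0.97, 0.96, 0.95):
            degraded = df.degrade_conformality(dose, structures, group, a)
            v99s.append(df.coverage(degraded, target, 4500.0, 0.99))
            v95s.append(df.coverage(degraded, target, 4500.0, 0.95))
        assert all(v < v99_orig for v in v99s)
        assert np.all(np.diff(v99s) <= 1e-9)  # lower a -> lower coverage
        assert v95s[-1] < df.coverage(dose, target, 4500.0, 0.95)

    def test_continuity_as_a_approaches_one(self, gyn_case):
        """As a → 1⁻ the output converges to the a = 1 limit of the operator
        (the residual kernel smoothing remains; only the scaling vanishes)."""
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        from doseforge.gac import T2_3X3, apply_gac, clamp_direction

        lam = df.build_t2_feature(structures, group, dose.spacing, dose.prescriptions)
        limit = clamp_direction(apply_gac(dose.values, lam, 1.0, T2_3X3), dose.values, "decrease")
        degraded = df.degrade_conformality(dose, structures, group, 0.9999)
        assert np.max(np.abs(degraded.values - limit)) < 1e-3 * dose.values.max()

    def test_rejects_a_out_of_range(self, gyn_case):
        dose, structures = gyn_case
        group = df.OAR_GROUPS["gyn"]["bladder"]
        for bad in (1.0, 1.1, 0.0):
            with pytest.raises(ValueError):
                df.degrade_conformality(dose, structures, group, bad)


class TestHotspots:
    def test_walk_contained_and_budget(self, gyn_case):
        _, structures = gyn_case
        mask = structures.targets["ptv_4500"]
        rng = np.random.default_rng(0)
        visited = df.random_walk(mask, 75, 0.9, rng)
        assert 1 <= len(visited) <= 76
        assert all(mask[v] for v in visited)

    def test_inplane_bias_monte_carlo(self):
        """Over ~1e5 steps of an actual walk in a large mask, the in-plane
        step fraction converges to the 0.9 bias (binomial 4σ band)."""
        mask = np.ones((201, 501, 501), dtype=bool)
        rng = np.random.default_rng(5)
        path = np.array(
            df.random_walk(mask, 100_000, 0.9, rng, return_path=True, start=(100, 250, 250))
        )
        steps = np.diff(path, axis=0)
        moved = np.abs(steps).sum(axis=1) > 0
        inplane = np.abs(steps[moved, 1:]).sum(axis=1) > 0
        assert abs(inplane.mean() - 0.9) < 0.01

    def test_walk_single_voxel_mask(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        visited = df.random_walk(mask, 10, 0.9, np.random.default_rng(0))
        assert visited == {(1, 1, 1)}

    def test_multiplier_bounds(self, gyn_case):
        dose, structures = gyn_case
        mask = structures.targets["ptv_4500"]
        cfg = df.HotspotConfig(n_hotspots=2, seed=9)
        mult = df.build_multiplier(mask, cfg, np.random.default_rng(9))
        assert mult.min() >= 1.0            # box-mean of values >= 1 cannot undershoot
        assert mult.max() <= 1.13 + 1e-12   # never above the drawn scale
        assert mult.max() > 1.0
        far = df.outside_distance(mask, dose.spacing) > 20.0
        np.testing.assert_array_equal(mult[far], 1.0)  # untouched away from walks

    def test_walk_budget_splits_by_hotspot_count(self):
        assert df.HotspotConfig(n_hotspots=1).walk_budget // 1 == 75
        assert df.HotspotConfig(n_hotspots=4).walk_budget // 4 == 18

    def test_config_validation(self):
        with pytest.raises(ValueError):
            df.HotspotConfig(n_hotspots=0)
        with pytest.raises(ValueError):
            df.HotspotConfig(scale_range=(0.9, 1.1))
        with pytest.raises(ValueError):
            df.HotspotConfig(xy_bias=1.5)

    def test_injection_creates_high_dose_tail(self, gyn_case):
        """The degraded DVH develops a tail above 107% of prescription that
        the original did not have; deterministic per seed."""
        dose, structures = gyn_case
        cfg = df.HotspotConfig(seed=21)
        degraded = df.inject_hotspots(dose, structures, cfg)
        target = structures.targets["ptv_4500"]
        v107_before = df.volume_above(dose, target, 1.07 * 4500.0)
        v107_after = df.volume_above(degraded, target, 1.07 * 4500.0)
        assert v107_before == 0.0
        assert v107_after > 0.0
        again = df.inject_hotspots(dose, structures, cfg)
        np.testing.assert_array_equal(degraded.values, again.values)
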