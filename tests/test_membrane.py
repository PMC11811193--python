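"""Thinning maps, radial minima, water defects, occupancy, depth traces."""

import numpy as np
import pytest

import memtraj as mt
from conftest import membrane_refs


def _flat_leaflet_frames(n=50, z=6.95, box=5.0, frames=40, zc=5.0):
    """One-leaflet toy system: phosphates on a plane, glycerols mirrored so
    the global centre sits at zc."""
    rng = np.random.default_rng(1)
    coords = np.zeros((frames, 2 * n, 3))
    coords[:, :, :2] = rng.uniform(0, box, size=(frames, 2 * n, 2))
    coords[:, :n, 2] = z
    coords[:, n:, 2] = 2 * zc - z  # mirror leaflet
    fs = mt.FrameSeries(coords, np.full((frames, 3), [box, box, 2 * zc]), dt=0.5)
    labels = [(i + 1, "POPC", "PO4") for i in range(2 * n)]
    phos = mt.BeadSelection(np.arange(2 * n), labels, "phosphate")
    refs = mt.MembraneFrameRefs(
        leaflet_of_lipid={i + 1: (mt.LEAFLET_TOP if i < n else mt.LEAFLET_BOTTOM)
                          for i in range(2 * n)},
        center_z_glycerol=np.full(frames, zc),
        center_z_global=np.full(frames, zc),
    )
    return fs, phos, refs


class TestThinningMap:
    def test_constant_field(self):
        fs, phos, refs = _flat_leaflet_frames(z=6.95, zc=5.0)
        cfg = mt.AnalysisConfig(min_bin_count=0, bin_xy=1.0)
        lmap = mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs, cfg)
        assert np.allclose(lmap.thickness[lmap.valid], 1.95)

    def test_funnel_minimum_matches_generator_truth(self):
        spec = mt.SyntheticSpec(seed=21, n_frames=3000)
        spec.funnels = [mt.FunnelSpec(x=4.0, y=7.0, depth=1.20, width=0.8)]
        frames, roles, truth = mt.make_bilayer(spec)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        lmap = mt.leaflet_thinning_map(frames, phos, mt.LEAFLET_TOP, refs)
        mn, _ = mt.map_summary(lmap)
        assert mn == pytest.approx(truth["funnels"][0]["analytic_min"], abs=0.05)
        # the minimum sits at the funnel centre
        xc, yc = lmap.bin_centers()
        i, j = np.unravel_index(
            np.nanargmin(np.where(lmap.valid, lmap.thickness, np.nan)), lmap.thickness.shape
        )
        assert np.hypot(xc[i] - 4.0, yc[j] - 7.0) < 0.5

    def test_count_mask_threshold_edge(self):
        # a bin with exactly 30 observations is masked; 31 makes it valid
        for count, expect_valid in [(30, False), (31, True)]:
            coords = np.zeros((count, 1, 3))
            coords[:, 0, :2] = 0.05  # always the same 0.1 nm bin
            coords[:, 0, 2] = 6.95
            fs = mt.FrameSeries(coords, np.full((count, 3), [5.0, 5.0, 10.0]), dt=0.5)
            phos = mt.BeadSelection([0], [(1, "POPC", "PO4")], "phosphate")
            refs = mt.MembraneFrameRefs(
                leaflet_of_lipid={1: mt.LEAFLET_TOP},
                center_z_global=np.full(count, 5.0),
            )
            lmap = mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs)
            assert bool(lmap.valid[0, 0]) is expect_valid

    def test_invariant_under_z_translation(self):
        spec = mt.SyntheticSpec(seed=22, n_frames=100)
        spec.bilayer.lipids_per_leaflet = 80
        frames, roles, _ = mt.make_bilayer(spec)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        m1 = mt.leaflet_thinning_map(frames, phos, mt.LEAFLET_TOP, refs)
        shifted = frames.copy()
        shifted.coords[:, :, 2] += 0.7
        _, _, _, refs2 = membrane_refs(shifted, roles)
        m2 = mt.leaflet_thinning_map(shifted, phos, mt.LEAFLET_TOP, refs2)
        assert np.allclose(
            m1.thickness[m1.valid], m2.thickness[m2.valid], atol=1e-9
        )

    def test_empty_leaflet_selection_rejected(self):
        fs, phos, refs = _flat_leaflet_frames()
        refs.leaflet_of_lipid = {k: mt.LEAFLET_BOTTOM for k in refs.leaflet_of_lipid}
        with pytest.raises(mt.SelectionError):
            mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs)


class TestMapSummary:
    def test_uniform_map(self):
        fs, phos, refs = _flat_leaflet_frames()
        cfg = mt.AnalysisConfig(min_bin_count=0, bin_xy=1.0)
        lmap = mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs, cfg)
        mn, avg = mt.map_summary(lmap)
        assert mn == pytest.approx(1.95) and avg == pytest.approx(1.95)

    def test_region_excluding_funnel_recovers_plane(self):
        spec = mt.SyntheticSpec(seed=23, n_frames=2000)
        spec.funnels = [mt.FunnelSpec(x=3.0, y=3.0, depth=1.0, width=0.6)]
        frames, roles, truth = mt.make_bilayer(spec)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        lmap = mt.leaflet_thinning_map(frames, phos, mt.LEAFLET_TOP, refs)
        xc, yc = lmap.bin_centers()
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        far = np.hypot(gx - 3.0, gy - 3.0) > 3.0
        _, avg = mt.map_summary(lmap, region=far)
        assert avg == pytest.approx(truth["plane"], abs=0.02)

    def test_all_masked_region_is_an_error(self):
        fs, phos, refs = _flat_leaflet_frames()
        cfg = mt.AnalysisConfig(min_bin_count=0, bin_xy=1.0)
        lmap = mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs, cfg)
        with pytest.raises(mt.EmptyRegionError):
            mt.map_summary(lmap, region=np.zeros_like(lmap.valid))


class TestRadialProfile:
    def test_uniform_map_flat_profile(self):
        fs, phos, refs = _flat_leaflet_frames(n=400, box=10.0, frames=60)
        cfg = mt.AnalysisConfig(min_bin_count=0, bin_xy=0.5)
        lmap = mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs, cfg)
        prof = mt.radial_minimum_profile(lmap, (5.0, 5.0), 2.0, 4.0, n_sectors=8)
        assert prof.ring_min == pytest.approx(1.95)
        assert np.allclose(prof.sector_min, 1.95)

    def test_two_funnels_local_minima_and_promotion(self):
        # two funnels at distinct azimuths: deeper wins the ring minimum;
        # regenerating without it promotes the shallower one
        def build(funnels):
            spec = mt.SyntheticSpec(seed=24, n_frames=2500)
            spec.funnels = funnels
            frames, roles, _ = mt.make_bilayer(spec)
            phos, gly, lipid, refs = membrane_refs(frames, roles)
            lmap = mt.leaflet_thinning_map(frames, phos, mt.LEAFLET_TOP, refs)
            return mt.radial_minimum_profile(lmap, (5.5, 5.5), 1.5, 2.6, n_sectors=12)

        deep = mt.FunnelSpec(x=5.5 + 2.0, y=5.5, depth=1.2, width=0.7)      # east
        shallow = mt.FunnelSpec(x=5.5, y=5.5 + 2.0, depth=0.7, width=0.7)   # north
        both = build([deep, shallow])
        east = np.argmin(np.abs(both.sector_deg - 0)) if both.sector_deg[0] < 30 else 0
        north = np.argmin(np.abs(both.sector_deg - 90))
        assert both.sector_min[east] < 1.1 and both.sector_min[north] < 1.5
        assert abs(both.ring_min_azimuth_deg - 0) < 45 or both.ring_min_azimuth_deg > 315
        only_shallow = build([shallow])
        assert abs(only_shallow.ring_min_azimuth_deg - 90) < 45
        assert only_shallow.ring_min > both.ring_min

    def test_empty_ring_is_an_error(self):
        fs, phos, refs = _flat_leaflet_frames()
        cfg = mt.AnalysisConfig(min_bin_count=0, bin_xy=1.0)
        lmap = mt.leaflet_thinning_map(fs, phos, mt.LEAFLET_TOP, refs, cfg)
        with pytest.raises(mt.EmptyRegionError):
            mt.radial_minimum_profile(lmap, (2.5, 2.5), 40.0, 50.0)


class TestWaterDefects:
    def _system(self, waters_xyz, box=10.0, anchor=(5.0, 5.0)):
        n = len(waters_xyz)
        coords = np.asarray(waters_xyz, float)[None]
        fs = mt.FrameSeries(coords, np.full((1, 3), box), dt=0.5)
        sel = mt.BeadSelection(
            np.arange(n), [(i + 1, "W", "W") for i in range(n)], "water"
        )
        refs = mt.MembraneFrameRefs(center_z_global=np.array([5.0]))
        return fs, sel, refs, np.array(anchor)

    def test_membership_by_construction(self):
        inside = [[5 + dx, 5, 5 + dz] for dx, dz in
                  [(0, 0), (1, 0.5), (-2, -1), (2.4, 1.4), (0, 1.49), (1, -1.2), (-1, 0)]]
        outside = [[5, 5, 7.0], [5, 5, 3.4], [8.0, 5, 5], [5, 9.0, 5], [9, 9, 9]]
        fs, sel, refs, anchor = self._system(inside + outside)
        trace = mt.water_defect_count(fs, sel, refs, anchor_xy=anchor)
        assert trace.counts[0] == 7

    def test_empty_cylinder(self):
        fs, sel, refs, anchor = self._system([[1.0, 1.0, 9.0], [9.0, 9.0, 1.0]])
        trace = mt.water_defect_count(fs, sel, refs, anchor_xy=anchor)
        assert trace.counts[0] == 0

    def test_matches_point_in_cylinder_brute_force(self, rng):
        box = 12.0
        pts = rng.uniform(0, box, size=(10_000, 3))
        fs, sel, refs, anchor = self._system(pts, box=box, anchor=(6.0, 6.0))
        refs.center_z_global = np.array([6.0])
        trace = mt.water_defect_count(fs, sel, refs, anchor_xy=anchor)
        brute = 0
        for p in pts:
            dx = p[0] - 6.0 - box * round((p[0] - 6.0) / box)
            dy = p[1] - 6.0 - box * round((p[1] - 6.0) / box)
            if dx * dx + dy * dy <= 2.5**2 and abs(p[2] - 6.0) <= 1.5:
                brute += 1
        assert trace.counts[0] == brute

    def test_invariant_under_xy_translation(self):
        spec = mt.SyntheticSpec(seed=25, n_frames=30)
        spec.bilayer.lipids_per_leaflet = 40
        frames, roles, _ = mt.make_membrane_system(spec)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        waters = mt.selection_from_roles(roles, "water")
        protein = mt.selection_from_roles(roles, "protein")
        t1 = mt.water_defect_count(frames, waters, refs, protein=protein)
        moved = frames.copy()
        moved.coords[:, :, 0] += 3.3
        moved.coords[:, :, 1] -= 1.7
        t2 = mt.water_defect_count(moved, waters, refs, protein=protein)
        assert np.array_equal(t1.counts, t2.counts)

    def test_mean_matches_generator_expectation(self):
        spec = mt.SyntheticSpec(seed=26, n_frames=600)
        spec.bilayer.lipids_per_leaflet = 40
        spec.waters = mt.WaterSpec(bulk_density=0.5, enrichment=4.0)
        frames, roles, truth = mt.make_membrane_system(spec)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        waters = mt.selection_from_roles(roles, "water")
        protein = mt.selection_from_roles(roles, "protein")
        trace = mt.water_defect_count(frames, waters, refs, protein=protein)
        lam = truth["waters"]["expected_in_column"]
        se = np.sqrt(lam / frames.n_frames)  # binomial-count MC error scale
        assert abs(trace.mean - lam) < 3 * max(se, 0.05)

    def test_zero_enrichment_means_dry_core(self):
        spec = mt.SyntheticSpec(seed=27, n_frames=50)
        spec.bilayer.lipids_per_leaflet = 40
        spec.waters = mt.WaterSpec(bulk_density=0.5, enrichment=0.0)
        frames, roles, _ = mt.make_membrane_system(spec)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        waters = mt.selection_from_roles(roles, "water")
        protein = mt.selection_from_roles(roles, "protein")
        trace = mt.water_defect_count(frames, waters, refs, protein=protein)
        assert trace.mean == 0.0

    def test_missing_anchor_is_a_config_error(self):
        fs, sel, refs, _ = self._system([[5.0, 5.0, 5.0]])
        with pytest.raises(mt.ConfigError):
            mt.water_defect_count(fs, sel, refs)


class TestOccupancy:
    def _bead_frames(self, positions, box=2.0):
        coords = np.asarray(positions, float)[:, None, :]
        fs = mt.FrameSeries(coords, np.full((len(positions), 3), box), dt=0.5)
        sel = mt.BeadSelection([0], [(1, "POPC", "PO4")], "phosphate")
        return fs, sel

    def test_static_bead_single_cell(self):
        fs, sel = self._bead_frames([[0.5, 0.5, 0.5]] * 10)
        grid = mt.occupancy_grid(fs, sel)
        assert grid.occupancy.max() == 100.0
        assert (grid.occupancy > 0).sum() == 1

    def test_alternating_bead_splits_50_50(self):
        pos = [[0.1, 0.1, 0.1] if f % 2 == 0 else [1.5, 1.5, 1.5] for f in range(20)]
        fs, sel = self._bead_frames(pos)
        grid = mt.occupancy_grid(fs, sel)
        nz = np.sort(grid.occupancy[grid.occupancy > 0])
        assert nz.tolist() == [50.0, 50.0]

    def test_single_bead_conservation(self, rng):
        pos = rng.uniform(-3, 5, size=(40, 3))  # includes out-of-box, wraps
        fs, sel = self._bead_frames(pos)
        grid = mt.occupancy_grid(fs, sel)
        assert grid.occupancy.sum() / 100.0 == pytest.approx(1.0)

    def test_isosurface_threshold_edges(self):
        fs, sel = self._bead_frames([[0.5, 0.5, 0.5]] * 4)
        grid = mt.occupancy_grid(fs, sel)
        surf = mt.export_isosurface(grid, threshold=0.5)
        assert surf.mask.sum() == 1
        empty = mt.export_isosurface(grid, threshold=99.9999)
        assert empty.mask.sum() == 1  # the 100% cell still clears 99.9999
        with pytest.raises(mt.ConfigError):
            mt.export_isosurface(grid, threshold=0.0)

    def test_mask_monotone_in_threshold(self, rng):
        pos = rng.uniform(0, 2, size=(60, 3))
        fs, sel = self._bead_frames(pos)
        grid = mt.occupancy_grid(fs, sel)
        prev = None
        for thr in [0.1, 0.5, 2.0, 10.0, 50.0, 99.0]:
            mask = mt.export_isosurface(grid, thr).mask
            if prev is not None:
                assert np.all(mask <= prev)  # mask(theta2) subset of mask(theta1)
            prev = mask

    def test_opendx_roundtrip(self, tmp_path, rng):
        pos = rng.uniform(0, 2, size=(10, 3))
        fs, sel = self._bead_frames(pos)
        grid = mt.occupancy_grid(fs, sel)
        from memtraj.membrane import write_opendx

        write_opendx(grid, tmp_path / "g.dx")
        from gridData import Grid

        back = Grid(str(tmp_path / "g.dx"))
        assert np.allclose(back.grid, grid.occupancy)

    def test_marching_cubes_surface_encloses_hot_cell(self):
        rngl = np.random.default_rng(3)
        pos = np.concatenate(
            [np.tile([[1.0, 1.0, 1.0]], (50, 1)), rngl.uniform(0, 2, (50, 3))]
        )
        fs, sel = self._bead_frames(pos)
        grid = mt.occupancy_grid(fs, sel)
        surf = mt.export_isosurface(grid, threshold=30.0)
        assert len(surf.vertices) > 0 and len(surf.faces) > 0


class TestDepthTrace:
    def test_simple_offset(self):
        coords = np.zeros((1, 1, 3))
        coords[0, 0, 2] = 1.2
        fs = mt.FrameSeries(coords, np.full((1, 3), 10.0), dt=0.5)
        sel = mt.BeadSelection([0], [(73, "GLU", "SC1")], "titratable_site")
        refs = mt.MembraneFrameRefs(center_z_glycerol=np.array([0.9]))
        dep = mt.residue_depth_trace(fs, sel, refs)
        assert dep.values[0] == pytest.approx(0.3)

    def test_constant_under_membrane_translation(self, rng):
        drift = rng.normal(0, 0.4, size=30)
        coords = np.zeros((30, 1, 3))
        coords[:, 0, 2] = 1.0 + drift
        fs = mt.FrameSeries(coords, np.full((30, 3), 10.0), dt=0.5)
        sel = mt.BeadSelection([0], [(73, "GLU", "SC1")], "titratable_site")
        refs = mt.MembraneFrameRefs(center_z_glycerol=0.6 + drift)
        dep = mt.residue_depth_trace(fs, sel, refs)
        assert np.allclose(dep.values, 0.4)
        assert dep.sd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("depth", [0.4, -0.4])
    def test_generator_glu_depth_recovered(self, depth):
        # flipped topology mirrors a channel inserted the other way up
        spec = mt.SyntheticSpec(seed=28, n_frames=300)
        spec.bilayer.lipids_per_leaflet = 80
        spec.protein.glu_depth = depth
        frames, roles, truth = mt.make_membrane_system(spec, with_waters=False)
        phos, gly, lipid, refs = membrane_refs(frames, roles)
        sel = mt.selection_from_roles(roles, "titratable_site")
        dep = mt.residue_depth_trace(frames, sel, refs)
        assert dep.mean == pytest.approx(depth, abs=0.02)
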