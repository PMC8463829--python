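"""Uniform and beam-specific optimization target volume construction."""

import numpy as np
import pytest

from pbsplan import Beam, OTVSpec, StructureSet, VoxelGrid, exclude_overlap, expand_beam_specific, expand_uniform
from pbsplan.phantom import _ellipsoid_mask


@pytest.fixture(scope="module")
def sphere_1mm():
    """Radius-10 mm sphere on a 1 mm grid."""
    shape = (40, 40, 40)
    spacing = np.array([1.0, 1.0, 1.0])
    origin = -(np.array(shape) - 1) / 2.0 * spacing
    grid = VoxelGrid(np.ones(shape, np.float32), spacing, origin, "RSP")
    return grid, _ellipsoid_mask(grid, (0, 0, 0), (10, 10, 10))


class TestExpandUniform:
    def test_zero_margin_is_identity(self, sphere_1mm):
        grid, m = sphere_1mm
        assert np.array_equal(expand_uniform(m, 0.0, grid.spacing), m)

    def test_concentric_sphere_volume_ratio(self, sphere_1mm):
        grid, m = sphere_1mm
        out = expand_uniform(m, 2.0, grid.spacing)
        assert out.sum() / m.sum() == pytest.approx((12.0 / 10.0) ** 3, rel=0.05)

    def test_superset_of_input(self, sphere_1mm):
        grid, m = sphere_1mm
        assert np.all(expand_uniform(m, 3.0, grid.spacing) >= m)

    def test_composition_vs_single_expansion(self, sphere_1mm):
        grid, m = sphere_1mm
        two_step = expand_uniform(expand_uniform(m, 2.0, grid.spacing), 3.0, grid.spacing)
        one_step = expand_uniform(m, 5.0, grid.spacing)
        # composition agrees with the single expansion up to re-voxelization
        # of the intermediate mask: symmetric difference within one shell
        shell = expand_uniform(m, 6.0, grid.spacing).sum() - one_step.sum()
        assert np.sum(two_step ^ one_step) <= shell
        assert two_step.sum() >= 0.99 * one_step.sum()

    def test_margin_monotonicity(self, sphere_1mm):
        grid, m = sphere_1mm
        a = expand_uniform(m, 2.0, grid.spacing)
        b = expand_uniform(m, 5.0, grid.spacing)
        assert np.all(b >= a)

    def test_negative_margin_rejected(self, sphere_1mm):
        grid, m = sphere_1mm
        with pytest.raises(ValueError):
            expand_uniform(m, -1.0, grid.spacing)


@pytest.fixture(scope="module")
def deep_sphere(water_rsp):
    """Radius-10 mm sphere with its distal surface 160 mm deep in water."""
    gtv = _ellipsoid_mask(water_rsp, (0.0, -40.0, 0.0), (10.0, 10.0, 10.0))
    beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
    return water_rsp, gtv, beam


def _axial_extent(grid, mask, beam):
    pos = grid.index_to_position(np.argwhere(mask))
    w = beam.to_beam_coords(pos)[:, 2]
    return w.min(), w.max()


class TestExpandBeamSpecific:
    def test_distal_extension_in_water(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        spec = OTVSpec(scheme="beam_specific", lateral_margin_mm=0.0, range_fraction=0.035)
        otv = expand_beam_specific(gtv, beam, grid, spec)
        _, w_gtv = _axial_extent(grid, gtv, beam)
        _, w_otv = _axial_extent(grid, otv, beam)
        # distal depth 160 mm, RSP=1: geometric extension = 0.035 x 160 = 5.6 mm
        assert w_otv - w_gtv == pytest.approx(5.6, abs=2.0)

    def test_zero_fraction_gives_lateral_only_growth(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        spec = OTVSpec(scheme="beam_specific", lateral_margin_mm=2.0, range_fraction=0.0)
        otv = expand_beam_specific(gtv, beam, grid, spec)
        lo_g, hi_g = _axial_extent(grid, gtv, beam)
        lo_o, hi_o = _axial_extent(grid, otv, beam)
        assert hi_o - hi_g <= 2.0 + 1e-6  # no axial growth beyond voxelization
        assert lo_g - lo_o <= 2.0 + 1e-6
        assert otv.sum() > gtv.sum()  # but lateral growth happened

    def test_superset_of_gtv(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        spec = OTVSpec(scheme="beam_specific")
        assert np.all(expand_beam_specific(gtv, beam, grid, spec) >= gtv)

    def test_monotone_in_range_fraction(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        masks = [
            expand_beam_specific(
                gtv, beam, grid, OTVSpec(scheme="beam_specific", range_fraction=f)
            )
            for f in (0.01, 0.035, 0.07)
        ]
        assert np.all(masks[1] >= masks[0])
        assert np.all(masks[2] >= masks[1])

    def test_axial_setup_margin_extends_further(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        base = expand_beam_specific(
            gtv, beam, grid, OTVSpec(scheme="beam_specific", axial_setup_margin_mm=0.0)
        )
        wider = expand_beam_specific(
            gtv, beam, grid, OTVSpec(scheme="beam_specific", axial_setup_margin_mm=2.0)
        )
        assert np.all(wider >= base)
        assert wider.sum() > base.sum()

    def test_beam_missing_gtv_rejected(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        with pytest.raises(ValueError):
            expand_beam_specific(
                np.zeros(grid.shape, bool), beam, grid, OTVSpec(scheme="beam_specific")
            )

    def test_wrong_scheme_rejected(self, deep_sphere):
        grid, gtv, beam = deep_sphere
        with pytest.raises(ValueError):
            expand_beam_specific(gtv, beam, grid, OTVSpec(scheme="uniform"))


class TestExcludeOverlap:
    @pytest.fixture()
    def fixture_set(self, sphere_1mm):
        grid, gtv = sphere_1mm
        otv = expand_uniform(gtv, 3.0, grid.spacing)
        oar = np.zeros(grid.shape, bool)
        oar[:, :5, :] = True  # disjoint slab
        abutting = np.zeros(grid.shape, bool)
        abutting[:, 5:12, :] = True  # overlaps the OTV shell
        ss = StructureSet(grid.like(np.zeros(grid.shape)), {})
        ss.masks = {"far": oar, "near": abutting}
        return grid, gtv, otv, ss

    def test_empty_list_is_identity(self, fixture_set):
        _, gtv, otv, ss = fixture_set
        assert np.array_equal(exclude_overlap(otv, ss, []), otv)

    def test_disjoint_oar_is_identity(self, fixture_set):
        _, gtv, otv, ss = fixture_set
        assert np.array_equal(exclude_overlap(otv, ss, ["far"]), otv)

    def test_removes_exactly_overlap_outside_gtv(self, fixture_set):
        _, gtv, otv, ss = fixture_set
        out = exclude_overlap(otv, ss, ["near"], gtv=gtv)
        overlap_outside_gtv = (otv & ss["near"] & ~gtv).sum()
        assert otv.sum() - out.sum() == overlap_outside_gtv

    def test_gtv_voxels_never_removed(self, fixture_set):
        _, gtv, otv, ss = fixture_set
        big = np.ones_like(gtv)
        ss.masks["everything"] = big
        out = exclude_overlap(otv, ss, ["everything"], gtv=gtv)
        assert np.array_equal(out, otv & gtv)

    def test_unknown_name_lists_available(self, fixture_set):
        _, gtv, otv, ss = fixture_set
        with pytest.raises(KeyError, match="far"):
            exclude_overlap(otv, ss, ["bogus"])


def test_otv2mm_subset_of_otv5mm(sphere_1mm):
    grid, m = sphere_1mm
    assert np.all(expand_uniform(m, 5.0, grid.spacing) >= expand_uniform(m, 2.0, grid.spacing))
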