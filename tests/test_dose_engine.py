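"""Analytic Bragg model, spot placement and influence computation."""

import numpy as np
import pytest

from pbsplan import (
    Beam,
    BeamDoseOperator,
    BeamWETMap,
    Scenario,
    Spot,
    VoxelGrid,
    bragg_depth_dose,
    compute_dose,
    compute_influence,
    place_spots,
)


class TestBraggCurve:
    def test_peak_at_range_and_normalized(self):
        d = np.linspace(0.0, 200.0, 20001)
        curve = bragg_depth_dose(160.0, d)
        assert d[np.argmax(curve)] == pytest.approx(160.0, abs=0.1)
        assert curve.max() == pytest.approx(1.0)

    def test_distal_falloff_below_1pct_within_5pct_of_range(self):
        for r in (80.0, 160.0, 250.0):
            assert bragg_depth_dose(r, 1.05 * r) < 0.01

    def test_entrance_plateau_low(self):
        assert 0.2 < bragg_depth_dose(160.0, 1.0) < 0.45

    def test_single_peaked(self):
        d = np.linspace(0.0, 200.0, 4000)
        curve = bragg_depth_dose(160.0, d)
        k = np.argmax(curve)
        assert np.all(np.diff(curve[:k]) >= -1e-12)
        assert np.all(np.diff(curve[k:]) <= 1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            bragg_depth_dose(0.0, 10.0)


@pytest.fixture(scope="module")
def water_box_target(water_rsp):
    """A 30x30x30 mm cubic target centered 150 mm deep (y = -40)."""
    mask = np.zeros(water_rsp.shape, bool)
    idx = water_rsp.position_to_index(np.array([-15.0, -55.0, -15.0]))
    lo = np.ceil(idx).astype(int)
    hi = lo + 15  # 30 mm at 2 mm spacing
    mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
    beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
    return water_rsp, mask, beam


class TestPlaceSpots:
    def test_hexagonal_neighbors(self, water_box_target):
        rsp, mask, beam = water_box_target
        spots = place_spots(mask, beam, rsp, lateral_spacing_mm=5.0)
        lat = np.unique(np.round([[s.u, s.v] for s in spots], 6), axis=0)
        # an interior lattice point has exactly 6 neighbors at the spacing
        center = lat[np.argmin(np.linalg.norm(lat - lat.mean(axis=0), axis=1))]
        d = np.linalg.norm(lat - center, axis=1)
        assert np.sum(np.abs(d - 5.0) < 1e-6) == 6

    def test_layer_count_for_30mm_span(self, water_box_target):
        rsp, mask, beam = water_box_target
        spots = place_spots(mask, beam, rsp, layer_spacing_wet_mm=5.0)
        layers = {s.range_wet for s in spots}
        assert len(layers) == 7  # ceil(30/5) + 1

    def test_halving_spacing_at_least_triples_count(self, water_box_target):
        rsp, mask, beam = water_box_target
        n5 = len(place_spots(mask, beam, rsp, lateral_spacing_mm=5.0))
        n25 = len(place_spots(mask, beam, rsp, lateral_spacing_mm=2.5))
        assert n25 >= 3 * n5

    def test_bad_spacing_rejected(self, water_box_target):
        rsp, mask, beam = water_box_target
        with pytest.raises(ValueError):
            place_spots(mask, beam, rsp, lateral_spacing_mm=0.0)


@pytest.fixture(scope="module")
def column_roi(water_rsp):
    """A thin column along the gantry-180 central axis, for depth profiles."""
    mask = np.zeros(water_rsp.shape, bool)
    i0 = int(round(water_rsp.position_to_index(np.zeros(3))[0]))
    k0 = int(round(water_rsp.position_to_index(np.zeros(3))[2]))
    mask[i0, :, k0] = True
    return mask


def _single_spot(range_wet):
    return [Spot(0, 0.0, 0.0, range_wet)]


class TestInfluence:
    def test_water_peak_at_geometric_depth(self, water_rsp, column_roi):
        beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
        infl = compute_influence(_single_spot(150.0), water_rsp, column_roi, beam=beam)
        dose = compute_dose(infl, np.array([1.0]))
        pos = water_rsp.index_to_position(infl.roi_indices)
        depth = 110.0 - pos[:, 1]  # entrance plane at y = +110
        assert depth[np.argmax(dose)] == pytest.approx(150.0, abs=2.0)

    def test_range_scaling_shifts_peak_proximally(self, water_rsp, column_roi):
        beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
        spots = _single_spot(160.0)
        peak = {}
        for scale in (1.0, 1.035):
            infl = compute_influence(
                spots, water_rsp, column_roi, scenario=Scenario(np.zeros(3), scale),
                beam=beam,
            )
            dose = compute_dose(infl, np.array([1.0]))
            pos = water_rsp.index_to_position(infl.roi_indices)
            peak[scale] = 110.0 - pos[np.argmax(dose), 1]
        # solve scale x depth = range: shift = 160 x 0.035/1.035 = 5.4 mm
        assert peak[1.0] - peak[1.035] == pytest.approx(5.4, abs=2.5)

    def test_distal_falloff_depth_scales_inversely(self, water_rsp, column_roi):
        beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
        d80 = {}
        for scale in (0.965, 1.035):
            infl = compute_influence(
                _single_spot(150.0), water_rsp, column_roi,
                scenario=Scenario(np.zeros(3), scale), beam=beam, threshold=0.0,
            )
            dose = compute_dose(infl, np.array([1.0]))
            pos = water_rsp.index_to_position(infl.roi_indices)
            depth = 110.0 - pos[:, 1]
            order = np.argsort(depth)
            depth, dose = depth[order], dose[order]
            k = np.argmax(dose)
            distal = dose[k:] / dose.max()
            d80[scale] = depth[k:][np.argmax(distal < 0.8)]
        ratio = d80[0.965] / d80[1.035]
        assert ratio == pytest.approx(1.035 / 0.965, rel=0.02)

    def test_column_concatenation_linearity(self, water_rsp, column_roi):
        beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
        s1, s2 = _single_spot(140.0), _single_spot(155.0)
        m1 = compute_influence(s1, water_rsp, column_roi, beam=beam).matrix
        m2 = compute_influence(s2, water_rsp, column_roi, beam=beam).matrix
        m12 = compute_influence(s1 + s2, water_rsp, column_roi, beam=beam).matrix
        assert np.allclose(m12, np.hstack([m1, m2]))

    def test_compute_dose_contracts(self, water_rsp, column_roi):
        beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
        infl = compute_influence(
            _single_spot(150.0) + _single_spot(140.0), water_rsp, column_roi, beam=beam
        )
        assert np.all(compute_dose(infl, np.zeros(2)) == 0.0)
        d1 = compute_dose(infl, np.array([1.0, 0.5]))
        assert np.allclose(compute_dose(infl, np.array([2.0, 1.0])), 2.0 * d1)
        assert np.allclose(compute_dose(infl, np.array([1.0, 0.0])), infl.matrix[:, 0])
        with pytest.raises(ValueError):
            compute_dose(infl, np.array([1.0, -0.1]))

    def test_superposition(self, water_rsp, column_roi):
        beam = Beam(180.0, np.array([0.0, -40.0, 0.0]))
        infl = compute_influence(
            _single_spot(150.0) + _single_spot(140.0), water_rsp, column_roi, beam=beam
        )
        w1, w2 = np.array([1.0, 0.2]), np.array([0.3, 2.0])
        assert np.allclose(
            compute_dose(infl, w1 + w2),
            compute_dose(infl, w1) + compute_dose(infl, w2),
            rtol=1e-6,
        )

    def test_operator_matches_dense_matrix(self, water_box_target):
        rsp, mask, beam = water_box_target
        spots = place_spots(mask, beam, rsp)
        wm = BeamWETMap.for_mask(rsp, beam, mask)
        pos = rsp.index_to_position(np.argwhere(mask))
        sc = Scenario([1.0, -1.0, 0.5], 1.035)
        op = BeamDoseOperator(spots, wm, pos, sc, lateral_sigma_mm=5.0)
        dense = compute_influence(
            spots, rsp, mask, scenario=sc, wetmap=wm, threshold=0.0
        ).matrix
        rng = np.random.default_rng(3)
        w = rng.uniform(0.0, 2.0, len(spots))
        assert np.allclose(op.dose(w), dense @ w, rtol=1e-4, atol=1e-5)
        r = rng.normal(size=dense.shape[0])
        assert np.allclose(op.adjoint(r), dense.T @ r, rtol=1e-4, atol=1e-4)

    def test_threshold_zeroes_small_entries(self, water_box_target):
        rsp, mask, beam = water_box_target
        spots = place_spots(mask, beam, rsp)[:10]
        wm = BeamWETMap.for_mask(rsp, beam, mask)
        m = compute_influence(spots, rsp, mask, wetmap=wm, threshold=1e-4).matrix
        for j in range(m.shape[1]):
            col = m[:, j]
            nz = col[col > 0]
            assert nz.size == 0 or nz.min() >= 1e-4 * col.max()


class TestScenario:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Scenario([11.0, 0.0, 0.0], 1.0)
        with pytest.raises(ValueError):
            Scenario([0.0, 0.0, 0.0], 1.2)
        assert Scenario().is_nominal

    def test_spot_invariants(self):
        with pytest.raises(ValueError):
            Spot(0, 0.0, 0.0, -5.0)
        with pytest.raises(ValueError):
            Spot(0, 0.0, 0.0, 100.0, weight=-1.0)
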