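"""DVH computation, bandwidth statistic and dose spread function."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import erfc

from pbsplan import (
    VoxelGrid,
    bandwidth,
    compute_dvh,
    dose_at_volume,
    dose_spread_function,
    locate_abutment_line,
    sample_line_dose,
    volume_at_dose,
)


class TestDVH:
    def test_uniform_dose(self):
        dvh = compute_dvh(np.full(100, 33.0), bin_width_gy=0.05, voxel_volume_ml=0.01)
        assert volume_at_dose(dvh, 33.0)[0] == pytest.approx(100.0)
        assert volume_at_dose(dvh, 33.05)[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_level_dose(self):
        d = np.concatenate([np.full(50, 10.0), np.full(50, 30.0)])
        dvh = compute_dvh(d, bin_width_gy=0.05)
        assert volume_at_dose(dvh, 20.0)[0] == pytest.approx(50.0)

    def test_counting_oracle_on_random_field(self):
        rng = np.random.default_rng(21)
        d = rng.uniform(0, 40, 1000)
        dvh = compute_dvh(d, bin_width_gy=0.05)
        for e, c in zip(dvh.edges[1:], dvh.cum_pct[1:]):
            assert c == pytest.approx(100.0 * np.mean(d >= e), abs=1e-9)

    def test_monotone_and_starts_at_100(self):
        rng = np.random.default_rng(22)
        dvh = compute_dvh(rng.uniform(0, 40, 500), bin_width_gy=0.1)
        assert dvh.cum_pct[0] == 100.0
        assert np.all(np.diff(dvh.cum_pct) <= 1e-12)

    def test_grid_input_and_volume(self):
        g = VoxelGrid(np.full((4, 4, 4), 33.0), (2.0, 2.0, 2.0), (0, 0, 0), "Gy(RBE)")
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        dvh = compute_dvh(g, mask)
        assert dvh.volume_ml == pytest.approx(32 * 0.008)

    def test_empty_mask_rejected(self):
        g = VoxelGrid(np.zeros((2, 2, 2)), (1, 1, 1), (0, 0, 0), "Gy(RBE)")
        with pytest.raises(ValueError):
            compute_dvh(g, np.zeros((2, 2, 2), bool))


class TestDqVd:
    def test_uniform_structure(self):
        dvh = compute_dvh(np.full(64, 20.0), bin_width_gy=0.05)
        for q in (2.0, 50.0, 98.0):
            assert dose_at_volume(dvh, q) == pytest.approx(20.0, abs=0.06)

    def test_quantile_ordering(self):
        rng = np.random.default_rng(23)
        dvh = compute_dvh(rng.uniform(0, 40, 300), bin_width_gy=0.05)
        d100 = dose_at_volume(dvh, 100.0)
        d98 = dose_at_volume(dvh, 98.0)
        d50 = dose_at_volume(dvh, 50.0)
        d2 = dose_at_volume(dvh, 2.0)
        assert d100 <= d98 <= d50 <= d2

    def test_four_voxel_enumeration(self):
        dvh = compute_dvh(np.array([1.0, 2.0, 3.0, 4.0]), bin_width_gy=0.05)
        assert volume_at_dose(dvh, 2.5)[0] == pytest.approx(50.0)
        assert 2.0 <= dose_at_volume(dvh, 50.0) <= 3.0

    def test_q_bounds(self):
        dvh = compute_dvh(np.ones(4), bin_width_gy=0.05)
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 101.0)


class TestBandwidth:
    def test_zero_when_all_nominal(self):
        assert bandwidth(33.0, [33.0, 33.0, 33.0]) == 0.0

    def test_two_point_example(self):
        # 2 sqrt((1+1)/1) / 33 x 100 = 8.571...
        assert bandwidth(33.0, [34.0, 32.0]) == pytest.approx(8.571, abs=1e-3)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        base = bandwidth(33.0, [30.0, 35.0, 34.0])
        assert bandwidth(33.0 * c, np.array([30.0, 35.0, 34.0]) * c) == pytest.approx(base)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            nom = rng.uniform(1, 40)
            vals = rng.uniform(0, 40, rng.integers(2, 9))
            expected = 2 * np.sqrt(((vals - nom) ** 2).sum() / (len(vals) - 1)) / nom * 100
            assert bandwidth(nom, vals) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            bandwidth(33.0, [33.0])
        with pytest.raises(ValueError):
            bandwidth(0.0, [1.0, 2.0])


@pytest.fixture()
def ramp_grid():
    vals = np.zeros((21, 21, 5))
    x = np.arange(21)[:, None, None] * 2.0
    vals = np.broadcast_to(0.5 * x, (21, 21, 5)).copy()
    return VoxelGrid(vals, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), "Gy(RBE)")


class TestLineDose:
    def test_constant_field(self):
        g = VoxelGrid(np.full((10, 10, 5), 7.0), (2, 2, 2), (0, 0, 0), "Gy(RBE)")
        prof = sample_line_dose(g, [2, 2, 2], [16, 16, 6], step_mm=0.5)
        assert np.allclose(prof["dose"], 7.0)

    def test_linear_ramp_slope(self, ramp_grid):
        prof = sample_line_dose(ramp_grid, [0, 20, 4], [40, 20, 4], step_mm=0.5)
        slope = np.polyfit(prof["position_mm"], prof["dose"], 1)[0]
        assert slope == pytest.approx(0.5, rel=1e-6)

    def test_reverse_is_mirror(self, ramp_grid):
        f = sample_line_dose(ramp_grid, [0, 20, 4], [40, 20, 4], step_mm=1.0)
        r = sample_line_dose(ramp_grid, [40, 20, 4], [0, 20, 4], step_mm=1.0)
        assert np.allclose(f["dose"].to_numpy(), r["dose"].to_numpy()[::-1])

    def test_bad_step_rejected(self, ramp_grid):
        with pytest.raises(ValueError):
            sample_line_dose(ramp_grid, [0, 20, 4], [40, 20, 4], step_mm=0.0)


def _erf_falloff_profile(sigma, step=0.5, noise=0.0, rng=None):
    r = np.arange(0.0, 60.0 + step, step)
    dose = 33.0 * 0.5 * erfc((r - 30.0) / (np.sqrt(2.0) * sigma))
    if noise:
        dose = dose + rng.normal(0.0, noise, dose.shape)
    return pd.DataFrame({"position_mm": r, "dose": dose})


class TestDSF:
    def test_recovers_gaussian_widths(self):
        res = dose_spread_function(_erf_falloff_profile(3.0))
        assert res.fwhm_mm == pytest.approx(2 * 3.0 * np.sqrt(2 * np.log(2)), rel=0.01)
        assert res.fw20m_mm == pytest.approx(2 * 3.0 * np.sqrt(2 * np.log(5)), rel=0.01)

    @pytest.mark.parametrize("sigma", [1.5, 3.0, 5.0])
    def test_sigma_recovery_within_5pct(self, sigma):
        res = dose_spread_function(_erf_falloff_profile(sigma))
        assert res.fit_params["sigma"] == pytest.approx(sigma, rel=0.05)
        assert not res.error_flag

    def test_step_falloff_widths_near_zero(self):
        step = 0.5
        r = np.arange(0.0, 40.0 + step, step)
        dose = np.where(r < 20.0, 33.0, 0.0)
        res = dose_spread_function(pd.DataFrame({"position_mm": r, "dose": dose}))
        assert res.fwhm_mm < 2 * step
        assert res.fw20m_mm < 2 * step * 2  # FW20M wider but still ~sampling scale

    def test_fwhm_not_wider_than_fw20m(self):
        for sigma in (1.0, 2.5, 6.0):
            res = dose_spread_function(_erf_falloff_profile(sigma))
            assert res.fwhm_mm <= res.fw20m_mm
            assert res.w_100_50_mm <= res.w_100_20_mm

    def test_no_plateau_rejected(self):
        r = np.arange(0.0, 20.0, 0.5)
        dose = 33.0 * np.exp(-r / 3.0)  # monotone decay, no plateau
        with pytest.raises(ValueError):
            dose_spread_function(pd.DataFrame({"position_mm": r, "dose": dose}))

    def test_logistic_family_widths(self):
        res = dose_spread_function(_erf_falloff_profile(3.0), fit_family="logistic")
        assert res.fwhm_mm <= res.fw20m_mm
        assert not np.isnan(res.fwhm_mm)


class TestAbutmentLine:
    def _dose_sphere(self):
        shape = (40, 40, 40)
        spacing = np.array([2.0, 2.0, 2.0])
        origin = -(np.array(shape) - 1) / 2.0 * spacing
        g = VoxelGrid(np.zeros(shape, np.float32), spacing, origin, "Gy(RBE)")
        idx = np.indices(shape, dtype=float)
        pos = [origin[a] + idx[a] * spacing[a] for a in range(3)]
        r = np.sqrt(sum(p**2 for p in pos))
        g.values[:] = 40.0 * np.exp(-np.maximum(r - 15.0, 0.0) / 8.0)
        return g

    def test_segment_through_gap_midpoint(self):
        g = self._dose_sphere()
        # 100% isodose at 33 Gy: radius ~ 15 + 8 ln(40/33) = 16.54 mm
        iso_r = 15.0 + 8.0 * np.log(40.0 / 33.0)
        oar = np.zeros(g.shape, bool)
        # slab starting 5 mm beyond the isodose surface along +x
        x0 = iso_r + 5.0
        i0 = int(np.ceil(g.position_to_index([x0, 0, 0])[0]))
        oar[i0:, 15:25, 15:25] = True
        p0, p1 = locate_abutment_line(g, 33.0, oar)
        mid = (iso_r + x0) / 2.0
        line = np.array([p0, p1])
        # the segment runs along x through the gap midpoint
        t = (mid - p0[0]) / (p1[0] - p0[0])
        point = p0 + t * (p1 - p0)
        assert 0.0 < t < 1.0
        assert abs(point[0] - mid) < 2.0

    def test_overlapping_oar_still_defined(self):
        g = self._dose_sphere()
        oar = np.zeros(g.shape, bool)
        oar[18:30, 15:25, 15:25] = True  # overlaps the isodose
        p0, p1 = locate_abutment_line(g, 33.0, oar)
        assert np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))

    def test_direction_reverses_under_swap(self):
        g = self._dose_sphere()
        oar_right = np.zeros(g.shape, bool)
        oar_right[35:, 15:25, 15:25] = True
        oar_left = np.zeros(g.shape, bool)
        oar_left[:5, 15:25, 15:25] = True
        pr = locate_abutment_line(g, 33.0, oar_right)
        pl = locate_abutment_line(g, 33.0, oar_left)
        dr = (pr[1] - pr[0])[0]
        dl = (pl[1] - pl[0])[0]
        assert dr > 0 and dl < 0

    def test_empty_isodose_rejected(self):
        g = self._dose_sphere()
        oar = np.zeros(g.shape, bool)
        oar[0] = True
        with pytest.raises(ValueError):
            locate_abutment_line(g, 100.0, oar)
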