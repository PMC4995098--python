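"""Shape descriptors, retinotopic polar maps and the linear fits."""

import numpy as np
import pytest

from dipmap import mapstats as ms
from dipmap import preprocess as pp
from dipmap import synthetic as syn
from dipmap.geometry import axial_difference_deg
from conftest import disc_mask


def _region_from_mask(mask, pixel_pitch=0.05):
    return pp.ActivationRegion(mask=mask, component_count=1,
                               labels=mask.astype(int),
                               smoothed=np.where(mask, -5.0, 0.0),
                               threshold=-3.09, pixel_pitch=pixel_pitch)


def _zmap(values, pitch=0.05):
    return pp.ZScoreMap(values=values, window=(1.5, 2.5),
                        blank_mean=np.zeros_like(values), blank_sd=1.0,
                        pixel_pitch=pitch)


def _ellipse_mask(shape, center, a, b, theta_deg):
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    th = np.radians(theta_deg)
    u = dc * np.cos(th) + dr * np.sin(th)
    v = -dc * np.sin(th) + dr * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestCenterOfMass:
    def test_symmetric_blob_centroid_at_center(self):
        rr, cc = np.mgrid[:41, :41]
        z = -8.0 * np.exp(-((rr - 20.0) ** 2 + (cc - 20.0) ** 2) / 50.0)
        mask = z <= -3.0
        com = ms.center_of_mass(_zmap(z), _region_from_mask(mask))
        assert com == pytest.approx((20.0, 20.0), abs=1e-9)

    def test_single_pixel(self):
        z = np.zeros((10, 10))
        z[3, 7] = -5.0
        mask = z < 0
        assert ms.center_of_mass(_zmap(z), _region_from_mask(mask)) == (3.0, 7.0)

    def test_hand_computed_weighted_mean(self):
        # weights 1 and 3 at columns 0 and 4 -> column (0*1 + 4*3)/4 = 3
        z = np.zeros((3, 5))
        z[1, 0] = -1.0
        z[1, 4] = -3.0
        mask = z < 0
        com = ms.center_of_mass(_zmap(z), _region_from_mask(mask))
        assert com == pytest.approx((1.0, 3.0))

    def test_empty_region_returns_none(self):
        z = np.zeros((5, 5))
        region = _region_from_mask(np.zeros((5, 5), dtype=bool))
        region.component_count = 0
        assert ms.center_of_mass(_zmap(z), region) is None


class TestEquivalentEllipse:
    def test_disc_axes_equal_diameter(self):
        mask = disc_mask((41, 41), (20, 20), 10.0)
        ell = ms.equivalent_ellipse(_region_from_mask(mask), pixel_pitch=1.0)
        assert ell.major_axis_len == pytest.approx(20.0, rel=0.03)
        assert ell.minor_axis_len == pytest.approx(20.0, rel=0.03)
        assert ell.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert ell.equivalent_diameter == pytest.approx(20.0, rel=0.02)

    def test_rectangle_aspect_ratio_exactly_four(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[10:20, 10:50] = True      # 10 rows x 40 cols
        ell = ms.equivalent_ellipse(_region_from_mask(mask), pixel_pitch=1.0)
        # second moments w^2/12 and h^2/12 with the unit-pixel correction
        assert ell.aspect_ratio == pytest.approx(4.0, rel=1e-12)
        assert ell.orientation == pytest.approx(0.0, abs=1e-9)
        assert ell.major_axis_len == pytest.approx(
            4.0 * np.sqrt(40.0 ** 2 / 12.0), rel=1e-12)

    def test_rotation_equivariance(self):
        base = _ellipse_mask((81, 81), (40, 40), 25.0, 10.0, 20.0)
        rot = _ellipse_mask((81, 81), (40, 40), 25.0, 10.0, 50.0)
        e0 = ms.equivalent_ellipse(_region_from_mask(base), pixel_pitch=1.0)
        e1 = ms.equivalent_ellipse(_region_from_mask(rot), pixel_pitch=1.0)
        d = float(axial_difference_deg(e1.orientation, e0.orientation))
        assert d == pytest.approx(30.0, abs=1.0)
        assert e1.aspect_ratio == pytest.approx(e0.aspect_ratio, rel=0.02)

    def test_translation_invariance_and_scale_invariant_ar(self):
        a = _ellipse_mask((101, 101), (30, 30), 20.0, 8.0, 70.0)
        b = _ellipse_mask((101, 101), (60, 65), 20.0, 8.0, 70.0)
        big = _ellipse_mask((201, 201), (100, 100), 40.0, 16.0, 70.0)
        ea = ms.equivalent_ellipse(_region_from_mask(a), pixel_pitch=1.0)
        eb = ms.equivalent_ellipse(_region_from_mask(b), pixel_pitch=1.0)
        ebig = ms.equivalent_ellipse(_region_from_mask(big), pixel_pitch=1.0)
        assert ea.major_axis_len == pytest.approx(eb.major_axis_len, rel=1e-9)
        assert ea.aspect_ratio == pytest.approx(eb.aspect_ratio, rel=1e-9)
        assert ebig.aspect_ratio == pytest.approx(ea.aspect_ratio, rel=0.03)

    def test_matches_bruteforce_second_moments(self):
        """Axis lengths/orientation agree with an explicit-loop moment
        computation on small random masks."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            mask = np.zeros((50, 50), dtype=bool)
            # random blobby mask: union of a few discs
            for _ in range(4):
                r0, c0 = rng.integers(10, 40, size=2)
                mask |= disc_mask((50, 50), (r0, c0), rng.uniform(3, 8))
            pts = [(r, c) for r in range(50) for c in range(50) if mask[r, c]]
            n = len(pts)
            mr = sum(p[0] for p in pts) / n
            mc = sum(p[1] for p in pts) / n
            srr = sum((p[0] - mr) ** 2 for p in pts) / n + 1 / 12
            scc = sum((p[1] - mc) ** 2 for p in pts) / n + 1 / 12
            src = sum((p[0] - mr) * (p[1] - mc) for p in pts) / n
            tr, det = srr + scc, srr * scc - src ** 2
            lam_hi = tr / 2 + np.sqrt(tr ** 2 / 4 - det)
            lam_lo = tr / 2 - np.sqrt(tr ** 2 / 4 - det)
            ell = ms.equivalent_ellipse(_region_from_mask(mask),
                                        pixel_pitch=1.0)
            assert ell.major_axis_len == pytest.approx(4 * np.sqrt(lam_hi),
                                                       rel=1e-9)
            assert ell.minor_axis_len == pytest.approx(4 * np.sqrt(lam_lo),
                                                       rel=1e-9)

    def test_degenerate_region_flagged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 3:15] = True           # one-pixel-thick line
        with pytest.warns(UserWarning, match="degenerate"):
            ell = ms.equivalent_ellipse(_region_from_mask(mask),
                                        pixel_pitch=1.0)
        assert ell.degenerate
        assert ell.minor_axis_len == 1.0

    def test_too_small_region_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            ms.equivalent_ellipse(_region_from_mask(mask), pixel_pitch=1.0)


class TestPolarMaps:
    def test_single_position_preference(self):
        maps = [_zmap(np.zeros((4, 4))) for _ in range(3)]
        maps[1].values[2, 2] = -5.0     # responds only to (20, 0)
        pm = ms.build_polar_maps(maps, [(0.0, 0.0), (20.0, 0.0), (40.0, 0.0)],
                                 response_floor=0.0)
        assert pm.azimuth_pref[2, 2] == pytest.approx(20.0)
        assert pm.elevation_pref[2, 2] == pytest.approx(0.0)
        assert np.isnan(pm.azimuth_pref[0, 0])

    def test_equal_responses_average(self):
        maps = [_zmap(np.zeros((2, 2))) for _ in range(2)]
        maps[0].values[0, 0] = -3.0
        maps[1].values[0, 0] = -3.0
        pm = ms.build_polar_maps(maps, [(0.0, 0.0), (40.0, 0.0)],
                                 response_floor=0.0)
        assert pm.azimuth_pref[0, 0] == pytest.approx(20.0)

    def test_positive_z_is_rectified_away(self):
        maps = [_zmap(np.full((2, 2), 4.0)), _zmap(np.full((2, 2), -1.0))]
        pm = ms.build_polar_maps(maps, [(0.0, 0.0), (40.0, 0.0)],
                                 response_floor=0.0)
        assert np.allclose(pm.azimuth_pref, 40.0)


@pytest.fixture(scope="module")
def session():
    acq = syn.AcquisitionConfig(frame_rate=10.0, trial_duration=4.0,
                                stim_onset=0.5, image_rows=48,
                                image_cols=48, pixel_pitch=0.05,
                                n_trials=4, n_blank_trials=4)
    return acq, syn.generate_retinotopy_session(
        acq, magnification=0.02, amplitude=-0.01, noise_sd=0.0005,
        seed=21)


@pytest.fixture(scope="module")
def zmaps(session, analysis_small):
    acq, bundle = session

    def prep(s):
        return pp.temporal_normalize(pp.subtract_border_trend(s))

    blank = prep(bundle.blank)
    return [pp.compute_static_zscore_map(prep(s), blank, analysis_small)
            for s in bundle.stacks]


class TestRetinotopyRoundTrip:
    def test_polar_maps_match_truth_at_blob_centers(self, session, zmaps):
        acq, bundle = session
        positions = list(zip(bundle.metadata["position_deg_x"],
                             bundle.metadata["position_deg_y"]))
        pm = ms.build_polar_maps(zmaps, positions)
        for stack, (az, el) in zip(bundle.stacks, positions):
            r, c = (int(round(x)) for x in stack.truth.center)
            assert pm.azimuth_pref[r, c] == pytest.approx(az, abs=4.0)
            assert pm.elevation_pref[r, c] == pytest.approx(el, abs=4.0)

    def test_expected_position_recovers_stimulus_center(self, session, zmaps):
        acq, bundle = session
        positions = list(zip(bundle.metadata["position_deg_x"],
                             bundle.metadata["position_deg_y"]))
        pm = ms.build_polar_maps(zmaps, positions)
        # interior grid positions (edge preferences are biased inward by
        # the weighted-centroid construction)
        for k, (az, el) in enumerate(positions):
            if abs(az) == 40 or abs(el) == 30:
                continue
            got = ms.expected_cortical_position(pm, (az, el))
            truth = bundle.stacks[k].truth.center
            assert np.hypot(got[0] - truth[0], got[1] - truth[1]) <= 3.0

    def test_outside_span_rejected(self, session, zmaps):
        acq, bundle = session
        positions = list(zip(bundle.metadata["position_deg_x"],
                             bundle.metadata["position_deg_y"]))
        pm = ms.build_polar_maps(zmaps, positions)
        with pytest.raises(ValueError, match="span"):
            ms.expected_cortical_position(pm, (80.0, 0.0))

    def test_magnification_recovered_from_centers(self, session, zmaps,
                                                  analysis_small):
        acq, bundle = session
        coms = []
        for z in zmaps:
            region = pp.extract_activation(z, analysis_small)
            coms.append(ms.center_of_mass(z, region))
        pos = bundle.metadata[["position_deg_x", "position_deg_y"]].to_numpy()
        pairs = []
        for i in range(len(coms)):
            for j in range(i + 1, len(coms)):
                vis = float(np.hypot(*(pos[i] - pos[j])))
                cort = float(np.hypot(coms[i][0] - coms[j][0],
                                      coms[i][1] - coms[j][1])) \
                    * acq.pixel_pitch
                pairs.append((vis, cort))
        fit = ms.fit_magnification(pairs)
        assert fit.slope == pytest.approx(0.02, rel=0.01)


class TestPositionalError:
    def test_identical_points(self):
        m = ms.positional_error((1.0, 1.0), (1.0, 1.0), 0.022)
        assert m.error_mm == 0.0 and m.error_deg_eq == 0.0

    def test_three_four_five(self):
        m = ms.positional_error((0.0, 0.0), (0.3, 0.4), 0.022)
        assert m.error_mm == pytest.approx(0.5)

    def test_symmetry(self):
        a = ms.positional_error((0.1, 0.9), (0.5, 0.2), 0.022)
        b = ms.positional_error((0.5, 0.2), (0.1, 0.9), 0.022)
        assert a.error_mm == b.error_mm

    def test_degree_equivalent_at_printed_magnification(self):
        m = ms.positional_error((0.0, 0.0), (0.0, 0.44), 0.022)
        assert m.error_deg_eq == pytest.approx(20.0)


class TestLinearFits:
    def test_exact_line_magnification(self):
        x = np.array([5.0, 10.0, 20.0, 40.0])
        fit = ms.fit_magnification(list(zip(x, 0.022 * x)))
        assert fit.slope == pytest.approx(0.022, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_intercept_free_fit(self):
        x = np.array([5.0, 10.0, 20.0])
        fit = ms.fit_magnification(list(zip(x, 0.022 * x)),
                                   fit_intercept=False)
        assert fit.slope == pytest.approx(0.022, rel=1e-12)

    def test_degenerate_abscissae_rejected(self):
        with pytest.raises(ValueError):
            ms.fit_magnification([(5.0, 0.1), (5.0, 0.2)])

    def test_size_tuning_inverse_consistency(self):
        sizes = np.array([2.0, 6.0, 10.0, 14.0, 18.0])
        fit = ms.fit_size_tuning(sizes, 0.081 * sizes + 0.05)
        assert fit.slope == pytest.approx(0.081, rel=1e-12)
        for s in sizes:
            assert fit.equivalent_visual_size(
                fit.extent_for_size(s)) == pytest.approx(s, rel=1e-9)

    def test_size_tuning_extrapolation_flagged(self):
        sizes = np.array([2.0, 6.0, 10.0])
        fit = ms.fit_size_tuning(sizes, 0.081 * sizes)
        with pytest.warns(UserWarning, match="extrapolates"):
            fit.equivalent_visual_size(0.081 * 40.0)

    def test_size_series_roundtrip_through_pipeline(self, analysis_small):
        """Measured half-max extents of a synthetic size series recover the
        generator's mm-per-degree size slope."""
        acq = syn.AcquisitionConfig(frame_rate=10.0, trial_duration=4.0,
                                    stim_onset=0.5, image_rows=60,
                                    image_cols=60, pixel_pitch=0.05,
                                    n_trials=4, n_blank_trials=4)
        bundle = syn.generate_size_series(acq, sizes_deg=(6.0, 10.0, 14.0),
                                          size_slope=0.081, noise_sd=0.0,
                                          seed=3)
        extents = []
        for stack in bundle.stacks:
            dii = pp.compute_dii_map(stack, bundle.blank, analysis_small)
            half = 0.5 * np.nanmin(dii.values)
            mask = dii.values <= half
            # FWHM-equivalent diameter of the half-max region
            extents.append(2.0 * np.sqrt(mask.sum() / np.pi)
                           * acq.pixel_pitch)
        fit = ms.fit_size_tuning(bundle.metadata["size_deg"], extents)
        assert fit.slope == pytest.approx(0.081, rel=0.05)
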