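"""Phantom generator: plate construction, rasterization, scanning, counter."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

import petlimit as pl
from petlimit.errors import (
    CapacityError,
    CoverageError,
    ReproducibilityError,
    ValidationError,
)
from petlimit.phantom import (
    CUBIC_PLATE_DEFAULT_LOADING,
    Cube,
    Cylinder,
    ScannerModel,
    StudyConfig,
)


class TestBuildPlateSpec:
    def test_truth_activity_is_cells_times_sa(self):
        plate = pl.build_plate_spec("six_well", [(1e6, 10.0)])
        assert len(plate.wells) == 1
        assert plate.wells[0].truth_kbq == pytest.approx(10.0)

    def test_cubic_plate_well_activities(self):
        plate = pl.build_plate_spec("cubic_3x3", CUBIC_PLATE_DEFAULT_LOADING)
        # M2 well: 3.25e4 cells at 15.41 kBq/1e6 cells -> ~0.501 kBq
        m2 = plate.wells[4]
        assert m2.cell_number == pytest.approx(3.25e4)
        assert m2.truth_kbq == pytest.approx(0.501, abs=5e-4)

    def test_cubic_density_definition(self):
        plate = pl.build_plate_spec("cubic_3x3", [(8.2e5, 7.23)])
        # 1 cm^3 well -> density = cells / 1e6 per mL
        assert plate.wells[0].cell_density == pytest.approx(0.82)

    @pytest.mark.parametrize(
        "layout,n", [("six_well", 7), ("cubic_3x3", 10)]
    )
    def test_over_capacity(self, layout, n):
        with pytest.raises(CapacityError):
            pl.build_plate_spec(layout, [(1e5, 1.0)] * n)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            pl.build_plate_spec("six_well", [(-1, 1.0)])
        with pytest.raises(ValidationError):
            pl.build_plate_spec("six_well", [(1e5, -0.5)])

    def test_six_well_empty_slots_become_background_sites(self):
        plate = pl.build_plate_spec("six_well", [(1e6, 1.0)] * 3)
        assert len(plate.background_sites) == 3


class TestRasterize:
    def test_uniform_cube_fill(self):
        plate = pl.build_plate_spec("cubic_3x3", [(1e6, 1.0)])  # 1 kBq, CD=1
        img = pl.rasterize_truth(plate)
        filled = img.voxels[img.voxels > 0]
        assert filled.size == 1000
        np.testing.assert_allclose(filled, 1.0)  # kBq/mL
        assert img.total_activity_kbq() == pytest.approx(1.0, rel=1e-12)

    def test_empty_plate_all_zero(self):
        plate = pl.build_plate_spec("six_well", [])
        img = pl.rasterize_truth(plate)
        assert img.voxels.sum() == 0.0

    def test_exact_conservation_two_wells(self):
        plate = pl.build_plate_spec("six_well", [(1e6, 4.0), (1e6, 6.0)])
        img = pl.rasterize_truth(plate)
        assert img.total_activity_kbq() == pytest.approx(10.0, rel=1e-12)

    def test_well_outside_grid_is_coverage_error(self):
        plate = pl.build_plate_spec("six_well", [(1e6, 1.0)])
        small = pl.ActivityImage(np.zeros((10, 10, 10)))
        with pytest.raises(CoverageError):
            pl.rasterize_truth(plate, grid=small)


class TestSimulateScan:
    def test_zero_truth_zero_background_gives_zero(self):
        truth = pl.ActivityImage(np.zeros((20, 20, 20)))
        scanner = ScannerModel("petct", background_kbq_ml=0.0)
        out = pl.simulate_scan(truth, scanner, seed=0)
        assert not out.voxels.any()

    def test_identity_limit(self):
        """No blur, no noise: output = truth + background inside support."""
        plate = pl.build_plate_spec("cubic_3x3", [(1e6, 1.0)])
        truth = pl.rasterize_truth(plate)
        scanner = ScannerModel(
            "ideal", psf_fwhm_mm=0.0, background_kbq_ml=0.2, noise_scale=None
        )
        out = pl.simulate_scan(truth, scanner)
        from petlimit.phantom import _support_mask

        mask = _support_mask(truth, truth.meta["support_bbox"])
        np.testing.assert_allclose(
            out.voxels, truth.voxels + 0.2 * mask, rtol=0, atol=1e-12
        )

    def test_blur_conserves_activity_and_spills_out(self):
        """1 kBq cube, 6 mm FWHM, noiseless: global conservation to 0.1 %,
        in-VOI activity below 1 kBq, matching a separable-Gaussian oracle."""
        plate = pl.build_plate_spec("cubic_3x3", [(1e6, 1.0)])
        truth = pl.rasterize_truth(plate, padding_mm=20.0)
        scanner = ScannerModel(
            "noblur", psf_fwhm_mm=6.0, background_kbq_ml=0.0, noise_scale=None
        )
        out = pl.simulate_scan(truth, scanner)
        assert out.total_activity_kbq() == pytest.approx(1.0, rel=1e-3)
        voi = pl.make_voi(Cube(10.0), plate.wells[0].center, out)
        recovered = pl.voi_total_activity(out, voi)
        assert recovered < 1.0
        # independent oracle: product of 1-D Gaussian-convolved box integrals
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2)))

        def axis_fraction(edge):
            x = np.linspace(-edge / 2, edge / 2, 2001)
            frac = 0.5 * (
                erf((edge / 2 - x) / (sigma * np.sqrt(2)))
                - erf((-edge / 2 - x) / (sigma * np.sqrt(2)))
            )
            return np.trapezoid(frac, x) / edge

        expected = axis_fraction(10.0) ** 3
        assert recovered == pytest.approx(expected, rel=0.02)

    def test_same_seed_identical_image(self):
        plate = pl.build_plate_spec("cubic_3x3", [(1e5, 5.0)])
        truth = pl.rasterize_truth(plate)
        scanner = ScannerModel("petct")
        a = pl.simulate_scan(truth, scanner, seed=42)
        b = pl.simulate_scan(truth, scanner, seed=42)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_missing_seed_with_noise_raises(self):
        truth = pl.ActivityImage(np.zeros((5, 5, 5)))
        with pytest.raises(ReproducibilityError):
            pl.simulate_scan(truth, ScannerModel("petct"))

    def test_recovered_fraction_monotone_in_fwhm(self):
        """Noiseless VOI recovery is non-increasing in the PSF FWHM."""
        plate = pl.build_plate_spec("cubic_3x3", [(1e6, 1.0)])
        truth = pl.rasterize_truth(plate)
        voi_shape = Cube(10.0)
        fracs = []
        for fwhm in (0.0, 2.0, 4.0, 6.0, 8.0):
            scanner = ScannerModel(
                "s", psf_fwhm_mm=fwhm, background_kbq_ml=0.0, noise_scale=None
            )
            out = pl.simulate_scan(truth, scanner)
            voi = pl.make_voi(voi_shape, plate.wells[0].center, out)
            fracs.append(pl.voi_total_activity(out, voi))
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestWellCounter:
    def test_zero_cv_returns_truth(self):
        plate = pl.build_plate_spec("six_well", [(1e6, 10.0)])
        table = pl.simulate_well_counter(plate, counter_cv=0.0)
        assert table["counter_kBq"].iloc[0] == 10.0

    def test_zero_truth_stays_zero(self):
        plate = pl.build_plate_spec("six_well", [(0, 0.0)])
        table = pl.simulate_well_counter(plate, counter_cv=0.5, seed=3)
        assert table["counter_kBq"].iloc[0] == 0.0

    def test_monte_carlo_mean_and_sd(self):
        """truth 10 kBq, cv 0.05 over 1e4 seeds: mean within 0.2 % of 10,
        SD within 5 % of 0.5."""
        plate = pl.build_plate_spec("six_well", [(1e6, 10.0)])
        draws = np.array(
            [
                pl.simulate_well_counter(plate, 0.05, seed=s)["counter_kBq"].iloc[0]
                for s in range(10_000)
            ]
        )
        assert draws.mean() == pytest.approx(10.0, rel=0.002)
        assert draws.std(ddof=1) == pytest.approx(0.5, rel=0.05)


class TestGenerateStudy:
    def test_default_design_counts(self, default_study):
        wt = default_study.well_table
        six = wt[(wt.layout == "six_well") & (wt.scanner == "petct")]
        assert len(six) == 36
        assert (~six.qc_excluded).sum() == 31
        cubes = wt[(wt.layout == "cubic_3x3") & (wt.scanner == "petct")]
        assert len(cubes) == 9

    def test_exclusions_shared_between_arms(self, default_study):
        wt = default_study.well_table
        for scanner in ("petct", "petmri"):
            arm = wt[(wt.layout == "six_well") & (wt.scanner == scanner)]
            assert arm.qc_excluded.sum() == 5
        ct = wt[wt.scanner == "petct"].set_index(["plate_id", "well_id"]).qc_excluded
        mr = wt[wt.scanner == "petmri"].set_index(["plate_id", "well_id"]).qc_excluded
        pd.testing.assert_series_equal(ct, mr)

    def test_same_seed_reproduces_tables(self, default_study):
        again = pl.generate_study(StudyConfig(seed=1))
        pd.testing.assert_frame_equal(default_study.well_table, again.well_table)

    def test_collapsed_sa_range(self):
        cfg = StudyConfig(seed=2, sa_range=(5.0, 5.0), include_cubic_plate=False)
        ds = pl.generate_study(cfg)
        assert (ds.well_table.specific_activity_kBq_per_1e6 == 5.0).all()

    def test_sa_within_configured_range(self, default_study):
        six = default_study.well_table.query("layout == 'six_well'")
        sa = six.specific_activity_kBq_per_1e6
        assert sa.between(0.43, 31.91).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            pl.generate_study(StudyConfig(n_experiments=0))
        with pytest.raises(ValidationError):
            pl.generate_study(StudyConfig(exclusion_count=100))

    def test_cnr_tracks_activity(self, quantified_wells):
        """Generated CNR regressed on total well activity: positive slope,
        r > 0.7 (the strong positive correlation the analysis assumes)."""
        six = quantified_wells.query("layout == 'six_well' and not qc_excluded")
        r, _ = pl.pearson(six.counter_kBq, six.cnr)
        assert r > 0.7
        fit = pl.fit_line(six.counter_kBq, six.cnr)
        assert fit.slope > 0
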