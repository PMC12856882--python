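"""Contact detection, spot sampling, time binning and acquisition planning."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import nanodesi4d as nd
from nanodesi4d.core import NoContactError, TruncationError
from nanodesi4d.pixelation import (align_to_contact, detect_contact,
                                   plan_acquisition, spot_sample, time_bin,
                                   transit_time)
from nanodesi4d.profiles import extract_xic
from nanodesi4d.simulate import (Phantom, simulate_continuous_run,
                                 simulate_discrete_run)


def flat_scan(i, t, level):
    mz = np.arange(2400.0, 2500.0, 1.0)
    return nd.MassSpectrum(i, t, mz, np.full(mz.size, float(level)))


class TestDetectContact:
    def test_baseline_then_signal(self):
        scans = [flat_scan(i, 2.6 * i, 1.0) for i in range(5)]
        scans += [flat_scan(5 + i, 2.6 * (5 + i), 50.0) for i in range(3)]
        assert detect_contact(scans) == 5

    def test_zero_threshold_returns_first_scan(self):
        scans = [flat_scan(i, 2.6 * i, 1.0) for i in range(4)]
        assert detect_contact(scans, threshold_factor=0.0) == 0

    def test_all_baseline_raises(self):
        scans = [flat_scan(i, 2.6 * i, 1.0) for i in range(6)]
        with pytest.raises(NoContactError):
            detect_contact(scans)

    def test_alignment_rezeroes_and_keeps_precontact_negative(self):
        scans = [flat_scan(i, 2.6 * i, 1.0) for i in range(5)]
        scans += [flat_scan(5, 13.0, 50.0)]
        aligned = align_to_contact(scans, 5)
        assert aligned[5].time_s == 0.0
        assert aligned[0].time_s == pytest.approx(-13.0)


class TestSpotSample:
    def test_two_pixels_rezeroed(self, species_panel, discrete_schedule):
        phantom = Phantom(2, 1, np.array([[0, 1]]))
        scans, _ = simulate_discrete_run(phantom, species_panel,
                                         discrete_schedule, seed=0,
                                         grid_step_mz=1.0)
        image = spot_sample(scans, discrete_schedule, phantom.pixel_order())
        for px in image.pixel_list():
            assert px.n_scans == 34
            assert px.spectra[0].time_s == 0.0

    def test_assignment_matches_simulator_truth_exactly(
            self, segmentation_run, discrete_schedule):
        phantom, scans, truth, image = segmentation_run
        order = phantom.pixel_order()
        by_scan = dict(zip(truth.scan_map["scan"], truth.scan_map["pixel"]))
        mismatches = 0
        for px in image.pixel_list():
            p = order.index((px.col, px.row))
            for s in px.spectra:
                if by_scan[s.scan_index] != p:
                    mismatches += 1
        assert mismatches == 0

    def test_scan_conservation(self, segmentation_run):
        _, scans, truth, image = segmentation_run
        audit = image.metadata["audit"]
        assert audit["assigned"] + audit["overhead"] + audit["precontact"] \
            + audit["beyond_schedule"] == len(scans)
        assert audit["assigned"] == (truth.scan_map["pixel"] >= 0).sum()
        assert audit["overhead"] == (truth.scan_map["pixel"] < 0).sum()

    def test_empty_pixel_order_empty_image(self, discrete_schedule):
        image = spot_sample([], discrete_schedule, [])
        assert image.n_pixels == 0

    def test_short_stream_truncation_error(self, species_panel,
                                           discrete_schedule):
        phantom = Phantom(1, 1, [[0]])
        scans, _ = simulate_discrete_run(phantom, species_panel,
                                         discrete_schedule, seed=0,
                                         grid_step_mz=1.0)
        order = [(0, 0), (1, 0), (2, 0)]
        with pytest.raises(TruncationError) as err:
            spot_sample(scans, discrete_schedule, order)
        assert (1, 0) in err.value.unfilled and (2, 0) in err.value.unfilled


class TestTimeBin:
    def test_bin_duration_94um_at_5um_per_s(self):
        sched = nd.AcquisitionSchedule.continuous_default()
        assert sched.pitch_x_um / sched.raster_speed_um_s == pytest.approx(18.8)

    def test_intensity_map_tracks_abundance(self, species_panel):
        sched = nd.AcquisitionSchedule.continuous_default()
        labels = np.tile(np.array([0, 0, 1, 1, 0, 1, 0, 0]), (3, 1))
        phantom = Phantom(8, 3, labels)
        scans, _ = simulate_continuous_run(phantom, species_panel, sched,
                                           seed=0, grid_step_mz=1.0)
        image = time_bin(scans, sched, (8, 3))
        sp = species_panel[3]  # strongly region-contrasted
        target = nd.XICTarget(sp.name, sp.mz_centers(), sp.charges,
                              (0.5, "mz"))
        values, expected = [], []
        for px in image.pixel_list():
            _, xic = extract_xic(px.spectra, target)
            values.append(xic[0])
            expected.append(sp.abundance_map[int(labels[px.row, px.col])])
        assert pearsonr(values, expected).statistic > 0.95

    def test_single_scan_bin_is_identity(self):
        sched = nd.AcquisitionSchedule(mode="continuous", pitch_x_um=100.0,
                                       pitch_y_um=200.0, scan_period_s=20.0,
                                       raster_speed_um_s=5.0,
                                       per_pixel_overhead_s=0.0)
        scans = [flat_scan(0, 0.0, 7.0)]
        image = time_bin(scans, sched, (1, 1))
        assert np.array_equal(image.pixel(0, 0).spectra[0].intensity,
                              scans[0].intensity)

    def test_short_line_error(self):
        sched = nd.AcquisitionSchedule.continuous_default()
        scans = [flat_scan(0, 0.0, 7.0)]
        with pytest.raises(TruncationError):
            time_bin(scans, sched, (4, 1))


class TestPlanner:
    def test_390_pixels_total_time(self, discrete_schedule):
        n, raster, dead, total = plan_acquisition(30, 13, discrete_schedule)
        assert n == 390
        assert total / 3600 == pytest.approx(390 * (90 + 12.9) / 3600)
        assert total / 3600 == pytest.approx(11.15, abs=0.01)

    def test_halving_pitch_quadruples_pixels_and_time(self, discrete_schedule):
        _, _, _, total = plan_acquisition(30, 13, discrete_schedule)
        n4, _, _, total4 = plan_acquisition(60, 26, discrete_schedule)
        assert n4 == 4 * 390
        assert total4 == pytest.approx(4 * total)

    def test_single_pixel(self, discrete_schedule):
        n, raster, dead, total = plan_acquisition(1, 1, discrete_schedule)
        assert (n, raster, dead) == (1, 90.0, 12.9)
        assert total == pytest.approx(102.9)


class TestTransit:
    def test_printed_value(self):
        assert transit_time(nd.AcquisitionSchedule.continuous_default()) == 20.0

    def test_linearity(self):
        base = nd.AcquisitionSchedule.continuous_default()
        fast = nd.AcquisitionSchedule(mode="continuous", pitch_x_um=94.0,
                                      pitch_y_um=200.0, scan_period_s=2.6,
                                      raster_speed_um_s=100.0,
                                      junction_diameter_um=100.0)
        wide = nd.AcquisitionSchedule(mode="continuous", pitch_x_um=94.0,
                                      pitch_y_um=200.0, scan_period_s=2.6,
                                      raster_speed_um_s=5.0,
                                      junction_diameter_um=200.0)
        assert transit_time(fast) == 1.0
        assert transit_time(wide) == 2 * transit_time(base)

    def test_discrete_mode_rejected(self, discrete_schedule):
        with pytest.raises(ValueError):
            transit_time(discrete_schedule)
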