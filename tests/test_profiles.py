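"""XIC extraction, elution-profile features, solubility classes, mass tools."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nanodesi4d as nd
from nanodesi4d.core import PROTON_MASS_DA
from nanodesi4d.io import Image4D
from nanodesi4d.profiles import (ElutionProfile, average_profiles,
                                 classify_solubility, default_ptm_catalog,
                                 extract_xic, match_mass_shift,
                                 neutral_mass_from_series, profile_features)
from nanodesi4d.simulate import (Phantom, SpeciesDefinition, elution_kinetics,
                                 simulate_discrete_run, synth_spectrum)
from .conftest import xic_target_for


def gaussian_scan(center=3067.81, t=0.0, height=1.0):
    mz = np.arange(center - 20, center + 20, 0.1)
    sigma = 0.66
    return nd.MassSpectrum(0, t, mz,
                           height * np.exp(-0.5 * ((mz - center) / sigma) ** 2))


class TestExtractXic:
    def test_captures_peak_apex(self):
        scan = gaussian_scan()
        target = nd.XICTarget("t", [3067.9], [10], (0.15, "mz"))
        _, xic = extract_xic([scan], target)
        assert xic[0] > 0

    def test_zero_spectra_zero_xic(self):
        mz = np.arange(2400.0, 2500.0, 1.0)
        scan = nd.MassSpectrum(0, 0.0, mz, np.zeros(mz.size))
        _, xic = extract_xic([scan], nd.XICTarget("t", [2450.0], [10]))
        assert np.all(xic == 0)

    def test_out_of_range_window_warns_not_errors(self):
        scan = gaussian_scan()
        target = nd.XICTarget("far", [9000.0], [5], (0.15, "mz"))
        with pytest.warns(UserWarning):
            _, xic = extract_xic([scan], target)
        assert np.all(xic == 0)

    @given(st.floats(2500, 3500), st.floats(0.3, 2.0))
    def test_disjoint_window_additivity(self, c1, gap):
        """XIC over a union of disjoint windows equals the sum of XICs."""
        scan = gaussian_scan(center=3000.0)
        c2 = c1 + 2 * 0.15 + gap
        both = nd.XICTarget("u", [c1, c2], [9, 8], (0.15, "mz"))
        only1 = nd.XICTarget("a", [c1], [9], (0.15, "mz"))
        only2 = nd.XICTarget("b", [c2], [8], (0.15, "mz"))
        _, x_union = extract_xic([scan], both)
        _, x1 = extract_xic([scan], only1)
        _, x2 = extract_xic([scan], only2)
        assert x_union[0] == x1[0] + x2[0]


def _identical_pixel_image(n_pixels=4, n_scans=10):
    spectra = [gaussian_scan(t=2.6 * k, height=np.exp(-k / 4)) for k in
               range(n_scans)]
    pixels = {}
    for i in range(n_pixels):
        spectra_i = [nd.MassSpectrum(s.scan_index, s.time_s, s.mz,
                                     s.intensity) for s in spectra]
        pixels[(i, 0)] = nd.PixelRecord(i, 0, (100.0 * i, 0.0), spectra_i)
    sched = nd.AcquisitionSchedule.discrete_default()
    return Image4D(pixels, n_pixels, 1, sched, np.arange(n_scans) * 2.6)


class TestAverageProfiles:
    def test_identical_pixels_sd_zero_and_equal_single_pixel(self):
        image = _identical_pixel_image()
        target = nd.XICTarget("t", [3067.9], [10], (0.15, "mz"))
        profile = average_profiles(image, target, normalize=True)
        assert np.allclose(profile.sd, 0.0)
        _, single = extract_xic(image.pixel(0, 0).spectra, target)
        assert np.allclose(profile.mean_intensity, single / single.max())
        assert profile.n_pixels == 4

    def test_recovers_generating_kinetics(self, small_run, uniform_panel,
                                          discrete_schedule):
        """Normalized mean profile matches the kinetics curve, RMSE < 0.05."""
        _, _, _, image = small_run
        dt = discrete_schedule.scan_period_s
        mid = (np.arange(image.time_axis.size) + 0.5) * dt
        for sp in uniform_panel:
            profile = average_profiles(image, xic_target_for(sp))
            kin = elution_kinetics(sp, mid)
            kin = kin / kin.max()
            rmse = np.sqrt(np.mean((profile.mean_intensity - kin) ** 2))
            assert rmse < 0.05, sp.name

    def test_soluble_species_depleted_by_30s(self, small_run, uniform_panel):
        _, _, _, image = small_run
        soluble = next(sp for sp in uniform_panel
                       if sp.kinetics_params[0] == 10.0
                       and sp.solubility_class == "soluble")
        profile = average_profiles(image, xic_target_for(soluble))
        assert np.argmax(profile.mean_intensity) == 0
        late = profile.mean_intensity[profile.time_s >= 30.0]
        assert np.all(late < 0.1)


class TestProfileFeatures:
    def _profile(self, t, y):
        target = nd.XICTarget("t", [3000.0], [10])
        return ElutionProfile(target, t, y, np.zeros(len(y)), 1, True)

    def test_delta_at_origin(self):
        y = np.zeros(34)
        y[0] = 1.0
        f = profile_features(self._profile(np.arange(34) * 2.6, y))
        assert f.frac_first_30s == 1.0
        assert f.t_peak_s == 0.0
        assert f.t_half_s == 0.0

    def test_uniform_profile(self):
        f = profile_features(self._profile(np.arange(90.0), np.ones(90)))
        assert f.frac_first_30s == pytest.approx(1.0 / 3.0)
        assert f.flatness == pytest.approx(1.0)

    def test_gamma_peak_within_one_slot(self):
        sp = SpeciesDefinition("m", 25000.0, (9,), (1.0,),
                               "membrane_associated", (10.0, 30.0, 120.0))
        t = np.arange(34) * 2.6
        y = elution_kinetics(sp, t + 1.3)
        f = profile_features(self._profile(t, y))
        assert abs(f.t_peak_s - 30.0) <= 2.6

    def test_all_zero_profile_undefined(self):
        with pytest.raises(ValueError):
            profile_features(self._profile(np.arange(5.0), np.zeros(5)))


class TestClassification:
    def test_simulated_species_recovered_noiseless(self, small_run,
                                                   uniform_panel):
        _, _, _, image = small_run
        for sp in uniform_panel:
            profile = average_profiles(image, xic_target_for(sp),
                                       background="flank")
            cls = classify_solubility(profile_features(profile))
            assert cls == sp.solubility_class, sp.name

    def test_class_reflects_elution_not_annotation(self, discrete_schedule):
        """A cytosolic protein released only on membrane dissolution (the
        myelin-trapped SIRT2 scenario) must not classify as soluble."""
        trapped = SpeciesDefinition("SIRT2_2", 43000.0, (13, 14), (0.5, 0.5),
                                    "membrane_associated", (10.0, 30.0, 120.0))
        phantom = Phantom(2, 2, np.zeros((2, 2), int))
        scans, _ = simulate_discrete_run(phantom, [trapped],
                                         discrete_schedule, seed=0)
        from nanodesi4d.pixelation import spot_sample
        image = spot_sample(scans, discrete_schedule, phantom.pixel_order())
        profile = average_profiles(image, xic_target_for(trapped))
        assert classify_solubility(profile_features(profile)) != "soluble"

    def test_threshold_cascade(self):
        make = lambda frac, flat: nd.ProfileFeatures(0.0, frac, flat, 0.0)
        assert classify_solubility(make(0.9, 0.0)) == "soluble"
        assert classify_solubility(make(0.3, 0.7)) == "transmembrane"
        assert classify_solubility(make(0.3, 0.2)) == "membrane_associated"


class TestNeutralMass:
    def test_vdac1_printed_series(self):
        peaks = [(2788.9, 11), (3067.9, 10), (3408.5, 9), (3834.6, 8)]
        mass, sd = neutral_mass_from_series(peaks)
        assert mass == pytest.approx(30668.0, abs=2.0)
        assert sd <= 2.0

    def test_single_peak(self):
        mass, sd = neutral_mass_from_series([(2900.3, 11)])
        assert mass == pytest.approx(11 * (2900.3 - PROTON_MASS_DA))
        assert sd == 0.0

    @given(st.floats(5000, 100000), st.integers(1, 30))
    def test_algebraic_round_trip(self, mass, z):
        mz = (mass + z * PROTON_MASS_DA) / z
        est, _ = neutral_mass_from_series([(mz, z)])
        assert est == pytest.approx(mass, rel=1e-12)

    def test_inconsistent_series_flagged(self):
        with pytest.warns(UserWarning):
            neutral_mass_from_series([(3000.0, 10), (3500.0, 10)])


def _oracle_match(delta, catalog, max_copies, tol):
    """Independent recursive enumeration of matching PTM multisets."""
    names = sorted(catalog.entries)
    out = []

    def recurse(i, counts, total):
        if i == len(names):
            if any(counts) and abs(total - delta) <= tol:
                out.append(frozenset((n, c) for n, c in zip(names, counts) if c))
            return
        for c in range(max_copies + 1):
            recurse(i + 1, counts + [c], total + c * catalog.entries[names[i]])

    recurse(0, [], 0.0)
    return set(out)


class TestMassShiftMatching:
    def test_286_is_geranylgeranylation_plus_methylation(self):
        matches = match_mass_shift(286.0, tol_da=1.0)
        combos = [m[0] for m in matches]
        assert {"S-geranylgeranylation": 1, "C-terminal methylation": 1} in combos
        assert not any("S-farnesylation" in c for c in combos)

    def test_558_is_double_geranylgeranylation_plus_methylation(self):
        matches = match_mass_shift(558.0, tol_da=1.0)
        combos = [m[0] for m in matches]
        assert {"S-geranylgeranylation": 2, "C-terminal methylation": 1} in combos

    @given(st.floats(10.0, 900.0), st.floats(0.1, 5.0))
    def test_agrees_with_bruteforce_oracle(self, delta, tol):
        catalog = default_ptm_catalog()
        got = {frozenset(m[0].items()) for m in
               match_mass_shift(delta, catalog, max_copies=3, tol_da=tol)}
        assert got == _oracle_match(delta, catalog, 3, tol)

    def test_empty_result_is_valid(self):
        assert match_mass_shift(3.0, tol_da=0.5) == []
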