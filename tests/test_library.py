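import json

import numpy as np
import pytest

from aquanmr import (
    BinnedSpectrum,
    CompoundEntry,
    LibraryError,
    LorentzianSignal,
    RangeError,
    SignalObservation,
    TargetSignal,
    adapt_matrix,
    bin_to_ppm,
    build_constant_matrix,
    calibration_vector,
    hz_to_ppm,
    load_library,
    lorentzian_heights,
    normalize_calibration,
    ppm_to_bin,
    save_library,
    synthesize_spectrum,
)


class TestSynthesize:
    def test_apex_and_half_height_values(self, axis):
        h, fwhm = 80.0, 1.2
        spec = synthesize_spectrum([LorentzianSignal(3.5, fwhm, h)], axis)
        assert spec.intensities[ppm_to_bin(spec, 3.5)] == pytest.approx(h, rel=1e-9)
        half_ppm = hz_to_ppm(fwhm, 600.0) / 2
        # evaluate the closed form at the exact half-height offsets
        assert lorentzian_heights(3.5 + half_ppm, [LorentzianSignal(3.5, fwhm, h)], 600.0) == pytest.approx(h / 2)
        assert lorentzian_heights(3.5 - half_ppm, [LorentzianSignal(3.5, fwhm, h)], 600.0) == pytest.approx(h / 2)

    def test_empty_signal_list_gives_zeros(self, axis):
        assert not synthesize_spectrum([], axis).intensities.any()

    def test_two_lines_ten_fwhm_apart_mutual_tail(self, axis):
        fwhm = 1.5
        gap = 10 * hz_to_ppm(fwhm, 600.0)
        sigs = [LorentzianSignal(3.5, fwhm, 1.0), LorentzianSignal(3.5 + gap, fwhm, 1.0)]
        spec = synthesize_spectrum(sigs, axis)
        for c in (3.5, 3.5 + gap):
            peak = spec.intensities[ppm_to_bin(spec, c)]
            assert peak == pytest.approx(1.0, rel=0.011)  # mutual tail ~ 1/101
            assert peak > 1.0  # the neighbour's tail adds a little

    def test_center_outside_axis_rejected(self, axis):
        with pytest.raises(RangeError):
            synthesize_spectrum([LorentzianSignal(5.0, 1.5, 1.0)], axis)


class TestNormalize:
    def test_scale_divides_by_reporter_height(self, axis):
        entry = CompoundEntry(
            "c", reporter_ppm=3.5, response_factor=1.0,
            signals=[LorentzianSignal(3.5, 1.5, 250.0)],
        )
        norm, scale = normalize_calibration(entry, axis)
        assert scale == pytest.approx(250.0, rel=1e-9)
        assert norm.intensities[ppm_to_bin(norm, 3.5)] == 1.0

    def test_idempotent_on_normalized_input(self, axis):
        entry = CompoundEntry(
            "c", reporter_ppm=3.5, response_factor=1.0,
            signals=[LorentzianSignal(3.5, 1.5, 7.0)],
        )
        norm1, _ = normalize_calibration(entry, axis)
        again = CompoundEntry("c", reporter_ppm=3.5, response_factor=1.0, spectrum=norm1)
        norm2, scale2 = normalize_calibration(again, axis)
        assert scale2 == 1.0
        assert np.array_equal(norm1.intensities, norm2.intensities)

    def test_zero_reporter_height_rejected(self, axis):
        entry = CompoundEntry(
            "c", reporter_ppm=3.9, response_factor=1.0,
            spectrum=BinnedSpectrum(3.0, 0.0002, np.zeros(5001), 600.0),
        )
        with pytest.raises(LibraryError):
            normalize_calibration(entry, axis)


class TestCalibrationVector:
    def test_isolated_compound_gives_unit_basis(self, axis, separated_pair):
        lib, targets = separated_pair
        norm, _ = normalize_calibration(lib[0], axis)
        vec = calibration_vector(norm, [3.2, 3.9])
        assert vec[0] == 1.0
        assert vec[1] < 1e-5  # Lorentzian tail 0.7 ppm out: (hw/d)^2 ~ 3e-6

    def test_direct_lookup(self, axis):
        cal = np.zeros(axis.n_bins)
        cal[1000] = 1.0
        cal[2000] = 0.37
        norm = BinnedSpectrum(3.0, 0.0002, cal, 600.0)
        vec = calibration_vector(norm, [bin_to_ppm(norm, 2000)])
        assert vec[0] == 0.37

    def test_negative_baseline_clamped(self, axis):
        cal = np.zeros(axis.n_bins)
        cal[1000] = 1.0
        cal[2000] = -0.05
        norm = BinnedSpectrum(3.0, 0.0002, cal, 600.0)
        assert calibration_vector(norm, [bin_to_ppm(norm, 2000)])[0] == 0.0


class TestConstantMatrix:
    def test_separated_compounds_give_identity(self, axis, separated_pair):
        lib, targets = separated_pair
        m = build_constant_matrix(lib, targets, axis)
        assert np.allclose(m.values, np.eye(2), atol=1e-5)
        assert m.values[0, 0] == 1.0 and m.values[1, 1] == 1.0

    def test_one_way_interference_matrix(self, axis, triangular_pair):
        lib, targets = triangular_pair
        m = build_constant_matrix(lib, targets, axis)
        assert m.values.tolist() == [[1.0, 0.5], [0.0, 1.0]]

    def test_elements_in_unit_interval_for_preset(self, axis):
        from aquanmr.simulate import edta_plasma_preset

        cfg = edta_plasma_preset(1, seed=0)
        m = build_constant_matrix(cfg.library, cfg.make_targets(), cfg.make_axis())
        assert np.all(m.values >= 0.0) and np.all(m.values <= 1.0)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_misaligned_order_rejected(self, axis, separated_pair):
        lib, targets = separated_pair
        with pytest.raises(LibraryError):
            build_constant_matrix(lib, targets[::-1], axis)

    def test_duplicate_targets_warn(self, axis):
        lib = [
            CompoundEntry("a", reporter_ppm=3.5, response_factor=1.0,
                          signals=[LorentzianSignal(3.5, 1.5, 1.0)]),
            CompoundEntry("b", reporter_ppm=3.5, response_factor=1.0,
                          signals=[LorentzianSignal(3.5, 1.5, 1.0)]),
        ]
        targets = [TargetSignal("a", 3.5, 0.0002), TargetSignal("b", 3.5, 0.0002)]
        with pytest.warns(UserWarning, match="duplicate"):
            with pytest.raises(Exception):  # identical rows are also singular
                build_constant_matrix(lib, targets, axis)


def _edta_like(axis):
    lib = [
        CompoundEntry("met", reporter_ppm=3.614, response_factor=30.0,
                      signals=[LorentzianSignal(3.614, 1.5, 1.0)]),
        CompoundEntry(
            "edta", reporter_ppm=3.62, response_factor=None,
            signals=[LorentzianSignal(3.62, 1.5, 1.0), LorentzianSignal(3.23, 1.5, 0.95)],
            variability="variable", compound_class="nonmetabolite",
        ),
    ]
    targets = [
        TargetSignal("met", 3.614, 0.0002),
        TargetSignal("edta", 3.62, 0.003, "variable"),
    ]
    return lib, targets


def _obs(cid, ppm, fwhm, axis, found=True):
    return SignalObservation(
        compound_id=cid,
        apex_ppm=ppm,
        apex_bin=ppm_to_bin(axis, ppm),
        height=1.0,
        fwhm_hz=fwhm if found else None,
        found=found,
    )


class TestAdaptMatrix:
    def test_identity_observations_reproduce_constant_matrix(self, axis):
        lib, targets = _edta_like(axis)
        m0 = build_constant_matrix(lib, targets, axis)
        obs = {"edta": [_obs("edta", 3.62, 1.5, axis), _obs("edta", 3.23, 1.5, axis)]}
        m1, fb = adapt_matrix(m0, obs, lib, targets, axis)
        assert fb == []
        assert np.array_equal(m1.values, m0.values)
        assert np.array_equal(m1.target_ppm, m0.target_ppm)

    def test_shift_away_decreases_interference_element(self, axis):
        lib, targets = _edta_like(axis)
        m0 = build_constant_matrix(lib, targets, axis)
        shifted = 3.62 + 10 * axis.bin_width  # away from the 3.614 metabolite
        obs = {"edta": [_obs("edta", shifted, 1.5, axis), _obs("edta", 3.23, 1.5, axis)]}
        m1, _ = adapt_matrix(m0, obs, lib, targets, axis)
        assert m1.values[0, 1] < m0.values[0, 1]

    def test_constant_portion_copied_exactly(self, axis):
        lib, targets = _edta_like(axis)
        m0 = build_constant_matrix(lib, targets, axis)
        obs = {"edta": [_obs("edta", 3.622, 2.1, axis), _obs("edta", 3.228, 1.9, axis)]}
        m1, _ = adapt_matrix(m0, obs, lib, targets, axis)
        # the met<-met element is in neither the variable column nor row
        assert m1.values[0, 0] == m0.values[0, 0] == 1.0
        assert np.allclose(np.diag(m1.values), 1.0)

    def test_not_found_reporter_falls_back_and_flags(self, axis):
        lib, targets = _edta_like(axis)
        m0 = build_constant_matrix(lib, targets, axis)
        obs = {"edta": [_obs("edta", 3.62, None, axis, found=False),
                        _obs("edta", 3.23, 1.5, axis)]}
        m1, fb = adapt_matrix(m0, obs, lib, targets, axis)
        assert fb == ["edta"]
        assert np.array_equal(m1.values, m0.values)

    def test_missing_observations_rejected(self, axis):
        lib, targets = _edta_like(axis)
        m0 = build_constant_matrix(lib, targets, axis)
        with pytest.raises(LibraryError, match="edta"):
            adapt_matrix(m0, {}, lib, targets, axis)


class TestSamplingConsistency:
    def test_vector_matches_closed_form_within_half_percent(self, axis):
        sigs = [LorentzianSignal(3.45, 1.4, 2.0), LorentzianSignal(3.75, 1.8, 0.6)]
        entry = CompoundEntry("c", reporter_ppm=3.45, response_factor=1.0, signals=sigs)
        norm, scale = normalize_calibration(entry, axis)
        positions = [3.45, 3.46, 3.70, 3.75, 3.80]
        vec = calibration_vector(norm, positions)
        for p, v in zip(positions, vec):
            snapped = bin_to_ppm(axis, ppm_to_bin(axis, p))
            closed = lorentzian_heights(snapped, sigs, 600.0) / scale
            assert v == pytest.approx(closed, rel=0.005)


class TestLibraryIO:
    def test_json_round_trip(self, tmp_path):
        lib = [
            CompoundEntry(
                "edta_free", reporter_ppm=3.62, response_factor=None,
                signals=[LorentzianSignal(3.62, 1.5, 1.0), LorentzianSignal(3.23, 1.5, 0.95)],
                variability="variable", compound_class="nonmetabolite",
            ),
            CompoundEntry(
                "alanine", reporter_ppm=1.48, response_factor=55.0,
                signals=[LorentzianSignal(1.48, 1.3, 1.0)],
            ),
        ]
        p = tmp_path / "lib.json"
        save_library(lib, p)
        back = load_library(p)
        assert [e.compound_id for e in back] == ["edta_free", "alanine"]
        assert back[0].variability == "variable"
        assert back[0].signals == lib[0].signals
        assert back[1].response_factor == 55.0

    def test_spectrum_path_entries(self, tmp_path, axis):
        from aquanmr import write_binned_spectrum

        cal = synthesize_spectrum([LorentzianSignal(3.5, 1.5, 9.0)], axis)
        write_binned_spectrum(cal, tmp_path / "cal.csv")
        (tmp_path / "lib.json").write_text(json.dumps([
            {"compound_id": "c", "class": "metabolite", "variability": "constant",
             "reporter_ppm": 3.5, "response_factor_uM_per_unit": 10.0,
             "spectrum_path": "cal.csv"}
        ]))
        back = load_library(tmp_path / "lib.json")
        assert back[0].spectrum is not None
        assert back[0].spectrum.n_bins == axis.n_bins
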