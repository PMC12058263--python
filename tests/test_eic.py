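"""EIC extraction, peak detection, mass/envelope confirmation, re-quantification."""

import numpy as np
import pytest

from parti.chem import compose_species, isotope_envelope
from parti.eic import (
    EIC,
    ISOTOPE_SPACING,
    detect_peaks,
    envelope_agreement,
    extract_eic,
    flag_fragmentation_artifacts,
    requantify_peak,
    validate_peak,
)
from parti.lcms_io import Run, Spectrum

PHE_ADE_MZ = 415.1724


def gaussian_run(peaks, rt0=1.4, rt1=4.0, dt=0.01, with_m1=True,
                 m1_fraction=None, extra=()):
    """Hand-built run: each peak is (mz, rt_apex, area, sigma)."""
    species = compose_species(None, 0)  # for default m1 fraction fall-back
    times = np.arange(rt0, rt1 + 1e-9, dt)
    spectra = []
    for t in times:
        mzs, ints = [], []
        for mz, rt, area, sigma in peaks:
            h = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((t - rt) / sigma) ** 2)
            if h < 1e-9:
                continue
            mzs.append(mz)
            ints.append(h)
            if with_m1:
                frac = m1_fraction if m1_fraction is not None else 0.21
                mzs.append(mz + ISOTOPE_SPACING)
                ints.append(h * frac)
        for mz, inten in extra:
            mzs.append(mz)
            ints.append(inten)
        uniq, inv = np.unique(np.array(mzs), return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inv, np.array(ints))
        spectra.append(Spectrum(float(t), uniq, summed))
    return Run(spectra, mz_range=(100.0, 3000.0))


class TestExtractEIC:
    def test_window_arithmetic(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.0, 1000.0, 0.02)])
        eic = extract_eic(run, PHE_ADE_MZ, ppm_window=100.0)
        lo, hi = eic.window
        assert lo == pytest.approx(415.13088, abs=1e-4)
        assert hi == pytest.approx(415.21392, abs=1e-4)

    def test_empty_window_gives_zero_trace(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.0, 1000.0, 0.02)])
        eic = extract_eic(run, 600.0, ppm_window=100.0)
        assert np.all(eic.intensities == 0)

    def test_target_outside_acquisition_range(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.0, 1000.0, 0.02)])
        with pytest.raises(ValueError, match="outside acquisition range"):
            extract_eic(run, 5000.0)

    def test_trace_integral_matches_injected_area(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.5, 12345.0, 0.02)], with_m1=False)
        eic = extract_eic(run, PHE_ADE_MZ)
        assert eic.integral == pytest.approx(12345.0, rel=0.01)

    def test_summed_eic_never_exceeds_tic(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.0, 1000.0, 0.02),
                            (556.2766, 3.0, 500.0, 0.02)])
        total = sum(extract_eic(run, mz).integral * 0  # integral is in min units
                    + extract_eic(run, mz).intensities.sum()
                    for mz in (PHE_ADE_MZ, 556.2766))
        tic = run.total_ion_current
        assert total <= tic + 1e-6


class TestDetectPeaks:
    def test_flat_zero_trace_empty(self):
        eic = EIC(400.0, (399.9, 400.1), np.linspace(1, 2, 50), np.zeros(50))
        assert detect_peaks(eic) == []

    def test_too_few_points(self):
        eic = EIC(400.0, (399.9, 400.1), np.array([1, 2, 3.0]), np.zeros(3))
        with pytest.raises(ValueError, match="at least 5"):
            detect_peaks(eic)

    def test_two_isomer_peaks_resolved(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.9, 1000.0, 0.02),
                            (PHE_ADE_MZ, 3.1, 800.0, 0.02)])
        peaks = detect_peaks(extract_eic(run, PHE_ADE_MZ), noise_floor=10.0)
        assert len(peaks) == 2
        assert peaks[0].apex_rt == pytest.approx(2.9, abs=0.011)
        assert peaks[1].apex_rt == pytest.approx(3.1, abs=0.011)

    def test_single_peak_area_within_one_percent(self):
        run = gaussian_run([(PHE_ADE_MZ, 2.5, 5000.0, 0.02)], with_m1=False)
        peaks = detect_peaks(extract_eic(run, PHE_ADE_MZ), noise_floor=1.0)
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(5000.0, rel=0.01)

    def test_translation_equivariance(self):
        base = extract_eic(gaussian_run([(PHE_ADE_MZ, 2.5, 5000.0, 0.02)]),
                           PHE_ADE_MZ)
        shifted = EIC(base.target_mz, base.window, base.times + 0.5,
                      base.intensities.copy())
        p0 = detect_peaks(base, noise_floor=1.0)
        p1 = detect_peaks(shifted, noise_floor=1.0)
        assert len(p0) == len(p1) == 1
        assert p1[0].apex_rt == pytest.approx(p0[0].apex_rt + 0.5, abs=1e-9)
        assert p1[0].area == pytest.approx(p0[0].area, rel=1e-9)


class TestValidatePeak:
    def _one_peak(self, run, mz):
        peaks = detect_peaks(extract_eic(run, mz), noise_floor=1.0)
        assert len(peaks) == 1
        return peaks[0]

    def test_exact_mass_validates(self):
        species = compose_species(None, 0)
        mz = species.protonated_mz
        # 0.125 is adenosine's predicted M+1/M ratio
        run = gaussian_run([(mz, 2.0, 5000.0, 0.02)], m1_fraction=0.125)
        p = validate_peak(run, self._one_peak(run, mz), species)
        assert p.mass_error_ppm == pytest.approx(0.0, abs=0.5)
        assert p.validated

    def test_five_ppm_boundary_rejects(self):
        species = compose_species(None, 0)
        theo = species.protonated_mz
        off = theo * (1 + 5.06e-6)  # just past the 5 ppm gate
        run = gaussian_run([(off, 2.0, 5000.0, 0.02)], m1_fraction=0.125)
        peaks = detect_peaks(extract_eic(run, theo), noise_floor=1.0)
        p = validate_peak(run, peaks[0], species)
        assert p.mass_error_ppm == pytest.approx(5.06, abs=0.1)
        assert not p.validated

    def test_missing_m1_line_fails_envelope(self):
        species = compose_species(None, 0)
        mz = species.protonated_mz
        run = gaussian_run([(mz, 2.0, 5000.0, 0.02)], with_m1=False)
        p = validate_peak(run, self._one_peak(run, mz), species)
        assert p.envelope_score == 0.0
        assert not p.validated

    def test_envelope_agreement_scale(self):
        assert envelope_agreement(0.125, 0.125) == 1.0
        assert envelope_agreement(0.25, 0.125) == 0.0
        assert envelope_agreement(0.1875, 0.125) == pytest.approx(0.5)


class TestRequantify:
    def test_nested_windows_agree_when_centroids_exact(self):
        species = compose_species(None, 0)
        mz = species.protonated_mz
        run = gaussian_run([(mz, 2.0, 5000.0, 0.02)], m1_fraction=0.125)
        p = detect_peaks(extract_eic(run, mz), noise_floor=1.0)[0]
        p = validate_peak(run, p, species)
        q = requantify_peak(run, p)
        assert q.area == pytest.approx(p.area, rel=1e-3)

    def test_interference_outside_narrow_window_removed(self):
        species = compose_species(None, 0)
        mz = species.protonated_mz
        interf = mz * (1 + 60e-6)  # 60 ppm away: inside discovery, outside requant
        run = gaussian_run([(mz, 2.0, 5000.0, 0.02),
                            (interf, 2.0, 300.0, 0.02)], m1_fraction=0.125)
        p = detect_peaks(extract_eic(run, mz), noise_floor=1.0)[0]
        p = validate_peak(run, p, species)
        assert p.validated  # small interference shifts the mean < 5 ppm
        q = requantify_peak(run, p)
        assert q.area < p.area
        assert q.area == pytest.approx(5000.0, rel=0.02)

    def test_large_interference_defeats_validation(self):
        # a big co-extracted interferent corrupts the weighted-mean apex
        # m/z past the 5 ppm gate, so the peak is (correctly) rejected
        species = compose_species(None, 0)
        mz = species.protonated_mz
        run = gaussian_run([(mz, 2.0, 5000.0, 0.02),
                            (mz * (1 + 60e-6), 2.0, 2000.0, 0.02)],
                           m1_fraction=0.125)
        p = detect_peaks(extract_eic(run, mz), noise_floor=1.0)[0]
        p = validate_peak(run, p, species)
        assert not p.validated
        assert p.mass_error_ppm > 5.0

    def test_empty_narrow_trace_falls_back_with_warning(self):
        species = compose_species(None, 0)
        mz = species.protonated_mz
        run = gaussian_run([(mz, 2.0, 5000.0, 0.02)], m1_fraction=0.125)
        p = detect_peaks(extract_eic(run, mz), noise_floor=1.0)[0]
        p = validate_peak(run, p, species)
        # pretend the observed centroid sits far from any signal
        from dataclasses import replace
        p = replace(p, apex_mz_observed=mz * (1 + 500e-6))
        with pytest.warns(UserWarning, match="empty"):
            q = requantify_peak(run, p)
        assert q.area == p.area


def test_fragmentation_overlap_flagging():
    from parti.eic import ChromatographicPeak

    mk = lambda lo, hi, ok=True: ChromatographicPeak(
        apex_rt=(lo + hi) / 2, rt_lo=lo, rt_hi=hi, area=1.0,
        apex_intensity=1.0, target_mz=268.104, validated=ok)
    ade = [mk(1.0, 1.2), mk(2.9, 3.1)]
    acyl = [mk(2.95, 3.15)]
    flagged = flag_fragmentation_artifacts(ade, acyl)
    assert [p.fragmentation_artifact for p in flagged] == [False, True]
    # unvalidated acyl peaks don't flag anything
    flagged = flag_fragmentation_artifacts(ade, [mk(2.95, 3.15, ok=False)])
    assert not any(p.fragmentation_artifact for p in flagged)
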