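"""Processing chain: apodization/zero-fill/FT, phasing, baseline,
referencing, alignment, and end-to-end quantitative sanity."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import curve_fit

from citrusnmr import (
    HIGH_FIELD_SCHEME,
    ExtractComposition,
    ProcessingParams,
    synthesize_fid,
)
from citrusnmr.processing import (
    ReferencingError,
    _apply_phase,
    align_spectra,
    apodize_zerofill_transform,
    baseline_correct,
    phase_correct,
    process_fid,
    reference_spectrum,
)
from citrusnmr.quantify import integrate_window
from citrusnmr.simulate import composition_for_ratio
from citrusnmr.types import Singlet, SpinSignal


def _lorentzian(f, amp, f0, fwhm):
    return amp * (fwhm / 2) ** 2 / ((f - f0) ** 2 + (fwhm / 2) ** 2)


@pytest.fixture(scope="module")
def mixture_fid(small_scheme):
    comp = dataclasses.replace(composition_for_ratio(8.0), shift_jitter_scale=0.0)
    return synthesize_fid(comp, small_scheme, noise_sd=0.01, seed=3)


@pytest.fixture(scope="module")
def mixture_spectrum(mixture_fid):
    return apodize_zerofill_transform(
        mixture_fid, ProcessingParams(zero_fill_to=8192)
    )


class TestApodizeZerofillTransform:
    def test_output_length_is_zero_fill_size(self):
        """32 K acquisition zero-filled to 64 K points."""
        comp = composition_for_ratio(8.0)
        fid = synthesize_fid(comp, HIGH_FIELD_SCHEME, noise_sd=0.0, seed=0)
        assert fid.complex_signal.size == 32768
        spec = apodize_zerofill_transform(fid, ProcessingParams(zero_fill_to=65536))
        assert spec.n_points == 65536

    def test_zero_lb_is_plain_transform(self, singlet_fid):
        a = apodize_zerofill_transform(
            singlet_fid, ProcessingParams(zero_fill_to=8192, exponential_lb=0.0)
        )
        x = singlet_fid.complex_signal.copy()
        x = np.concatenate([x, np.zeros(8192 - x.size, dtype=complex)])
        x[0] *= 0.5
        ref = np.fft.fftshift(np.fft.fft(x))[::-1]
        np.testing.assert_allclose(a.real_part, ref.real, rtol=0, atol=1e-9)

    def test_apodization_adds_lorentzian_width(self):
        """0.3 Hz exponential window on a 1.0 Hz natural line gives a
        1.3 Hz Lorentzian within 5% (closed-form convolution).  Needs a
        long enough acquisition that the decay is fully sampled."""
        scheme = dataclasses.replace(HIGH_FIELD_SCHEME, n_points=16384, n_scans=1)
        comp = ExtractComposition(10.0, 0, 0, 0, shift_jitter_scale=0.0)
        line = [SpinSignal("sucrose", 5.40, Singlet(), 1)]
        fid = synthesize_fid(comp, scheme, line_list=line, noise_sd=0.0, seed=0)
        spec = apodize_zerofill_transform(
            fid, ProcessingParams(zero_fill_to=32768, exponential_lb=0.3)
        )
        mhz = spec.scheme.spectrometer_frequency
        sel = np.abs(spec.ppm_axis - 5.40) < 0.03
        x = spec.ppm_axis[sel] * mhz
        y = spec.real_part[sel]
        p, _ = curve_fit(_lorentzian, x, y, p0=[y.max(), 5.40 * mhz, 1.0])
        assert p[2] == pytest.approx(1.3, rel=0.05)

    def test_rejects_zero_fill_smaller_than_data(self, singlet_fid):
        with pytest.raises(ValueError):
            apodize_zerofill_transform(singlet_fid, ProcessingParams(zero_fill_to=2048))

    def test_zero_filling_preserves_energy(self, mixture_fid):
        """Parseval: spectral energy equals time-domain energy whatever
        the zero-fill size (up to the first-point convention)."""
        e_time = np.sum(np.abs(mixture_fid.complex_signal) ** 2)
        for nzf in (4096, 8192, 16384):
            params = ProcessingParams(zero_fill_to=nzf, exponential_lb=0.0)
            spec = apodize_zerofill_transform(mixture_fid, params)
            e_freq = np.sum(spec.real_part**2 + spec.imag_part**2) / nzf
            assert e_freq == pytest.approx(e_time, rel=0.01)

    def test_history_records_each_step(self, mixture_spectrum):
        steps = [h["step"] for h in mixture_spectrum.history]
        assert steps == ["apodize", "zero_fill", "fourier_transform"]


class TestPhaseCorrect:
    def test_fixed_zero_is_identity(self, mixture_spectrum):
        out = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        np.testing.assert_allclose(out.real_part, mixture_spectrum.real_part)

    def test_auto_on_absorption_spectrum_is_near_zero(self, mixture_spectrum):
        out = phase_correct(mixture_spectrum, "auto")
        h = out.history[-1]
        assert abs(h["ph0_deg"]) <= 1.0

    @pytest.mark.parametrize("ph0,ph1", [(25.0, 40.0), (-60.0, 0.0), (130.0, -35.0)])
    def test_recovers_known_dephasing(self, mixture_spectrum, ph0, ph1):
        """Known (ph0, ph1) dephasing recovered within 2 and 10 degrees."""
        spoiled = mixture_spectrum.copy()
        spoiled.real_part, spoiled.imag_part = _apply_phase(
            mixture_spectrum.real_part, mixture_spectrum.imag_part, ph0, ph1
        )
        out = phase_correct(spoiled, "auto")
        h = out.history[-1]
        assert abs(h["ph0_deg"] + ph0) <= 2.0
        assert abs(h["ph1_deg"] + ph1) <= 10.0

    def test_requires_imaginary_part(self, mixture_spectrum):
        real_only = mixture_spectrum.copy()
        real_only.imag_part = None
        with pytest.raises(ValueError):
            phase_correct(real_only, "auto")


class TestBaselineCorrect:
    def test_flat_baseline_unchanged(self, mixture_spectrum):
        phased = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        out = baseline_correct(phased, "iterative")
        scale = np.abs(phased.real_part).max()
        assert np.abs(out.real_part - phased.real_part).max() <= 0.01 * scale

    def test_removes_injected_linear_ramp(self, mixture_spectrum):
        phased = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        peak = phased.real_part.max()
        ramped = phased.copy()
        ramped.real_part = phased.real_part + np.linspace(0, 0.05 * peak, phased.n_points)
        out = baseline_correct(ramped, "iterative")
        assert np.abs(out.real_part - phased.real_part).max() <= 0.01 * peak

    def test_none_mode_is_noop_with_record(self, mixture_spectrum):
        out = baseline_correct(mixture_spectrum, "none")
        np.testing.assert_array_equal(out.real_part, mixture_spectrum.real_part)
        assert out.history[-1] == {"step": "baseline", "mode": "none"}

    def test_polynomial_mode(self, mixture_spectrum):
        out = baseline_correct(mixture_spectrum, ("polynomial", 1))
        assert out.history[-1]["order"] == 1


class TestReferenceSpectrum:
    def test_peak_already_at_target_zero_shift(self, singlet_fid):
        spec = apodize_zerofill_transform(singlet_fid, ProcessingParams(zero_fill_to=8192))
        out = reference_spectrum(spec, target=5.40, search_window=(5.30, 5.50))
        assert abs(out.history[-1]["shift_ppm"]) <= spec.digital_resolution

    def test_shift_arithmetic(self, small_scheme):
        comp = ExtractComposition(10.0, 0, 0, 0, shift_jitter_scale=0.0)
        line = [SpinSignal("sucrose", 5.30, Singlet(), 1)]
        fid = synthesize_fid(comp, small_scheme, line_list=line, noise_sd=0.0, seed=0)
        spec = apodize_zerofill_transform(fid, ProcessingParams(zero_fill_to=8192))
        out = reference_spectrum(spec, target=5.22, search_window=(5.20, 5.40))
        assert out.history[-1]["shift_ppm"] == pytest.approx(-0.08, abs=2 * spec.digital_resolution)

    def test_alpha_glucose_lands_on_target(self):
        """After the full chain the alpha-glucose doublet centre sits at
        5.22 ppm within one digital resolution step."""
        comp = dataclasses.replace(composition_for_ratio(8.0), shift_jitter_scale=0.005)
        fid = synthesize_fid(comp, HIGH_FIELD_SCHEME, noise_sd=0.01, seed=5)
        spec = process_fid(fid, ProcessingParams(
            phase_mode=("fixed", 0.0, 0.0), baseline_mode="none"))
        sel = np.abs(spec.ppm_axis - 5.22) < 0.05
        w = np.clip(spec.real_part[sel], 0, None)
        mask = w >= 0.3 * w.max()
        centroid = np.sum(spec.ppm_axis[sel][mask] * w[mask]) / np.sum(w[mask])
        assert abs(centroid - 5.22) <= 2 * spec.digital_resolution

    def test_no_peak_raises_referencing_error(self, singlet_fid):
        spec = apodize_zerofill_transform(singlet_fid, ProcessingParams(zero_fill_to=8192))
        with pytest.raises(ReferencingError):
            reference_spectrum(spec, target=3.0, search_window=(2.9, 3.1))


class TestAlignment:
    def test_identical_spectra_zero_shifts(self, mixture_spectrum):
        phased = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        out = align_spectra([phased, phased.copy(), phased.copy()])
        for s in out:
            assert s.history[-1]["shifts_ppm"] == [0.0]

    def test_recovers_injected_displacement(self, mixture_spectrum):
        phased = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        res = phased.digital_resolution
        lag = int(round(0.02 / res))
        displaced = phased.copy()
        displaced.real_part = np.roll(phased.real_part, lag)
        out = align_spectra([phased, phased.copy(), displaced], max_shift=0.05)
        shift = out[2].history[-1]["shifts_ppm"][0]
        assert abs(abs(shift) - lag * res) <= res
        # aligned intensities match the undisplaced spectrum
        core = slice(2 * lag, -2 * lag)
        np.testing.assert_allclose(
            out[2].real_part[core], phased.real_part[core],
            atol=0.02 * phased.real_part.max(),
        )

    def test_alignment_preserves_marker_integrals(self, mixture_spectrum):
        """Round trip: displacement then alignment changes the sucrose
        window integral by < 1%."""
        phased = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        truth = integrate_window(phased, (5.54, 5.32))
        lag = int(round(0.02 / phased.digital_resolution))
        displaced = phased.copy()
        displaced.real_part = np.roll(phased.real_part, lag)
        out = align_spectra([phased, phased.copy(), displaced], max_shift=0.05)
        after = integrate_window(out[2], (5.54, 5.32))
        assert after == pytest.approx(truth, rel=0.01)

    def test_conserves_total_intensity(self, mixture_spectrum):
        phased = phase_correct(mixture_spectrum, ("fixed", 0.0, 0.0))
        lag = int(round(0.01 / phased.digital_resolution))
        displaced = phased.copy()
        displaced.real_part = np.roll(phased.real_part, lag)
        out = align_spectra([phased, phased.copy(), displaced], max_shift=0.05)
        assert np.sum(out[2].real_part) == pytest.approx(
            np.sum(displaced.real_part), rel=1e-3
        )

    def test_needs_common_grid(self, mixture_spectrum):
        other = mixture_spectrum.copy()
        other.ppm_axis = other.ppm_axis + 0.01
        with pytest.raises(ValueError):
            align_spectra([mixture_spectrum, other])

    def test_needs_two_spectra(self, mixture_spectrum):
        with pytest.raises(ValueError):
            align_spectra([mixture_spectrum])


class TestEndToEnd:
    def test_processing_is_purely_functional(self, mixture_fid, fast_params):
        a = process_fid(mixture_fid, fast_params)
        b = process_fid(mixture_fid, fast_params)
        assert np.array_equal(a.real_part, b.real_part)
        assert np.array_equal(a.ppm_axis, b.ppm_axis)

    def test_integral_proportional_to_amount(self, small_scheme):
        """Noise-free single resonance: window integral scales exactly
        with amount x proton_count (two compositions within 0.5%)."""
        line = [SpinSignal("sucrose", 5.40, Singlet(), 1)]
        integrals = []
        for amount in (10.0, 25.0):
            comp = ExtractComposition(amount, 0, 0, 0, shift_jitter_scale=0.0)
            fid = synthesize_fid(comp, small_scheme, line_list=line, noise_sd=0.0, seed=0)
            spec = apodize_zerofill_transform(fid, ProcessingParams(zero_fill_to=8192))
            integrals.append(integrate_window(spec, (5.54, 5.32)))
        assert integrals[1] / integrals[0] == pytest.approx(2.5, rel=0.005)
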