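"""Axial-response models: normalization, parameter monotonicities, closed
forms, quadrature convergence, and the cross-method sectioning ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optisect.axial import (
    axial_response,
    fwhm_of_curve,
    reference_params,
    response_confocal,
    response_light_sheet,
    response_limo,
    response_modulated,
    response_two_photon,
    sectioning_ranking,
    sinc,
)
from optisect.config import MethodParams
from optisect.pupil import make_otf_grid, otf_defocused


def fwhm(params, otf, **kw):
    return axial_response(params, otf, **kw).fwhm if not kw else None


class TestFWHMExtraction:
    def test_gaussian_closed_form(self):
        u = np.linspace(-20, 20, 2001)
        sigma = 2.5
        y = np.exp(-(u**2) / (2 * sigma**2))
        expected = 2 * sigma * np.sqrt(2 * np.log(2))
        assert fwhm_of_curve(u, y) == pytest.approx(expected, rel=1e-4)

    def test_no_crossing_raises(self):
        u = np.linspace(-1, 1, 11)
        with pytest.raises(ValueError, match="half maximum"):
            fwhm_of_curve(u, np.ones_like(u))


class TestConfocal:
    def test_unit_peak_and_nonnegative(self, otf):
        curve = response_confocal(MethodParams(method="confocal_pinhole", beta=0.5), otf)
        assert curve.intensity[np.argmin(np.abs(curve.u_grid))] == pytest.approx(1.0)
        assert np.all(curve.intensity >= -1e-12)

    def test_pinhole_size_monotonicity(self, otf):
        widths = [
            response_confocal(MethodParams(method="confocal_pinhole", beta=b), otf).fwhm
            for b in (0.2, 0.5, 1.0, 2.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(widths, widths[1:]))

    def test_pinhole_beats_slit(self, otf):
        pin = response_confocal(MethodParams(method="confocal_pinhole", beta=0.5), otf)
        slit = response_confocal(MethodParams(method="confocal_slit", beta=0.5), otf)
        assert pin.fwhm < slit.fwhm

    def test_empty_u_grid_rejected(self):
        from optisect.pupil import OTFGrid

        empty = OTFGrid(
            s_grid=np.linspace(0, 2, 5),
            u_grid=np.array([]),
            values=np.zeros((5, 0)),
        )
        with pytest.raises(ValueError, match="empty"):
            response_confocal(MethodParams(method="confocal_pinhole", beta=0.5), empty)


class TestTwoPhoton:
    def test_pinhole_tightens_response(self, otf):
        params = MethodParams(method="two_photon")
        bare = response_two_photon(params, otf)
        pinholed = response_two_photon(params, otf, pinhole_beta=0.5)
        assert pinholed.fwhm <= bare.fwhm + 1e-9

    def test_wider_than_ideal_confocal(self, otf):
        # unconstrained detection costs sectioning relative to a pinhole
        tp = response_two_photon(MethodParams(method="two_photon"), otf)
        conf = response_confocal(
            MethodParams(method="confocal_pinhole", beta=0.05), otf
        )
        assert tp.fwhm > conf.fwhm


class TestModulated:
    def test_structured_is_normalized_otf_slice(self, otf):
        curve = response_modulated(MethodParams(method="structured", s0=1.0), otf)
        expected = np.abs(otf_defocused(1.0, curve.u_grid))
        expected /= expected[np.argmin(np.abs(curve.u_grid))]
        assert np.allclose(curve.intensity, expected, atol=5e-3)

    def test_half_cutoff_is_the_optimum_frequency(self, otf):
        widths = {
            s0: response_modulated(MethodParams(method="structured", s0=s0), otf).fwhm
            for s0 in (0.3, 0.7, 1.0, 1.5, 1.9)
        }
        assert min(widths, key=widths.get) == 1.0

    def test_hybrid_bandwidth_tunes_sectioning(self, otf):
        # s_max pinned at the cutoff; narrowing the band toward the optimum
        # modulation frequency (half the cutoff) sharpens the response, and
        # the bandwidth is an effective tuning knob throughout
        widths = {
            bw: response_modulated(
                MethodParams(method="hybrid", s_min=2.0 - bw, s_max=2.0), otf
            ).fwhm
            for bw in (2.0, 1.5, 1.0, 0.5)
        }
        assert widths[2.0] > widths[1.5] > widths[1.0]
        # near-cutoff-only bands lose sectioning again: frequencies close to
        # the cutoff decay slowly with defocus, so the knob is non-monotone
        assert widths[0.5] > widths[1.0]

    def test_degenerate_hybrid_band_rejected(self, otf):
        with pytest.raises(ValueError, match="structured"):
            response_modulated(
                MethodParams(method="hybrid", s_min=1.0, s_max=1.0), otf
            )


class TestLightSheet:
    def test_half_maximum_at_c_sqrt_2ln2(self, otf):
        c = 1.3
        curve = response_light_sheet(MethodParams(method="light_sheet", c=c), otf)
        u_half = c * np.sqrt(2 * np.log(2))
        val = np.interp(u_half, curve.u_grid, curve.intensity)
        assert val == pytest.approx(0.5, abs=5e-3)

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(min_value=0.4, max_value=5.0))
    def test_fwhm_closed_form(self, c):
        otf = make_otf_grid(n_s=5, n_u=801, u_max=40.0)
        curve = response_light_sheet(MethodParams(method="light_sheet", c=c), otf)
        assert curve.fwhm == pytest.approx(2 * c * np.sqrt(2 * np.log(2)), rel=5e-3)

    def test_thinner_sheet_sections_better(self, otf):
        f = lambda c: response_light_sheet(
            MethodParams(method="light_sheet", c=c), otf
        ).fwhm
        assert f(0.5) < f(1.0)


class TestLiMo:
    def test_sharper_than_line_confocal(self, otf):
        limo = response_limo(MethodParams(method="limo", b=0.0, beta=0.5), otf)
        lc = response_confocal(
            MethodParams(method="line_confocal", b=0.0, beta=0.5), otf
        )
        assert limo.fwhm < lc.fwhm

    def test_value_against_refined_quadrature(self, otf):
        # independent fine-grid quadrature of the same integrand at u = 5
        params = MethodParams(method="limo", b=0.0, beta=0.5)
        curve = response_limo(params, otf)
        got = np.interp(5.0, curve.u_grid, curve.intensity)

        s = np.linspace(0.0, 2.0, 4097)
        w = sinc(params.beta * s) * (1.0 - np.cos(2 * params.beta * s))

        def integral(u):
            t2 = otf_defocused(s, u) ** 2
            return np.trapezoid(w * t2, s)

        ref = integral(5.0) / integral(0.0)
        assert got == pytest.approx(ref, rel=1e-2)


class TestGridConvergence:
    def test_fwhm_stable_under_refinement(self):
        coarse = make_otf_grid(n_s=257, n_u=401)
        fine = make_otf_grid(n_s=513, n_u=801)
        for params in (
            MethodParams(method="confocal_pinhole", beta=0.5),
            MethodParams(method="limo", beta=0.5),
            MethodParams(method="structured", s0=1.0),
        ):
            f_c = axial_response(params, coarse).fwhm
            f_f = axial_response(params, fine).fwhm
            assert f_c == pytest.approx(f_f, rel=5e-3)


class TestSectioningRanking:
    def test_reference_order(self, cfg, otf):
        order = [m for m, _ in sectioning_ranking(cfg, otf=otf)]
        assert order[0] == "light_sheet"
        assert order[1] == "limo"
        assert order[2] == "confocal"
        assert set(order[3:5]) == {"structured", "hybrid"}
        assert order[5] == "two_photon"
        assert order[6] == "line_confocal"

    def test_single_method_returns_itself(self, cfg, otf):
        only = {"confocal": MethodParams(method="confocal_pinhole", beta=0.5)}
        assert [m for m, _ in sectioning_ranking(cfg, only, otf=otf)] == ["confocal"]

    def test_empty_set_rejected(self, cfg, otf):
        with pytest.raises(ValueError, match="at least one"):
            sectioning_ranking(cfg, {}, otf=otf)

    def test_curves_decay_into_the_tails(self, cfg, otf):
        for params in reference_params(cfg).values():
            curve = axial_response(params, otf)
            edge = max(curve.intensity[0], curve.intensity[-1])
            assert edge < 0.5
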