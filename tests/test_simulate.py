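"""Scan-simulator forward model: linearity, determinism, shift equivariance,
aperture conservation, illumination/detection-mask duality, and agreement
with the analytic axial-response theory."""

import dataclasses

import numpy as np
import pytest

from optisect.axial import axial_response
from optisect.config import MethodParams, OpticalConfig, ScanConfig
from optisect.phantoms import SampleVolume, fluorescent_sheet, point_source
from optisect.pupil import make_otf_grid, optical_coordinate
from optisect.simulate import (
    illumination_mask_equivalence,
    prepare_kernels,
    simulate_full_aperture,
    simulate_plane,
    simulate_volume,
    widefield_equivalent,
)

SHAPE = (9, 64, 64)
VOXEL = (0.5, 0.1, 0.1)


@pytest.fixture(scope="module")
def point_stack(cfg, fine_scan):
    ps = point_source((4, 32, 32), SHAPE, VOXEL)
    return ps, simulate_plane(ps, cfg, fine_scan, plane_z=0.0)


class TestBasicContracts:
    def test_zero_volume_gives_zero_stack(self, cfg, fine_scan):
        vol = SampleVolume(values=np.zeros(SHAPE, np.float32), voxel=VOXEL)
        stack = simulate_plane(vol, cfg, fine_scan, plane_z=0.0)
        assert not stack.images.any()

    def test_images_nonnegative_and_shaped(self, point_stack):
        _, stack = point_stack
        assert stack.images.shape == (6, 64, 64)
        assert np.all(stack.images >= 0)

    def test_scan_step_must_match_voxel(self, cfg):
        vol = point_source((4, 32, 32), SHAPE, VOXEL)
        bad = ScanConfig(pitch=0.3, scan_step=0.2, noise="none")
        with pytest.raises(ValueError, match="scan step"):
            simulate_plane(vol, cfg, bad, plane_z=0.0)

    def test_mismatched_kernels_rejected(self, cfg, fine_scan):
        vol = point_source((4, 32, 32), SHAPE, VOXEL)
        kern = prepare_kernels(vol, cfg, fine_scan, 0.0)
        other = point_source((2, 16, 16), (5, 32, 32), VOXEL)
        with pytest.raises(ValueError, match="kernels"):
            simulate_plane(other, cfg, fine_scan, plane_z=0.0, kernels=kern)

    def test_plane_outside_volume_rejected(self, cfg, fine_scan):
        vol = point_source((4, 32, 32), SHAPE, VOXEL)
        with pytest.raises(ValueError, match="axial range"):
            simulate_plane(vol, cfg, fine_scan, plane_z=50.0)


class TestPhysics:
    def test_point_source_image_is_kernel_section(self, cfg, fine_scan, point_stack):
        ps, stack = point_stack
        kern = prepare_kernels(ps, cfg, fine_scan, 0.0)
        # delta at the volume centre: image = kernel slice at that z offset
        for n in range(6):
            expected = kern.kernels[4, n]
            got = stack.images[n]
            assert np.abs(got - expected).max() <= 1e-5 * expected.max()

    def test_in_focus_point_intensity_falls_off_axis(self, point_stack):
        _, stack = point_stack
        centre = [im[32, 32] for im in stack.images]
        # symmetric layout: lines 3,4 brightest, 1,6 dimmest
        assert centre[2] > centre[1] > centre[0]
        assert centre[3] > centre[4] > centre[5]

    def test_deep_sheet_washes_out_off_axis_modulation(self, cfg, fine_scan):
        sheet = fluorescent_sheet(4.0, (17, 64, 64), VOXEL)
        stack = simulate_plane(sheet, cfg, fine_scan, plane_z=0.0)
        means = stack.images.mean(axis=(1, 2))
        assert (means.max() - means.min()) / means.mean() < 0.10

    def test_in_focus_sheet_keeps_modulation(self, cfg, fine_scan):
        sheet = fluorescent_sheet(0.0, (17, 64, 64), VOXEL)
        stack = simulate_plane(sheet, cfg, fine_scan, plane_z=0.0)
        means = stack.images.mean(axis=(1, 2))
        assert means[2] > 3 * means[0]

    def test_linearity_without_noise(self, cfg, fine_scan, rng):
        a = SampleVolume(
            values=rng.random(SHAPE).astype(np.float32), voxel=VOXEL
        )
        b = SampleVolume(
            values=rng.random(SHAPE).astype(np.float32), voxel=VOXEL
        )
        combo = SampleVolume(values=2.5 * a.values + b.values, voxel=VOXEL)
        kern = prepare_kernels(a, cfg, fine_scan, 0.0)
        ia = simulate_plane(a, cfg, fine_scan, 0.0, kernels=kern).images
        ib = simulate_plane(b, cfg, fine_scan, 0.0, kernels=kern).images
        ic = simulate_plane(combo, cfg, fine_scan, 0.0, kernels=kern).images
        assert np.allclose(ic, 2.5 * ia + ib, atol=1e-5 * ic.max())

    def test_shift_equivariance_along_scan_axis(self, cfg, fine_scan):
        a = point_source((4, 32, 24), SHAPE, VOXEL)
        b = point_source((4, 32, 40), SHAPE, VOXEL)
        kern = prepare_kernels(a, cfg, fine_scan, 0.0)
        ia = simulate_plane(a, cfg, fine_scan, 0.0, kernels=kern).images
        ib = simulate_plane(b, cfg, fine_scan, 0.0, kernels=kern).images
        assert np.allclose(np.roll(ia, 16, axis=2), ib, atol=1e-6 * ia.max())


class TestNoise:
    def test_noise_is_seed_deterministic(self, cfg):
        vol = point_source((4, 32, 32), SHAPE, VOXEL)
        scan = ScanConfig(
            pitch=0.3, scan_step=0.1, pixel_width=0.3,
            noise="poisson+gaussian", photons_per_unit=500.0, seed=11,
        )
        kern = prepare_kernels(vol, cfg, scan, 0.0)
        a = simulate_plane(vol, cfg, scan, 0.0, kernels=kern).images
        b = simulate_plane(vol, cfg, scan, 0.0, kernels=kern).images
        assert np.array_equal(a, b)
        scan2 = dataclasses.replace(scan, seed=12)
        c = simulate_plane(vol, cfg, scan2, 0.0, kernels=kern).images
        assert not np.array_equal(a, c)


class TestApertureIdentities:
    def test_widefield_equivalent_is_elementwise_sum(self, point_stack):
        _, stack = point_stack
        assert np.allclose(
            widefield_equivalent(stack), stack.images.sum(axis=0), atol=0
        )

    def test_sum_matches_direct_full_aperture_simulation(self, cfg, fine_scan, point_stack):
        ps, stack = point_stack
        direct = simulate_full_aperture(ps, cfg, fine_scan, plane_z=0.0)
        wf = widefield_equivalent(stack)
        assert np.abs(wf - direct).max() / direct.max() < 0.01

    def test_sum_broader_than_central_line(self, point_stack):
        _, stack = point_stack
        wf = widefield_equivalent(stack)
        row_wf = wf[32]
        row_c = stack.images[2][32]

        def width(prof):
            above = np.where(prof >= prof.max() / 2)[0]
            return above[-1] - above[0]

        assert width(row_wf) >= width(row_c)

    def test_illumination_mask_duality(self, cfg):
        # patterned illumination + uniform detection vs uniform illumination
        # + detection-side mask: interior agreement within 1% on a
        # y-invariant phantom (edges differ only by padding roll-off)
        scan = ScanConfig(pitch=0.3, scan_step=0.1, pixel_width=0.3, noise="none")
        rng = np.random.default_rng(5)
        profile = np.zeros((5, 64, 64), np.float32)
        profile[:, :, 16:48] = rng.random((5, 1, 32)).astype(np.float32)
        vol = SampleVolume(values=profile, voxel=VOXEL)
        weights = np.array([0.2, 0.5, 1.0, 1.0, 0.5, 0.2])
        img_a, img_b = illumination_mask_equivalence(vol, cfg, scan, weights)
        interior = np.s_[20:44, :]
        scale = np.abs(img_b[interior]).max()
        assert np.abs(img_a[interior] - img_b[interior]).max() / scale < 0.01


class TestVolumeScanning:
    def test_single_plane_equals_simulate_plane(self, cfg, fine_scan):
        vol = point_source((4, 32, 32), (5, 48, 48), VOXEL)
        stacks = simulate_volume(vol, cfg, fine_scan, z_step=10.0, z_range=(0.0, 0.0))
        ref = simulate_plane(vol, cfg, fine_scan, plane_z=0.0)
        assert len(stacks) == 1
        assert np.allclose(stacks[0].images, ref.images)

    def test_doubling_z_step_halves_plane_count(self, cfg, fine_scan):
        vol = point_source((4, 32, 32), (9, 48, 48), VOXEL)
        fine = simulate_volume(vol, cfg, fine_scan, z_step=0.5)
        coarse = simulate_volume(vol, cfg, fine_scan, z_step=1.0)
        assert len(fine) == 2 * len(coarse) - 1

    def test_nonpositive_z_step_rejected(self, cfg, fine_scan):
        vol = point_source((2, 16, 16), (5, 32, 32), VOXEL)
        with pytest.raises(ValueError, match="z_step"):
            simulate_volume(vol, cfg, fine_scan, z_step=0.0)

    def test_axial_integral_stable_under_step_refinement(self, cfg, fine_scan):
        # total collected signal x z_step approximates the same axial
        # integral whichever step is used (energy bookkeeping)
        vol = point_source((4, 24, 24), (9, 48, 48), VOXEL)
        tot = {}
        for step in (0.5, 0.25):
            stacks = simulate_volume(
                vol, cfg, fine_scan, z_step=step, z_range=(-2.0, 2.0)
            )
            planes = np.array([s.plane_z for s in stacks])
            sums = np.array([s.images.sum() for s in stacks])
            tot[step] = np.trapezoid(sums, planes)
        assert tot[0.25] == pytest.approx(tot[0.5], rel=0.01)


class TestAgainstAxialTheory:
    def test_sheet_sweep_reproduces_line_confocal_response(self, cfg_equal_wavelengths):
        # centred 5-line layout; detector pixel of width w maps to the slit
        # half-width beta = 2 pi NA (w/2) / lambda of the analytic model
        cfg = cfg_equal_wavelengths
        scan = ScanConfig(n_lines=5, pitch=0.32, scan_step=0.08, pixel_width=0.08, noise="none")
        vol = fluorescent_sheet(0.0, (31, 64, 64), (0.1, 0.08, 0.08))
        kern = prepare_kernels(vol, cfg, scan, 0.0)
        resp = kern.kernels[:, 2].sum(axis=(1, 2))
        resp = resp / resp.max()
        u = optical_coordinate(kern.z_offsets, cfg, "detection")
        beta = 2 * np.pi * cfg.na_det * (0.08 / 2) / cfg.wavelength_em
        otf = make_otf_grid()
        curve = axial_response(
            MethodParams(method="line_confocal", b=0.0, beta=beta), otf
        )
        theory = np.interp(u, curve.u_grid, curve.intensity)
        assert np.abs(resp - theory).max() < 0.02
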