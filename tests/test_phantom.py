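"""Phantom rendering and cryo-ET imaging-model properties."""

import math

import numpy as np
import pytest

from ribbonmetrics import phantom as ph
from ribbonmetrics.phantom import (CylinderSpec, ImagingModel, LayerSpec,
                                   PhantomSpec, PhantomError, add_noise,
                                   apply_missing_wedge, apply_psf,
                                   canonical_ribbon_phantom, render_phantom)
from ribbonmetrics.volume import VoxelGrid


def _fwhm_of_trace(trace, step=1.0):
    """Independent linear-interpolated FWHM of a 1-D trace (test oracle)."""
    y = np.asarray(trace, dtype=float)
    y = y - y.min()
    pk = int(np.argmax(y))
    half = y[pk] / 2
    i = pk
    while i > 0 and y[i] > half:
        i -= 1
    left = i + (half - y[i]) / (y[i + 1] - y[i])
    i = pk
    while i < len(y) - 1 and y[i] > half:
        i += 1
    right = i - (half - y[i]) / (y[i - 1] - y[i])
    return (right - left) * step


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_empty_spec_renders_uniform_background():
    spec = PhantomSpec(grid_shape=(8, 16, 16), voxel_size_nm=1.0, background=0.3)
    grid, truth = render_phantom(spec)
    np.testing.assert_allclose(grid.data, 0.3, atol=1e-7)
    assert truth["n_sheets"] == 0


def test_two_sheet_truth_by_construction():
    spec = PhantomSpec(
        grid_shape=(8, 128, 16), voxel_size_nm=1.0,
        layers=[LayerSpec("sheet", 0.0, 8.0, 0.8),
                LayerSpec("sheet", 16.0, 8.0, 0.8)])
    _, truth = render_phantom(spec)
    assert truth["intersheet"] == pytest.approx(16.0)
    assert truth["n_sheets"] == 2


def test_canonical_layer_peaks_at_specified_offsets(tight_identity):
    """Each layer's column-mean density maximum sits on the layer centre.

    Slab tops are flat to float32 precision, so the brute-force position
    oracle is the intensity-weighted centroid of the local plateau rather
    than a bare argmax.
    """
    grid, _ = tight_identity
    spec = ph.canonical_spec("tight")
    col = grid.data.mean(axis=(0, 2), dtype=np.float64)
    y_nm = np.arange(grid.shape[1]) * grid.voxel_size_nm
    for layer in spec.layers:
        center = spec.reference_nm + layer.center_offset_nm
        win = (y_nm > center - 6) & (y_nm < center + 6)
        local = col[win] - col[win].min()
        top = local >= 0.5 * local.max()
        centroid = float(np.sum(y_nm[win][top] * local[top]) / np.sum(local[top]))
        assert abs(centroid - center) <= 0.5 * grid.voxel_size_nm


def test_layer_outside_grid_rejected():
    spec = PhantomSpec(grid_shape=(8, 32, 16), voxel_size_nm=1.0,
                       layers=[LayerSpec("OM", 100.0, 6.0, 1.0)])
    with pytest.raises(PhantomError, match="does not fit"):
        render_phantom(spec)


@pytest.mark.parametrize("variant, quantity, expected", [
    ("tight", "om_to_sheet", 16.0),
    ("tight", "intersheet", 16.0),
    ("tight", "im_to_belt", 24.0),
    ("tight", "belt_interlayer", 15.0),
    ("loose", "om_to_sheet", 99.0),
    ("width", "sheet_width", 38.0),
    ("width", "belt_width", 47.0),
    ("fibril", "fibril_diameter", 11.0),
])
def test_canonical_ground_truths(variant, quantity, expected):
    _, truth = canonical_ribbon_phantom(variant, ImagingModel())
    assert truth[quantity] == pytest.approx(expected)


def test_unknown_variant_rejected():
    with pytest.raises(PhantomError, match="unknown"):
        canonical_ribbon_phantom("banana", ImagingModel())


def test_identity_imaging_is_elementwise_identity(tight_identity):
    grid, _ = tight_identity
    out = ph.apply_imaging(grid, ImagingModel())
    np.testing.assert_array_equal(out.data, grid.data)


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

def test_psf_sigma_zero_is_identity(tight_identity):
    grid, _ = tight_identity
    out = apply_psf(grid, 0.0)
    np.testing.assert_array_equal(out.data, grid.data)


def test_psf_negative_sigma_rejected(tight_identity):
    with pytest.raises(PhantomError):
        apply_psf(tight_identity[0], -1.0)


def test_psf_impulse_fwhm_matches_gaussian():
    data = np.zeros((64, 64, 64), dtype=np.float32)
    data[32, 32, 32] = 1.0
    grid = VoxelGrid(data, voxel_size_nm=1.0)
    out = apply_psf(grid, 2.0)
    measured = _fwhm_of_trace(out.data[32, :, 32], step=1.0)
    assert measured == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 2.0,
                                     abs=0.1)


def test_psf_conserves_summed_density(tight_identity):
    grid, _ = tight_identity
    out = apply_psf(grid, 2.0)
    total_in = float(np.sum(grid.data, dtype=np.float64))
    total_out = float(np.sum(out.data, dtype=np.float64))
    assert abs(total_out - total_in) <= 1e-3 * abs(total_in)


def test_slab_fwhm_monotone_in_blur_sigma():
    """Blur only ever widens a slab profile: the defocus-overestimation bias."""
    data = np.zeros((16, 128, 16), dtype=np.float32)
    spec = PhantomSpec(grid_shape=(16, 128, 16), voxel_size_nm=1.0,
                       layers=[LayerSpec("sheet", 0.0, 8.0, 1.0)])
    grid, _ = render_phantom(spec)
    widths = []
    for sigma in (0.0, 1.0, 2.0, 4.0):
        out = apply_psf(grid, sigma)
        widths.append(_fwhm_of_trace(out.data[8, :, 8], step=1.0))
    assert widths[0] >= 8.0 - 1e-6  # blur never shrinks a top-hat FWHM
    assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))
    assert widths[-1] > widths[0]


def test_psf_matches_direct_space_convolution():
    """Cross-check the blur against an explicit small-kernel convolution."""
    rng = np.random.default_rng(7)
    data = rng.normal(size=(24, 24, 24)).astype(np.float64)
    grid = VoxelGrid(data, voxel_size_nm=1.0)
    sigma = 1.5
    out = apply_psf(grid, sigma)
    ax = np.arange(-12, 12)
    k1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k1 /= k1.sum()
    ref = data.copy()
    for axis in range(3):
        ref = np.apply_along_axis(
            lambda v: np.real(np.fft.ifft(np.fft.fft(v) * np.fft.fft(np.roll(k1, 12)))),
            axis, ref)
    np.testing.assert_allclose(out.data, ref, atol=5e-4)


def test_peak_positions_invariant_under_moderate_blur():
    spec = PhantomSpec(grid_shape=(8, 128, 8), voxel_size_nm=1.0,
                       layers=[LayerSpec("sheet", -8.0, 6.0, 1.0),
                               LayerSpec("sheet", 8.0, 6.0, 1.0)])
    grid, _ = render_phantom(spec)
    for sigma in (1.0, 2.0, 3.0):
        out = apply_psf(grid, sigma)
        col = out.data[4, :, 4]
        y = np.arange(128)
        lo = y[(y < 64)][np.argmax(col[y < 64])]
        hi = y[(y >= 64)][np.argmax(col[y >= 64])]
        assert abs((hi - lo) - 16.0) <= 0.5


# ---------------------------------------------------------------------------
# missing wedge
# ---------------------------------------------------------------------------

def test_full_tilt_range_is_identity(tight_identity):
    grid, _ = tight_identity
    out = apply_missing_wedge(grid, 90.0)
    np.testing.assert_allclose(out.data, grid.data, atol=1e-5)


def test_wedge_filter_is_linear():
    rng = np.random.default_rng(3)
    g1 = VoxelGrid(rng.normal(size=(16, 16, 16)).astype(np.float32), 1.0)
    g2 = VoxelGrid(rng.normal(size=(16, 16, 16)).astype(np.float32), 1.0)
    a = 2.5
    lhs = apply_missing_wedge(
        VoxelGrid(a * g1.data + g2.data, 1.0), 60.0).data
    rhs = (a * apply_missing_wedge(g1, 60.0).data
           + apply_missing_wedge(g2, 60.0).data)
    np.testing.assert_allclose(lhs, rhs, atol=1e-4)


def test_wedge_matches_independent_full_fft_implementation():
    """Oracle: dense complex FFT mask built from first principles."""
    rng = np.random.default_rng(11)
    data = rng.normal(size=(16, 20, 24)).astype(np.float64)
    out = apply_missing_wedge(VoxelGrid(data.astype(np.float32), 1.0), 55.0,
                              tilt_axis="x").data

    kz = np.fft.fftfreq(16).reshape(-1, 1, 1)
    ky = np.fft.fftfreq(20).reshape(1, -1, 1)  # perpendicular in-plane axis
    cot = 1.0 / math.tan(math.radians(55.0))
    missing = np.abs(ky) < np.abs(kz) * cot
    F = np.fft.fftn(data)
    F[np.broadcast_to(missing, F.shape)] = 0.0
    ref = np.fft.ifftn(F).real
    np.testing.assert_allclose(out, ref, atol=1e-4)


def test_wedge_elongates_beam_axis_not_tilt_axis():
    """Impulse response: beam/in-plane FWHM ratio > 1.4 at ±60 deg, while
    extent along the tilt axis stays that of the unfiltered impulse."""
    n = 128
    data = np.zeros((n, n, n), dtype=np.float32)
    data[n // 2, n // 2, n // 2] = 1.0
    grid = apply_psf(VoxelGrid(data, 1.0), 1.0)
    out = apply_missing_wedge(grid, 60.0, tilt_axis="x")
    c = n // 2
    f_beam = _fwhm_of_trace(out.data[:, c, c])
    f_perp = _fwhm_of_trace(out.data[c, :, c])
    f_tilt = _fwhm_of_trace(out.data[c, c, :])
    f_unfiltered = _fwhm_of_trace(grid.data[c, :, c])
    assert 1.4 < f_beam / f_perp < 1.7
    assert abs(f_tilt / f_unfiltered - 1.0) < 0.1


def test_beam_normal_slab_appears_thicker_than_inplane_slab():
    """A finite slab facing the beam elongates; the same slab standing
    in-plane does not (its normal is well sampled)."""
    n = 64
    ax = np.arange(n) - n / 2.0
    thick = np.clip((4.0 - np.abs(ax)) / 1.0 + 0.5, 0, 1)   # 8 wide
    broad = np.clip((10.0 - np.abs(ax)) / 1.0 + 0.5, 0, 1)  # 20 wide
    # thickness along beam (z), finite extent along y, infinite along x
    beam_normal = (thick[:, None, None] * broad[None, :, None]
                   * np.ones((1, 1, n))).astype(np.float32)
    # thickness along y (in-plane), finite extent along z
    inplane = (broad[:, None, None] * thick[None, :, None]
               * np.ones((1, 1, n))).astype(np.float32)
    out_beam = apply_missing_wedge(VoxelGrid(beam_normal, 1.0), 60.0, "x")
    out_inplane = apply_missing_wedge(VoxelGrid(inplane, 1.0), 60.0, "x")
    c = n // 2
    t_beam = _fwhm_of_trace(out_beam.data[:, c, c])
    t_inplane = _fwhm_of_trace(out_inplane.data[c, :, c])
    assert t_beam > t_inplane


def test_inplane_spacing_along_tilt_axis_unchanged_by_wedge():
    spec = PhantomSpec(grid_shape=(32, 32, 128), voxel_size_nm=1.0)
    grid, _ = render_phantom(spec)
    data = grid.data.copy()
    # two rods along the profile axis, separated along the tilt axis (2)
    data[:, :, 48] = 1.0
    data[:, :, 80] = 1.0
    out = apply_missing_wedge(VoxelGrid(data, 1.0), 60.0, tilt_axis="x")
    trace = out.data[16, 16, :]
    lo = np.argmax(trace[:64])
    hi = 64 + np.argmax(trace[64:])
    assert abs((hi - lo) - 32) <= 0.5


def test_wedge_tilt_range_validation(tight_identity):
    with pytest.raises(PhantomError):
        apply_missing_wedge(tight_identity[0], 0.0)
    with pytest.raises(PhantomError):
        apply_missing_wedge(tight_identity[0], 91.0)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_noise_sigma_zero_is_identity(tight_identity):
    grid, _ = tight_identity
    out = add_noise(grid, 0.0, seed=1)
    np.testing.assert_array_equal(out.data, grid.data)


def test_noise_is_deterministic_per_seed(tight_identity):
    grid, _ = tight_identity
    a = add_noise(grid, 0.5, seed=42)
    b = add_noise(grid, 0.5, seed=42)
    c = add_noise(grid, 0.5, seed=43)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_noise_sample_sd_and_mean():
    grid = VoxelGrid(np.zeros((128, 128, 128), dtype=np.float32), 1.0)
    out = add_noise(grid, 0.5, seed=9)
    sd = float(np.std(out.data, dtype=np.float64))
    assert 0.497 <= sd <= 0.503
    n = out.data.size
    assert abs(float(np.mean(out.data, dtype=np.float64))) < 3 * 0.5 / math.sqrt(n)


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(label="nope", center_offset_nm=0, thickness_nm=6, amplitude=1),
    dict(label="OM", center_offset_nm=0, thickness_nm=0, amplitude=1),
    dict(label="OM", center_offset_nm=0, thickness_nm=6, amplitude=0),
])
def test_invalid_layers_rejected(bad):
    with pytest.raises(PhantomError):
        LayerSpec(**bad)


def test_invalid_imaging_models_rejected():
    with pytest.raises(PhantomError):
        ImagingModel(psf_sigma_nm=-1)
    with pytest.raises(PhantomError):
        ImagingModel(tilt_range_deg=0)
    with pytest.raises(PhantomError):
        ImagingModel(noise_sigma=-0.1)
    with pytest.raises(PhantomError):
        ImagingModel(tilt_axis="z")


def test_cylinder_validation():
    with pytest.raises(PhantomError):
        CylinderSpec(diameter_nm=0, axis_direction=[0, 1, 0],
                     center_nm=[0, 0, 0], length_nm=10, amplitude=1)
    with pytest.raises(PhantomError):
        CylinderSpec(diameter_nm=5, axis_direction=[0, 0, 0],
                     center_nm=[0, 0, 0], length_nm=10, amplitude=1)
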