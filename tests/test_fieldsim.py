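import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import ironrelax as ir
from ironrelax.fieldsim import PPB, _dipole_kernel_rfft


def uniform_iron(shape, c_nm=0.0, c_ft=0.0, vox=0.88):
    mask = np.full(shape, c_nm > 0, dtype=bool)
    return ir.IronMap3D(
        c_nm=np.full(shape, c_nm),
        c_ft=np.full(shape, c_ft) * (~mask if c_nm > 0 else 1.0),
        nm_mask=mask,
        voxel_size=vox,
    )


class TestSusceptibility:
    def test_zero_iron_zero_chi(self, magnet):
        m = uniform_iron((6, 6, 6))
        assert np.all(ir.susceptibility_from_iron(m, magnet).chi == 0)

    def test_nm_voxel_value(self, magnet):
        """387 ug/g of NM-bound iron at 3.3 ppb/(ug/g) -> ~1277 ppb."""
        m = uniform_iron((6, 6, 6), c_nm=387.0)
        chi = ir.susceptibility_from_iron(m, magnet).chi
        assert np.allclose(chi, 387.0 * 3.3)

    @given(scale=st.floats(0.1, 10.0))
    def test_linearity_in_concentration(self, scale):
        magnet = ir.MagneticParams()
        base = uniform_iron((4, 4, 4), c_ft=56.0)
        scaled = uniform_iron((4, 4, 4), c_ft=56.0 * scale)
        chi0 = ir.susceptibility_from_iron(base, magnet).chi
        chi1 = ir.susceptibility_from_iron(scaled, magnet).chi
        assert np.allclose(chi1, scale * chi0)


class TestLarmorShift:
    def test_uniform_chi_gives_zero_field_periodic(self, magnet):
        chi = ir.SusceptibilityMap(np.full((8, 8, 8), 123.0), 0.88)
        f = ir.larmor_shift_map(chi, magnet, padding=1)
        assert np.allclose(f.df, 0.0, atol=1e-9 * magnet.larmor_freq_hz)

    def test_mean_free(self, dilute_field, magnet):
        assert abs(dilute_field.df.mean()) < 1e-9 * magnet.larmor_freq_hz

    def test_sphere_dipole_oracle(self, magnet):
        """FFT field vs the closed-form dipole field of a magnetized sphere."""
        n, vox, chi0 = 64, 1.0, 1000.0
        radius = 8.0
        ic = n // 2  # sphere center sits exactly on voxel (ic, ic, ic)
        coords = (np.arange(n) - ic) * vox
        x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
        # rasterized sphere (voxel-center inclusion), like the phantom module
        r2 = x**2 + y**2 + z**2
        inside = r2 <= radius**2
        chi = ir.SusceptibilityMap(np.where(inside, chi0, 0.0), vox)
        f = ir.larmor_shift_map(chi, magnet, padding=2)

        # moment of the rasterized sphere differs slightly from 4/3 pi a^3
        vol_ratio = inside.sum() * vox**3 / (4.0 / 3.0 * np.pi * radius**3)
        r = np.sqrt(r2)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2 = np.where(r > 0, (z / np.maximum(r, 1e-12)) ** 2, 0.0)
            analytic = (
                f.f0
                * (chi0 * PPB / 3.0)
                * vol_ratio
                * (radius / np.maximum(r, 1e-12)) ** 3
                * (3 * cos2 - 1)
            )
        analytic[inside] = 0.0
        analytic -= analytic.mean()  # same ROI-mean convention as the solver

        shell = np.abs(r - radius) <= 2 * vox  # within 2 voxels of the surface
        compare = ~shell
        scale = np.abs(analytic).max()
        rel_err = np.abs(f.df - analytic)[compare].max() / scale
        assert rel_err < 0.05

        # spot value: on the z axis at r = 2a the shift is f0 * dchi / 12
        iz = ic + int(2 * radius / vox)
        expected = f.f0 * chi0 * PPB / 12.0 * vol_ratio
        assert f.df[ic, ic, iz] == pytest.approx(expected, rel=0.05)

    def test_linearity_and_superposition(self, magnet):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(12, 12, 12)) * 100
        b = rng.normal(size=(12, 12, 12)) * 100
        fa = ir.larmor_shift_map(ir.SusceptibilityMap(a, 0.88), magnet).df
        fb = ir.larmor_shift_map(ir.SusceptibilityMap(b, 0.88), magnet).df
        fab = ir.larmor_shift_map(ir.SusceptibilityMap(a + b, 0.88), magnet).df
        fneg = ir.larmor_shift_map(ir.SusceptibilityMap(-a, 0.88), magnet).df
        assert np.allclose(fab, fa + fb, atol=1e-9)
        assert np.allclose(fneg, -fa, atol=1e-12)

    def test_parseval_variance(self, magnet):
        """Field variance equals the kernel-filtered chi spectral power."""
        rng = np.random.default_rng(4)
        chi = rng.normal(size=(16, 16, 16)) * 50
        f = ir.larmor_shift_map(ir.SusceptibilityMap(chi, 0.88), magnet, padding=1)
        kernel = _dipole_kernel_rfft(chi.shape, 0.88)
        spec = np.fft.fftn(chi * PPB)
        kx = np.fft.fftfreq(16, d=0.88)
        kz = kx
        k2 = kx[:, None, None] ** 2 + kx[None, :, None] ** 2 + kz[None, None, :] ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            full_kernel = 1.0 / 3.0 - kz[None, None, :] ** 2 / k2
        full_kernel[0, 0, 0] = 0.0
        n = chi.size
        var_spectral = np.sum(np.abs(full_kernel * spec) ** 2) / n**2 * f.f0**2
        assert f.df.var() == pytest.approx(var_spectral, rel=1e-6)
        del kernel

    @pytest.mark.parametrize("bad", [np.zeros((8, 8)), np.zeros((8, 8, 2))])
    def test_degenerate_inputs_rejected(self, bad, magnet):
        with pytest.raises(ValueError):
            ir.larmor_shift_map(ir.SusceptibilityMap(bad.reshape(bad.shape), 0.88), magnet)


class TestFrequencyHistogram:
    def test_constant_field_is_point_mass(self, magnet):
        f = ir.FrequencyMap(np.zeros((8, 8, 8)), 0.88, magnet.larmor_freq_hz)
        spec = ir.frequency_histogram(f)
        assert spec.bin_centers.size == 1
        assert spec.bin_centers[0] == 0.0
        assert spec.density[0] == 1.0

    def test_gaussian_field_density(self, magnet):
        rng = np.random.default_rng(8)
        df = rng.normal(0.0, 20.0, size=(32, 32, 32))
        f = ir.FrequencyMap(df, 0.88, magnet.larmor_freq_hz)
        spec = ir.frequency_histogram(f, n_bins=128)
        assert spec.integral() == pytest.approx(1.0, abs=1e-6)
        ks = stats.kstest(df.ravel(), "norm", args=(0, 20)).pvalue
        assert ks > 0.01  # the generated values really are N(0, 20)
        # histogram density tracks the normal pdf
        pdf = stats.norm.pdf(spec.bin_centers, 0, 20)
        assert np.abs(spec.density - pdf).max() < 0.1 * pdf.max()

    def test_union_mask_is_count_weighted_mixture(self, magnet):
        values = np.zeros((4, 4, 4))
        values.flat[:32] = np.linspace(-50, 50, 32)  # region A spans the range
        values.flat[32:] = np.linspace(-50, 50, 32)  # region B spans it too
        f = ir.FrequencyMap(values, 0.88, magnet.larmor_freq_hz)
        mask_a = np.zeros((4, 4, 4), dtype=bool)
        mask_a.flat[:32] = True
        mask_b = ~mask_a
        spec_a = ir.frequency_histogram(f, mask_a, n_bins=16)
        spec_b = ir.frequency_histogram(f, mask_b, n_bins=16)
        spec_u = ir.frequency_histogram(f, None, n_bins=16)
        mixture = 0.5 * spec_a.density + 0.5 * spec_b.density
        assert np.allclose(spec_u.density, mixture, atol=1e-9)

    def test_empty_mask_rejected(self, magnet):
        f = ir.FrequencyMap(np.zeros((4, 4, 4)), 0.88, magnet.larmor_freq_hz)
        with pytest.raises(ValueError):
            ir.frequency_histogram(f, np.zeros((4, 4, 4), dtype=bool))

    def test_too_few_bins_rejected(self, magnet):
        f = ir.FrequencyMap(np.zeros((4, 4, 4)), 0.88, magnet.larmor_freq_hz)
        with pytest.raises(ValueError):
            ir.frequency_histogram(f, n_bins=8)
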