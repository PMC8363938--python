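"""Iron maps -> susceptibility -> Larmor frequency shift fields.

The forward model: spatially varying iron concentrations scale to a magnetic
volume susceptibility (chi, in ppb), which is convolved with the unit dipole
kernel in Fourier space to give the Larmor frequency shift df (Hz) around the
iron-rich structures.  The k-space kernel is 1/3 - kz^2/k^2 (B0 along the z
grid axis), with the k=0 component set to zero, defining df relative to the
ROI mean.  Intravoxel frequency histograms feed the static-dephasing decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .phantom import IronMap3D

__all__ = [
    "GAMMA_PROTON",
    "MagneticParams",
    "SusceptibilityMap",
    "FrequencyMap",
    "FrequencySpectrum",
    "susceptibility_from_iron",
    "larmor_shift_map",
    "frequency_histogram",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.675e8

#: 1 ppb of volume susceptibility in SI dimensionless units
PPB = 1e-9


@dataclass(frozen=True)
class MagneticParams:
    """Static field and magnetic tissue properties.

    chi_nm / chi_ft are effective mass susceptibilities *per iron load* of
    neuromelanin- and ferritin-bound iron, in ppb/(ug/g); rho is the tissue
    density in g/cm^3 converting mass to volume susceptibility.
    """

    B0: float = 7.0
    gamma: float = GAMMA_PROTON
    chi_nm: float = 3.3
    chi_ft: float = 1.3
    rho: float = 1.0
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.chi_nm < 0 or self.chi_ft < 0:
            raise ValueError("susceptibilities per iron load must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def larmor_freq_hz(self) -> float:
        """f0 = gamma * B0 / (2 pi), Hz."""
        return self.gamma * self.B0 / (2.0 * np.pi)

    @property
    def larmor_omega(self) -> float:
        """omega_L = gamma * B0, rad/s."""
        return self.gamma * self.B0


@dataclass
class SusceptibilityMap:
    """Volume susceptibility map, ppb (1 ppb = 1e-9 SI)."""

    chi: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=np.float64)
        if self.chi.ndim != 3:
            raise ValueError("susceptibility map must be 3D")
        if not np.all(np.isfinite(self.chi)):
            raise ValueError("susceptibility map contains non-finite values")


@dataclass
class FrequencyMap:
    """Larmor frequency shift volume, Hz, mean-free over the ROI."""

    df: np.ndarray
    voxel_size: float
    f0: float

    def __post_init__(self) -> None:
        self.df = np.asarray(self.df, dtype=np.float64)
        if self.df.ndim != 3:
            raise ValueError("frequency map must be 3D")


@dataclass
class FrequencySpectrum:
    """Intravoxel Larmor-frequency probability density rho(df).

    ``density`` is per Hz and integrates to one (trapezoid over
    ``bin_centers``).  A single-bin spectrum represents a point mass.
    """

    bin_centers: np.ndarray
    density: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.bin_centers.shape != self.density.shape or self.bin_centers.ndim != 1:
            raise ValueError("bin_centers and density must be matching 1D arrays")
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0")

    def integral(self) -> float:
        if self.bin_centers.size == 1:
            return float(self.density[0])
        return float(np.trapezoid(self.density, self.bin_centers))


def susceptibility_from_iron(iron_map: IronMap3D, p: MagneticParams) -> SusceptibilityMap:
    """chi(r) = rho * (c_nm(r) chi_nm + c_ft(r) chi_ft), in ppb."""
    chi = p.rho * (iron_map.c_nm * p.chi_nm + iron_map.c_ft * p.chi_ft)
    return SusceptibilityMap(chi=chi, voxel_size=iron_map.voxel_size)


def _dipole_kernel_rfft(shape: tuple[int, ...], voxel: float) -> np.ndarray:
    """1/3 - kz^2/k^2 on the rfftn half-spectrum grid; k=0 -> 0."""
    kx = np.fft.fftfreq(shape[0], d=voxel)
    ky = np.fft.fftfreq(shape[1], d=voxel)
    kz = np.fft.rfftfreq(shape[2], d=voxel)
    kx2 = (kx**2)[:, None, None]
    ky2 = (ky**2)[None, :, None]
    kz2 = (kz**2)[None, None, :]
    k2 = kx2 + ky2 + kz2
    with np.errstate(invalid="ignore", divide="ignore"):
        kernel = 1.0 / 3.0 - kz2 / k2
    kernel[0, 0, 0] = 0.0
    return kernel


def larmor_shift_map(
    chi_map: SusceptibilityMap, p: MagneticParams, padding: int = 2
) -> FrequencyMap:
    """Dipole-kernel convolution of the susceptibility map, in Fourier space.

    df = f0 * F^-1[(1/3 - kz^2/k^2) F[chi_SI]], B0 along the z grid axis.

    ``padding`` is the zero-padding factor per axis (2 by default) used to
    suppress wrap-around from the circular convolution; ``padding=1`` gives
    the periodic mode for phantoms meant to tile space.  The output is
    cropped back to the input shape and demeaned over the ROI (the k=0
    convention leaves the constant offset undefined; the shift is reported
    relative to the ROI mean).
    """
    chi = chi_map.chi
    if chi.ndim != 3:
        raise ValueError("need a 3D susceptibility map")
    if chi.shape[2] < 4:
        raise ValueError("need at least 4 planes along z (the B0 axis)")
    if padding < 1:
        raise ValueError("padding factor must be >= 1")
    shape = chi.shape
    big = tuple(int(padding) * n for n in shape)
    work = np.zeros(big)
    work[: shape[0], : shape[1], : shape[2]] = chi * PPB
    kernel = _dipole_kernel_rfft(big, chi_map.voxel_size)
    spec = sfft.rfftn(work)
    spec *= kernel
    field = sfft.irfftn(spec, s=big)
    f0 = p.larmor_freq_hz
    df = f0 * field[: shape[0], : shape[1], : shape[2]]
    df -= df.mean()
    return FrequencyMap(df=df, voxel_size=chi_map.voxel_size, f0=f0)


def frequency_histogram(
    f_map: FrequencyMap,
    mask: np.ndarray | None = None,
    n_bins: int = 256,
    provenance: str = "",
) -> FrequencySpectrum:
    """Normalized probability density of df over the (masked) volume.

    Compartment-restricted histograms (e.g. the field of the NM channel
    alone) are obtained by building the FrequencyMap from the corresponding
    single-channel iron map and histogramming it here.
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    values = f_map.df if mask is None else f_map.df[np.asarray(mask, dtype=bool)]
    values = np.ravel(values)
    if values.size == 0:
        raise ValueError("empty mask: no voxels to histogram")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        # degenerate point-mass spectrum
        return FrequencySpectrum(
            bin_centers=np.array([lo]), density=np.array([1.0]), provenance=provenance
        )
    density, edges = np.histogram(values, bins=n_bins, range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    norm = np.trapezoid(density, centers)
    if norm > 0:
        density = density / norm
    return FrequencySpectrum(bin_centers=centers, density=density, provenance=provenance)
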