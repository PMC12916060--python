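"""V1-like Gabor filter front-end.

An input image is convolved with a bank of even-symmetric Gabor kernels at 4
spatial frequencies (wavelength halving per step) and 4 orientations; each
signed response map is split into rectified positive (P) and negative (N)
channels, giving the 32-channel "retina" the network samples from.  Channel
responses are normalised into [0, 1] by a bank-level constant — the peak
response of each kernel to a full-contrast matched grating — fixed once at
bank construction so filtering stays image-independent and linear up to the
final clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["GaborBank", "build_gabor_bank", "filter_image"]

DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)

#: Gaussian envelope sigma as a fraction of the wavelength
SIGMA_PER_WAVELENGTH = 0.5
#: envelope elongation perpendicular to the wave direction
ASPECT_RATIO = 1.5


@dataclass
class GaborBank:
    """Bank of 2-D Gabor kernels with per-kernel normalisation constants.

    Channels are indexed ``(frequency, orientation, sign)`` with frequency 0
    the lowest (longest wavelength), orientations in degrees, and sign ``+1``
    (P) or ``-1`` (N).  The P and N channels of one (f, theta) pair are the
    rectified positive and negative parts of a single signed convolution.
    """

    wavelengths: tuple[float, ...]
    orientations: tuple[float, ...]
    kernels: list[np.ndarray] = field(repr=False)
    norms: np.ndarray = field(repr=False)

    @property
    def n_frequencies(self) -> int:
        return len(self.wavelengths)

    @property
    def n_channels(self) -> int:
        return 2 * len(self.wavelengths) * len(self.orientations)

    def channel_index(self, freq: int, orient: int, sign: int) -> int:
        """Flat channel index; sign is +1 (P) or -1 (N)."""
        s = 0 if sign > 0 else 1
        return (freq * len(self.orientations) + orient) * 2 + s

    def channel_meta(self) -> list[tuple[int, float, int]]:
        """Per-channel (frequency_index, orientation_deg, sign) tuples."""
        meta = []
        for f in range(self.n_frequencies):
            for o, theta in enumerate(self.orientations):
                meta.append((f, theta, +1))
                meta.append((f, theta, -1))
        return meta


def _gabor_kernel(wavelength: float, theta_deg: float) -> np.ndarray:
    """Even-symmetric, zero-mean Gabor kernel.

    The cosine carrier runs perpendicular to the bar orientation ``theta``
    (so a theta=0 kernel responds best to a vertical grating drifting in x).
    The DC component is removed by subtracting a scaled copy of the envelope,
    so uniform images produce exactly zero response.
    """
    sigma = SIGMA_PER_WAVELENGTH * wavelength
    sigma_y = ASPECT_RATIO * sigma
    half = int(np.ceil(3.0 * sigma_y))
    ax = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    t = np.deg2rad(theta_deg)
    xr = xx * np.cos(t) + yy * np.sin(t)
    yr = -xx * np.sin(t) + yy * np.cos(t)
    envelope = np.exp(-0.5 * ((xr / sigma) ** 2 + (yr / sigma_y) ** 2))
    kernel = envelope * np.cos(2.0 * np.pi * xr / wavelength)
    # remove DC so the kernel is exactly zero-mean
    kernel -= envelope * (kernel.sum() / envelope.sum())
    return kernel


def _grating_norm(kernel: np.ndarray, wavelength: float, theta_deg: float) -> float:
    """Peak |response| of the kernel to a full-contrast matched grating.

    The grating has luminance in [0, 1] (mean 0.5, amplitude 0.5) at the
    kernel's own wavelength and orientation; the maximum is taken over a full
    cycle of phases.  Used as the bank-level [0, 1] normalisation constant.
    """
    half = kernel.shape[0] // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    t = np.deg2rad(theta_deg)
    xr = xx * np.cos(t) + yy * np.sin(t)
    best = 0.0
    for phase in np.linspace(0, 2 * np.pi, 16, endpoint=False):
        grating = 0.5 + 0.5 * np.cos(2.0 * np.pi * xr / wavelength + phase)
        best = max(best, abs(float((kernel * grating).sum())))
    return best


def build_gabor_bank(
    base_wavelength: float = 16.0,
    n_frequencies: int = 4,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
) -> GaborBank:
    """Build the filter bank; wavelength halves (frequency doubles) per step.

    Parameters
    ----------
    base_wavelength : float
        Wavelength in pixels of the lowest-frequency filters.  Successive
        frequencies halve it; the highest-frequency wavelength must stay
        >= 2 px (the Nyquist limit on a pixel grid).
    n_frequencies : int
        Number of frequency bands (default 4, giving 4 x 4 x 2 = 32 channels).
    """
    if n_frequencies < 1:
        raise ValueError("n_frequencies must be >= 1")
    wavelengths = tuple(base_wavelength / (2.0**f) for f in range(n_frequencies))
    if wavelengths[-1] < 2.0:
        raise ValueError(
            f"highest-frequency wavelength {wavelengths[-1]:.3g} px is below the "
            "2 px pixel-grid limit; increase base_wavelength or reduce n_frequencies"
        )
    kernels: list[np.ndarray] = []
    norms = []
    for lam in wavelengths:
        for theta in orientations:
            k = _gabor_kernel(lam, theta)
            kernels.append(k)
            norms.append(_grating_norm(k, lam, theta))
    return GaborBank(
        wavelengths=wavelengths,
        orientations=tuple(orientations),
        kernels=kernels,
        norms=np.asarray(norms),
    )


def filter_image(image: np.ndarray, bank: GaborBank, clip: bool = True) -> np.ndarray:
    """Filter one image into the (size, size, n_channels) rectified representation.

    The signed convolution of each (frequency, orientation) kernel is split
    into its positive part (P channel) and the positive part of its negation
    (N channel), then divided by that kernel's grating norm.  With ``clip``
    (the default) responses are clipped into [0, 1]; P and N channels of one
    pair are never simultaneously positive at a pixel.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {image.shape}")
    size = image.shape[0]
    out = np.zeros((size, size, bank.n_channels), dtype=np.float64)
    ki = 0
    for f in range(bank.n_frequencies):
        for o in range(len(bank.orientations)):
            # edge-pad so boundary responses see a continuation of the image
            # rather than an artificial dark frame; a uniform image then
            # yields exactly zero response everywhere
            pad = bank.kernels[ki].shape[0] // 2
            padded = np.pad(image, pad, mode="edge")
            signed = fftconvolve(padded, bank.kernels[ki], mode="valid")
            signed /= bank.norms[ki]
            p = bank.channel_index(f, o, +1)
            n = bank.channel_index(f, o, -1)
            out[:, :, p] = np.maximum(signed, 0.0)
            out[:, :, n] = np.maximum(-signed, 0.0)
            ki += 1
    if clip:
        np.clip(out, 0.0, 1.0, out=out)
    return out
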