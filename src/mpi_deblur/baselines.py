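"""Classical deconvolution baselines: Wiener, Richardson-Lucy, blind.

All three operate on the same native images and (for the non-blind methods)
the same Langevin-derivative PSF as the learned network, providing the
conventional comparison points.  Richardson-Lucy is implemented directly so
that convolutions use symmetric boundary padding consistent with the forward
model (library implementations zero-pad, which breaks the uniform-image fixed
point at the borders); Wiener uses the standard per-frequency closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .forward_model import NativeImage, PsfKernel

__all__ = [
    "BaselineConfig",
    "wiener_deconvolve",
    "lucy_richardson",
    "blind_deconvolve",
    "run_baseline",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BaselineConfig:
    """Baseline selection and hyperparameters.

    ``noise_to_signal`` regularizes Wiener (default ``10**(-SNR/10)`` at the
    dataset's mid SNR); iterative methods default to 30 iterations.
    """

    method: str = "wiener"
    iterations: int = 30
    noise_to_signal: float = 0.1
    psf_guess_size: int = 15

    def __post_init__(self) -> None:
        if self.method not in ("wiener", "lucy_richardson", "blind"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.noise_to_signal < 0:
            raise ValueError("noise_to_signal must be nonnegative")


def _image_of(native) -> np.ndarray:
    if isinstance(native, NativeImage):
        return np.asarray(native.values, dtype=float)
    return np.asarray(native, dtype=float)


def _kernel_of(psf) -> np.ndarray:
    k = psf.values if isinstance(psf, PsfKernel) else np.asarray(psf, dtype=float)
    if np.all(k == 0):
        raise ValueError("PSF is identically zero")
    return k


def _psf2otf(kernel: np.ndarray, shape) -> np.ndarray:
    """Zero-pad the kernel to ``shape`` and circularly center it at (0, 0)."""
    padded = np.zeros(shape, dtype=float)
    kh, kw = kernel.shape
    padded[:kh, :kw] = kernel
    padded = np.roll(padded, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.fft2(padded)


def wiener_deconvolve(native, psf, nsr: float) -> np.ndarray:
    """Frequency-domain Wiener inverse ``H* Y / (|H|^2 + nsr)``.

    ``nsr`` is the noise-to-signal power ratio; ``nsr = 0`` on noise-free
    input inverts the blur (up to boundary effects).  As ``nsr -> inf`` the
    output tends to zero everywhere.
    """
    image = _image_of(native)
    kernel = _kernel_of(psf)
    if nsr < 0:
        raise ValueError("nsr must be nonnegative")
    H = _psf2otf(kernel, image.shape)
    Y = np.fft.fft2(image)
    denom = np.abs(H) ** 2 + nsr
    # guard exact zeros of H when nsr == 0
    denom = np.where(denom == 0, _EPS, denom)
    X = np.conj(H) * Y / denom
    return np.real(np.fft.ifft2(X))


def _correlate(image: np.ndarray, kernel: np.ndarray, mode: str = "reflect") -> np.ndarray:
    return ndimage.correlate(image, kernel, mode=mode)


def _convolve(image: np.ndarray, kernel: np.ndarray, mode: str = "reflect") -> np.ndarray:
    return ndimage.convolve(image, kernel, mode=mode)


def lucy_richardson(native, psf, iterations: int, boundary: str = "symmetric") -> np.ndarray:
    """Richardson-Lucy deconvolution with multiplicative updates.

    ``x <- x * corr(psf, y / conv(psf, x))`` starting from the observed
    image, with symmetric boundary padding by default (``boundary`` accepts
    any forward-model mode, e.g. ``"wrap"`` for circular consistency).  Nonnegativity is preserved and a
    uniform image is an exact fixed point.  Negative observation pixels (from
    noise) are clipped to zero with a warning.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = _image_of(native)
    kernel = _kernel_of(psf)
    if (y < 0).any():
        warnings.warn("negative pixels in observation clipped to zero", stacklevel=2)
        y = np.clip(y, 0.0, None)
    mode = {"symmetric": "reflect"}.get(boundary, boundary)
    x = y.copy()
    for _ in range(iterations):
        denom = _convolve(x, kernel, mode)
        ratio = y / np.maximum(denom, _EPS)
        x = x * _correlate(ratio, kernel, mode)
    return x


def blind_deconvolve(native, psf_guess_size: int, iterations: int):
    """Blind deconvolution by alternating Richardson-Lucy updates.

    Starts from a flat kernel of the given (odd) size and alternates one RL
    update of the image with one RL update of the kernel per iteration; the
    returned kernel is normalized to unit sum.  Deterministic.
    """
    if psf_guess_size % 2 == 0 or psf_guess_size < 3:
        raise ValueError("psf_guess_size must be odd and >= 3")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.clip(_image_of(native), 0.0, None)
    if psf_guess_size > min(y.shape):
        raise ValueError("psf_guess_size exceeds image size")
    k = np.full((psf_guess_size, psf_guess_size), 1.0 / psf_guess_size**2)
    x = y.copy()
    for _ in range(iterations):
        # image update given current kernel
        ratio = y / np.maximum(_convolve(x, k), _EPS)
        x = x * _correlate(ratio, k)
        # kernel update given current image: full correlation restricted to
        # the kernel support
        ratio = y / np.maximum(_convolve(x, k), _EPS)
        corr = ndimage.correlate(ratio, x, mode="reflect")
        c0, c1 = corr.shape[0] // 2, corr.shape[1] // 2
        h = psf_guess_size // 2
        k = k * corr[c0 - h : c0 + h + 1, c1 - h : c1 + h + 1] / max(x.sum(), _EPS)
        k = np.clip(k, 0.0, None)
        s = k.sum()
        k = np.full_like(k, 1.0 / k.size) if s <= 0 else k / s
    return x, k


def run_baseline(natives, psf, config: BaselineConfig) -> list[np.ndarray]:
    """Apply the configured baseline to a stack of native images."""
    outputs = []
    for img in natives:
        if config.method == "wiener":
            outputs.append(wiener_deconvolve(img, psf, config.noise_to_signal))
        elif config.method == "lucy_richardson":
            outputs.append(lucy_richardson(img, psf, config.iterations))
        else:
            outputs.append(blind_deconvolve(img, config.psf_guess_size, config.iterations)[0])
    return outputs
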