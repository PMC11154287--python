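"""Physics of X-space MPI image formation.

Magnetic particle imaging (MPI) measures the voltage induced by the nonlinear
magnetization response of superparamagnetic nanoparticle tracers as a field-free
point (FFP) is swept across the field of view.  Gridding the received signal by
instantaneous FFP position (X-space reconstruction) yields the tracer
concentration map convolved with a point-spread function (PSF) that is the
field-derivative of the Langevin magnetization law.

This module provides that physics: the Langevin function and its derivative,
PSF construction on a pixel grid, 1-D signal synthesis for a sinusoidal FFP
trajectory, image-domain blurring, and SNR-controlled noise injection used to
turn clean phantoms into realistic "native" MPI images.

Conventions
-----------
* The 2-D model is scalar (single receive channel, x-z plane) with constant
  coil sensitivity; the native image is ``PSF (*) phantom`` plus noise.
* The dimensionless Langevin argument along a spatial offset ``x`` is
  ``xi = k * G * x`` with ``k = mu0 * m0 / (kB * T0 * h_sat)``; ``h_sat`` is
  the saturation field scale normalizing the drive-field argument.
* Convolution uses symmetric (mirror) boundary padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DomainError",
    "ConfigurationError",
    "SimulationParams",
    "PsfKernel",
    "PhantomImage",
    "NativeImage",
    "SignalTrace",
    "langevin",
    "langevin_derivative",
    "build_psf",
    "simulate_signal",
    "blur",
    "add_noise",
    "synth_noise_field",
]

#: below this |xi| the Taylor series is used instead of the closed form, which
#: suffers catastrophic cancellation near zero
SERIES_THRESHOLD = 1e-2


class DomainError(ValueError):
    """Raised for arguments outside an operation's mathematical domain."""


class ConfigurationError(ValueError):
    """Raised for physically inconsistent simulation parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Physical constants of the simulated MPI system.

    Defaults reproduce the published simulation table: vacuum permeability
    ``mu0 = 4 pi x 1e-7`` N A^-2, particle diameter 20 nm, temperature 293 K,
    ``kB = 1.28e-23`` J K^-1 (as printed; the CODATA value 1.38e-23 can be set
    explicitly), magnetic moment ``m0 = 6.75e-18`` A m^2, selection-field
    gradient ``G = 6`` T m^-1 mu0^-1, and target SNR drawn from 5-15 dB.

    ``h_sat`` (saturation field scale, A m^-1) normalizes the Langevin
    argument; its default makes the Langevin argument span the nonlinear
    region across the field of view (PSF full width at half maximum ~6 px of
    a 50 px / 40 mm image at G = 6).
    """

    mu0: float = 4e-7 * math.pi
    particle_diameter_nm: float = 20.0
    temperature_k: float = 293.0
    boltzmann_k: float = 1.28e-23
    magnetic_moment: float = 6.75e-18
    gradient: float = 6.0
    snr_db_range: tuple[float, float] = (5.0, 15.0)
    h_sat: float = 1.6e-5

    def __post_init__(self) -> None:
        positive = {
            "mu0": self.mu0,
            "particle_diameter_nm": self.particle_diameter_nm,
            "temperature_k": self.temperature_k,
            "boltzmann_k": self.boltzmann_k,
            "magnetic_moment": self.magnetic_moment,
            "gradient": self.gradient,
            "h_sat": self.h_sat,
        }
        for name, value in positive.items():
            if not (np.isfinite(value) and value > 0):
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        lo, hi = self.snr_db_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ConfigurationError(f"snr_db_range must be ordered, got {self.snr_db_range!r}")

    @property
    def xi_per_mm(self) -> float:
        """Langevin argument accumulated per mm of FFP offset, ``k * G / 1000``."""
        k = self.mu0 * self.magnetic_moment / (self.boltzmann_k * self.temperature_k * self.h_sat)
        return k * self.gradient / 1000.0


@dataclass(frozen=True)
class PsfKernel:
    """Discretized Langevin-derivative point-spread function.

    ``values`` sum to one, are symmetric under 180-degree rotation and have a
    single global maximum at the center pixel.
    """

    values: np.ndarray
    pixel_size_mm: float
    params: SimulationParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def fwhm_mm(self) -> float:
        """Full width at half maximum of the central row, by linear interpolation."""
        row = self.values[self.values.shape[0] // 2].astype(float)
        c = row.shape[0] // 2
        half = row[c] / 2.0

        def crossing(segment: np.ndarray) -> float:
            # distance in pixels from the center to the half-maximum crossing
            for i in range(len(segment) - 1):
                if segment[i] >= half > segment[i + 1]:
                    frac = (segment[i] - half) / (segment[i] - segment[i + 1])
                    return i + frac
            raise ValueError("half-maximum crossing not inside kernel; enlarge the grid")

        right = crossing(row[c:])
        left = crossing(row[c::-1])
        return (left + right) * self.pixel_size_mm


@dataclass(frozen=True)
class PhantomImage:
    """Ground-truth relative nanoparticle concentration map, values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("phantom must be a 2-D grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("phantom values must be finite")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("phantom values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NativeImage:
    """PSF-blurred, noise-corrupted simulated MPI image."""

    values: np.ndarray
    realized_snr_db: float
    source_phantom_id: str = ""
    rng_seed: int | None = None


@dataclass(frozen=True)
class SignalTrace:
    """Induced-voltage samples along a sinusoidal FFP trajectory."""

    times: np.ndarray
    values: np.ndarray
    ffp_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if not (len(t) == len(self.values) == len(self.ffp_positions_mm)):
            raise ValueError("times, values and ffp_positions must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


def _check_finite(xi: np.ndarray) -> None:
    if not np.all(np.isfinite(xi)):
        raise DomainError("Langevin argument must be finite")


def langevin(xi):
    """Langevin function ``L(xi) = coth(xi) - 1/xi``.

    The removable singularity at zero is handled with the odd Taylor series
    ``xi/3 - xi**3/45`` for ``|xi| < SERIES_THRESHOLD``.  Odd function with
    range (-1, 1).
    """
    arr = np.asarray(xi, dtype=float)
    _check_finite(arr)
    out = np.empty_like(arr)
    small = np.abs(arr) < SERIES_THRESHOLD
    xs = arr[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xb = arr[~small]
    out[~small] = 1.0 / np.tanh(xb) - 1.0 / xb
    return out if arr.ndim else float(out)


def langevin_derivative(xi):
    """Derivative ``L'(xi) = 1/xi**2 - csch(xi)**2`` — the X-space PSF profile.

    Even, strictly positive, maximal at ``L'(0) = 1/3`` and monotone
    decreasing in ``|xi|``.  Near zero the series ``1/3 - xi**2/15 +
    2 xi**4/189`` avoids cancellation.
    """
    arr = np.asarray(xi, dtype=float)
    _check_finite(arr)
    out = np.empty_like(arr)
    small = np.abs(arr) < SERIES_THRESHOLD
    xs = arr[small]
    out[small] = 1.0 / 3.0 - xs**2 / 15.0 + 2.0 * xs**4 / 189.0
    xb = arr[~small]
    with np.errstate(over="ignore"):
        sinh2 = np.sinh(xb) ** 2
    # sinh overflows to inf for |xi| > ~355; csch**2 correctly underflows to 0
    out[~small] = 1.0 / xb**2 - np.where(np.isinf(sinh2), 0.0, 1.0 / sinh2)
    return out if arr.ndim else float(out)


def build_psf(params: SimulationParams, fov_mm: float, grid_px: int) -> PsfKernel:
    """Build the radially symmetric X-space PSF on a ``grid_px`` square kernel.

    The kernel evaluates ``L'(xi_per_mm * r)`` at each pixel's radial distance
    ``r`` from the center (isotropic convention) and normalizes to unit sum.
    ``fov_mm`` is the physical extent of the kernel, so
    ``pixel_size = fov_mm / grid_px``.
    """
    if not isinstance(params, SimulationParams):
        raise ConfigurationError("params must be a SimulationParams instance")
    if not (np.isfinite(fov_mm) and fov_mm > 0):
        raise ConfigurationError(f"fov_mm must be positive, got {fov_mm!r}")
    if grid_px < 3 or grid_px % 2 == 0:
        raise ConfigurationError(f"grid_px must be odd and >= 3, got {grid_px!r}")

    pixel = fov_mm / grid_px
    coords = (np.arange(grid_px) - grid_px // 2) * pixel
    xx, yy = np.meshgrid(coords, coords)
    r = np.hypot(xx, yy)
    values = langevin_derivative(params.xi_per_mm * r)
    values /= values.sum()
    return PsfKernel(values=values, pixel_size_mm=pixel, params=params)


def simulate_signal(
    phantom_1d,
    params: SimulationParams,
    drive_amplitude_mm: float,
    n_samples: int,
    pixel_size_mm: float = 0.8,
    drive_freq_hz: float = 25e3,
) -> SignalTrace:
    """Synthesize the received 1-D MPI signal for one drive-field period.

    The FFP follows ``x_s(t) = A cos(2 pi f t)`` over a full period sampled at
    ``n_samples`` points (endpoints included).  With constant coil sensitivity
    the induced voltage is the time derivative of the total magnetization

        s(t) = m0 * sum_i rho_i * L'(k G (x_s - x_i)) * k G * dx_s/dt,

    evaluated analytically.  An all-zero concentration profile yields an
    all-zero signal.
    """
    rho = np.asarray(phantom_1d, dtype=float)
    if rho.ndim != 1:
        raise ValueError("phantom_1d must be one-dimensional")
    if np.any(rho < 0):
        raise ValueError("concentration profile must be nonnegative")
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")

    n = rho.shape[0]
    x = (np.arange(n) - (n - 1) / 2.0) * pixel_size_mm
    period = 1.0 / drive_freq_hz
    times = np.linspace(0.0, period, n_samples)
    omega = 2.0 * math.pi * drive_freq_hz
    xs = drive_amplitude_mm * np.cos(omega * times)
    dxs = -drive_amplitude_mm * omega * np.sin(omega * times)

    c = params.xi_per_mm
    xi = c * (xs[:, None] - x[None, :])  # (time, position)
    dMdt = params.magnetic_moment * (langevin_derivative(xi) @ rho) * c * dxs
    return SignalTrace(times=times, values=dMdt, ffp_positions_mm=xs)


def total_magnetization(
    phantom_1d,
    params: SimulationParams,
    ffp_positions_mm,
    pixel_size_mm: float = 0.8,
):
    """Total magnetization ``m0 * sum_i rho_i L(k G (x_s - x_i))`` per FFP position."""
    rho = np.asarray(phantom_1d, dtype=float)
    n = rho.shape[0]
    x = (np.arange(n) - (n - 1) / 2.0) * pixel_size_mm
    xs = np.asarray(ffp_positions_mm, dtype=float)
    xi = params.xi_per_mm * (xs[:, None] - x[None, :])
    return params.magnetic_moment * (langevin(xi) @ rho)


def blur(phantom, psf: PsfKernel, boundary: str = "symmetric") -> np.ndarray:
    """Convolve a concentration map with the PSF ("same" size output).

    True 2-D convolution with symmetric (mirror) boundary padding by default;
    ``boundary`` accepts any :func:`scipy.ndimage.convolve` mode name
    (``"symmetric"`` is mapped to ndimage's ``"reflect"``).
    """
    image = phantom.values if isinstance(phantom, PhantomImage) else np.asarray(phantom, dtype=float)
    kernel = psf.values if isinstance(psf, PsfKernel) else np.asarray(psf, dtype=float)
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} does not fit within image {image.shape}"
        )
    mode = {"symmetric": "reflect"}.get(boundary, boundary)
    return ndimage.convolve(image, kernel, mode=mode)


def add_noise(
    image,
    target_snr_db: float,
    noise_field,
    rng_seed: int | None = None,
    source_phantom_id: str = "",
) -> NativeImage:
    """Add a scaled noise field so the realized SNR equals ``target_snr_db``.

    The noise field is rescaled so that ``10 log10(P_signal / P_noise)``
    (powers as mean squares over all pixels) matches the request exactly.
    ``target_snr_db = inf`` is the no-noise sentinel.  Deterministic given its
    inputs; ``rng_seed`` is recorded for provenance only.
    """
    img = np.asarray(image, dtype=float)
    p_signal = float(np.mean(img**2))
    if p_signal == 0.0:
        raise ValueError("signal image has zero power; SNR is undefined")
    if np.isinf(target_snr_db) and target_snr_db > 0:
        return NativeImage(
            values=img.copy(),
            realized_snr_db=float("inf"),
            source_phantom_id=source_phantom_id,
            rng_seed=rng_seed,
        )
    if not np.isfinite(target_snr_db):
        raise ValueError(f"target_snr_db must be finite or +inf, got {target_snr_db!r}")

    noise = np.asarray(noise_field, dtype=float)
    if noise.shape != img.shape:
        raise ValueError(f"noise field shape {noise.shape} != image shape {img.shape}")
    p_noise_raw = float(np.mean(noise**2))
    if p_noise_raw == 0.0:
        raise ValueError("noise field has zero power")

    p_noise_target = p_signal / 10.0 ** (target_snr_db / 10.0)
    scaled = noise * math.sqrt(p_noise_target / p_noise_raw)
    realized = 10.0 * math.log10(p_signal / float(np.mean(scaled**2)))
    return NativeImage(
        values=img + scaled,
        realized_snr_db=realized,
        source_phantom_id=source_phantom_id,
        rng_seed=rng_seed,
    )


def synth_noise_field(shape, correlation_px: float, rng_seed: int) -> np.ndarray:
    """Zero-mean unit-variance random field, optionally spatially correlated.

    ``correlation_px = 0`` gives white Gaussian noise; larger values smooth the
    field with a Gaussian of that sigma, emulating the spatially varying
    background noise of a real scanner.  Reproducible under a fixed seed.
    """
    if correlation_px < 0:
        raise ValueError("correlation_px must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    field = rng.standard_normal(shape)
    if correlation_px > 0:
        field = ndimage.gaussian_filter(field, sigma=correlation_px, mode="wrap")
    field = field - field.mean()
    std = field.std()
    if std > 0:
        field = field / std
    return field
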