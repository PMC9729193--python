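"""Forward simulator for layered turbid gel phantoms under point-focus excitation.

The simulator renders the 2D detector frames a digital spatially-offset
hyperspectral instrument would record from an agarose-gel phantom with
embedded narrow-band emitter volumes (SERS-labelled gold nanostars,
quantum dots).  It reproduces the one piece of physics the offset method
relies on: photons emitted deeper in the medium re-emerge at the surface
over a wider radial area, so larger pixel radii on the detector are
enriched in signal from depth.

Photon transport is closed-form diffusion theory, not Monte Carlo:

* excitation: a focused Gaussian spot treated as a pencil beam, attenuated
  with the effective attenuation coefficient
  ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))`` piecewise per layer
  (Beer-Lambert in depth, no lateral spread — the spot is far smaller
  than any phantom feature);
* emission escape: the dipole (source + image-source) diffusion
  reflectance kernel of a point emitter at depth ``z`` below a
  semi-infinite boundary, evaluated at radial surface distance ``rho``.

Both are standard diffuse-optics approximations; their parameters are
stated per layer as absorption ``mu_a`` (1/mm), reduced scattering
``mu_s'`` (1/mm) and refractive index ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "Layer",
    "SpectralLine",
    "ReferenceSpectrum",
    "EmitterVolume",
    "Phantom",
    "DetectorModel",
    "ScanPlan",
    "CCDFrame",
    "AcquisitionSet",
    "excitation_fluence",
    "surface_escape_kernel",
    "boundary_mismatch_A",
    "emission_wavelength_profile",
    "render_frame",
    "simulate_scan",
    "builtin_fixtures",
    "uniform_background_phantom",
    "default_detector",
    "DEFAULT_OPTICS",
    "FIXTURE_NAMES",
    "nano_target_background_positions",
]

DEFAULT_VOXEL_MM = 0.25       # <= 1/8 of the smallest phantom feature (2 mm)
DEFAULT_BEAM_SIGMA_MM = 0.05  # Gaussian excitation-spot sigma (50 um focus)


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one layer.

    mu_a and mu_s_prime in 1/mm; n dimensionless (>= 1).
    """

    mu_a: float
    mu_s_prime: float
    n: float = 1.33

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be > 0")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_eff(self) -> float:
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))

    @property
    def diffusion_const(self) -> float:
        """Diffusion constant D = 1 / (3 (mu_a + mu_s')) in mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))


# Placeholder gel optics: the gels' mu_a / mu_s' are instrument-phantom
# unknowns, so these defaults are explicit knobs, not measured constants.
DEFAULT_OPTICS = OpticalProperties(mu_a=0.01, mu_s_prime=1.0, n=1.33)


@dataclass(frozen=True)
class Layer:
    """One slab of the phantom.

    ``autofluorescence_coeffs`` are ascending polynomial coefficients in the
    emission wavelength (nm) describing a broad background emission density
    (arbitrary counts units per s per mm^2 of surface per mm of thickness).
    """

    thickness: float
    optics: OpticalProperties = DEFAULT_OPTICS
    autofluorescence_coeffs: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        object.__setattr__(
            self, "autofluorescence_coeffs", tuple(float(c) for c in self.autofluorescence_coeffs)
        )

    def autofluorescence(self, lam) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(lam, dtype=float),
                                                np.asarray(self.autofluorescence_coeffs))


@dataclass(frozen=True)
class SpectralLine:
    """One Lorentzian emission line.

    ``center`` is a Raman shift (cm^-1) or a direct emission wavelength (nm)
    depending on the parent spectrum's mode; ``fwhm`` is always in nm on the
    detector wavelength axis.
    """

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


RAMAN_SHIFT = "raman_shift"
DIRECT_WAVELENGTH = "direct_wavelength"


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Narrow-band reference emission of one probe (GNS-dye or quantum dot)."""

    id: str
    mode: str
    lines: tuple[SpectralLine, ...]

    def __post_init__(self):
        if self.mode not in (RAMAN_SHIFT, DIRECT_WAVELENGTH):
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        if not self.lines:
            raise ValueError("reference spectrum needs at least one line")
        object.__setattr__(self, "lines", tuple(self.lines))


@dataclass(frozen=True)
class EmitterVolume:
    """Axis-aligned box of emitters in sample coordinates (mm, z down)."""

    region: tuple[float, float, float, float, float, float]  # x0,x1,y0,y1,z0,z1
    spectrum_id: str
    concentration: float

    def __post_init__(self):
        x0, x1, y0, y1, z0, z1 = self.region
        if not (x0 < x1 and y0 < y1 and z0 < z1):
            raise ValueError(f"degenerate emitter region {self.region}")
        if z0 < 0:
            raise ValueError("emitter region must start at or below the surface (z >= 0)")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class Phantom:
    """Layered turbid medium with embedded emitter volumes.

    Sample coordinates: x in [0, Lx], y in [0, Ly] laterally, z positive
    downward from the surface z = 0.  ``af_envelope_scale_mm`` sets the
    radial decay length of the broad autofluorescence background around the
    excitation axis (None = laterally uniform background).
    """

    layers: tuple[Layer, ...]
    emitters: tuple[EmitterVolume, ...]
    spectra: tuple[ReferenceSpectrum, ...]
    lateral_extent: tuple[float, float]
    af_envelope_scale_mm: float | None = 25.0

    def __post_init__(self):
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "emitters", tuple(self.emitters))
        object.__setattr__(self, "spectra", tuple(self.spectra))
        ids = {s.id for s in self.spectra}
        total = self.total_thickness
        lx, ly = self.lateral_extent
        for em in self.emitters:
            x0, x1, y0, y1, z0, z1 = em.region
            if em.spectrum_id not in ids:
                raise ValueError(f"emitter references unknown spectrum {em.spectrum_id!r}")
            if x0 < 0 or y0 < 0 or x1 > lx or y1 > ly or z1 > total + 1e-9:
                raise ValueError(f"emitter region {em.region} outside phantom")

    @property
    def total_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)

    @property
    def layer_boundaries(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum([l.thickness for l in self.layers])))

    def spectrum(self, spectrum_id: str) -> ReferenceSpectrum:
        for s in self.spectra:
            if s.id == spectrum_id:
                return s
        raise KeyError(spectrum_id)

    def layer_at(self, depth: float) -> Layer:
        b = self.layer_boundaries
        i = int(np.clip(np.searchsorted(b, depth, side="right") - 1, 0, len(self.layers) - 1))
        return self.layers[i]


@dataclass(frozen=True)
class DetectorModel:
    """CCD geometry and noise model."""

    n_rows: int = 512
    n_cols: int = 512
    pixel_pitch: float = 12.0      # um
    magnification: float = 1.0     # sample-to-detector scale
    dark_offset: float = 100.0     # counts
    read_noise_sigma: float = 3.0  # counts rms
    gain: float = 1.0              # counts per collected photon

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("detector must have positive pixel counts")
        if self.pixel_pitch <= 0 or self.magnification <= 0:
            raise ValueError("pixel_pitch and magnification must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def sample_pixel_mm(self) -> float:
        """Size of one pixel projected to the sample plane (mm)."""
        return self.pixel_pitch * 1e-3 / self.magnification


def default_detector(**overrides) -> DetectorModel:
    return DetectorModel(**overrides)


@dataclass(frozen=True)
class ScanPlan:
    """Stage grid plus wavelength scan.

    Positions are raster ordered, y (slow axis) outer, x inner; the flat
    position index is ``iy * nx + ix``.
    """

    x_positions: tuple[float, ...]
    y_positions: tuple[float, ...]
    lambda_start: float
    lambda_stop: float
    lambda_step: float
    exposure: float = 1.0
    excitation_wavelength: float = 785.0

    def __post_init__(self):
        if self.lambda_step <= 0:
            raise ValueError("lambda_step must be > 0")
        if not self.lambda_start < self.lambda_stop:
            raise ValueError("lambda_start must be < lambda_stop")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        object.__setattr__(self, "x_positions", tuple(float(x) for x in self.x_positions))
        object.__setattr__(self, "y_positions", tuple(float(y) for y in self.y_positions))
        if not self.x_positions or not self.y_positions:
            raise ValueError("scan plan needs at least one stage position")

    @classmethod
    def from_grid(
        cls,
        x0: float,
        y0: float,
        nx: int,
        ny: int,
        step: float,
        **kwargs,
    ) -> "ScanPlan":
        xs = tuple(x0 + i * step for i in range(nx))
        ys = tuple(y0 + j * step for j in range(ny))
        return cls(xs, ys, **kwargs)

    @property
    def lambda_axis(self) -> np.ndarray:
        n = int(round((self.lambda_stop - self.lambda_start) / self.lambda_step)) + 1
        return self.lambda_start + self.lambda_step * np.arange(n)

    @property
    def n_positions(self) -> int:
        return len(self.x_positions) * len(self.y_positions)

    @property
    def positions(self) -> list[tuple[float, float]]:
        return [(x, y) for y in self.y_positions for x in self.x_positions]

    def position_index(self, iy: int, ix: int) -> int:
        return iy * len(self.x_positions) + ix


@dataclass
class CCDFrame:
    """One raw detector exposure (counts; dark offset not subtracted)."""

    data: np.ndarray
    stage_xy: tuple[float, float]
    wavelength: float
    exposure: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2D")


@dataclass
class AcquisitionSet:
    """Complete frame grid of one scan: frames[pos, lambda, row, col]."""

    frames: np.ndarray
    plan: ScanPlan
    detector: DetectorModel
    rng_seed: int | None = None

    def __post_init__(self):
        lam = self.plan.lambda_axis
        expected = (self.plan.n_positions, len(lam), self.detector.n_rows, self.detector.n_cols)
        if self.frames.shape != expected:
            raise ValueError(
                f"frame stack shape {self.frames.shape} does not match plan/detector {expected}"
            )

    @property
    def lambda_axis(self) -> np.ndarray:
        return self.plan.lambda_axis

    def frame(self, pos_index: int, lambda_index: int) -> CCDFrame:
        return CCDFrame(
            self.frames[pos_index, lambda_index],
            self.plan.positions[pos_index],
            float(self.lambda_axis[lambda_index]),
            self.plan.exposure,
        )

    def frames_at_position(self, pos_index: int) -> list[CCDFrame]:
        return [self.frame(pos_index, j) for j in range(len(self.lambda_axis))]


# ---------------------------------------------------------------------------
# photon transport

def excitation_fluence(phantom: Phantom, depth: float, excitation_wavelength: float) -> float:
    """Relative on-axis excitation fluence Phi(z) = exp(-int_0^z mu_eff dz').

    Piecewise Beer-Lambert with the effective attenuation coefficient of
    each layer; Phi(0) = 1 by construction.  The excitation wavelength is
    accepted for interface symmetry (layer optics are treated as
    achromatic over the narrow near-IR scan ranges used here).
    """
    if depth < 0 or depth > phantom.total_thickness + 1e-9:
        raise ValueError(
            f"depth {depth} mm outside phantom (0..{phantom.total_thickness} mm)"
        )
    b = phantom.layer_boundaries
    tau = 0.0
    for i, layer in enumerate(phantom.layers):
        lo, hi = b[i], b[i + 1]
        if depth <= lo:
            break
        seg = min(depth, hi) - lo
        tau += layer.optics.mu_eff * seg
    return math.exp(-tau)


def boundary_mismatch_A(n_rel: float) -> float:
    """Internal-reflection boundary factor A(n) (Groenhuis approximation)."""
    if n_rel <= 0:
        raise ValueError("relative refractive index must be > 0")
    r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


def surface_escape_kernel(depth: float, optics: OpticalProperties, rho, A: float = 1.0):
    """Diffuse surface-escape kernel K(rho; z) of a point emitter at depth z.

    Dipole (source plus image source across the extrapolated boundary)
    diffusion reflectance of a semi-infinite medium:

        K = (1/4pi) [ z (mu_eff + 1/r1) exp(-mu_eff r1)/r1^2
                    + (z + 2 z_b)(mu_eff + 1/r2) exp(-mu_eff r2)/r2^2 ]

    with r1^2 = rho^2 + z^2, r2^2 = rho^2 + (z + 2 z_b)^2,
    z_b = 2 A D, D = 1/(3(mu_a + mu_s')).  A = 1 is the index-matched
    boundary; use :func:`boundary_mismatch_A` for a mismatch.  Units 1/mm^2;
    its integral over the plane is the escape probability (<= 1).
    """
    if depth <= 0:
        raise ValueError("emitter depth must be > 0")
    rho = np.asarray(rho, dtype=float)
    mu_eff = optics.mu_eff
    z_b = 2.0 * A * optics.diffusion_const
    z2 = depth + 2.0 * z_b
    r1 = np.sqrt(rho**2 + depth**2)
    r2 = np.sqrt(rho**2 + z2**2)
    k = (
        depth * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
        + z2 * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    ) / (4.0 * math.pi)
    return k


def emission_wavelength_profile(
    spectrum: ReferenceSpectrum,
    excitation_wavelength: float,
    lambda_axis,
) -> np.ndarray:
    """Relative emission intensity of a reference spectrum on a nm axis.

    Sum of Lorentzian lines; Raman-shift line centres are first converted
    to emission wavelengths for the given excitation line.
    """
    from .spectral import shift_to_wavelength

    lam = np.asarray(lambda_axis, dtype=float)
    if lam.ndim != 1 or np.any(np.diff(lam) <= 0):
        raise ValueError("lambda axis must be strictly increasing")
    out = np.zeros_like(lam)
    for line in spectrum.lines:
        if spectrum.mode == RAMAN_SHIFT:
            center = shift_to_wavelength(line.center, excitation_wavelength)
        else:
            center = line.center
        hwhm = line.fwhm / 2.0
        out += line.amplitude * hwhm**2 / ((lam - center) ** 2 + hwhm**2)
    return out


# ---------------------------------------------------------------------------
# frame rendering

def _spectral_weight(
    spectrum: ReferenceSpectrum, excitation_wavelength: float, wavelength: float
) -> float:
    """Relative emission intensity of a spectrum at one wavelength."""
    from .spectral import shift_to_wavelength

    w = 0.0
    for line in spectrum.lines:
        if spectrum.mode == RAMAN_SHIFT:
            center = shift_to_wavelength(line.center, excitation_wavelength)
        else:
            center = line.center
        hwhm = line.fwhm / 2.0
        w += line.amplitude * hwhm**2 / ((wavelength - center) ** 2 + hwhm**2)
    return w


def _voxel_centers(region, voxel_mm):
    """Voxel centre coordinates covering an axis-aligned box, per axis."""
    out = []
    for lo, hi in zip(region[0::2], region[1::2]):
        n = max(1, int(round((hi - lo) / voxel_mm)))
        out.append(lo + (hi - lo) * (np.arange(n) + 0.5) / n)
    return out  # [x centers, y centers, z centers]


def _pixel_sample_offsets(detector: DetectorModel):
    """Sample-plane (mm) offsets of pixel centres from the excitation axis."""
    s = detector.sample_pixel_mm
    dy = (np.arange(detector.n_rows) - (detector.n_rows - 1) / 2.0) * s
    dx = (np.arange(detector.n_cols) - (detector.n_cols - 1) / 2.0) * s
    return dx, dy


def _beam_overlap(lo: float, hi: float, s: float, sigma: float) -> float:
    """Fraction of a 1D Gaussian beam profile falling inside [lo, hi]."""
    from scipy.special import erf

    inv = 1.0 / (sigma * math.sqrt(2.0))
    return 0.5 * (erf((hi - s) * inv) - erf((lo - s) * inv))


def _emitter_photon_image(
    phantom: Phantom,
    emitter: EmitterVolume,
    detector: DetectorModel,
    stage_xy: tuple[float, float],
    excitation_wavelength: float,
    beam_sigma: float,
    voxel_mm: float,
    A: float,
) -> np.ndarray | None:
    """Expected photons/s/pixel from one emitter volume at unit spectral weight.

    Pencil-beam limit: only the emitter column under the excitation axis is
    excited (the focused spot is far smaller than a voxel), so emission is
    collapsed onto the axis with weight concentration x Phi(z) x the
    analytic lateral overlap of the Gaussian beam footprint with the box.
    Each depth slice spreads over the surface with its escape kernel.
    Returns None when the beam misses the volume.
    """
    sx, sy = stage_xy
    x0, x1, y0, y1, z0, z1 = emitter.region
    w_lat = _beam_overlap(x0, x1, sx, beam_sigma) * _beam_overlap(y0, y1, sy, beam_sigma)
    if w_lat < 1e-12:
        return None
    _, _, zs = _voxel_centers(emitter.region, voxel_mm)
    dz = (z1 - z0) / len(zs)
    pixel_area = detector.sample_pixel_mm**2

    dx, dy = _pixel_sample_offsets(detector)
    rho = np.hypot(dy[:, None], dx[None, :])
    img = np.zeros(detector.shape)
    for z in zs:
        phi = excitation_fluence(phantom, z, excitation_wavelength)
        optics = phantom.layer_at(z).optics
        img += phi * surface_escape_kernel(z, optics, rho, A=A)
    img *= emitter.concentration * dz * w_lat * pixel_area
    return img


def _autofluorescence_image(
    phantom: Phantom,
    detector: DetectorModel,
    wavelength: float,
    excitation_wavelength: float,
) -> np.ndarray:
    """Expected broad-background photons/s/pixel at one wavelength."""
    rate = 0.0
    b = phantom.layer_boundaries
    for i, layer in enumerate(phantom.layers):
        z_mid = 0.5 * (b[i] + b[i + 1])
        val = float(layer.autofluorescence(wavelength))
        if val < 0:
            raise ValueError(
                f"autofluorescence of layer {i} negative at {wavelength} nm"
            )
        rate += val * layer.thickness * excitation_fluence(
            phantom, z_mid, excitation_wavelength
        )
    if rate == 0.0:
        return np.zeros(detector.shape)
    pixel_area = detector.sample_pixel_mm**2
    if phantom.af_envelope_scale_mm is None:
        env = np.ones(detector.shape)
    else:
        dx, dy = _pixel_sample_offsets(detector)
        rho = np.hypot(dy[:, None], dx[None, :])
        env = np.exp(-rho / phantom.af_envelope_scale_mm)
    return rate * pixel_area * env


def _check_stage(phantom: Phantom, stage_xy) -> None:
    sx, sy = stage_xy
    lx, ly = phantom.lateral_extent
    if not (0 <= sx <= lx and 0 <= sy <= ly):
        raise ValueError(
            f"stage position {stage_xy} moves the excitation axis off the phantom "
            f"(extent {phantom.lateral_extent})"
        )


def expected_frame(
    phantom: Phantom,
    detector: DetectorModel,
    stage_xy: tuple[float, float],
    wavelength: float,
    exposure: float,
    excitation_wavelength: float,
    beam_sigma: float = DEFAULT_BEAM_SIGMA_MM,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    A: float = 1.0,
    _spatial_cache: dict | None = None,
) -> np.ndarray:
    """Noise-free expected frame in counts (includes the dark offset).

    ``_spatial_cache`` lets a scan reuse the wavelength-independent spatial
    images of each emitter across the wavelength axis.
    """
    _check_stage(phantom, stage_xy)
    photons = np.zeros(detector.shape)
    cache = _spatial_cache if _spatial_cache is not None else {}
    key = (stage_xy,)
    if key not in cache:
        per_spectrum: dict[str, np.ndarray] = {}
        for em in phantom.emitters:
            img = _emitter_photon_image(
                phantom, em, detector, stage_xy, excitation_wavelength,
                beam_sigma, voxel_mm, A,
            )
            if img is None:
                continue
            if em.spectrum_id in per_spectrum:
                per_spectrum[em.spectrum_id] = per_spectrum[em.spectrum_id] + img
            else:
                per_spectrum[em.spectrum_id] = img
        cache[key] = per_spectrum
    for sid, img in cache[key].items():
        w = _spectral_weight(phantom.spectrum(sid), excitation_wavelength, wavelength)
        if w > 0:
            photons = photons + w * img
    photons = photons + _autofluorescence_image(
        phantom, detector, wavelength, excitation_wavelength
    )
    return detector.dark_offset + detector.gain * exposure * photons


def render_frame(
    phantom: Phantom,
    detector: DetectorModel,
    stage_xy: tuple[float, float],
    wavelength: float,
    exposure: float,
    excitation_wavelength: float,
    noise: str = "off",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    beam_sigma: float = DEFAULT_BEAM_SIGMA_MM,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    A: float = 1.0,
    _spatial_cache: dict | None = None,
) -> CCDFrame:
    """Render one detector frame.

    With ``noise="off"`` the exact expectation is returned.  With
    ``noise="on"`` Poisson shot noise is applied to the photon term,
    Gaussian read noise is added, and the frame is clipped at zero; the
    output is fully determined by ``seed`` (or a supplied generator).
    """
    if noise not in ("on", "off"):
        raise ValueError("noise must be 'on' or 'off'")
    expected = expected_frame(
        phantom, detector, stage_xy, wavelength, exposure, excitation_wavelength,
        beam_sigma=beam_sigma, voxel_mm=voxel_mm, A=A, _spatial_cache=_spatial_cache,
    )
    if noise == "off":
        data = expected
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        photon_mean = (expected - detector.dark_offset) / detector.gain
        counts = detector.gain * rng.poisson(np.clip(photon_mean, 0, None)).astype(float)
        counts += detector.dark_offset
        if detector.read_noise_sigma > 0:
            counts += rng.normal(0.0, detector.read_noise_sigma, size=counts.shape)
        data = np.clip(counts, 0.0, None)
    return CCDFrame(data, tuple(stage_xy), float(wavelength), float(exposure))


def simulate_scan(
    phantom: Phantom,
    detector: DetectorModel,
    plan: ScanPlan,
    noise: str = "off",
    seed: int = 0,
    beam_sigma: float = DEFAULT_BEAM_SIGMA_MM,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    A: float = 1.0,
) -> AcquisitionSet:
    """Simulate the full stage x wavelength grid of a scan plan.

    One frame per (position, wavelength); a fixed seed fully determines the
    output.  Per-frame random streams are spawned from the seed so the
    result does not depend on rendering order.
    """
    lam = plan.lambda_axis
    positions = plan.positions
    # validate autofluorescence positivity over the scan range up front
    for i, layer in enumerate(phantom.layers):
        vals = layer.autofluorescence(lam)
        if np.any(np.asarray(vals) < 0):
            raise ValueError(f"autofluorescence of layer {i} negative within scan range")
    frames = np.empty((len(positions), len(lam), detector.n_rows, detector.n_cols))
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(positions) * len(lam))
    for ip, pos in enumerate(positions):
        cache: dict = {}
        for j, wl in enumerate(lam):
            rng = np.random.default_rng(children[ip * len(lam) + j]) if noise == "on" else None
            try:
                fr = render_frame(
                    phantom, detector, pos, float(wl), plan.exposure,
                    plan.excitation_wavelength, noise=noise, rng=rng,
                    beam_sigma=beam_sigma, voxel_mm=voxel_mm, A=A,
                    _spatial_cache=cache,
                )
            except ValueError as exc:
                raise ValueError(
                    f"render failed at position {ip} {pos}, wavelength {wl} nm: {exc}"
                ) from exc
            frames[ip, j] = fr.data
    return AcquisitionSet(frames, plan, detector, rng_seed=seed)


# ---------------------------------------------------------------------------
# built-in phantom fixtures

def _af_parabola(level: float, center: float = 860.0, half_width: float = 120.0):
    """Ascending coefficients of level * (1 - ((lam-center)/half_width)^2).

    Positive over roughly [center - hw, center + hw]; used as the layers'
    broad autofluorescence background.
    """
    w2 = half_width**2
    return (
        level * (1 - center**2 / w2),
        level * 2 * center / w2,
        -level / w2,
    )


def _gns_dttc() -> ReferenceSpectrum:
    # Main band at 497 cm^-1 (~816.9 nm at 785 nm excitation); the second
    # band is a documented synthetic choice for waterfall realism.
    return ReferenceSpectrum(
        "GNS-DTTC", RAMAN_SHIFT,
        (SpectralLine(497.0, 2.0, 1.0), SpectralLine(1125.0, 2.2, 0.55)),
    )


def _gns_ir780() -> ReferenceSpectrum:
    # Main band at 905 cm^-1 (~845.0 nm at 785 nm excitation).
    return ReferenceSpectrum(
        "GNS-IR780", RAMAN_SHIFT,
        (SpectralLine(905.0, 2.0, 1.0), SpectralLine(1205.0, 2.2, 0.5)),
    )


def _qd900() -> ReferenceSpectrum:
    return ReferenceSpectrum(
        "QD900", DIRECT_WAVELENGTH, (SpectralLine(900.0, 30.0, 1.0),)
    )


GEL_AF_LEVEL = 3.0e4       # per-layer autofluorescence scale (arb. counts units)
GNS_CONCENTRATION = 1.0e7  # arb. emitter units / mm^3
QD_CONCENTRATION = 1.0e8

FIXTURE_NAMES = ("single_layer_cube", "stacked_dual_3mm", "embedded_dual_2mm", "nano_qd")

# 5x7 bitmap strokes for the quantum-dot lettering
_LETTERS = {
    "N": ("#...#", "##..#", "##..#", "#.#.#", "#..##", "#..##", "#...#"),
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
}
_NANO_CELL_MM = 1.4
_NANO_TEXT = "NANO"


def _nano_letter_boxes(z0: float, z1: float, extent: tuple[float, float]):
    """Emitter boxes spelling 'NANO', one box per on-cell of a 5x7 font."""
    cell = _NANO_CELL_MM
    n_cols = len(_NANO_TEXT) * 6 - 1  # 5 cells + 1 spacing per letter
    width = n_cols * cell
    height = 7 * cell
    x_off = (extent[0] - width) / 2.0
    y_off = (extent[1] - height) / 2.0
    boxes = []
    for li, ch in enumerate(_NANO_TEXT):
        glyph = _LETTERS[ch]
        for r, rowtxt in enumerate(glyph):
            for c, v in enumerate(rowtxt):
                if v == "#":
                    x0 = x_off + (li * 6 + c) * cell
                    y0 = y_off + r * cell
                    boxes.append((x0, x0 + cell, y0, y0 + cell, z0, z1))
    return boxes


def nano_target_background_positions() -> tuple[tuple[float, float], tuple[float, float]]:
    """A stage position centred on a letter stroke and one far from any letter.

    Convenience for signal-vs-radius studies on the ``nano_qd`` fixture.
    """
    phantom, _ = builtin_fixtures("nano_qd")
    boxes = [em.region for em in phantom.emitters]
    # centre of the crossbar cell of the 'A' (letter index 1, row 3, col 2)
    cell = _NANO_CELL_MM
    n_cols = len(_NANO_TEXT) * 6 - 1
    x_off = (phantom.lateral_extent[0] - n_cols * cell) / 2.0
    y_off = (phantom.lateral_extent[1] - 7 * cell) / 2.0
    target = (x_off + (6 + 2.5) * cell, y_off + 3.5 * cell)
    background = (phantom.lateral_extent[0] / 2.0, phantom.lateral_extent[1] - 4.0)
    return target, background


def uniform_background_phantom(
    extent: tuple[float, float] = (30.0, 30.0),
    thickness: float = 10.0,
    af_level: float = GEL_AF_LEVEL,
) -> Phantom:
    """Emitter-free gel slab with a laterally uniform broad background."""
    return Phantom(
        layers=(Layer(thickness, DEFAULT_OPTICS, _af_parabola(af_level)),),
        emitters=(),
        spectra=(),
        lateral_extent=extent,
        af_envelope_scale_mm=None,
    )


def stacked_dual_phantom(
    layer_thickness: float = 3.0,
    extent: tuple[float, float] = (20.0, 20.0),
    af_level: float = GEL_AF_LEVEL,
    deep_dye_on_top: bool = False,
) -> Phantom:
    """Two stacked dye-gel layers: GNS-DTTC above GNS-IR780 (by default)."""
    t = layer_thickness
    af = _af_parabola(af_level)
    top_id, bottom_id = ("GNS-IR780", "GNS-DTTC") if deep_dye_on_top else ("GNS-DTTC", "GNS-IR780")
    return Phantom(
        layers=(Layer(t, DEFAULT_OPTICS, af), Layer(t, DEFAULT_OPTICS, af)),
        emitters=(
            EmitterVolume((0, extent[0], 0, extent[1], 0.0, t), top_id, GNS_CONCENTRATION),
            EmitterVolume((0, extent[0], 0, extent[1], t, 2 * t), bottom_id, GNS_CONCENTRATION),
        ),
        spectra=(_gns_dttc(), _gns_ir780()),
        lateral_extent=extent,
    )


def builtin_fixtures(name: str) -> tuple[Phantom, ScanPlan]:
    """Phantom geometries and scan plans of the published demonstrations.

    single_layer_cube : 5 x 5 mm GNS-DTTC cube (2 mm thick) sandwiched
        between 5 mm gel slabs; 1 mm stage increments, 800-830 nm at 1 nm.
    stacked_dual_3mm  : two stacked 3 mm dye layers (GNS-DTTC over
        GNS-IR780), single spot, 800-880 nm at 1 nm.
    embedded_dual_2mm : two 2 mm dye layers (GNS-IR780 over GNS-DTTC)
        embedded between 2 mm gel layers; 5 mm increments, 800-880 nm.
    nano_qd           : 900 nm quantum-dot lettering ("NANO") ~1 mm below
        the surface; 4 mm increments over 4 cm x 4 cm, 100 ms exposure.
    """
    af = _af_parabola(GEL_AF_LEVEL)
    if name == "single_layer_cube":
        extent = (30.0, 30.0)
        cube = (12.5, 17.5, 12.5, 17.5, 5.0, 7.0)  # 5x5 mm, 2 mm thick, centred
        phantom = Phantom(
            layers=(
                Layer(5.0, DEFAULT_OPTICS, af),
                Layer(2.0, DEFAULT_OPTICS, af),
                Layer(5.0, DEFAULT_OPTICS, af),
            ),
            emitters=(EmitterVolume(cube, "GNS-DTTC", GNS_CONCENTRATION),),
            spectra=(_gns_dttc(),),
            lateral_extent=extent,
        )
        plan = ScanPlan.from_grid(
            10.0, 10.0, 11, 11, 1.0,
            lambda_start=800.0, lambda_stop=830.0, lambda_step=1.0,
            exposure=1.0, excitation_wavelength=785.0,
        )
    elif name == "stacked_dual_3mm":
        phantom = stacked_dual_phantom(3.0)
        plan = ScanPlan.from_grid(
            10.0, 10.0, 1, 1, 1.0,
            lambda_start=800.0, lambda_stop=880.0, lambda_step=1.0,
            exposure=1.0, excitation_wavelength=785.0,
        )
    elif name == "embedded_dual_2mm":
        extent = (30.0, 30.0)
        box = (10.0, 20.0, 10.0, 20.0)
        phantom = Phantom(
            layers=(
                Layer(2.0, DEFAULT_OPTICS, af),
                Layer(2.0, DEFAULT_OPTICS, af),
                Layer(2.0, DEFAULT_OPTICS, af),
                Layer(2.0, DEFAULT_OPTICS, af),
            ),
            emitters=(
                EmitterVolume((*box, 2.0, 4.0), "GNS-IR780", GNS_CONCENTRATION),
                EmitterVolume((*box, 4.0, 6.0), "GNS-DTTC", GNS_CONCENTRATION),
            ),
            spectra=(_gns_dttc(), _gns_ir780()),
            lateral_extent=extent,
        )
        plan = ScanPlan.from_grid(
            5.0, 5.0, 5, 5, 5.0,
            lambda_start=800.0, lambda_stop=880.0, lambda_step=1.0,
            exposure=1.0, excitation_wavelength=785.0,
        )
    elif name == "nano_qd":
        extent = (44.0, 44.0)
        phantom = Phantom(
            layers=(
                Layer(1.0, DEFAULT_OPTICS, af),
                Layer(1.0, DEFAULT_OPTICS, af),
                Layer(8.0, DEFAULT_OPTICS, af),
            ),
            emitters=tuple(
                EmitterVolume(b, "QD900", QD_CONCENTRATION)
                for b in _nano_letter_boxes(1.0, 2.0, extent)
            ),
            spectra=(_qd900(),),
            lateral_extent=extent,
        )
        plan = ScanPlan.from_grid(
            2.0, 2.0, 11, 11, 4.0,
            lambda_start=880.0, lambda_stop=920.0, lambda_step=4.0,
            exposure=0.1, excitation_wavelength=785.0,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return phantom, plan
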