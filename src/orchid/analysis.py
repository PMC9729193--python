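"""Quantitative readouts: ratiometric depth sensing, signal vs. bin radius,
optimal-radius selection, and model-based depth estimation.

These operations turn binned offset data into the numbers a depth-resolved
narrowband experiment reports: how the deep/shallow peak ratio grows with
offset, where the background-subtracted target signal peaks as a function
of bin radius, and what effective emitter depth best explains a measured
radial profile under the diffusion forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar

from .binning import ANNULUS, CUMULATIVE, OffsetBinningScheme, OffsetProfile, bin_frame, default_center
from .hypercube import HyperCube
from .phantom import AcquisitionSet, DetectorModel, OpticalProperties, surface_escape_kernel
from .spectral import OffsetSpectrum, measure_peak, remove_background

__all__ = [
    "RatioCurve",
    "RadialCurveSet",
    "OptimalRadius",
    "DepthEstimate",
    "ratiometric_curve",
    "signal_vs_radius",
    "optimal_radius",
    "estimate_depth",
    "expected_offset_profile",
]


@dataclass
class RatioCurve:
    """Deep/shallow peak ratio per offset bin.

    ``ratio`` is NaN where the shallow peak fell below the measurement
    floor; those bins stay in the curve, flagged by ``defined``.
    """

    offset_bins: tuple[tuple[float, float], ...]
    ratio: np.ndarray
    defined: np.ndarray
    peaks_used: tuple[tuple[str, float], tuple[str, float]]

    @property
    def defined_ratio(self) -> np.ndarray:
        return self.ratio[self.defined]


@dataclass
class RadialCurveSet:
    """Target/background/difference/SNR as a function of bin radius."""

    radii: np.ndarray
    target: np.ndarray
    background: np.ndarray
    difference: np.ndarray
    snr: np.ndarray
    mode: str
    annuli: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        n = len(self.radii)
        for arr in (self.target, self.background, self.difference, self.snr):
            if len(arr) != n:
                raise ValueError("curve arrays must share one length")


@dataclass
class OptimalRadius:
    """Arg-max radii of the difference and SNR curves."""

    radius_px: float | None
    snr_radius_px: float | None
    boundary_maximum: bool
    detected: bool
    message: str = ""


@dataclass
class DepthEstimate:
    """Best-fit effective emitter depth with a bootstrap interval."""

    depth_mm: float | None
    amplitude: float | None
    ci_mm: tuple[float, float] | None
    ok: bool
    message: str = ""


def ratiometric_curve(
    spectrum: OffsetSpectrum,
    peak_deep: float,
    peak_shallow: float,
    window: float = 4.0,
    background_removal: bool = True,
    floor: float = 10.0,
    poly_order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RatioCurve:
    """Per-bin ratio of the deep-layer peak to the shallow-layer peak.

    The deep dye is the numerator, so growth of the curve across bins reads
    directly as enrichment of signal from depth.  Bins whose shallow peak
    is below ``floor`` counts are flagged undefined rather than dropped.
    """
    if abs(peak_deep - peak_shallow) < window:
        raise ValueError(
            f"peaks {peak_deep} and {peak_shallow} nm closer than the window ({window} nm)"
        )
    lam = spectrum.lambda_axis
    n = spectrum.n_offsets
    ratio = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for k in range(n):
        row = spectrum.row(k)
        if background_removal:
            row = remove_background(
                row, poly_order=poly_order, max_iter=max_iter, tol=tol, lambda_axis=lam
            ).corrected
        deep = measure_peak(row, lam, peak_deep, window)
        shallow = measure_peak(row, lam, peak_shallow, window)
        if shallow >= floor:
            ratio[k] = deep / shallow
            defined[k] = True
    return RatioCurve(
        spectrum.scheme.annuli,
        ratio,
        defined,
        (("deep", float(peak_deep)), ("shallow", float(peak_shallow))),
    )


def _scheme_from_radii(radii: np.ndarray, mode: str) -> OffsetBinningScheme:
    if mode == ANNULUS:
        edges = np.concatenate(([0.0], radii))
        annuli = tuple(zip(edges[:-1], edges[1:]))
    else:
        annuli = tuple((0.0, r) for r in radii)
    return OffsetBinningScheme(annuli, mode=mode)


def _nearest_lambda_index(lam: np.ndarray, wavelength: float) -> int:
    step = float(np.min(np.diff(lam))) if len(lam) > 1 else 1.0
    j = int(np.argmin(np.abs(lam - wavelength)))
    if abs(lam[j] - wavelength) > step / 2.0 + 1e-12:
        raise ValueError(f"wavelength {wavelength} nm outside scanned axis")
    return j


def signal_vs_radius(
    data,
    target_position: tuple[int, int],
    background_position: tuple[int, int],
    wavelength: float,
    radii,
    mode: str = ANNULUS,
    center=None,
) -> RadialCurveSet:
    """Target and background bin sums versus bin radius at one wavelength.

    ``data`` is an :class:`AcquisitionSet` (frames are binned on the fly)
    or a :class:`HyperCube` whose scheme matches ``radii``/``mode``.
    Positions are (iy, ix) stage-grid indices.  SNR uses the shot-noise
    form ``(T - B) / sqrt(T + B)``.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) == 0 or np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ValueError("radii must be a strictly increasing positive sequence")
    t_iy, t_ix = target_position
    b_iy, b_ix = background_position
    if (t_iy, t_ix) == (b_iy, b_ix):
        pass  # allowed; difference is identically zero

    if isinstance(data, AcquisitionSet):
        plan = data.plan
        j = _nearest_lambda_index(plan.lambda_axis, wavelength)
        scheme = _scheme_from_radii(radii, mode)
        if center is None:
            center = default_center(data.detector.shape)
        sums = {}
        for (iy, ix) in {(t_iy, t_ix), (b_iy, b_ix)}:
            if not (0 <= iy < len(plan.y_positions) and 0 <= ix < len(plan.x_positions)):
                raise ValueError(f"position ({iy}, {ix}) not on the stage grid")
            ip = plan.position_index(iy, ix)
            sums[(iy, ix)] = bin_frame(data.frames[ip, j], scheme, center).sums.astype(float)
        target = sums[(t_iy, t_ix)]
        background = sums[(b_iy, b_ix)]
        annuli = scheme.annuli
    elif isinstance(data, HyperCube):
        if data.scheme.mode != mode:
            raise ValueError(f"cube scheme mode {data.scheme.mode!r} != requested {mode!r}")
        outer = data.scheme.outer_radii
        if len(outer) != len(radii) or not np.allclose(outer, radii):
            raise ValueError("cube scheme radii do not match the requested radii")
        j = _nearest_lambda_index(data.lambda_axis, wavelength)
        for (iy, ix) in ((t_iy, t_ix), (b_iy, b_ix)):
            if not (0 <= iy < data.data.shape[0] and 0 <= ix < data.data.shape[1]):
                raise ValueError(f"position ({iy}, {ix}) not on the stage grid")
        target = data.data[t_iy, t_ix, :, j].astype(float)
        background = data.data[b_iy, b_ix, :, j].astype(float)
        annuli = data.scheme.annuli
    else:
        raise TypeError("data must be an AcquisitionSet or a HyperCube")

    difference = target - background
    tot = target + background
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(tot > 0, difference / np.sqrt(np.clip(tot, 1e-300, None)), 0.0)
    return RadialCurveSet(radii, target, background, difference, snr, mode, annuli)


def optimal_radius(curves: RadialCurveSet) -> OptimalRadius:
    """Radius maximizing the background-subtracted target signal.

    Ties break toward the smaller radius; a maximum on either end of the
    radius range is flagged as a boundary maximum.  The SNR-maximizing
    radius is reported separately.
    """
    if len(curves.radii) == 0:
        raise ValueError("empty curve set")
    diff = curves.difference
    if np.all(diff == 0):
        return OptimalRadius(None, None, False, False, "no target detected")
    k = int(np.argmax(diff))
    k_snr = int(np.argmax(curves.snr))
    boundary = k in (0, len(diff) - 1)
    return OptimalRadius(
        float(curves.radii[k]),
        float(curves.radii[k_snr]),
        boundary,
        True,
        "maximum on range boundary" if boundary else "",
    )


# ---------------------------------------------------------------------------
# model-based depth estimation

from functools import lru_cache


@lru_cache(maxsize=32)
def _cached_model_matrix(
    annuli_key: tuple, mu_a: float, mu_sp: float, z_key: tuple
) -> np.ndarray:
    optics = OpticalProperties(mu_a, mu_sp)
    annuli_mm = np.array(annuli_key)
    z_grid = np.geomspace(z_key[0], z_key[1], int(z_key[2]))
    return np.stack([_annulus_model(annuli_mm, z, optics) for z in z_grid])


def _annulus_model(
    annuli_mm: np.ndarray, depth: float, optics: OpticalProperties, n_grid: int = 2048
) -> np.ndarray:
    """Escape-kernel mass in each annulus (continuum integral, mm units)."""
    r_max = annuli_mm[-1, 1]
    rho = np.linspace(0.0, r_max, n_grid)
    k = surface_escape_kernel(depth, optics, rho)
    cum = np.concatenate(([0.0], cumulative_trapezoid(2 * np.pi * rho * k, rho)))
    lo = np.interp(annuli_mm[:, 0], rho, cum)
    hi = np.interp(annuli_mm[:, 1], rho, cum)
    return hi - lo


def expected_offset_profile(
    depth: float,
    optics: OpticalProperties,
    detector: DetectorModel,
    scheme: OffsetBinningScheme,
    total_counts: float | None = None,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Forward-model per-annulus expectation for a point emitter at ``depth``.

    Radii of the scheme are pixels; the detector's sample-plane pixel scale
    converts them to mm.  If ``total_counts`` is given the profile is
    rescaled to that total.
    """
    scale = detector.sample_pixel_mm
    annuli_mm = np.array(scheme.annuli) * scale
    prof = amplitude * _annulus_model(annuli_mm, depth, optics)
    if total_counts is not None:
        s = prof.sum()
        if s <= 0:
            raise ValueError("degenerate model profile")
        prof = prof * (total_counts / s)
    return prof


def _fit_depth(
    y: np.ndarray,
    annuli_mm: np.ndarray,
    optics: OpticalProperties,
    z_grid: np.ndarray,
    model_matrix: np.ndarray,
    refine: bool = True,
) -> tuple[float, float]:
    """Least-squares depth with profiled amplitude; returns (z, amplitude)."""
    mm = model_matrix
    num = mm @ y
    den = np.einsum("ij,ij->i", mm, mm)
    amp = np.where(den > 0, np.clip(num / den, 0.0, None), 0.0)
    sse = np.sum(y**2) - 2 * amp * num + amp**2 * den
    i = int(np.argmin(sse))
    z0 = z_grid[i]
    if not refine:
        return float(z0), float(amp[i])

    lo = z_grid[max(0, i - 1)]
    hi = z_grid[min(len(z_grid) - 1, i + 1)]

    def sse_of(z: float) -> float:
        m = _annulus_model(annuli_mm, z, optics)
        d = float(m @ m)
        a = max(0.0, float(m @ y) / d) if d > 0 else 0.0
        r = y - a * m
        return float(r @ r)

    res = minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    z = float(res.x)
    m = _annulus_model(annuli_mm, z, optics)
    d = float(m @ m)
    a = max(0.0, float(m @ y) / d) if d > 0 else 0.0
    return z, a


def estimate_depth(
    profile: OffsetProfile,
    optics: OpticalProperties,
    detector: DetectorModel,
    z_bounds: tuple[float, float] = (0.05, 10.0),
    n_boot: int = 100,
    seed: int | None = None,
) -> DepthEstimate:
    """Effective emitter depth from one annulus profile by inverse model fit.

    Fits ``amplitude x (escape-kernel annulus mass at depth z)`` to the
    measured per-annulus sums by least squares, with the amplitude profiled
    out (the estimate is therefore invariant to overall scaling).  Assumes
    a single dominant emitter depth and known bulk optics — a strong
    idealization that transfers poorly to layered or irregular samples.
    The confidence interval is a percentile bootstrap over annuli.
    """
    if profile.scheme.mode != ANNULUS:
        raise ValueError("depth estimation expects an annulus-mode profile")
    y = np.asarray(profile.sums, dtype=float)
    if y.max() <= 0 or (y.max() - y.min()) <= 1e-12 * max(1.0, abs(y.max())):
        return DepthEstimate(None, None, None, False, "profile flat or empty; depth not identifiable")
    scale = detector.sample_pixel_mm
    annuli_mm = np.array(profile.scheme.annuli) * scale
    n_z = 120
    z_grid = np.geomspace(z_bounds[0], z_bounds[1], n_z)
    model_matrix = _cached_model_matrix(
        tuple(map(tuple, annuli_mm)), optics.mu_a, optics.mu_s_prime,
        (z_bounds[0], z_bounds[1], n_z),
    )
    z, amp = _fit_depth(y, annuli_mm, optics, z_grid, model_matrix)

    ci = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        zs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            zb, _ = _fit_depth(
                y[idx], annuli_mm[idx], optics, z_grid, model_matrix[:, idx], refine=False
            )
            zs.append(zb)
        ci = (float(np.percentile(zs, 2.5)), float(np.percentile(zs, 97.5)))
    return DepthEstimate(float(z), float(amp), ci, True)
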