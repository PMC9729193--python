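"""Wavelength/Raman-shift bookkeeping, offset spectra, background removal.

Spectra live on the instrument's wavelength axis (nm) because the tunable
filter scans wavelengths; Raman shifts (cm^-1) are a view obtained through
the exact conversion against the excitation line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import OffsetBinningScheme, bin_frame, default_center

__all__ = [
    "shift_to_wavelength",
    "wavelength_to_shift",
    "OffsetSpectrum",
    "BackgroundFitResult",
    "build_offset_spectrum",
    "remove_background",
    "measure_peak",
]

NM_PER_CM = 1e7  # nm * cm^-1


def shift_to_wavelength(shift_cm1: float, excitation_nm: float):
    """Emission wavelength (nm) of a Raman shift (cm^-1) for a given laser line.

    lambda = 1 / (1/lambda_ex - shift * 1e-7), with the shift expressed in
    cm^-1 and wavelengths in nm.  Raises for shifts at or beyond the
    excitation photon energy (nonphysical Stokes shift).
    """
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be > 0")
    shift = np.asarray(shift_cm1, dtype=float)
    wn = NM_PER_CM / excitation_nm - shift
    if np.any(wn <= 0):
        raise ValueError(
            f"shift {shift_cm1} cm^-1 is >= the excitation wavenumber "
            f"({NM_PER_CM / excitation_nm:.1f} cm^-1)"
        )
    out = NM_PER_CM / wn
    return float(out) if np.isscalar(shift_cm1) else out


def wavelength_to_shift(wavelength_nm: float, excitation_nm: float):
    """Inverse of :func:`shift_to_wavelength` (exact round trip)."""
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be > 0")
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    out = NM_PER_CM / excitation_nm - NM_PER_CM / lam
    return float(out) if np.isscalar(wavelength_nm) else out


@dataclass
class OffsetSpectrum:
    """Binned intensities at one stage position: (n_offsets x n_wavelengths)."""

    intensities: np.ndarray
    lambda_axis: np.ndarray
    scheme: OffsetBinningScheme
    stage_xy: tuple[float, float]
    pixel_counts: np.ndarray | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.lambda_axis = np.asarray(self.lambda_axis, dtype=float)
        if np.any(np.diff(self.lambda_axis) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.intensities.shape != (self.scheme.n_bins, len(self.lambda_axis)):
            raise ValueError(
                f"intensity matrix {self.intensities.shape} does not match "
                f"scheme ({self.scheme.n_bins}) x axis ({len(self.lambda_axis)})"
            )

    @property
    def n_offsets(self) -> int:
        return self.scheme.n_bins

    def row(self, k: int) -> np.ndarray:
        return self.intensities[k]

    def to_csv(self, path) -> None:
        """CSV export: wavelength first, one ``Ir<.>_Or<.>`` column per bin."""
        import pandas as pd

        cols = {"wavelength_nm": self.lambda_axis}
        for k, (a, b) in enumerate(self.scheme.annuli):
            cols[f"Ir{a:g}_Or{b:g}"] = self.intensities[k]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode: str = "annulus", stage_xy=(0.0, 0.0)) -> "OffsetSpectrum":
        import pandas as pd

        df = pd.read_csv(path)
        lam = df["wavelength_nm"].to_numpy()
        annuli = []
        rows = []
        for c in df.columns:
            if c.startswith("Ir"):
                a, b = c[2:].split("_Or")
                annuli.append((float(a), float(b)))
                rows.append(df[c].to_numpy())
        scheme = OffsetBinningScheme(tuple(annuli), mode=mode)
        return cls(np.vstack(rows), lam, scheme, tuple(stage_xy))


def build_offset_spectrum(
    frames_at_position,
    scheme: OffsetBinningScheme,
    center=None,
    lambda_axis=None,
) -> OffsetSpectrum:
    """Bin a per-wavelength frame list into an offset-by-wavelength matrix.

    All frames must share one stage position and carry distinct wavelengths;
    if ``lambda_axis`` is given, the frames must cover it exactly.
    """
    frames = list(frames_at_position)
    if not frames:
        raise ValueError("no frames given")
    pos = frames[0].stage_xy
    for f in frames:
        if f.stage_xy != pos:
            raise ValueError(f"frames mix stage positions {pos} and {f.stage_xy}")
    wls = np.array([f.wavelength for f in frames])
    order = np.argsort(wls)
    wls = wls[order]
    frames = [frames[i] for i in order]
    if len(np.unique(wls)) != len(wls):
        raise ValueError("duplicate wavelengths in frame list")
    if lambda_axis is not None:
        lam = np.asarray(lambda_axis, dtype=float)
        if len(lam) != len(wls) or not np.allclose(lam, wls):
            missing = sorted(set(np.round(lam, 6)) - set(np.round(wls, 6)))
            raise ValueError(f"frame wavelengths do not cover the axis; missing {missing}")
    if center is None:
        center = default_center(frames[0].data.shape)
    cols = []
    counts = None
    for f in frames:
        prof = bin_frame(f, scheme, center)
        cols.append(prof.sums)
        counts = prof.pixel_counts
    matrix = np.stack(cols, axis=1).astype(float)
    return OffsetSpectrum(matrix, wls, scheme, tuple(pos), pixel_counts=counts)


@dataclass
class BackgroundFitResult:
    """Result of iterative-polynomial background removal on one spectrum row."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations_used: int
    converged: bool


def remove_background(
    spectrum_row,
    poly_order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    lambda_axis=None,
    final_refit: bool = True,
) -> BackgroundFitResult:
    """Strip a broad fluorescence background by iterative modified polyfit.

    Repeatedly (1) least-squares fit a polynomial of order ``poly_order``
    to the working vector, (2) clip every point lying above the fit plus
    the current noise deviation down to that level, until the deviation
    stabilises to within ``tol`` times the input range (or ``max_iter``).
    Narrow peaks survive because the clipping removes their pull on the
    fit; the smooth background does not.  Clipping at ``fit + dev`` rather
    than at the fit itself avoids the downward ratchet of the plain
    clipped iteration.

    With ``final_refit`` (default) the converged polynomial is then refit
    in a few passes restricted to background samples (residual below a
    noise-scaled margin), which sheds the residual lift that broad peak
    wings exert on the baseline.  The final polynomial is the baseline and
    ``corrected = input - baseline``.
    """
    y = np.asarray(spectrum_row, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1D spectrum row")
    if len(y) <= poly_order + 1:
        raise ValueError(
            f"need more than poly_order+1={poly_order + 1} samples, got {len(y)}"
        )
    x = np.asarray(lambda_axis, dtype=float) if lambda_axis is not None else np.arange(len(y), dtype=float)
    y_range = float(y.max() - y.min())
    if y_range == 0.0:
        return BackgroundFitResult(y.copy(), np.zeros_like(y), 1, True)

    work = y.copy()
    baseline = work
    dev = 0.0
    prev_dev = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        poly = np.polynomial.Polynomial.fit(x, work, poly_order)
        baseline = poly(x)
        dev = float(np.std(work - baseline))
        work = np.minimum(work, baseline + dev)
        if prev_dev is not None and abs(dev - prev_dev) < tol * y_range:
            converged = True
            break
        prev_dev = dev
    if final_refit:
        for _ in range(5):
            resid = y - baseline
            neg = resid[resid < 0]
            scale = min(dev, float(np.std(neg))) if len(neg) > 3 else dev
            margin = max(tol * y_range, 3.0 * scale)
            keep = resid <= margin
            if keep.sum() <= poly_order + 2:
                break
            poly = np.polynomial.Polynomial.fit(x[keep], y[keep], poly_order)
            baseline = poly(x)
    return BackgroundFitResult(baseline, y - baseline, iterations, converged)


def measure_peak(
    spectrum_row,
    lambda_axis,
    target: float,
    window: float = 4.0,
    remove_bg: bool = False,
    **bg_kwargs,
) -> float:
    """Peak intensity: maximum of the (optionally background-corrected) row
    within ``target +/- window/2`` nm."""
    y = np.asarray(spectrum_row, dtype=float)
    lam = np.asarray(lambda_axis, dtype=float)
    if y.shape != lam.shape:
        raise ValueError("row and axis lengths differ")
    if window <= 0:
        raise ValueError("window must be > 0")
    sel = np.abs(lam - target) <= window / 2.0
    if not np.any(sel):
        raise ValueError(
            f"window {target}+-{window / 2} nm contains no axis samples "
            f"(axis {lam[0]}..{lam[-1]} nm)"
        )
    if remove_bg:
        y = remove_background(y, lambda_axis=lam, **bg_kwargs).corrected
    return float(y[sel].max())
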