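"""Assembly of per-position offset spectra into the 4D hypercube.

The cube is indexed ``[y, x, offset, wavelength]`` with y increasing
downward to match raster scanning.  One stage position maps to exactly one
map superpixel; no overlap blending is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import OffsetBinningScheme, bin_frame, default_center
from .phantom import AcquisitionSet

__all__ = [
    "HyperCube",
    "SliceMap",
    "assemble_hypercube",
    "slice_map",
    "write_hypercube",
    "read_hypercube",
]


@dataclass
class HyperCube:
    """4D dataset [y_index, x_index, offset_index, lambda_index] (counts)."""

    data: np.ndarray
    stage_x: np.ndarray
    stage_y: np.ndarray
    scheme: OffsetBinningScheme
    lambda_axis: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.stage_x = np.asarray(self.stage_x, dtype=float)
        self.stage_y = np.asarray(self.stage_y, dtype=float)
        self.lambda_axis = np.asarray(self.lambda_axis, dtype=float)
        expected = (
            len(self.stage_y),
            len(self.stage_x),
            self.scheme.n_bins,
            len(self.lambda_axis),
        )
        if self.data.shape != expected:
            raise ValueError(f"cube shape {self.data.shape} does not match axes {expected}")
        for ax, name in ((self.stage_x, "stage_x"), (self.stage_y, "stage_y")):
            if len(ax) > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")


@dataclass
class SliceMap:
    """2D stage-grid map at one wavelength and one offset selection."""

    values: np.ndarray
    stage_x: np.ndarray
    stage_y: np.ndarray
    wavelength: float
    offset: object  # bin index or "summed"

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.stage_y, columns=self.stage_x).to_csv(path)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32), software=False)


def assemble_hypercube(
    acquisition: AcquisitionSet,
    scheme: OffsetBinningScheme,
    center=None,
) -> HyperCube:
    """Bin every frame of a complete scan into the 4D cube.

    ``cube[y, x, k, j]`` is the bin-k sum of the frame at stage position
    (x, y) and wavelength j; the binned representation is lossless in the
    sense that it is exactly the per-frame :func:`~orchid.binning.bin_frame`
    output, in scan order.
    """
    plan = acquisition.plan
    lam = plan.lambda_axis
    nx, ny = len(plan.x_positions), len(plan.y_positions)
    if acquisition.frames.shape[0] != nx * ny:
        raise ValueError(
            f"acquisition holds {acquisition.frames.shape[0]} positions, "
            f"plan grid needs {nx * ny}"
        )
    if center is None:
        center = default_center(acquisition.detector.shape)
    data = np.empty((ny, nx, scheme.n_bins, len(lam)))
    for iy in range(ny):
        for ix in range(nx):
            ip = plan.position_index(iy, ix)
            for j in range(len(lam)):
                prof = bin_frame(acquisition.frames[ip, j], scheme, center)
                data[iy, ix, :, j] = prof.sums
    return HyperCube(
        data,
        np.asarray(plan.x_positions, dtype=float),
        np.asarray(plan.y_positions, dtype=float),
        scheme,
        lam,
    )


def slice_map(cube: HyperCube, wavelength: float, offset="summed") -> SliceMap:
    """Extract the 2D stage map at one wavelength and one offset bin.

    The wavelength snaps to the nearest scanned wavelength within half a
    step; ``offset`` is a bin index or ``"summed"`` (all bins added).
    """
    lam = cube.lambda_axis
    step = float(np.min(np.diff(lam))) if len(lam) > 1 else 1.0
    j = int(np.argmin(np.abs(lam - wavelength)))
    if abs(lam[j] - wavelength) > step / 2.0 + 1e-12:
        raise ValueError(
            f"wavelength {wavelength} nm outside the scanned axis {lam[0]}..{lam[-1]} nm"
        )
    if offset == "summed":
        values = cube.data[:, :, :, j].sum(axis=2)
    else:
        k = int(offset)
        if not 0 <= k < cube.scheme.n_bins:
            raise ValueError(f"offset bin {k} out of range 0..{cube.scheme.n_bins - 1}")
        values = cube.data[:, :, k, j]
    return SliceMap(values, cube.stage_x, cube.stage_y, float(lam[j]), offset)


def write_hypercube(cube: HyperCube, path) -> None:
    """HDF5 layout: /cube plus axis datasets (byte-reproducible writer)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data, track_times=False)
        f.create_dataset("stage_x_mm", data=cube.stage_x, track_times=False)
        f.create_dataset("stage_y_mm", data=cube.stage_y, track_times=False)
        f.create_dataset(
            "offset_bins", data=np.array(cube.scheme.annuli, dtype=float), track_times=False
        )
        f.create_dataset("lambda_nm", data=cube.lambda_axis, track_times=False)
        f["cube"].attrs["binning_mode"] = cube.scheme.mode
        f["cube"].attrs["axis_order"] = "y,x,offset,lambda"


def read_hypercube(path) -> HyperCube:
    import h5py

    with h5py.File(path, "r") as f:
        scheme = OffsetBinningScheme(
            tuple(map(tuple, f["offset_bins"][()])),
            mode=f["cube"].attrs["binning_mode"],
        )
        return HyperCube(
            f["cube"][()],
            f["stage_x_mm"][()],
            f["stage_y_mm"][()],
            scheme,
            f["lambda_nm"][()],
        )
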