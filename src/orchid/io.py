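"""File formats, run configuration, and the staged processing pipeline.

Scan frame stacks are stored either as HDF5 (``/frames[pos, lambda, row,
col]`` with stage/wavelength axis datasets) or as multi-page 32-bit float
TIFF with per-page JSON metadata, so externally acquired stacks can enter
the pipeline at the frame boundary.  All writers are byte-reproducible:
rerunning a pipeline with the same config and seed gives identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np

from .binning import ANNULUS, OffsetBinningScheme
from .hypercube import assemble_hypercube, read_hypercube, write_hypercube
from .phantom import (
    AcquisitionSet,
    DetectorModel,
    EmitterVolume,
    Layer,
    OpticalProperties,
    Phantom,
    ReferenceSpectrum,
    ScanPlan,
    SpectralLine,
    builtin_fixtures,
    default_detector,
    simulate_scan,
)

__all__ = [
    "write_scan_h5",
    "read_scan_h5",
    "write_scan_tiff",
    "read_scan_tiff",
    "RunConfig",
    "load_run_config",
    "phantom_from_dict",
    "run_pipeline",
]


def _package_version() -> str:
    try:
        return _pkg_version("orchid-sonos")
    except PackageNotFoundError:
        return "unknown"


# ---------------------------------------------------------------------------
# scan stacks

def write_scan_h5(acq: AcquisitionSet, path) -> None:
    """HDF5 scan layout: /frames[pos, lambda, row, col] (float32) plus axes."""
    import h5py

    plan = acq.plan
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=acq.frames.astype(np.float32), track_times=False)
        f.create_dataset("stage_x", data=np.asarray(plan.x_positions), track_times=False)
        f.create_dataset("stage_y", data=np.asarray(plan.y_positions), track_times=False)
        f.create_dataset("lambda_nm", data=plan.lambda_axis, track_times=False)
        g = f["frames"]
        g.attrs["exposure_s"] = plan.exposure
        g.attrs["excitation_nm"] = plan.excitation_wavelength
        g.attrs["lambda_step_nm"] = plan.lambda_step
        g.attrs["position_order"] = "iy*nx+ix"
        if acq.rng_seed is not None:
            g.attrs["rng_seed"] = acq.rng_seed
        d = f.create_group("detector")
        for k, v in asdict(acq.detector).items():
            d.attrs[k] = v


def read_scan_h5(path) -> AcquisitionSet:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["frames"]
        det = DetectorModel(**{k: v.item() if hasattr(v, "item") else v
                               for k, v in f["detector"].attrs.items()})
        lam = f["lambda_nm"][()]
        plan = ScanPlan(
            tuple(f["stage_x"][()]),
            tuple(f["stage_y"][()]),
            float(lam[0]),
            float(lam[-1]),
            float(g.attrs["lambda_step_nm"]),
            exposure=float(g.attrs["exposure_s"]),
            excitation_wavelength=float(g.attrs["excitation_nm"]),
        )
        seed = int(g.attrs["rng_seed"]) if "rng_seed" in g.attrs else None
        return AcquisitionSet(g[()].astype(np.float64), plan, det, rng_seed=seed)


def write_scan_tiff(acq: AcquisitionSet, path) -> None:
    """Multi-page float32 TIFF, one page per (position, wavelength) frame.

    Page order is position-major; each page description carries the stage
    position, wavelength and exposure as JSON, and the first page also
    carries the plan and detector so the stack is self-describing.
    """
    import tifffile

    plan = acq.plan
    lam = plan.lambda_axis
    with tifffile.TiffWriter(str(path)) as tw:
        for ip, (sx, sy) in enumerate(plan.positions):
            for j, wl in enumerate(lam):
                meta = {
                    "stage_x_mm": sx,
                    "stage_y_mm": sy,
                    "lambda_nm": float(wl),
                    "exposure_s": plan.exposure,
                }
                if ip == 0 and j == 0:
                    meta["plan"] = {
                        "x_positions": list(plan.x_positions),
                        "y_positions": list(plan.y_positions),
                        "lambda_start": plan.lambda_start,
                        "lambda_stop": plan.lambda_stop,
                        "lambda_step": plan.lambda_step,
                        "exposure": plan.exposure,
                        "excitation_wavelength": plan.excitation_wavelength,
                    }
                    meta["detector"] = asdict(acq.detector)
                    if acq.rng_seed is not None:
                        meta["rng_seed"] = acq.rng_seed
                tw.write(
                    acq.frames[ip, j].astype(np.float32),
                    description=json.dumps(meta, sort_keys=True),
                    software=False,
                    datetime=False,
                    contiguous=False,
                )


def read_scan_tiff(path) -> AcquisitionSet:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        first = json.loads(tf.pages[0].description)
        plan = ScanPlan(
            tuple(first["plan"]["x_positions"]),
            tuple(first["plan"]["y_positions"]),
            first["plan"]["lambda_start"],
            first["plan"]["lambda_stop"],
            first["plan"]["lambda_step"],
            exposure=first["plan"]["exposure"],
            excitation_wavelength=first["plan"]["excitation_wavelength"],
        )
        det = DetectorModel(**first["detector"])
        lam = plan.lambda_axis
        n_pos = plan.n_positions
        frames = np.empty((n_pos, len(lam), det.n_rows, det.n_cols))
        seen = set()
        for page in tf.pages:
            meta = json.loads(page.description)
            pos = (meta["stage_x_mm"], meta["stage_y_mm"])
            ip = plan.positions.index(pos)
            j = int(round((meta["lambda_nm"] - plan.lambda_start) / plan.lambda_step))
            if (ip, j) in seen:
                raise ValueError(f"duplicate frame for position {pos}, {meta['lambda_nm']} nm")
            seen.add((ip, j))
            frames[ip, j] = page.asarray()
        if len(seen) != n_pos * len(lam):
            raise ValueError(
                f"incomplete stack: {len(seen)} frames for a {n_pos} x {len(lam)} grid"
            )
        return AcquisitionSet(frames, plan, det, rng_seed=first.get("rng_seed"))


# ---------------------------------------------------------------------------
# configuration

def phantom_from_dict(d: dict) -> Phantom:
    """Build a phantom from the documented YAML-compatible key tree.

    Schema (units in key names or documented here; mm throughout)::

        lateral_extent_mm: [30, 30]
        af_envelope_scale_mm: 25      # or null for laterally uniform
        layers:                       # top to bottom
          - {thickness_mm: 5, mu_a: 0.01, mu_s_prime: 1.0, n: 1.33,
             autofluorescence_coeffs: [c0, c1, ...]}   # ascending, vs nm
        spectra:
          - {id: GNS-DTTC, mode: raman_shift,          # or direct_wavelength
             lines: [[center, fwhm_nm, amplitude], ...]}
        emitters:
          - {box_mm: [x0, x1, y0, y1, z0, z1], spectrum: GNS-DTTC,
             concentration: 1e7}
    """
    layers = tuple(
        Layer(
            l["thickness_mm"],
            OpticalProperties(l.get("mu_a", 0.01), l.get("mu_s_prime", 1.0), l.get("n", 1.33)),
            tuple(l.get("autofluorescence_coeffs", (0.0,))),
        )
        for l in d["layers"]
    )
    spectra = tuple(
        ReferenceSpectrum(
            s["id"], s["mode"], tuple(SpectralLine(*line) for line in s["lines"])
        )
        for s in d.get("spectra", ())
    )
    emitters = tuple(
        EmitterVolume(tuple(e["box_mm"]), e["spectrum"], e["concentration"])
        for e in d.get("emitters", ())
    )
    return Phantom(
        layers,
        emitters,
        spectra,
        tuple(d["lateral_extent_mm"]),
        af_envelope_scale_mm=d.get("af_envelope_scale_mm", 25.0),
    )


def _plan_from_dict(d: dict) -> ScanPlan:
    if "x_positions" in d:
        return ScanPlan(
            tuple(d["x_positions"]), tuple(d["y_positions"]),
            d["lambda_start"], d["lambda_stop"], d["lambda_step"],
            exposure=d.get("exposure", 1.0),
            excitation_wavelength=d.get("excitation_wavelength", 785.0),
        )
    return ScanPlan.from_grid(
        d["x0"], d["y0"], d["nx"], d["ny"], d["step"],
        lambda_start=d["lambda_start"], lambda_stop=d["lambda_stop"],
        lambda_step=d["lambda_step"], exposure=d.get("exposure", 1.0),
        excitation_wavelength=d.get("excitation_wavelength", 785.0),
    )


def _scheme_from_dict(d: dict) -> OffsetBinningScheme:
    mode = d.get("mode", ANNULUS)
    if "annuli" in d:
        return OffsetBinningScheme(tuple(map(tuple, d["annuli"])), mode=mode)
    return OffsetBinningScheme.from_width(
        d["r_max"], d.get("width", 1.0), d.get("r_min", 0.0), mode=mode
    )


@dataclass
class RunConfig:
    """Fully validated pipeline configuration.

    Every field is resolved (fixture names expanded, defaults applied)
    before any computation starts; the canonical dict form is hashed into
    the provenance record.
    """

    phantom: Phantom
    plan: ScanPlan
    detector: DetectorModel
    scheme: OffsetBinningScheme
    seed: int = 0
    noise: str = "on"
    poly_order: int = 5
    max_iter: int = 100
    tol: float = 1e-6
    peak_window: float = 4.0
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_run_config(source) -> RunConfig:
    """Parse and validate a YAML config file (or an equivalent dict)."""
    import yaml

    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if "fixture" in raw:
        phantom, plan = builtin_fixtures(raw["fixture"])
    else:
        phantom = phantom_from_dict(raw["phantom"])
        plan = _plan_from_dict(raw["plan"])
    if "plan" in raw and "fixture" in raw:
        plan = _plan_from_dict(raw["plan"])  # explicit plan overrides fixture plan
    detector = (
        DetectorModel(**raw["detector"]) if "detector" in raw else default_detector()
    )
    scheme = _scheme_from_dict(raw.get("scheme", {"r_max": 150.0, "width": 1.0}))
    proc = raw.get("processing", {})
    cfg = RunConfig(
        phantom=phantom,
        plan=plan,
        detector=detector,
        scheme=scheme,
        seed=int(raw.get("seed", 0)),
        noise=raw.get("noise", "on"),
        poly_order=int(proc.get("poly_order", 5)),
        max_iter=int(proc.get("max_iter", 100)),
        tol=float(proc.get("tol", 1e-6)),
        peak_window=float(proc.get("peak_window", 4.0)),
        raw=raw,
    )
    if cfg.noise not in ("on", "off"):
        raise ValueError("noise must be 'on' or 'off'")
    return cfg


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, outdir, ingest=None) -> dict:
    """Simulate (or ingest) -> bin -> assemble -> report, checkpointed to disk.

    Returns the artifact paths.  With a fixed config and seed the outputs
    are byte-identical across reruns.  ``ingest`` may name an existing scan
    file (.h5 or .tif) to skip simulation, so real instrument data can
    enter at the frame-stack boundary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scan": outdir / "scan.h5",
        "cube": outdir / "cube.h5",
        "report": outdir / "report.json",
    }
    try:
        if ingest is not None:
            ingest = Path(ingest)
            acq = (
                read_scan_tiff(ingest)
                if ingest.suffix.lower() in (".tif", ".tiff")
                else read_scan_h5(ingest)
            )
        else:
            acq = simulate_scan(
                config.phantom, config.detector, config.plan,
                noise=config.noise, seed=config.seed,
            )
        write_scan_h5(acq, paths["scan"])
    except ValueError as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    try:
        # re-read the checkpoint so ingested and simulated scans follow the
        # exact same (float32 frame) path into the cube
        acq = read_scan_h5(paths["scan"])
        cube = assemble_hypercube(acq, config.scheme)
        write_hypercube(cube, paths["cube"])
    except ValueError as exc:
        raise RuntimeError(f"stage 'cube' failed: {exc}") from exc
    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "noise": config.noise,
            "package_version": _package_version(),
        },
        "scan": {
            "n_positions": config.plan.n_positions,
            "n_wavelengths": len(config.plan.lambda_axis),
            "detector": asdict(config.detector),
        },
        "cube_shape": list(cube.data.shape),
    }
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
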