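"""Disk formats: multi-page TIFF stacks and maps with JSON sidecars.

An interferogram stack is stored as a multi-page TIFF in acquisition order
(step-major) plus a ``.json`` sidecar carrying the per-step reference
phases, timestamps, optics/plan/drive parameters and the scene's optical
contrast — everything needed to reconstruct without the original scene.
Float maps (thickness series, displacement, stiffness) are float32
multi-page TIFFs with metadata sidecars.  All writers round-trip losslessly
through the matching readers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .reconstruct import ThicknessSeries
from .simulate import (
    AcousticDrive,
    AcquisitionPlan,
    InterferogramStack,
    NoiseModel,
    OpticalConfig,
)
from .stiffness import StiffnessMap

__all__ = [
    "write_stack",
    "read_stack",
    "write_series",
    "read_series",
    "write_stiffness_map",
    "read_stiffness_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: InterferogramStack, path: str | Path) -> None:
    """Write frames (acquisition order) + metadata sidecar."""
    path = Path(path)
    n_steps, fps, ny, nx = stack.frames.shape
    frames = stack.frames.reshape(n_steps * fps, ny, nx)
    if np.issubdtype(frames.dtype, np.integer) or (
        np.all(frames == np.rint(frames)) and frames.max() < 65536
    ):
        data = frames.astype(np.uint16)
        dtype = "uint16"
    else:
        data = frames.astype(np.float32)
        dtype = "float32"
    tifffile.imwrite(path, data, photometric="minisblack")
    optics = dataclasses.asdict(stack.optics)
    optics["background_phase"] = (
        None
        if stack.optics.background_phase is None
        else np.asarray(stack.optics.background_phase).tolist()
    )
    meta = {
        "dtype": dtype,
        "n_steps": int(n_steps),
        "frames_per_step": int(fps),
        "theta": stack.theta.tolist(),
        "timestamps": stack.timestamps.tolist(),
        "psi": stack.psi.tolist(),
        "optics": optics,
        "plan": dataclasses.asdict(stack.plan),
        "drive": dataclasses.asdict(stack.drive),
        "delta_n": stack.delta_n,
        "pixel_pitch": stack.pixel_pitch,
        "step_offsets": None
        if stack.step_offsets is None
        else np.asarray(stack.step_offsets).tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_stack(path: str | Path) -> InterferogramStack:
    """Read a stack written by :func:`write_stack`, validating the sidecar."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    n_steps, fps = meta["n_steps"], meta["frames_per_step"]
    if frames.shape[0] != n_steps * fps:
        raise ValueError(
            f"sidecar declares {n_steps} steps x {fps} frames = {n_steps * fps} "
            f"pages but the TIFF holds {frames.shape[0]}"
        )
    timestamps = np.asarray(meta["timestamps"], dtype=float)
    if np.any(np.diff(timestamps.ravel()) <= 0):
        raise ValueError("sidecar timestamps are not strictly increasing")
    optics_meta = dict(meta["optics"])
    noise = NoiseModel(**optics_meta.pop("noise"))
    bg = optics_meta.pop("background_phase", None)
    optics = OpticalConfig(
        background_phase=None if bg is None else np.asarray(bg, dtype=float),
        noise=noise,
        **optics_meta,
    )
    return InterferogramStack(
        frames=frames.reshape(n_steps, fps, *frames.shape[1:]).astype(float),
        theta=np.asarray(meta["theta"], dtype=float),
        timestamps=timestamps,
        psi=np.asarray(meta["psi"], dtype=float),
        optics=optics,
        plan=AcquisitionPlan(**meta["plan"]),
        drive=AcousticDrive(**meta["drive"]),
        delta_n=meta["delta_n"],
        pixel_pitch=meta["pixel_pitch"],
        step_offsets=None
        if meta["step_offsets"] is None
        else np.asarray(meta["step_offsets"], dtype=int),
    )


def write_series(series: ThicknessSeries, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(series.maps, dtype=np.float32), photometric="minisblack")
    meta = {
        "psi": np.asarray(series.psi).tolist(),
        "wavelength": series.wavelength,
        "n_sample": series.n_sample,
        "n_medium": series.n_medium,
        "pixel_pitch": series.pixel_pitch,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_series(path: str | Path) -> ThicknessSeries:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    maps = tifffile.imread(path).astype(float)
    if maps.ndim == 2:
        maps = maps[None]
    return ThicknessSeries(
        maps=maps,
        psi=np.asarray(meta["psi"], dtype=float),
        wavelength=meta["wavelength"],
        n_sample=meta["n_sample"],
        n_medium=meta["n_medium"],
        pixel_pitch=meta["pixel_pitch"],
    )


def write_stiffness_map(smap: StiffnessMap, path: str | Path) -> None:
    """Stiffness map as float32 pages (E, mask) + JSON summary sidecar."""
    path = Path(path)
    pages = np.stack([smap.E, smap.mask.astype(float)]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = smap.summary()
    meta["n_iterations"] = smap.n_iterations
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stiffness_map(path: str | Path) -> StiffnessMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path).astype(float)
    return StiffnessMap(
        E=pages[0],
        mask=pages[1] > 0.5,
        pressure=meta["pressure_Pa"],
        poisson_ratio=meta["poisson_ratio"],
        lateral_tension=meta["lateral_tension_N_per_m"],
        model=meta["model"],
        n_iterations=meta.get("n_iterations", 0),
    )
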