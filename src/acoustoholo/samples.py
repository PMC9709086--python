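"""Synthetic phase objects: reference microbeads and cell-like blobs.

A :class:`SampleScene` is the ground truth the rest of the package works
against: a projected-thickness field ``h0(x, y)`` (µm), a Young's-modulus
field ``E_true(x, y)`` (Pa), and the refractive indices that turn thickness
into optical phase.  Scenes are generated deterministically from explicit
seeds so that simulated acquisitions are exactly reproducible.

Material presets collect refractive indices and nominal elastic moduli of
the reference materials commonly used to validate holographic stiffness
measurements (polystyrene, polyacrylamide and agarose microbeads, plus the
immersion media they are measured in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "MaterialPreset",
    "PRESETS",
    "SampleScene",
    "bead_scene",
    "cell_scene",
    "ensemble",
    "bead_factory",
    "cell_factory",
]


@dataclass(frozen=True)
class MaterialPreset:
    """Optical and mechanical constants of a sample or medium material.

    Parameters
    ----------
    refractive_index : dimensionless (> 1).
    nominal_stiffness : Pa, Young's modulus; ``None`` for pure media.
    nominal_diameter : µm, typical particle diameter; ``None`` if n/a.
    medium_index : refractive index of the medium the material is usually
        immersed in, if there is a conventional pairing.
    """

    name: str
    refractive_index: float
    nominal_stiffness: float | None = None
    nominal_diameter: float | None = None
    medium_index: float | None = None

    def __post_init__(self) -> None:
        if not self.refractive_index > 1.0:
            raise ValueError(
                f"refractive_index must exceed 1 (got {self.refractive_index})"
            )
        if self.nominal_stiffness is not None and not self.nominal_stiffness > 0:
            raise ValueError("nominal_stiffness must be positive when present")


#: Reference materials.  Refractive indices are the standard handbook values
#: at visible wavelengths (PS at 589 nm, 8% PAA and 0.04% agarose beads near
#: room temperature); moduli are the nominal values for the usual validation
#: particles (vendor GPa-scale PS standards, kPa-scale hydrogel beads) and a
#: generic epithelial cell.
PRESETS: dict[str, MaterialPreset] = {
    "PS": MaterialPreset("PS", 1.5915, 1.05e9, 5.0, medium_index=1.334),
    "PAA": MaterialPreset("PAA", 1.349, 1.94e3, 31.0, medium_index=1.334),
    "agarose": MaterialPreset("agarose", 1.3329, 2.43e3, 34.7, medium_index=1.334),
    "cell": MaterialPreset("cell", 1.370, 1.08e3, 16.0, medium_index=1.337),
    "DI_water": MaterialPreset("DI_water", 1.334),
    "DMEM_F12": MaterialPreset("DMEM_F12", 1.337),
    "glycerol": MaterialPreset("glycerol", 1.4722),
}


@dataclass
class SampleScene:
    """Ground-truth phase object on a regular pixel grid.

    ``h0`` is the projected (integrated) thickness in µm, ``E_true`` the
    Young's modulus in Pa.  ``h0 > 0`` exactly on the support; ``E_true > 0``
    on the support and 0 outside.
    """

    h0: np.ndarray
    E_true: np.ndarray
    n_sample: float
    n_medium: float
    pixel_pitch: float
    name: str = ""

    def __post_init__(self) -> None:
        self.h0 = np.asarray(self.h0, dtype=float)
        self.E_true = np.asarray(self.E_true, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.h0.shape != self.E_true.shape:
            raise ValueError("h0 and E_true must share one shape")
        if self.h0.ndim != 2 or min(self.h0.shape) < 4:
            raise ValueError(f"degenerate grid {self.h0.shape}")
        if np.any(self.h0 < 0):
            raise ValueError("thickness must be non-negative everywhere")
        sup = self.support_mask
        if np.any(self.E_true[sup] <= 0):
            raise ValueError("stiffness must be positive on the support")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def support_mask(self) -> np.ndarray:
        return self.h0 > 0

    @property
    def delta_n(self) -> float:
        return self.n_sample - self.n_medium

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.h0.shape  # type: ignore[return-value]

    def mean_stiffness(self) -> float:
        """Support-averaged Young's modulus (Pa)."""
        return float(self.E_true[self.support_mask].mean())

    def mean_thickness(self) -> float:
        """Support-averaged projected thickness (µm)."""
        return float(self.h0[self.support_mask].mean())

    # -- serialization ---------------------------------------------------
    def _meta(self) -> dict:
        return {
            "n_sample": self.n_sample,
            "n_medium": self.n_medium,
            "pixel_pitch": self.pixel_pitch,
            "name": self.name,
        }

    def to_tiff(self, path: str | Path) -> None:
        """Write (h0, E_true) as two float32 pages plus a JSON sidecar."""
        path = Path(path)
        pages = np.stack([self.h0, self.E_true]).astype(np.float32)
        tifffile.imwrite(path, pages, photometric="minisblack")
        path.with_suffix(".json").write_text(json.dumps(self._meta(), indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "SampleScene":
        path = Path(path)
        pages = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(h0=pages[0], E_true=pages[1], **meta)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("h0", data=self.h0)
            f.create_dataset("E_true", data=self.E_true)
            for k, v in self._meta().items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SampleScene":
        with h5py.File(path, "r") as f:
            return cls(
                h0=f["h0"][...],
                E_true=f["E_true"][...],
                n_sample=float(f.attrs["n_sample"]),
                n_medium=float(f.attrs["n_medium"]),
                pixel_pitch=float(f.attrs["pixel_pitch"]),
                name=str(f.attrs.get("name", "")),
            )


def _pixel_coords(grid_shape: tuple[int, int], pixel_pitch: float):
    ny, nx = grid_shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_pitch
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_pitch
    return np.meshgrid(y, x, indexing="ij")


def bead_scene(
    diameter: float,
    material: MaterialPreset,
    medium: MaterialPreset,
    grid_shape: tuple[int, int] = (256, 256),
    pixel_pitch: float = 0.05,
    stiffness: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
    name: str = "",
) -> SampleScene:
    """Spherical microbead resting on the substrate.

    The projected thickness is the chord length of a sphere of diameter
    ``d``: ``h0(r) = 2*sqrt((d/2)^2 - r^2)`` for ``r < d/2`` and 0 outside,
    so the central thickness equals the diameter.  Stiffness is uniform at
    ``material.nominal_stiffness`` unless overridden.
    """
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    ny, nx = grid_shape
    fov = (min(ny, nx) - 1) * pixel_pitch
    if diameter >= fov:
        raise ValueError(
            f"bead diameter {diameter} µm does not fit inside the "
            f"{fov:.3g} µm field of view ({ny}x{nx} px at {pixel_pitch} µm/px)"
        )
    E0 = stiffness if stiffness is not None else material.nominal_stiffness
    if E0 is None or not E0 > 0:
        raise ValueError("material has no positive nominal stiffness; pass stiffness=")
    yy, xx = _pixel_coords(grid_shape, pixel_pitch)
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    R = diameter / 2.0
    h0 = np.where(r2 < R**2, 2.0 * np.sqrt(np.clip(R**2 - r2, 0.0, None)), 0.0)
    E = np.where(h0 > 0, E0, 0.0)
    return SampleScene(
        h0=h0,
        E_true=E,
        n_sample=material.refractive_index,
        n_medium=medium.refractive_index,
        pixel_pitch=pixel_pitch,
        name=name or f"bead_{material.name}_{diameter:g}um",
    )


def cell_scene(
    mean_diameter: float,
    mean_thickness: float,
    base_stiffness: float,
    heterogeneity: float = 0.13,
    seed: int | np.random.Generator | None = 0,
    grid_shape: tuple[int, int] = (256, 256),
    pixel_pitch: float = 0.1,
    refractive_index: float = 1.370,
    medium_index: float = 1.337,
    corr_length: float | None = None,
    boundary_modes: int = 4,
    boundary_amp: float = 0.08,
    aspect_jitter: float = 0.15,
    profile_power: float = 1.5,
    name: str = "",
) -> SampleScene:
    """Cell-like blob: perturbed-ellipse outline, smooth dome thickness,
    log-normal spatially correlated stiffness.

    The outline is an ellipse whose radius is modulated by a low-order
    Fourier series (modes 2..boundary_modes+1); the thickness profile is
    ``(1 - rho^2)^p`` in the normalized radius, scaled so the support mean
    equals ``mean_thickness``.  The stiffness field is log-normal with mean
    ``base_stiffness`` and relative standard deviation ``heterogeneity``,
    spatially correlated over ``corr_length`` (default: diameter / 10).
    Fully reproducible for a fixed seed.
    """
    if min(mean_diameter, mean_thickness, base_stiffness) <= 0:
        raise ValueError("all scale parameters must be positive")
    if not 0 <= heterogeneity < 1:
        raise ValueError("heterogeneity must lie in [0, 1)")
    ny, nx = grid_shape
    if min(ny, nx) < 8:
        raise ValueError(f"degenerate grid {grid_shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    yy, xx = _pixel_coords(grid_shape, pixel_pitch)
    ecc = aspect_jitter * rng.uniform(-1.0, 1.0)
    a = (mean_diameter / 2.0) * (1.0 + ecc)
    b = (mean_diameter / 2.0) * (1.0 - ecc)
    ang = np.arctan2(yy, xx)
    rho_ell = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
    # band-limited radial boundary perturbation
    mod = np.ones_like(ang)
    for m in range(2, 2 + boundary_modes):
        am, bm = rng.normal(0.0, 1.0, size=2)
        mod += (boundary_amp / m) * (am * np.cos(m * ang) + bm * np.sin(m * ang))
    mod = np.clip(mod, 0.3, None)
    rho = rho_ell / mod

    dome = np.where(rho < 1.0, np.clip(1.0 - rho**2, 0.0, None) ** profile_power, 0.0)
    peak = mean_thickness * (profile_power + 1.0)
    h0 = peak * dome
    support = h0 > 0
    if not support.any():
        raise ValueError("cell outline does not intersect the grid")

    if heterogeneity == 0.0:
        E = np.where(support, base_stiffness, 0.0)
    else:
        cl = corr_length if corr_length is not None else mean_diameter / 10.0
        g = gaussian_filter(rng.standard_normal(grid_shape), cl / pixel_pitch, mode="reflect")
        s = g.std()
        g = g / s if s > 0 else g
        sig = np.sqrt(np.log1p(heterogeneity**2))
        E = base_stiffness * np.exp(sig * g - 0.5 * sig**2)
        E = np.where(support, E, 0.0)
    return SampleScene(
        h0=h0,
        E_true=E,
        n_sample=refractive_index,
        n_medium=medium_index,
        pixel_pitch=pixel_pitch,
        name=name or "cell",
    )


def ensemble(
    scene_factory: Callable[[np.random.Generator], SampleScene],
    n: int,
    seed: int = 0,
) -> list[SampleScene]:
    """``n`` independent scenes with deterministically derived child streams.

    Child random generators are spawned by counter from a master
    ``SeedSequence(seed)``, so ``ensemble(f, n, seed)[i]`` is identical to
    calling ``f`` directly with the i-th spawned stream.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n)
    return [scene_factory(np.random.default_rng(c)) for c in children]


def bead_factory(
    material: MaterialPreset,
    medium: MaterialPreset,
    diameter_mean: float | None = None,
    diameter_sd: float = 0.0,
    stiffness_sd_rel: float = 0.0,
    grid_shape: tuple[int, int] = (256, 256),
    pixel_pitch: float = 0.05,
) -> Callable[[np.random.Generator], SampleScene]:
    """Factory drawing per-bead diameter and stiffness jitter for `ensemble`."""
    d0 = diameter_mean if diameter_mean is not None else material.nominal_diameter
    if d0 is None:
        raise ValueError("material has no nominal diameter; pass diameter_mean=")
    E0 = material.nominal_stiffness

    def make(rng: np.random.Generator) -> SampleScene:
        d = float(np.clip(rng.normal(d0, diameter_sd), 0.2 * d0, None)) if diameter_sd else d0
        E = (
            float(np.clip(rng.normal(E0, stiffness_sd_rel * E0), 0.1 * E0, None))
            if stiffness_sd_rel
            else E0
        )
        return bead_scene(d, material, medium, grid_shape, pixel_pitch, stiffness=E)

    return make


def cell_factory(
    base_stiffness: float = 1.08e3,
    stiffness_sd_rel: float = 0.0,
    mean_diameter: float = 16.0,
    diameter_sd: float = 0.0,
    mean_thickness: float = 4.0,
    heterogeneity: float = 0.13,
    grid_shape: tuple[int, int] = (256, 256),
    pixel_pitch: float = 0.1,
    **kwargs,
) -> Callable[[np.random.Generator], SampleScene]:
    """Factory drawing cell-to-cell diameter/stiffness jitter for `ensemble`."""

    def make(rng: np.random.Generator) -> SampleScene:
        d = mean_diameter + (rng.normal(0.0, diameter_sd) if diameter_sd else 0.0)
        E = base_stiffness * (
            1.0 + (rng.normal(0.0, stiffness_sd_rel) if stiffness_sd_rel else 0.0)
        )
        return cell_scene(
            mean_diameter=max(d, 0.2 * mean_diameter),
            mean_thickness=mean_thickness,
            base_stiffness=max(E, 0.1 * base_stiffness),
            heterogeneity=heterogeneity,
            seed=rng,
            grid_shape=grid_shape,
            pixel_pitch=pixel_pitch,
            **kwargs,
        )

    return make
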