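"""Run configuration: one YAML-serializable object describing a full run.

A :class:`RunConfig` resolves into the domain objects of the simulator and
inversion (scene, optics, drive, plan, elastic model).  It round-trips
losslessly through YAML, and every pipeline run writes its resolved config
next to its outputs so runs are reproducible from the artefacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import samples
from .samples import PRESETS, SampleScene
from .simulate import AcousticDrive, AcquisitionPlan, NoiseModel, OpticalConfig
from .stiffness import ElasticModelParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to simulate, reconstruct and invert one sample.

    ``scene`` is a mapping with a ``kind`` ("bead" or "cell") plus the
    keyword arguments of the corresponding scene builder (material/medium
    given by preset name for beads).  ``snr_db`` sets additive intensity
    noise relative to the mean level; ``None`` means noise-free.
    """

    scene: dict = field(default_factory=lambda: {
        "kind": "bead", "diameter": 5.0, "material": "PAA", "medium": "DI_water",
    })
    grid_shape: tuple[int, int] = (256, 256)
    pixel_pitch: float = 0.05
    wavelength: float = 0.532
    mean_intensity: float = 2000.0
    fringe_visibility: float = 0.9
    snr_db: float | None = None
    full_scale: float = 4095.0
    quantize: bool = False
    frequency: float = 1000.0
    pressure: float = 100.0
    n_steps: int = 20
    step_phase: float = float(np.pi / 10.0)
    frames_per_step: int = 50
    delta_f: float | None = None
    step_offsets: list[int] | str | None = None
    poisson_ratio: float = 0.5
    lateral_tension: float = 0.0
    denoise_sigma: float = 0.0
    denoise_method: str = "wavelet"
    seed: int = 0

    # -- domain object builders -----------------------------------------
    def build_scene(self) -> SampleScene:
        params = dict(self.scene)
        kind = params.pop("kind")
        if kind == "bead":
            material = PRESETS[params.pop("material")]
            medium = PRESETS[params.pop("medium")]
            return samples.bead_scene(
                material=material, medium=medium,
                grid_shape=tuple(self.grid_shape), pixel_pitch=self.pixel_pitch,
                **params,
            )
        if kind == "cell":
            params.setdefault("seed", self.seed)
            return samples.cell_scene(
                grid_shape=tuple(self.grid_shape), pixel_pitch=self.pixel_pitch,
                **params,
            )
        raise ValueError(f"unknown scene kind {kind!r}")

    def build_optics(self) -> OpticalConfig:
        noise = (
            NoiseModel.from_snr(self.mean_intensity, self.snr_db)
            if self.snr_db is not None
            else NoiseModel()
        )
        return OpticalConfig(
            wavelength=self.wavelength,
            mean_intensity=self.mean_intensity,
            fringe_visibility=self.fringe_visibility,
            noise=noise,
            full_scale=self.full_scale,
        )

    def build_drive(self) -> AcousticDrive:
        return AcousticDrive(frequency=self.frequency, pressure=self.pressure)

    def build_plan(self) -> AcquisitionPlan:
        return AcquisitionPlan(
            n_steps=self.n_steps,
            step_phase=self.step_phase,
            frames_per_step=self.frames_per_step,
            delta_f=self.delta_f,
        )

    def build_elastic(self) -> ElasticModelParams:
        return ElasticModelParams(
            poisson_ratio=self.poisson_ratio,
            lateral_tension=self.lateral_tension,
            pressure=self.pressure,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
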