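"""Forward model: acoustic deformation + phase-shifting interferometry.

Software stand-in for the measurement hardware: a piezo actuator steps the
reference-arm phase in increments of π/10 (20 steps spanning 2π), a PZT
transducer drives the sample at ~1 kHz, and a camera synced at
``f_a + Δf`` records 50 frames per phase step — 1000 interferograms per
acquisition.  Because the camera rate is detuned from the drive by Δf, the
frames within one step sweep slowly (stroboscopically) through the vibration
cycle; the default ``Δf = f_a / (frames_per_step − 1)`` makes the 50 frames
tile one cycle uniformly.

The optical model is a pure phase projection: a transparent object of
thickness ``h`` in an immersion medium imposes the phase
``φ = 2π (n_s − n_m) h / λ`` and the detector sees

    I = I0 * (1 + V cos(φ + θ + φ_bg))

plus shot noise (variance proportional to intensity) and additive read
noise, clipped to the detector range.  Deformation follows the compression
convention ``h(ψ) = h0 − w (1 + sin ψ)/2`` with ``w`` from the elastic
forward model, so the thickness never exceeds the resting thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .samples import SampleScene
from .stiffness import ElasticModelParams, elastic_forward

__all__ = [
    "NoiseModel",
    "OpticalConfig",
    "AcousticDrive",
    "AcquisitionPlan",
    "InterferogramStack",
    "deform_thickness",
    "render_interferogram",
    "acquire_stack",
]


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise. Variance at intensity I is shot_scale*I + read_sigma²."""

    shot_scale: float = 0.0  # counts of variance per count of signal
    read_sigma: float = 0.0  # counts

    def __post_init__(self) -> None:
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def enabled(self) -> bool:
        return self.shot_scale > 0 or self.read_sigma > 0

    def predicted_variance(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return self.shot_scale * intensity + self.read_sigma**2

    @classmethod
    def from_snr(cls, mean_intensity: float, snr_db: float) -> "NoiseModel":
        """Additive noise sized so the intensity SNR at I0 is ``snr_db`` dB."""
        return cls(read_sigma=mean_intensity / 10.0 ** (snr_db / 20.0))


@dataclass
class OpticalConfig:
    """Interferometer and detector parameters.

    wavelength in µm (527 nm laser for cell work, 532 nm for bead work in
    water); ``mean_intensity`` I0 and ``full_scale`` in detector counts
    (12-bit default); ``background_phase`` an optional low-order aberration
    field in rad, added to the object phase.
    """

    wavelength: float = 0.527
    mean_intensity: float = 2000.0
    fringe_visibility: float = 0.9
    background_phase: np.ndarray | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    full_scale: float = 4095.0

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if not 0.0 <= self.fringe_visibility <= 1.0:
            raise ValueError("fringe_visibility must lie in [0, 1]")
        if self.mean_intensity <= 0 or self.full_scale <= 0:
            raise ValueError("intensity scales must be positive")


@dataclass(frozen=True)
class AcousticDrive:
    """Acoustic stimulation: frequency (Hz) and pressure amplitude p0 (Pa).

    ``electrical_power`` (W) is carried as metadata only; the mapping from
    drive power to in-chamber pressure is an instrument property resolved by
    reference-bead calibration, not modelled here.
    """

    frequency: float = 1000.0
    pressure: float = 100.0
    electrical_power: float | None = 0.05

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("drive frequency must be positive")
        if self.pressure < 0:
            raise ValueError("pressure amplitude must be non-negative")


@dataclass(frozen=True)
class AcquisitionPlan:
    """Phase-stepping and stroboscopic sampling schedule.

    ``delta_f`` is the camera-vs-drive detuning; ``None`` selects
    ``f_a / (frames_per_step − 1)`` so one step's frames tile the vibration
    cycle uniformly.
    """

    n_steps: int = 20
    step_phase: float = np.pi / 10.0
    frames_per_step: int = 50
    delta_f: float | None = None

    def __post_init__(self) -> None:
        if self.frames_per_step < 3:
            raise ValueError("frames_per_step must be at least 3")
        if self.n_steps * self.step_phase < 2.0 * np.pi - 1e-9:
            raise ValueError("n_steps * step_phase must span at least 2π")
        if self.delta_f is not None and self.delta_f == 0:
            raise ValueError("delta_f must be nonzero: zero detuning gives no "
                             "stroboscopic sweep of the vibration cycle")

    @property
    def n_frames(self) -> int:
        return self.n_steps * self.frames_per_step

    def resolved_delta_f(self, drive: AcousticDrive) -> float:
        if self.delta_f is not None:
            return self.delta_f
        return drive.frequency / (self.frames_per_step - 1)

    def frame_rate(self, drive: AcousticDrive) -> float:
        return drive.frequency + self.resolved_delta_f(drive)

    def theta(self) -> np.ndarray:
        """Nominal reference phase of each step, θ_k = k·step_phase."""
        return np.arange(self.n_steps) * self.step_phase


@dataclass
class InterferogramStack:
    """Recorded frames indexed [step, frame, y, x] with acquisition metadata.

    ``psi`` holds the vibration phase of every frame as reconstructed from
    the timestamps (plus any injected per-step cyclic start offset); it is
    simulator ground truth, carried for validation, and is not consumed by
    the reconstruction pipeline.
    """

    frames: np.ndarray
    theta: np.ndarray
    timestamps: np.ndarray
    psi: np.ndarray
    optics: OpticalConfig
    plan: AcquisitionPlan
    drive: AcousticDrive
    delta_n: float = 0.0
    pixel_pitch: float = 1.0
    step_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must be indexed [step, frame, y, x]")
        n_steps, fps = self.frames.shape[:2]
        if n_steps * fps != self.plan.n_frames:
            raise ValueError(
                f"frame count {n_steps * fps} does not match the plan "
                f"({self.plan.n_steps} steps x {self.plan.frames_per_step} frames)"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        t = np.asarray(self.timestamps).ravel()
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0] * self.frames.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[2:]  # type: ignore[return-value]

    @property
    def expected_shifts(self) -> np.ndarray:
        """Cyclic shifts a frame matcher should recover (0 if none injected)."""
        if self.step_offsets is None:
            return np.zeros(self.frames.shape[0], dtype=int)
        return np.asarray(self.step_offsets, dtype=int)


def deform_thickness(
    scene: SampleScene,
    drive: AcousticDrive,
    model: ElasticModelParams,
    vibration_phase: float,
) -> np.ndarray:
    """Instantaneous thickness h(x, y; ψ) = h0 − w (1 + sin ψ)/2.

    The deflection amplitude ``w`` comes from the elastic forward model at
    the drive pressure.  Pressure only compresses: at sin ψ = −1 the sample
    is undeformed, at sin ψ = +1 it is indented by the full amplitude.
    """
    psi = float(vibration_phase)
    if not 0.0 <= psi < 2.0 * np.pi + 1e-12:
        raise ValueError("vibration phase must lie in [0, 2π)")
    params = replace(model, pressure=drive.pressure)
    w = elastic_forward(scene.E_true, scene.h0, params, scene.pixel_pitch)
    sup = scene.support_mask
    if np.any(w[sup] >= scene.h0[sup]):
        raise ValueError(
            "deflection amplitude reaches the resting thickness somewhere on "
            "the support (full compression is unphysical); lower the drive "
            "pressure or stiffen the sample"
        )
    return scene.h0 - w * (1.0 + np.sin(psi)) / 2.0


def render_interferogram(
    h: np.ndarray,
    theta: float,
    optics: OpticalConfig,
    delta_n: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Single fringe image of a thickness field at reference phase θ.

    Noise-free intensity I = I0 (1 + V cos(φ + θ + φ_bg)) with
    φ = 2π Δn h / λ; shot/read noise is then applied and the result clipped
    to [0, full_scale].  With the default noise model (all zeros) the output
    is the exact noise-free pattern.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("negative thickness input")
    phi = 2.0 * np.pi * delta_n * h / optics.wavelength
    if optics.background_phase is not None:
        phi = phi + optics.background_phase
    img = optics.mean_intensity * (
        1.0 + optics.fringe_visibility * np.cos(phi + theta)
    )
    if optics.noise.enabled:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        sigma = np.sqrt(optics.noise.predicted_variance(img))
        img = img + rng.normal(0.0, 1.0, img.shape) * sigma
        img = np.clip(img, 0.0, optics.full_scale)
    return img


def acquire_stack(
    scene: SampleScene,
    drive: AcousticDrive,
    plan: AcquisitionPlan,
    optics: OpticalConfig,
    seed: int | np.random.Generator | None = 0,
    model: ElasticModelParams | None = None,
    step_offsets: Sequence[int] | str | None = None,
    quantize: bool = False,
) -> InterferogramStack:
    """Simulate a full phase-stepped, stroboscopically sampled acquisition.

    Frame j of step k is rendered at time ``t = (k·F + j) / frame_rate``
    with vibration phase ``ψ = 2π f_a t mod 2π`` and reference phase
    ``θ_k = k·step_phase``.  ``step_offsets`` optionally injects a random
    (``"random"``) or explicit per-step cyclic start offset of the vibration
    phase, in units of the per-frame phase increment, to exercise the frame
    matcher; step 0 always starts unshifted.  ``quantize`` rounds to integer
    detector counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delta_f = plan.resolved_delta_f(drive)
    if delta_f == 0:
        raise ValueError("zero delta_f: no stroboscopic sweep")
    fs = drive.frequency + delta_f
    n_steps, F = plan.n_steps, plan.frames_per_step

    if step_offsets is None:
        offsets = None
    elif isinstance(step_offsets, str):
        if step_offsets != "random":
            raise ValueError("step_offsets must be a sequence, 'random', or None")
        offsets = rng.integers(0, F, size=n_steps)
        offsets[0] = 0
    else:
        offsets = np.asarray(step_offsets, dtype=int) % F
        if offsets.shape != (n_steps,):
            raise ValueError("step_offsets must have one entry per step")

    params = replace(model or ElasticModelParams(), pressure=drive.pressure)
    if drive.pressure > 0:
        w = elastic_forward(scene.E_true, scene.h0, params, scene.pixel_pitch)
        sup = scene.support_mask
        if np.any(w[sup] >= scene.h0[sup]):
            raise ValueError(
                "deflection amplitude reaches the resting thickness; lower the "
                "drive pressure or stiffen the sample"
            )
    else:
        w = np.zeros_like(scene.h0)

    idx = np.arange(n_steps * F).reshape(n_steps, F)
    timestamps = idx / fs
    psi = (2.0 * np.pi * drive.frequency * timestamps) % (2.0 * np.pi)
    if offsets is not None:
        psi = (psi + (2.0 * np.pi / F) * offsets[:, None]) % (2.0 * np.pi)

    theta = plan.theta()
    ny, nx = scene.grid_shape
    frames = np.empty((n_steps, F, ny, nx), dtype=float)
    noise_free = OpticalConfig(
        wavelength=optics.wavelength,
        mean_intensity=optics.mean_intensity,
        fringe_visibility=optics.fringe_visibility,
        background_phase=optics.background_phase,
        full_scale=optics.full_scale,
    )
    for k in range(n_steps):
        modulation = (1.0 + np.sin(psi[k]))[:, None, None] / 2.0
        h = scene.h0[None, :, :] - w[None, :, :] * modulation
        step = render_interferogram(h, theta[k], noise_free, scene.delta_n)
        if optics.noise.enabled:
            sigma = np.sqrt(optics.noise.predicted_variance(step))
            step = step + rng.normal(0.0, 1.0, step.shape) * sigma
            step = np.clip(step, 0.0, optics.full_scale)
        if quantize:
            step = np.clip(np.rint(step), 0, optics.full_scale)
        frames[k] = step

    return InterferogramStack(
        frames=frames,
        theta=theta,
        timestamps=timestamps,
        psi=psi,
        optics=optics,
        plan=plan,
        drive=drive,
        delta_n=scene.delta_n,
        pixel_pitch=scene.pixel_pitch,
        step_offsets=offsets,
    )
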