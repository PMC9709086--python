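"""Elastic forward model, displacement fitting, and stiffness inversion.

The acoustic drive applies a (spatially uniform) pressure ``p0`` to the
sample surface.  The sample is treated as an isotropic, linear-elastic layer
in the small-indentation (Hertzian half-space) regime: each pixel responds as
an elastic column of height ``h0``,

    w = p0 * h0 * (1 - nu^2) / E,

optionally coupled laterally by a membrane tension term so that the
deflection amplitude ``w(x, y)`` solves

    (E / ((1 - nu^2) h0)) w  -  T * laplacian(w) = p0

on the support with zero deflection outside.  With ``T = 0`` the relation
inverts pixelwise in closed form, which is the default inversion used for
whole-cell stiffness maps; ``T > 0`` is solved sparsely and inverted by a
damped fixed-point iteration.

Units: thickness and pixel pitch in µm, moduli and pressure in Pa, membrane
tension ``T`` in N/m (converted internally to Pa·µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

if TYPE_CHECKING:  # pragma: no cover
    from .reconstruct import ThicknessSeries

__all__ = [
    "ElasticModelParams",
    "DisplacementMap",
    "StiffnessMap",
    "CalibrationResult",
    "InversionError",
    "fit_displacement",
    "elastic_forward",
    "invert_stiffness",
    "calibrate_pressure",
]

#: N/m -> Pa·µm conversion for the membrane tension term.
_T_TO_PA_UM = 1.0e6


class InversionError(RuntimeError):
    """Raised when the stiffness fixed-point iteration fails to converge."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class ElasticModelParams:
    """Parameters of the elastic response model.

    poisson_ratio : ν, default 0.5 (incompressible soft-matter limit).
    lateral_tension : membrane coupling T in N/m; 0 = purely local columns.
    pressure : acoustic pressure amplitude p0 (Pa); must be set (directly or
        through :func:`calibrate_pressure`) before inversion.
    """

    poisson_ratio: float = 0.5
    lateral_tension: float = 0.0
    pressure: float | None = None
    tolerance: float = 1.0e-6
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio <= 0.5 + 1e-12:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.lateral_tension < 0:
            raise ValueError("lateral_tension must be non-negative")

    @property
    def compliance_prefactor(self) -> float:
        return 1.0 - self.poisson_ratio**2


@dataclass
class DisplacementMap:
    """Per-pixel oscillation of the thickness over one vibration cycle.

    amplitude : peak-to-trough deflection δ (µm).
    phase : oscillation phase (rad), informational.
    h0_est : undeformed thickness implied by the compression convention (µm).
    residual : per-pixel RMS misfit of the sinusoidal fit (µm).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    h0_est: np.ndarray
    residual: np.ndarray


@dataclass
class StiffnessMap:
    """Per-pixel Young's modulus with a validity mask and summary stats."""

    E: np.ndarray
    mask: np.ndarray
    pressure: float
    poisson_ratio: float
    lateral_tension: float
    model: str = "elastic-column"
    n_iterations: int = 0

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        return self.E[self.mask]

    def summary(self) -> dict:
        vals = self.masked_values()
        return {
            "mean_Pa": float(vals.mean()),
            "sd_Pa": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n_pixels": int(vals.size),
            "model": self.model,
            "pressure_Pa": self.pressure,
            "poisson_ratio": self.poisson_ratio,
            "lateral_tension_N_per_m": self.lateral_tension,
        }


@dataclass
class CalibrationResult:
    """Acoustic pressure recovered from a reference object."""

    pressure: float
    dispersion: float  # robust CV: 1.4826*MAD/median of per-pixel estimates
    n_pixels: int


def _sincos_lstsq(values: np.ndarray, angles: np.ndarray):
    """Per-pixel least squares of v = c0 + c_cos*cos(a) + c_sin*sin(a).

    ``values`` has shape (n, ...); returns (c0, c_cos, c_sin, rms_residual),
    each of shape ``values.shape[1:]``.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    design = np.column_stack([np.ones(n), np.cos(angles), np.sin(angles)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "rank-deficient design: need at least 3 distinct angles "
            f"(got {np.unique(np.round(angles, 12)).size})"
        )
    flat = values.reshape(n, -1)
    gram = design.T @ design
    coef = np.linalg.solve(gram, design.T @ flat)  # (3, P)
    resid = flat - design @ coef
    rms = np.sqrt(np.mean(resid**2, axis=0))
    shape = values.shape[1:]
    return (
        coef[0].reshape(shape),
        coef[1].reshape(shape),
        coef[2].reshape(shape),
        rms.reshape(shape),
    )


def fit_displacement(
    series: "ThicknessSeries", phase_mode: str = "global"
) -> DisplacementMap:
    """Fit per-pixel thickness waveforms h(ψ) = c0 + c1 sin ψ + c2 cos ψ.

    Under the compression convention h(ψ) = h0 − w (1 + sin ψ)/2 the
    peak-to-trough amplitude is δ = 2 sqrt(c1² + c2²) and the undeformed
    thickness is h0 = c0 + δ/2.

    The acoustic deflection is phase-locked across the field of view (the
    drive is quasi-static relative to any structural resonance), so after
    the free per-pixel fit the oscillation phase is consolidated: with
    ``phase_mode="global"`` (default) one field-wide phase is estimated from
    the amplitude-weighted quadratures and every pixel is refitted against
    the single known-phase sinusoid.  This halves the amplitude variance and
    removes the positive amplitude bias of the two-quadrature estimator at
    low signal, which matters for thin sample margins.  ``"free"`` keeps the
    unconstrained per-pixel fit.
    """
    psi = np.asarray(series.psi, dtype=float)
    if psi.size < 3:
        raise ValueError("need at least 3 bins with distinct vibration phases")
    maps = np.asarray(series.maps)
    c0, c_cos, c_sin, rms = _sincos_lstsq(maps, psi)
    phase = np.arctan2(c_cos, c_sin)
    if phase_mode == "free":
        delta = 2.0 * np.hypot(c_sin, c_cos)
        return DisplacementMap(
            amplitude=delta, phase=phase, h0_est=c0 + delta / 2.0, residual=rms
        )
    if phase_mode != "global":
        raise ValueError("phase_mode must be 'global' or 'free'")
    # amplitude²-weighted global quadrature direction
    phi0 = float(np.arctan2(np.sum(c_cos * np.hypot(c_sin, c_cos)),
                            np.sum(c_sin * np.hypot(c_sin, c_cos))))
    s = np.sin(psi + phi0)
    s_c = s - s.mean()
    denom = float(np.sum(s_c**2))
    flat = maps.reshape(psi.size, -1)
    a = (s_c @ flat) / denom
    base = flat.mean(axis=0) - a * s.mean()
    shape = maps.shape[1:]
    a = a.reshape(shape)
    base = base.reshape(shape)
    fitted = base[None] + a[None] * s[:, None, None] if maps.ndim == 3 else None
    if fitted is not None:
        rms = np.sqrt(np.mean((maps - fitted) ** 2, axis=0))
    # φ0 is the direction of the mean quadrature vector, so every pixel's
    # projection a = w/2 ≥ 0 (thickness maximal, i.e. undeformed, at
    # sin(ψ+φ0) = +1); a negative a is pure noise, clipped to zero
    delta = np.clip(2.0 * a, 0.0, None)
    return DisplacementMap(
        amplitude=delta,
        phase=np.full(shape, phi0),
        h0_est=base + delta / 2.0,
        residual=rms,
    )


def elastic_forward(
    E: np.ndarray,
    h0: np.ndarray,
    params: ElasticModelParams,
    pixel_pitch: float = 1.0,
) -> np.ndarray:
    """Deflection amplitude w(x, y) under pressure ``params.pressure``.

    With ``lateral_tension == 0`` this is the closed-form elastic column
    w = p0 h0 (1−ν²)/E on the support; otherwise the coupled
    spring–membrane system is assembled sparsely (5-point Laplacian,
    zero-deflection Dirichlet boundary at the support edge) and solved
    directly.
    """
    E = np.asarray(E, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    if E.shape != h0.shape:
        raise ValueError("E and h0 must share one shape")
    p0 = params.pressure
    if p0 is None or p0 < 0:
        raise ValueError("params.pressure must be set and non-negative")
    support = h0 > 0
    bad = support & ~(E > 0)
    if bad.any():
        loc = tuple(np.argwhere(bad)[0])
        raise ValueError(
            f"zero/negative stiffness inside the support (first at pixel {loc}); "
            "the elastic system is singular"
        )
    w = np.zeros_like(h0)
    pref = p0 * params.compliance_prefactor
    if params.lateral_tension == 0.0:
        w[support] = pref * h0[support] / E[support]
        return w

    # sparse spring + membrane solve on the support
    t_mu = params.lateral_tension * _T_TO_PA_UM / pixel_pitch**2  # Pa/µm
    idx = -np.ones(h0.shape, dtype=np.int64)
    pts = np.argwhere(support)
    idx[support] = np.arange(len(pts))
    k_spring = E[support] / (params.compliance_prefactor * h0[support])
    rows, cols, vals = [], [], []
    diag = k_spring + 4.0 * t_mu
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ny, nx = pts[:, 0] + dy, pts[:, 1] + dx
        inside = (
            (ny >= 0) & (ny < h0.shape[0]) & (nx >= 0) & (nx < h0.shape[1])
        )
        nbr = np.full(len(pts), -1, dtype=np.int64)
        nbr[inside] = idx[ny[inside], nx[inside]]
        has = nbr >= 0
        rows.append(np.arange(len(pts))[has])
        cols.append(nbr[has])
        vals.append(np.full(has.sum(), -t_mu))
        # neighbours outside the support are Dirichlet w = 0: diagonal only
    rows.append(np.arange(len(pts)))
    cols.append(np.arange(len(pts)))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(pts), len(pts)),
    )
    w_vec = spsolve(A, np.full(len(pts), float(p0)))
    w[support] = w_vec
    return w


def _masked_laplacian(f: np.ndarray, mask: np.ndarray, pixel_pitch: float) -> np.ndarray:
    """5-point Laplacian of ``f`` treating non-mask neighbours as 0."""
    g = np.where(mask, f, 0.0)
    lap = (
        np.roll(g, 1, 0) + np.roll(g, -1, 0) + np.roll(g, 1, 1) + np.roll(g, -1, 1)
        - 4.0 * g
    )
    return lap / pixel_pitch**2


def invert_stiffness(
    disp: DisplacementMap,
    params: ElasticModelParams,
    pixel_pitch: float = 1.0,
    noise_floor: float | None = None,
    min_amplitude: float = 0.05,
    min_thickness: float = 0.05,
    damping: float = 0.7,
) -> StiffnessMap:
    """Per-pixel Young's modulus from the observed deflection amplitude.

    Pixels with amplitude below the noise floor or with negligible thickness
    are masked out, not extrapolated.  The default floor is the larger of 3x
    the median per-pixel fit residual (statistical noise) and
    ``min_amplitude`` (µm) — an absolute displacement-resolution floor at
    the scale of the axial resolution of interferometric thickness mapping
    (tens of nm): where the expected deflection is below what the optics can
    resolve, the inversion is meaningless however small the fit residual.
    With ``lateral_tension == 0`` the model inverts in closed form
    E = p0 h0 (1−ν²)/δ; otherwise a local estimate seeds a damped
    multiplicative fixed point refined through :func:`elastic_forward`.
    """
    p0 = params.pressure
    if p0 is None or not p0 > 0:
        raise ValueError("params.pressure must be positive for inversion")
    delta = np.asarray(disp.amplitude, dtype=float)
    h0 = np.asarray(disp.h0_est, dtype=float)
    if noise_floor is None:
        noise_floor = max(3.0 * float(np.median(disp.residual)), min_amplitude)
    mask = (
        (delta > max(noise_floor, 1e-300))
        & (h0 > min_thickness)
        & np.isfinite(delta)
        & np.isfinite(h0)
        & (delta < h0)
    )
    if not mask.any():
        raise ValueError("all pixels masked: no displacement above the noise floor")

    pref = params.compliance_prefactor
    E = np.zeros_like(delta)
    n_iter = 0
    if params.lateral_tension == 0.0:
        E[mask] = p0 * pref * h0[mask] / delta[mask]
        model = "elastic-column"
    else:
        model = "elastic-column+membrane"
        t_mu = params.lateral_tension * _T_TO_PA_UM  # Pa·µm
        lap = _masked_laplacian(delta, mask, pixel_pitch)  # µm / µm²
        # local membrane-corrected seed: E ≈ (1−ν²) h0 (p0 + T ∇²δ) / δ
        E0 = pref * h0 * (p0 + t_mu * lap) / np.where(mask, delta, 1.0)
        med = np.median(pref * p0 * h0[mask] / delta[mask])
        E[mask] = np.clip(E0[mask], 1e-3 * med, None)
        h_field = np.where(mask, h0, 0.0)
        history: list[float] = []
        for n_iter in range(1, params.max_iterations + 1):
            E_field = np.where(mask, E, 0.0)
            w = elastic_forward(E_field, h_field, params, pixel_pitch)
            ratio = w[mask] / delta[mask]
            E[mask] *= ratio**damping
            rel = float(np.max(np.abs(ratio - 1.0)))
            history.append(rel)
            if rel < params.tolerance:
                break
        else:
            raise InversionError(
                f"stiffness iteration did not converge within "
                f"{params.max_iterations} iterations (last update {history[-1]:.3g})",
                history,
            )
    return StiffnessMap(
        E=np.where(mask, E, 0.0),
        mask=mask,
        pressure=float(p0),
        poisson_ratio=params.poisson_ratio,
        lateral_tension=params.lateral_tension,
        model=model,
        n_iterations=n_iter,
    )


def calibrate_pressure(
    disp_ref: DisplacementMap,
    E_ref: float | np.ndarray,
    params: ElasticModelParams,
    noise_floor: float | None = None,
    min_thickness: float = 0.05,
) -> CalibrationResult:
    """Acoustic pressure from a reference object of known stiffness.

    Inverts the local (T = 0) model pixelwise, p0 = E_ref δ / ((1−ν²) h0),
    and takes the median over the valid mask; the dispersion diagnostic is a
    robust coefficient of variation (1.4826 MAD / median).
    """
    E_ref_arr = np.asarray(E_ref, dtype=float)
    if np.any(E_ref_arr <= 0):
        raise ValueError("E_ref must be positive")
    delta = np.asarray(disp_ref.amplitude, dtype=float)
    h0 = np.asarray(disp_ref.h0_est, dtype=float)
    if noise_floor is None:
        noise_floor = 3.0 * float(np.median(disp_ref.residual))
    mask = (delta > max(noise_floor, 1e-300)) & (h0 > min_thickness)
    if not mask.any():
        raise ValueError("empty calibration mask: reference displacement invalid")
    e = E_ref_arr[mask] if E_ref_arr.shape == delta.shape else E_ref_arr
    p_px = e * delta[mask] / (params.compliance_prefactor * h0[mask])
    p0 = float(np.median(p_px))
    mad = float(np.median(np.abs(p_px - p0)))
    return CalibrationResult(
        pressure=p0,
        dispersion=1.4826 * mad / p0 if p0 > 0 else np.inf,
        n_pixels=int(mask.sum()),
    )
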