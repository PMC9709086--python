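"""Interferogram stacks -> per-vibration-phase thickness maps.

The reconstruction chain mirrors the acquisition inversely:

1. :func:`match_step_offsets` — find, per phase step, the cyclic frame shift
   aligning every step's stroboscopic sweep to step 0 (wavelet-correlation
   proposal refined by a phase-retrieval residual search).
2. :func:`bin_frames` — regroup the stack into one bin per vibration phase,
   each holding one frame from every phase step.
3. :func:`denoise_frame` — optional patch-based / transform-domain denoising
   of individual interferograms (never of phase maps).
4. :func:`retrieve_phase` — per-pixel least squares over the phase-stepped
   frames, I_k = A + B cos θ_k + C sin θ_k, giving the wrapped phase.
5. :func:`unwrap_phase` — least-squares unwrapping via a DCT Poisson solve,
   upgraded to preconditioned conjugate gradients when quality weights are
   present.
6. :func:`phase_to_thickness` — h = φ λ / (2π Δn).

Sign convention (fixed here, mirrored by the simulator): a thicker sample
produces a larger positive phase, i.e. n_sample > n_medium gives Δn > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.fft import dctn, idctn
from skimage.restoration import denoise_nl_means, denoise_wavelet

from .simulate import InterferogramStack

__all__ = [
    "MatchResult",
    "BinSet",
    "WrappedPhaseMap",
    "UnwrappedPhaseMap",
    "ThicknessSeries",
    "UnwrapError",
    "match_step_offsets",
    "bin_frames",
    "denoise_frame",
    "retrieve_phase",
    "unwrap_phase",
    "anchor_background",
    "reference_subtract",
    "phase_to_thickness",
]


class UnwrapError(RuntimeError):
    """PCG unwrapping failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class MatchResult:
    """Per-step cyclic shifts aligning every step's sweep to step 0."""

    shifts: np.ndarray
    scores: np.ndarray  # (n_steps, frames_per_step) wavelet correlation
    ambiguous: bool = False
    refined: bool = False


@dataclass
class BinSet:
    """One bin per vibration phase; each bin holds one frame per phase step.

    ``frames`` is indexed [bin, step, y, x]; ``psi`` annotates the bins with
    ψ_j = 2π j / n_bins, strictly increasing over [0, 2π).
    """

    frames: np.ndarray
    theta: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError("bins must be indexed [bin, step, y, x]")
        if self.frames.shape[1] != self.theta.size:
            raise ValueError("every bin must hold exactly one frame per step")
        if np.any(np.diff(self.psi) <= 0) or self.psi[0] < 0 or self.psi[-1] >= 2 * np.pi:
            raise ValueError("bin phases must be strictly increasing over [0, 2π)")

    @property
    def n_bins(self) -> int:
        return self.frames.shape[0]


@dataclass
class WrappedPhaseMap:
    """Least-squares wrapped phase in (−π, π] plus fit diagnostics."""

    phase: np.ndarray
    amplitude: np.ndarray
    visibility: np.ndarray
    quality: np.ndarray


@dataclass
class UnwrappedPhaseMap:
    """Continuous phase (rad, unbounded) and the solver residual norm."""

    phase: np.ndarray
    residual: float = 0.0
    n_iterations: int = 0


@dataclass
class ThicknessSeries:
    """Per-bin thickness maps (µm) with the optical metadata used."""

    maps: np.ndarray  # (n_bins, y, x)
    psi: np.ndarray
    wavelength: float
    n_sample: float
    n_medium: float
    pixel_pitch: float = 1.0


def wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap into the principal interval (−π, π]."""
    return np.arctan2(np.sin(phase), np.cos(phase))


# ---------------------------------------------------------------------------
# frame matching
# ---------------------------------------------------------------------------

def _detail_coeffs(series: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    coeffs = pywt.wavedec(series, wavelet, level=level, mode="periodization")
    return np.concatenate(coeffs[1:])


def _wavelet_scores(series: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Normalized correlation of DWT detail coefficients over cyclic lags.

    ``series`` has shape (n_steps, F); returns (n_steps, F) with entry
    [k, s] the correlation between step k cyclically advanced by s frames
    and step 0.
    """
    n_steps, F = series.shape
    ref = _detail_coeffs(series[0] - series[0].mean(), wavelet, level)
    ref_norm = np.linalg.norm(ref)
    scores = np.zeros((n_steps, F))
    for k in range(n_steps):
        x = series[k] - series[k].mean()
        for s in range(F):
            d = _detail_coeffs(np.roll(x, -s), wavelet, level)
            denom = np.linalg.norm(d) * ref_norm
            scores[k, s] = float(d @ ref) / denom if denom > 0 else 0.0
    return scores


def _lag_costs(
    sub: np.ndarray,
    theta: np.ndarray,
    aligned: list[int],
    shifts: np.ndarray,
    k: int,
    probe: np.ndarray,
) -> np.ndarray:
    """Summed phase-retrieval residual of step ``k`` at every candidate lag.

    Fits the per-pixel three-parameter fringe model to the aligned steps'
    frames plus step k's candidate frame; the candidate enters the normal
    equations as a rank-one update, so all lags are scored in one vectorised
    pass per probe bin.
    """
    F = sub.shape[1]
    rows_idx = aligned + [k]
    a = np.column_stack(
        [np.ones(len(rows_idx)), np.cos(theta[rows_idx]), np.sin(theta[rows_idx])]
    )
    Minv = np.linalg.inv(a.T @ a)
    a_k = a[-1]
    cost = np.zeros(F)
    for b in probe:
        rows = np.stack([sub[j, (b + shifts[j]) % F] for j in aligned])  # (K, P)
        b0 = a[:-1].T @ rows  # (3, P)
        ss0 = np.sum(rows**2, axis=0)
        cand = sub[k, (b + np.arange(F)) % F]  # (F, P); row s = lag s
        bs = b0[None, :, :] + a_k[None, :, None] * cand[:, None, :]
        fit = np.einsum("sip,ij,sjp->sp", bs, Minv, bs)
        cost += np.sum(ss0[None, :] + cand**2 - fit, axis=1)
    return cost


def _bootstrap_triple(
    sub: np.ndarray, theta: np.ndarray, k1: int, k2: int
) -> tuple[int, int]:
    """Joint lag search for two steps against step 0 in closed form.

    Three frames per bin fit the three-parameter fringe model exactly, so
    residual scoring alone cannot seed the alignment.  Instead the fringe
    quadrature is projected out: with v the unit vector orthogonal to the
    (cos θ, sin θ) columns of the three-step design, g_b(x) = v·I_b(x)
    collapses to A(x)·(v·1) for correctly matched bins — constant across
    bins.  The across-bin variance of g, summed over pixels, is therefore
    exactly zero at the true lag pair and positive elsewhere.
    """
    F = sub.shape[1]
    c = np.cos(theta[[0, k1, k2]])
    s = np.sin(theta[[0, k1, k2]])
    # v_i = sin(theta_j - theta_k) for the other two steps: every component
    # must be nonzero or one step's lag is unconstrained
    v = np.cross(c, s)
    nv = np.linalg.norm(v)
    if nv < 1e-12 or np.abs(v).min() < 1e-6 * nv or abs(v.sum()) < 1e-6 * nv:
        raise ValueError("degenerate bootstrap step triple")
    v /= nv
    T0 = sub[0]  # (F, P)
    j = np.arange(F)
    gather = (j[:, None] + j[None, :]) % F  # [lag, bin]
    T1 = sub[k1][gather]  # (F_lags, F_bins, P)
    T2 = sub[k2][gather]
    base = v[0] * T0  # (F, P)
    best = (0, 0, np.inf)
    for s1 in range(F):
        g = base[None] + v[1] * T1[s1][None] + v[2] * T2  # (F_lags2, F, P)
        score = np.sum(g.var(axis=1), axis=1)  # (F_lags2,)
        s2 = int(np.argmin(score))
        if score[s2] < best[2]:
            best = (s1, s2, float(score[s2]))
    return best[0], best[1]


def _residual_refine(
    frames: np.ndarray,
    theta: np.ndarray,
    n_probe_bins: int = 8,
    max_passes: int = 5,
    max_pixels: int = 4096,
) -> np.ndarray:
    """Alignment by phase-retrieval consistency, independent of any seed.

    A bootstrap triple of steps is aligned jointly in closed form; the
    remaining steps are added greedily, each at the lag minimising the
    phase-retrieval residual against the already-aligned set; finally full
    sweeps rescore every step against all others until a fixed point.
    """
    n_steps, F, ny, nx = frames.shape
    flat = frames.reshape(n_steps, F, ny * nx).astype(float)
    # score alignment on the fringe-active pixels: the vibration signature
    # lives where the intensity actually swings over a step's sweep
    activity = flat[0].var(axis=0)
    n_px = min(max_pixels, ny * nx)
    sel = np.argpartition(activity, ny * nx - n_px)[-n_px:]
    sub = np.ascontiguousarray(flat[:, :, sel])
    probe = np.unique((np.arange(n_probe_bins) * F) // n_probe_bins)
    shifts = np.zeros(n_steps, dtype=int)

    # bootstrap step triple: pick the pair whose reference phases, together
    # with step 0, leave no step unconstrained (no pairwise difference
    # congruent to 0 mod π) and condition the projection best
    best_pair, best_q = None, 0.0
    for k1 in range(1, n_steps):
        for k2 in range(k1 + 1, n_steps):
            v = np.array([
                np.sin(theta[k2] - theta[k1]),
                np.sin(theta[0] - theta[k2]),
                np.sin(theta[k1] - theta[0]),
            ])
            q = float(min(np.abs(v).min(), abs(v.sum())))
            if q > best_q:
                best_q, best_pair = q, (k1, k2)
    if best_pair is None or best_q < 1e-6:
        return shifts  # all reference phases collinear: cannot bootstrap
    k1, k2 = best_pair
    s1, s2 = _bootstrap_triple(sub, theta, k1, k2)
    shifts[k1], shifts[k2] = s1, s2
    aligned = [0, k1, k2]
    for k in range(n_steps):
        if k in aligned:
            continue
        cost = _lag_costs(sub, theta, aligned, shifts, k, probe)
        shifts[k] = int(np.argmin(cost))
        aligned.append(k)
    # fixed-point sweeps over the full set
    for _ in range(max_passes):
        updated = False
        for k in range(1, n_steps):
            others = [j for j in range(n_steps) if j != k]
            cost = _lag_costs(sub, theta, others, shifts, k, probe)
            best = int(np.argmin(cost))
            if best != shifts[k] and cost[best] < cost[shifts[k]] * (1.0 - 1e-9):
                shifts[k] = best
                updated = True
        if not updated:
            break
    return shifts


def match_step_offsets(
    stack: InterferogramStack,
    wavelet: str = "db4",
    level: int = 3,
    refine: bool = True,
) -> MatchResult:
    """Cyclic frame shift of every phase step relative to step 0.

    Stage 1 scores candidate lags by the normalized correlation of the DWT
    detail coefficients of each step's per-frame spatial-mean series against
    step 0 (Daubechies-4, 3 levels, by default).  Because the spatial-mean
    series is modulated by the reference phase, the correlation alone can
    confuse a lag with its half-period partner; stage 2 therefore rescores
    candidate lags by the per-pixel phase-retrieval residual and keeps the
    best.  Vibration-free (constant) sequences are flagged ambiguous and
    default to zero shift with a warning.
    """
    frames = np.asarray(stack.frames, dtype=float)
    n_steps, F = frames.shape[:2]
    if n_steps < 2:
        raise ValueError("need at least 2 phase steps to match")
    if F < 4:
        raise ValueError("need at least 4 frames per step to match")
    series = frames.mean(axis=(2, 3))
    variation = series.std(axis=1)
    scale = max(float(np.abs(series).mean()), 1e-300)
    if np.all(variation < 1e-9 * scale):
        warnings.warn(
            "vibration-free (constant) frame sequences: cyclic shifts are "
            "ambiguous, defaulting to 0",
            RuntimeWarning,
        )
        return MatchResult(
            shifts=np.zeros(n_steps, dtype=int),
            scores=np.zeros((n_steps, F)),
            ambiguous=True,
        )
    level = min(level, pywt.dwt_max_level(F, pywt.Wavelet(wavelet).dec_len))
    scores = _wavelet_scores(series, wavelet, max(level, 1))
    shifts = np.argmax(np.abs(scores), axis=1).astype(int)
    shifts[0] = 0
    refined = False
    if refine and n_steps >= 4:
        shifts = _residual_refine(frames, np.asarray(stack.theta, dtype=float))
        refined = True
    return MatchResult(shifts=shifts, scores=scores, refined=refined)


def bin_frames(stack: InterferogramStack, shifts: np.ndarray | MatchResult) -> BinSet:
    """Stroboscopic re-ordering: bin j collects frame (j + s_k) mod F of step k."""
    if isinstance(shifts, MatchResult):
        shifts = shifts.shifts
    shifts = np.asarray(shifts, dtype=int)
    frames = np.asarray(stack.frames)
    n_steps, F = frames.shape[:2]
    if shifts.shape != (n_steps,):
        raise ValueError(f"need one shift per step ({n_steps}), got {shifts.shape}")
    j = np.arange(F)
    binned = np.empty_like(frames.swapaxes(0, 1))
    for k in range(n_steps):
        binned[:, k] = frames[k, (j + shifts[k]) % F]
    psi = 2.0 * np.pi * j / F
    return BinSet(frames=binned, theta=np.asarray(stack.theta, dtype=float), psi=psi)


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def denoise_frame(
    frame: np.ndarray,
    noise_sigma: float,
    method: str = "nl_means",
    full_scale: float | None = None,
) -> np.ndarray:
    """Denoise a single interferogram.

    ``noise_sigma`` is the additive noise standard deviation in counts;
    0 returns the input unchanged.  ``"nl_means"`` groups similar patches
    and averages them (collaborative patch filtering); ``"wavelet"`` applies
    transform-domain soft shrinkage and is roughly an order of magnitude
    faster, which matters when filtering full 1000-frame stacks.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    frame = np.asarray(frame, dtype=float)
    if noise_sigma == 0:
        return frame
    scale = full_scale if full_scale else max(float(frame.max()), 1.0)
    x = frame / scale
    s = noise_sigma / scale
    if method == "nl_means":
        out = denoise_nl_means(
            x, h=0.8 * s, sigma=s, patch_size=5, patch_distance=6, fast_mode=True
        )
    elif method == "wavelet":
        out = denoise_wavelet(
            x, sigma=s, method="BayesShrink", mode="soft", rescale_sigma=True
        )
    else:
        raise ValueError(f"unknown denoising method {method!r}")
    return out * scale


# ---------------------------------------------------------------------------
# phase retrieval
# ---------------------------------------------------------------------------

def retrieve_phase(
    frames: np.ndarray,
    theta: np.ndarray,
    visibility_floor: float = 0.05,
) -> WrappedPhaseMap:
    """Per-pixel least-squares fringe fit over the phase-stepped frames.

    Solves I_k = A + B cos θ_k + C sin θ_k per pixel; the wrapped phase is
    atan2(−C, B) ∈ (−π, π], the modulation amplitude sqrt(B² + C²), the
    visibility amplitude/A.  The quality weight decays with the relative fit
    residual and is zeroed below the visibility floor.  Exactly invariant to
    a global intensity scale or offset on all frames.
    """
    frames = np.asarray(frames, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if frames.shape[0] != theta.size:
        raise ValueError("one reference phase per frame is required")
    if frames.shape[0] < 3:
        raise ValueError("need at least 3 phase-stepped frames")
    from .stiffness import _sincos_lstsq  # shared normal-equations kernel

    A, B, C, rms = _sincos_lstsq(frames, theta)
    phase = np.arctan2(-C, B)
    amplitude = np.hypot(B, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        visibility = np.where(A > 0, amplitude / np.where(A > 0, A, 1.0), 0.0)
    quality = 1.0 / (1.0 + rms / (amplitude + 1e-300))
    quality = np.where(visibility < visibility_floor, 0.0, quality)
    return WrappedPhaseMap(
        phase=phase, amplitude=amplitude, visibility=visibility, quality=quality
    )


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

def _wrapped_gradients(psi_w: np.ndarray):
    dx = np.zeros_like(psi_w)
    dy = np.zeros_like(psi_w)
    dx[:, :-1] = wrap(np.diff(psi_w, axis=1))
    dy[:-1, :] = wrap(np.diff(psi_w, axis=0))
    return dy, dx


def _divergence(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    rho = np.zeros_like(dx)
    rho += dx
    rho[:, 1:] -= dx[:, :-1]
    rho += dy
    rho[1:, :] -= dy[:-1, :]
    return rho


def _poisson_dct(rho: np.ndarray) -> np.ndarray:
    """Solve the discrete Poisson equation with Neumann BCs via DCT."""
    m, n = rho.shape
    r = dctn(rho, type=2, norm="ortho")
    denom = 2.0 * (
        np.cos(np.pi * np.arange(m) / m)[:, None]
        + np.cos(np.pi * np.arange(n) / n)[None, :]
        - 2.0
    )
    denom[0, 0] = 1.0
    r /= denom
    r[0, 0] = 0.0
    return idctn(r, type=2, norm="ortho")


def _weighted_laplace(phi: np.ndarray, wy: np.ndarray, wx: np.ndarray) -> np.ndarray:
    dx = np.zeros_like(phi)
    dy = np.zeros_like(phi)
    dx[:, :-1] = np.diff(phi, axis=1)
    dy[:-1, :] = np.diff(phi, axis=0)
    return _divergence(wy * dy, wx * dx)


def unwrap_phase(
    wrapped: WrappedPhaseMap | np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1.0e-8,
    max_iterations: int = 500,
) -> UnwrappedPhaseMap:
    """Least-squares two-dimensional phase unwrapping.

    Unweighted fields are solved in one shot: the divergence of the wrapped
    phase gradients feeds a discrete Poisson equation solved by forward DCT,
    spectral division, and inverse DCT.  When quality weights below 1 are
    supplied (or carried by the input map with zeroed pixels), the weighted
    normal equations are solved by conjugate gradients preconditioned with
    that same DCT solver.  The additive constant is fixed to the 2π multiple
    nearest the median over the background (lowest-phase quartile) region,
    which keeps the output exactly wrap-consistent with the input.
    """
    if isinstance(wrapped, WrappedPhaseMap):
        psi_w = np.asarray(wrapped.phase, dtype=float)
        if weights is None and np.any(wrapped.quality <= 0):
            weights = wrapped.quality
    else:
        psi_w = np.asarray(wrapped, dtype=float)
    if not np.all(np.isfinite(psi_w)):
        raise ValueError("wrapped phase must be finite")

    dy, dx = _wrapped_gradients(psi_w)
    n_iter = 0
    if weights is None:
        phi = _poisson_dct(_divergence(dy, dx))
        residual = 0.0
    else:
        w = np.clip(np.asarray(weights, dtype=float), 0.0, 1.0) ** 2
        wx = np.minimum(w, np.roll(w, -1, axis=1))
        wy = np.minimum(w, np.roll(w, -1, axis=0))
        wx[:, -1] = 0.0
        wy[-1, :] = 0.0
        c = _divergence(wy * dy, wx * dx)
        c -= c.mean()
        phi = np.zeros_like(psi_w)
        r = c.copy()
        norm_c = np.linalg.norm(c)
        if norm_c == 0:
            norm_c = 1.0
        z = _poisson_dct(r)
        p = z.copy()
        rz = float(np.sum(r * z))
        residual = float(np.linalg.norm(r)) / norm_c
        for n_iter in range(1, max_iterations + 1):
            Ap = _weighted_laplace(p, wy, wx)
            denom = float(np.sum(p * Ap))
            if denom == 0:
                break
            alpha = rz / denom
            phi += alpha * p
            r -= alpha * Ap
            residual = float(np.linalg.norm(r)) / norm_c
            if residual < tol:
                break
            z = _poisson_dct(r)
            rz_new = float(np.sum(r * z))
            p = z + (rz_new / rz) * p
            rz = rz_new
        else:
            raise UnwrapError(
                f"PCG unwrapping did not reach tol={tol} within "
                f"{max_iterations} iterations (relative residual {residual:.3g})",
                residual,
            )
        phi -= phi.mean()

    # re-align to the wrapped input (the LS solution is defined up to a
    # constant and the DCT solve returns the zero-mean representative)
    offset = np.median(wrap(psi_w - phi))
    phi = phi + offset
    # wrap-consistent anchoring: shift by the 2π multiple nearest the
    # background median
    bg = phi <= np.quantile(phi, 0.25)
    shift = 2.0 * np.pi * np.round(np.median(phi[bg]) / (2.0 * np.pi))
    phi -= shift
    return UnwrappedPhaseMap(phase=phi, residual=residual, n_iterations=n_iter)


def anchor_background(
    phase: np.ndarray,
    background_mask: np.ndarray | None = None,
    quantile: float = 0.25,
) -> np.ndarray:
    """Zero-median the background (lowest-phase) region of an unwrapped map."""
    phase = np.asarray(phase, dtype=float)
    if background_mask is None:
        background_mask = phase <= np.quantile(phase, quantile)
    if not background_mask.any():
        raise ValueError("empty background mask")
    return phase - np.median(phase[background_mask])


def reference_subtract(
    phase: UnwrappedPhaseMap | np.ndarray,
    blank: UnwrappedPhaseMap | np.ndarray,
) -> UnwrappedPhaseMap:
    """Remove the system background aberration using a blank recording.

    Pixelwise difference of the sample and blank unwrapped phases,
    re-anchored to a zero-median background.
    """
    p = phase.phase if isinstance(phase, UnwrappedPhaseMap) else np.asarray(phase, float)
    b = blank.phase if isinstance(blank, UnwrappedPhaseMap) else np.asarray(blank, float)
    if p.shape != b.shape:
        raise ValueError(f"shape mismatch: sample {p.shape} vs blank {b.shape}")
    return UnwrappedPhaseMap(phase=anchor_background(p - b))


def phase_to_thickness(
    phase: UnwrappedPhaseMap | np.ndarray,
    wavelength: float,
    n_sample: float,
    n_medium: float,
) -> np.ndarray:
    """h = φ λ / (2π (n_sample − n_medium)), thickness in the wavelength unit."""
    if n_sample == n_medium:
        raise ValueError("n_sample equals n_medium: zero optical contrast")
    p = phase.phase if isinstance(phase, UnwrappedPhaseMap) else np.asarray(phase, float)
    return p * wavelength / (2.0 * np.pi * (n_sample - n_medium))
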