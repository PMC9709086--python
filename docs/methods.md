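# Methods

`acoustoholo` simulates and reconstructs acousto-holographic whole-cell
stiffness maps: a transparent sample immersed in a medium is compressed by a
~1 kHz acoustic pressure wave while a phase-shifting Mach–Zehnder
interferometer records its optical thickness; the periodic thickness change
at every pixel is inverted into a Young's-modulus map. This note documents
the model, the numerical choices, and what the synthetic data do and do not
establish.

## Forward model

**Phase object.** A scene is a projected-thickness field `h0(x, y)` (µm)
and a stiffness field `E(x, y)` (Pa) on a regular grid, with uniform
refractive indices `n_s` (sample) and `n_m` (medium). The optical phase is
the pure projection `φ = 2π (n_s − n_m) h / λ`; diffraction, defocus and
speckle are not modelled. Bead scenes use the chord profile of a sphere
resting on the substrate, `h0(r) = 2√((d/2)² − r²)`, which is the projected
path length a transmission interferometer measures. Cell scenes are
perturbed-ellipse blobs (low-order Fourier boundary modes) with a smooth
dome profile `(1 − ρ²)^p`, p = 1.5, scaled so the support-mean thickness
equals the requested value, and a log-normal stiffness field with mean
`E_base`, relative SD `heterogeneity`, and Gaussian spatial correlation
length defaulting to diameter/10. Internal refractive-index structure is
not modelled: thickness is the only phase source, as implied by the single-Δn
conversion.

**Elastic response.** The sample is an isotropic linear-elastic solid in the
small-indentation (Hertzian half-space) regime. Each pixel responds as an
elastic column under the uniform acoustic pressure amplitude `p0`:

    w = p0 · h0 · (1 − ν²) / E,

optionally coupled laterally by a membrane tension `T` (N/m), in which case
`(E/((1−ν²)h0))·w − T∇²w = p0` is solved sparsely with zero deflection
outside the support. The column relation uses exactly the observable the
method measures — thickness change at the measured point — and inverts in
closed form; the membrane variant exists behind the same interface so a
different small-indentation relation can be swapped in. Defaults: ν = 0.5
(incompressible soft matter), T = 0. Lengths are in µm, moduli and
pressures in Pa; `T` converts internally as 1 N/m = 10⁶ Pa·µm.

**Deformation convention.** Pressure only compresses:
`h(ψ) = h0 − w·(1 + sin ψ)/2`, so the sample is undeformed at `sin ψ = −1`
and indented by the full amplitude at `sin ψ = +1`; `δ = w` is the
peak-to-trough displacement. The simulator rejects any configuration with
`w ≥ h0` (full compression) as unphysical.

**Acquisition.** The reference phase steps through `θ_k = k·π/10` for
k = 0..19 (2π total); at each step the camera records 50 frames at rate
`f_a + Δf`. The detuning makes successive frames sweep slowly through the
vibration cycle (stroboscopic sampling); the default
`Δf = f_a/(frames_per_step − 1) ≈ 20.4 Hz` tiles one cycle uniformly with
the 50 frames of a step, which also makes every step start at the same
vibration phase. An optional per-step random cyclic offset de-synchronises
the steps to exercise the frame matcher. Detector model: 12-bit full scale,
fringe visibility V (default 0.9), shot noise (variance ∝ intensity) plus
additive read noise, optional rounding to integer counts. "30 dB intensity
SNR" means additive noise with σ = I0/10^(30/20).

**Acoustic pressure.** The electrical drive power of such instruments
(~0.05 W) does not determine the pressure at the sample; `p0` is therefore
a free configuration parameter recovered in practice by reference-bead
calibration. Simulation defaults were chosen once, from the sub-micron
deflection regime the method operates in (`δ = p0·h0·(1−ν²)/E` between
~0.1 and 1 µm): 500 Pa for 5 µm kPa-scale beads, 100 Pa for cells. GPa-scale
polystyrene beads deflect by <1 nm under any such pressure — below any
axial resolution — which is why the soft (polyacrylamide-stiffness,
1.94 kPa) bead is the end-to-end validation object, mirroring the role of
soft hydrogel reference particles in practice.

## Reconstruction

1. **Frame matching.** Each step's 50-frame sweep may start at an unknown
   point of the vibration cycle; binning needs the per-step cyclic shift.
   A 1-D statistic (normalized correlation of Daubechies-4 detail
   coefficients of the per-frame spatial-mean series, 3 levels) scores
   candidate lags cheaply, but is intrinsically ambiguous: the series is a
   function of sin ψ modulated by cos(θ_k − θ_0), so its odd part flips
   sign with the reference-phase difference and a lag can masquerade as its
   half-period partner. The shifts actually used therefore come from
   phase-retrieval consistency: a bootstrap triple of steps (chosen so no
   pairwise θ difference is ≡ 0 mod π) is aligned jointly in closed form —
   projecting the three intensities onto the direction orthogonal to the
   (cos θ, sin θ) design columns collapses correctly matched bins to a
   bin-independent value, so the across-bin variance of the projection is
   exactly zero at the true lag pair — after which the remaining steps are
   added greedily at the lag minimising the per-pixel three-parameter
   fringe-fit residual (a rank-one update of the normal equations,
   vectorised over all 50 lags), followed by fixed-point sweeps. Scoring
   uses the ~4096 most fringe-active pixels. Recovery of injected offsets
   is exact in the noise-free limit; at 30 dB a scatter of ±1–2 lags
   (ψ error ≲ 0.25 rad) remains and is negligible downstream. Vibration-free
   stacks are flagged ambiguous and default to zero shift with a warning.
2. **Binning.** Bin j collects frame `(j + s_k) mod 50` from step k,
   giving 50 bins × 20 phase-stepped interferograms, annotated
   `ψ_j = 2πj/50`.
3. **Denoising.** Applied to individual interferograms, never to phase
   maps. Two filters: patch-based non-local means (grouping of similar
   patches and collaborative averaging — the BM3D-class filter role; ~65 ms
   per 256² frame) and wavelet soft shrinkage (BayesShrink; ~3 ms).
   `sigma = 0` is the bit-exact identity. Noisy runs use non-local means at
   the configured noise σ; noise-free runs skip filtering.
4. **Phase retrieval.** Per pixel, linear least squares of
   `I_k = A + B cos θ_k + C sin θ_k` over the 20 frames of a bin;
   `φ = atan2(−C, B) ∈ (−π, π]`, amplitude `√(B²+C²)`, visibility
   amplitude/A, and a quality weight that decays with the relative fit
   residual and is zeroed below a visibility floor (default 0.05). Exactly
   invariant to global intensity scale and offset; requires ≥3 distinct
   reference phases.
5. **Unwrapping.** Least-squares two-dimensional unwrapping: the divergence
   of the wrapped phase gradients feeds a discrete Poisson equation solved
   by DCT (Neumann boundaries). When quality weights below 1 are present,
   the weighted normal equations are solved by conjugate gradients with the
   DCT solver as preconditioner (relative residual tolerance 1e−8, cap 500
   iterations; non-convergence raises with the residual). The additive
   constant is fixed to the 2π multiple nearest the background median, so
   the output is exactly wrap-consistent with the input; the exact
   zero-median background anchoring (background = lowest-phase quartile, or
   an explicit mask) is applied as a separate step before thickness
   conversion, and also after blank-field (reference) subtraction.
6. **Thickness.** `h = φ λ / (2π Δn)`; rejected when Δn = 0.

## Displacement and stiffness

Per pixel, the 50-bin thickness waveform is fitted as
`h_j = c0 + c1 sin ψ_j + c2 cos ψ_j`; under the compression convention
`δ = 2√(c1²+c2²)` and `h0 = c0 + δ/2`. Because the acoustic deflection is
phase-locked across the field of view (the 1 kHz drive is quasi-static
relative to structural resonances), the default estimator consolidates the
oscillation phase: one field-wide phase is estimated from the
amplitude-weighted quadratures and every pixel is refitted against the
single known-phase sinusoid, which removes the positive amplitude bias of
the two-quadrature estimator at low signal (`phase_mode="free"` restores
the unconstrained fit).

Inversion with T = 0 is the closed form `E = p0·h0·(1−ν²)/δ`; with T > 0 a
membrane-corrected local seed is refined by a damped multiplicative fixed
point through the sparse forward solve (damping 0.7, relative update
tolerance 1e−6 default). Pixels are masked, never extrapolated, when the
amplitude falls below `max(3 × median fit residual, 0.05 µm)` or the
thickness below 0.05 µm. The absolute 0.05 µm amplitude floor is the axial
resolution scale of interferometric thickness mapping (tens of nm): below
it the expected deflection is unresolvable however small the fit residual,
and sample margins thinner than ~δ/compression-ratio would otherwise
dominate the map with unstable ratios of two near-zero quantities.

**Pressure calibration.** `p0` is never hard-coded: it is either supplied
or recovered from a reference object of known stiffness as the median of
`E_ref·δ/((1−ν²)·h0)` over the valid mask, with a robust dispersion
diagnostic (1.4826·MAD/median). Calibration closure is exact in the
noise-free limit.

## Statistics

Distribution similarity uses the coefficient of determination
`R² = 1 − Σ(y_obs − y_calc)²/Σ(y_obs − ȳ)²` with ȳ the mean of the
*observed* vector — deliberately asymmetric; the measurement under
evaluation occupies the observed slot. Histograms compared pairwise share
Freedman–Diaconis edges computed on the pooled data of all groups involved,
are normalized to unit mass by default, and carry a binning fingerprint so
mismatched binnings are rejected. Pairwise comparison of two ensembles
yields the full |A|×|B| matrix (35×35 → 1225 values; 35×25 → 875) with
mean ± SD. Group summaries report per-object mean stiffness/thickness as
mean ± SD (SD = 0 for singleton groups). Inferential statistics (ANOVA,
t tests) are out of scope.

## What the synthetic data establish — and what they do not

The generator reproduces the geometry, optics, sampling structure and noise
of the measurement, so closed-loop tests demonstrate that the
reconstruction and inversion are *algorithmically* correct: exact recovery
in the noise-free limit, sub-percent bead-stiffness recovery and pixelwise
correlation >0.95 for heterogeneous fields at 30 dB intensity SNR.

They do not establish absolute accuracy on real cells: real data add
internal refractive-index structure (the single-Δn thickness conversion is
then approximate), spatially varying acoustic pressure, aberrations beyond
a low-order background field, viscoelastic (frequency-dependent) response,
and an unknown pressure-to-indentation relation whose absolute scale the
reference-bead calibration absorbs only to the extent the reference and
sample share the same contact mechanics. Agreement with kPa-scale moduli
from the literature should therefore be read as order-of-magnitude
consistency, not validation.

## Problem sizes

Default study-scale runs use 256×256 pixel scenes (20×50 = 1000
interferograms); unit tests use 32–128 px grids and, where exactness
permits, reduced plans (8 steps of π/4). The comparison-bookkeeping
ensembles use 35/35/25 scenes on 32² grids. These sizes are the package's
own defaults for a desk-scale study; all are configurable.
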