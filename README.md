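# acoustoholo

Simulation and reconstruction for **acousto-holographic whole-cell
stiffness mapping**: a label-free technique in which a low-intensity
acoustic wave (~1 kHz) periodically compresses cells or reference
microbeads while a phase-shifting Mach–Zehnder interferometer records
their optical thickness, and the per-pixel thickness oscillation is
inverted into a map of the Young's modulus `E(x, y)`.

The package is aimed at quantitative-phase-imaging and cell-mechanics
researchers who want to prototype, stress-test, or teach the full
measurement chain without the instrument: it provides synthetic phase
objects (beads, cell-like blobs), a forward model of the acquisition
(phase stepping, stroboscopic sampling, detector noise), the complete
reconstruction pipeline, and the statistics used to compare stiffness
distributions.

## Method

A transparent object of thickness `h` in a medium imposes the phase
`φ = 2π(n_s − n_m)h/λ`. The interferometer steps the reference phase in
increments of π/10 (20 steps over 2π) and records 50 frames per step at a
camera rate `f_a + Δf`, so the 1000 interferograms of one acquisition
stroboscopically sweep the vibration cycle. Reconstruction proceeds:

1. **frame matching** — recover each step's cyclic start offset within the
   vibration cycle (wavelet-correlation proposal, phase-retrieval
   consistency refinement);
2. **binning** — 50 vibration-phase bins × 20 phase-stepped frames;
3. **denoising** — patch-based filtering of individual interferograms;
4. **phase retrieval** — per-pixel least squares
   `I_k = A + B cos θ_k + C sin θ_k`, `φ = atan2(−C, B)`;
5. **unwrapping** — least-squares 2-D unwrapping via a DCT Poisson solve,
   preconditioned conjugate gradients when quality weights are present;
6. **thickness** — `h = φλ/(2πΔn)`, background-anchored;
7. **displacement** — per-pixel sinusoid fit over the cycle giving the
   peak-to-trough amplitude `δ` and resting thickness `h0`;
8. **stiffness inversion** — small-indentation (Hertzian half-space)
   elastic-column model `E = p0·h0·(1−ν²)/δ`, with an optional membrane
   coupling term `T∇²w`, and masking of unresolvable pixels.

The acoustic pressure amplitude `p0` is either supplied or calibrated from
a reference bead of known stiffness. Stiffness distributions are compared
with the coefficient of determination
`R² = 1 − Σ(y_obs − y_calc)²/Σ(y_obs − ȳ)²` over histograms sharing one
binning rule. See `docs/methods.md` for models, conventions, and
limitations.

## Worked example

Simulate a 5 µm soft reference bead (polyacrylamide stiffness preset,
1.94 kPa, refractive index 1.349 in water at 1.334), acquire its 1000
interferograms, and run the full reconstruction:

```python
from acoustoholo import RunConfig, run_pipeline

cfg = RunConfig(
    scene={"kind": "bead", "diameter": 5.0, "material": "PAA", "medium": "DI_water"},
    grid_shape=(64, 64), pixel_pitch=0.2, wavelength=0.532,
    pressure=500.0, seed=1,
)
result = run_pipeline(cfg)
summary = result.stiffness.summary()
print(f"valid pixels : {summary['n_pixels']}")
print(f"mean E       : {summary['mean_Pa']:.1f} Pa")
print(f"SD           : {summary['sd_Pa']:.3g} Pa")
print(f"ground truth : {result.scene.mean_stiffness():.1f} Pa")
```

prints

```
valid pixels : 484
mean E       : 1940.0 Pa
SD           : 1.84e-12 Pa
ground truth : 1940.0 Pa
```

— in the noise-free limit the chain recovers the bead's modulus to machine
precision over the 484 pixels whose deflection is above the resolution
floor. With detector noise at 30 dB intensity SNR and non-local-means
denoising enabled the recovered mean stays within ~1% and heterogeneous
cell-like stiffness fields are recovered with pixelwise correlation >0.95.

The same stages are available from the shell:

```sh
acoustoholo pipeline -c run.yaml -o out/          # simulate → reconstruct → invert
acoustoholo simulate -c run.yaml -o out/          # stack TIFF + JSON sidecar
acoustoholo reconstruct -i out/stack.tiff -o rec/ # thickness series
acoustoholo stiffness -i rec/thickness_series.tiff --pressure 500 -o maps/
acoustoholo compare -a mapsA/*.tiff -b mapsB/*.tiff -o cmp/   # pairwise R²
```

Every run writes its resolved configuration and per-stage diagnostics next
to its outputs.

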