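# twinpeak

Viscoelasticity estimation from shear-wave elastography (SWE) motion data by
**twin-peak matching** in the frequency–wavenumber domain.

## The problem

Ultrasound SWE launches a shear wave with an acoustic-radiation-force (ARF)
push and tracks the particle velocity `v(x, t)` along a lateral line.
Elasticity sets the wave speed; viscosity sets attenuation and dispersion,
and is notoriously hard to estimate because it degrades the very signal used
to measure it. In the 2D Fourier plane `(f, kx)` the response has a ridge
whose location is robust against noise even when its width and amplitude are
not. The ridge can be summarized two ways:

* **f(k) peaks** — for each wavenumber `kx`, the frequency of maximum
  |response|,
* **k(f) peaks** — for each frequency `f`, the wavenumber of maximum
  |response|.

For a lossless medium both collapse onto the dispersion line `ω = cs·k`. With
viscosity they *diverge*: for a Kelvin–Voigt medium with complex shear
modulus `G(ω) = G0(1 + iτω)` the far-field curves are

    f(k):  ω(kx) = cs·kx                    (independent of τ)
    k(f):  kx(ω) = ω / (cs·√(1 + τ²ω²))     (bends down with viscosity)

with `cs = √(G0/ρ)`. The separation between the two curves is the viscosity
observable; their slope is the elasticity observable. The estimator minimizes

    Fobj(p) = Σ(ks−km)²/Σkm² + Σ(fs−fm)²/Σfm²

— the relative least-squares mismatch between measured (m) and simulated (s)
twin peaks — over the rheological parameters `p`, using BFGS with
finite-difference gradients. The simulated peaks come from a forward model
run on the *identical* grid and pushed through the *identical*
truncation/padding/transform pipeline, so sampling artifacts cancel instead
of biasing the fit.

The package implements the whole chain: Kelvin–Voigt and spring-pot
(`G = G0(iω/ω0)^α`) rheologies, 2D/3D forward solvers (modal time–wavenumber
for Kelvin–Voigt, general frequency–wavenumber for any rheology), peak
extraction, the inversion, a synthetic-data generator with the
multiplicative+additive measurement-noise model, closed-form oracles, an
HDF5 motion container, and a CLI.

## Worked example

```python
import numpy as np
import twinpeak as tp

# a soft-tissue-like Kelvin-Voigt phantom: G0 = 2 kPa, tau = 0.5 ms
model = tp.RheologyModel.kelvin_voigt(G0=2000.0, tau=0.5e-3)

# simulate a full 3D acquisition and observe the center-depth line,
# then pollute it with the study noise model
data = tp.generate_insilico(model, dims=3, noise=tp.NoiseSpec(seed=0))

# invert with the (much cheaper) 2D forward model
cfg = tp.InversionConfig(prange=tp.default_peak_range(0.5e-3))
res = tp.invert(data, cfg)
print(f"G0  = {res.parameters['G0']:.1f} Pa")
print(f"tau = {res.parameters['tau']*1e3:.4f} ms")
print(f"Fobj = {res.fobj:.2e}, converged = {res.converged}")
```

prints

```
G0  = 2035.9 Pa
tau = 0.5504 ms
Fobj = 1.94e-04, converged = True
```

i.e. the storage modulus is recovered to 1.8 % and the relaxation time to
10 % from a single heavily noisy realization (multiplicative noise level
0.30, additive 0.007 of the peak velocity) — viscosity is intrinsically the
harder parameter, and ~10 % is the expected accuracy at this noise level.
`res.matched_peaks` holds the simulated peaks at the optimum for plotting
against the measured ones.

The same workflow is available from the shell:

```bash
twinpeak simulate run.yaml motion.h5
twinpeak peaks motion.h5 peaks.csv --config run.yaml
twinpeak invert motion.h5 result.json --config run.yaml
twinpeak verify          # closed-form oracle vs pipeline deviations
twinpeak study sweep.csv # relaxation-time sweep error table
```

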