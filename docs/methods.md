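# Methods

## Model and governing equations

Tissue is a homogeneous, incompressible viscoelastic bulk of density ρ
(default 1000 kg/m³, the soft-tissue convention; configurable). The
z-polarized displacement u obeys the scalar viscoelastic wave equation
ρ∂²u/∂t² − G∗∇²u = f, where ∗ is the memory convolution and f the ARF body
force, separable into a spatial profile and a rectangular temporal pulse of
duration T = 400 µs. In Fourier space the convolution becomes multiplication
by the complex shear modulus G(ω):

* Kelvin–Voigt: `G(ω) = G0 (1 + iτω)` — storage modulus G0 [Pa], relaxation
  time τ [s] (viscosity/elasticity ratio). Loss modulus exactly G0τω.
* Spring-pot: `G(ω) = G0 (iω/ω0)^α` — fractional order α ∈ (0, 1)
  interpolating spring→dashpot. The reference frequency ω0 only keeps G0 in
  Pa; it is fixed by configuration (default 2π·200 rad/s) and never
  inverted.
* Custom: any user map ω → G(ω) with a flat parameter vector.

All families enforce `G(−ω) = conj(G(ω))` so synthesized fields are real.

## Forward solvers

**Time–wavenumber (Kelvin–Voigt).** The spatial Fourier transform turns each
wavenumber magnitude k into a damped oscillator (mass ρ, stiffness ρcs²k²,
damping ρcs²k²τ, natural frequency ωn = cs·k, damping ratio ζ = cs·k·τ/2)
whose response to the rectangular pulse is closed-form — a difference of
exponentials in the roots λ₁,₂ = ωn(−ζ ± √(ζ²−1)), with the pulse end
handled by superposing a delayed negative step. The solution is exact at the
observation instants (no time discretization error). Degenerate cases: k = 0
uses the rigid-mode limit F·t/ρ; |ζ−1| < 1e−9 is nudged by 1e−8 to avoid the
repeated-root 0/0 (error far below neighbouring-bin round-off).

**Frequency–wavenumber (any rheology).** `V(k, ω) = iω·F̂ / (G(ω)k² − ρω²)`
with the analytic sinc-type spectrum of the rectangular pulse (a discrete
transform of the sampled pulse would alias badly at Δt = 0.1 ms), the ω = 0
plane zeroed (this also covers the spring-pot DC degeneracy), and Hermitian
symmetry enforced by a real inverse FFT. For a lossless medium whose pole
lands on a grid bin, the bin is zeroed and a conditioning warning raised.

**Conventions.** Temporal kernel e^{−iωt}, spatial kernel e^{+ikx}; a wave
travelling toward +x lies in the (f > 0, kx > 0) quadrant. Wavenumbers are
angular (rad/m) throughout; frequencies in Hz.

**Periodicity control.** Spectral solvers are periodic. Each spatial axis is
expanded to `expansion_factor × (extent + cs_ref·tmax)` (default factor 2),
and the frequency-domain solver's time axis to
`expansion_factor × (tmax + xmax/cs_ref)`, before cropping to the
observation window. The exact-in-time modal solver is then causal to below
1e−6 of the peak; the time-periodic frequency solver retains wrap-around
ringing of the slowly decaying low-k modes at the ~1e−3 level, which stays
below one spectral bin's influence on the peaks (verified by the solver
cross-check test). The two solvers agree pointwise to well under 1 % of the
peak once the force pulse has ended; the source samples themselves differ
because one pulse is exact and the other band-limited.

**Fused observed-field path.** The modal/denominator response depends on the
wavenumber vector only through |k|, so the observed line (y = 0, z = 0 or a
depth strip) is computed by collapsing the transverse wavenumbers onto a
dense radial grid (default 3000–4000 bins, weights linearly split between
bracketing bins) followed by one small matrix product and a 1D inverse FFT
— exact physics, interpolation error ~1e−4 relative. Only non-negative kx
rows are materialized (the observed spectrum is even in kx). This is what
makes a 2D forward evaluation ~0.1 s and a full inversion seconds, and it is
validated against the full-field solvers on coarse grids.

## ARF surrogate

The push is a separable Gaussian (σx = σy = 0.4 mm) times the 400 µs
rectangular pulse, with arbitrary amplitude (peaks are amplitude-invariant).
The axial extent is σz = 10 mm (FWHM ≈ 23 mm). The choice matters: the
protocol of inverting center-depth observations of **3D** data with a **2D**
(kz = 0) model presumes the push is long compared with the probed shear
wavelengths (up to 2π/300 ≈ 21 mm at the low-viscosity band edge). The
center-depth observation mixes modes of magnitude √(kx²+ky²+kz²) over the
push's kz spread 1/σz, so a short push biases the apparent wave speed — and
hence G0 — upward by ~(1/(σz·k))²/2. A 4 mm push would inflate noise-free G0
errors to 5–12 %, violating the long-push premise the 2D approximation rests
on; at σz = 10 mm the 3D→2D protocol errors are 0.9–2.7 % in G0 and ≤ 0.5 %
in τ across τ = 0.1–1.0 ms, while a genuine 3D inverse-crime inversion is
exact to ~1e−5 (confirming the bias is physics, not implementation).

## Peak pipeline

The x–t field (optionally truncated to a coordinate window — no taper; the
method's contract is that measured and simulated data are truncated
*identically* so truncation bias cancels) is zero-padded to
`pad_factor × next_pow2` per axis (default 4) and transformed. Peaks are
per-row/per-column argmaxes of |spectrum| restricted to the configured
(f, k) box, ties to the lowest index. Rows/columns whose maximum falls below
1e−12 of the box maximum are excluded, as are argmaxes pinned to the box
boundary (a clipped ridge is not an interior maximum — without this rule,
band edges contribute pure-noise points to the objective). No r-modulation
is applied anywhere in the pipeline. Optional 3-point parabolic sub-bin
refinement on the log magnitude is OFF for plain extraction, ON inside the
inversion (below).

In the lossless 2D/3D limit the f(k) ridge follows ω = cs·k within one bin
(a band-edge singularity pins the argmax), but the k(f) ridge is poorly
localized because nothing damps the geometric spread of off-axis modes; the
exact twin-curve coincidence at τ = 0 is a property of the 1D far-field
model and is tested there.

## Inversion

The objective is the sum of relative least-squares mismatches of the k(f)
and f(k) curves, evaluated at identical spectral bins (no interpolation;
only abscissae valid on both sides contribute, counts reported).
Minimization: BFGS on log-parameters (logit for α) with forward
finite-difference gradients at relative step 1e−5, gradient tolerance 1e−6,
maximum 200 iterations. The default start is a coarse 4×4 log grid
(G0 ∈ [0.5, 10] kPa × τ ∈ [0.05, 2] ms or α ∈ [0.15, 0.85]); BFGS runs from
the two best candidates and keeps the lower minimum, because the noisy
objective is occasionally multimodal and a single descent can strand in a
secondary basin. The log/logit transform keeps the nominally unconstrained
search inside the physical domain without changing the optimum. The
gradient tolerance matches what the finite differences can actually
resolve — a tighter setting only prolongs line searches without moving the
minimizer. BFGS frequently stops with scipy's "precision loss" status once
gradients reach that floor; the minimizer has converged in parameters at
that point and the result is flagged converged.

Sub-bin refinement is enabled by default *inside the inversion* (applied
identically to measured and simulated peaks): with raw argmax peaks the
objective is piecewise constant in p, and a 1e−5 relative step returns
exactly zero gradients. Refinement makes the simulated peaks vary
continuously with p while preserving the identical-processing contract.

The simulation domain for an inversion is sized once with a conservative
speed cap (3.5 m/s, covering the whole search box) so the expensive geometry
is shared across all iterates; candidates exceeding the cap are rejected
with an infinite objective. Multiple datasets (several pushes, both
propagation directions) are inverted jointly by summing objectives.

## Synthetic data and noise

`generate_insilico` runs the 3D solver (modal for Kelvin–Voigt, frequency
domain otherwise) on the acquisition grid Δx = 0.25 mm, Δt = 0.1 ms,
xmax = 30 mm, tmax = 15 ms, observes the center-depth line, and applies

    v_noisy = v(1 + αm ε₁) + αa ε₂ max|v|,

with independent per-sample standard-normal draws (a `same_draw` flag reuses
one draw for sensitivity checks) at the study operating point αm = 0.30,
αa = 0.007, fully seeded. Peak-matching bands follow the sweep convention:
100–500 Hz × 500–1500 rad/m for τ < 0.5 ms, 100–200 Hz × 300–800 rad/m
otherwise (attenuation empties the upper band at high viscosity).

What the generator emulates: the acquisition geometry, sampling, push
timing, the 3D-data/2D-inversion protocol, and the amplitude structure of
measurement noise. What it does not: speckle tracking/IQ-autocorrelation
noise physics and its spatial correlation, transducer point-spread
functions, beam aberration, tissue heterogeneity, or the exact Field-II
beam shape (replaced by the parametric Gaussian above). Passing the
synthetic studies therefore demonstrates the estimator's correctness and
noise robustness under this noise model — not clinical accuracy.

## Accuracy at the study conditions

Noise-free (3D data, 2D inversion): G0 errors 0.9–2.7 %, τ errors ≤ 0.5 %
over τ = 0.1–1.0 ms; the residual G0 bias concentrates at the low-k band of
the high-viscosity protocol, where the finite push length matters most.
Noisy (ten realizations per τ): per-τ mean G0 errors run 0.8–3.8 % for
τ ≤ 0.7 ms and ~7 % at τ = 1.0 ms (sweep-wide mean ~3 %); per-τ mean τ
errors run ~5–14 % — viscosity is intrinsically the noise-limited
parameter. For the noisy
spring-pot configuration the objective's *global minimum itself* shifts:
additive noise at 0.007·max|v| rivals the in-band signal beyond ~10 mm in
this strongly lossy medium (constant loss tangent tan(απ/2) ≈ 0.73), and
typical single-realization errors in α are 10–25 % even when the optimizer
verifiably beats the true parameters' objective value. Reported spring-pot
results are therefore seed-sensitive; the noise-free configuration recovers
(G0, α) to better than 1 %.

## Numerical choices and limitations

* pad_factor 4 balances peak quantization (≈10 Hz, ≈49 rad/m bins) against
  FFT cost; doubling it moves peaks by at most one coarse bin.
* Radial-bin count 3000 (inversion) / 4000 (generation); binning error is
  far below the spectral bin width.
* Band selection is manual configuration; automatic range selection from
  peak repeatability is out of scope.
* Uncertainty quantification (bootstrap/CIs) and heterogeneous-medium
  imaging are out of scope; the estimator assumes homogeneity along the
  measurement line, which averages over any heterogeneity present.
* Full-field 3D simulation is intended for coarse verification grids; the
  fused observed-field path is the production route.
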