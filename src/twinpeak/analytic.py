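"""Closed-form 1D far-field model and its twin-peak formulas.

For an infinitely long axisymmetric push, r-modulation of the displacement
turns the axisymmetric wave equation into a standard 1D wave equation whose
Kelvin-Voigt frequency-wavenumber velocity response is

    V(kx, omega) = i*omega / (rho*cs^2*kx^2*(1 + i*tau*omega) - rho*omega^2).

Its magnitude admits closed-form peak curves:

* f(k):  the maximizer over omega at fixed kx is omega = cs*kx — exactly the
  elastic dispersion line, independent of tau;
* k(f):  the maximizer over kx at fixed omega is
  kx = omega / (cs*sqrt(1 + tau^2*omega^2)), which bends below the elastic
  line as viscosity grows.

The two curves coincide iff tau = 0; their divergence is the signature the
twin-peak method inverts. These formulas (re-derived from d|V|/dk = 0, and
cross-checked against brute-force maximization in the tests) serve as
independent oracles for the numerical spectral pipeline. The r-modulation
exists only to justify this 1D model; it is never applied to data.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .forward import MotionField, SamplingGrid, _even_fast_len
from .peaks import FKSpectrum
from .rheology import KelvinVoigtParams, Medium, shear_speed

__all__ = [
    "farfield_velocity",
    "fk_peak_closed_form",
    "kf_peak_closed_form",
    "farfield_spectrum",
    "farfield_field_1d",
]


def farfield_velocity(kv: KelvinVoigtParams, medium: Medium, kx, omega):
    """Complex far-field velocity spectrum i*omega / (G(omega) kx^2 - rho omega^2).

    At tau = 0 the lossless medium has a pole on omega = cs*|kx|; an exact
    on-grid hit returns inf magnitude rather than raising.
    """
    kx = np.asarray(kx, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if not (np.all(np.isfinite(kx)) and np.all(np.isfinite(omega))):
        raise ValidationError("kx and omega must be finite")
    rho = medium.density
    den = rho * shear_speed(kv, medium) ** 2 * kx ** 2 * (1.0 + 1j * kv.tau * omega) \
        - rho * omega ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.inf + 0j, 1j * omega / np.where(den == 0, 1.0, den))
    out = np.where(omega == 0, 0.0 + 0.0j, out)
    return out if out.ndim else complex(out)


def fk_peak_closed_form(kv: KelvinVoigtParams, medium: Medium, kx):
    """Peak angular frequency over omega at fixed kx: omega = cs*kx (any tau)."""
    return shear_speed(kv, medium) * np.asarray(kx, dtype=float)


def kf_peak_closed_form(kv: KelvinVoigtParams, medium: Medium, omega):
    """Peak wavenumber over kx at fixed omega: kx = omega/(cs*sqrt(1 + tau^2 omega^2))."""
    omega = np.asarray(omega, dtype=float)
    return omega / (shear_speed(kv, medium) * np.sqrt(1.0 + (kv.tau * omega) ** 2))


def farfield_spectrum(kv: KelvinVoigtParams, medium: Medium,
                      f: np.ndarray, k: np.ndarray) -> FKSpectrum:
    """The analytic far-field response sampled on an (f [Hz], kx [rad/m]) grid,
    packaged as an :class:`FKSpectrum` so the peak-extraction machinery can be
    exercised against the closed forms without any FFT in between."""
    f = np.asarray(f, dtype=float)
    k = np.asarray(k, dtype=float)
    V = farfield_velocity(kv, medium, k[None, :], 2.0 * np.pi * f[:, None])
    return FKSpectrum(V, f, k, pad={"analytic": True})


def farfield_field_1d(kv: KelvinVoigtParams, medium: Medium,
                      grid: SamplingGrid, crop: bool = True,
                      shape: tuple[int, int] | None = None) -> MotionField:
    """Synthesize the sampled 1D far-field x-t response on an expanded periodic
    domain and crop it to the observation window.

    This is the bridge between the closed-form oracles and the numerical
    pipeline: running truncate/pad/transform/extract on this field must
    reproduce the closed-form peak curves as the grid is refined. Requires
    tau > 0 (the lossless pole cannot be sampled).

    With ``crop=False`` the full two-sided field (entire expanded domain and
    simulated time span) is returned. A one-sided acquisition window biases
    the extracted peaks by the asymmetric spectral smearing of the half-space
    truncation — exactly the processing effect the identical-pipeline
    contract is designed to cancel — so oracle-agreement checks use the
    uncropped field, where the wave has decayed before the domain edge and
    truncation is benign.
    """
    if kv.tau <= 0:
        raise ValidationError("the sampled far-field model needs tau > 0")
    cs = shear_speed(kv, medium)
    if shape is not None:
        nx, nt = shape
    else:
        half = grid.expansion_factor * (grid.xmax + cs * grid.tmax)
        nx = _even_fast_len(2 * int(np.ceil(half / grid.dx)))
        duration = grid.expansion_factor * (grid.tmax + grid.xmax / cs)
        nt = _even_fast_len(int(np.ceil(duration / grid.dt)) + 1)
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, grid.dx)
    omega = 2.0 * np.pi * np.fft.rfftfreq(nt, grid.dt)
    V = farfield_velocity(kv, medium, kx[:, None], omega[None, :])
    vt = np.fft.irfft(V, n=nt, axis=1) / grid.dt
    meta = {"solver": "farfield_1d",
            "model": {"family": "kelvin_voigt", "parameters": [kv.G0, kv.tau]}}
    if crop:
        v = np.fft.fftshift(np.fft.ifft(vt[:, : grid.t.size], axis=0), axes=0).real
        i0 = nx // 2
        return MotionField(v[i0: i0 + grid.x.size], grid.x, grid.t, meta=meta)
    v = np.fft.fftshift(np.fft.ifft(vt, axis=0), axes=0).real
    x_full = (np.arange(nx) - nx // 2) * grid.dx
    t_full = np.arange(nt) * grid.dt
    return MotionField(v, x_full, t_full, meta=meta)
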