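"""Rheological models for shear-wave viscoelasticity.

A rheology model is a parameterized complex shear modulus G(omega) [Pa]
evaluated at angular frequency omega [rad/s]. Two families are built in:

* Kelvin-Voigt:  G(omega) = G0 * (1 + i * tau * omega), with storage modulus
  G0 [Pa] and relaxation time tau [s] (viscosity / elastic modulus).
* Spring-pot:    G(omega) = G0 * (i * omega / omega0)**alpha, a fractional
  element interpolating between a spring (alpha -> 0) and a dashpot
  (alpha -> 1). omega0 [rad/s] is a fixed reference frequency that keeps the
  modulus factor G0 dimensionally a modulus; it is configuration, never a
  fitted parameter.

All models satisfy G(-omega) = conj(G(omega)) by construction so that
time-domain responses synthesized from them are real valued. Internal units
are strict SI (Pa, s, m, kg); unit conversion from kPa/ms/mm happens only at
the configuration boundary (see :mod:`twinpeak.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import UnsupportedModelError, ValidationError

__all__ = [
    "Medium",
    "KelvinVoigtParams",
    "SpringPotParams",
    "RheologyModel",
    "complex_modulus_kv",
    "complex_modulus_springpot",
    "shear_speed",
]

#: Soft-tissue density convention, kg/m^3. Configurable via Medium(density=...).
DEFAULT_DENSITY = 1000.0


@dataclass(frozen=True)
class Medium:
    """Homogeneous medium description shared by all solvers.

    Parameters
    ----------
    density : float
        Mass density rho in kg/m^3. Must be positive. Soft tissue is
        conventionally taken as 1000 kg/m^3.
    """

    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if not np.isfinite(self.density) or self.density <= 0:
            raise ValidationError(f"density must be positive, got {self.density}")


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Kelvin-Voigt parameters: storage modulus G0 [Pa], relaxation time tau [s]."""

    G0: float
    tau: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.G0) or self.G0 <= 0:
            raise ValidationError(f"G0 must be positive, got {self.G0}")
        if not np.isfinite(self.tau) or self.tau < 0:
            raise ValidationError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class SpringPotParams:
    """Spring-pot parameters: modulus factor G0 [Pa], fractional order alpha,
    reference frequency omega0 [rad/s] (fixed by configuration, not inverted)."""

    G0: float
    alpha: float
    omega0: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.G0) or self.G0 <= 0:
            raise ValidationError(f"G0 must be positive, got {self.G0}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not np.isfinite(self.omega0) or self.omega0 <= 0:
            raise ValidationError(f"omega0 must be positive, got {self.omega0}")


def _check_omega(omega) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValidationError("omega must be finite and real")
    return omega


def complex_modulus_kv(params: KelvinVoigtParams, omega) -> np.ndarray | complex:
    """Kelvin-Voigt complex shear modulus G0 * (1 + i*tau*omega) [Pa].

    The linear-in-omega imaginary part makes the loss modulus exactly
    G0*tau*omega; the formula is conjugate-symmetric in omega as written.
    """
    omega = _check_omega(omega)
    out = params.G0 * (1.0 + 1j * params.tau * omega)
    return out if out.ndim else complex(out)


def complex_modulus_springpot(params: SpringPotParams, omega) -> np.ndarray | complex:
    """Spring-pot complex shear modulus G0 * (i*omega/omega0)**alpha [Pa].

    Evaluated on the principal branch for omega > 0, i.e.
    G0 * (omega/omega0)**alpha * exp(i*alpha*pi/2); conjugated for omega < 0,
    and exactly 0 at omega = 0 (the DC bin of any frequency-domain solve
    carries no velocity response since the numerator i*omega vanishes there).
    """
    omega = _check_omega(omega)
    mag = params.G0 * (np.abs(omega) / params.omega0) ** params.alpha
    phase = np.exp(1j * params.alpha * np.pi / 2.0 * np.sign(omega))
    out = np.where(omega == 0.0, 0.0 + 0.0j, mag * phase)
    return out if out.ndim else complex(out)


def shear_speed(params: KelvinVoigtParams, medium: Medium) -> float:
    """Shear wave speed cs = sqrt(G0 / rho) [m/s] of the elastic backbone."""
    return float(np.sqrt(params.G0 / medium.density))


class RheologyModel:
    """A rheology family plus its parameter record, callable as omega -> G(omega).

    Construct through the classmethods :meth:`kelvin_voigt`, :meth:`spring_pot`
    or :meth:`custom`. Calling the model with an array of angular frequencies
    returns the complex modulus in Pa with conjugate symmetry enforced (custom
    models are evaluated only at omega >= 0 and conjugated for omega < 0).
    """

    def __init__(self, family: str, params, fn: Callable | None = None,
                 vector: Sequence[float] | None = None):
        self.family = family
        self.params = params
        self._fn = fn
        self._vector = None if vector is None else np.asarray(vector, dtype=float)

    # -- constructors ------------------------------------------------------

    @classmethod
    def kelvin_voigt(cls, G0: float, tau: float) -> "RheologyModel":
        return cls("kelvin_voigt", KelvinVoigtParams(G0=G0, tau=tau))

    @classmethod
    def spring_pot(cls, G0: float, alpha: float, omega0: float) -> "RheologyModel":
        return cls("spring_pot", SpringPotParams(G0=G0, alpha=alpha, omega0=omega0))

    @classmethod
    def custom(cls, fn: Callable, vector: Sequence[float]) -> "RheologyModel":
        """User-supplied modulus.

        ``fn(omega, vector)`` must return G(omega) [Pa] for omega >= 0; the
        negative-frequency branch is generated by conjugation so time-domain
        responses stay real.
        """
        return cls("custom", None, fn=fn, vector=vector)

    # -- evaluation --------------------------------------------------------

    def __call__(self, omega) -> np.ndarray | complex:
        omega = _check_omega(omega)
        if self.family == "kelvin_voigt":
            return complex_modulus_kv(self.params, omega)
        if self.family == "spring_pot":
            return complex_modulus_springpot(self.params, omega)
        if self.family == "custom":
            pos = self._fn(np.abs(omega), self._vector)
            out = np.where(omega >= 0, pos, np.conj(pos))
            return out if np.ndim(out) else complex(out)
        raise UnsupportedModelError(f"unknown rheology family {self.family!r}")

    # -- parameter vector plumbing (used by the inversion) -----------------

    @property
    def parameter_names(self) -> tuple:
        if self.family == "kelvin_voigt":
            return ("G0", "tau")
        if self.family == "spring_pot":
            return ("G0", "alpha")
        return tuple(f"p{i}" for i in range(len(self._vector)))

    @property
    def parameters(self) -> np.ndarray:
        """The invertible parameter vector (omega0 of a spring-pot is fixed)."""
        if self.family == "kelvin_voigt":
            return np.array([self.params.G0, self.params.tau])
        if self.family == "spring_pot":
            return np.array([self.params.G0, self.params.alpha])
        return self._vector.copy()

    def with_parameters(self, vector) -> "RheologyModel":
        """A copy of this model with a new physical parameter vector."""
        vector = np.asarray(vector, dtype=float)
        if self.family == "kelvin_voigt":
            return RheologyModel.kelvin_voigt(G0=vector[0], tau=vector[1])
        if self.family == "spring_pot":
            return RheologyModel.spring_pot(G0=vector[0], alpha=vector[1],
                                            omega0=self.params.omega0)
        return RheologyModel.custom(self._fn, vector)

    def reference_speed(self, medium: Medium, omega_ref: float | None = None) -> float:
        """A characteristic shear speed [m/s] used to size simulation domains.

        Kelvin-Voigt: sqrt(G0/rho). Otherwise sqrt(|G(omega_ref)|/rho) with
        omega_ref defaulting to the spring-pot reference frequency (or
        2*pi*200 rad/s for custom models).
        """
        if self.family == "kelvin_voigt":
            return shear_speed(self.params, medium)
        if omega_ref is None:
            omega_ref = self.params.omega0 if self.family == "spring_pot" else 2 * np.pi * 200.0
        return float(np.sqrt(np.abs(self(omega_ref)) / medium.density))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RheologyModel({self.family}, {self.params or self._vector})"
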