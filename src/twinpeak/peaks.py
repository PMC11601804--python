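"""Frequency-wavenumber spectra and twin-peak extraction.

An x-t motion field is zero-padded and Fourier transformed into the
(f [Hz], kx [rad/m]) plane, restricted to the propagating-wave quadrant
(f >= 0, kx > 0 for a +x-travelling wave under the package conventions).
The *twin peaks* are then

* ``f(k)``: for each retained wavenumber column, the frequency of maximum
  spectral magnitude, and
* ``k(f)``: for each retained frequency row, the wavenumber of maximum
  magnitude.

The two curves coincide for an elastic medium and diverge with viscosity;
matching both against a forward model is what identifies elasticity and
viscosity simultaneously. The cardinal rule of the method is that measured
and simulated fields are truncated, padded and transformed *identically*, so
discretization bias cancels in the comparison; nothing here tapers or
r-modulates the data by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .forward import MotionField

__all__ = [
    "PeakRange",
    "FKSpectrum",
    "TwinPeaks",
    "truncate_window",
    "fk_transform",
    "extract_twin_peaks",
    "normalize_for_display",
    "split_directions",
]

#: Rows/columns whose maximum falls below this fraction of the global maximum
#: are numerically empty and excluded from the peak curves.
VALIDITY_FLOOR = 1e-12


@dataclass(frozen=True)
class PeakRange:
    """Retained band for peak matching: [fmin, fmax] Hz x [kmin, kmax] rad/m."""

    fmin: float
    fmax: float
    kmin: float
    kmax: float

    def __post_init__(self) -> None:
        if not (0 <= self.fmin < self.fmax):
            raise ValidationError("need 0 <= fmin < fmax")
        if not (0 <= self.kmin < self.kmax):
            raise ValidationError("need 0 <= kmin < kmax")

    def validate_against(self, dt: float, dx: float) -> None:
        if self.fmax > 0.5 / dt * (1 + 1e-9):
            raise ValidationError(f"fmax {self.fmax} exceeds temporal Nyquist {0.5 / dt}")
        if self.kmax > np.pi / dx * (1 + 1e-9):
            raise ValidationError(f"kmax {self.kmax} exceeds spatial Nyquist {np.pi / dx}")


@dataclass
class FKSpectrum:
    """Complex spectrum over (f >= 0, kx > 0) with uniform axes.

    ``values`` has shape (n_f, n_k); ``f`` in Hz, ``k`` in rad/m (angular
    wavenumber, the convention in which the elastic dispersion line is
    omega = cs * k). ``pad`` records the padded transform sizes.
    """

    values: np.ndarray
    f: np.ndarray
    k: np.ndarray
    pad: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.f = np.asarray(self.f, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.values.shape != (self.f.size, self.k.size):
            raise ValidationError("spectrum shape does not match axes")

    @property
    def df(self) -> float:
        return float(self.f[1] - self.f[0])

    @property
    def dk(self) -> float:
        return float(self.k[1] - self.k[0])


@dataclass
class TwinPeaks:
    """The paired peak curves restricted to a :class:`PeakRange`.

    ``f_of_k[j]`` is the peak frequency at wavenumber ``k_grid[j]`` (the f(k)
    curve); ``k_of_f[i]`` the peak wavenumber at ``f_grid[i]`` (the k(f)
    curve). Invalid entries (numerically empty rows/columns) are NaN with
    their mask recorded.
    """

    k_grid: np.ndarray
    f_of_k: np.ndarray
    fk_valid: np.ndarray
    f_grid: np.ndarray
    k_of_f: np.ndarray
    kf_valid: np.ndarray
    prange: PeakRange

    @property
    def n_invalid(self) -> int:
        return int((~self.fk_valid).sum() + (~self.kf_valid).sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: curve in {fk, kf}, abscissa, peak, valid.

        For the fk curve the abscissa is kx [rad/m] and the peak value f [Hz];
        for the kf curve the abscissa is f [Hz] and the peak value kx [rad/m].
        """
        fk = pd.DataFrame({"curve": "fk", "abscissa": self.k_grid,
                           "peak": self.f_of_k, "valid": self.fk_valid})
        kf = pd.DataFrame({"curve": "kf", "abscissa": self.f_grid,
                           "peak": self.k_of_f, "valid": self.kf_valid})
        return pd.concat([fk, kf], ignore_index=True)


def truncate_window(field: MotionField, x_range=None, t_range=None) -> MotionField:
    """Restrict an x-t field to a coordinate window (no tapering).

    ``x_range``/``t_range`` are (lo, hi) in meters/seconds, inclusive; None
    keeps the full extent. Axis coordinates are preserved, so downstream
    processing sees physical positions, not indices.
    """
    if field.ndim_space != 1:
        raise ValidationError("truncate_window expects an x-t field")
    xsel = np.ones(field.x.size, dtype=bool)
    tsel = np.ones(field.t.size, dtype=bool)
    if x_range is not None:
        lo, hi = x_range
        xsel = (field.x >= lo - 1e-12) & (field.x <= hi + 1e-12)
    if t_range is not None:
        lo, hi = t_range
        tsel = (field.t >= lo - 1e-15) & (field.t <= hi + 1e-15)
    if not xsel.any() or not tsel.any():
        raise ValidationError("empty truncation window")
    meta = dict(field.meta)
    meta["window"] = {"x_range": None if x_range is None else list(map(float, x_range)),
                      "t_range": None if t_range is None else list(map(float, t_range))}
    return MotionField(field.velocity[np.ix_(xsel, tsel)], field.x[xsel],
                       field.t[tsel], meta=meta)


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def fk_transform(field: MotionField, pad_factor: int = 4) -> FKSpectrum:
    """Zero-padded 2D Fourier transform of an x-t field into the (f, kx) plane.

    Each axis is padded to ``pad_factor`` times the next power of two of its
    length. Temporal kernel exp(-i*omega*t), spatial kernel exp(+i*kx*x); the
    returned quadrant is f >= 0 (rfft half) by kx > 0 (positive spatial
    frequencies), which holds the +x-travelling wave. No r-modulation and no
    taper are applied — identical processing of measured and simulated data
    is the method's bias-cancellation contract.
    """
    if field.ndim_space != 1:
        raise ValidationError("fk_transform expects an x-t field")
    if field.x.size < 2 or field.t.size < 2:
        raise ValidationError("single-sample axes cannot be transformed")
    if pad_factor < 1:
        raise ValidationError("pad_factor must be >= 1")
    nt_pad = pad_factor * _next_pow2(field.t.size)
    nx_pad = pad_factor * _next_pow2(field.x.size)
    spec_t = np.fft.rfft(field.velocity, n=nt_pad, axis=1)       # exp(-i w t)
    spec = np.fft.ifft(spec_t, n=nx_pad, axis=0) * nx_pad        # exp(+i k x)
    f = np.fft.rfftfreq(nt_pad, field.dt)
    k_all = 2.0 * np.pi * np.fft.fftfreq(nx_pad, field.dx)
    pos = slice(1, nx_pad // 2)                                  # kx > 0
    return FKSpectrum(spec[pos, :].T, f, k_all[pos],
                      pad={"nt": nt_pad, "nx": nx_pad, "pad_factor": pad_factor})


def _parabolic(y_m1: np.ndarray, y_0: np.ndarray, y_p1: np.ndarray) -> np.ndarray:
    """Sub-bin offset of the vertex of a parabola through three samples."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (y_m1 - y_p1) / denom
    return np.where(np.abs(denom) > 0, np.clip(off, -0.5, 0.5), 0.0)


def extract_twin_peaks(spec: FKSpectrum, prange: PeakRange, refine: bool = False) -> TwinPeaks:
    """Locate the twin f(k)/k(f) argmax curves inside a retained range.

    Ties break to the lowest index (numpy argmax); with ``refine`` a 3-point
    parabolic fit on the log magnitude interpolates the peak between bins,
    which makes the curves vary continuously with the underlying medium
    parameters (useful to the inversion; OFF by default since on identical
    grids the discretization bias cancels between measured and simulated
    peaks anyway).
    """
    fsel = (spec.f >= prange.fmin) & (spec.f <= prange.fmax)
    ksel = (spec.k >= prange.kmin) & (spec.k <= prange.kmax)
    if not fsel.any() or not ksel.any():
        raise ValidationError("peak range does not intersect the spectrum support")
    mag = np.abs(spec.values[np.ix_(fsel, ksel)])
    f_grid = spec.f[fsel]
    k_grid = spec.k[ksel]
    floor = VALIDITY_FLOOR * mag.max() if mag.size else 0.0

    def curve(m: np.ndarray, axis_vals: np.ndarray):
        """argmax of each column of m over axis_vals (rows)."""
        idx = np.argmax(m, axis=0)
        colmax = m[idx, np.arange(m.shape[1])]
        valid = colmax > floor
        pos = axis_vals[idx].astype(float)
        if refine:
            interior = (idx > 0) & (idx < m.shape[0] - 1) & valid
            cols = np.arange(m.shape[1])[interior]
            ii = idx[interior]
            with np.errstate(divide="ignore"):
                logm = np.log(np.maximum(m, 1e-300))
            off = _parabolic(logm[ii - 1, cols], logm[ii, cols], logm[ii + 1, cols])
            step = axis_vals[1] - axis_vals[0] if axis_vals.size > 1 else 0.0
            pos[interior] = pos[interior] + off * step
        pos[~valid] = np.nan
        return pos, valid

    f_of_k, fk_valid = curve(mag, f_grid)          # per k column
    k_of_f, kf_valid = curve(mag.T, k_grid)        # per f row
    return TwinPeaks(k_grid=k_grid, f_of_k=f_of_k, fk_valid=fk_valid,
                     f_grid=f_grid, k_of_f=k_of_f, kf_valid=kf_valid,
                     prange=prange)


def normalize_for_display(spec: FKSpectrum, axis: str = "k") -> np.ndarray:
    """|spectrum| with each k column (axis='k', visualizes f(k)) or each f row
    (axis='f', visualizes k(f)) scaled by its own maximum. Display only —
    never used in the inversion objective. Zero rows/columns stay zero."""
    mag = np.abs(spec.values)
    if mag.max() == 0:
        raise ValidationError("cannot normalize an all-zero spectrum")
    if axis == "k":
        m = mag.max(axis=0, keepdims=True)
    elif axis == "f":
        m = mag.max(axis=1, keepdims=True)
    else:
        raise ValidationError("axis must be 'f' or 'k'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m > 0, mag / np.where(m > 0, m, 1.0), 0.0)
    return out


def split_directions(field: MotionField) -> tuple[MotionField, MotionField]:
    """Split a two-sided acquisition into right- and left-travelling halves.

    The x <= 0 half is reflected (x -> -x) so both outputs present a
    +x-travelling wave to the rest of the pipeline and map onto the positive
    kx quadrant.
    """
    if field.ndim_space != 1:
        raise ValidationError("split_directions expects an x-t field")
    right_sel = field.x >= -1e-12
    left_sel = field.x <= 1e-12
    if not right_sel.any() or not left_sel.any():
        raise ValidationError("field does not straddle x = 0")
    right = MotionField(field.velocity[right_sel], field.x[right_sel] - field.x[right_sel][0],
                        field.t, meta={**field.meta, "direction": "right"})
    lv = field.velocity[left_sel][::-1]
    lx = -field.x[left_sel][::-1]
    left = MotionField(lv, lx - lx[0], field.t, meta={**field.meta, "direction": "left"})
    return right, left
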