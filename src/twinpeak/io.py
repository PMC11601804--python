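"""File formats and configuration: HDF5 motion containers, peaks CSV, YAML config.

The motion container is a self-describing HDF5 file with datasets
``velocity`` (m/s), ``x``, ``t`` (and ``y``, ``z`` when present), attributes
``dx``, ``dt``, ``units`` and a JSON ``provenance`` string; round trips are
lossless. Configuration files use semantic units (kPa, ms, mm) which are
converted to SI exactly once, here at the boundary — everything inside the
package is strict SI.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError
from .forward import ARFSource, MotionField, SamplingGrid
from .peaks import PeakRange, TwinPeaks
from .rheology import Medium, RheologyModel
from .synthdata import NoiseSpec

__all__ = [
    "write_motion", "read_motion",
    "write_peaks_csv", "read_peaks_csv",
    "load_config", "config_to_objects",
]


def write_motion(path, field: MotionField) -> None:
    """Write a MotionField to the HDF5 motion container."""
    with h5py.File(path, "w") as h:
        h.create_dataset("velocity", data=field.velocity)
        h.create_dataset("x", data=field.x)
        h.create_dataset("t", data=field.t)
        if field.y is not None:
            h.create_dataset("y", data=field.y)
        if field.z is not None:
            h.create_dataset("z", data=field.z)
        h.attrs["dx"] = field.dx
        h.attrs["dt"] = field.dt
        h.attrs["units"] = "m/s"
        h.attrs["provenance"] = json.dumps(field.meta, default=float)


def read_motion(path) -> MotionField:
    """Read the HDF5 motion container; missing pieces raise a SchemaError
    naming the offending dataset/attribute (nothing is guessed)."""
    with h5py.File(path, "r") as h:
        for ds in ("velocity", "x", "t"):
            if ds not in h:
                raise SchemaError(f"motion container is missing dataset '{ds}'")
        for at in ("dx", "dt", "units"):
            if at not in h.attrs:
                raise SchemaError(f"motion container is missing attribute '{at}'")
        meta = json.loads(h.attrs.get("provenance", "{}"))
        return MotionField(
            velocity=h["velocity"][()],
            x=h["x"][()],
            t=h["t"][()],
            y=h["y"][()] if "y" in h else None,
            z=h["z"][()] if "z" in h else None,
            meta=meta,
        )


def write_peaks_csv(path, peaks: TwinPeaks) -> None:
    """Tidy CSV export: curve in {fk, kf}, abscissa, peak, valid.

    Units are stated in a comment header: fk rows are (kx [rad/m] -> f [Hz]),
    kf rows are (f [Hz] -> kx [rad/m]).
    """
    frame = peaks.to_frame()
    with open(path, "w") as fh:
        fh.write("# twin peaks; curve fk: abscissa kx [rad/m], peak f [Hz]; "
                 "curve kf: abscissa f [Hz], peak kx [rad/m]\n")
        frame.to_csv(fh, index=False)


def read_peaks_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# configuration (semantic units at the boundary)
# ---------------------------------------------------------------------------

_KPA, _MS, _MM, _US = 1e3, 1e-3, 1e-3, 1e-6


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def _model_from(block: dict) -> RheologyModel:
    family = block.get("family")
    if family == "kelvin_voigt":
        return RheologyModel.kelvin_voigt(G0=block["G0_kPa"] * _KPA,
                                          tau=block["tau_ms"] * _MS)
    if family == "spring_pot":
        omega0 = 2 * np.pi * block.get("f0_Hz", 200.0)
        return RheologyModel.spring_pot(G0=block["G0_Pa"], alpha=block["alpha"],
                                        omega0=omega0)
    raise ValidationError(f"unknown model family {family!r}")


def config_to_objects(cfg: dict) -> dict:
    """Convert a parsed semantic-unit config into package objects (SI)."""
    out: dict = {}
    if "model" in cfg:
        out["model"] = _model_from(cfg["model"])
    out["medium"] = Medium(**cfg.get("medium", {}))
    s = cfg.get("source", {})
    out["source"] = ARFSource(
        sigma_x=s.get("sigma_x_mm", 0.4) * _MM,
        sigma_y=s.get("sigma_y_mm", 0.4) * _MM,
        sigma_z=s.get("sigma_z_mm", 10.0) * _MM,
        duration=s.get("duration_us", 400.0) * _US,
        amplitude=s.get("amplitude", 1.0),
    )
    g = cfg.get("grid", {})
    out["grid"] = SamplingGrid(
        dx=g.get("dx_mm", 0.25) * _MM, dt=g.get("dt_ms", 0.1) * _MS,
        xmax=g.get("xmax_mm", 30.0) * _MM, tmax=g.get("tmax_ms", 15.0) * _MS,
        dy=g.get("dy_mm", 0.5) * _MM, ymax=g.get("ymax_mm", 15.0) * _MM,
        dz=g.get("dz_mm", 0.5) * _MM, zmax=g.get("zmax_mm", 15.0) * _MM,
        expansion_factor=g.get("expansion_factor", 2.0),
    )
    n = cfg.get("noise")
    if n is not None:
        out["noise"] = NoiseSpec(alpha_m=n.get("alpha_m", 0.30),
                                 alpha_a=n.get("alpha_a", 0.007),
                                 seed=n.get("seed", 0),
                                 same_draw=n.get("same_draw", False))
    p = cfg.get("peaks")
    if p is not None:
        out["prange"] = PeakRange(fmin=p.get("fmin_Hz", 100.0),
                                  fmax=p.get("fmax_Hz", 500.0),
                                  kmin=p.get("kmin_per_m", 500.0),
                                  kmax=p.get("kmax_per_m", 1500.0))
    out["dims"] = cfg.get("dims", 3)
    out["inversion"] = cfg.get("inversion", {})
    return out
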