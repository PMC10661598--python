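"""HDF5 container for dictionaries, signals, and images.

Layout (schema_version 1):

* ``/dictionary`` — 2-D ``(T, N)`` dataset, chunked by column blocks;
* ``/signals/<name>`` — 1-D traces with per-dataset ``fs`` and
  ``pulse_energy`` attributes;
* ``/images/<name>`` — 3-D volumes of shape ``(nz, ny, nx)`` so voxel
  ``(ix, iy, iz)`` sits at ``[iz, iy, ix]``;
* root attributes — grid geometry, acoustic parameters, encoder
  config, and anything the caller adds (seeds, solver settings), so
  every artifact records how to regenerate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from .core_model import AcousticParams, MeasuredSignal, VolumeGrid, VolumeImage
from .encoder_sim import CalibrationDictionary, EncoderConfig

__all__ = ["SCHEMA_VERSION", "SchemaError", "Container", "save_container",
           "load_container"]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when a file does not carry the expected container schema."""


@dataclass
class Container:
    dictionary: Optional[CalibrationDictionary] = None
    signals: dict = field(default_factory=dict)
    images: dict = field(default_factory=dict)
    grid: Optional[VolumeGrid] = None
    params: Optional[AcousticParams] = None
    encoder: Optional[EncoderConfig] = None
    attrs: dict = field(default_factory=dict)


def _write_grid(attrs, grid: VolumeGrid) -> None:
    attrs["grid.extent_mm"] = np.asarray(grid.extent_mm)
    attrs["grid.inc_mm"] = np.asarray(grid.inc_mm)
    attrs["grid.origin_mm"] = np.asarray(grid.origin_mm)


def _read_grid(attrs) -> Optional[VolumeGrid]:
    if "grid.extent_mm" not in attrs:
        return None
    return VolumeGrid(tuple(attrs["grid.extent_mm"]),
                      tuple(attrs["grid.inc_mm"]),
                      tuple(attrs["grid.origin_mm"]))


def _write_params(attrs, p: AcousticParams) -> None:
    for k in ("v_water", "v_pipe", "f_c", "frac_bw_6db", "pipe_length",
              "pipe_radius", "fs"):
        attrs[f"acoustic.{k}"] = getattr(p, k)
    attrs["acoustic.n_samples"] = int(p.n_samples)


def _read_params(attrs) -> Optional[AcousticParams]:
    if "acoustic.f_c" not in attrs:
        return None
    return AcousticParams(
        v_water=float(attrs["acoustic.v_water"]),
        v_pipe=float(attrs["acoustic.v_pipe"]),
        f_c=float(attrs["acoustic.f_c"]),
        frac_bw_6db=float(attrs["acoustic.frac_bw_6db"]),
        pipe_length=float(attrs["acoustic.pipe_length"]),
        pipe_radius=float(attrs["acoustic.pipe_radius"]),
        fs=float(attrs["acoustic.fs"]),
        n_samples=int(attrs["acoustic.n_samples"]),
    )


def _write_encoder(attrs, e: EncoderConfig) -> None:
    attrs["encoder.coda_len"] = int(e.coda_len)
    attrs["encoder.coda_decay_tau"] = e.coda_decay_tau
    attrs["encoder.lateral_fwhm_mm"] = e.lateral_fwhm_mm
    attrs["encoder.calib_snr_db"] = (math.inf if e.calib_snr_db is None
                                     else e.calib_snr_db)
    attrs["encoder.n_avg"] = int(e.n_avg)
    attrs["encoder.seed"] = int(e.seed)


def _read_encoder(attrs) -> Optional[EncoderConfig]:
    if "encoder.coda_len" not in attrs:
        return None
    snr = float(attrs["encoder.calib_snr_db"])
    return EncoderConfig(
        coda_len=int(attrs["encoder.coda_len"]),
        coda_decay_tau=float(attrs["encoder.coda_decay_tau"]),
        lateral_fwhm_mm=float(attrs["encoder.lateral_fwhm_mm"]),
        calib_snr_db=None if math.isinf(snr) else snr,
        n_avg=int(attrs["encoder.n_avg"]),
        seed=int(attrs["encoder.seed"]),
    )


def save_container(path, dictionary: Optional[CalibrationDictionary] = None,
                   signals: Optional[dict] = None,
                   images: Optional[dict] = None,
                   grid: Optional[VolumeGrid] = None,
                   params: Optional[AcousticParams] = None,
                   encoder: Optional[EncoderConfig] = None,
                   attrs: Optional[dict] = None) -> None:
    """Write a container file; metadata travels with every artifact."""
    if dictionary is not None:
        grid = grid or dictionary.grid
        params = params or dictionary.params
        encoder = encoder or dictionary.encoder
    if grid is None and images:
        grid = next(iter(images.values())).grid

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if grid is not None:
            _write_grid(f.attrs, grid)
        if params is not None:
            _write_params(f.attrs, params)
        if encoder is not None:
            _write_encoder(f.attrs, encoder)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        if dictionary is not None:
            T, N = dictionary.columns.shape
            f.create_dataset("dictionary", data=dictionary.columns,
                             chunks=(T, min(N, 64)))
        if signals:
            g = f.create_group("signals")
            for name, sig in signals.items():
                d = g.create_dataset(name, data=sig.samples)
                d.attrs["fs"] = sig.fs
                d.attrs["pulse_energy"] = sig.pulse_energy
        if images:
            g = f.create_group("images")
            for name, img in images.items():
                g.create_dataset(name, data=img.as_array())


def load_container(path) -> Container:
    """Read a container file back into domain objects (lossless round-trip)."""
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise SchemaError(f"{path} has no schema_version attribute; "
                              "not a recognized container")
        version = int(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaError(f"{path}: schema_version {version} not supported "
                              f"(expected {SCHEMA_VERSION})")
        grid = _read_grid(f.attrs)
        params = _read_params(f.attrs)
        encoder = _read_encoder(f.attrs)
        out = Container(grid=grid, params=params, encoder=encoder)
        reserved = {"schema_version"}
        out.attrs = {k: v for k, v in f.attrs.items()
                     if k not in reserved and "." not in k}
        if "dictionary" in f:
            if grid is None or params is None or encoder is None:
                raise SchemaError(f"{path}: dictionary present but grid/params/"
                                  "encoder metadata missing")
            out.dictionary = CalibrationDictionary(
                f["dictionary"][()], grid, params, encoder)
        if "signals" in f:
            for name, d in f["signals"].items():
                out.signals[name] = MeasuredSignal(
                    d[()], fs=float(d.attrs["fs"]),
                    pulse_energy=float(d.attrs["pulse_energy"]))
        if "images" in f:
            if grid is None:
                raise SchemaError(f"{path}: images present but grid missing")
            for name, d in f["images"].items():
                out.images[name] = VolumeImage.from_array(d[()], grid)
        return out
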