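"""Readers and writers for the external formats the pipeline touches.

Supported spectrum dialects:

``bes3t``
    Bruker BES3T descriptor/data pairs (``.DSC`` text + ``.DTA`` big-endian
    float64).  Field values are normalized to mT on ingest (BES3T stores
    Gauss unless the descriptor says otherwise) and the microwave frequency
    to GHz.  The axis convention is inclusive endpoints: XMIN is the first
    point and XWID the span (last - first).
``jcamp``
    A JCAMP-DX 4.24 subset using ``##XYDATA=(X++(Y..Y))`` with AFFN numbers;
    acquisition metadata travels in private ``##$`` comment records.
``csv``
    Comma-separated two-column text with a required header row and
    ``#``-prefixed comments carrying metadata.

Tabular curves (buildup, decay, dose series, ...) are plain columnar text
read through pandas.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError
from .types import CurveSeries, CWSpectrum

__all__ = [
    "read_cw_spectrum",
    "write_cw_spectrum",
    "read_curve",
    "load_spin_system",
    "save_spin_system",
]

# metadata fields serialized into csv comments / jcamp ##$ records
_META_FIELDS = (
    "mw_frequency_GHz",
    "modulation_frequency_kHz",
    "modulation_amplitude_mT",
    "sweep_rate_mT_s",
    "q_factor",
    "receiver_gain",
    "sample_mass_mg",
    "label",
)


def read_cw_spectrum(path: str | os.PathLike, dialect: str = "csv") -> CWSpectrum:
    """Read a CW-EPR spectrum from ``path`` in the given dialect."""
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "jcamp":
        return _read_jcamp(path)
    if dialect == "bes3t":
        return _read_bes3t(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_cw_spectrum(spectrum: CWSpectrum, path: str | os.PathLike, dialect: str = "csv") -> str:
    """Write ``spectrum`` to ``path``; returns the path written."""
    if spectrum.intensity.size == 0:
        raise ValidationError("cannot write an empty spectrum")
    if dialect == "csv":
        _write_csv(spectrum, path)
    elif dialect == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unwritable dialect {dialect!r}")
    return os.fspath(path)


# ---------------------------------------------------------------- csv

def _meta_dict(spectrum: CWSpectrum) -> dict:
    out = {}
    for key in _META_FIELDS:
        value = getattr(spectrum, key)
        if value is not None and value != "":
            out[key] = value
    return out


def _write_csv(spectrum: CWSpectrum, path) -> None:
    with open(path, "w") as fh:
        for key, value in _meta_dict(spectrum).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("field_mT,intensity\n")
        for b, y in zip(spectrum.field_mT, spectrum.intensity):
            fh.write(f"{b:.15g},{y:.15g}\n")


def _read_csv(path) -> CWSpectrum:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    table = pd.read_csv(path, comment="#")
    if "field_mT" not in table.columns or "intensity" not in table.columns:
        raise FormatError("csv spectrum requires 'field_mT' and 'intensity' columns")
    kwargs = {}
    for key in _META_FIELDS:
        if key in meta:
            kwargs[key] = meta[key] if key == "label" else float(meta[key])
    kwargs.setdefault("mw_frequency_GHz", 9.6)
    return CWSpectrum(table["field_mT"].to_numpy(), table["intensity"].to_numpy(), **kwargs)


# ---------------------------------------------------------------- jcamp

def _write_jcamp(spectrum: CWSpectrum, path) -> None:
    x = spectrum.field_mT
    y = spectrum.intensity
    with open(path, "w") as fh:
        fh.write(f"##TITLE={spectrum.label or 'CW EPR spectrum'}\n")
        fh.write("##JCAMP-DX=4.24\n##DATA TYPE=EPR SPECTRUM\n")
        fh.write("##XUNITS=mT\n##YUNITS=ARBITRARY UNITS\n")
        fh.write(f"##FIRSTX={x[0]:.15g}\n##LASTX={x[-1]:.15g}\n##NPOINTS={x.size}\n")
        fh.write("##XFACTOR=1\n##YFACTOR=1\n")
        for key, value in _meta_dict(spectrum).items():
            fh.write(f"##${key.upper()}={value}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        for i in range(0, x.size, 4):
            ys = " ".join(f"{v:.15g}" for v in y[i : i + 4])
            fh.write(f"{x[i]:.15g} {ys}\n")
        fh.write("##END=\n")


def _read_jcamp(path) -> CWSpectrum:
    records: dict = {}
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                label, _, value = line[2:].partition("=")
                label = label.strip().upper()
                if label == "XYDATA":
                    in_data = True
                    continue
                if label == "END":
                    in_data = False
                    continue
                records[label] = value.strip()
            elif in_data:
                parts = line.split()
                ys.extend(float(v) for v in parts[1:])
    for required in ("FIRSTX", "LASTX", "NPOINTS"):
        if required not in records:
            raise FormatError(f"jcamp file missing ##{required}")
    npts = int(records["NPOINTS"])
    if len(ys) != npts:
        raise FormatError(f"jcamp file declares {npts} points but carries {len(ys)}")
    yfac = float(records.get("YFACTOR", 1.0))
    x = np.linspace(float(records["FIRSTX"]), float(records["LASTX"]), npts)
    kwargs = {}
    for key in _META_FIELDS:
        rec = f"${key.upper()}"
        if rec in records:
            kwargs[key] = records[rec] if key == "label" else float(records[rec])
    kwargs.setdefault("mw_frequency_GHz", 9.6)
    return CWSpectrum(x, np.asarray(ys) * yfac, **kwargs)


# ---------------------------------------------------------------- bes3t

_BES3T_REQUIRED = ("XPTS", "XMIN", "XWID", "MWFQ")


def _read_bes3t(path) -> CWSpectrum:
    """Read a Bruker BES3T descriptor/data pair.

    ``path`` may point at either the ``.DSC`` or the ``.DTA`` part.
    """
    base, _ = os.path.splitext(os.fspath(path))
    dsc, dta = base + ".DSC", base + ".DTA"
    if not os.path.exists(dsc):
        raise FormatError(f"BES3T descriptor part not found: {dsc}")
    if not os.path.exists(dta):
        raise FormatError(f"BES3T data part not found: {dta}")
    fields: dict = {}
    with open(dsc) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("*", "#", ".DVC")):
                continue
            parts = line.split(None, 1)
            if len(parts) == 2:
                fields[parts[0]] = parts[1].strip().strip("'")
    for key in _BES3T_REQUIRED:
        if key not in fields:
            raise FormatError(f"BES3T descriptor missing required key {key}")
    npts = int(fields["XPTS"])
    xmin, xwid = float(fields["XMIN"]), float(fields["XWID"])
    # unit normalization: BES3T stores field in Gauss unless XUNI says otherwise
    xuni = fields.get("XUNI", "G").strip("'\"")
    scale = {"G": 0.1, "mT": 1.0, "T": 1000.0}.get(xuni)
    if scale is None:
        raise FormatError(f"unsupported BES3T field unit {xuni!r}")
    # inclusive-endpoint convention: XMIN is the first point, XWID = last - first
    axis_mT = (xmin + xwid * np.arange(npts) / (npts - 1)) * scale
    data = np.fromfile(dta, dtype=">f8")
    if data.size != npts:
        raise FormatError(f"BES3T data part has {data.size} points, descriptor says {npts}")
    if np.any(np.diff(axis_mT) <= 0):
        raise ValidationError("BES3T field axis is not strictly increasing")
    kwargs = {"mw_frequency_GHz": float(fields["MWFQ"]) / 1e9}
    if "B0MA" in fields:
        kwargs["modulation_amplitude_mT"] = float(fields["B0MA"]) * 1e3  # stored in T
    if "B0MF" in fields:
        kwargs["modulation_frequency_kHz"] = float(fields["B0MF"]) / 1e3  # stored in Hz
    if "QValue" in fields:
        kwargs["q_factor"] = float(fields["QValue"])
    if "RCAG" in fields:
        kwargs["receiver_gain"] = float(fields["RCAG"])
    if "TITL" in fields:
        kwargs["label"] = fields["TITL"]
    return CWSpectrum(axis_mT, data.astype(float), **kwargs)


# ---------------------------------------------------------------- curves

def read_curve(path, columns: Sequence[str] = ("t", "y"), sep: Optional[str] = None) -> CurveSeries:
    """Read a (t, y) curve from columnar text with a header row.

    ``columns`` names the time and signal columns; extra columns are ignored
    and recorded in ``meta``.
    """
    table = pd.read_csv(path, comment="#", sep=sep, engine="python" if sep is None else "c")
    tcol, ycol = columns
    for col in (tcol, ycol):
        if col not in table.columns:
            raise FormatError(f"curve file missing column {col!r}")
    extra = [c for c in table.columns if c not in (tcol, ycol)]
    return CurveSeries(
        table[tcol].to_numpy(float),
        table[ycol].to_numpy(float),
        meta={"source": os.fspath(path), "ignored_columns": extra},
    )


# ---------------------------------------------------------------- spin systems

def load_spin_system(path):
    """Load a :class:`~spinpol.spinsim.SpinSystem` from a YAML config.

    Expected keys: ``g.principal``, ``g.euler``, ``couplings`` (list with
    ``isotope``, ``I``, ``A_MHz``, ``euler``), ``lineshape`` (``shape``,
    ``fwhm_mT``, optional ``gauss_fraction``), optional ``weight``.
    """
    from .spinsim import LineBroadening, NucleusCoupling, SpinSystem, TensorSpec

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    g = cfg.get("g", {})
    gt = TensorSpec(g.get("principal", [2.0023] * 3), g.get("euler", [0.0, 0.0, 0.0]))
    couplings = [
        NucleusCoupling(
            c["isotope"],
            float(c.get("I", 0.5)),
            TensorSpec(c["A_MHz"], c.get("euler", [0.0, 0.0, 0.0])),
        )
        for c in cfg.get("couplings", [])
    ]
    ls = cfg.get("lineshape", {})
    lb = LineBroadening(
        shape=ls.get("shape", "pseudo-voigt"),
        fwhm_mT=float(ls.get("fwhm_mT", 0.8)),
        gauss_fraction=float(ls.get("gauss_fraction", 0.5)),
    )
    return SpinSystem(gt, couplings, lb, weight=float(cfg.get("weight", 1.0)))


def save_spin_system(system, path) -> str:
    """Write a SpinSystem back to the YAML layout read by load_spin_system."""
    cfg = {
        "g": {
            "principal": [float(v) for v in system.g.principal_values],
            "euler": [float(v) for v in system.g.euler_angles],
        },
        "couplings": [
            {
                "isotope": c.isotope,
                "I": float(c.I),
                "A_MHz": [float(v) for v in c.tensor.principal_values],
                "euler": [float(v) for v in c.tensor.euler_angles],
            }
            for c in system.couplings
        ],
        "lineshape": {
            "shape": system.line_broadening.shape,
            "fwhm_mT": float(system.line_broadening.fwhm_mT),
            "gauss_fraction": float(system.line_broadening.gauss_fraction),
        },
        "weight": float(system.weight),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return os.fspath(path)
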