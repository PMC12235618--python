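"""Plain-text readers/writers for traces and spectra.

Both formats are two-column TSV preceded by ``# key: value`` metadata
lines.  Traces use microseconds on disk (columns ``t_us``,
``intensity``); spectra use kilohertz offsets (columns ``offset_khz``,
``intensity``).  Numbers are written at 6 significant digits with a
stable format so round trips are reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from endortools.endor_spectra import Spectrum
from endortools.relaxation_analysis import Trace

__all__ = ["read_trace", "write_trace", "read_spectrum", "write_spectrum"]

_FLOAT_META = {
    "temperature_K",
    "rf_offset_khz",
    "tau_ns",
    "nu_ref_mhz",
    "h2o_frac",
    "a_hf_hz",
    "r_GdF",
    "noise_frac",
    "true_T1e",
    "true_beta",
    "true_A",
    "true_T2n",
    "true_fraction_fast",
    "true_rate_fast",
    "true_rate_slow",
}


def _read_table(path):
    meta, rows = {}, []
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    if key in _FLOAT_META:
                        try:
                            value = float(value)
                        except ValueError:
                            pass
                    elif key == "seed":
                        value = int(value)
                    meta[key] = value
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append([float(v) for v in fields])
    if header is None or not rows:
        raise ValueError(f"{path}: no tabular data found")
    return meta, header, np.asarray(rows, dtype=float)


def _write_table(path, meta, header, columns):
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        fh.write("\t".join(header) + "\n")
        for row in zip(*columns):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def write_trace(path, trace: Trace) -> None:
    """Write a trace as TSV with metadata header; times in microseconds."""
    _write_table(path, trace.meta, ["t_us", "intensity"], [trace.t * 1e6, trace.I])


def read_trace(path) -> Trace:
    """Read a trace TSV written by :func:`write_trace` (tolerant of comments)."""
    meta, header, data = _read_table(path)
    if header[:2] != ["t_us", "intensity"]:
        raise ValueError(f"{path}: expected columns t_us, intensity, got {header}")
    if "kind" not in meta:
        raise ValueError(f"{path}: trace metadata must include 'kind'")
    return Trace(t=data[:, 0] * 1e-6, I=data[:, 1], meta=meta)


def write_spectrum(path, spectrum: Spectrum) -> None:
    """Write a spectrum as TSV with metadata header; offsets in kHz."""
    _write_table(
        path,
        spectrum.meta,
        ["offset_khz", "intensity"],
        [spectrum.offsets * 1e-3, spectrum.intensities],
    )


def read_spectrum(path) -> Spectrum:
    """Read a spectrum TSV written by :func:`write_spectrum`."""
    meta, header, data = _read_table(path)
    if header[:2] != ["offset_khz", "intensity"]:
        raise ValueError(f"{path}: expected columns offset_khz, intensity, got {header}")
    return Spectrum(offsets=data[:, 0] * 1e3, intensities=data[:, 1], meta=meta)
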