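"""File formats: spectrum CSV dialect, dose-response tables, JSON reports.

Spectrum files are plain CSV with a comment header of ``# key: value``
metadata lines followed by the column header
``frequency_hz,z_real_ohm,z_imag_ohm``; one spectrum per file, imaginary
part stored as measured (negative in the capacitive region). Comma and
semicolon delimiters are both accepted on read. Round trips are lossless.

Dose-response tables are long-format CSV with columns
``concentration,unit,rct_ohm,electrode_id``; blanks are rows with
concentration 0.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .assay import DoseResponseSeries
from .circuit import ImpedanceSpectrum, SpectrumMeta

__all__ = [
    "SpectrumFormatError",
    "DuplicateFrequencyError",
    "read_spectrum",
    "write_spectrum",
    "read_dose_response",
    "write_dose_response",
    "write_json_report",
    "read_json_report",
    "file_sha256",
]

_COLUMNS = ["frequency_hz", "z_real_ohm", "z_imag_ohm"]
_META_FIELDS = {"dc_potential_v": float, "ac_amplitude_v": float,
                "electrolyte": str, "label": str}


class SpectrumFormatError(ValueError):
    """The file does not match the spectrum CSV dialect."""


class DuplicateFrequencyError(SpectrumFormatError):
    """A frequency appears more than once in the file."""


def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    path = Path(path)
    m = spectrum.meta
    lines = [
        f"# dc_potential_v: {m.dc_potential_v!r}",
        f"# ac_amplitude_v: {m.ac_amplitude_v!r}",
        f"# electrolyte: {m.electrolyte}",
        f"# label: {m.label}",
        ",".join(_COLUMNS),
    ]
    for f, z in zip(spectrum.frequency, spectrum.z):
        # repr of Python floats is shortest-exact: round trips bit-for-bit
        lines.append(f"{float(f)!r},{float(z.real)!r},{float(z.imag)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum CSV; lossless inverse of :func:`write_spectrum`.

    Frequencies are re-sorted high-to-low with a warning if the file order
    differed. Malformed headers, non-numeric cells and duplicated
    frequencies each raise a distinct, descriptive error.
    """
    path = Path(path)
    meta_kwargs: dict[str, Any] = {}
    body_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key in _META_FIELDS:
                conv = _META_FIELDS[key]
                try:
                    meta_kwargs[key] = conv(value.strip())
                except ValueError as e:
                    raise SpectrumFormatError(
                        f"bad metadata value for {key!r}: {value.strip()!r}"
                    ) from e
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise SpectrumFormatError(f"{path}: no data rows")
    header = body_lines[0]
    delim = ";" if header.count(";") > header.count(",") else ","
    cols = [c.strip() for c in header.split(delim)]
    if cols != _COLUMNS:
        missing = set(_COLUMNS) - set(cols)
        raise SpectrumFormatError(
            f"{path}: expected header {','.join(_COLUMNS)}, got {header!r}"
            + (f" (missing {sorted(missing)})" if missing else "")
        )
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(body_lines)), sep=delim,
            float_precision="round_trip",
        )
        arr = df[_COLUMNS].to_numpy(dtype=float)
    except (ValueError, TypeError) as e:
        raise SpectrumFormatError(f"{path}: non-numeric cell in data rows: {e}") from e
    f = arr[:, 0]
    uniq, counts = np.unique(f, return_counts=True)
    if np.any(counts > 1):
        dups = uniq[counts > 1].tolist()
        raise DuplicateFrequencyError(
            f"{path}: duplicated frequencies {dups} Hz"
        )
    if np.any(np.diff(f) > 0):
        warnings.warn(
            f"{path}: frequencies not in descending sweep order; re-sorting",
            UserWarning,
            stacklevel=2,
        )
    z = arr[:, 1] + 1j * arr[:, 2]
    return ImpedanceSpectrum(frequency=f, z=z, meta=SpectrumMeta(**meta_kwargs))


def write_dose_response(series: DoseResponseSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_dose_response(path, analyte: str = "") -> DoseResponseSeries:
    df = pd.read_csv(path)
    return DoseResponseSeries.from_frame(df, analyte=analyte)


def write_json_report(obj: Any, path, kind: str = "") -> None:
    """Serialize a result object (anything with to_dict, or a dict) to JSON."""
    d = obj.to_dict() if hasattr(obj, "to_dict") else dict(obj)
    payload = {"kind": kind, **d} if kind else d
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
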