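"""Reading and writing recordings, annotations and report tables.

All on-disk formats are plain text:

* recordings — one sample per line, optional ``# key=value`` header lines
  (``fs``, ``sequence``, ``orientation``, ``source``), or two columns
  ``time value`` from which the sampling rate is inferred;
* annotations — two integer columns ``start end``, 0-based half-open sample
  intervals;
* reports — one CSV per table plus a single ``report.json`` that round-trips
  all numbers exactly (floats are serialized with ``repr`` precision).

Interval convention: everywhere in this package intervals are 0-based,
half-open ``[start, end)`` sample indices.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "Recording",
    "AnnotationSet",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "write_report",
    "read_report",
]

#: significant digits used when writing samples; 17 guarantees exact float64
#: round-trip (the documented promise is >= 12).
_FLOAT_FMT = ".17g"


@dataclass
class Recording:
    """A single-channel sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in arbitrary units (units are carried as an opaque
        string in ``source`` if needed; z-scoring makes them moot).
    fs : float
        Sampling rate in Hz.
    label : str
        Sequence identifier (e.g. ``"FSE-like"``).
    orientation : str
        Slice-orientation identifier (``coronal``/``axial``/``sagittal``).
    source : str
        Free-form provenance string.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    orientation: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("a Recording needs a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("Recording samples must be finite")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got fs={self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def crop(self, seconds: float) -> "Recording":
        """Return the first ``seconds`` of the recording (at most the whole)."""
        if seconds <= 0:
            raise ValidationError("crop length must be positive")
        n = min(self.n, int(round(seconds * self.fs)))
        return replace(self, samples=self.samples[:n].copy())


@dataclass
class AnnotationSet:
    """Ordered, disjoint half-open sample intervals over a parent recording."""

    intervals: np.ndarray  # (n, 2) int array
    n_samples: int = 0  # extent of the parent recording, 0 = unchecked

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=int).reshape(-1, 2)
        self.intervals = iv
        bad = []
        for i, (a, b) in enumerate(iv):
            if a < 0 or b <= a:
                bad.append((i, "start<0 or end<=start"))
            elif self.n_samples and b > self.n_samples:
                bad.append((i, "end beyond recording"))
            elif i > 0 and a < iv[i - 1, 1]:
                bad.append((i, "overlaps or precedes previous interval"))
        if bad:
            detail = "; ".join(f"row {i}: {why}" for i, why in bad)
            raise ValidationError(f"invalid annotation intervals ({detail})")

    def __len__(self) -> int:
        return self.intervals.shape[0]


# -- recordings ---------------------------------------------------------------

_HEADER_RE = re.compile(r"#\s*(\w+)\s*=\s*(.*\S)\s*$")


def read_recording(path, fs_override: float | None = None) -> Recording:
    """Read a recording from delimited text.

    One-column files need the sampling rate from a ``# fs=<Hz>`` header or
    ``fs_override``; two-column files carry time (s) in the first column and
    the rate is inferred after verifying uniform sampling (relative deviation
    of sample intervals above 1e-6 is an error).
    """
    path = Path(path)
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _HEADER_RE.match(line)
                if m:
                    headers[m.group(1).lower()] = m.group(2)
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: not numeric: {line!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no data lines")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows) or ncol not in (1, 2):
        raise FormatError(f"{path}: expected a uniform 1- or 2-column layout")
    data = np.asarray(rows, dtype=float)

    if ncol == 2:
        t, x = data[:, 0], data[:, 1]
        if len(t) < 2:
            raise FormatError(f"{path}: need >= 2 rows to infer the sampling rate")
        dt = np.diff(t)
        dt0 = np.median(dt)
        if dt0 <= 0 or np.max(np.abs(dt - dt0)) / dt0 > 1e-6:
            raise FormatError(f"{path}: time column is not uniformly sampled")
        fs = fs_override if fs_override is not None else 1.0 / dt0
    else:
        x = data[:, 0]
        if fs_override is not None:
            fs = fs_override
        elif "fs" in headers:
            fs = float(headers["fs"])
        else:
            raise ConfigurationError(
                f"{path}: sampling rate missing (no '# fs=' header and no override)"
            )
    return Recording(
        samples=x,
        fs=fs,
        label=headers.get("sequence", ""),
        orientation=headers.get("orientation", ""),
        source=headers.get("source", str(path)),
    )


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as one sample per line with ``# key=value`` headers."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={format(rec.fs, _FLOAT_FMT)}\n")
        if rec.label:
            fh.write(f"# sequence={rec.label}\n")
        if rec.orientation:
            fh.write(f"# orientation={rec.orientation}\n")
        if rec.source:
            fh.write(f"# source={rec.source}\n")
        for v in rec.samples:
            fh.write(format(v, _FLOAT_FMT) + "\n")
    return path


# -- annotations --------------------------------------------------------------


def read_annotations(path, rec: Recording | None = None) -> AnnotationSet:
    """Read two-column integer ``start end`` intervals, validated against
    ``rec`` when given."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer bounds") from exc
            rows.append((a, b))
    iv = np.asarray(rows, dtype=int).reshape(-1, 2)
    return AnnotationSet(iv, n_samples=rec.n if rec is not None else 0)


def write_annotations(ann: AnnotationSet, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# start end (0-based half-open sample indices)\n")
        for a, b in ann.intervals:
            fh.write(f"{a} {b}\n")
    return path


# -- report tables ------------------------------------------------------------


def _table_to_jsonable(df: pd.DataFrame) -> dict:
    return {
        "index": [str(i) for i in df.index],
        "columns": [str(c) for c in df.columns],
        "data": df.to_numpy(dtype=float).tolist(),
    }


def _table_from_jsonable(obj: dict) -> pd.DataFrame:
    return pd.DataFrame(
        np.asarray(obj["data"], dtype=float),
        index=obj["index"],
        columns=obj["columns"],
    )


def write_report(tables: Mapping[str, pd.DataFrame], path) -> Path:
    """Write report tables to a directory: one ``<name>.csv`` each plus a
    combined ``report.json``.

    Missing cells are written as ``NA`` in the CSVs and ``NaN`` in the JSON;
    the JSON round-trips all floats exactly.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", na_rep="NA", float_format="%.17g")
    payload = {name: _table_to_jsonable(df) for name, df in tables.items()}
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir


def read_report(path) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`write_report` (reads ``report.json``)."""
    p = Path(path)
    if p.is_dir():
        p = p / "report.json"
    with open(p) as fh:
        payload = json.load(fh)
    return {name: _table_from_jsonable(obj) for name, obj in payload.items()}
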