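"""Readers and writers for the package's CSV / YAML / JSON artifacts.

File dialects (units at the boundary follow instrument conventions:
micrometres for PSD bin edges, nanometres for D50 series; everything
internal is nondimensional):

* PSD series CSV, header exactly ``time_min,d_lower_um,d_upper_um,volume_pct``;
  one row per (time, bin); times ascending, bins ascending and contiguous
  within each time.
* D50 series CSV, header ``time_min,d50_nm``.
* Assay CSV, header ``label,a0,ax``.
* Kernel parameters as a YAML mapping with exactly the keys
  ``K1, mu, K2, y1, y2, c, p`` -- unknown or missing keys are rejected so a
  typo cannot silently fall back to a default.
* Fit reports as JSON carrying the seed and configuration needed to
  reproduce the run.

All writes are atomic (written to a temporary file in the destination
directory, then renamed), and numbers are serialized with shortest
round-trip precision so read(write(x)) is bit-identical.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import yaml

from .exceptions import IOFormatError
from .assay import AssaySample
from .grid_psd import PSDRecord
from .kernels import PARAM_NAMES, PBMParams

__all__ = [
    "read_psd_series",
    "write_psd_series",
    "read_d50_series",
    "write_d50_series",
    "read_params",
    "write_params",
    "read_assay_csv",
    "write_table_csv",
    "write_fit_report",
]

PSD_HEADER = "time_min,d_lower_um,d_upper_um,volume_pct"
D50_HEADER = "time_min,d50_nm"
ASSAY_HEADER = "label,a0,ax"


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _parse_float(token: str, line_no: int, path) -> float:
    try:
        return float(token)
    except ValueError:
        raise IOFormatError(f"{path}:{line_no}: not a number: {token!r}") from None


def read_psd_series(path) -> list[PSDRecord]:
    """Read a PSD time series CSV; validates dialect and PSD invariants."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise IOFormatError(f"{path}: empty file")
    if lines[0].strip() != PSD_HEADER:
        raise IOFormatError(
            f"{path}: header mismatch: got {lines[0].strip()!r}, "
            f"expected {PSD_HEADER!r}"
        )
    rows: list[tuple[float, float, float, float]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise IOFormatError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
        rows.append(tuple(_parse_float(p, ln, path) for p in parts))
    if not rows:
        raise IOFormatError(f"{path}: no data rows")
    records: list[PSDRecord] = []
    i = 0
    prev_time = -np.inf
    while i < len(rows):
        t = rows[i][0]
        if t <= prev_time:
            raise IOFormatError(f"{path}: times not strictly ascending at t={t}")
        prev_time = t
        block = []
        while i < len(rows) and rows[i][0] == t:
            block.append(rows[i])
            i += 1
        edges = [block[0][1]]
        vol = []
        for _, lo, hi, v in block:
            if lo != edges[-1]:
                raise IOFormatError(
                    f"{path}: bins at t={t} are not ascending/contiguous "
                    f"(gap at d_lower={lo})"
                )
            if hi <= lo:
                raise IOFormatError(f"{path}: empty bin [{lo}, {hi}] at t={t}")
            edges.append(hi)
            vol.append(v)
        try:
            records.append(
                PSDRecord(time=t, d_edges=np.array(edges), vol_pct=np.array(vol))
            )
        except Exception as exc:
            raise IOFormatError(f"{path}: invalid PSD at t={t}: {exc}") from exc
    return records


def write_psd_series(path, records: list[PSDRecord]) -> None:
    lines = [PSD_HEADER]
    for rec in records:
        for lo, hi, v in zip(rec.d_edges[:-1], rec.d_edges[1:], rec.vol_pct):
            lines.append(f"{rec.time!r},{float(lo)!r},{float(hi)!r},{float(v)!r}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_d50_series(path):
    """Read a D50(t) CSV; returns (times_min, d50_nm) arrays."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != D50_HEADER:
        raise IOFormatError(f"{path}: expected header {D50_HEADER!r}")
    t, d = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise IOFormatError(f"{path}:{ln}: expected 2 columns")
        t.append(_parse_float(parts[0], ln, path))
        d.append(_parse_float(parts[1], ln, path))
    if not t:
        raise IOFormatError(f"{path}: no data rows")
    return np.array(t), np.array(d)


def write_d50_series(path, times, d50s) -> None:
    lines = [D50_HEADER]
    for t, d in zip(times, d50s):
        lines.append(f"{float(t)!r},{float(d)!r}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_params(path) -> PBMParams:
    """Read kernel parameters from YAML; keys must be exactly the seven."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise IOFormatError(f"{path}: expected a YAML mapping of parameters")
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise IOFormatError(f"{path}: unknown parameter keys: {sorted(unknown)}")
    missing = set(PARAM_NAMES) - set(data)
    if missing:
        raise IOFormatError(f"{path}: missing parameter keys: {sorted(missing)}")
    try:
        return PBMParams(**{k: float(data[k]) for k in PARAM_NAMES})
    except Exception as exc:
        raise IOFormatError(f"{path}: invalid parameters: {exc}") from exc


def write_params(path, params: PBMParams) -> None:
    text = "\n".join(f"{name}: {getattr(params, name)!r}" for name in PARAM_NAMES)
    _atomic_write_text(path, text + "\n")


def read_assay_csv(path) -> list[AssaySample]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != ASSAY_HEADER:
        raise IOFormatError(f"{path}: expected header {ASSAY_HEADER!r}")
    samples = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise IOFormatError(f"{path}:{ln}: expected 3 columns")
        try:
            samples.append(
                AssaySample(
                    label=parts[0],
                    a0=_parse_float(parts[1], ln, path),
                    ax=_parse_float(parts[2], ln, path),
                )
            )
        except IOFormatError:
            raise
        except Exception as exc:
            raise IOFormatError(f"{path}:{ln}: {exc}") from exc
    if not samples:
        raise IOFormatError(f"{path}: no data rows")
    return samples


def write_table_csv(path, frame) -> None:
    """Write a pandas DataFrame as CSV atomically."""
    _atomic_write_text(path, frame.to_csv(index=False))


def write_fit_report(path, report: dict) -> None:
    """Write a JSON fit report.

    Schema (all keys required): ``tool`` (str), ``version`` (str), ``seed``
    (int or null), ``config`` (object with everything needed to reproduce),
    ``results`` (object with the fitted quantities).
    """
    required = {"tool", "version", "seed", "config", "results"}
    missing = required - set(report)
    if missing:
        raise IOFormatError(f"fit report missing keys: {sorted(missing)}")

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    _atomic_write_text(path, json.dumps(report, indent=2, default=default) + "\n")
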