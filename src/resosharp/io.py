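"""Trace file ingestion and serialization.

Two dialects are supported: two-column CSV (frequency, return loss in
dB) and Touchstone v1 one-port ``.s1p`` files, whose S11 magnitude is
converted to return loss on read.  CSV frequency units are never guessed
from magnitudes — the caller must say Hz or GHz.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from .errors import InvalidInputError, ParseError
from .signalmodel import ReturnLossTrace, rl_from_gamma

__all__ = ["read_trace", "write_trace"]

log = logging.getLogger(__name__)

_UNIT_SCALE = {"hz": 1.0, "khz": 1e3, "mhz": 1e6, "ghz": 1e9}


def read_trace(
    path,
    dialect: str | None = None,
    unit: str | None = None,
) -> ReturnLossTrace:
    """Read a return-loss trace from ``path``.

    ``dialect`` is ``"csv"`` or ``"touchstone_s1p"``; if omitted it is
    inferred from the file extension (``.s1p`` → Touchstone, anything
    else → CSV).  For CSV, ``unit`` ("hz" or "ghz") is required; for
    Touchstone the unit comes from the option line.
    """
    path = Path(path)
    if dialect is None:
        dialect = "touchstone_s1p" if path.suffix.lower() == ".s1p" else "csv"
    if dialect == "csv":
        return _read_csv(path, unit)
    if dialect == "touchstone_s1p":
        return _read_touchstone(path)
    raise InvalidInputError(f"unknown dialect {dialect!r}")


def _parse_floats(fields: list[str], line_no: int, expected: int) -> list[float]:
    if len(fields) < expected:
        raise ParseError(
            f"expected {expected} numeric columns, found {len(fields)}", line_no
        )
    try:
        return [float(x) for x in fields[:expected]]
    except ValueError as exc:
        raise ParseError(f"non-numeric value: {exc}", line_no) from None


def _read_csv(path: Path, unit: str | None) -> ReturnLossTrace:
    if unit is None:
        raise InvalidInputError(
            "CSV traces need an explicit frequency unit ('hz' or 'ghz')"
        )
    unit = unit.lower()
    if unit not in _UNIT_SCALE:
        raise InvalidInputError(f"unknown frequency unit {unit!r}")
    scale = _UNIT_SCALE[unit]

    freqs: list[float] = []
    vals: list[float] = []
    header_allowed = True
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace(",", " ").split() if f]
            if header_allowed and not _is_number(fields[0]):
                header_allowed = False  # single header row tolerated
                continue
            header_allowed = False
            f, v = _parse_floats(fields, line_no, 2)
            freqs.append(f * scale)
            vals.append(v)
    if len(freqs) < 3:
        raise ParseError(f"{path} holds fewer than 3 data rows")
    freq_arr = np.asarray(freqs)
    if not np.all(np.diff(freq_arr) > 0):
        raise InvalidInputError(f"{path}: frequencies are not strictly increasing")
    return ReturnLossTrace(frequencies=freq_arr, values=np.asarray(vals))


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _read_touchstone(path: Path) -> ReturnLossTrace:
    """Touchstone v1 one-port reader (formats RI, MA, DB)."""
    unit_scale = 1e9
    fmt = "ma"
    freqs: list[float] = []
    mags: list[float] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].lower().split()
                for i, tok in enumerate(tokens):
                    if tok in _UNIT_SCALE:
                        unit_scale = _UNIT_SCALE[tok]
                    elif tok in ("ri", "ma", "db"):
                        fmt = tok
                    elif tok == "s":
                        pass
                    elif tok == "r":
                        if i + 1 >= len(tokens) or not _is_number(tokens[i + 1]):
                            raise ParseError("malformed reference impedance", line_no)
                continue
            f, a, b = _parse_floats(line.split(), line_no, 3)
            if fmt == "ri":
                mag = math.hypot(a, b)
            elif fmt == "ma":
                mag = a
            else:  # db
                mag = 10.0 ** (a / 20.0)
            freqs.append(f * unit_scale)
            mags.append(mag)
    if len(freqs) < 3:
        raise ParseError(f"{path} holds fewer than 3 data rows")
    freq_arr = np.asarray(freqs)
    if not np.all(np.diff(freq_arr) > 0):
        raise InvalidInputError(f"{path}: frequencies are not strictly increasing")
    mag_arr = np.asarray(mags)
    n_over = int(np.count_nonzero(mag_arr > 1.0))
    if n_over:
        log.warning(
            "%s: clamped %d |S11| samples above 1 (calibration noise?)",
            path,
            n_over,
        )
        mag_arr = np.minimum(mag_arr, 1.0)
    return rl_from_gamma(mag_arr, freq_arr)


def write_trace(path, trace: ReturnLossTrace, unit: str = "hz") -> None:
    """Write a trace as two-column CSV; floats round-trip bit-exactly."""
    unit = unit.lower()
    if unit not in _UNIT_SCALE:
        raise InvalidInputError(f"unknown frequency unit {unit!r}")
    scale = _UNIT_SCALE[unit]
    lines = [f"frequency_{unit},return_loss_db"]
    for f, v in zip(trace.frequencies, trace.values):
        lines.append(f"{float(f / scale)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
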