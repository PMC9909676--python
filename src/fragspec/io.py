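"""Spectrum I/O: NIST-style MSP text records and a JSON dialect.

MSP records look like::

    Name: ethanol
    Formula: C2H6O
    MW: 46
    Num Peaks: 3
    31 100; 45 52; 46 22;

Header fields other than ``Num Peaks`` are carried through untouched as
metadata, so round-trips are lossless.  The JSON dialect stores the
resolution explicitly; MSP has no such field, so the caller states the
resolution when reading.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np

from .spectrum import Spectrum, bin_peaks


class MSPParseError(ValueError):
    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


_PEAK_RE = re.compile(r"([0-9.eE+-]+)[\s:]+([0-9.eE+-]+)")


def read_msp(
    path: Union[str, Path], resolution: float = 1.0
) -> List[Tuple[Dict[str, str], Spectrum]]:
    """Read all records from an MSP file.

    Peaks are binned at the stated ``resolution`` (peaks written by
    :func:`write_msp` sit exactly on bin centers, so the round-trip is
    lossless).  Returns ``(metadata, Spectrum)`` pairs in file order.
    """
    records: List[Tuple[Dict[str, str], Spectrum]] = []
    meta: Dict[str, str] = {}
    peaks: List[Tuple[float, float]] = []
    expected: int = -1
    start_line = 0

    def flush(line_no: int):
        nonlocal meta, peaks, expected
        if not meta and not peaks:
            return
        if expected < 0:
            raise MSPParseError("record is missing a 'Num Peaks' field", start_line)
        if len(peaks) != expected:
            raise MSPParseError(
                f"expected {expected} peaks, found {len(peaks)}", line_no
            )
        records.append((meta, bin_peaks(peaks, resolution)))
        meta, peaks, expected = {}, [], -1

    lines = Path(path).read_text().splitlines()
    for no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            flush(no)
            continue
        if expected >= 0 and len(peaks) < expected:
            found = _PEAK_RE.findall(line)
            if not found:
                raise MSPParseError(f"expected peak data, got {raw!r}", no)
            for m, i in found:
                peaks.append((float(m), float(i)))
            continue
        if ":" in line:
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if not meta and not peaks:
                start_line = no
            if key.lower() == "num peaks":
                try:
                    expected = int(value)
                except ValueError:
                    raise MSPParseError(f"bad Num Peaks value {value!r}", no) from None
            else:
                meta[key] = value
        else:
            raise MSPParseError(f"unexpected line {raw!r}", no)
    flush(len(lines))
    return records


def write_msp(
    records: Iterable[Tuple[Dict[str, str], Spectrum]], path: Union[str, Path]
) -> None:
    """Write ``(metadata, Spectrum)`` records as MSP text."""
    out = []
    for meta, spec in records:
        for key, value in meta.items():
            out.append(f"{key}: {value}")
        out.append(f"Num Peaks: {len(spec)}")
        pairs = [
            f"{mz:.6f} {inten:.8g};"
            for mz, inten in zip(spec.mz.tolist(), spec.intensity.tolist())
        ]
        for i in range(0, len(pairs), 5):
            out.append(" ".join(pairs[i : i + 5]))
        out.append("")
    Path(path).write_text("\n".join(out))


def spectrum_to_json_dict(meta: Dict[str, str], spec: Spectrum) -> dict:
    return {
        "metadata": dict(meta),
        "resolution": spec.resolution,
        "norm": spec.norm,
        "peaks": [
            [float(mz), float(inten)]
            for mz, inten in zip(spec.mz.tolist(), spec.intensity.tolist())
        ],
    }


def write_json(
    records: Iterable[Tuple[Dict[str, str], Spectrum]], path: Union[str, Path]
) -> None:
    payload = [spectrum_to_json_dict(m, s) for m, s in records]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_json(path: Union[str, Path]) -> List[Tuple[Dict[str, str], Spectrum]]:
    payload = json.loads(Path(path).read_text())
    out = []
    for rec in payload:
        res = float(rec["resolution"])
        spec = bin_peaks([(m, i) for m, i in rec["peaks"]], res)
        out.append((rec.get("metadata", {}), spec))
    return out
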