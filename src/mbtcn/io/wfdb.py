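"""Minimal WFDB (PhysioNet waveform database) reader/writer.

Supports the subset of the format family this package needs: single- or
multi-channel format-16 signal files (little-endian int16 with gain/baseline
scaling), their ``.hea`` headers, and MIT-format ``.atr`` beat annotations
(10-bit time increments with 6-bit type codes, SKIP escapes for long
intervals, NUM/SUB/CHN/AUX modifier words tolerated on read).

This is a clean-room implementation of the documented on-disk layout; it is
exercised by round-trip tests against the synthetic record generator.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = [
    "read_header", "read_signal", "read_annotations",
    "write_record", "BEAT_SYMBOLS", "SYMBOL_TO_CODE", "CODE_TO_SYMBOL",
]

# MIT annotation type codes for the beat symbols used by the AAMI grouping,
# plus the non-beat codes a reader must recognize and skip.
SYMBOL_TO_CODE: dict[str, int] = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16,
    "s": 18, "T": 19, '"': 22, "+": 28, "?": 30, "!": 31, "e": 34,
    "n": 35, "x": 37, "f": 38, "r": 41,
}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}

#: The 15 beat-type symbols that map onto the five AAMI classes.
BEAT_SYMBOLS = frozenset("NLRejAaJSVEF/fQ")

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_header(path: Path) -> dict:
    """Parse a ``.hea`` file; returns record line fields and per-signal specs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB header: {path}")
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    name, n_sig = rec[0], int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        f = ln.split()
        gain_field = f[2].split("/")[0]
        if "(" in gain_field:
            gain, baseline = gain_field.rstrip(")").split("(")
        else:
            gain, baseline = gain_field, "0"
        signals.append({
            "file_name": f[0],
            "format": int(f[1].split("x")[0]),
            "gain": float(gain) or 200.0,
            "baseline": int(baseline),
        })
    return {"record_name": name, "n_sig": n_sig, "fs": fs,
            "n_samples": n_samples, "signals": signals}


def read_signal(header_path: Path, channel: int = 0) -> tuple[np.ndarray, float]:
    """Read one channel in physical units (mV); returns (signal, fs)."""
    header_path = Path(header_path)
    hdr = read_header(header_path)
    if not 0 <= channel < hdr["n_sig"]:
        raise ValueError(
            f"channel {channel} out of range for {hdr['n_sig']}-channel record")
    spec = hdr["signals"][channel]
    if spec["format"] != 16:
        raise NotImplementedError(
            f"signal format {spec['format']} not supported (only format 16)")
    dat = header_path.with_name(spec["file_name"])
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    n_sig = hdr["n_sig"]
    raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)
    adc = raw[:, channel].astype(np.float64)
    return (adc - spec["baseline"]) / spec["gain"], hdr["fs"]


def read_annotations(path: Path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file -> [(sample_index, symbol), ...]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB annotation file: {path}")
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        field = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi = struct.unpack_from("<H", data, i)[0]
            lo = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            t += (hi << 16) | lo
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += field + (field & 1)
        else:
            t += field
            out.append((t, CODE_TO_SYMBOL.get(code, "?")))
    return out


def write_record(directory: Path, record_name: str, signal: np.ndarray,
                 fs: float, annotations: list[tuple[int, str]],
                 gain: float = 200.0) -> Path:
    """Write a single-channel format-16 record triple; returns the header path.

    ``signal`` is in mV; samples are quantized at ``gain`` ADU/mV and clipped
    to the int16 range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signal = np.asarray(signal, dtype=np.float64)
    adc = np.clip(np.rint(signal * gain), -32768, 32767).astype("<i2")

    dat_name = f"{record_name}.dat"
    (directory / dat_name).write_bytes(adc.tobytes())

    hea = directory / f"{record_name}.hea"
    first = int(adc[0]) if adc.size else 0
    checksum = int(adc.astype(np.int64).sum() % 65536)
    hea.write_text(
        f"{record_name} 1 {fs:g} {len(adc)}\n"
        f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 ECG\n"
    )

    words = bytearray()
    prev = 0
    for sample, symbol in annotations:
        code = SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {symbol!r}")
        delta = int(sample) - prev
        if delta < 0:
            raise ValueError("annotation sample indices must be non-decreasing")
        if delta > 1023:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<H", (delta >> 16) & 0xFFFF)
            words += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        words += struct.pack("<H", (code << 10) | delta)
        prev = int(sample)
    words += struct.pack("<H", 0)
    (directory / f"{record_name}.atr").write_bytes(bytes(words))
    return hea
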