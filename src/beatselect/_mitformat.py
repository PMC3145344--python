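"""Low-level codecs for the WFDB-style dialect.

Implements the subset of the classic header/signal/annotation layout needed
for two-lead format-212 records: a plain-text ``.hea`` header, a packed
12-bit ``.dat`` signal file, and MIT-format annotation streams (used both
for beat files and for fiducial-point files).

Pseudo-annotation handling: SKIP carries long time intervals; NUM and CHN
set the num/chan fields for subsequent annotations; SUB and AUX are parsed
and ignored.  Modifier words are emitted before the annotation they first
affect and persist, which is sufficient to read plain beat streams and is
exactly round-trippable within this package.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

# annotation pseudo-codes
SKIP = 59
NUM = 60
SUB = 61
CHN = 62
AUX = 63

_MAX_DELTA = 1023  # 10-bit interval field


class ParseError(ValueError):
    """Raised when a header or annotation stream cannot be decoded."""


@dataclass
class AnnEntry:
    """One decoded annotation: absolute sample index, code, num and chan."""

    sample: int
    code: int
    num: int = 0
    chan: int = 0


def _word(code: int, interval: int) -> bytes:
    return struct.pack("<H", ((code & 0x3F) << 10) | (interval & 0x3FF))


def write_annotations(path: Path | str, entries: list[AnnEntry]) -> None:
    entries = sorted(entries, key=lambda e: (e.sample, e.chan, e.num, e.code))
    buf = bytearray()
    t = 0
    cur_num = 0
    cur_chan = 0
    for e in entries:
        if e.sample < 0:
            raise ValueError("annotation sample indices must be nonnegative")
        if e.chan != cur_chan:
            buf += _word(CHN, e.chan)
            cur_chan = e.chan
        if e.num != cur_num:
            buf += _word(NUM, e.num)
            cur_num = e.num
        delta = e.sample - t
        if delta > _MAX_DELTA:
            buf += _word(SKIP, 0)
            buf += struct.pack("<hH", delta >> 16, delta & 0xFFFF)
            buf += _word(e.code, 0)
        else:
            buf += _word(e.code, delta)
        t = e.sample
    buf += _word(0, 0)
    Path(path).write_bytes(bytes(buf))


def read_annotations(path: Path | str) -> list[AnnEntry]:
    raw = Path(path).read_bytes()
    if len(raw) % 2:
        raise ParseError(f"{path}: odd byte count in annotation file")
    words = np.frombuffer(raw, dtype="<u2")
    entries: list[AnnEntry] = []
    t = 0
    num = 0
    chan = 0
    skip = 0
    i = 0
    n = len(words)
    while i < n:
        w = int(words[i])
        if w == 0:
            break
        code = w >> 10
        interval = w & 0x3FF
        if code == SKIP and interval == 0:
            if i + 2 >= n:
                raise ParseError(f"{path}: truncated SKIP at word {i}")
            hi = int(np.int16(words[i + 1]))
            lo = int(words[i + 2])
            skip = (hi << 16) | lo
            i += 3
            continue
        if code == NUM:
            num = interval
        elif code == CHN:
            chan = interval
        elif code == SUB:
            pass
        elif code == AUX:
            i += (interval + 1) // 2  # skip padded aux bytes
        else:
            t += interval + skip
            skip = 0
            entries.append(AnnEntry(sample=t, code=code, num=num, chan=chan))
        i += 1
    return entries


def encode_212(digital: np.ndarray) -> bytes:
    """Pack a (2, n) int array of 12-bit samples into format-212 bytes."""
    if digital.ndim != 2 or digital.shape[0] != 2:
        raise ValueError("encode_212 expects a (2, n) array")
    s = np.empty(digital.shape[1] * 2, dtype=np.int64)
    s[0::2] = digital[0]
    s[1::2] = digital[1]
    if np.any(s > 2047) or np.any(s < -2048):
        raise ValueError("sample out of 12-bit range for format 212")
    u = (s & 0xFFF).astype(np.uint16)
    a, b = u[0::2], u[1::2]
    out = np.empty(3 * len(a), dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((b >> 8) << 4) | (a >> 8)
    out[2::3] = b & 0xFF
    return out.tobytes()


def decode_212(raw: bytes, n_per_sig: int) -> np.ndarray:
    """Unpack format-212 bytes into a (2, n_per_sig) int array."""
    need = 3 * n_per_sig  # two interleaved signals -> n_per_sig byte triplets
    if len(raw) < need:
        raise ParseError("signal file shorter than header declares")
    arr = np.frombuffer(raw[:need], dtype=np.uint8)
    b0 = arr[0::3].astype(np.uint16)
    b1 = arr[1::3].astype(np.uint16)
    b2 = arr[2::3].astype(np.uint16)
    a = ((b1 & 0x0F) << 8) | b0
    b = ((b1 >> 4) << 8) | b2
    s = np.empty(2 * n_per_sig, dtype=np.int64)
    s[0::2] = a
    s[1::2] = b
    s[s >= 2048] -= 4096
    return np.stack([s[0::2], s[1::2]])


def write_header(
    path: Path | str,
    record_id: str,
    fs: float,
    n_samples: int,
    lead_names: tuple[str, str],
    gain: float,
    adc_zero: int = 0,
) -> None:
    fs_txt = f"{fs:g}"
    lines = [f"{record_id} 2 {fs_txt} {n_samples}"]
    for name in lead_names:
        lines.append(f"{record_id}.dat 212 {gain:g} 12 {adc_zero} 0 0 0 {name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_header(path: Path | str) -> dict:
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path}: empty header (line 1)")
    top = lines[0].split()
    if len(top) < 4:
        raise ParseError(f"{path}: malformed record line (line 1)")
    record_id = top[0].split("/")[0]
    try:
        n_sig = int(top[1])
        fs = float(top[2].split("/")[0])
        n_samples = int(top[3])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed record line (line 1): {exc}") from exc
    signals = []
    for offset, ln in enumerate(lines[1 : 1 + n_sig], start=2):
        tok = ln.split()
        if len(tok) < 3:
            raise ParseError(f"{path}: malformed signal line (line {offset})")
        fmt_txt = tok[1]
        fmt = int("".join(ch for ch in fmt_txt if ch.isdigit()) or "0")
        gain_txt = tok[2]
        adc_zero = 0
        if "(" in gain_txt:
            base, rest = gain_txt.split("(", 1)
            adc_zero = int(rest.split(")")[0])
            gain_txt = base + rest.split(")", 1)[1]
        gain_txt = gain_txt.split("/")[0]
        try:
            gain = float(gain_txt)
        except ValueError as exc:
            raise ParseError(f"{path}: bad gain (line {offset}): {exc}") from exc
        name = tok[-1] if len(tok) > 3 else f"sig{offset - 2}"
        signals.append(
            {"file": tok[0], "fmt": fmt, "gain": gain or 200.0,
             "adc_zero": adc_zero, "name": name}
        )
    if len(signals) != n_sig:
        raise ParseError(f"{path}: header declares {n_sig} signals, found {len(signals)}")
    return {
        "record_id": record_id,
        "n_sig": n_sig,
        "fs": fs,
        "n_samples": n_samples,
        "signals": signals,
    }
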