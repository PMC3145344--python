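"""Record, beat-annotation and fiducial-point I/O.

Two on-disk dialects are supported:

* ``wfdb`` — the classic header/signal/annotation layout for two-lead
  format-212 records: ``<rec>.hea``, ``<rec>.dat``, ``<rec>.atr`` (beats)
  and ``<rec>.pu`` (fiducial points).  Fiducials use the ecgpuwave
  vocabulary — ``(`` / ``)`` with num 0/1/2 for P/QRS/T onsets and offsets,
  ``p`` and ``t`` for P and T peaks, a beat mark for the R spike — plus a
  documented dialect extension: Q and S peaks are carried with the MEASURE
  code (23) and num 1/2.  The chan field holds the lead (0/1).
  Amplitudes are quantized at the header gain (default 200 adu/mV), so a
  write/read cycle is exact only for gain-representable amplitudes; a
  second cycle is always the identity.
* ``csv`` — a plain-text directory layout: ``signals.csv`` (sample plus one
  mV column per lead, with record id / sampling rate on a leading comment
  line), ``beats.csv`` (sample, symbol, provenance) and ``fiducials.csv``
  (beat_idx, lead, point, sample-or-ABSENT).  Lossless round trip.

Sample indices are 0-based throughout; wave windows are half-open
``[on, off)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _mitformat as mf
from ._mitformat import AnnEntry, ParseError

__all__ = [
    "ECGRecord", "BeatAnnotationSet", "FiducialMap",
    "DialectError", "ParseError",
    "POINT_NAMES", "EXCLUDED", "AAMI_CLASSES", "map_aami",
    "read_record", "write_record", "read_beats", "write_beats",
    "read_fiducials", "write_fiducials",
]

DIALECTS = ("wfdb", "csv")

#: Canonical fiducial points, in their physiological order within a beat.
POINT_NAMES = (
    "P_on", "P_peak", "P_off",
    "QRS_on", "Q", "R", "S", "QRS_off",
    "T_on", "T_peak", "T_off",
)

#: AAMI label assigned to beat types outside the four classes of interest
#: (paced, unclassifiable, unknown codes).  Such beats are kept through
#: annotation handling and only dropped at feature-matrix assembly.
EXCLUDED = "excluded"
AAMI_CLASSES = ("N", "S", "V", "F")

# MIT-BIH beat symbol -> AAMI class (four groups; everything else excluded).
_AAMI_OF_SYMBOL = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": EXCLUDED, "f": EXCLUDED, "Q": EXCLUDED,
}

# beat symbol <-> MIT annotation code
_SYMBOL_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "e": 34, "f": 38,
}
_CODE_SYMBOL = {v: k for k, v in _SYMBOL_CODE.items()}

# fiducial point -> (annotation code, num); chan carries the lead.
_FID_CODE = {
    "P_on": (39, 0), "P_peak": (24, 0), "P_off": (40, 0),
    "QRS_on": (39, 1), "Q": (23, 1), "R": (1, 0), "S": (23, 2),
    "QRS_off": (40, 1),
    "T_on": (39, 2), "T_peak": (27, 0), "T_off": (40, 2),
}
_CODE_FID = {v: k for k, v in _FID_CODE.items()}


class DialectError(ValueError):
    """A file does not satisfy the contract of the requested dialect."""


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


@dataclass
class ECGRecord:
    """A two-lead ECG record: synchronized signals in millivolts."""

    record_id: str
    fs: float
    lead_signals: np.ndarray  # shape (2, n_samples), mV
    lead_names: tuple[str, str] = ("lead1", "lead2")

    def __post_init__(self) -> None:
        self.lead_signals = np.asarray(self.lead_signals, dtype=float)
        if self.lead_signals.ndim != 2 or self.lead_signals.shape[0] != 2:
            raise DialectError(
                f"record {self.record_id!r}: exactly 2 leads required, "
                f"got shape {self.lead_signals.shape}"
            )
        if self.lead_signals.shape[1] == 0:
            raise ValueError(f"record {self.record_id!r}: empty signals")
        if not self.fs > 0:
            raise ValueError(f"record {self.record_id!r}: fs must be positive")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != 2:
            raise DialectError("exactly 2 lead names required")

    @property
    def n_samples(self) -> int:
        return self.lead_signals.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ECGRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.fs == other.fs
            and self.lead_names == other.lead_names
            and np.array_equal(self.lead_signals, other.lead_signals)
        )


def map_aami(symbols) -> np.ndarray:
    """Map raw MIT-BIH beat symbols to AAMI labels (N/S/V/F/excluded).

    Total: the output always has one label per input symbol.  Codes outside
    the four AAMI groups — paced ('/'), paced fusion ('f'), unclassifiable
    ('Q') — and unknown codes map to :data:`EXCLUDED`; unknown codes
    additionally raise a warning, never a silent drop.
    """
    symbols = list(symbols)
    unknown = sorted({s for s in symbols if s not in _AAMI_OF_SYMBOL})
    if unknown:
        warnings.warn(
            f"unknown beat symbols mapped to {EXCLUDED!r}: {unknown}",
            stacklevel=2,
        )
    return np.array([_AAMI_OF_SYMBOL.get(s, EXCLUDED) for s in symbols], dtype=object)


@dataclass
class BeatAnnotationSet:
    """R-spike sample indices with raw symbols and AAMI labels."""

    r_samples: np.ndarray
    symbols: np.ndarray
    aami_labels: np.ndarray
    provenance: str  # "reference" | "detected"

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=np.int64)
        self.symbols = np.asarray(self.symbols, dtype=object)
        self.aami_labels = np.asarray(self.aami_labels, dtype=object)
        if not (len(self.r_samples) == len(self.symbols) == len(self.aami_labels)):
            raise ValueError("r_samples, symbols and aami_labels must align")
        if len(self.r_samples) > 1 and np.any(np.diff(self.r_samples) <= 0):
            raise ValueError("r_samples must be strictly increasing")
        if self.provenance not in ("reference", "detected"):
            raise ValueError(f"bad provenance {self.provenance!r}")

    @classmethod
    def from_symbols(cls, r_samples, symbols, provenance: str) -> "BeatAnnotationSet":
        return cls(np.asarray(r_samples), np.asarray(symbols, dtype=object),
                   map_aami(symbols), provenance)

    def __len__(self) -> int:
        return len(self.r_samples)

    def check_within(self, n_samples: int) -> None:
        if len(self.r_samples) and (
            self.r_samples[0] < 0 or self.r_samples[-1] >= n_samples
        ):
            raise ValueError("beat sample index outside record")


class FiducialMap:
    """Per-beat, per-lead fiducial sample indices with explicit absence.

    Internally a float array with NaN marking ABSENT; the public accessors
    return ``int`` or ``None`` so absence is never a usable index.
    """

    def __init__(self, n_beats: int, n_leads: int = 2):
        self._arr = np.full((n_beats, n_leads, len(POINT_NAMES)), np.nan)
        self.n_unassigned = 0  # marks that could not be attached on read

    @property
    def n_beats(self) -> int:
        return self._arr.shape[0]

    @property
    def n_leads(self) -> int:
        return self._arr.shape[1]

    def set(self, beat: int, lead: int, point: str, sample: int | None) -> None:
        j = POINT_NAMES.index(point)
        self._arr[beat, lead, j] = np.nan if sample is None else float(sample)

    def get(self, beat: int, lead: int, point: str) -> int | None:
        v = self._arr[beat, lead, POINT_NAMES.index(point)]
        return None if np.isnan(v) else int(v)

    def row(self, beat: int, lead: int) -> dict[str, int | None]:
        vals = self._arr[beat, lead]
        return {
            p: (None if np.isnan(v) else int(v))
            for p, v in zip(POINT_NAMES, vals)
        }

    def n_absent(self) -> int:
        return int(np.isnan(self._arr).sum())

    def subset(self, beat_indices) -> "FiducialMap":
        out = FiducialMap(len(beat_indices), self.n_leads)
        out._arr = self._arr[np.asarray(beat_indices)].copy()
        return out

    def enforce_order(self) -> int:
        """Drop points that violate the physiological order; return count."""
        dropped = 0
        for b in range(self.n_beats):
            for ld in range(self.n_leads):
                last = -np.inf
                for j in range(len(POINT_NAMES)):
                    v = self._arr[b, ld, j]
                    if np.isnan(v):
                        continue
                    if v < last:
                        self._arr[b, ld, j] = np.nan
                        dropped += 1
                    else:
                        last = v
        return dropped

    def to_frame(self) -> pd.DataFrame:
        frames = {}
        for ld in range(self.n_leads):
            for j, p in enumerate(POINT_NAMES):
                frames[(f"lead{ld + 1}", p)] = pd.array(
                    [None if np.isnan(v) else int(v) for v in self._arr[:, ld, j]],
                    dtype="Int64",
                )
        return pd.DataFrame(frames)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FiducialMap):
            return NotImplemented
        a, b = self._arr, other._arr
        return a.shape == b.shape and bool(
            np.all((np.isnan(a) & np.isnan(b)) | (a == b))
        )


# ---------------------------------------------------------------------------
# records


def _csv_dir(path: Path) -> Path:
    path = Path(path)
    return path.parent if path.suffix == ".csv" else path


def _wfdb_stem(path: Path) -> Path:
    path = Path(path)
    return path.with_suffix("") if path.suffix else path


def read_record(path, dialect: str) -> ECGRecord:
    """Read a two-lead record; amplitudes returned in millivolts."""
    _check_dialect(dialect)
    if dialect == "csv":
        f = _csv_dir(path) / "signals.csv"
        if not f.exists():
            raise FileNotFoundError(f)
        with open(f) as fh:
            first = fh.readline()
        if not first.startswith("#"):
            raise ParseError(f"{f}: missing metadata comment line (line 1)")
        meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
        try:
            fs = float(meta["fs"])
            record_id = meta["record_id"]
            lead_names = tuple(meta["leads"].split(","))
        except KeyError as exc:
            raise ParseError(f"{f}: metadata line lacks {exc} (line 1)") from exc
        df = pd.read_csv(f, skiprows=1, float_precision="round_trip")
        sig_cols = [c for c in df.columns if c != "sample"]
        if len(sig_cols) != 2:
            raise DialectError(
                f"{f}: expected 2 signal columns, found {len(sig_cols)}"
            )
        return ECGRecord(record_id, fs, df[sig_cols].to_numpy().T, lead_names)
    stem = _wfdb_stem(path)
    hea = stem.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    hdr = mf.read_header(hea)
    if hdr["n_sig"] != 2:
        raise DialectError(f"{hea}: expected 2 signals, header declares {hdr['n_sig']}")
    for s in hdr["signals"]:
        if s["fmt"] != 212:
            raise DialectError(f"{hea}: unsupported signal format {s['fmt']}")
    raw = (stem.parent / hdr["signals"][0]["file"]).read_bytes()
    digital = mf.decode_212(raw, hdr["n_samples"])
    gains = np.array([s["gain"] for s in hdr["signals"]])[:, None]
    zeros = np.array([s["adc_zero"] for s in hdr["signals"]])[:, None]
    mv = (digital - zeros) / gains
    names = tuple(s["name"] for s in hdr["signals"])
    return ECGRecord(hdr["record_id"], hdr["fs"], mv, names)


def write_record(rec: ECGRecord, path, dialect: str, gain: float = 200.0) -> None:
    _check_dialect(dialect)
    if dialect == "csv":
        d = _csv_dir(path)
        d.mkdir(parents=True, exist_ok=True)
        f = d / "signals.csv"
        df = pd.DataFrame({"sample": np.arange(rec.n_samples)})
        for i, name in enumerate(rec.lead_names):
            df[f"{name}_mV"] = rec.lead_signals[i]
        with open(f, "w") as fh:
            fh.write(
                f"# record_id={rec.record_id} fs={rec.fs:g} "
                f"leads={','.join(rec.lead_names)}\n"
            )
            # %.17g guarantees an exact float64 round trip
            df.to_csv(fh, index=False, float_format="%.17g")
        return
    stem = _wfdb_stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    digital = np.round(rec.lead_signals * gain).astype(np.int64)
    digital = np.clip(digital, -2048, 2047)
    mf.write_header(
        stem.with_suffix(".hea"), rec.record_id, rec.fs, rec.n_samples,
        rec.lead_names, gain,
    )
    stem.with_suffix(".dat").write_bytes(mf.encode_212(digital))


# ---------------------------------------------------------------------------
# beats


def read_beats(path, dialect: str, provenance: str | None = None) -> BeatAnnotationSet:
    _check_dialect(dialect)
    if dialect == "csv":
        name = "beats.csv" if provenance in (None, "reference") else f"beats_{provenance}.csv"
        f = _csv_dir(path) / name
        df = pd.read_csv(f, dtype={"symbol": str})
        prov = provenance or (df["provenance"].iloc[0] if len(df) else "reference")
        return BeatAnnotationSet.from_symbols(
            df["sample"].to_numpy(), df["symbol"].to_numpy(), prov
        )
    ext = ".atr" if provenance in (None, "reference") else f".{provenance[:3]}"
    f = _wfdb_stem(path).with_suffix(ext)
    entries = [e for e in mf.read_annotations(f) if e.code in _CODE_SYMBOL]
    samples = np.array([e.sample for e in entries], dtype=np.int64)
    if len(samples) > 1 and np.any(np.diff(samples) < 0):
        raise ParseError(f"{f}: annotation stream not sorted")
    symbols = np.array([_CODE_SYMBOL[e.code] for e in entries], dtype=object)
    return BeatAnnotationSet.from_symbols(samples, symbols, provenance or "reference")


def write_beats(beats: BeatAnnotationSet, path, dialect: str) -> None:
    _check_dialect(dialect)
    if dialect == "csv":
        d = _csv_dir(path)
        d.mkdir(parents=True, exist_ok=True)
        name = "beats.csv" if beats.provenance == "reference" else f"beats_{beats.provenance}.csv"
        pd.DataFrame(
            {"sample": beats.r_samples, "symbol": beats.symbols,
             "provenance": beats.provenance}
        ).to_csv(d / name, index=False)
        return
    ext = ".atr" if beats.provenance == "reference" else f".{beats.provenance[:3]}"
    entries = [
        AnnEntry(int(s), _SYMBOL_CODE.get(sym, _SYMBOL_CODE["Q"]))
        for s, sym in zip(beats.r_samples, beats.symbols)
    ]
    mf.write_annotations(_wfdb_stem(path).with_suffix(ext), entries)


# ---------------------------------------------------------------------------
# fiducials


# typical offset of each fiducial from its beat's R spike (seconds); used
# to disambiguate attachment when a mark (e.g. T offset) falls nearer the
# next, possibly premature, beat's R spike
_EXPECTED_OFFSET_S = {
    "P_on": -0.22, "P_peak": -0.18, "P_off": -0.12,
    "QRS_on": -0.06, "Q": -0.03, "R": 0.0, "S": 0.03, "QRS_off": 0.08,
    "T_on": 0.18, "T_peak": 0.30, "T_off": 0.42,
}


def _assign_to_beats(
    marks, beats: BeatAnnotationSet, n_beats: int, fs: float = 360.0
) -> FiducialMap:
    """Attach (sample, lead, point) marks to beats by nearest R-spike
    window, after correcting for the point's expected offset from R."""
    fid = FiducialMap(n_beats)
    r = beats.r_samples
    unassigned = 0
    for sample, lead, point in marks:
        adj = sample - int(round(_EXPECTED_OFFSET_S[point] * fs))
        j = int(np.searchsorted(r, adj))
        cands = [c for c in (j - 1, j) if 0 <= c < n_beats]
        if not cands:
            unassigned += 1
            continue
        beat = min(cands, key=lambda c: abs(int(r[c]) - adj))
        if fid.get(beat, lead, point) is not None:
            unassigned += 1
            continue
        fid.set(beat, lead, point, sample)
    unassigned += fid.enforce_order()
    fid.n_unassigned = unassigned
    if unassigned:
        warnings.warn(
            f"{unassigned} fiducial marks could not be attached and were "
            "left ABSENT",
            stacklevel=3,
        )
    return fid


def read_fiducials(
    path, dialect: str, beats: BeatAnnotationSet | None = None,
    n_beats: int | None = None, fs: float = 360.0,
) -> FiducialMap:
    """Read fiducial points; beats are required for the wfdb dialect.

    Beat count is preserved: missing fiducials never remove beats.
    """
    _check_dialect(dialect)
    if dialect == "csv":
        f = _csv_dir(path) / "fiducials.csv"
        df = pd.read_csv(f, dtype={"sample": str})
        if n_beats is None:
            n_beats = len(beats) if beats is not None else (
                int(df["beat_idx"].max()) + 1 if len(df) else 0
            )
        fid = FiducialMap(n_beats)
        for row in df.itertuples(index=False):
            s = row.sample
            absent = isinstance(s, float) or s in ("ABSENT", "", None)
            fid.set(int(row.beat_idx), int(row.lead) - 1, row.point,
                    None if absent else int(s))
        return fid
    if beats is None:
        raise ValueError("wfdb fiducial reading requires the beat annotations")
    f = _wfdb_stem(path).with_suffix(".pu")
    entries = mf.read_annotations(f)
    samples = [e.sample for e in entries]
    if any(b < a for a, b in zip(samples, samples[1:])):
        raise ParseError(f"{f}: annotation stream not sorted")
    marks = []
    for e in entries:
        key = (e.code, e.num if e.code in (39, 40, 23) else 0)
        point = _CODE_FID.get(key)
        if point is not None:
            marks.append((e.sample, e.chan, point))
    return _assign_to_beats(marks, beats, n_beats or len(beats), fs=fs)


def write_fiducials(fid: FiducialMap, path, dialect: str) -> None:
    _check_dialect(dialect)
    if dialect == "csv":
        d = _csv_dir(path)
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        for b in range(fid.n_beats):
            for ld in range(fid.n_leads):
                for p in POINT_NAMES:
                    v = fid.get(b, ld, p)
                    rows.append((b, ld + 1, p, "ABSENT" if v is None else v))
        pd.DataFrame(rows, columns=["beat_idx", "lead", "point", "sample"]).to_csv(
            d / "fiducials.csv", index=False
        )
        return
    entries = []
    for b in range(fid.n_beats):
        for ld in range(fid.n_leads):
            for p in POINT_NAMES:
                v = fid.get(b, ld, p)
                if v is not None:
                    code, num = _FID_CODE[p]
                    entries.append(AnnEntry(v, code, num=num, chan=ld))
    mf.write_annotations(_wfdb_stem(path).with_suffix(".pu"), entries)
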