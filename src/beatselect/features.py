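"""Per-beat feature extraction: the 249-column heart-beat feature matrix.

Seven feature groups are computed per beat:

* segmentation intervals (24 per lead) — areas, extrema, moments and
  durations of the delineated P, QRS and T waves;
* R-R intervals (4 from the reference annotations, shared by both leads,
  plus 4 per lead from the detected annotations);
* morphological features (19 per lead) — the ECG amplitude uniformly
  resampled inside the QRS window (10 points) and the QRS-offset-to-T-offset
  window (9 points), by linear interpolation, endpoints included;
* Hermite basis function (HBF) expansion coefficients (20 per lead) — the
  beat projected on orthonormal Hermite functions of orders 0..19, with the
  width sigma chosen on a geometric grid to minimize the RMS
  reconstruction error;
* higher-order statistics (30 per lead) — the 2nd, 3rd and 4th order
  cumulant functions of the R-centered window sampled at 10 equally spaced
  lags in [-250, +250] ms;
* normalized R-R intervals (3 reference + 3 per lead detected) — previous,
  next and windowed-average R-R divided by the patient mean R-R (the mean
  itself normalizes to 1 and is dropped);
* normalized segmentation intervals (21 per lead) — the non-flag
  segmentation features divided by their per-patient mean.

Lead accounting: 2 x (24 + 19 + 20 + 30 + 21) + (4 + 4 x 2) + (3 + 3 x 2)
= 249 columns.  Column names are fixed by this module, never by the data.

A feature whose required fiducial points are absent (or which is undefined,
e.g. skewness of a zero-variance window) is *missing*, not an error;
missing entries are replaced by the patient's mean feature value at
imputation time, and the missingness mask is preserved for audit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import EXCLUDED, BeatAnnotationSet, ECGRecord, FiducialMap

__all__ = [
    "FeatureMatrix", "BeatWindow", "HermiteFit",
    "canonical_feature_names", "feature_metadata",
    "rr_features", "normalized_rr_features",
    "segmentation_features", "morphological_features",
    "hermite_features", "hos_features",
    "normalized_segmentation_features", "impute_patient_mean",
    "assemble_matrix", "extract_features",
    "SEG_FIELDS", "SEG_FLAG_FIELDS", "HOS_LAG_TIMES",
]

LEADS = ("lead1", "lead2")
REF = "ref"

# segmentation fields, in the canonical order
SEG_FIELDS = (
    "qrs_flag", "qrs_area", "qrs_max", "qrs_min", "qrs_pos_area",
    "qrs_neg_area", "qrs_std", "qrs_skew", "qrs_kurt", "qrs_len",
    "qr_len", "rs_len",
    "p_flag", "p_area", "p_max", "p_min", "p_len",
    "t_flag", "t_area", "t_max", "t_min", "t_len", "qt_len", "st_len",
)
SEG_FLAG_FIELDS = ("qrs_flag", "p_flag", "t_flag")
SEG_NONFLAG_FIELDS = tuple(f for f in SEG_FIELDS if f not in SEG_FLAG_FIELDS)

RR_FIELDS = ("rr_prev", "rr_next", "rr_avg10", "rr_mean")
NRR_FIELDS = ("rr_prev_norm", "rr_next_norm", "rr_avg10_norm")
MORPH_FIELDS = tuple(f"morph_qrs_u{i}" for i in range(10)) + tuple(
    f"morph_st_u{i}" for i in range(9)
)
HBF_FIELDS = tuple(f"hbf_c{i:02d}" for i in range(20))

#: 10 equally spaced cumulant lags spanning -250..+250 ms around the R spike.
HOS_LAG_TIMES = np.linspace(-0.25, 0.25, 10)
_HOS_LAG_MS = tuple(int(round(t * 1000)) for t in HOS_LAG_TIMES)
HOS_FIELDS = tuple(
    f"hos{order}_lag{ms:+d}ms" for order in (2, 3, 4) for ms in _HOS_LAG_MS
)
NSEG_FIELDS = tuple(f"nseg_{f}" for f in SEG_NONFLAG_FIELDS)

#: half-width of the R-centered analysis window used for HBF and HOS
BEAT_HALF_WINDOW_S = 0.30
#: geometric sigma grid for the Hermite width search, seconds
HERMITE_SIGMA_GRID = tuple(np.geomspace(0.005, 0.100, 30))
#: tolerance for pairing reference and detected R spikes, seconds
DETECTED_MATCH_TOL_S = 0.15


def _name(base: str, lead: str) -> str:
    return f"{base}__{lead}"


def canonical_feature_names() -> list[str]:
    """The 249 column names, a function of the layout only."""
    names: list[str] = []
    for lead in LEADS:
        names += [_name(f"seg_{f}", lead) for f in SEG_FIELDS]
    names += [_name(f, REF) for f in RR_FIELDS]
    for lead in LEADS:
        names += [_name(f"{f}_det", lead) for f in RR_FIELDS]
    for lead in LEADS:
        names += [_name(f, lead) for f in MORPH_FIELDS]
    for lead in LEADS:
        names += [_name(f, lead) for f in HBF_FIELDS]
    for lead in LEADS:
        names += [_name(f, lead) for f in HOS_FIELDS]
    names += [_name(f, REF) for f in NRR_FIELDS]
    for lead in LEADS:
        names += [_name(f"{f}_det", lead) for f in NRR_FIELDS]
    for lead in LEADS:
        names += [_name(f, lead) for f in NSEG_FIELDS]
    return names


def feature_metadata() -> pd.DataFrame:
    """Per-column group/lead/base metadata, indexed by column name."""
    rows = []
    for name in canonical_feature_names():
        base, lead = name.rsplit("__", 1)
        if base.startswith("seg_"):
            group = "segmentation"
        elif base.startswith("nseg_"):
            group = "segmentation_norm"
        elif base.startswith("morph_"):
            group = "morphological"
        elif base.startswith("hbf_"):
            group = "hbf"
        elif base.startswith("hos"):
            group = "hos"
        elif "norm" in base:
            group = "rr_norm"
        else:
            group = "rr"
        rows.append((name, group, lead, base))
    return pd.DataFrame(
        rows, columns=["name", "group", "lead", "base"]
    ).set_index("name")


@dataclass
class FeatureMatrix:
    """N beats x 249 named features with missingness mask and beat metadata."""

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    meta: pd.DataFrame
    record_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.missing_mask.columns):
            raise ValueError("values and mask columns must align")
        if len(self.values) != len(self.record_ids) or len(self.values) != len(self.labels):
            raise ValueError("row metadata must align with the matrix")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values.iloc[idx].reset_index(drop=True),
            self.missing_mask.iloc[idx].reset_index(drop=True),
            self.meta,
            np.asarray(self.record_ids)[idx],
            np.asarray(self.labels)[idx],
        )

    @classmethod
    def concat(cls, parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        return cls(
            pd.concat([p.values for p in parts], ignore_index=True),
            pd.concat([p.missing_mask for p in parts], ignore_index=True),
            parts[0].meta,
            np.concatenate([np.asarray(p.record_ids) for p in parts]),
            np.concatenate([np.asarray(p.labels) for p in parts]),
        )

    def to_csv(self, path) -> None:
        path = Path(path)
        df = self.values.copy()
        df.insert(0, "record_id", self.record_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, index=False)
        missing = [
            [int(i), self.names[j]]
            for i, j in zip(*np.nonzero(self.missing_mask.to_numpy()))
        ]
        sidecar = {
            "groups": self.meta["group"].to_dict(),
            "leads": self.meta["lead"].to_dict(),
            "missing_entries": missing,
            "missing_count": len(missing),
        }
        path.with_suffix(".meta.json").write_text(
            json.dumps(sidecar, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        record_ids = df.pop("record_id").to_numpy()
        labels = df.pop("label").to_numpy()
        mask = pd.DataFrame(False, index=df.index, columns=df.columns)
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            for i, name in info.get("missing_entries", []):
                mask.loc[i, name] = True
        return cls(df, mask, feature_metadata(), record_ids, labels)


@dataclass
class BeatWindow:
    """An R-centered amplitude window; spans at least +-250 ms around R."""

    samples: np.ndarray
    fs: float
    center_offset: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        need = int(round(0.25 * self.fs))
        if self.center_offset < need or len(self.samples) - self.center_offset <= need:
            raise ValueError("beat window must span at least +-250 ms around R")


@dataclass
class HermiteFit:
    order: int
    sigma: float
    coefficients: np.ndarray
    reconstruction_error: float


# ---------------------------------------------------------------------------
# R-R features


def rr_features(r_samples, i: int, fs: float) -> np.ndarray:
    """Previous, next, 10-spike windowed-average and signal-mean R-R (s).

    The windowed average is the mean of the up-to-10 intervals formed by the
    5 beats before and 5 after beat ``i``, truncated at the record edges.
    Boundary beats fall back to the signal mean for the missing neighbor.
    """
    r = np.asarray(r_samples, dtype=np.int64)
    n = len(r)
    if n < 2:
        raise ValueError("at least 2 beats are needed for R-R features")
    if not 0 <= i < n:
        raise IndexError(f"beat index {i} outside [0, {n})")
    rr = np.diff(r) / fs
    mean_rr = float(rr.mean())
    prev = float(rr[i - 1]) if i > 0 else mean_rr
    nxt = float(rr[i]) if i < n - 1 else mean_rr
    lo = max(0, i - 5)
    hi = min(n - 2, i + 4)
    avg10 = float(rr[lo : hi + 1].mean())
    return np.array([prev, nxt, avg10, mean_rr])


def normalized_rr_features(rr4, patient_mean: float) -> np.ndarray:
    """Previous/next/windowed-average R-R divided by the patient mean.

    The signal-mean feature is dropped: it normalizes to the constant 1.
    """
    if not patient_mean > 0:
        raise ValueError("patient mean R-R must be positive")
    rr4 = np.asarray(rr4, dtype=float)
    return rr4[:3] / patient_mean


# ---------------------------------------------------------------------------
# segmentation features


def _window_or_none(fid_row, on_key, off_key):
    on, off = fid_row.get(on_key), fid_row.get(off_key)
    if on is None or off is None or off <= on:
        return None
    return on, off


def segmentation_features(
    fid_row: dict, signal: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """The 24 segmentation features of one beat on one lead.

    Returns (values, missing) aligned with :data:`SEG_FIELDS`.  Flags are 1
    when the wave's on/off pair is present and are never missing; every
    other feature is missing when a required point is absent or the value
    is undefined (zero-variance skewness/kurtosis).
    """
    dt = 1.0 / fs
    values = np.zeros(len(SEG_FIELDS))
    missing = np.ones(len(SEG_FIELDS), dtype=bool)
    out = dict(zip(SEG_FIELDS, range(len(SEG_FIELDS))))

    def put(fld, val):
        values[out[fld]] = val
        missing[out[fld]] = False

    qrs = _window_or_none(fid_row, "QRS_on", "QRS_off")
    put("qrs_flag", 1.0 if qrs else 0.0)
    if qrs:
        seg = np.asarray(signal[qrs[0] : qrs[1]], dtype=float)
        put("qrs_area", seg.sum() * dt)
        put("qrs_max", seg.max())
        put("qrs_min", seg.min())
        put("qrs_pos_area", seg.clip(min=0).sum() * dt)
        put("qrs_neg_area", seg.clip(max=0).sum() * dt)
        put("qrs_std", seg.std())
        put("qrs_len", (qrs[1] - qrs[0]) * dt)
        if len(seg) >= 3 and seg.std() > 0:
            put("qrs_skew", sstats.skew(seg))
            put("qrs_kurt", sstats.kurtosis(seg, fisher=False))
    q, r_pt, s_pt = fid_row.get("Q"), fid_row.get("R"), fid_row.get("S")
    if q is not None and r_pt is not None:
        put("qr_len", (r_pt - q) * dt)
    if r_pt is not None and s_pt is not None:
        put("rs_len", (s_pt - r_pt) * dt)

    p = _window_or_none(fid_row, "P_on", "P_off")
    put("p_flag", 1.0 if p else 0.0)
    if p:
        seg = np.asarray(signal[p[0] : p[1]], dtype=float)
        put("p_area", seg.sum() * dt)
        put("p_max", seg.max())
        put("p_min", seg.min())
        put("p_len", (p[1] - p[0]) * dt)

    t = _window_or_none(fid_row, "T_on", "T_off")
    put("t_flag", 1.0 if t else 0.0)
    if t:
        seg = np.asarray(signal[t[0] : t[1]], dtype=float)
        put("t_area", seg.sum() * dt)
        put("t_max", seg.max())
        put("t_min", seg.min())
        put("t_len", (t[1] - t[0]) * dt)
    t_off, qrs_on, qrs_off, t_on = (
        fid_row.get("T_off"), fid_row.get("QRS_on"),
        fid_row.get("QRS_off"), fid_row.get("T_on"),
    )
    if t_off is not None and qrs_on is not None:
        put("qt_len", (t_off - qrs_on) * dt)
    if t_on is not None and qrs_off is not None:
        put("st_len", (t_on - qrs_off) * dt)
    return values, missing


# ---------------------------------------------------------------------------
# morphological features


def morphological_features(
    signal: np.ndarray, qrs_on, qrs_off, t_off, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """10 uniform samples on [QRS_on, QRS_off] and 9 on [QRS_off, T_off].

    Linear interpolation between stored samples, endpoints included.  An
    absent boundary point marks every feature of that window missing.
    """
    del fs  # positions are expressed directly in sample coordinates
    values = np.zeros(19)
    missing = np.ones(19, dtype=bool)
    grid = np.arange(len(signal))
    if qrs_on is not None and qrs_off is not None and qrs_off >= qrs_on:
        pos = np.linspace(qrs_on, qrs_off, 10)
        values[:10] = np.interp(pos, grid, signal)
        missing[:10] = False
    if qrs_off is not None and t_off is not None and t_off >= qrs_off:
        pos = np.linspace(qrs_off, t_off, 9)
        values[10:] = np.interp(pos, grid, signal)
        missing[10:] = False
    return values, missing


# ---------------------------------------------------------------------------
# Hermite basis function expansion


@lru_cache(maxsize=512)
def _hermite_design(n: int, center: int, fs: float, sigma: float, order: int):
    """Discrete orthonormalized Hermite functions and their pseudo-inverse."""
    t = (np.arange(n) - center) / fs
    x = t / sigma
    env = np.exp(-0.5 * x * x)
    B = np.empty((n, order))
    B[:, 0] = env
    if order > 1:
        B[:, 1] = np.sqrt(2.0) * x * env
    for k in range(1, order - 1):
        B[:, k + 1] = (
            np.sqrt(2.0 / (k + 1)) * x * B[:, k]
            - np.sqrt(k / (k + 1)) * B[:, k - 1]
        )
    norms = np.linalg.norm(B, axis=0)
    norms[norms == 0] = 1.0
    B = B / norms
    return B, np.linalg.pinv(B)


def hermite_features(
    beat: BeatWindow, order: int = 20, sigma_grid=HERMITE_SIGMA_GRID
) -> HermiteFit:
    """Fit the beat with 20 Hermite basis functions; sigma minimizes the
    RMS reconstruction error over a geometric grid (ties -> smaller sigma)."""
    x = beat.samples
    if len(x) < order:
        raise ValueError("beat window shorter than the Hermite order")
    sigma_grid = tuple(float(s) for s in sigma_grid)
    if not np.any(x):
        return HermiteFit(order, sigma_grid[len(sigma_grid) // 2],
                          np.zeros(order), 0.0)
    best = None
    for sigma in sigma_grid:
        B, pinv = _hermite_design(len(x), beat.center_offset, beat.fs, sigma, order)
        c = pinv @ x
        err = float(np.sqrt(np.mean((x - B @ c) ** 2)))
        if best is None or err < best[0]:
            best = (err, sigma, c)
    err, sigma, c = best
    return HermiteFit(order, sigma, c, err)


# ---------------------------------------------------------------------------
# higher-order statistics


def _lag_moment(x: np.ndarray, tau: int, power: int) -> float:
    """(1/N) sum_n x[n] * x[n+tau]**power over the valid overlap."""
    n = len(x)
    if abs(tau) >= n:
        return 0.0
    if tau >= 0:
        a, b = x[: n - tau], x[tau:]
    else:
        a, b = x[-tau:], x[: n + tau]
    return float(np.sum(a * b**power) / n)


def hos_features(beat: BeatWindow, lag_times=HOS_LAG_TIMES) -> np.ndarray:
    """2nd/3rd/4th-order cumulant functions at 10 lags in +-250 ms.

    Sample (biased, 1/N) diagonal-slice estimators on the mean-removed
    R-centered +-250 ms segment:

    * c2(tau) = E[x(n) x(n+tau)]           (autocorrelation)
    * c3(tau) = E[x(n) x(n+tau)^2]
    * c4(tau) = E[x(n) x(n+tau)^3] - 3 c2(tau) c2(0)

    Values are ordered (order, lag): 10 lags of c2, then c3, then c4.
    """
    half = int(round(0.25 * beat.fs))
    c = beat.center_offset
    x = beat.samples[c - half : c + half + 1].astype(float)
    x = x - x.mean()
    lags = [int(round(t * beat.fs)) for t in np.asarray(lag_times)]
    c2 = np.array([_lag_moment(x, tau, 1) for tau in lags])
    c3 = np.array([_lag_moment(x, tau, 2) for tau in lags])
    c20 = _lag_moment(x, 0, 1)
    c4 = np.array(
        [_lag_moment(x, tau, 3) - 3.0 * c2k * c20 for tau, c2k in zip(lags, c2)]
    )
    return np.concatenate([c2, c3, c4])


# ---------------------------------------------------------------------------
# normalization and imputation


def normalized_segmentation_features(
    seg_values: np.ndarray, seg_missing: np.ndarray, patient_means: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The 21 non-flag segmentation features divided by their patient mean.

    ``patient_means`` aligns with :data:`SEG_NONFLAG_FIELDS`.  A zero
    patient mean (or a missing input) flags the feature missing.
    """
    nonflag_idx = [SEG_FIELDS.index(f) for f in SEG_NONFLAG_FIELDS]
    vals = np.asarray(seg_values, dtype=float)[nonflag_idx]
    miss = np.asarray(seg_missing, dtype=bool)[nonflag_idx].copy()
    means = np.asarray(patient_means, dtype=float)
    out = np.zeros(len(vals))
    bad = miss | (means == 0) | ~np.isfinite(means)
    ok = ~bad
    out[ok] = vals[ok] / means[ok]
    return out, bad


def impute_patient_mean(matrix: FeatureMatrix, patient_ids=None) -> FeatureMatrix:
    """Replace missing entries by the patient's mean of the feature.

    A feature with no observed value for a patient falls back to the global
    column mean, then to 0.  Non-missing entries are never changed and the
    mask is preserved for audit.
    """
    ids = np.asarray(patient_ids if patient_ids is not None else matrix.record_ids)
    vals = matrix.values.to_numpy(dtype=float).copy()
    mask = matrix.missing_mask.to_numpy(dtype=bool)
    if vals.size == 0 or not mask.any():
        return matrix
    obs = np.where(mask, np.nan, vals)

    def _colmeans(block: np.ndarray) -> np.ndarray:
        # nanmean of an all-NaN column is the fallback path, not a warning
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(block, axis=0)

    global_mean = _colmeans(obs)
    global_mean = np.where(np.isfinite(global_mean), global_mean, 0.0)
    for pid in pd.unique(ids):
        rows = ids == pid
        pm = _colmeans(obs[rows])
        pm = np.where(np.isfinite(pm), pm, global_mean)
        block = vals[rows]
        block[mask[rows]] = np.broadcast_to(pm, block.shape)[mask[rows]]
        vals[rows] = block
    return FeatureMatrix(
        pd.DataFrame(vals, columns=matrix.names),
        matrix.missing_mask.reset_index(drop=True),
        matrix.meta,
        matrix.record_ids,
        matrix.labels,
    )


# ---------------------------------------------------------------------------
# assembly


def _beat_window(signal: np.ndarray, r: int, half: int, fs: float) -> BeatWindow:
    lo, hi = r - half, r + half + 1
    w = np.zeros(2 * half + 1)
    src_lo, src_hi = max(0, lo), min(len(signal), hi)
    w[src_lo - lo : src_hi - lo] = signal[src_lo:src_hi]
    return BeatWindow(w, fs, half)


def _match_detected(r_ref: np.ndarray, r_det: np.ndarray, fs: float) -> np.ndarray:
    """Index of the nearest detected spike per reference beat, -1 if none
    within the pairing tolerance."""
    out = np.full(len(r_ref), -1, dtype=np.int64)
    if len(r_det) == 0:
        return out
    tol = DETECTED_MATCH_TOL_S * fs
    pos = np.searchsorted(r_det, r_ref)
    for i, (r, j) in enumerate(zip(r_ref, pos)):
        cands = [c for c in (j - 1, j) if 0 <= c < len(r_det)]
        if not cands:
            continue
        best = min(cands, key=lambda c: abs(int(r_det[c]) - r))
        if abs(int(r_det[best]) - r) <= tol:
            out[i] = best
    return out


def extract_features(
    rec: ECGRecord,
    beats_ref: BeatAnnotationSet,
    beats_det: BeatAnnotationSet,
    fid: FiducialMap,
    impute: bool = True,
) -> FeatureMatrix:
    """Assemble the 249-column feature matrix for one (filtered) record.

    Rows are the reference beats whose AAMI label is not excluded; the
    fiducial map must align beat-for-beat with the reference annotations.
    Lead-1 and lead-2 columns are produced by the same code path.
    """
    if fid.n_beats != len(beats_ref):
        raise ValueError(
            f"fiducial map has {fid.n_beats} beats, annotations have "
            f"{len(beats_ref)}"
        )
    beats_ref.check_within(rec.n_samples)
    fs = rec.fs
    keep = np.flatnonzero(np.asarray(beats_ref.aami_labels) != EXCLUDED)
    names = canonical_feature_names()
    n_rows = len(keep)
    values = np.zeros((n_rows, len(names)))
    missing = np.zeros((n_rows, len(names)), dtype=bool)
    col = {name: j for j, name in enumerate(names)}
    half = int(round(BEAT_HALF_WINDOW_S * fs))

    det_match = _match_detected(beats_ref.r_samples, beats_det.r_samples, fs)
    rr_mean_ref = float(np.diff(beats_ref.r_samples).mean() / fs) if len(beats_ref) > 1 else np.nan
    rr_mean_det = float(np.diff(beats_det.r_samples).mean() / fs) if len(beats_det) > 1 else np.nan

    # raw segmentation per kept beat and lead, for patient-mean normalization
    seg_vals = np.zeros((n_rows, 2, len(SEG_FIELDS)))
    seg_miss = np.zeros((n_rows, 2, len(SEG_FIELDS)), dtype=bool)
    for row, b in enumerate(keep):
        for ld, lead in enumerate(LEADS):
            sv, sm = segmentation_features(fid.row(b, ld), rec.lead_signals[ld], fs)
            seg_vals[row, ld] = sv
            seg_miss[row, ld] = sm

    nonflag_idx = [SEG_FIELDS.index(f) for f in SEG_NONFLAG_FIELDS]
    seg_means = np.empty((2, len(SEG_NONFLAG_FIELDS)))
    for ld in range(2):
        obs = np.where(seg_miss[:, ld, nonflag_idx], np.nan, seg_vals[:, ld, nonflag_idx])
        with np.errstate(invalid="ignore"):
            seg_means[ld] = np.nanmean(obs, axis=0) if n_rows else np.nan

    def put(row, name, val, miss=False):
        j = col[name]
        values[row, j] = 0.0 if miss else val
        missing[row, j] = miss

    for row, b in enumerate(keep):
        # reference R-R (shared by both leads)
        rr_ref = rr_features(beats_ref.r_samples, int(b), fs)
        for f, v in zip(RR_FIELDS, rr_ref):
            put(row, _name(f, REF), v)
        nrr_ref = normalized_rr_features(rr_ref, rr_mean_ref)
        for f, v in zip(NRR_FIELDS, nrr_ref):
            put(row, _name(f, REF), v)

        # detected R-R (the detection is shared, columns are per lead)
        j_det = det_match[b]
        det_ok = j_det >= 0 and len(beats_det) >= 2
        if det_ok:
            rr_det = rr_features(beats_det.r_samples, int(j_det), fs)
            nrr_det = normalized_rr_features(rr_det, rr_mean_det)
        for lead in LEADS:
            for k, f in enumerate(RR_FIELDS):
                put(row, _name(f"{f}_det", lead),
                    rr_det[k] if det_ok else 0.0, miss=not det_ok)
            for k, f in enumerate(NRR_FIELDS):
                put(row, _name(f"{f}_det", lead),
                    nrr_det[k] if det_ok else 0.0, miss=not det_ok)

        for ld, lead in enumerate(LEADS):
            sig = rec.lead_signals[ld]
            frow = fid.row(b, ld)
            for f, v, m in zip(SEG_FIELDS, seg_vals[row, ld], seg_miss[row, ld]):
                put(row, _name(f"seg_{f}", lead), v, miss=bool(m))
            mv, mm = morphological_features(
                sig, frow["QRS_on"], frow["QRS_off"], frow["T_off"], fs
            )
            for f, v, m in zip(MORPH_FIELDS, mv, mm):
                put(row, _name(f, lead), v, miss=bool(m))
            window = _beat_window(sig, int(beats_ref.r_samples[b]), half, fs)
            hb = hermite_features(window)
            for f, v in zip(HBF_FIELDS, hb.coefficients):
                put(row, _name(f, lead), v)
            for f, v in zip(HOS_FIELDS, hos_features(window)):
                put(row, _name(f, lead), v)
            nv, nm = normalized_segmentation_features(
                seg_vals[row, ld], seg_miss[row, ld], seg_means[ld]
            )
            for f, v, m in zip(NSEG_FIELDS, nv, nm):
                put(row, _name(f, lead), v, miss=bool(m))

    fm = FeatureMatrix(
        pd.DataFrame(values, columns=names),
        pd.DataFrame(missing, columns=names),
        feature_metadata(),
        np.repeat(rec.record_id, n_rows),
        np.asarray(beats_ref.aami_labels)[keep],
    )
    return impute_patient_mean(fm) if impute else fm


#: spec-facing alias for the assembly operation
assemble_matrix = extract_features
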