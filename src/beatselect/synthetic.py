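"""Synthetic two-lead ECG generator with ground-truth fiducials and labels.

Each beat is a sum of five Gaussian waves (P, Q, R, S, T) whose amplitude,
center and width depend on the beat class:

* **N** — the template, with small per-beat jitter;
* **S** (supraventricular ectopic) — normal morphology, but the preceding
  R-R interval is shortened (x U(0.5, 0.8)) with a compensatory
  lengthening of the following interval;
* **V** (ventricular ectopic) — widened QRS (x U(1.8, 2.5)), absent P
  wave, inverted T wave, and premature timing (coupling interval
  x U(0.65, 0.90) of the sinus cycle, with a compensatory pause):
  premature ventricular contractions are early by definition, which is
  what makes the previous R-R interval the classic rhythm feature;
* **F** (fusion) — a convex mix of the N and V wave parameters.

Default class prevalences (~89.9 / 1.9 / 7.4 / 0.8 %) follow the customary
interpatient training distribution of ambulatory recordings.  White noise
and a sinusoidal baseline drift are added; "detected" annotations are the
reference R indices jittered by +-1 sample with a 1% miss rate.  Fiducial
ground truth is placed at mu +- 3w of the generative waves and each point
is dropped with ``missing_fiducial_rate`` to exercise the imputation path.

Patients are simulated with their own heart rate, amplitude scale and wave
width scale so that interpatient variability is real: unnormalized
morphology and rhythm features genuinely shift between patients, which is
exactly what the patient-normalized feature groups are meant to remove.

Everything is driven by a single integer seed; a fixed seed reproduces the
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import BeatAnnotationSet, ECGRecord, FiducialMap

__all__ = [
    "SimSpec", "SimResult", "simulate_record", "simulate_patients",
    "gaussian_feature_problem",
]

CLASS_NAMES = ("N", "S", "V", "F")
_SYMBOL_OF_CLASS = {"N": "N", "S": "A", "V": "V", "F": "F"}

# wave templates: (amplitude mV, center offset s relative to R, width s)
_TEMPLATE = {
    "lead1": {
        "P": (0.15, -0.18, 0.025),
        "Q": (-0.12, -0.035, 0.010),
        "R": (1.20, 0.0, 0.012),
        "S": (-0.25, 0.035, 0.010),
        "T": (0.35, 0.30, 0.055),
    },
    "lead2": {
        "P": (0.08, -0.18, 0.025),
        "Q": (-0.05, -0.035, 0.010),
        "R": (0.70, 0.0, 0.012),
        "S": (-0.35, 0.035, 0.010),
        "T": (0.20, 0.30, 0.055),
    },
}
_WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class SimSpec:
    """Conditions for one simulated record (one patient)."""

    seed: int
    n_beats: int = 500
    fs: float = 360.0
    class_probs: tuple = (0.899, 0.019, 0.074, 0.008)
    noise_sd: float = 0.02            # mV, white noise
    baseline_amp: float = 0.10        # mV, respiratory drift sinusoid
    baseline_freq: float = 0.3        # Hz
    missing_fiducial_rate: float = 0.006
    rr_mean: float = 0.8              # s, patient mean R-R
    amp_scale: float = 1.0            # per-patient amplitude factor
    width_scale: float = 1.0          # per-patient wave width factor
    record_id: str = "sim000"

    def validate(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if len(p) != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 4 nonnegative values summing to 1")
        if self.n_beats < 2:
            raise ValueError("n_beats must be >= 2")


class SimResult(NamedTuple):
    record: ECGRecord
    beats_ref: BeatAnnotationSet
    beats_det: BeatAnnotationSet
    fiducials: FiducialMap
    labels: np.ndarray


def _patient_template(rng: np.random.Generator) -> dict:
    """Draw this patient's resting beat morphology.

    Real cohorts are morphologically diverse — conduction pattern, cardiac
    axis and electrode placement reshape every wave while the beat is still
    'normal' — so each patient gets per-wave amplitude factors (U(0.7, 1.3))
    and width factors (U(0.9, 1.15)), and its own P and T wave positions.
    This interpatient spread is what the patient-normalized feature groups
    are designed to remove.
    """
    amp_f = {w: rng.uniform(0.7, 1.3) for w in _WAVES}
    wid_f = {w: rng.uniform(0.9, 1.15) for w in _WAVES}
    p_mu = rng.uniform(-0.20, -0.16)
    t_mu = rng.uniform(0.26, 0.34)
    template = {}
    for lead in ("lead1", "lead2"):
        waves = {}
        for w in _WAVES:
            a, mu, wd = _TEMPLATE[lead][w]
            if w == "P":
                mu = p_mu
            elif w == "T":
                mu = t_mu
            waves[w] = (a * amp_f[w], mu, wd * wid_f[w])
        template[lead] = waves
    return template


def _beat_params(
    label: str, rng: np.random.Generator, spec: SimSpec, template: dict
) -> dict:
    """Per-beat wave parameters for both leads (shared timing and widths).

    Beat-to-beat amplitude (~10%) and width (~8%) jitter emulate
    respiratory modulation and electrode drift; ectopic beats additionally
    get a per-beat amplitude factor (multiform ectopy).  Timing, by
    contrast, is crisp — which is exactly why rhythm features generalize
    across patients better than raw morphology.
    """
    jitter_a = 1.0 + rng.normal(0.0, 0.10, len(_WAVES))
    jitter_w = 1.0 + rng.normal(0.0, 0.08, len(_WAVES))
    if label == "V" or label == "F":
        qrs_widen = rng.uniform(1.8, 2.5)
        t_inv = rng.uniform(0.9, 1.1)
        jitter_a *= rng.uniform(0.7, 1.3)
    lam = rng.uniform(0.3, 0.7) if label == "F" else 1.0
    params = {}
    for lead in ("lead1", "lead2"):
        waves = {}
        for i, w in enumerate(_WAVES):
            a, mu, wd = template[lead][w]
            a_n, wd_n = a, wd
            if label in ("V", "F"):
                a_v, wd_v = a, wd
                if w == "P":
                    a_v = 0.0
                elif w in ("Q", "R", "S"):
                    wd_v = wd * qrs_widen
                    a_v = a * (1.15 if w == "R" else 1.3) if w in ("R", "S") else a
                elif w == "T":
                    a_v = -a * t_inv
                if label == "V":
                    a, wd = a_v, wd_v
                else:  # fusion: convex mix of N and V parameters
                    a = (1 - lam) * a_n + lam * a_v
                    wd = (1 - lam) * wd_n + lam * wd_v
            a *= spec.amp_scale * jitter_a[i]
            wd *= spec.width_scale * jitter_w[i]
            waves[w] = (a, mu, wd)
        params[lead] = waves
    return params


def simulate_record(spec: SimSpec) -> SimResult:
    """Generate one labeled record with ground-truth fiducials.

    Deterministic given ``spec.seed``: repeated calls are byte-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = spec.n_beats
    labels = np.array(
        [CLASS_NAMES[i] for i in rng.choice(4, size=n, p=np.asarray(spec.class_probs))],
        dtype=object,
    )

    template = _patient_template(rng)

    # R-R intervals; rr[i] is the interval preceding beat i (rr[0] is a
    # lead-in).  Ectopic coupling intervals are fractions of the *sinus*
    # cycle, and the compensatory pause restores the sinus schedule —
    # unless the next beat is itself ectopic, in which case its own
    # coupling wins.
    sinus = spec.rr_mean * (1.0 + rng.normal(0.0, 0.03, n))
    rr = sinus.copy()
    for i in range(1, n):
        if labels[i] == "S":
            f = rng.uniform(0.5, 0.8)
        elif labels[i] == "V":
            f = rng.uniform(0.65, 0.90)  # PVC coupling interval
        else:
            continue
        rr[i] = sinus[i] * f
        if i + 1 < n and labels[i + 1] not in ("S", "V"):
            rr[i + 1] = sinus[i + 1] * (2.0 - f)  # compensatory pause
    r = np.empty(n, dtype=np.int64)
    r[0] = int(round(0.45 * fs))
    for i in range(1, n):
        r[i] = r[i - 1] + max(1, int(round(rr[i] * fs)))
    n_samples = int(r[-1] + round(0.8 * fs))

    signals = np.zeros((2, n_samples))
    fid = FiducialMap(n)
    half_render = int(round(0.45 * fs))
    for i in range(n):
        params = _beat_params(labels[i], rng, spec, template)
        lo = max(0, r[i] - half_render)
        hi = min(n_samples, r[i] + half_render + 1)
        t = (np.arange(lo, hi) - r[i]) / fs
        for ld, lead in enumerate(("lead1", "lead2")):
            for a, mu, wd in params[lead].values():
                if a != 0.0:
                    signals[ld, lo:hi] += a * np.exp(-0.5 * ((t - mu) / wd) ** 2)
        # ground-truth fiducials from the generative wave boundaries
        waves = params["lead1"]  # timing/widths shared by both leads
        marks = {
            "P_on": waves["P"][1] - 3 * waves["P"][2],
            "P_peak": waves["P"][1],
            "P_off": waves["P"][1] + 3 * waves["P"][2],
            "QRS_on": waves["Q"][1] - 3 * waves["Q"][2],
            "Q": waves["Q"][1],
            "R": waves["R"][1],
            "S": waves["S"][1],
            "QRS_off": waves["S"][1] + 3 * waves["S"][2],
            "T_on": waves["T"][1] - 3 * waves["T"][2],
            "T_peak": waves["T"][1],
            "T_off": waves["T"][1] + 3 * waves["T"][2],
        }
        # overlapping waves (wide QRS, fusion) may cross: clamp outward from
        # R so the marks honor the physiological point order
        keys = list(marks)
        r_pos = keys.index("R")
        for j in range(r_pos - 1, -1, -1):
            marks[keys[j]] = min(marks[keys[j]], marks[keys[j + 1]])
        for j in range(r_pos + 1, len(keys)):
            marks[keys[j]] = max(marks[keys[j]], marks[keys[j - 1]])
        p_absent = labels[i] == "V"
        drop = rng.random((2, len(marks))) < spec.missing_fiducial_rate
        for ld in range(2):
            for j, (point, offset) in enumerate(marks.items()):
                if p_absent and point.startswith("P"):
                    continue
                if drop[ld, j]:
                    continue
                sample = int(r[i] + round(offset * fs))
                if 0 <= sample < n_samples:
                    fid.set(i, ld, point, sample)

    tgrid = np.arange(n_samples) / fs
    for ld in range(2):
        phase = rng.uniform(0, 2 * np.pi)
        signals[ld] += spec.baseline_amp * np.sin(
            2 * np.pi * spec.baseline_freq * tgrid + phase
        )
        signals[ld] += rng.normal(0.0, spec.noise_sd, n_samples)

    symbols = np.array([_SYMBOL_OF_CLASS[l] for l in labels], dtype=object)
    beats_ref = BeatAnnotationSet.from_symbols(r, symbols, "reference")

    miss = rng.random(n) < 0.01
    jit = rng.integers(-1, 2, size=n)
    keep = ~miss
    det_samples = np.clip(r[keep] + jit[keep], 0, n_samples - 1)
    beats_det = BeatAnnotationSet.from_symbols(
        det_samples, symbols[keep], "detected"
    )

    record = ECGRecord(spec.record_id, fs, signals, ("lead1", "lead2"))
    return SimResult(record, beats_ref, beats_det, fid, labels)


def simulate_patients(
    n_patients: int, n_beats: int, seed: int, **common
) -> list[SimResult]:
    """Simulate a cohort; each patient gets its own rate/amplitude/width.

    Per-patient draws: mean R-R ~ U(0.7, 0.95) s, amplitude scale
    ~ U(0.85, 1.15), wave width scale ~ U(0.85, 1.25).
    """
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_patients):
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = SimSpec(
            seed=child_seed,
            n_beats=n_beats,
            rr_mean=float(rng.uniform(0.70, 0.95)),
            amp_scale=float(rng.uniform(0.85, 1.15)),
            width_scale=float(rng.uniform(0.85, 1.25)),
            record_id=f"sim{p:03d}",
            **common,
        )
        out.append(simulate_record(spec))
    return out


def gaussian_feature_problem(
    n: int = 200,
    n_informative: int = 2,
    n_noise: int = 20,
    delta: float = 2.5,
    n_groups: int = 10,
    seed: int = 0,
):
    """Two-class Gaussian benchmark for selection methods.

    The informative features have class means +-delta/2 with unit variance;
    the noise features are standard normal and label-independent.  Samples
    are assigned round-robin to ``n_groups`` synthetic patients.  Returns
    (X DataFrame, y, groups, informative_names).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    sign = np.where(y == 1, 1.0, -1.0)
    cols = {}
    informative = [f"inf{i}" for i in range(n_informative)]
    for name in informative:
        cols[name] = sign * delta / 2 + rng.normal(0, 1, n)
    for i in range(n_noise):
        cols[f"noise{i:02d}"] = rng.normal(0, 1, n)
    X = pd.DataFrame(cols)
    groups = np.arange(n) % n_groups
    return X, y, groups, informative
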