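"""Feature extraction oracles: R-R, segmentation, morphology, HBF, HOS."""

import numpy as np
import pandas as pd
import pytest

from beatselect.features import (
    BeatWindow, FeatureMatrix, HERMITE_SIGMA_GRID, HOS_LAG_TIMES,
    MORPH_FIELDS, NSEG_FIELDS, SEG_FIELDS, SEG_NONFLAG_FIELDS,
    canonical_feature_names, extract_features, feature_metadata,
    hermite_features, hos_features, impute_patient_mean,
    morphological_features, normalized_rr_features,
    normalized_segmentation_features, rr_features, segmentation_features,
)
from beatselect.io import BeatAnnotationSet, ECGRecord, FiducialMap, POINT_NAMES
from beatselect.synthetic import SimSpec, simulate_record

FS = 360.0


class TestRRFeatures:
    def test_metronomic_rhythm(self):
        r = np.arange(20) * int(0.8 * FS)
        assert np.allclose(rr_features(r, 10, FS), [0.8, 0.8, 0.8, 0.8])

    def test_premature_beat(self):
        rr = [0.8] * 6 + [0.4, 1.2] + [0.8] * 6
        r = np.concatenate([[0], np.cumsum(np.round(np.array(rr) * FS))])
        prev, nxt, _, _ = rr_features(r.astype(int), 7, FS)
        assert prev == pytest.approx(0.4, abs=1e-2)
        assert nxt == pytest.approx(1.2, abs=1e-2)

    def test_boundary_beats_fall_back_to_mean(self):
        r = np.array([0, 288, 576, 864])
        mean = np.diff(r).mean() / FS
        assert rr_features(r, 0, FS)[0] == pytest.approx(mean)
        assert rr_features(r, 3, FS)[1] == pytest.approx(mean)

    def test_windowed_average_matches_enumeration(self, rng):
        # oracle: direct enumeration of the <=10 intervals nearest i
        for _ in range(25):
            n = rng.integers(3, 40)
            r = np.cumsum(rng.integers(100, 500, size=n))
            rr = np.diff(r) / FS
            i = int(rng.integers(0, n))
            expected = np.mean(
                [rr[j] for j in range(len(rr)) if i - 5 <= j <= i + 4]
            )
            assert rr_features(r, i, FS)[2] == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_beats(self):
        with pytest.raises(ValueError):
            rr_features([100], 0, FS)


class TestNormalizedRR:
    def test_uniform_rhythm_gives_ones(self):
        assert np.allclose(normalized_rr_features([0.8, 0.8, 0.8, 0.8], 0.8), 1.0)

    def test_division(self):
        out = normalized_rr_features([0.4, 1.2, 0.8, 0.8], 0.8)
        assert np.allclose(out, [0.5, 1.5, 1.0])

    def test_scale_invariance(self):
        a = normalized_rr_features([0.4, 1.2, 0.8, 0.8], 0.8)
        b = normalized_rr_features([0.8, 2.4, 1.6, 1.6], 1.6)
        assert np.allclose(a, b)

    def test_nonpositive_mean(self):
        with pytest.raises(ValueError):
            normalized_rr_features([1, 1, 1, 1], 0.0)


def _fid_row(**points):
    row = {p: None for p in POINT_NAMES}
    row.update(points)
    return row


class TestSegmentation:
    def test_group_size(self):
        assert len(SEG_FIELDS) == 24

    def test_flat_zero_signal(self):
        sig = np.zeros(500)
        row = _fid_row(P_on=50, P_peak=60, P_off=70, QRS_on=90, Q=95, R=100,
                       S=105, QRS_off=110, T_on=150, T_peak=170, T_off=190)
        vals, miss = segmentation_features(row, sig, FS)
        named = dict(zip(SEG_FIELDS, vals))
        missing = dict(zip(SEG_FIELDS, miss))
        for f in ("qrs_area", "qrs_max", "qrs_min", "qrs_std", "p_area", "t_area"):
            assert named[f] == 0.0 and not missing[f]
        # zero variance: skewness/kurtosis undefined, flagged missing
        assert missing["qrs_skew"] and missing["qrs_kurt"]
        assert named["qrs_flag"] == 1.0 and named["p_flag"] == 1.0

    def test_symmetric_triangular_qrs(self):
        sig = np.zeros(400)
        on, off = 100, 120  # 20 samples, value-symmetric triangle
        t = np.arange(off - on)
        sig[on:off] = 9.5 - np.abs(t - 9.5)
        row = _fid_row(QRS_on=on, QRS_off=off)
        vals, miss = segmentation_features(row, sig, FS)
        named = dict(zip(SEG_FIELDS, vals))
        assert abs(named["qrs_skew"]) < 1e-12  # symmetric value multiset
        assert named["qrs_len"] == pytest.approx((off - on) / FS)

    def test_absent_points_flag_missing_not_error(self):
        vals, miss = segmentation_features(_fid_row(), np.zeros(100), FS)
        named_miss = dict(zip(SEG_FIELDS, miss))
        assert not named_miss["qrs_flag"] and vals[SEG_FIELDS.index("qrs_flag")] == 0.0
        assert named_miss["qrs_area"] and named_miss["qt_len"]


class TestMorphological:
    def test_constant_signal(self):
        vals, miss = morphological_features(np.full(300, 1.7), 50, 100, 200, FS)
        assert np.allclose(vals, 1.7) and not miss.any()
        assert len(vals) == len(MORPH_FIELDS) == 19

    def test_linear_ramp_closed_form(self):
        a, b = 0.3, 0.01
        sig = a + b * np.arange(400)
        vals, _ = morphological_features(sig, 100, 190, 350, FS)
        qrs_pos = np.linspace(100, 190, 10)
        st_pos = np.linspace(190, 350, 9)
        assert np.allclose(vals[:10], a + b * qrs_pos, atol=1e-12)
        assert np.allclose(vals[10:], a + b * st_pos, atol=1e-12)

    def test_absent_boundary_marks_window_missing(self):
        vals, miss = morphological_features(np.zeros(300), None, 100, 200, FS)
        assert miss[:10].all() and not miss[10:].any()


def _window(x):
    return BeatWindow(np.asarray(x, dtype=float), FS, len(x) // 2)


class TestHermite:
    def test_order0_beat_recovered(self):
        sigma = HERMITE_SIGMA_GRID[12]
        n, c = 217, 108
        t = (np.arange(n) - c) / FS
        g = np.exp(-0.5 * (t / sigma) ** 2)
        x = 3.7 * g / np.linalg.norm(g)
        fit = hermite_features(BeatWindow(x, FS, c))
        assert fit.sigma == pytest.approx(sigma)
        assert fit.coefficients[0] == pytest.approx(3.7, abs=1e-8)
        assert np.max(np.abs(fit.coefficients[1:])) < 1e-8
        assert fit.reconstruction_error < 1e-10

    def test_group_size(self):
        fit = hermite_features(_window(np.sin(np.arange(217) / 10)))
        assert len(fit.coefficients) == 20

    def test_nested_projection_error(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 217)
            e20 = hermite_features(_window(x), order=20).reconstruction_error
            e5 = hermite_features(_window(x), order=5).reconstruction_error
            assert e20 <= e5 + 1e-12

    def test_degenerate_zero_beat(self):
        fit = hermite_features(_window(np.zeros(217)))
        assert np.all(fit.coefficients == 0)
        assert fit.sigma == HERMITE_SIGMA_GRID[len(HERMITE_SIGMA_GRID) // 2]


class TestHOS:
    def test_group_size(self):
        assert len(hos_features(_window(np.sin(np.arange(217) / 7)))) == 30

    def test_odd_beat_third_order_vanishes_at_zero_lag(self):
        n, c = 217, 108
        k = np.arange(n) - c
        x = np.sin(k / 9.0)  # odd around the center: odd moments vanish
        w = BeatWindow(x, FS, c)
        c2_0, c3_0, _ = hos_features(w, lag_times=[0.0])
        assert abs(c3_0) < 1e-12 and c2_0 > 0
        c3 = hos_features(w)[10:20]
        # antisymmetry across the symmetric lag grid
        assert np.allclose(c3, -c3[::-1], atol=1e-10)

    def test_second_order_matches_direct_lag_sums(self, rng):
        x_raw = rng.normal(0, 1, 217)
        w = BeatWindow(x_raw, FS, 108)
        out = hos_features(w)
        half = int(round(0.25 * FS))
        x = x_raw[108 - half : 108 + half + 1].astype(float)
        x = x - x.mean()
        n = len(x)
        for j, t in enumerate(HOS_LAG_TIMES):
            tau = int(round(t * FS))
            acc = 0.0
            for i in range(n):  # brute-force lag sum
                if 0 <= i + tau < n:
                    acc += x[i] * x[i + tau]
            assert out[j] == pytest.approx(acc / n, abs=1e-12)

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            BeatWindow(np.zeros(100), FS, 50)


class TestNormalizedSegmentation:
    def test_group_size(self):
        assert len(NSEG_FIELDS) == 21

    def test_beat_at_patient_mean_gives_ones(self):
        vals = np.arange(1.0, 25.0)
        miss = np.zeros(24, dtype=bool)
        nonflag = [SEG_FIELDS.index(f) for f in SEG_NONFLAG_FIELDS]
        out, bad = normalized_segmentation_features(vals, miss, vals[nonflag])
        assert np.allclose(out, 1.0) and not bad.any()

    def test_scale_invariance(self):
        vals = np.linspace(1, 3, 24)
        miss = np.zeros(24, dtype=bool)
        nonflag = [SEG_FIELDS.index(f) for f in SEG_NONFLAG_FIELDS]
        a, _ = normalized_segmentation_features(vals, miss, vals[nonflag] * 0.5)
        b, _ = normalized_segmentation_features(vals * 2, miss, vals[nonflag])
        assert np.allclose(a, b)

    def test_zero_patient_mean_flags_missing(self):
        vals = np.ones(24)
        miss = np.zeros(24, dtype=bool)
        means = np.ones(21)
        means[3] = 0.0
        _, bad = normalized_segmentation_features(vals, miss, means)
        assert bad[3] and bad.sum() == 1


class TestImputation:
    def _fm(self, vals, mask, ids):
        vals = pd.DataFrame(vals, columns=["a", "b"])
        mask = pd.DataFrame(mask, columns=["a", "b"])
        n = len(vals)
        return FeatureMatrix(vals, mask, feature_metadata(), np.asarray(ids),
                             np.array(["N"] * n, dtype=object))

    def test_no_missing_is_identity(self):
        fm = self._fm([[1.0, 2.0], [3.0, 4.0]], [[False] * 2] * 2, ["p", "p"])
        out = impute_patient_mean(fm)
        assert np.array_equal(out.values.to_numpy(), fm.values.to_numpy())

    def test_single_missing_gets_patient_mean(self):
        fm = self._fm(
            [[2.0, 1.0], [4.0, 1.0], [0.0, 1.0]],
            [[False, False], [False, False], [True, False]],
            ["p", "p", "p"],
        )
        out = impute_patient_mean(fm)
        assert out.values.iloc[2, 0] == pytest.approx(3.0)  # mean of {2, 4}

    def test_never_changes_observed_entries(self, matrix200):
        out = impute_patient_mean(matrix200)
        obs = ~matrix200.missing_mask.to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[obs], matrix200.values.to_numpy()[obs]
        )

    def test_mask_preserved_for_audit(self, matrix200):
        assert matrix200.missing_mask.to_numpy().sum() > 0
        assert np.all(np.isfinite(matrix200.values.to_numpy()))


class TestAssembly:
    def test_249_columns(self, matrix200):
        assert matrix200.values.shape[1] == 249
        assert len(set(matrix200.names)) == 249

    def test_names_are_layout_only(self, matrix200):
        assert canonical_feature_names() == matrix200.names
        assert canonical_feature_names() == canonical_feature_names()

    def test_zero_beats_keeps_full_name_list(self):
        sig = np.zeros((2, 4000))
        rec = ECGRecord("empty", FS, sig)
        beats = BeatAnnotationSet.from_symbols([500, 900], ["/", "/"], "reference")
        det = BeatAnnotationSet.from_symbols([500, 900], ["/", "/"], "detected")
        fm = extract_features(rec, beats, det, FiducialMap(2))
        assert len(fm) == 0 and fm.values.shape[1] == 249

    def test_misaligned_fiducials_rejected(self, sim200):
        with pytest.raises(ValueError, match="fiducial"):
            extract_features(sim200.record, sim200.beats_ref, sim200.beats_det,
                             FiducialMap(3))

    def test_identical_leads_give_identical_columns(self):
        sim = simulate_record(SimSpec(seed=21, n_beats=60,
                                      missing_fiducial_rate=0.0))
        sig = sim.record.lead_signals
        rec = ECGRecord(sim.record.record_id, sim.record.fs,
                        np.stack([sig[0], sig[0]]), sim.record.lead_names)
        fm = extract_features(rec, sim.beats_ref, sim.beats_det, sim.fiducials)
        meta = fm.meta
        lead1 = [n for n in fm.names if meta.loc[n, "lead"] == "lead1"]
        for n1 in lead1:
            n2 = n1.replace("__lead1", "__lead2")
            assert np.allclose(fm.values[n1], fm.values[n2]), (n1, n2)

    def test_csv_round_trip(self, matrix200, tmp_path):
        matrix200.to_csv(tmp_path / "fm.csv")
        back = FeatureMatrix.from_csv(tmp_path / "fm.csv")
        assert back.names == matrix200.names
        assert np.allclose(back.values.to_numpy(), matrix200.values.to_numpy())
        assert np.array_equal(back.missing_mask.to_numpy(),
                              matrix200.missing_mask.to_numpy())
        assert list(back.labels) == list(matrix200.labels)
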