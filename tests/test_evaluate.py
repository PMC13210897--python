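"""Beat matching, detection metrics, and HR agreement statistics."""
import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from scgbeat.datatypes import BeatAnnotation
from scgbeat.evaluate import (
    detection_metrics,
    hr_agreement,
    match_beats,
)
from scgbeat.heart_rate import HrSeries


def _beats(times):
    return BeatAnnotation(np.asarray(times, dtype=float))


class TestMatching:
    def test_within_tolerance_is_true_positive(self):
        m = match_beats(_beats([1.05]), _beats([1.00]), 0.1)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_outside_tolerance_counts_both_errors(self):
        m = match_beats(_beats([1.15]), _beats([1.00]), 0.1)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_one_to_one_enforced(self):
        m = match_beats(_beats([1.0, 1.05]), _beats([1.0]), 0.1)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_tolerance_boundary_inclusive(self):
        m = match_beats(_beats([1.1]), _beats([1.0]), 0.1)
        assert m.tp == 1

    def test_greedy_equals_maximum_matching_on_valid_spacing(self, rng):
        # with reference spacing > 2x tolerance, the chronological greedy
        # matcher attains maximum-cardinality one-to-one matching
        tol = 0.1
        for _ in range(500):
            n_ref = int(rng.integers(0, 12))
            gaps = rng.uniform(2 * tol + 0.01, 1.0, size=n_ref)
            ref = np.cumsum(gaps)
            n_pred = int(rng.integers(0, 12))
            hi = ref[-1] + 0.2 if n_ref else 1.0
            pred = np.sort(rng.uniform(-0.2, hi, n_pred))
            if pred.size:
                pred = pred[np.concatenate([[True], np.diff(pred) > 1e-9])]
            pred = pred[pred >= 0]
            m = match_beats(_beats(pred), _beats(ref), tol)
            # brute-force maximum bipartite matching on the feasible pairs
            rows, cols = [], []
            for i, tp_ in enumerate(pred):
                for j, tr in enumerate(ref):
                    if abs(tp_ - tr) <= tol:
                        rows.append(i)
                        cols.append(j)
            if rows:
                graph = csr_matrix(
                    (np.ones(len(rows)), (rows, cols)),
                    shape=(len(pred), len(ref)),
                )
                perm = maximum_bipartite_matching(graph, perm_type="column")
                max_card = int(np.sum(perm >= 0))
            else:
                max_card = 0
            assert m.tp == max_card


class TestMetrics:
    def test_formulae(self):
        m = match_beats(_beats([]), _beats([]), 0.1)
        m.tp, m.fp, m.fn = 9, 1, 1
        dm = detection_metrics(m)
        assert dm.ppv == pytest.approx(0.9)
        assert dm.sensitivity == pytest.approx(0.9)
        assert dm.f1 == pytest.approx(0.9)

    def test_perfect_detection(self):
        m = match_beats(_beats([1.0, 2.0]), _beats([1.0, 2.0]), 0.1)
        dm = detection_metrics(m)
        assert dm.ppv == dm.sensitivity == dm.f1 == 1.0

    def test_undefined_ppv_reported_as_none(self):
        m = match_beats(_beats([]), _beats([1.0]), 0.1)
        dm = detection_metrics(m)
        assert dm.ppv is None
        assert dm.sensitivity == 0.0

    def test_f1_between_ppv_and_sensitivity(self, rng):
        for _ in range(50):
            tp = int(rng.integers(1, 50))
            fp = int(rng.integers(0, 20))
            fn = int(rng.integers(0, 20))
            m = match_beats(_beats([]), _beats([]), 0.1)
            m.tp, m.fp, m.fn = tp, fp, fn
            dm = detection_metrics(m)
            assert min(dm.ppv, dm.sensitivity) - 1e-12 <= dm.f1
            assert dm.f1 <= max(dm.ppv, dm.sensitivity) + 1e-12


def _hr(centers, values):
    values = np.asarray(values, dtype=float)
    return HrSeries(np.asarray(centers, dtype=float), values,
                    np.where(np.isfinite(values), 1.0, 0.0))


class TestAgreement:
    def test_identical_series(self):
        c = np.arange(10) * 20.0 + 10.0
        v = 60 + 5 * np.sin(np.arange(10))
        s = hr_agreement(_hr(c, v), _hr(c, v))
        assert s.mae_bpm == 0 and s.rmse_bpm == 0 and s.bias_bpm == 0
        assert s.pearson_r == pytest.approx(1.0)

    def test_zero_variance_gives_undefined_r(self):
        c = np.arange(5) * 20.0
        s = hr_agreement(_hr(c, [60.0] * 5), _hr(c, [60.0] * 5))
        assert s.pearson_r is None
        assert s.mae_bpm == 0

    def test_constant_offset(self):
        c = np.arange(6) * 20.0
        ref = 60 + np.arange(6.0)
        s = hr_agreement(_hr(c, ref + 2.0), _hr(c, ref))
        assert s.mae_bpm == pytest.approx(2.0)
        assert s.rmse_bpm == pytest.approx(2.0)
        assert s.bias_bpm == pytest.approx(2.0)
        assert s.see_bpm == pytest.approx(0.0, abs=1e-9)
        assert s.loa_low_bpm == pytest.approx(2.0)
        assert s.loa_high_bpm == pytest.approx(2.0)

    def test_matches_naive_reference_computation(self, rng):
        c = np.arange(100) * 20.0
        e = 60 + 10 * rng.random(100)
        r = 60 + 10 * rng.random(100)
        s = hr_agreement(_hr(c, e), _hr(c, r))
        d = e - r
        assert s.mae_bpm == pytest.approx(np.mean(np.abs(d)), abs=1e-10)
        assert s.rmse_bpm == pytest.approx(np.sqrt(np.mean(d**2)), abs=1e-10)
        assert s.bias_bpm == pytest.approx(np.mean(d), abs=1e-10)
        sd = np.std(d, ddof=1)
        assert s.loa_low_bpm == pytest.approx(np.mean(d) - 1.96 * sd, abs=1e-10)
        assert s.loa_high_bpm == pytest.approx(np.mean(d) + 1.96 * sd, abs=1e-10)
        r_naive = np.corrcoef(e, r)[0, 1]
        assert s.pearson_r == pytest.approx(r_naive, abs=1e-10)

    def test_swapping_series_negates_bias(self, rng):
        c = np.arange(30) * 20.0
        e = 60 + 10 * rng.random(30)
        r = 60 + 10 * rng.random(30)
        s1 = hr_agreement(_hr(c, e), _hr(c, r))
        s2 = hr_agreement(_hr(c, r), _hr(c, e))
        assert s1.bias_bpm == pytest.approx(-s2.bias_bpm)
        assert s1.mae_bpm == pytest.approx(s2.mae_bpm)
        assert s1.rmse_bpm == pytest.approx(s2.rmse_bpm)
        assert s1.pearson_r == pytest.approx(s2.pearson_r)

    def test_undefined_windows_excluded_from_agreement(self):
        c = np.arange(4) * 20.0
        est = _hr(c, [60.0, np.nan, 62.0, 64.0])
        ref = _hr(c, [61.0, 60.0, np.nan, 64.0])
        s = hr_agreement(est, ref)
        assert s.n == 2  # only windows defined in both series

    def test_too_few_common_windows_undefined(self):
        assert hr_agreement(_hr([10.0], [60.0]), _hr([10.0], [60.0])) is None
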