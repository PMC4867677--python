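"""BVS bracket scoring, elemental brain scores, group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import neurovitals as nv
from neurovitals.normative import BEST_DIRECTION, NormativeStats


def _stats(mu=10.0, sigma=2.0, lo=None, hi=None, best=None, measure_id="P300_amplitude"):
    lo = mu - 4 * sigma if lo is None else lo
    hi = mu + 4 * sigma if hi is None else hi
    best = hi if best is None else best
    return NormativeStats(measure_id=measure_id, mu=mu, sigma=sigma, min=lo, max=hi,
                          best=best, n_kept=100, n_removed=0)


class TestMeasurePoints:
    @pytest.mark.parametrize(
        "kind, component, z_offset, expected",
        [
            # P300 amplitude: penalize the low tail
            ("amplitude", "P300", 0.0, 5),
            ("amplitude", "P300", -0.99, 5),
            ("amplitude", "P300", -1.0, 4),   # boundary -> lower score
            ("amplitude", "P300", -1.2, 4),
            ("amplitude", "P300", -1.7, 3),
            ("amplitude", "P300", -2.2, 2),
            ("amplitude", "P300", -3.0, 1),
            # N100/N400 amplitude: mirrored, penalize the positive tail
            ("amplitude", "N400", 0.0, 5),
            ("amplitude", "N400", 1.0, 4),
            ("amplitude", "N400", 2.2, 2),
            ("amplitude", "N400", 2.5, 1),
            ("amplitude", "N100", -3.0, 5),
            # latency: penalize the slow tail
            ("latency", "P300", 0.0, 5),
            ("latency", "P300", 1.2, 4),
            ("latency", "P300", 1.5, 3),
            ("latency", "N400", 2.0, 2),
            ("latency", "N100", 2.5, 1),
        ],
    )
    def test_bracket_examples(self, kind, component, z_offset, expected):
        st_ = _stats(mu=0.0, sigma=1.0)
        assert nv.measure_points(z_offset, st_, kind, component) == expected

    def test_nonfinite_value_rejected(self):
        with pytest.raises(ValueError):
            nv.measure_points(np.nan, _stats(), "amplitude", "P300")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            nv.measure_points(1.0, _stats(), "power", "P300")

    @given(z=st.floats(-6, 6), sigma=st.floats(0.5, 30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_bad_direction(self, z, sigma):
        """Points never increase as a measure moves further into the bad tail."""
        st_ = _stats(mu=100.0, sigma=sigma)
        step = 0.25 * sigma
        for kind, component, bad_sign in [
            ("amplitude", "P300", -1.0),
            ("amplitude", "N400", +1.0),
            ("latency", "P300", +1.0),
        ]:
            value = 100.0 + z * sigma
            worse = value + bad_sign * step
            assert (nv.measure_points(worse, st_, kind, component)
                    <= nv.measure_points(value, st_, kind, component))


class TestEbs:
    def test_best_scores_one(self):
        st_ = _stats(lo=0.0, hi=20.0, best=20.0)
        assert nv.ebs(20.0, st_) == 1.0

    def test_full_range_distance_scores_zero(self):
        st_ = _stats(lo=0.0, hi=20.0, best=20.0)
        assert nv.ebs(0.0, st_) == 0.0

    def test_latency_midpoint_scores_half(self):
        st_ = _stats(mu=300.0, sigma=20.0, lo=250.0, hi=350.0, best=250.0,
                     measure_id="P300_latency")
        assert nv.ebs(300.0, st_) == pytest.approx(0.5)

    def test_clamped_outside_normative_span(self):
        st_ = _stats(lo=0.0, hi=20.0, best=20.0)
        assert nv.ebs(-30.0, st_) == 0.0

    def test_degenerate_range_rejected(self):
        st_ = _stats()
        st_.max = st_.min = st_.best = 5.0
        with pytest.raises(ValueError):
            nv.ebs(5.0, st_)

    @given(m=st.floats(-50, 50), scale=st.floats(0.1, 100), shift=st.floats(-1000, 1000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_unit_invariance(self, m, scale, shift):
        """Consistent unit changes leave the score unchanged."""
        st_raw = _stats(mu=0.0, sigma=10.0, lo=-40.0, hi=40.0, best=40.0)
        st_scaled = _stats(mu=shift, sigma=10 * scale, lo=-40 * scale + shift,
                           hi=40 * scale + shift, best=40 * scale + shift)
        assert nv.ebs(m, st_raw) == pytest.approx(nv.ebs(m * scale + shift, st_scaled), abs=1e-9)


def _normative_db(mu_sigma=None):
    """Synthetic database with convenient mu/sigma per measure."""
    defaults = {
        "N100_amplitude": (-6.74, 2.13), "N100_latency": (100.0, 10.0),
        "P300_amplitude": (11.09, 3.39), "P300_latency": (276.0, 20.59),
        "N400_amplitude": (-5.93, 3.60), "N400_latency": (460.67, 65.11),
    }
    mu_sigma = mu_sigma or defaults
    measures = {}
    for mid, (mu, sigma) in mu_sigma.items():
        lo, hi = mu - 3 * sigma, mu + 3 * sigma
        best = lo if BEST_DIRECTION[mid] == "min" else hi
        measures[mid] = NormativeStats(measure_id=mid, mu=mu, sigma=sigma, min=lo, max=hi,
                                       best=best, n_kept=100, n_removed=0)
    return {"source": "synthetic-unit", "measures": measures}


class TestTotalBvs:
    def test_all_measures_at_means_score_thirty(self):
        db = _normative_db()
        values = {mid: st.mu for mid, st in db["measures"].items()}
        report = nv.total_bvs(values, db)
        assert report.subscores == {"A": 10, "B": 10, "C": 10}
        assert report.total == 30
        assert report.complete

    def test_one_slow_latency_scores_twenty_nine(self):
        db = _normative_db()
        values = {mid: st.mu for mid, st in db["measures"].items()}
        st_lat = db["measures"]["P300_latency"]
        values["P300_latency"] = st_lat.mu + 1.2 * st_lat.sigma
        assert nv.total_bvs(values, db).total == 29

    def test_extreme_tails_score_six(self):
        db = _normative_db()
        values = {}
        for mid, st_ in db["measures"].items():
            bad = -1.0 if mid == "P300_amplitude" else 1.0
            values[mid] = st_.mu + bad * 5.0 * st_.sigma
        assert nv.total_bvs(values, db).total == 6

    def test_missing_component_yields_partial_report(self):
        db = _normative_db()
        values = {mid: st.mu for mid, st in db["measures"].items()}
        del values["N400_latency"]
        report = nv.total_bvs(values, db)
        assert not report.complete
        assert report.total is None
        assert report.missing == ["N400_latency"]

    def test_total_range_and_top_score_condition(self):
        rng = np.random.default_rng(2)
        db = _normative_db()
        for _ in range(100):
            values = {mid: st_.mu + rng.normal(0, 3) * st_.sigma
                      for mid, st_ in db["measures"].items()}
            report = nv.total_bvs(values, db)
            assert 6 <= report.total <= 30
            if report.total == 30:
                assert all(p == 5 for p in report.points.values())


class TestGroupComparisons:
    def test_p300_latency_from_published_summaries(self):
        t, df, p = nv.compare_groups_from_summaries(276.00, 20.59, 6, 310.00, 15.02, 6)
        assert df == 10
        assert round(p, 3) == 0.008

    def test_equal_means_give_t_zero_p_one(self):
        t, _, p = nv.compare_groups_from_summaries(10.0, 2.0, 6, 10.0, 3.0, 6)
        assert t == 0.0 and p == 1.0

    def test_n400_latency_from_published_summaries(self):
        _, _, p = nv.compare_groups_from_summaries(460.67, 65.11, 6, 516.67, 57.53, 6)
        assert p == pytest.approx(0.145, abs=0.005)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nv.compare_groups_from_summaries(1.0, 0.0, 6, 2.0, 1.0, 6)
        with pytest.raises(ValueError):
            nv.compare_groups_from_summaries(1.0, 1.0, 1, 2.0, 1.0, 6)

    def test_null_p_values_uniform(self):
        """Same-distribution Gaussian samples give calibrated p-values."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            a, b = rng.standard_normal(12), rng.standard_normal(12)
            _, p, test = nv.compare_groups(a, b)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_skewed_sample_takes_ranksum_branch(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.standard_normal(30) * 2.0)  # heavy lognormal
        b = rng.standard_normal(30)
        _, _, test = nv.compare_groups(a, b)
        assert test == "rank-sum"

    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p, _ = nv.compare_groups(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            nv.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
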