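"""Quantile edges, shift estimation, replicate averaging, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import edgeshift as es
from edgeshift.edge_shift import EdgeEstimate, _order_index


def check_loss_quantile(values, tau):
    """Independent oracle: grid search of the check loss over data points.

    The minimizer of sum rho_tau(y - q) over constants is attained at a
    data point; scanning sorted unique values and keeping the smallest
    minimizer reproduces the lower endpoint of a flat minimum.
    """
    y = np.asarray(values, dtype=float)
    best_q, best_loss = None, np.inf
    for q in np.sort(np.unique(y)):
        u = y - q
        loss = np.sum(u * (tau - (u < 0)))
        if loss < best_loss - 1e-12:
            best_q, best_loss = q, loss
    return best_q


class TestQuantileEdge:
    def test_constant_sample(self):
        assert es.quantile_edge([5, 5, 5], 0.9) == 5

    def test_fractional_rank_rounds_up(self):
        assert es.quantile_edge(range(1, 11), 0.75) == 8

    def test_integer_rank_takes_lower_endpoint(self):
        assert es.quantile_edge(range(1, 11), 0.9) == 9

    def test_rejects_empty_and_bad_tau(self):
        with pytest.raises(ValueError):
            es.quantile_edge([], 0.9)
        with pytest.raises(ValueError):
            es.quantile_edge([1.0], 1.0)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.lists(st.integers(1, 6), min_size=1, max_size=12),
        st.sampled_from([0.5, 0.75, 0.9]),
    )
    def test_matches_check_loss_oracle(self, values, tau):
        assert es.quantile_edge(values, tau) == check_loss_quantile(values, tau)


class TestEstimateShift:
    def test_uniform_translation_recovered(self):
        t1 = np.arange(1, 11) * 1000.0
        t2 = np.arange(11, 21) * 1000.0
        e = es.estimate_shift(t1, t2, 0.9, ci="none")
        assert e.edge_T1_m == 9000.0 and e.edge_T2_m == 19000.0
        assert e.shift_km == pytest.approx(10.0)

    def test_identical_periods_shift_zero_ci_contains_zero(self):
        y = np.linspace(0, 1e5, 40)
        e = es.estimate_shift(y, y, 0.9, ci="bootstrap", B=200, seed=1)
        assert e.shift_km == 0.0
        assert e.ci_low_km <= 0.0 <= e.ci_high_km

    def test_swapping_periods_negates_shift(self):
        rng = np.random.default_rng(2)
        y1, y2 = rng.uniform(0, 1e6, 30), rng.uniform(0, 1e6, 30)
        fwd = es.estimate_shift(y1, y2, 0.9, ci="none")
        rev = es.estimate_shift(y2, y1, 0.9, ci="none")
        assert fwd.shift_km == -rev.shift_km

    def test_support_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="support"):
            es.estimate_shift([1.0] * 4, [1.0] * 10, 0.9)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        e = es.estimate_shift(
            rng.uniform(0, 1e6, 25), rng.uniform(0, 1e6, 25), 0.9, B=300, seed=4
        )
        assert e.ci_low_km <= e.shift_km <= e.ci_high_km

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        y1, y2 = rng.uniform(0, 1e6, 20), rng.uniform(0, 1e6, 20)
        a = es.estimate_shift(y1, y2, 0.9, B=100, seed=6)
        b = es.estimate_shift(y1, y2, 0.9, B=100, seed=6)
        assert a == b

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=5, max_size=20),
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=5, max_size=20),
        st.floats(-1e5, 1e5, allow_nan=False),
    )
    def test_shift_invariant_to_translation(self, y1, y2, c):
        base = es.estimate_shift(y1, y2, 0.75, ci="none")
        moved = es.estimate_shift(
            np.asarray(y1) + c, np.asarray(y2) + c, 0.75, ci="none"
        )
        assert moved.shift_km == pytest.approx(base.shift_km, abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=5, max_size=20),
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=5, max_size=20),
        st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_shift_equivariant_under_scaling(self, y1, y2, a):
        base = es.estimate_shift(y1, y2, 0.75, ci="none")
        scaled = es.estimate_shift(
            np.asarray(y1) * a, np.asarray(y2) * a, 0.75, ci="none"
        )
        assert scaled.shift_km == pytest.approx(a * base.shift_km, rel=1e-9, abs=1e-9)


def _estimate(shift, lo, hi, species="s", tau=0.9):
    return EdgeEstimate(species, tau, 0.0, shift * 1000, shift, lo, hi, 10, 10)


class TestAverageReplicates:
    def test_arithmetic_means(self):
        out = es.average_replicates([_estimate(10, 5, 15), _estimate(20, 15, 25)])
        assert (out.shift_km, out.ci_low_km, out.ci_high_km) == (15, 10, 20)
        assert out.n_replicates == 2

    def test_single_replicate_identity(self):
        e = _estimate(7, 3, 11)
        out = es.average_replicates([e])
        assert (out.shift_km, out.ci_low_km, out.ci_high_km) == (7, 3, 11)

    def test_identical_replicates_idempotent(self):
        out = es.average_replicates([_estimate(7, 3, 11)] * 5)
        assert (out.shift_km, out.ci_low_km, out.ci_high_km) == (7, 3, 11)

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError):
            es.average_replicates([_estimate(1, 0, 2, "a"), _estimate(1, 0, 2, "b")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.average_replicates([])


class TestClassifyShift:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(2, 8, "northward"), (-3, 5, "none"), (-8, -2, "southward")],
    )
    def test_classification_by_ci(self, lo, hi, expected):
        assert es.classify_shift(_estimate((lo + hi) / 2, lo, hi)) == expected


class TestSummarizeShifts:
    def _taxon_table(self):
        rows = []
        for group, mean, n in [("moth", 24.4, 239), ("butterfly", 43.1, 57),
                               ("bird", 33.2, 87)]:
            rows += [{"species_id": f"{group}{i}", "group": group,
                      "shift_km": mean} for i in range(n)]
        return pd.DataFrame(rows)

    def test_count_weighted_overall_mean(self):
        out = es.summarize_shifts(self._taxon_table())
        overall = out.loc[out["group"] == "overall", "mean_shift_km"].iloc[0]
        assert overall == pytest.approx(29.2, abs=0.05)

    def test_bird_speed_from_midyears(self):
        out = es.summarize_shifts(
            self._taxon_table(),
            midyears={"bird": (1981.5, 2008.0), "moth": (1994.0, 2015.0),
                      "butterfly": (1994.0, 2015.0)},
        )
        bird = out.loc[out["group"] == "bird"].iloc[0]
        assert bird["speed_km_per_yr"] == pytest.approx(1.25, abs=0.005)

    def test_zero_shifts_zero_summary(self):
        df = pd.DataFrame(
            {"species_id": ["a", "b"], "group": ["g", "g"], "shift_km": [0.0, 0.0]}
        )
        out = es.summarize_shifts(df, midyears={"g": (1994.0, 2015.0)})
        assert (out["mean_shift_km"] == 0).all()
        assert (out.loc[out["group"] == "g", "speed_km_per_yr"] == 0).all()

    def test_bad_midyears_rejected(self):
        df = pd.DataFrame(
            {"species_id": ["a"], "group": ["g"], "shift_km": [1.0]}
        )
        with pytest.raises(ValueError, match="midyears"):
            es.summarize_shifts(df, midyears={"g": (2015.0, 1994.0)})


class TestEstimateShiftsTable:
    def test_low_support_species_reported(self):
        pres = pd.DataFrame(
            {
                "species_id": ["a"] * 12 + ["b"] * 3,
                "cell_id": range(15),
                "easting_m": 0.0,
                "northing_m": np.r_[np.linspace(0, 1e5, 12), [0, 1, 2]],
                "period": ["T1"] * 6 + ["T2"] * 6 + ["T1", "T2", "T2"],
            }
        )
        report = {}
        out = es.estimate_shifts_table([pres], ci="none", report=report)
        assert set(out["species_id"]) == {"a"}
        assert report["skipped_low_support"] == ["b"]
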