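"""Rating deltas, the Phi-based feeling score, and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phistress.exceptions import ReliabilityError
from phistress.scores import (
    binned_phase_means,
    correlate_scores,
    phi_feeling_score,
    rating_deltas,
    valence_composites,
)
from phistress.synthetic import CONDITIONS, PHASES, RATING_ITEMS

from .conftest import make_series_stub


def full_ratings(value_fn):
    rows = []
    for p in ("P01", "P02"):
        for c in CONDITIONS:
            for ph in PHASES:
                for item in RATING_ITEMS:
                    rows.append((p, c, ph, item, value_fn(p, c, ph, item)))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "phase", "item", "value"]
    )


class TestRatingDeltas:
    def test_equal_phases_leave_only_baseline_offset(self):
        # r = 0 everywhere except Moderate where Task - Pre = 7 -> dr = -7
        def fn(p, c, ph, item):
            return 50.0 + (7.0 if (c == "Moderate" and ph == "Task") else 0.0)

        out = rating_deltas(full_ratings(fn))
        non_base = out[out["condition"] != "Moderate"]
        assert np.allclose(non_base["r"], 0.0)
        assert np.allclose(non_base["dr"], -7.0)

    def test_baseline_condition_has_zero_dr(self):
        rng = np.random.default_rng(0)
        out = rating_deltas(full_ratings(lambda *a: float(rng.uniform(0, 100))))
        base = out[out["condition"] == "Moderate"]
        assert np.allclose(base["dr"], 0.0)

    def test_planted_offsets_recovered_exactly(self):
        offsets = {"Easy": 12.0, "Moderate": 0.0, "Difficult": -5.0}

        def fn(p, c, ph, item):
            return 40.0 + (offsets[c] if ph == "Task" else 0.0)

        out = rating_deltas(full_ratings(fn))
        for cond, off in offsets.items():
            sub = out[out["condition"] == cond]
            assert np.allclose(sub["dr"], off - offsets["Moderate"])

    def test_missing_phase_yields_nan_not_zero(self):
        table = full_ratings(lambda *a: 50.0)
        table = table[
            ~(
                (table.participant == "P01")
                & (table.condition == "Easy")
                & (table.phase == "Pre")
            )
        ]
        out = rating_deltas(table)
        row = out[(out.participant == "P01") & (out.condition == "Easy")]
        assert row["r"].isna().all() and row["dr"].isna().all()

    def test_row_order_independence(self):
        rng = np.random.default_rng(1)
        table = full_ratings(lambda *a: float(rng.uniform(0, 100)))
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = rating_deltas(table).sort_values(["participant", "condition", "item"])
        b = rating_deltas(shuffled).sort_values(["participant", "condition", "item"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_value_range_and_duplicates_validated(self):
        bad = full_ratings(lambda *a: 101.0)
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            rating_deltas(bad)
        dup = pd.concat([full_ratings(lambda *a: 1.0)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            rating_deltas(dup)


class TestFeelingScore:
    def test_identical_series_scores_zero(self):
        s = make_series_stub(np.linspace(-1, 1, 20))
        sc = phi_feeling_score(s, make_series_stub(np.linspace(-1, 1, 20)), 5, 100)
        assert sc.si == 0.0

    def test_constant_difference_sums_linearly(self):
        a = make_series_stub(np.full(30, 0.75))
        b = make_series_stub(np.full(30, 0.25))
        sc = phi_feeling_score(a, b, 5.0, 5.0 + 29 * 5.0)
        assert sc.n_windows_used == 30
        assert sc.si == pytest.approx(30 * 0.5)

    def test_antisymmetry_under_series_swap(self):
        rng = np.random.default_rng(2)
        x, m = rng.standard_normal(25), rng.standard_normal(25)
        si_xm = phi_feeling_score(make_series_stub(x), make_series_stub(m), 5, 200).si
        si_mx = phi_feeling_score(make_series_stub(m), make_series_stub(x), 5, 200).si
        assert si_xm == pytest.approx(-si_mx)

    def test_invariant_to_common_additive_shift(self):
        rng = np.random.default_rng(3)
        x, m = rng.standard_normal(25), rng.standard_normal(25)
        a = phi_feeling_score(make_series_stub(x), make_series_stub(m), 5, 200).si
        b = phi_feeling_score(
            make_series_stub(x + 3.3), make_series_stub(m + 3.3), 5, 200
        ).si
        assert a == pytest.approx(b, abs=1e-9)

    def test_skipped_windows_counted_and_limited(self):
        x = np.full(20, 1.0)
        x[:8] = np.nan
        sc = phi_feeling_score(make_series_stub(x), make_series_stub(np.zeros(20)), 5, 200)
        assert sc.n_windows_skipped == 8 and sc.n_windows_used == 12
        x[:11] = np.nan
        with pytest.raises(ReliabilityError):
            phi_feeling_score(make_series_stub(x), make_series_stub(np.zeros(20)), 5, 200)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="window grid"):
            phi_feeling_score(
                make_series_stub(np.zeros(10), spacing_s=5.0),
                make_series_stub(np.zeros(10), spacing_s=4.0),
                5,
                40,
            )


class TestValence:
    def test_zero_deltas_give_zero_composites(self):
        out = valence_composites(rating_deltas(full_ratings(lambda *a: 50.0)))
        assert np.allclose(out["positive"], 0.0)
        assert np.allclose(out["negative"], 0.0)

    def test_positive_triple_sums(self):
        vals = {"Exciting": 10.0, "Effort": 5.0, "Tiredness": 5.0}

        def fn(p, c, ph, item):
            if c == "Easy" and ph == "Task" and item in vals:
                return 50.0 + vals[item]
            return 50.0

        out = valence_composites(rating_deltas(full_ratings(fn)))
        easy = out[out["condition"] == "Easy"]
        assert np.allclose(easy["positive"], 20.0)
        assert np.allclose(easy["negative"], 0.0)

    def test_missing_component_propagates_nan(self):
        table = full_ratings(lambda *a: 50.0)
        table = table[table["item"] != "Boring"]
        out = valence_composites(rating_deltas(table))
        assert out["negative"].isna().all()
        assert np.allclose(out["positive"], 0.0)


class TestCorrelation:
    def test_perfect_linear_pair(self):
        res = correlate_scores([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6 or np.isnan(res.p) is False

    def test_t_statistic_formula(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(18)
        y = 0.6 * x + 0.8 * rng.standard_normal(18)
        res = correlate_scores(x, y)
        expect_t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.t == pytest.approx(expect_t)
        # p from the t distribution with n-2 dof matches scipy's exact p
        p_t = 2 * stats.t.sf(abs(res.t), res.n - 2)
        assert res.p == pytest.approx(p_t, rel=1e-6)

    def test_sampling_distribution_of_r_at_rho_06(self):
        # n = 18 draws from a rho = 0.6 bivariate normal: the mean estimate
        # over replicates sits inside the analytic sampling band
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(500):
            x = rng.standard_normal(18)
            y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(18)
            rs.append(correlate_scores(x, y).r)
        # E[r] ~ rho - rho(1-rho^2)/(2n): mild negative bias
        expect = 0.6 - 0.6 * (1 - 0.36) / (2 * 18)
        assert np.mean(rs) == pytest.approx(expect, abs=0.03)

    def test_null_calibration_at_five_percent(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.standard_normal(18)
            y = rng.standard_normal(18)
            hits += correlate_scores(x, y).p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate_scores([1, 2], [3, 4])
        res = correlate_scores([1.0, 1.0, 1.0], [1, 2, 3])
        assert not res.defined


class TestBinnedMeans:
    def test_constant_series_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            binned_phase_means(np.ones(100), np.arange(100.0), 10, (0, 50))

    def test_one_sd_task_shift_reads_as_plus_one(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 12000, 1.0)
        v = rng.standard_normal(len(t))
        v[t >= 6000] += 1.0
        out = binned_phase_means(v, t, bin_seconds=1500, baseline_range=(0, 6000))
        task = out[out["bin_start_s"] >= 6000]
        assert task["z"].mean() == pytest.approx(1.0, abs=0.1)

    def test_bin_width_equal_to_length_gives_single_bin(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(50)
        out = binned_phase_means(v, np.arange(50.0), bin_seconds=50.0,
                                 baseline_range=(0, 50))
        assert len(out) == 1
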