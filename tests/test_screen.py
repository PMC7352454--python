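"""Screen quantification: normalization, fold changes, slopes, IQR hit calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscreen import screen
from mirscreen.types import ValidationError

from conftest import make_screen_counts


def brute_force_slope(x, y, lo=None, hi=None, rounds=4, grid=2001):
    """Independent zero-intercept LS fit: refined grid search plus a final
    parabolic-vertex step (the SSE is exactly quadratic in the slope, so the
    vertex through three bracketing grid points is the minimizer)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def sse(b):
        return ((y - b * x) ** 2).sum()

    if lo is None:
        # a priori bound: |b*| <= sum|x||y| / sum x^2 for any LS minimizer
        bound = 1.0 + np.sum(np.abs(x) * np.abs(y)) / np.sum(x * x)
        lo, hi = -bound, bound
    for _ in range(rounds):
        bs = np.linspace(lo, hi, grid)
        vals = ((y[None, :] - bs[:, None] * x[None, :]) ** 2).sum(axis=1)
        best = bs[int(np.argmin(vals))]
        width = (hi - lo) / (grid - 1)
        lo, hi = best - 2 * width, best + 2 * width
    h = max(abs(best) * 1e-3, 1e-3)
    f_m, f_0, f_p = sse(best - h), sse(best), sse(best + h)
    denom = f_p - 2 * f_0 + f_m
    if denom == 0:
        return best
    return best - h / 2 * (f_p - f_m) / denom


class TestNormalizeTotals:
    def test_proportional_scaling(self):
        sc = make_screen_counts({"A": [10], "B": [30]}, days=[5])
        out = screen.normalize_totals(sc, 50_000)
        assert out.counts.iloc[:, 0].tolist() == [12_500.0, 37_500.0]

    def test_column_at_target_unchanged(self):
        sc = make_screen_counts({"A": [20_000], "B": [30_000]}, days=[5])
        out = screen.normalize_totals(sc, 50_000)
        assert out.counts.iloc[:, 0].tolist() == [20_000.0, 30_000.0]

    def test_zero_total_column_names_sample(self):
        sc = make_screen_counts({"A": [0, 5], "B": [0, 5]}, days=[5, 7])
        with pytest.raises(ValidationError, match="d5"):
            screen.normalize_totals(sc, 50_000)

    def test_every_column_sums_to_target(self, rng):
        vals = rng.integers(1, 1000, size=(30, 6))
        sc = make_screen_counts(
            {f"c{i}": row for i, row in enumerate(vals)}, days=[5, 7, 15], pcr_reps=2
        )
        out = screen.normalize_totals(sc, 20_000)
        assert np.allclose(out.counts.sum(axis=0), 20_000, rtol=1e-9)


class TestAveragePcrReplicates:
    def test_duplicate_mean(self):
        sc = make_screen_counts({"A": [100, 200]}, days=[5], pcr_reps=2)
        out = screen.average_pcr_replicates(sc)
        assert out.counts.shape[1] == 1
        assert out.counts.iloc[0, 0] == 150.0

    def test_triplicate_mean(self):
        sc = make_screen_counts({"A": [0, 3, 6]}, days=[5], pcr_reps=3)
        out = screen.average_pcr_replicates(sc)
        assert out.counts.iloc[0, 0] == 3.0

    def test_single_replicate_identity(self):
        sc = make_screen_counts({"A": [7, 9]}, days=[5, 7])
        out = screen.average_pcr_replicates(sc)
        assert out.counts.iloc[0].tolist() == [7.0, 9.0]


class TestFilterLowAbundance:
    def test_below_threshold_in_any_infection_excluded(self):
        # first-time-point averages 49 (infection 1) and 120 (infection 2)
        sc = make_screen_counts(
            {"A": [49, 100, 120, 100], "B": [80, 80, 80, 80]},
            days=[5, 7],
            infections=2,
        )
        kept, excluded = screen.filter_low_abundance(sc, min_reads=50)
        assert excluded == ["A"]
        assert kept.constructs == ["B"]

    def test_exactly_at_threshold_kept(self):
        sc = make_screen_counts({"A": [50, 10], "B": [60, 10]}, days=[5, 7])
        kept, excluded = screen.filter_low_abundance(sc, min_reads=50)
        assert excluded == []
        assert kept.constructs == ["A", "B"]


class TestAdaptFoldChange:
    def test_anchor_values(self):
        assert screen.adapt_fold_change(1.0) == 0.0
        assert screen.adapt_fold_change(2.0) == 1.0
        assert screen.adapt_fold_change(0.5) == -1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            screen.adapt_fold_change(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetric_under_inversion(self, f):
        a = screen.adapt_fold_change(f)
        b = screen.adapt_fold_change(1.0 / f)
        assert a == pytest.approx(-b, rel=1e-9, abs=1e-12)

    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_increasing(self, f, g):
        lo, hi = sorted([f, g])
        assert screen.adapt_fold_change(lo) <= screen.adapt_fold_change(hi)


class TestFitSlope:
    def test_flat_scores_give_zero(self):
        assert screen.fit_slope([0, 2, 10], [0, 0, 0]) == 0.0

    def test_exact_linear_recovered(self):
        x = np.array([0, 2, 10, 20, 35], float)
        assert screen.fit_slope(x, 0.1 * x) == pytest.approx(0.1)

    def test_example_matches_grid_search_oracle(self):
        x = np.array([0, 2, 10, 20, 35], float)
        y = np.array([0, 0.1, 0.8, 1.5, 3.1])
        assert screen.fit_slope(x, y) == pytest.approx(
            brute_force_slope(x, y, lo=-10, hi=10), abs=1e-6
        )

    def test_random_instances_match_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(2, 8)
            x = rng.normal(size=n) * 10
            y = rng.normal(size=n) * 5
            if np.sum(x * x) == 0:
                continue
            assert screen.fit_slope(x, y) == pytest.approx(
                brute_force_slope(x, y), abs=1e-8
            )

    def test_all_zero_offsets_rejected(self):
        with pytest.raises(ValidationError):
            screen.fit_slope([0, 0], [1, 2])


class TestIqrBounds:
    def test_hand_computed_quartiles(self):
        lo, hi = screen.iqr_bounds(np.arange(1, 9), k=1)
        assert (lo, hi) == (-0.75, 9.75)

    def test_constant_slopes_give_degenerate_bounds(self):
        lo, hi = screen.iqr_bounds(np.full(10, 3.2))
        assert lo == hi == 3.2

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            screen.iqr_bounds(np.array([1.0, 2.0, 3.0]))


class TestCallHits:
    def _slopes(self, values_by_construct):
        out = []
        for construct, per_inf in values_by_construct.items():
            for inf, slope in enumerate(per_inf, start=1):
                out.append(
                    screen.SlopeResult(construct, "CL", inf, slope, n_points=5)
                )
        return out

    def test_consistent_low_outlier_called_depleted(self):
        base = {f"n{i}": [v, v] for i, v in enumerate([-0.2, -0.1, 0.0, 0.1, 0.2, 0.05])}
        base["hit"] = [-5.0, -4.0]
        calls = {c.construct: c for c in screen.call_hits(self._slopes(base))}
        assert calls["hit"].direction == "depleted"
        assert calls["hit"].per_infection == {1: "below", 2: "below"}
        assert all(calls[f"n{i}"].direction == "none" for i in range(6))

    def test_inconsistent_infections_called_none(self):
        base = {f"n{i}": [v, v] for i, v in enumerate([-0.2, -0.1, 0.0, 0.1, 0.2, 0.05])}
        base["hit"] = [-5.0, 0.1]
        calls = {c.construct: c for c in screen.call_hits(self._slopes(base))}
        assert calls["hit"].direction == "none"

    def test_slope_exactly_at_bound_is_within(self):
        slopes = [
            screen.SlopeResult(c, "CL", 1, s, 5)
            for c, s in zip("abcdefgh", [1, 2, 3, 4, 5, 6, 7, 8])
        ]
        # bounds are (-0.75, 9.75); add a construct exactly at the upper bound
        slopes.append(screen.SlopeResult("edge", "CL", 1, 9.75, 5))
        lo, hi = screen.iqr_bounds(np.array([s.slope for s in slopes]))
        calls = {c.construct: c for c in screen.call_hits(slopes)}
        assert calls["edge"].per_infection[1] == "within"

    def test_mismatched_construct_sets_rejected(self):
        slopes = [
            screen.SlopeResult("a", "CL", 1, 0.0, 5),
            screen.SlopeResult("b", "CL", 2, 0.0, 5),
        ]
        with pytest.raises(ValidationError):
            screen.call_hits(slopes)


class TestPipeline:
    def test_fold_change_division(self):
        sc = make_screen_counts({"A": [80.0, 20.0], "B": [100.0, 200.0]}, days=[5, 7])
        fc = screen.fold_changes(sc)
        a = fc[(fc.construct == "A")].set_index("day")["fc"]
        assert a[5] == 1.0 and a[7] == 0.25
        b = fc[(fc.construct == "B")].set_index("day")["fc"]
        assert b[7] == 2.0

    def test_missing_baseline_rejected(self):
        sc = make_screen_counts({"A": [80.0, 20.0]}, days=[5, 7])
        with pytest.raises(ValidationError):
            screen.fold_changes(sc, baseline_day=4)

    def test_zero_later_count_gets_pseudocount(self):
        sc = make_screen_counts({"A": [100.0, 0.0], "B": [100.0, 50.0]}, days=[5, 7])
        fc = screen.fold_changes(sc)
        a7 = fc[(fc.construct == "A") & (fc.day == 7)]["fc"].item()
        assert a7 == 0.005  # 0.5 pseudocount / 100

    def test_end_to_end_recovers_planted_dropout(self):
        rng = np.random.default_rng(5)
        days = [5, 7, 15, 25, 40]
        counts = {}
        for i in range(20):
            counts[f"n{i}"] = [
                max(1, 800 + int(rng.normal(0, 25))) for _ in range(2 * len(days))
            ]
        counts["hit"] = [
            int(800 * 0.85 ** (d - 5)) for _ in range(2) for d in days
        ]
        sc = make_screen_counts(counts, days=days, infections=2)
        calls, slopes, excluded = screen.analyze_screen(sc, target_total=50_000)
        assert excluded == []
        by_name = {c.construct: c for c in calls}
        assert by_name["hit"].direction == "depleted"
        fp = sum(c.direction != "none" for c in calls if c.construct != "hit")
        assert fp <= 2
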