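import numpy as np
import pytest

from abstention.core import (
    EvaluationPoint,
    GridSpec,
    LabeledScores,
    classify_with_abstention,
    cost,
    fit_asymmetric,
    fit_symmetric,
    interval_from_params,
    pareto_front,
)
from abstention.metrics import REJECT

# the 20-point endpoint-inclusive anchor grid used throughout
ANCHORS = np.linspace(-0.2, 0.2, 20)


class TestInterval:
    @pytest.mark.parametrize(
        "anchor, half_width, lower, upper",
        [
            (0.0, 0.13, 0.37, 0.63),
            (ANCHORS[3], 0.10, 0.263, 0.463),  # asymmetric: 4th grid anchor
            (0.0, 0.0, 0.5, 0.5),
        ],
    )
    def test_bounds_formula(self, anchor, half_width, lower, upper):
        iv = interval_from_params(anchor, half_width)
        assert round(iv.lower, 3) == lower
        assert round(iv.upper, 3) == upper

    def test_negative_half_width_rejected(self):
        with pytest.raises(ValueError):
            interval_from_params(0.0, -0.01)

    def test_out_of_range_bounds_clip_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            iv = interval_from_params(0.4, 0.2)
        assert iv.upper == 1.0 and iv.lower == pytest.approx(0.7)


class TestClassify:
    def test_three_regions(self):
        iv = interval_from_params(0.0, 0.13)
        assert classify_with_abstention([0.1, 0.5, 0.9], iv).tolist() == [0, REJECT, 1]

    def test_boundary_scores_are_classified_not_rejected(self):
        iv = interval_from_params(0.0, 0.13)
        assert classify_with_abstention([0.37, 0.63], iv).tolist() == [0, 1]

    def test_interior_score_rejected(self):
        iv = interval_from_params(ANCHORS[7], 0.02)  # [0.427, 0.467]
        assert classify_with_abstention([0.45], iv).tolist() == [REJECT]

    def test_zero_width_is_plain_threshold(self):
        iv = interval_from_params(0.0, 0.0)
        assert classify_with_abstention([0.49, 0.5, 0.51], iv).tolist() == [0, 1, 1]


class TestCost:
    def test_no_abstention_identity(self, make_scores):
        s = make_scores(seed=0)
        m, f = cost(s, anchor=0.0, half_width=0.0)
        assert f == 1.0
        # equal to plain thresholding at 0.5
        from abstention.metrics import count_confusion, mcc
        preds = (s.scores >= 0.5).astype(int)
        assert m == pytest.approx(mcc(count_confusion(s.labels, preds)))

    def test_hand_evaluated_case(self):
        s = LabeledScores([0.2, 0.8, 0.55, 0.45], [0, 1, 0, 1])
        m, f = cost(s, anchor=0.0, half_width=0.1)
        assert (m, f) == (1.0, 0.5)

    def test_separated_scores_keep_full_coverage(self):
        s = LabeledScores([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], [0, 0, 0, 1, 1, 1])
        assert cost(s, 0.0, 0.05) == (1.0, 1.0)

    @pytest.mark.parametrize("half_width", [-0.01, 0.51])
    def test_half_width_range_check(self, half_width, make_scores):
        with pytest.raises(ValueError):
            cost(make_scores(seed=1), 0.0, half_width)


class TestGridSpec:
    def test_default_half_width_grid_stops_below_high(self):
        widths = GridSpec().half_widths()
        assert len(widths) == 16
        assert widths[0] == 0.0 and widths[-1] == pytest.approx(0.15)

    def test_replication_anchor_grid_has_endpoints_and_no_zero(self):
        a = GridSpec.replication_profile().anchors()
        assert len(a) == 20
        assert a[0] == -0.2 and a[-1] == 0.2
        assert not np.any(a == 0.0)

    def test_zero_anchor_injected_by_default(self):
        a = GridSpec().anchors()
        assert len(a) == 21 and np.any(a == 0.0)
        assert np.all(np.diff(a) > 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(interval_low=0.2, interval_high=0.1),
            dict(interval_step=0.0),
            dict(num_anchors=0),
            dict(interval_high=0.6),
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)


class TestOptimizers:
    def test_symmetric_evaluates_whole_grid_at_zero_anchor(self, make_scores):
        res = fit_symmetric(make_scores(seed=3))
        assert len(res.grid) == 16
        assert all(p.anchor == 0.0 for p in res.grid)
        assert res.interval.lower + res.interval.upper == pytest.approx(1.0)

    def test_separable_scores_choose_zero_width(self):
        s = LabeledScores([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], [0, 0, 0, 1, 1, 1])
        res = fit_symmetric(s)
        assert res.best.half_width == 0.0
        assert res.best.objective == 1.0

    def test_replication_grid_cardinality(self, make_scores):
        res = fit_asymmetric(make_scores(seed=4), GridSpec.replication_profile())
        assert len(res.grid) == 16 * 20

    def test_objective_is_product_of_mcc_and_size(self, make_scores):
        res = fit_asymmetric(make_scores(seed=5))
        for p in res.grid:
            assert p.objective == p.mcc * p.size_fraction

    def test_asymmetric_with_single_zero_anchor_equals_symmetric(self, make_scores):
        s = make_scores(seed=6)
        g = GridSpec(anchor_width=0.0, num_anchors=1)
        assert fit_asymmetric(s, g) == fit_symmetric(s)

    def test_asymmetric_dominates_symmetric_when_zero_anchor_present(self, make_scores):
        for seed in range(5):
            s = make_scores(seed=seed)
            assert fit_asymmetric(s).best.objective >= fit_symmetric(s).best.objective

    def test_best_point_belongs_to_grid_and_is_argmax(self, make_scores):
        res = fit_asymmetric(make_scores(seed=7))
        assert res.best in res.grid
        assert res.best.objective == max(p.objective for p in res.grid)

    def test_best_not_strictly_dominated_by_front(self, make_scores):
        res = fit_asymmetric(make_scores(seed=8))
        for p in res.pareto_front:
            assert not (p.mcc > res.best.mcc and p.size_fraction > res.best.size_fraction)

    def test_deterministic_across_runs(self, make_scores):
        s = make_scores(seed=9)
        assert fit_asymmetric(s) == fit_asymmetric(s)

    def test_empty_grid_errors(self, make_scores):
        s = make_scores(seed=10)
        from abstention.core import _fit
        with pytest.raises(ValueError):
            _fit(s, np.array([]), np.array([0.0]))

    def test_coverage_monotone_and_rejected_sets_nested(self, make_scores):
        for seed in range(10):
            s = make_scores(seed=seed, n=150)
            for anchor in (-0.1, 0.0, 0.07):
                previous = None
                prev_frac = None
                for w in GridSpec().half_widths():
                    preds = classify_with_abstention(s, interval_from_params(anchor, w))
                    rejected = set(np.flatnonzero(preds == REJECT).tolist())
                    frac = 1 - len(rejected) / len(s)
                    if previous is not None:
                        assert previous <= rejected
                        assert frac <= prev_frac
                    previous, prev_frac = rejected, frac


def _brute_front(points):
    out = []
    for p in points:
        dominated = any(
            (q.mcc >= p.mcc and q.size_fraction >= p.size_fraction)
            and (q.mcc > p.mcc or q.size_fraction > p.size_fraction)
            for q in points
        )
        if not dominated:
            out.append(p)
    return out


class TestPareto:
    def _point(self, m, f):
        return EvaluationPoint(0.0, 0.0, m, f, m * f)

    def test_dominated_point_dropped(self):
        pts = [self._point(0.5, 1.0), self._point(0.9, 0.8), self._point(0.4, 0.9)]
        front = pareto_front(pts)
        assert {(p.mcc, p.size_fraction) for p in front} == {(0.5, 1.0), (0.9, 0.8)}

    def test_single_point_is_its_own_front(self):
        pts = [self._point(0.3, 0.4)]
        assert pareto_front(pts) == pts

    def test_sorted_by_coverage_descending(self, make_scores):
        front = fit_asymmetric(make_scores(seed=11)).pareto_front
        assert all(a.size_fraction >= b.size_fraction for a, b in zip(front, front[1:]))

    def test_matches_pairwise_domination_oracle_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            pts = [self._point(m, f) for m, f in rng.random((100, 2))]
            assert set(map(id, pareto_front(pts))) == set(map(id, _brute_front(pts)))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            pareto_front([])
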