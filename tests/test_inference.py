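import numpy as np
import pandas as pd
import pytest

import dynflux as dx
from dynflux.inference import (
    Bin,
    BinDatabase,
    BinMember,
    InferenceError,
    Pair,
    PairSet,
)

from conftest import v3_truth


def _series(dataset_id, t, **cols):
    return dx.TimeSeries(dataset_id, np.asarray(t, float), pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# equation selection
# ---------------------------------------------------------------------------

class TestSelectTargetEquation:
    def test_branched_prefers_the_two_flux_equation(self):
        ranked = dx.select_target_equation(dx.branched_system().topology)
        assert ranked[0].metabolite == "X3"
        assert set(ranked[0].fluxes) == {"v3", "v4"}

    def test_linear_chain_ties_break_by_equation_order(self):
        ranked = dx.select_target_equation(dx.linear_feedback_system().topology)
        assert [c.metabolite for c in ranked] == ["X1", "X2", "X3"]
        assert all(c.eligible for c in ranked)

    def test_no_two_flux_equation_raises(self):
        spec = dict(
            metabolites=["A", "B"],
            fluxes=[
                {"name": "u", "depends_on": ["A"]},
                {"name": "v", "depends_on": ["A"]},
                {"name": "w", "depends_on": ["B"]},
            ],
            equations={
                "A": [
                    {"flux": "u", "coeff": 1},
                    {"flux": "v", "coeff": -1},
                    {"flux": "w", "coeff": -1},
                ],
                "B": [
                    {"flux": "u", "coeff": 1},
                    {"flux": "v", "coeff": 1},
                    {"flux": "w", "coeff": -1},
                ],
            },
        )
        with pytest.raises(InferenceError, match="manually"):
            dx.select_target_equation(dx.load_topology(spec))


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

class TestBinning:
    def test_worked_example_counts_are_deterministic(self, linear_inference):
        bins, pairs_all, pairs, _, _ = linear_inference
        # Counts computed by this pipeline for the standard design (50 noise-
        # free samples, width 0.05 anchored at the data minimum).
        assert bins.occupied == 29
        assert bins.n_retained == 11
        assert len(pairs_all) == 21
        assert len(pairs) == 10

    def test_members_lie_in_their_half_open_interval(self, linear_inference):
        bins, *_ = linear_inference
        w = bins.widths[0]
        for b in bins.bins:
            lo = b.lower[0]
            for m in b.members:
                assert lo <= m.fixed_values[0] < lo + w

    def test_each_point_lands_in_exactly_one_bin(self, linear_inference):
        bins, *_ = linear_inference
        seen = [
            (m.dataset_id, m.time_index) for b in bins.bins for m in b.members
        ]
        assert len(seen) == len(set(seen)) == bins.n_points == 50

    def test_all_identical_values_form_one_full_bin(self):
        t = np.arange(10.0)
        ts = dx.TimeSeriesSet(
            [_series("d", t, F=np.full(10, 2.0), X=np.linspace(1, 3, 10))]
        )
        slopes = dx.estimate_slopes(ts)
        bins = dx.bin_fixed_variable(ts, slopes, "F", "X", "X", 0.05)
        assert bins.occupied == 1
        assert len(bins.bins[0].members) == 10

    def test_well_separated_values_retain_nothing(self):
        t = np.arange(5.0)
        ts = dx.TimeSeriesSet(
            [_series("d", t, F=np.array([0.0, 1, 2, 3, 4]), X=t + 1)]
        )
        slopes = dx.estimate_slopes(ts)
        bins = dx.bin_fixed_variable(ts, slopes, "F", "X", "X", 0.05)
        assert bins.n_retained == 0

    def test_nonpositive_width_rejected(self, linear_slopes):
        sm, slopes = linear_slopes
        with pytest.raises(InferenceError, match="positive"):
            dx.bin_fixed_variable(sm, slopes, "X1", "X2", "X2", 0.0)

    def test_members_may_come_from_different_datasets(self, linear_run):
        ts, _ = linear_run
        half1 = dx.TimeSeries(
            "a", ts[0].time[:25], ts[0].values.iloc[:25].reset_index(drop=True)
        )
        half2 = dx.TimeSeries(
            "b", ts[0].time[25:], ts[0].values.iloc[25:].reset_index(drop=True)
        )
        split = dx.TimeSeriesSet([half1, half2])
        slopes = dx.estimate_slopes(split)
        bins = dx.bin_fixed_variable(split, slopes, "X1", "X2", "X2", 0.05)
        cross = [
            b
            for b in bins.retained_bins
            if len({m.dataset_id for m in b.members}) > 1
        ]
        assert cross  # at least one bin mixes the two datasets


class TestMultivariateBinning:
    def test_no_joint_coincidence_gives_no_retained_bins(self):
        t = np.arange(6.0)
        ts = dx.TimeSeriesSet(
            [
                _series(
                    "d",
                    t,
                    A=np.array([0.0, 1, 2, 3, 4, 5]),
                    B=np.array([0.0, 0, 0, 1, 1, 1]),
                    X=t + 1,
                )
            ]
        )
        slopes = dx.estimate_slopes(ts)
        bins = dx.bin_fixed_combination(ts, slopes, ("A", "B"), "X", "X", 0.05)
        assert bins.n_retained == 0

    def test_constant_second_variable_reduces_to_univariate(self, linear_run):
        ts, _ = linear_run
        with_const = dx.TimeSeriesSet(
            [
                dx.TimeSeries(
                    "d",
                    ts[0].time,
                    ts[0].values.assign(C=1.0),
                )
            ]
        )
        slopes = dx.estimate_slopes(with_const)
        uni = dx.bin_fixed_variable(with_const, slopes, "X1", "X2", "X2", 0.05)
        multi = dx.bin_fixed_combination(
            with_const, slopes, ("X1", "C"), "X2", "X2", (0.05, 0.05)
        )
        assert uni.occupied == multi.occupied
        assert uni.n_retained == multi.n_retained

    def test_branched_v5_inference_setup_finds_joint_bins(self):
        """Fixing (X1, X2) jointly across the multi-dataset branched design
        leaves usable bins for inferring v6(X4) from the X4 equation."""
        ts, _ = dx.simulate_branched()
        sm = dx.smooth_series(ts)
        slopes = dx.estimate_slopes(sm)
        bins = dx.bin_fixed_combination(
            sm, slopes, ("X1", "X2"), "X4", "X4", (0.05, 0.05)
        )
        assert bins.n_retained >= 2
        pairs = dx.filter_pairs(dx.extract_pairs(bins), 0.2)
        assert len(pairs) >= 2


# ---------------------------------------------------------------------------
# pairing and filtering
# ---------------------------------------------------------------------------

def _bin_of(xy):
    members = [
        BinMember("d", i, (0.26,), x, y) for i, (x, y) in enumerate(xy)
    ]
    return Bin(bin_id=(0,), lower=(0.25,), members=members)


class TestPairs:
    def test_four_members_give_three_adjacent_pairs(self):
        """The published four-point bin yields exactly its three pairs."""
        db = BinDatabase(
            fixed_variables=("X1",),
            widths=(0.05,),
            out_variable="X2",
            target_metabolite="X2",
            sign=-1,
            bins=[
                _bin_of([(1.37, 0.35), (1.99, 1.65), (1.20, 0.05), (1.66, 1.02)])
            ],
            n_points=4,
        )
        pairs = dx.extract_pairs(db)
        assert [(p.point1, p.point2) for p in pairs] == [
            ((1.20, 0.05), (1.37, 0.35)),
            ((1.37, 0.35), (1.66, 1.02)),
            ((1.66, 1.02), (1.99, 1.65)),
        ]

    def test_two_member_bin_gives_one_pair(self):
        db = BinDatabase(
            ("X1",), (0.05,), "X2", "X2", -1,
            [_bin_of([(2.93, 0.93), (1.54, -1.35)])], 2,
        )
        pairs = dx.extract_pairs(db)
        assert len(pairs) == 1
        assert pairs.pairs[0].point1 == (1.54, -1.35)
        assert pairs.pairs[0].separation == pytest.approx(1.39)

    def test_no_retained_bins_means_no_pairs(self):
        db = BinDatabase(
            ("X1",), (0.05,), "X2", "X2", -1, [_bin_of([(1.0, 0.0)])], 1
        )
        assert len(dx.extract_pairs(db)) == 0

    def test_pair_count_law(self, linear_inference):
        """Sum over retained bins of (q-1) equals the unfiltered pair count."""
        bins, pairs_all, *_ = linear_inference
        expected = sum(len(b.members) - 1 for b in bins.retained_bins)
        assert len(pairs_all) == expected

    def test_filter_thresholds(self):
        close = Pair((0,), (1.20, 0.05), (1.37, 0.35))
        far = Pair((0,), (1.54, -1.35), (2.93, 0.93))
        ps = PairSet([close, far])
        kept = dx.filter_pairs(ps, 0.2)
        assert [p.point1 for p in kept] == [(1.54, -1.35)]
        with pytest.raises(InferenceError):
            dx.filter_pairs(ps, -0.1)

    def test_coverage_reports_range_and_gaps(self):
        ps = PairSet(
            [
                Pair((0,), (1.0, 0.0), (2.0, 1.0)),
                Pair((1,), (3.0, 2.0), (4.0, 3.0)),
            ]
        )
        cov = ps.coverage()
        assert (cov["x_min"], cov["x_max"]) == (1.0, 4.0)
        assert cov["gaps"] == [(2.0, 3.0)]


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def bruteforce_offsets(pairs, maxiter=40000):
    """Independent oracle: offsets minimising the summed squared slope
    changes (second divided differences) of the merged curve, so an exact
    straight line has zero roughness; first offset pinned at zero."""
    from scipy.optimize import minimize

    pts = np.array(
        [[[p.point1[0], p.point1[1]], [p.point2[0], p.point2[1]]] for p in pairs]
    )
    P = len(pts)
    po = np.repeat(np.arange(P), 2)
    x = pts[:, :, 0].ravel()
    y0 = pts[:, :, 1].ravel()
    order = np.argsort(x, kind="stable")
    xs = x[order]
    dx_steps = np.maximum(np.diff(xs), 1e-9)

    def roughness(free):
        off = np.concatenate([[0.0], free])
        y = (y0 + off[po])[order]
        slopes = np.diff(y) / dx_steps
        return float((np.diff(slopes) ** 2).sum())

    best = None
    for start in (np.zeros(P - 1), np.linspace(-1, 1, P - 1) if P > 1 else []):
        res = minimize(
            roughness,
            np.asarray(start, float),
            method="Nelder-Mead",
            options=dict(maxiter=maxiter, xatol=1e-12, fatol=1e-16),
        )
        if best is None or res.fun < best.fun:
            best = res
    off = np.concatenate([[0.0], best.x])
    return off - off.mean()


def _pairs_from_line(slope, segments, offsets):
    """Pairs sampled exactly from y = slope*x, each shifted vertically."""
    pairs = []
    for (x1, x2), c in zip(segments, offsets):
        pairs.append(
            Pair((0,), (x1, slope * x1 + c), (x2, slope * x2 + c))
        )
    return PairSet(pairs)


class TestMerge:
    def test_single_pair_is_returned_unchanged(self):
        ps = PairSet([Pair((0,), (1.0, 5.0), (2.0, 7.0))])
        rel = dx.merge_pairs(ps)
        assert np.allclose(rel.offsets, [0.0])
        assert np.allclose(rel.y, [5.0, 7.0])

    def test_empty_pair_set_rejected(self):
        with pytest.raises(InferenceError):
            dx.merge_pairs(PairSet([]))

    def test_collinear_pairs_recover_the_line(self):
        ps = _pairs_from_line(
            2.0, [(0.0, 1.0), (0.5, 1.5), (1.2, 2.2)], [3.0, -1.0, 0.7]
        )
        rel = dx.merge_pairs(ps)
        # merged points are collinear with slope 2 (up to a global constant)
        fitted = np.polyfit(rel.x, rel.y, 1)
        assert fitted[0] == pytest.approx(2.0, abs=1e-6)
        assert np.abs(np.polyval(fitted, rel.x) - rel.y).max() < 1e-6
        # and match the brute-force roughness-minimising oracle
        oracle = bruteforce_offsets(ps)
        got = rel.offsets - rel.offsets.mean()
        assert np.abs(got - oracle).max() < 1e-6

    @pytest.mark.parametrize("n_pairs", [2, 3, 4, 5])
    def test_oracle_equivalence_on_small_line_instances(self, n_pairs):
        rng = np.random.default_rng(12345 + n_pairs)
        starts = np.sort(rng.uniform(0, 3, n_pairs))
        segments = [(s, s + rng.uniform(0.4, 1.2)) for s in starts]
        offsets = rng.uniform(-2, 2, n_pairs)
        ps = _pairs_from_line(1.7, segments, offsets)
        rel = dx.merge_pairs(ps)
        oracle = bruteforce_offsets(ps)
        got = rel.offsets - rel.offsets.mean()
        assert np.abs(got - oracle).max() < 1e-3

    def test_shift_invariance_of_the_full_pipeline(self, linear_inference):
        """Adding constants to individual input pairs leaves the anchored
        curve unchanged - the offsets absorb them exactly."""
        _, _, pairs, _, curve = linear_inference
        rng = np.random.default_rng(7)
        shifted = PairSet(
            [
                Pair(
                    p.bin_id,
                    (p.point1[0], p.point1[1] + c),
                    (p.point2[0], p.point2[1] + c),
                )
                for p, c in zip(pairs, rng.uniform(-5, 5, len(pairs)))
            ],
            threshold=pairs.threshold,
        )
        rel2 = dx.merge_pairs(shifted)
        curve2 = dx.anchor_curve(
            rel2, "known_point", x0=1.0, v0=v3_truth(1.0)
        )
        assert np.allclose(curve2.x, curve.x, atol=1e-9)
        assert np.allclose(curve2.v, curve.v, atol=1e-9)

    def test_system_a_merged_curve_is_monotone(self, linear_inference):
        """The true v3 is monotone in X2, so the anchored estimate must be
        non-decreasing along x."""
        *_, curve = linear_inference
        assert np.all(np.diff(curve.v) >= -1e-6)

    def test_within_bin_flux_variation_bounded_by_lipschitz_width(
        self, linear_inference
    ):
        """The method treats the influx as constant within a bin; on the
        synthetic truth the actual spread is at most Lipschitz-bound*width."""
        bins, *_ = linear_inference
        width = bins.widths[0]
        v2 = lambda x1: 2.4 * x1**0.8
        for b in bins.retained_bins:
            xs = np.array([m.fixed_values[0] for m in b.members])
            spread = v2(xs).max() - v2(xs).min()
            lipschitz = 2.4 * 0.8 * min(xs) ** -0.2  # decreasing derivative
            assert spread <= lipschitz * width + 1e-12


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

class TestAnchor:
    def test_known_point_already_on_curve_needs_no_shift(self):
        ps = _pairs_from_line(2.0, [(0.0, 1.0), (0.8, 1.8)], [0.0, 0.0])
        rel = dx.merge_pairs(ps)
        curve = dx.anchor_curve(rel, "known_point", x0=0.9, v0=1.8)
        assert curve(0.9) == pytest.approx(1.8, abs=1e-9)
        assert np.allclose(curve.v, rel.y[np.argsort(rel.x, kind="stable")],
                           atol=1e-9)

    def test_zero_at_zero_with_flat_left_tail(self):
        # sigmoid-like relative curve with a flat left tail far above zero,
        # sampled as overlapping shiftable segments (as binning produces)
        x = np.linspace(0.25, 3.0, 12)
        y = 6.0 / (1 + np.exp(-5 * (x - 2.0))) - 6.0
        rng = np.random.default_rng(3)
        pairs = PairSet(
            [
                Pair(
                    (i,),
                    (x[i], y[i] + c),
                    (x[i + 2], y[i + 2] + c),
                )
                for i, c in zip(range(10), rng.uniform(-1, 1, 10))
            ]
        )
        rel = dx.merge_pairs(pairs)
        curve = dx.anchor_curve(rel, "zero_at_zero")
        # the leftmost raw point is pinned to zero exactly
        assert curve.raw_v[np.argmin(curve.raw_x)] == pytest.approx(0.0, abs=1e-9)
        assert curve.v[0] == pytest.approx(0.0, abs=0.05)
        # flat tail means the implied upshift is about six units
        assert -rel.y[0] == pytest.approx(6.3, abs=0.4)

    def test_zero_at_zero_refused_without_justification(self, linear_inference):
        *_, rel, _ = (*linear_inference[:3], linear_inference[3], None)
        with pytest.raises(InferenceError, match="refused"):
            dx.anchor_curve(linear_inference[3], "zero_at_zero")

    def test_fit_family_anchor_on_well_covered_hill_curve(self):
        """Joint family+offset anchoring recovers the exact generating Hill
        parameters when the curve covers the saturation plateau.  (On the
        worked example's truncated support, x only up to ~3, the quadruple
        (V_max, K, h, offset) is weakly identified - see the half-saturation
        test below.)"""
        x = np.linspace(0.3, 8.0, 25)
        rel_y = v3_truth(x) - 2.5  # relative curve: truth minus unknown shift
        rng = np.random.default_rng(9)
        pairs = PairSet(
            [
                Pair((i,), (x[i], rel_y[i] + c), (x[i + 2], rel_y[i + 2] + c))
                for i, c in zip(range(23), rng.uniform(-1, 1, 23))
            ]
        )
        rel = dx.merge_pairs(pairs)
        curve = dx.anchor_curve(rel, "fit_family", family="hill")
        fit = dx.fit_rate_law(curve, "hill")
        assert fit.parameters["v_max"] == pytest.approx(5.0, rel=0.02)
        assert fit.parameters["k"] == pytest.approx(2.0, rel=0.02)
        assert fit.parameters["h"] == pytest.approx(3.0, rel=0.05)

    def test_fit_family_anchor_on_worked_example_recovers_half_saturation(
        self, linear_inference
    ):
        """On the truncated worked-example support the joint fit still pins
        the half-saturation constant even though V_max drifts."""
        curve = dx.anchor_curve(linear_inference[3], "fit_family", family="hill")
        fit = dx.fit_rate_law(curve, "hill")
        assert fit.parameters["k"] == pytest.approx(2.0, rel=0.1)

    def test_unknown_strategy_rejected(self, linear_inference):
        with pytest.raises(InferenceError, match="unknown anchor"):
            dx.anchor_curve(linear_inference[3], "nope")


class TestCurveAccuracy:
    def test_exact_curve_scores_zero(self):
        x = np.linspace(0.5, 3, 8)
        curve = dx.FluxCurve(x=x, v=v3_truth(x), anchor_method="known_point",
                             anchor_value=0.0)
        assert dx.curve_accuracy(curve, v3_truth) == 0.0

    def test_branched_end_to_end_v3_curve(self):
        """Multi-dataset inference on the branched pathway: fixing X3 (the
        efflux's argument) traces the Hill influx v3(X2); the flat-tailed
        curve zero-anchors and tracks the truth to a mean error below 0.1
        (2% of V_max) over the covered range."""
        ts, _ = dx.simulate_branched()
        sm = dx.smooth_series(ts)
        slopes = dx.estimate_slopes(sm)
        bins = dx.bin_fixed_variable(
            sm, slopes, "X3", "X2", "X3", width=0.033, sign=+1
        )
        pairs = dx.filter_pairs(dx.extract_pairs(bins), 0.2)
        assert len(pairs) >= 10
        cov = pairs.coverage()
        assert cov["x_min"] < 0.5 and cov["x_max"] > 2.0
        curve = dx.anchor_curve(dx.merge_pairs(pairs), "zero_at_zero")
        truth = lambda x: 5.0 * np.asarray(x, float) ** 4 / (
            5.0 + np.asarray(x, float) ** 4
        )
        assert dx.curve_accuracy(curve, truth, "mean_abs") < 0.1

    def test_metrics_on_worked_example(self, linear_inference):
        """End-to-end accuracy of the v3 estimate against the Hill truth."""
        *_, curve = linear_inference
        assert dx.curve_accuracy(curve, v3_truth, "sum_sq") < 0.1
        assert dx.curve_accuracy(curve, v3_truth, "sum_abs") < 1.5
        with pytest.raises(InferenceError):
            dx.curve_accuracy(curve, v3_truth, "bogus")
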