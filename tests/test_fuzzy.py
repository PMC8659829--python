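"""Histogram fuzzification, λ-cuts, membership functions, union, decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzypima import (
    FitConfig,
    FuzzyClassifierModel,
    MembershipFunction,
    aggregate_union,
    build_histogram,
    classify,
    fit,
    lambda_cut,
    mf_from_cut,
    mf_from_thresholds,
)
from fuzzypima.fuzzy import FuzzyHistogram, IntervalSet


def random_histogram(rng, bins=None):
    bins = bins or int(rng.integers(3, 30))
    mems = rng.random(bins)
    mems[rng.integers(bins)] = 1.0  # valid fuzzy histogram: modal bin at 1
    edges = np.linspace(0, float(rng.uniform(0.5, 3.0)), bins + 1)
    return FuzzyHistogram(edges, mems)


def random_mf(rng):
    """Random continuous piecewise-linear MF (endpoints at 0, interior in [0,1])."""
    n = int(rng.integers(3, 9))
    z = np.sort(rng.uniform(0, 2, n))
    while (np.diff(z) <= 0).any():
        z = np.sort(rng.uniform(0, 2, n))
    mu = rng.random(n)
    mu[0] = mu[-1] = 0.0
    return MembershipFunction(z, mu)


class TestBuildHistogram:
    def test_all_equal_values_put_mass_in_one_bin(self):
        h = build_histogram([0.7, 0.7, 0.7], bins=4)
        assert (h.memberships == 1.0).sum() == 1
        assert (h.memberships == 0.0).sum() == 3

    def test_height_normalization_reaches_one(self, rng):
        h = build_histogram(rng.random(200), bins=10)
        assert h.memberships.max() == 1.0
        assert ((0 <= h.memberships) & (h.memberships <= 1)).all()

    def test_explicit_axis_range_is_respected(self):
        h = build_histogram([0.1, 1.3], bins=14, range=(0.0, 1.4))
        np.testing.assert_allclose(h.bin_edges[[0, -1]], [0.0, 1.4])

    def test_value_on_upper_edge_falls_in_last_bin(self):
        h = build_histogram([0.25, 1.0], bins=2, range=(0.0, 1.0))
        np.testing.assert_array_equal(h.memberships, [1.0, 1.0])

    def test_value_outside_explicit_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            build_histogram([0.5, 1.5], bins=4, range=(0.0, 1.4))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no values"):
            build_histogram([])


class TestLambdaCut:
    def test_adjacent_qualifying_bins_merge(self):
        h = FuzzyHistogram(np.arange(5.0), [0.2, 1.0, 0.9, 0.1])
        cut = lambda_cut(h, 0.5)
        assert cut.intervals == ((1.0, 3.0),)

    def test_top_cut_keeps_only_modal_bins(self):
        h = FuzzyHistogram(np.arange(5.0), [0.2, 1.0, 0.9, 1.0])
        cut = lambda_cut(h, 1.0)
        assert cut.intervals == ((1.0, 2.0), (3.0, 4.0))

    def test_invalid_level_errors(self):
        h = FuzzyHistogram(np.arange(3.0), [1.0, 0.5])
        for lam in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="lambda"):
                lambda_cut(h, lam)

    def test_nesting_on_random_histograms(self, rng):
        """λ1 <= λ2 implies every λ2 interval sits inside some λ1 interval."""
        for _ in range(100):
            h = random_histogram(rng)
            lo, hi = sorted(rng.uniform(0.05, 1.0, 2))
            outer, inner = lambda_cut(h, lo), lambda_cut(h, hi)
            for a, b in inner.intervals:
                assert any(c <= a and b <= d for c, d in outer.intervals)


class TestMembershipFunctions:
    def test_threshold_segments_cover_axis(self):
        left, right = mf_from_thresholds([0.5], (0.0, 1.0), shoulder=0.1)
        assert left(0.25) == 1.0 and right(0.75) == 1.0
        assert left(0.0) == 1.0  # shoulder clipped at the axis end
        assert right(0.49) == pytest.approx(0.9)

    def test_published_classifier1_thresholds_give_four_segments(self):
        mfs = mf_from_thresholds([0.2, 0.4, 0.8], (0.0, 1.4), shoulder=0.07)
        assert len(mfs) == 4
        # segment midpoints: own MF at 1, non-adjacent MFs at 0
        mids = [0.1, 0.3, 0.6, 1.1]
        for i, mf in enumerate(mfs):
            assert mf(mids[i]) == 1.0
            for j in range(len(mfs)):
                if abs(i - j) > 1:
                    assert mfs[j](mids[i]) == 0.0

    def test_non_increasing_thresholds_error(self):
        with pytest.raises(ValueError, match="increasing"):
            mf_from_thresholds([0.4, 0.2], (0.0, 1.0), shoulder=0.1)

    def test_trapezoid_from_cut_interval(self):
        cut = IntervalSet(((0.3, 0.5),), lam=0.5)
        mf = mf_from_cut(cut, shoulder=0.1)
        assert mf(0.4) == 1.0
        assert mf(0.25) == pytest.approx(0.5)
        assert mf(0.15) == 0.0

    def test_two_intervals_give_bimodal_mf(self):
        cut = IntervalSet(((0.1, 0.2), (0.6, 0.8)), lam=0.5)
        mf = mf_from_cut(cut, shoulder=0.05)
        assert mf(0.15) == 1.0 and mf(0.7) == 1.0
        assert mf(0.4) == 0.0

    def test_empty_cut_advises_smaller_lambda(self):
        with pytest.raises(ValueError, match="smaller lambda"):
            mf_from_cut(IntervalSet((), lam=0.9), shoulder=0.1)

    def test_shrinking_lambda_never_shrinks_plateau(self, rng):
        for _ in range(50):
            h = random_histogram(rng)
            lo, hi = sorted(rng.uniform(0.05, 1.0, 2))
            w = h.bin_width
            mf_lo = mf_from_cut(lambda_cut(h, lo), w)
            mf_hi = mf_from_cut(lambda_cut(h, hi), w)
            plateau_hi = mf_hi.z[mf_hi.mu == 1.0]
            for z in plateau_hi:
                assert mf_lo(z) == pytest.approx(1.0)

    def test_evaluation_zero_outside_support(self):
        mf = MembershipFunction([0.0, 1.0], [1.0, 1.0])
        assert mf(-0.1) == 0.0 and mf(1.1) == 0.0 and mf(0.5) == 1.0


class TestUnion:
    def test_idempotent_and_neutral_element(self, rng):
        mf = random_mf(rng)
        zero = MembershipFunction(mf.z, np.zeros_like(mf.mu))
        grid = np.linspace(mf.z[0] - 0.5, mf.z[-1] + 0.5, 200)
        np.testing.assert_allclose(aggregate_union([mf, mf])(grid), mf(grid))
        np.testing.assert_allclose(aggregate_union([mf, zero])(grid), mf(grid))

    def test_union_equals_pointwise_max_oracle(self, rng):
        for _ in range(25):
            mfs = [random_mf(rng) for _ in range(3)]
            union = aggregate_union(mfs)
            z = rng.uniform(-0.5, 2.5, 1000)
            naive = np.max(np.column_stack([mf(z) for mf in mfs]), axis=1)
            np.testing.assert_allclose(union(z), naive, atol=1e-12)

    def test_commutative_and_associative(self, rng):
        a, b, c = (random_mf(rng) for _ in range(3))
        grid = np.linspace(-0.5, 2.5, 500)
        ab_c = aggregate_union([aggregate_union([a, b]), c])
        a_bc = aggregate_union([a, aggregate_union([b, c])])
        cba = aggregate_union([c, b, a])
        np.testing.assert_allclose(ab_c(grid), a_bc(grid), atol=1e-12)
        np.testing.assert_allclose(ab_c(grid), cba(grid), atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6), st.integers(0, 2**31 - 1))
    def test_union_bounded_in_unit_interval(self, mus, seed):
        rng = np.random.Generator(np.random.Philox(seed))
        z = np.sort(rng.uniform(0, 3, len(mus)))
        if (np.diff(z) <= 0).any():
            return
        mf = aggregate_union([MembershipFunction(z, mus), random_mf(rng)])
        samples = mf(rng.uniform(-1, 4, 500))
        assert ((samples >= 0) & (samples <= 1)).all()


class TestClassifyAndFit:
    def test_healthy_wins_when_membership_higher_or_tied(self, fitted_auto):
        model = fitted_auto.model1
        # synthesize direct comparisons through the public classify() surface
        feats, _ = fitted_auto.test.stacked()
        label, mu_h, mu_s = classify(feats[0], model)
        assert label == (0 if mu_h >= mu_s else 1)

    def test_uncovered_record_defaults_to_healthy(self, fitted_auto):
        model = fitted_auto.model1
        label, mu_h, mu_s = classify(np.zeros(model.profile.direction.size), model)
        assert (mu_h, mu_s) == (0.0, 0.0)
        assert label == 0

    def test_memberships_always_in_unit_interval(self, fitted_auto, rng):
        for model in fitted_auto.models:
            records = rng.random((10_000, model.profile.direction.size))
            mu_h, mu_s = model.memberships(records)
            assert ((mu_h >= 0) & (mu_h <= 1)).all()
            assert ((mu_s >= 0) & (mu_s <= 1)).all()

    def test_dimension_mismatch_errors(self, fitted_auto):
        with pytest.raises(ValueError, match="features"):
            fitted_auto.model1.predict(np.zeros((1, 3)))

    def test_paper_mode_stores_configured_thresholds(self, fitted_auto):
        model1, model2 = fit(fitted_auto.train, FitConfig(threshold_mode="paper"))
        assert model1.config["thresholds_c1"] == [0.2, 0.4, 0.8]
        assert model1.config["axis_c1"] == [0.0, 1.4]
        assert model2.config["thresholds_c2"] == [0.5]

    def test_auto_mode_top_cut_of_unimodal_histogram_single_plateau(self):
        h = FuzzyHistogram(np.linspace(0, 1, 6), [0.1, 0.4, 1.0, 0.5, 0.2])
        mf = mf_from_cut(lambda_cut(h, 1.0), h.bin_width)
        plateaus = mf.z[mf.mu == 1.0]
        assert plateaus.min() == pytest.approx(0.4)
        assert plateaus.max() == pytest.approx(0.6)

    def test_refit_yields_identical_model_files(self, tmp_path, fitted_auto):
        config = FitConfig(threshold_mode="auto")
        for run in ("a", "b"):
            m1, _ = fit(fitted_auto.train, config)
            m1.save(tmp_path / f"{run}.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_model_json_round_trip_is_bit_exact(self, tmp_path, fitted_auto):
        for model in fitted_auto.models:
            path = tmp_path / f"m{model.classifier_id}.json"
            model.save(path)
            loaded = FuzzyClassifierModel.load(path)
            np.testing.assert_array_equal(loaded.profile.direction, model.profile.direction)
            assert loaded.profile.scale0 == model.profile.scale0
            assert loaded.profile.scale1 == model.profile.scale1
            feats, _ = fitted_auto.test.stacked()
            np.testing.assert_array_equal(loaded.predict(feats), model.predict(feats))
            loaded.save(tmp_path / "again.json")
            assert (tmp_path / "again.json").read_bytes() == path.read_bytes()

    def test_region_diagnostic_matches_single_cut_rule(self, fitted_auto):
        model = fitted_auto.model1
        feats, _ = fitted_auto.test.stacked()
        inside = model.region_diagnostic(feats)
        t = feats @ model.profile.direction * model.profile.scale1
        expected = np.array([model.region.contains(z) for z in t])
        np.testing.assert_array_equal(inside, expected)
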