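"""Diversity curves, Delta classification, Bray-Curtis, ECx inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gemtox.ensemble import PosteriorEnsemble
from gemtox.inference import (
    DissimilarityCurve,
    bray_curtis,
    classify_from_raw,
    classify_otus,
    delta_statistic,
    dissimilarity_curve,
    diversity_curve,
    ecx,
    raw_shannon_points,
    sensitivity_specificity,
)
from gemtox.tables import CovariateVector, OTUCountTable


def _ensemble(comps, grid, genera=None):
    comps = np.asarray(comps, float)
    n_otus = comps.shape[2] - 1
    return PosteriorEnsemble(
        compositions=comps, grid=np.asarray(grid, float),
        M_trace=np.ones(comps.shape[0]), bandwidth_trace=None,
        otu_ids=tuple(f"o{j}" for j in range(n_otus)),
        stick_of_otu=np.arange(n_otus), genera=genera)


def _repeat(comp_per_point, n_draws=200, noise=0.0, seed=0):
    """Stack one composition per grid point into a (draws, points, J+1) array."""
    rng = np.random.default_rng(seed)
    base = np.asarray(comp_per_point, float)[None].repeat(n_draws, axis=0)
    if noise:
        base = base + rng.normal(0, noise, size=base.shape)
        base = np.abs(base)
        base /= base.sum(-1, keepdims=True)
    return base


class TestDiversityCurve:
    def test_degenerate_ensemble_flat_zero_width(self):
        comp = [[0.5, 0.3, 0.2]] * 4
        ens = _ensemble(_repeat(comp), grid=[0, 1, 2, 3])
        est = diversity_curve(ens)
        assert np.ptp(est.mean) < 1e-12
        np.testing.assert_allclose(est.upper, est.lower, atol=1e-12)

    def test_planted_peak_recovered(self):
        # diversity peaks at the middle grid point
        comps = np.stack([
            np.array([0.9, 0.06, 0.04]),
            np.array([1 / 3, 1 / 3, 1 / 3]),
            np.array([0.8, 0.15, 0.05]),
        ])
        ens = _ensemble(_repeat(comps, noise=0.01, seed=1), grid=[0, 10, 20])
        est = diversity_curve(ens)
        assert int(np.argmax(est.mean)) == 1

    def test_raw_points_match_summation_oracle(self, tiny_table):
        H = raw_shannon_points(tiny_table)
        props = tiny_table.counts / tiny_table.counts.sum(0)
        oracle = [-sum(p * np.log(p) for p in props[:, i] if p > 0)
                  for i in range(tiny_table.n_sites)]
        np.testing.assert_allclose(H, oracle, atol=1e-12)


class TestDelta:
    def test_flat_otu_is_zero(self):
        comp = [[0.5, 0.3, 0.2]] * 4
        ens = _ensemble(_repeat(comp), grid=[0, 1, 2, 3])
        delta = delta_statistic(ens, split=1.5)
        np.testing.assert_allclose(delta.draws, 0.0, atol=1e-14)

    def test_two_point_hand_value(self):
        comps = np.array([[0.3, 0.7], [0.1, 0.9]])
        ens = _ensemble(_repeat(comps), grid=[0, 10])
        delta = delta_statistic(ens, split=5.0)
        np.testing.assert_allclose(delta.draws[:, 0], 0.2, atol=1e-14)

    def test_monotone_decreasing_has_positive_delta(self):
        grid = np.arange(5.0)
        p0 = np.linspace(0.5, 0.1, 5)
        comps = np.stack([np.array([p, (1 - p) / 2, (1 - p) / 2]) for p in p0])
        ens = _ensemble(_repeat(comps), grid=grid)
        delta = delta_statistic(ens, split=2.0)
        assert (delta.draws[:, 0] > 0).all()

    def test_split_outside_grid_rejected(self):
        ens = _ensemble(_repeat([[0.6, 0.4]] * 3), grid=[0, 1, 2])
        with pytest.raises(ValueError):
            delta_statistic(ens, split=5.0)


class TestClassify:
    def _delta_like(self, draws):
        ens = _ensemble(_repeat([[0.5, 0.5]] * 2), grid=[0, 1])
        d = delta_statistic(ens, split=0.5)
        object.__setattr__(d, "draws", np.asarray(draws, float))
        return d

    def test_sign_conventions(self):
        draws = np.column_stack([
            np.full(500, 0.1),        # always positive -> decreasing
            np.full(500, -0.1),       # always negative -> increasing
            np.random.default_rng(0).normal(0, 1, 500),  # straddles zero
        ])
        labels = classify_otus(self._delta_like(draws))
        assert list(labels) == ["decreasing", "increasing", "no_classification"]

    def test_level_extremes(self):
        # draws straddling zero: level -> 1 widens the interval to the full
        # range (nothing classified); level -> 0 shrinks it to the median
        # (everything classified)
        rng = np.random.default_rng(1)
        draws = rng.normal(0.05, 0.1, size=(1_000, 3))
        d = self._delta_like(draws)
        assert (classify_otus(d, level=0.9999999) == "no_classification").all()
        assert (classify_otus(d, level=1e-7) != "no_classification").all()

    def test_needs_enough_draws(self):
        with pytest.raises(ValueError):
            classify_otus(self._delta_like(np.zeros((50, 2))))

    def test_raw_classification_one_sided_support_and_ties(self):
        counts = np.array([[10, 0], [0, 10], [5, 5]])
        t = OTUCountTable(counts=counts, otu_ids=("a", "b", "c"),
                          site_ids=("s1", "s2"))
        cov = CovariateVector(raw=np.array([0.0, 100.0]), site_ids=("s1", "s2"))
        labels = classify_from_raw(t, cov, split=50.0)
        # equal proportions on both sides tie-break toward increasing
        assert list(labels) == ["decreasing", "increasing", "increasing"]


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        u = np.array([0.5, 0.5, 0.0, 0.0])
        v = np.array([0.0, 0.0, 0.25, 0.75])
        assert bray_curtis(u, u) == 0.0
        assert bray_curtis(u, v) == 1.0

    def test_hand_value(self):
        u = np.array([0.5, 0.5, 0.0])
        v = np.array([0.25, 0.25, 0.5])
        assert bray_curtis(u, v) == pytest.approx(0.5)

    @given(st.integers(2, 30), st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=100)
    def test_semimetric_properties(self, k, seed):
        rng = np.random.default_rng(seed)
        u = rng.dirichlet(np.ones(k))
        v = rng.dirichlet(np.ones(k))
        buv, bvu = bray_curtis(u, v), bray_curtis(v, u)
        assert buv == pytest.approx(bvu, abs=1e-12)
        assert -1e-12 <= buv <= 1 + 1e-12
        assert bray_curtis(u, u) == pytest.approx(0.0, abs=1e-12)
        # half-L1 identity for compositions
        assert buv == pytest.approx(0.5 * np.abs(u - v).sum(), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([1.0]), np.array([0.5, 0.5]))


class TestDissimilarityCurve:
    def test_zero_at_origin_and_flat_ensemble(self):
        comp = [[0.5, 0.3, 0.2]] * 3
        ens = _ensemble(_repeat(comp), grid=[0, 1, 2])
        curve = dissimilarity_curve(ens)
        np.testing.assert_allclose(curve.draws[:, 0], 0.0, atol=1e-14)
        np.testing.assert_allclose(curve.mean, 0.0, atol=1e-14)

    def test_grid_without_zero_rejected(self):
        ens = _ensemble(_repeat([[0.6, 0.4]] * 2), grid=[1, 2])
        with pytest.raises(ValueError, match="covariate 0"):
            dissimilarity_curve(ens)

    def test_planted_turnover_is_increasing(self):
        grid = np.linspace(0, 10, 6)
        comps = np.stack([np.array([1 - 0.08 * g, 0.05 + 0.04 * g, 0.03 + 0.04 * g])
                          for g in grid])
        ens = _ensemble(_repeat(comps, noise=0.005, seed=3), grid=grid)
        curve = dissimilarity_curve(ens)
        assert curve.mean[-1] > curve.mean[1] > curve.mean[0]
        band = curve.upper[-1] - curve.lower[-1]
        assert curve.mean[-1] - curve.mean[0] > band

    def test_raw_pairwise_d0(self, tiny_table):
        cov = CovariateVector(raw=np.array([0.0, 0.0]), site_ids=("s1", "s2"))
        comp = [[0.5, 0.3, 0.2]] * 2
        ens = _ensemble(_repeat(comp), grid=[0, 1])
        curve = dissimilarity_curve(ens, d0_method="raw_pairwise",
                                    table=tiny_table, cov=cov)
        props = tiny_table.counts / tiny_table.counts.sum(0)
        expected = 1 - np.minimum(props[:, 0], props[:, 1]).sum()
        assert curve.d0 == pytest.approx(expected)


def _linear_curve(d0=0.2, xmax=25_000.0, n=41, band=0.0):
    grid = np.linspace(0.0, xmax, n)
    mean = d0 + (1 - d0) * grid / xmax
    draws = mean[None].repeat(10, axis=0)
    return DissimilarityCurve(grid=grid, draws=draws, mean=mean,
                              lower=np.clip(mean - band, 0, 1),
                              upper=np.clip(mean + band, 0, 1),
                              d0=d0, level=0.95)


class TestECx:
    def test_linear_curve_analytic_inversion(self):
        est = ecx(_linear_curve(), 50.0)
        assert est.threshold == pytest.approx(0.6)
        assert est.ec == pytest.approx(12_500.0)

    def test_small_x_limit_hits_origin(self):
        est = ecx(_linear_curve(), 0.001)
        assert est.ec == pytest.approx(0.0, abs=1.0)

    def test_non_monotone_takes_smallest_crossing(self):
        grid = np.array([0, 1_000, 3_000, 5_000, 7_000, 9_000, 11_000], float)
        mean = np.array([0.1, 0.2, 0.65, 0.5, 0.4, 0.7, 0.8])
        curve = DissimilarityCurve(grid=grid, draws=mean[None].repeat(5, 0),
                                   mean=mean, lower=mean, upper=mean,
                                   d0=0.1, level=0.95)
        est = ecx(curve, 50.0)  # threshold 0.55, first reached before 3,000
        assert est.ec <= 3_000.0
        assert est.ec > 1_000.0

    def test_monotone_in_x_and_censoring(self):
        curve = _linear_curve(band=0.1)
        ests = [ecx(curve, x) for x in range(5, 85, 5)]
        ecs = [e.ec for e in ests]
        assert ecs == sorted(ecs)
        los = [e.lower for e in ests]
        his = [e.upper for e in ests]
        assert los == sorted(los) and his == sorted(his)
        assert all(e.lower <= e.ec <= e.upper for e in ests)
        # wide band at small x censors the lower bound at the origin
        assert ests[0].censored_low
        assert not ests[0].censored_high

    def test_unreachable_threshold_right_censors(self):
        curve = _linear_curve(d0=0.0)
        shallow = DissimilarityCurve(
            grid=curve.grid, draws=curve.draws * 0.3, mean=curve.mean * 0.3,
            lower=curve.lower * 0.3, upper=curve.upper * 0.3, d0=0.0, level=0.95)
        est = ecx(shallow, 50.0)
        assert est.censored_high
        assert est.ec == pytest.approx(curve.grid[-1])

    def test_rejects_bad_x(self):
        with pytest.raises(ValueError):
            ecx(_linear_curve(), 0.0)
        with pytest.raises(ValueError):
            ecx(_linear_curve(), 100.0)


class TestSensitivitySpecificity:
    def _table(self, totals, genera):
        counts = np.array(totals)[:, None]
        return OTUCountTable(counts=counts,
                             otu_ids=tuple(f"o{i}" for i in range(len(totals))),
                             site_ids=("s1",), genera=genera)

    def test_half_sensitivity(self):
        t = self._table([10, 10, 10, 10], ("ga", "gb", "gc", "gd"))
        labels = np.array(["increasing", "increasing", "decreasing", "decreasing"],
                          dtype=object)
        sens, spec, _, _ = sensitivity_specificity(
            labels, {"ga", "gb", "gc", "gd"}, t)
        assert sens == pytest.approx(0.5)

    def test_perfect_specificity(self):
        t = self._table([10, 10, 10], ("ga", "gb", "gc"))
        labels = np.array(["increasing", "decreasing", "decreasing"], dtype=object)
        _, spec, _, _ = sensitivity_specificity(labels, {"ga"}, t)
        assert spec == 1.0

    def test_weighted_by_abundance(self):
        t = self._table([90, 10], ("ga", "gb"))
        labels = np.array(["increasing", "decreasing"], dtype=object)
        sens, _, wsens, _ = sensitivity_specificity(labels, {"ga", "gb"}, t)
        assert sens == pytest.approx(0.5)
        assert wsens == pytest.approx(0.9)

    def test_excludes_unclassified_and_missing_genus(self):
        t = self._table([10, 10, 10], ("ga", None, "gc"))
        labels = np.array(["increasing", "increasing", "no_classification"],
                          dtype=object)
        sens, spec, _, _ = sensitivity_specificity(labels, {"ga", "gc"}, t)
        assert sens == 1.0  # only the first OTU is counted
        assert np.isnan(spec)  # no classified negatives -> undefined

    def test_no_classified_reference_warns(self):
        t = self._table([10], ("ga",))
        labels = np.array(["no_classification"], dtype=object)
        with pytest.warns(UserWarning, match="undefined"):
            sens, _, _, _ = sensitivity_specificity(labels, {"ga"}, t)
        assert np.isnan(sens)
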