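import numpy as np
import pytest
from scipy import stats

from chipregulon.enrichment import (
    DifferenceTrack,
    StatParams,
    call_condition,
    difference_track,
    hochberg_adjust,
    local_enrichment,
    normal_pvalues,
    significant_positions,
)
from chipregulon.genome_io import CoverageTrack


def brute_force_enrichment(values, params):
    """O(n*w) per-position re-summation: the independent oracle."""
    length = len(values)
    centers = np.arange(params.grid_phase, length + 1, params.step)
    ratios = []
    for c in centers:
        fg = values[max(c - params.fg_window // 2, 1) - 1:
                    min(c + params.fg_window // 2, length)].sum()
        bg = values[max(c - params.bg_window // 2, 1) - 1:
                    min(c + params.bg_window // 2, length)].sum()
        ratios.append(fg / bg if bg > 0 else np.nan)
    return centers, np.array(ratios)


def brute_force_hochberg(p):
    """min over suffix of (n - j + 1) * p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(n)
    for i in range(n):
        adj_sorted[i] = min(
            min((n - j) * sorted_p[j] for j in range(i, n)), 1.0
        )
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def _track(values):
    return CoverageTrack(chrom_id="c", values=np.asarray(values))


class TestLocalEnrichment:
    def test_uniform_coverage_gives_window_ratio(self):
        t = _track(np.full(10_000, 7))
        e = local_enrichment(t, StatParams())
        interior = (e.grid_positions > 1000) & (e.grid_positions < 9000)
        assert np.allclose(e.ratios[interior], 51 / 2001)

    def test_isolated_spike_gives_ratio_one(self):
        vals = np.zeros(10_000, dtype=int)
        vals[5000 - 1] = 100  # exactly at grid center 5000
        e = local_enrichment(_track(vals), StatParams())
        i = np.flatnonzero(e.grid_positions == 5000)[0]
        assert e.ratios[i] == 1.0

    def test_matches_brute_force_oracle(self, rng):
        params = StatParams()
        vals = rng.poisson(30, size=10_000)
        e = local_enrichment(_track(vals), params)
        centers, expected = brute_force_enrichment(vals, params)
        assert np.array_equal(e.grid_positions, centers)
        assert np.allclose(e.ratios, expected, equal_nan=True)

    def test_scale_invariance(self, rng):
        vals = rng.poisson(20, size=5_000)
        a = local_enrichment(_track(vals), StatParams())
        b = local_enrichment(_track(vals * 17), StatParams())
        assert np.allclose(a.ratios, b.ratios, equal_nan=True)

    def test_ratios_bounded_in_unit_interval(self, rng):
        vals = rng.poisson(2, size=8_000)  # sparse: exercises zero windows
        e = local_enrichment(_track(vals), StatParams())
        ok = ~np.isnan(e.ratios)
        assert np.all(e.ratios[ok] >= 0) and np.all(e.ratios[ok] <= 1)

    def test_zero_background_is_missing_not_zero(self):
        vals = np.zeros(10_000, dtype=int)
        vals[:100] = 5  # coverage only near the left edge
        e = local_enrichment(_track(vals), StatParams())
        far = e.grid_positions > 2000
        assert np.isnan(e.ratios[far]).all()

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError, match="shorter than background"):
            local_enrichment(_track(np.ones(500)), StatParams())

    def test_all_zero_coverage_warns_and_is_all_missing(self):
        with pytest.warns(UserWarning, match="missing"):
            e = local_enrichment(_track(np.zeros(5_000)), StatParams())
        assert np.isnan(e.ratios).all()

    def test_edge_drop_removes_clipped_windows(self):
        e = local_enrichment(_track(np.ones(10_000)),
                             StatParams(edge="drop"))
        assert e.grid_positions.min() >= 1001
        assert e.grid_positions.max() <= 9000
        assert np.allclose(e.ratios, 51 / 2001)


class TestDifference:
    def test_equal_tracks_give_zero(self, rng):
        vals = rng.poisson(30, size=5_000)
        e = local_enrichment(_track(vals), StatParams())
        d = difference_track(e, e)
        assert np.allclose(d.d, 0.0)

    def test_spike_minus_uniform_value(self):
        # ratio 1.0 at the spike minus the uniform ratio 51/2001
        vals = np.zeros(10_000, dtype=int)
        vals[5000 - 1] = 100
        ip = local_enrichment(_track(vals), StatParams())
        total = local_enrichment(_track(np.full(10_000, 9)), StatParams())
        d = difference_track(ip, total)
        i = np.flatnonzero(d.grid_positions == 5000)[0]
        assert d.d[i] == pytest.approx(1.0 - 51 / 2001, abs=1e-12)

    def test_antisymmetry(self, rng):
        a = local_enrichment(_track(rng.poisson(30, 5_000)), StatParams())
        b = local_enrichment(_track(rng.poisson(30, 5_000)), StatParams())
        assert np.allclose(difference_track(a, b).d, -difference_track(b, a).d,
                           equal_nan=True)

    def test_grid_mismatch_rejected(self, rng):
        a = local_enrichment(_track(rng.poisson(30, 5_000)), StatParams())
        b = local_enrichment(_track(rng.poisson(30, 5_100)), StatParams())
        with pytest.raises(ValueError, match="grid"):
            difference_track(a, b)

    def test_missing_propagates(self):
        g = np.array([25, 50])
        a = DifferenceTrack(grid_positions=g, d=np.array([0.1, np.nan]))
        assert np.isnan(a.d[1])


class TestNormalPvalues:
    def _diff(self, d):
        d = np.asarray(d, dtype=float)
        return DifferenceTrack(grid_positions=np.arange(25, 25 * (len(d) + 1), 25),
                               d=d)

    def test_difference_at_mean_gives_half(self, rng):
        d = rng.normal(size=1001)
        d[0] = d[1:].mean()  # then d[0] equals the overall mean exactly
        t = normal_pvalues(self._diff(d))
        assert t.p_raw[0] == pytest.approx(0.5, abs=1e-9)

    def test_upper_tail_quantile(self, rng):
        import math

        # inverse-normal fact behind the alpha threshold: a 3.719-sd
        # excursion has upper-tail probability ~1e-4
        assert 0.5 * math.erfc(3.719 / math.sqrt(2)) == pytest.approx(1e-4,
                                                                      rel=5e-3)
        # and on an exactly standardized track the implementation matches
        # the complementary-error-function evaluation of that tail
        base = rng.normal(size=1000)
        b = (base - base.mean()) / base.std(ddof=1)
        t = normal_pvalues(self._diff(b))
        assert t.mu_hat == pytest.approx(0.0, abs=1e-12)
        assert t.sigma_hat == pytest.approx(1.0, abs=1e-12)
        from scipy.special import erfc

        assert np.allclose(t.p_raw, 0.5 * erfc(b / np.sqrt(2)))

    def test_uniform_under_null_probability_integral_transform(self):
        # raw p-values of N(0,1) draws are Uniform(0,1); KS at alpha=0.01
        passes = 0
        for seed in range(20):
            d = np.random.default_rng(seed).normal(size=1000)
            t = normal_pvalues(self._diff(d))
            if stats.kstest(t.p_raw, "uniform").pvalue > 0.01:
                passes += 1
        assert passes >= 18

    def test_constant_differences_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            normal_pvalues(self._diff(np.full(10, 0.5)))

    def test_two_sided_tail(self, rng):
        d = rng.normal(size=500)
        up = normal_pvalues(self._diff(d), StatParams(tail="upper"))
        two = normal_pvalues(self._diff(d), StatParams(tail="two_sided"))
        z = (d - up.mu_hat) / up.sigma_hat
        assert np.allclose(two.p_raw, 2 * stats.norm.sf(np.abs(z)))


class TestHochberg:
    def test_single_test_is_identity(self):
        assert hochberg_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        adj = hochberg_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_suffix_min_beats_cap(self):
        # for (0.5, 0.9): adjusted_(1) = min(2*0.5, 1*0.9) = 0.9 — the
        # suffix minimum, not the capped 2*0.5 = 1.0
        adj = hochberg_adjust(np.array([0.5, 0.9]))
        assert np.allclose(adj, [0.9, 0.9])
        assert np.allclose(brute_force_hochberg([0.5, 0.9]), [0.9, 0.9])

    def test_cap_at_one(self):
        adj = hochberg_adjust(np.array([0.6, 0.7, 0.9]))
        assert adj.max() <= 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 200))
            p = rng.uniform(size=n)
            assert np.allclose(hochberg_adjust(p), brute_force_hochberg(p))

    def test_ties_share_adjusted_value(self):
        adj = hochberg_adjust(np.array([0.02, 0.02, 0.5]))
        assert adj[0] == adj[1]

    def test_dominated_by_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(2, 100)))
            bonf = np.minimum(len(p) * p, 1.0)
            assert np.all(hochberg_adjust(p) <= bonf + 1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        assert np.all(hochberg_adjust(p) >= p - 1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(hochberg_adjust(p)[perm], hochberg_adjust(p[perm]))

    def test_nan_passthrough_excluded_from_n(self):
        p = np.array([0.03, np.nan])
        adj = hochberg_adjust(p)
        assert adj[0] == pytest.approx(0.03)  # n = 1, not 2
        assert np.isnan(adj[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust(np.array([0.5, 1.5]))


class TestSignificantPositions:
    def _track_with_padj(self, p_adj):
        n = len(p_adj)
        return DifferenceTrack(
            grid_positions=np.arange(25, 25 * (n + 1), 25),
            d=np.linspace(0.1, 0.2, n), p_adj=np.asarray(p_adj, dtype=float),
        )

    def test_no_significant_positions(self):
        t = self._track_with_padj([0.5] * 10)
        assert significant_positions(t, StatParams()) == []

    def test_threshold_is_inclusive(self):
        t = self._track_with_padj([0.5, 1e-4, 0.5])
        sig = significant_positions(t, StatParams())
        assert [p for p, _, _ in sig] == [50]

    def test_count_matches_filter_recount(self, rng):
        p_adj = rng.uniform(size=500) ** 4  # some small values
        t = self._track_with_padj(p_adj)
        sig = significant_positions(t, StatParams())
        assert len(sig) == int(np.sum(p_adj <= 1e-4))

    def test_positions_in_genomic_order(self, rng):
        t = self._track_with_padj(rng.uniform(size=200) ** 6)
        sig = significant_positions(t, StatParams())
        pos = [p for p, _, _ in sig]
        assert pos == sorted(pos)


def test_call_condition_composes_all_stages(rng):
    ip = _track(rng.poisson(50, 20_000))
    total = _track(rng.poisson(50, 20_000))
    t = call_condition(ip, total)
    assert t.p_adj is not None and t.mu_hat is not None
    ok = ~np.isnan(t.p_adj)
    assert np.all(t.p_adj[ok] >= t.p_raw[ok] - 1e-12)
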