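"""Exact trend-test tails against enumeration oracles, trend classification
on generated gradients, and breakpoint recovery."""

import itertools
import math

import numpy as np
import pytest

from biofilmgeo.spatial import (
    breakpoint_fit,
    classify_trends,
    runs_distribution,
    runs_test,
    spearman_trend,
)
from biofilmgeo.synthetic import (
    SyntheticConfig,
    generate_biofilm,
    generate_distance_decay,
)


def exact_spearman_tail(x, y, rho_obs):
    """Two-sided permutation tail by direct enumeration of orderings."""
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    hits = total = 0
    for perm in itertools.permutations(range(len(x))):
        rho = float(rx_c[list(perm)] @ ry_c) / denom
        hits += abs(rho) >= abs(rho_obs) - 1e-9
        total += 1
    return hits / total


def runs_count(seq):
    return 1 + sum(a != b for a, b in zip(seq, seq[1:]))


class TestSpearmanTrend:
    def test_perfect_monotone(self):
        up = spearman_trend([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        down = spearman_trend([5, 4, 3, 2, 1], [1, 2, 3, 4, 5])
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_constant_series_degenerate(self):
        res = spearman_trend([2, 2, 2, 2], [1, 2, 3, 4])
        assert res == (0.0, 1.0, True)

    def test_exact_p_small_example(self):
        res = spearman_trend([1, 2, 3, 5, 4], [1, 2, 3, 4, 5])
        assert res.rho == pytest.approx(0.9)
        assert res.p == pytest.approx(
            exact_spearman_tail([1, 2, 3, 5, 4], [1, 2, 3, 4, 5], 0.9))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        """All n <= 7 inputs agree with the full permutation oracle."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        x = rng.normal(size=n)
        if seed % 2:  # exercise ties
            x = np.round(x)
            if np.ptp(x) == 0:
                x[0] += 1
        y = np.arange(n, dtype=float)
        res = spearman_trend(x, y)
        assert res.p == pytest.approx(exact_spearman_tail(x, y, res.rho))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_trend([1, 2, 3], [1, 2, 3])


class TestRunsTest:
    def test_blocked_series_one_tail(self):
        """(1,1,1,0,0,0): R=2 with n1=n2=3; one tail is 2/20, doubled."""
        res = runs_test([1, 1, 1, 0, 0, 0])
        assert res.n_runs == 2 and res.n_above == res.n_below == 3
        assert res.p == pytest.approx(2 * 0.1)

    def test_alternating_series_small_p(self):
        res = runs_test([0, 1] * 6)
        assert res.n_runs == 12
        pmf = runs_distribution(6, 6)
        assert res.p == pytest.approx(min(1.0, 2 * pmf[12:].sum()))
        assert res.p < 0.01

    def test_distribution_sums_to_one(self):
        for n1, n2 in [(3, 3), (5, 7), (12, 12), (2, 10)]:
            assert runs_distribution(n1, n2).sum() == pytest.approx(1.0)

    def test_distribution_matches_enumeration(self):
        """Exact runs pmf equals counting over all arrangements, n1+n2 <= 12."""
        for n1, n2 in [(3, 3), (4, 6), (6, 6), (5, 5)]:
            pmf = runs_distribution(n1, n2)
            counts = np.zeros(n1 + n2 + 1)
            for pos in itertools.combinations(range(n1 + n2), n1):
                seq = np.zeros(n1 + n2, dtype=int)
                seq[list(pos)] = 1
                counts[runs_count(seq)] += 1
            np.testing.assert_allclose(pmf, counts / counts.sum(), atol=1e-12)

    def test_exact_and_normal_regimes_agree(self):
        """At n1 = n2 = 10 the normal approximation with continuity
        correction tracks the exact tail within 0.02 for every runs count."""
        from scipy.stats import norm
        n1 = n2 = 10
        pmf = runs_distribution(n1, n2)
        n = n1 + n2
        mu = 1 + 2 * n1 * n2 / n
        sd = math.sqrt(2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1)))
        for r in range(2, n + 1):
            exact = min(1.0, 2 * min(pmf[: r + 1].sum(), pmf[r:].sum()))
            approx = min(1.0, 2 * norm.sf((abs(r - mu) - 0.5) / sd))
            assert abs(exact - approx) < 0.02, r

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            runs_test([3, 3, 3, 3, 3, 3])


class TestClassifyTrends:
    def test_strong_gradients_detected(self):
        """Nearly all taxa flagged monotonic when every taxon has a strong
        gradient and noise is low."""
        cfg = SyntheticConfig(n_taxa=100, n_sections=100, depth=10_000,
                              n_sides=1, frac_monotonic=1.0, frac_peaked=0.0,
                              gradient_strength=0.05,
                              noise_overdispersion=50.0, seed=17)
        table, meta, _ = generate_biofilm(cfg)
        res = classify_trends(table, meta)
        assert (res.classification == "monotonic").mean() >= 0.9

    def test_null_preset_controls_fdr(self):
        """Without spatial structure the detected fraction stays near the
        BH-controlled false-discovery level."""
        fracs = []
        for seed in range(8):
            cfg = SyntheticConfig(n_taxa=80, n_sections=60, depth=2000,
                                  frac_monotonic=0.0, frac_peaked=0.0,
                                  noise_overdispersion=5.0, seed=seed)
            table, meta, _ = generate_biofilm(cfg)
            res = classify_trends(table, meta, alpha_level=0.05)
            fracs.append((res.classification != "none").mean())
        assert np.mean(fracs) <= 0.05

    def test_patterned_taxa_recalled(self):
        """Taxa generated with strong monotonic gradients are recalled as
        patterned.  The detected fraction over all taxa can exceed the
        generated fraction because compositional closure induces real
        compensatory trends in the remaining taxa, so recall on the
        ground-truth roles is the meaningful consistency check."""
        recalls = []
        for seed in range(10):
            cfg = SyntheticConfig(n_taxa=100, n_sections=100, depth=5000,
                                  frac_monotonic=0.2, frac_peaked=0.1,
                                  gradient_strength=0.06,
                                  noise_overdispersion=10.0, seed=seed)
            table, meta, _ = generate_biofilm(cfg)
            res = classify_trends(table, meta).set_index("taxon_id")
            roles = meta.attrs["spatial_roles"]
            mono = [t for t, r in roles.items() if r == "monotonic"]
            recalls.append(
                (res.loc[mono, "classification"] != "none").mean())
        assert np.mean(recalls) >= 0.8

    def test_deterministic(self, small_survey):
        table, meta, _ = small_survey
        a = classify_trends(table, meta)
        b = classify_trends(table, meta)
        assert a.equals(b)

    def test_bh_adjustment_monotone(self, small_survey):
        table, meta, _ = small_survey
        res = classify_trends(table, meta)
        assert (res.rho_p_adj >= res.spearman_p - 1e-12).all()
        tested = res[~res.degenerate].sort_values("spearman_p")
        assert tested.rho_p_adj.is_monotonic_increasing


class TestBreakpointFit:
    def test_noiseless_two_segment_recovered(self):
        df = generate_distance_decay(200, breakpoint_cm=30, slope1=0.012,
                                     slope2=0.002, noise_sd=0.0,
                                     max_distance_cm=100, seed=2)
        fit = breakpoint_fit(df.distance_cm, df.dissimilarity, n_boot=20, seed=0)
        assert fit.breakpoint_cm == pytest.approx(30, abs=0.5)
        assert fit.sse < 1e-8
        assert not fit.no_breakpoint
        assert fit.slope_left == pytest.approx(0.012, abs=1e-4)
        assert fit.slope_right == pytest.approx(0.002, abs=1e-4)

    def test_single_slope_flags_no_breakpoint(self):
        df = generate_distance_decay(200, breakpoint_cm=30, slope1=0.005,
                                     slope2=0.005, noise_sd=0.002, seed=5)
        fit = breakpoint_fit(df.distance_cm, df.dissimilarity, n_boot=20, seed=0)
        assert fit.no_breakpoint

    def test_sse_never_exceeds_single_line(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = rng.uniform(0, 100, 80)
            y = np.clip(0.2 + 0.004 * d + rng.normal(0, 0.05, 80), 0, 1)
            fit = breakpoint_fit(d, y, n_boot=5, seed=0)
            assert fit.sse <= fit.sse_single_line + 1e-9

    def test_recovery_within_bootstrap_se(self):
        """Known 40 cm breakpoint recovered within 3 bootstrap SE in nearly
        all seeded replicates."""
        hits = 0
        n_runs = 15
        for seed in range(n_runs):
            df = generate_distance_decay(500, breakpoint_cm=40, slope1=0.012,
                                         slope2=0.003, noise_sd=0.02,
                                         max_distance_cm=120, seed=seed)
            fit = breakpoint_fit(df.distance_cm, df.dissimilarity,
                                 n_boot=60, seed=seed)
            hits += abs(fit.breakpoint_cm - 40) <= 3 * fit.breakpoint_se_cm
        assert hits >= 0.9 * n_runs

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 10"):
            breakpoint_fit([1] * 5, [0.1] * 5)
        with pytest.raises(ValueError, match="span"):
            breakpoint_fit([1.0] * 12, [0.1] * 12)
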