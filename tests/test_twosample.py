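"""Two-sample MR estimators against independent algebraic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from mrphewas import (SummaryStatsPair, TwoSampleMR, egger, harmonize, ivw,
                      mode_based, wald_ratio, weighted_median)


def make_pairs(rng, k=20, theta=0.1):
    bx = rng.uniform(0.1, 0.6, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.005, 0.03, k)
    by = theta * bx + rng.normal(0, 1, k) * sy
    return [SummaryStatsPair(f"rs{i}", bx[i], sx[i], by[i], sy[i])
            for i in range(k)]


def stats_frame(rows):
    return pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele",
                                       "eaf", "beta", "se"])


class TestHarmonize:
    def test_identical_alleles_pass_through(self):
        exp = stats_frame([["rs1", "A", "G", 0.3, 0.2, 0.02]])
        out = stats_frame([["rs1", "A", "G", 0.31, 0.05, 0.01]])
        pairs, exc = harmonize(exp, out)
        assert len(pairs) == 1 and not exc
        assert pairs[0].beta_y == pytest.approx(0.05)

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = stats_frame([["rs1", "A", "G", 0.3, 0.2, 0.02]])
        out = stats_frame([["rs1", "G", "A", 0.7, 0.05, 0.01]])
        pairs, _ = harmonize(exp, out)
        assert pairs[0].beta_y == pytest.approx(-0.05)

    def test_strand_flip_resolved(self):
        exp = stats_frame([["rs1", "A", "G", 0.3, 0.2, 0.02]])
        out = stats_frame([["rs1", "T", "C", 0.3, 0.05, 0.01]])  # complements
        pairs, exc = harmonize(exp, out)
        assert len(pairs) == 1
        assert pairs[0].beta_y == pytest.approx(0.05)

    def test_palindromic_ambiguous_frequency_excluded(self):
        exp = stats_frame([["rs1", "A", "T", 0.5, 0.2, 0.02]])
        out = stats_frame([["rs1", "A", "T", 0.5, 0.05, 0.01]])
        pairs, exc = harmonize(exp, out)
        assert pairs == []
        assert exc[0] == ("rs1", "palindromic_ambiguous")

    def test_palindromic_clear_frequency_aligned(self):
        exp = stats_frame([["rs1", "A", "T", 0.1, 0.2, 0.02]])
        out = stats_frame([["rs1", "A", "T", 0.9, 0.05, 0.01]])  # other strand
        pairs, _ = harmonize(exp, out)
        assert pairs[0].beta_y == pytest.approx(-0.05)

    def test_irreconcilable_alleles_excluded_with_reason(self):
        exp = stats_frame([["rs1", "A", "G", 0.3, 0.2, 0.02]])
        out = stats_frame([["rs1", "A", "C", 0.3, 0.05, 0.01]])
        pairs, exc = harmonize(exp, out)
        assert pairs == []
        assert exc[0] == ("rs1", "allele_mismatch")

    def test_unmatched_snps_logged(self):
        exp = stats_frame([["rs1", "A", "G", 0.3, 0.2, 0.02]])
        out = stats_frame([["rs2", "A", "G", 0.3, 0.05, 0.01]])
        pairs, exc = harmonize(exp, out)
        assert pairs == []
        assert ("rs1", "not_in_outcome") in exc
        assert ("rs2", "not_in_exposure") in exc


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(SummaryStatsPair("rs1", 0.5, 0.01, 0.05, 0.01),
                         per_decrease=False)
        assert est.estimate == pytest.approx(0.1)
        assert est.se == pytest.approx(0.02)

    def test_zero_outcome_beta_gives_zero(self):
        est = wald_ratio(SummaryStatsPair("rs1", 0.5, 0.01, 0.0, 0.01))
        assert est.estimate == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(SummaryStatsPair("rs1", 0.0, 0.01, 0.05, 0.01))

    def test_delta_se_close_to_bootstrap_se(self, rng):
        pair = SummaryStatsPair("rs1", 0.5, 1e-6, 0.05, 0.01)
        est = wald_ratio(pair, per_decrease=False)
        boot = (pair.beta_y + rng.normal(0, pair.se_y, 200_000)) / pair.beta_x
        assert est.se == pytest.approx(np.std(boot), rel=0.05)


def wls_oracle(bx, by, w, intercept):
    """Weighted-least-squares normal equations, independent of the package."""
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * by)
    return np.linalg.solve(A, b)


class TestIvw:
    def test_all_zero_outcome_betas(self, rng):
        pairs = [SummaryStatsPair(f"rs{i}", 0.2 + 0.01 * i, 0.01, 0.0, 0.01)
                 for i in range(5)]
        assert ivw(pairs).estimate == 0.0

    def test_single_pair_delegates_to_wald_ratio(self):
        est = ivw([SummaryStatsPair("rs1", 0.5, 0.01, 0.05, 0.01)],
                  per_decrease=False)
        assert est.method == "wald_ratio"
        assert est.estimate == pytest.approx(0.1)

    def test_collinear_printed_fixture_exact(self):
        pairs = [SummaryStatsPair("a", 0.5, 0.01, 0.05, 0.01),
                 SummaryStatsPair("b", 0.3, 0.01, 0.03, 0.01),
                 SummaryStatsPair("c", 0.2, 0.01, 0.02, 0.01)]
        assert ivw(pairs, per_decrease=False).estimate == pytest.approx(0.1)

    def test_matches_wls_through_origin_oracle_to_8_digits(self, rng):
        for _ in range(100):
            pairs = make_pairs(rng, k=15, theta=rng.normal(0, 0.2))
            bx, _, by, sy = (np.array([getattr(p, a) for p in pairs])
                             for a in ("beta_x", "se_x", "beta_y", "se_y"))
            expected = wls_oracle(bx, by, 1 / sy**2, intercept=False)[0]
            got = ivw(pairs, per_decrease=False).estimate
            assert got == pytest.approx(expected, abs=1e-8)

    def test_sign_convention_flip(self, rng):
        pairs = make_pairs(rng, theta=0.1)
        inc = ivw(pairs, per_decrease=False).estimate
        dec = ivw(pairs, per_decrease=True).estimate
        assert inc == pytest.approx(-dec)


class TestEgger:
    def test_matches_wls_oracle_to_8_digits(self, rng):
        for _ in range(100):
            pairs = make_pairs(rng, k=15, theta=rng.normal(0, 0.2))
            bx, _, by, sy = (np.array([getattr(p, a) for p in pairs])
                             for a in ("beta_x", "se_x", "beta_y", "se_y"))
            sign = np.where(bx < 0, -1.0, 1.0)
            expected = wls_oracle(bx * sign, by * sign, 1 / sy**2,
                                  intercept=True)
            est = egger(pairs, per_decrease=False)
            assert est.intercept == pytest.approx(expected[0], abs=1e-8)
            assert est.estimate == pytest.approx(expected[1], abs=1e-8)

    def test_null_intercept_without_pleiotropy(self, rng):
        pairs = make_pairs(rng, k=50, theta=0.1)
        est = egger(pairs)
        assert abs(est.intercept) < 3 * est.intercept_se

    def test_intercept_constrained_to_zero_is_fixed_effect_ivw(self, rng):
        # algebraic cross-check: forcing the line through the origin
        # reproduces the fixed-effect IVW slope on any fixture
        pairs = make_pairs(rng, k=12, theta=0.15)
        bx, _, by, sy = (np.array([getattr(p, a) for p in pairs])
                         for a in ("beta_x", "se_x", "beta_y", "se_y"))
        sign = np.where(bx < 0, -1.0, 1.0)
        constrained = wls_oracle(bx * sign, by * sign, 1 / sy**2,
                                 intercept=False)[0]
        assert ivw(pairs, per_decrease=False).estimate == pytest.approx(
            constrained, abs=1e-10)

    def test_needs_three_instruments(self, rng):
        with pytest.raises(ValueError):
            egger(make_pairs(rng, k=2))


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_ordinary_median(self):
        pairs = [SummaryStatsPair(f"rs{i}", 1.0, 0.01, r, 0.01)
                 for i, r in enumerate([0.05, 0.1, 0.2])]
        est = weighted_median(pairs, n_boot=50, per_decrease=False)
        assert est.estimate == pytest.approx(0.1)

    def test_dominant_weight_snp_returns_its_ratio(self):
        # middle SNP carries > 50% of the weight
        pairs = [SummaryStatsPair("a", 1.0, 0.01, 0.05, 0.05),
                 SummaryStatsPair("b", 1.0, 0.01, 0.10, 0.005),
                 SummaryStatsPair("c", 1.0, 0.01, 0.20, 0.05)]
        est = weighted_median(pairs, n_boot=50, per_decrease=False)
        assert est.estimate == pytest.approx(0.10, abs=1e-6)

    def test_matches_exhaustive_interpolation_oracle(self, rng):
        pairs = make_pairs(rng, k=5, theta=0.1)
        est = weighted_median(pairs, n_boot=50, per_decrease=False)
        ratios = np.array([p.beta_y / p.beta_x for p in pairs])
        w = np.array([(abs(p.beta_x) / p.se_y) ** 2 for p in pairs])
        order = np.argsort(ratios)
        r, ww = ratios[order], w[order] / w.sum()
        cum = np.cumsum(ww) - 0.5 * ww
        below = np.where(cum < 0.5)[0]
        j = below[-1]
        expected = r[j] + (r[j + 1] - r[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j])
        assert est.estimate == pytest.approx(expected, abs=1e-12)

    def test_zero_beta_x_snp_excluded(self, rng):
        pairs = make_pairs(rng, k=5) + [
            SummaryStatsPair("z", 0.0, 0.01, 0.05, 0.01)]
        est = weighted_median(pairs, n_boot=50)
        assert est.n_snps == 5


class TestModeBased:
    def test_identical_ratios_return_common_value(self):
        pairs = [SummaryStatsPair(f"rs{i}", b, 0.01, 0.1 * b, 0.01)
                 for i, b in enumerate([0.2, 0.4, 0.5])]
        est = mode_based(pairs, n_boot=50, per_decrease=False)
        assert est.estimate == pytest.approx(0.1)

    def test_heavier_cluster_wins(self, rng):
        # 12 ratios near 0.1, 4 outliers near 0.5
        pairs = ([SummaryStatsPair(f"a{i}", 0.5, 0.01,
                                   0.5 * (0.1 + rng.normal(0, 0.003)), 0.01)
                  for i in range(12)]
                 + [SummaryStatsPair(f"b{i}", 0.5, 0.01,
                                     0.5 * (0.5 + rng.normal(0, 0.003)), 0.01)
                    for i in range(4)])
        est = mode_based(pairs, n_boot=50, per_decrease=False)
        assert est.estimate == pytest.approx(0.1, abs=0.05)

    def test_uniform_weights_match_simple_mode(self, rng):
        pairs = [SummaryStatsPair(f"rs{i}", 0.3, 0.01,
                                  0.3 * rng.normal(0.1, 0.02), 0.01)
                 for i in range(10)]  # identical se_y and |beta_x| -> equal w
        simple = mode_based(pairs, weighted=False, n_boot=10, seed=1)
        weighted = mode_based(pairs, weighted=True, n_boot=10, seed=1)
        assert simple.estimate == pytest.approx(weighted.estimate)


class TestInvariancesAndSuite:
    @settings(max_examples=20, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_joint_sign_flip_equivariance(self, seed):
        """Relabeling alleles (flipping beta_x and beta_y together for any
        subset) leaves every estimator's causal estimate unchanged."""
        rng = np.random.default_rng(seed)
        pairs = make_pairs(rng, k=8, theta=0.1)
        flip = rng.random(8) < 0.5
        flipped = [SummaryStatsPair(p.snp, -p.beta_x if f else p.beta_x,
                                    p.se_x, -p.beta_y if f else p.beta_y,
                                    p.se_y)
                   for p, f in zip(pairs, flip)]
        for fn in (lambda q: ivw(q, per_decrease=False),
                   lambda q: egger(q, per_decrease=False),
                   lambda q: weighted_median(q, n_boot=10, seed=3,
                                             per_decrease=False)):
            assert fn(pairs).estimate == pytest.approx(fn(flipped).estimate,
                                                       abs=1e-10)

    def test_cross_estimator_concordance_under_no_pleiotropy(self, rng):
        pairs = make_pairs(rng, k=150, theta=0.1)
        model = TwoSampleMR(pairs)
        res = model.fit(n_boot=200, seed=9, per_decrease=False)
        for est in res.estimates:
            assert est.estimate == pytest.approx(0.1, abs=3 * est.se)

    def test_results_frame_and_summary(self, rng):
        res = TwoSampleMR(make_pairs(rng)).fit(n_boot=50, seed=1)
        df = res.to_frame()
        assert list(df["method"]) == ["ivw", "egger", "weighted_median",
                                      "simple_mode", "weighted_mode"]
        assert "intercept" in res.summary() or "ivw" in res.summary()
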