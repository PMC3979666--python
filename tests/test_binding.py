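"""ZIB/binomial emission model: pmfs, estimation, and site decoding."""

import math

import numpy as np
import pytest

from clipcall import binding
from clipcall.clustering import BaseProfile
from tests import oracles


def exact_binom(m, x, p):
    """Exact-arithmetic oracle, independent of scipy."""
    return math.comb(x, m) * p**m * (1 - p) ** (x - m)


class TestBinomialPmf:
    @pytest.mark.parametrize(
        "m,x,p",
        [(3, 10, 0.2), (3, 10, 0.1), (30, 100, 0.2), (30, 100, 0.1), (0, 0, 0.7)],
    )
    def test_matches_exact_arithmetic(self, m, x, p):
        assert binding.binomial_pmf(m, x, p) == pytest.approx(
            exact_binom(m, x, p), rel=1e-12
        )

    def test_empty_trial_is_certain(self):
        assert binding.binomial_pmf(0, 0, 0.3) == 1.0

    def test_m_above_x_rejected(self):
        with pytest.raises(ValueError):
            binding.binomial_pmf(5, 3, 0.2)


class TestZibPmf:
    def test_reduces_to_binomial_at_zero_inflation(self):
        for m, x, p in [(0, 5, 0.1), (2, 9, 0.3), (9, 9, 0.8)]:
            assert binding.zib_pmf(m, x, p, 0.0) == pytest.approx(
                exact_binom(m, x, p)
            )

    def test_stated_zero_mass_value(self):
        assert binding.zib_pmf(0, 5, 0.1, 0.5) == pytest.approx(
            0.5 + 0.5 * 0.9**5
        )
        assert binding.zib_pmf(0, 5, 0.1, 0.5) == pytest.approx(0.795245)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalizes_over_support(self, seed):
        rng = np.random.default_rng(seed)
        x = int(rng.integers(1, 60))
        p = rng.uniform(0.01, 0.9)
        phi = rng.uniform(0.0, 0.95)
        total = sum(binding.zib_pmf(m, x, p, phi) for m in range(x + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_nonzero_mass_scaled_by_one_minus_phi(self):
        assert binding.zib_pmf(2, 10, 0.2, 0.4) == pytest.approx(
            0.6 * exact_binom(2, 10, 0.2)
        )


class TestEstimateModes:
    def test_recovers_two_planted_modes(self):
        rng = np.random.default_rng(8)
        rates = np.concatenate(
            [
                np.clip(rng.normal(0.01, 0.015, 8000), 1e-4, 1.0),
                np.clip(rng.normal(0.25, 0.04, 2000), 1e-4, 1.0),
            ]
        )
        m0, m1 = binding.estimate_mutation_modes(rates)
        assert abs(m0 - 0.01) < 0.05
        assert abs(m1 - 0.25) < 0.05

    def test_all_zero_rates_fail(self):
        with pytest.raises(binding.ModeEstimationError):
            binding.estimate_mutation_modes(np.zeros(500))

    def test_modes_invariant_to_sample_duplication(self):
        rng = np.random.default_rng(9)
        rates = np.concatenate(
            [rng.uniform(0.0, 0.08, 3000), rng.uniform(0.2, 0.3, 800)]
        )
        once = binding.estimate_mutation_modes(rates)
        twice = binding.estimate_mutation_modes(np.concatenate([rates, rates]))
        # duplication only tightens the KDE bandwidth (n-dependent rule);
        # mode locations stay put
        assert once == pytest.approx(twice, abs=0.01)

    def test_single_mode_falls_back_to_upper_quantile(self):
        rng = np.random.default_rng(10)
        rates = np.clip(rng.normal(0.05, 0.01, 5000), 1e-4, 1.0)
        m0, m1 = binding.estimate_mutation_modes(rates)
        assert abs(m0 - 0.05) < 0.02
        assert m1 == pytest.approx(np.quantile(rates[rates > 0], 0.9))


class TestPartition:
    def test_threshold_is_convex_combination_of_modes(self):
        assert binding.split_threshold(0.02, 0.22, 0.5) == pytest.approx(0.12)

    def test_low_rate_base_is_background(self):
        m = np.array([1, 10])
        x = np.array([20, 20])
        candidate, tau = binding.partition_by_threshold(m, x, (0.02, 0.22), 0.5)
        assert tau == pytest.approx(0.12)
        assert candidate.tolist() == [False, True]  # 0.05 <= tau < 0.5

    def test_c_limits_move_threshold_between_modes(self):
        lo = binding.split_threshold(0.02, 0.22, 1e-9)
        hi = binding.split_threshold(0.02, 0.22, 1 - 1e-9)
        assert lo == pytest.approx(0.02)
        assert hi == pytest.approx(0.22)

    def test_empty_candidate_set_fails_with_guidance(self):
        m = np.zeros(10, int)
        x = np.full(10, 20)
        with pytest.raises(binding.ModeEstimationError, match="smaller c"):
            binding.partition_by_threshold(m, x, (0.02, 0.22), 0.5)


class TestEstimateZib:
    def test_recovers_planted_parameters(self):
        rng = np.random.default_rng(7)
        n = 50_000
        x = np.full(n, 20)
        m = rng.binomial(20, 0.05, size=n)
        m[rng.random(n) < 0.6] = 0
        p0, phi = binding.estimate_zib(m, x)
        assert abs(p0 - 0.05) / 0.05 < 0.10
        assert abs(phi - 0.6) / 0.6 < 0.10

    def test_agrees_with_em_oracle(self):
        rng = np.random.default_rng(7)
        n = 50_000
        x = rng.integers(5, 50, size=n)
        m = rng.binomial(x, 0.05)
        m[rng.random(n) < 0.6] = 0
        p0, phi = binding.estimate_zib(m, x)
        p_em, phi_em = oracles.zib_em(m, x)
        assert abs(p0 - p_em) / p_em < 0.15
        assert abs(phi - phi_em) / phi_em < 0.15

    def test_no_inflation_reduces_to_pooled_ratio(self):
        rng = np.random.default_rng(3)
        x = np.full(50_000, 20)
        m = rng.binomial(20, 0.03, size=50_000)
        p0, phi = binding.estimate_zib(m, x)
        assert phi < 0.02  # sampling noise may leave a sliver of inflation
        assert p0 == pytest.approx(m.sum() / x.sum(), rel=0.01)

    def test_all_zero_mutations_floors_rate(self):
        x = np.full(1000, 20)
        p0, phi = binding.estimate_zib(np.zeros(1000, int), x)
        assert p0 == pytest.approx(1e-6)
        assert 0 <= phi < 1


class TestEstimateBinomial:
    def test_pooled_ratio(self):
        assert binding.estimate_binomial(
            np.array([5, 3]), np.array([20, 10])
        ) == pytest.approx(8 / 30)

    def test_single_candidate(self):
        assert binding.estimate_binomial(
            np.array([2]), np.array([7])
        ) == pytest.approx(2 / 7)

    def test_recovery_at_scale(self):
        rng = np.random.default_rng(4)
        x = np.full(10_000, 25)
        m = rng.binomial(25, 0.2, size=10_000)
        assert abs(binding.estimate_binomial(m, x) - 0.2) / 0.2 < 0.05

    def test_model_order_violation_raises(self):
        with pytest.raises(binding.ModelOrderError, match="c"):
            binding.estimate_binomial(np.array([1]), np.array([100]), p0=0.05)


def make_profile(m, x, region_id=0, cluster_id=0):
    return BaseProfile(
        region_id=region_id,
        cluster_id=cluster_id,
        chrom="chr1",
        strand="+",
        start=500,
        x=np.asarray(x),
        m=np.asarray(m),
    )


class TestInferBindingSites:
    PARAMS = binding.MutationMixtureParams(
        p0=0.01, phi=0.3, p1=0.3, theta=0.05, c=0.5
    )

    def test_strong_site_in_quiet_region_scores_above_999(self):
        x = np.full(30, 45)
        m = np.zeros(30, int)
        m[14] = 14  # 14 mutant tags out of 45
        (site,) = binding.infer_binding_sites([make_profile(m, x)], self.PARAMS)
        assert site.position == 514
        assert site.m == 14 and site.x == 45
        assert site.score > 0.999

    def test_mutation_free_region_yields_no_sites(self):
        x = np.full(25, 40)
        m = np.zeros(25, int)
        assert binding.infer_binding_sites([make_profile(m, x)], self.PARAMS) == []

    def test_uncovered_bases_pinned_to_background(self):
        x = np.array([0, 0, 45, 0])
        m = np.array([0, 0, 20, 0])
        (site,) = binding.infer_binding_sites([make_profile(m, x)], self.PARAMS)
        assert site.position == 502

    def test_equal_evidence_symmetric_chain_scores_half_and_unreported(self):
        params = binding.MutationMixtureParams(
            p0=0.1, phi=0.0, p1=0.9, theta=0.5, c=0.5
        )
        # m/x = 0.5 with p0, p1 symmetric around it -> equal emissions
        x = np.array([2])
        m = np.array([1])
        sites = binding.infer_binding_sites([make_profile(m, x)], params)
        assert sites == []  # Viterbi tie resolves to background

    def test_more_tags_same_rate_scores_higher(self):
        """30/100 is stronger cross-link evidence than 3/10 at rate 0.3."""
        params = binding.MutationMixtureParams(
            p0=0.1, phi=0.0, p1=0.2, theta=0.05, c=0.5
        )
        quiet = np.zeros(10, int)
        small = binding.infer_binding_sites(
            [make_profile(np.r_[quiet, 3, quiet], np.r_[quiet + 10, 10, quiet + 10])],
            params,
            decoding="posterior",
        )
        large = binding.infer_binding_sites(
            [make_profile(np.r_[quiet, 30, quiet], np.r_[quiet + 100, 100, quiet + 100])],
            params,
            decoding="posterior",
        )
        score_small = small[0].score if small else 0.0
        assert large[0].score > score_small

    def test_posterior_decoding_selectable(self):
        x = np.full(11, 45)
        m = np.zeros(11, int)
        m[5] = 14
        for decoding in ("viterbi", "posterior"):
            (site,) = binding.infer_binding_sites(
                [make_profile(m, x)], self.PARAMS, decoding=decoding
            )
            assert site.score > 0.99
        with pytest.raises(ValueError):
            binding.infer_binding_sites([make_profile(m, x)], self.PARAMS,
                                        decoding="map")


class TestFitMutationMixture:
    def test_full_fit_on_synthetic_profiles(self):
        rng = np.random.default_rng(12)
        profiles = []
        for i in range(300):
            x = np.full(40, 30)
            m = rng.binomial(30, 0.01, size=40)
            m[rng.random(40) < 0.3] = 0
            m[20] = rng.binomial(30, 0.25)  # one site per region
            profiles.append(make_profile(m, x, region_id=i, cluster_id=i))
        params = binding.fit_mutation_mixture(profiles, c=0.5)
        assert params.p0 < 0.05 < params.p1
        assert abs(params.p1 - 0.25) / 0.25 < 0.15
        assert 0 < params.theta < 0.1
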