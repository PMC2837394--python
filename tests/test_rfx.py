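"""Random-effects inference: priors, Gibbs sampler, exceedance, VB, families.

The sampler is checked against the closed-form conjugate oracle: when every
subject's preference is decisive (log-evidence margin >= 10), the assignment
step is pinned and the frequency posterior is exactly
Dirichlet(alpha0 + counts), whose moments are known analytically.
"""

import numpy as np
import pytest

from groupbms.evidence import LogEvidenceMatrix
from groupbms.model_space import complete_partition
from groupbms.rfx import (
    DirichletParams,
    RandomEffectsBMS,
    batch_means_mcse,
    default_model_prior,
    exceedance_from_samples,
    family_posterior,
    family_uniform_prior,
    gibbs_sample,
    vb_update,
)
from groupbms.synthetic import GroupSimSpec, simulate_group_evidence


def decisive_matrix(counts, margin=10.0):
    """N x M matrix where counts[m] subjects decisively prefer model m."""
    assignments = [m for m, c in enumerate(counts) for _ in range(c)]
    spec = GroupSimSpec(n_subjects=len(assignments), assignments=tuple(assignments),
                        margin=margin, seed=0)
    L, _ = simulate_group_evidence(spec, M=len(counts))
    return L


def conjugate_moments(counts, alpha0):
    """Closed-form Dirichlet(alpha0 + counts) mean and sd — the oracle."""
    a = np.asarray(alpha0, float) + np.asarray(counts, float)
    a0 = a.sum()
    mean = a / a0
    sd = np.sqrt(a * (a0 - a) / (a0**2 * (a0 + 1)))
    return mean, sd


class TestPriors:
    def test_default_prior_is_all_ones(self):
        assert default_model_prior(3).alpha.tolist() == [1.0, 1.0, 1.0]
        assert default_model_prior(1).alpha.tolist() == [1.0]

    def test_default_prior_predictive_is_uniform(self):
        rng = np.random.default_rng(0)
        draws = rng.dirichlet(default_model_prior(4).alpha, size=50_000)
        np.testing.assert_allclose(draws.mean(axis=0), 0.25, atol=0.01)

    def test_family_uniform_prior_counts(self):
        part = complete_partition({"a": list(range(64)), "b": list(range(64, 128))}, 128)
        prior = family_uniform_prior(part)
        np.testing.assert_allclose(prior.alpha, 1.0 / 64.0)

    def test_family_uniform_reduces_to_default_for_singletons(self):
        part = complete_partition({"a": [0], "b": [1], "c": [2]}, 3)
        np.testing.assert_allclose(family_uniform_prior(part).alpha, 1.0)

    def test_family_totals_are_one(self):
        part = complete_partition({"a": [0, 1, 2], "b": [3]}, 6)
        prior = family_uniform_prior(part)
        totals = part.indicator() @ prior.alpha
        np.testing.assert_allclose(totals, 1.0)

    def test_positive_counts_enforced(self):
        with pytest.raises(ValueError):
            DirichletParams(np.array([1.0, 0.0]))


class TestExceedance:
    def test_two_column_exceedances_sum_to_one(self):
        rng = np.random.default_rng(1)
        s = rng.dirichlet([2.0, 1.0], size=5000)
        xp = exceedance_from_samples(s)
        assert xp.sum() == pytest.approx(1.0)
        assert xp[0] == pytest.approx((s[:, 0] > s[:, 1]).mean())

    def test_degenerate_identical_rows(self):
        s = np.tile([0.2, 0.5, 0.3], (10, 1))
        assert exceedance_from_samples(s).tolist() == [0.0, 1.0, 0.0]

    def test_symmetric_dirichlet_is_uniform(self):
        rng = np.random.default_rng(2)
        s = rng.dirichlet([1.0, 1.0, 1.0], size=60_000)
        np.testing.assert_allclose(exceedance_from_samples(s), 1 / 3, atol=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exceedance_from_samples(np.empty((0, 2)))


class TestGibbs:
    def test_single_model_degenerate(self):
        L = LogEvidenceMatrix(np.zeros((3, 1)), ("a", "b", "c"), ("m1",))
        res = gibbs_sample(L, default_model_prior(1), n_total=200, burn_in=50, seed=0)
        np.testing.assert_allclose(res.r_samples, 1.0)
        assert res.exceedance.tolist() == [1.0]

    def test_invariants_of_retained_draws(self):
        L = decisive_matrix([3, 2])
        res = gibbs_sample(L, default_model_prior(2), n_total=2000, burn_in=500, seed=3)
        np.testing.assert_allclose(res.r_samples.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(res.g.sum(axis=1), 1.0, atol=1e-10)
        assert res.r_samples.shape == (1500, 2)
        assert res.seed == 3 and res.burn_in == 500 and res.n_total == 2000

    def test_conjugate_oracle_decisive_counts(self):
        """Decisive evidence pins assignments: posterior = Dirichlet(alpha0 + c)."""
        counts = [5, 3, 2]
        L = decisive_matrix(counts)
        res = gibbs_sample(L, default_model_prior(3), n_total=12_000, burn_in=2_000, seed=4)
        mean, _ = conjugate_moments(counts, [1, 1, 1])
        mcse = batch_means_mcse(res.r_samples)
        assert (np.abs(res.expected_r - mean) < 3 * np.maximum(mcse, 1e-4)).all()

    def test_comparison_set_proportions(self):
        """17 subjects split 7/10: expected frequencies track the proportions."""
        L = decisive_matrix([7, 10])
        res = gibbs_sample(L, default_model_prior(2), n_total=12_000, burn_in=2_000, seed=5)
        mean, _ = conjugate_moments([7, 10], [1, 1])  # (8/19, 11/19)
        np.testing.assert_allclose(res.expected_r, mean, atol=0.01)
        assert res.best_model == 1

    def test_prior_preservation_flat_evidence(self):
        L = LogEvidenceMatrix(np.zeros((4, 3)), tuple("abcd"), ("m1", "m2", "m3"))
        alpha0 = np.array([2.0, 1.0, 1.0])
        res = gibbs_sample(L, alpha0, n_total=20_000, burn_in=4_000, seed=6)
        np.testing.assert_allclose(res.expected_r, alpha0 / alpha0.sum(), atol=0.02)

    def test_chains_agree_across_seeds(self):
        L = decisive_matrix([4, 6])
        r1 = gibbs_sample(L, default_model_prior(2), 12_000, 2_000, seed=10)
        r2 = gibbs_sample(L, default_model_prior(2), 12_000, 2_000, seed=11)
        se = np.sqrt(batch_means_mcse(r1.r_samples) ** 2 + batch_means_mcse(r2.r_samples) ** 2)
        assert (np.abs(r1.expected_r - r2.expected_r) < 3 * np.maximum(se, 1e-4)).all()

    def test_same_seed_is_reproducible(self):
        L = decisive_matrix([2, 3])
        r1 = gibbs_sample(L, default_model_prior(2), 1000, 200, seed=42)
        r2 = gibbs_sample(L, default_model_prior(2), 1000, 200, seed=42)
        np.testing.assert_array_equal(r1.r_samples, r2.r_samples)
        np.testing.assert_array_equal(r1.g, r2.g)

    def test_small_shape_prior_yields_valid_simplex_draws(self):
        """Family-uniform priors (alpha = 1/64) must not underflow to zeros."""
        part = complete_partition(
            {"a": list(range(64)), "b": list(range(64, 128))}, 128
        )
        L = LogEvidenceMatrix(
            np.zeros((2, 128)), ("s1", "s2"), tuple(f"m{i}" for i in range(128))
        )
        res = gibbs_sample(L, family_uniform_prior(part), 300, 100, seed=7)
        assert np.isfinite(res.r_samples).all()
        assert (res.r_samples > 0).all()
        np.testing.assert_allclose(res.r_samples.sum(axis=1), 1.0, atol=1e-9)

    def test_argument_validation(self):
        L = decisive_matrix([1, 1])
        with pytest.raises(ValueError):
            gibbs_sample(L, default_model_prior(2), n_total=100, burn_in=100)
        with pytest.raises(ValueError):
            gibbs_sample(L, default_model_prior(3), n_total=100, burn_in=10)


class TestFamilyRfx:
    def test_single_family_is_certain(self):
        L = decisive_matrix([2, 2])
        res = gibbs_sample(L, default_model_prior(2), 1000, 200, seed=8)
        fam = family_posterior(res, complete_partition({}, 2))
        np.testing.assert_allclose(fam.s_samples, 1.0)

    def test_flat_evidence_family_uniform_gives_1_over_K(self):
        """Unequal family sizes, flat data: family posterior stays uniform."""
        part = complete_partition({"a": [0], "b": [1, 2], "c": [3, 4, 5, 6]}, 7)
        L = LogEvidenceMatrix(
            np.zeros((5, 7)), tuple(f"s{i}" for i in range(5)), tuple(f"m{i}" for i in range(7))
        )
        res = gibbs_sample(L, family_uniform_prior(part), 20_000, 4_000, seed=9)
        fam = family_posterior(res, part)
        mcse = np.maximum(fam.mcse, 1e-3)
        assert (np.abs(fam.expected_s - 1 / 3) < 3 * mcse).all()

    def test_family_frequencies_sum_to_one(self):
        L = decisive_matrix([3, 1, 2])
        res = gibbs_sample(L, default_model_prior(3), 2000, 500, seed=12)
        fam = family_posterior(res, complete_partition({"x": [0, 2]}, 3, remainder_name="y"))
        np.testing.assert_allclose(fam.s_samples.sum(axis=1), 1.0, atol=1e-10)
        assert fam.expected_s.sum() == pytest.approx(1.0)

    def test_partition_must_cover(self):
        L = decisive_matrix([1, 1])
        res = gibbs_sample(L, default_model_prior(2), 500, 100, seed=13)
        with pytest.raises(ValueError):
            family_posterior(res, complete_partition({}, 3))


class TestVariational:
    def test_agrees_with_gibbs_at_unit_counts(self):
        L = decisive_matrix([7, 10])
        vb = vb_update(L, default_model_prior(2))
        gibbs = gibbs_sample(L, default_model_prior(2), 12_000, 2_000, seed=14)
        np.testing.assert_allclose(vb.expected_r, gibbs.expected_r, atol=0.02)

    def test_flat_evidence_fixed_point(self):
        N, M = 6, 3
        L = LogEvidenceMatrix(
            np.zeros((N, M)), tuple(f"s{i}" for i in range(N)), tuple(f"m{i}" for i in range(M))
        )
        vb = vb_update(L, default_model_prior(M))
        np.testing.assert_allclose(vb.alpha, 1.0 + N / M, atol=1e-5)
        assert vb.converged

    def test_warns_for_small_prior_counts(self):
        L = decisive_matrix([2, 2])
        with pytest.warns(UserWarning, match="Gibbs"):
            vb_update(L, DirichletParams(np.array([1 / 64, 1 / 64])))

    def test_exceedance_available(self):
        L = decisive_matrix([3, 7])
        vb = vb_update(L, default_model_prior(2))
        xp = vb.exceedance
        assert xp.sum() == pytest.approx(1.0, abs=0.01)
        assert xp[1] > xp[0]


class TestModelInterface:
    def test_model_fit_summary(self):
        L = decisive_matrix([3, 2])
        part = complete_partition({"a": [0]}, 2, remainder_name="b")
        model = RandomEffectsBMS(L, prior="family-uniform", partition=part)
        res = model.fit(n_total=2000, burn_in=500, seed=15)
        txt = res.summary()
        assert "expected_r" in txt and "exceedance" in txt
        fam = res.family(part)
        assert "expected_s" in fam.summary()
        d = res.to_dict()
        assert set(d) >= {"expected_r", "exceedance", "g", "seed"}

    def test_bad_prior_name(self):
        L = decisive_matrix([1, 1])
        with pytest.raises(ValueError):
            RandomEffectsBMS(L, prior="bogus")
        with pytest.raises(ValueError):
            RandomEffectsBMS(L, prior="family-uniform")  # no partition
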