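import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from f2impute import (
    GenomeMap,
    HMMParams,
    HaplotypeImputer,
    em_update,
    emission_likelihood,
    forward_backward_diploid,
    info_score,
    make_genome_map,
    run_em,
    transition_schedule,
)
from f2impute.hmm import _e_step, _e_step_numpy
from conftest import enumerate_paths, random_instance


def simple_map(positions, length=10_000_000, exp_rate=2.0):
    pos = np.asarray(positions, dtype=np.int64)
    return GenomeMap((("chr1", length),), np.zeros(len(pos), dtype=int), pos, exp_rate)


class TestTransitionSchedule:
    def test_one_megabase_interval(self):
        gm = simple_map([1, 1_000_001])
        rho = transition_schedule(gm, n_gen=2, exp_rate=2.0).rho
        assert rho[0] == pytest.approx(1 - np.exp(-0.04), abs=1e-9)
        assert rho[0] == pytest.approx(0.039211, abs=1e-6)

    def test_short_interval_is_nearly_zero(self):
        gm = simple_map([100, 101])
        rho = transition_schedule(gm, 2, 2.0).rho
        assert rho[0] < 1e-6

    def test_long_interval_saturates(self):
        gm = GenomeMap((("chr1", 10**10),), np.zeros(2, dtype=int), np.array([1, 9 * 10**9]), 2.0)
        rho = transition_schedule(gm, 2, 2.0).rho
        assert rho[0] > 0.999999

    def test_chromosome_boundary_resets(self):
        gm = GenomeMap(
            (("chr1", 1000), ("chr2", 1000)),
            np.array([0, 0, 1, 1]),
            np.array([10, 20, 10, 20]),
            2.0,
        )
        rho = transition_schedule(gm, 2, 2.0).rho
        assert rho[1] == 1.0
        assert rho[0] < 1e-6 and rho[2] < 1e-6


class TestEmission:
    @pytest.mark.parametrize(
        "ref,alt,p,eps,expected",
        [
            (0, 0, 0.3, 0.01, 1.0),
            (0, 1, 1.0, 0.0, 1.0),
            (2, 1, 0.5, 0.01, 0.125),
            (2, 1, 0.5, 0.2, 0.125),  # symmetry makes each read 1/2 regardless of error
            (1, 0, 0.0, 0.0, 1.0),
        ],
    )
    def test_closed_form_values(self, ref, alt, p, eps, expected):
        assert emission_likelihood(ref, alt, p, eps) == pytest.approx(expected, abs=1e-12)


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            T = int(rng.integers(2, 5))
            gm, theta, alpha, reads = random_instance(rng, K=2, T=T)
            sched = transition_schedule(gm, 2, 2.0)
            post, ll = forward_backward_diploid(reads, theta, sched, alpha, 0.01)
            post_bf, ll_bf = enumerate_paths(reads, theta, sched.rho_in(), alpha, 0.01)
            assert abs(ll - ll_bf) < 1e-8
            assert np.abs(post - post_bf).max() < 1e-8

    def test_single_haplotype_posterior_is_degenerate(self):
        gm = simple_map([1, 500_000, 1_000_000])
        theta = np.array([[0.2, 0.7, 0.9]])
        sched = transition_schedule(gm, 2, 2.0)
        reads = np.array([[1, 1], [0, 2], [0, 0]])
        post, _ = forward_backward_diploid(reads, theta, sched, np.array([1.0]), 0.01)
        assert np.allclose(post, 1.0)

    def test_uniform_theta_gives_equiposterior_states(self):
        gm = simple_map([1, 500_000, 1_000_000])
        K = 3
        theta = np.full((K, 3), 0.5)
        sched = transition_schedule(gm, 2, 2.0)
        reads = np.array([[2, 0], [1, 1], [0, 3]])
        post, _ = forward_backward_diploid(reads, theta, sched, np.full(K, 1 / K), 0.01)
        assert np.abs(post - 1 / K**2).max() < 1e-12

    def test_empty_sites_rejected(self):
        gm = simple_map([1, 2])
        sched = transition_schedule(gm, 2, 2.0)
        with pytest.raises(ValueError):
            forward_backward_diploid(np.empty((0, 2)), np.empty((2, 0)), sched, np.array([0.5, 0.5]), 0.01)

    def test_unnormalized_alpha_rejected(self):
        gm = simple_map([1, 100])
        theta = np.full((2, 2), 0.5)
        sched = transition_schedule(gm, 2, 2.0)
        with pytest.raises(ValueError):
            forward_backward_diploid(np.ones((2, 2), dtype=int), theta, sched, np.array([0.8, 0.8]), 0.01)


class TestKernelAgainstReference:
    """The compiled E-step must agree with the vectorized numpy reference."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_statistics_agree(self, seed):
        rng = np.random.default_rng(seed)
        K, T, N = int(rng.integers(2, 5)), int(rng.integers(5, 25)), int(rng.integers(2, 10))
        gm = make_genome_map(1, 3_000_000, T, 2.0, rng.integers(2**31))
        theta = rng.uniform(0.05, 0.95, (K, T))
        alpha = rng.dirichlet(np.ones(K))
        ref = rng.integers(0, 4, (N, T))
        alt = rng.integers(0, 4, (N, T))
        rho_in = transition_schedule(gm, 2, 2.0).rho_in()
        s1 = _e_step(ref, alt, theta, rho_in, alpha, 0.01, want_outputs=True)
        s2 = _e_step_numpy(ref, alt, theta, rho_in, alpha, 0.01, want_outputs=True)
        for key in ("num", "den", "adoption", "usage", "loglik", "jumps", "dosage", "genotype_probs"):
            np.testing.assert_allclose(s1[key], s2[key], atol=1e-12, err_msg=key)


class TestEMUpdate:
    def test_saturated_alt_evidence_hits_upper_clip(self):
        # posterior fully on haplotype 0 at both chains, all-alt reads, eps=0
        T, K = 1, 2
        theta = np.array([[0.5], [0.5]])
        post = np.zeros((1, T, K, K))
        post[0, 0, 0, 0] = 1.0
        ref = np.zeros((1, T), dtype=int)
        alt = np.full((1, T), 5)
        theta2, _ = em_update(theta, post, ref, alt, base_error=0.0)
        assert theta2[0, 0] == pytest.approx(0.9999)

    def test_no_reads_keeps_theta(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0.2, 0.8, (3, 4))
        post = np.full((2, 4, 3, 3), 1 / 9)
        z = np.zeros((2, 4), dtype=int)
        theta2, alpha2 = em_update(theta, post, z, z, 0.01)
        np.testing.assert_array_equal(theta2, theta)
        np.testing.assert_allclose(alpha2, 1 / 3)

    def test_balanced_evidence_is_symmetric(self):
        # two haplotypes used equally, half ref / half alt reads -> theta 0.5
        theta = np.array([[0.5], [0.5]])
        post = np.full((4, 1, 2, 2), 0.25)
        ref = np.array([[2], [2], [2], [2]])
        alt = np.array([[2], [2], [2], [2]])
        theta2, alpha2 = em_update(theta, post, ref, alt, 0.01)
        np.testing.assert_allclose(theta2, 0.5, atol=1e-12)
        np.testing.assert_allclose(alpha2, 0.5)


class TestRunEM:
    def test_seeded_rerun_is_bit_identical(self, small_cohort):
        _, cohort = small_cohort
        params = HMMParams(K=4, n_iterations=3, seed=9)
        a = run_em(cohort.ref_counts, cohort.alt_counts, cohort.genome_map, params, 0.01)
        b = run_em(cohort.ref_counts, cohort.alt_counts, cohort.genome_map, params, 0.01)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.loglik_trace, b.loglik_trace)
        assert np.array_equal(a.theta, b.theta)

    def test_loglik_monotone_on_small_cohort(self, small_cohort):
        _, cohort = small_cohort
        params = HMMParams(K=4, n_iterations=15, seed=2)
        res = run_em(cohort.ref_counts, cohort.alt_counts, cohort.genome_map, params, 0.01)
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_genotype_probs_normalized_and_dosage_consistent(self, small_cohort):
        _, cohort = small_cohort
        params = HMMParams(K=4, n_iterations=5, seed=3)
        res = run_em(cohort.ref_counts, cohort.alt_counts, cohort.genome_map, params, 0.01)
        np.testing.assert_allclose(res.genotype_probs.sum(axis=2), 1.0, atol=1e-8)
        np.testing.assert_allclose(
            res.dosage, res.genotype_probs[:, :, 1] + 2 * res.genotype_probs[:, :, 2], atol=1e-8
        )

    def test_label_permutation_leaves_dosage_invariant(self):
        # permuting the haplotype indices of the initialization must permute
        # theta rows but leave every sample-level quantity unchanged
        from f2impute.hmm import _e_step as estep, transition_schedule as ts, THETA_MIN

        rng = np.random.default_rng(4)
        N, T, K = 12, 30, 3
        gm = make_genome_map(1, 3_000_000, T, 2.0, 5)
        ref = rng.integers(0, 3, (N, T))
        alt = rng.integers(0, 3, (N, T))
        rho_in = ts(gm, 2, 2.0).rho_in()
        theta0 = rng.uniform(0.1, 0.9, (K, T))
        perm = np.array([2, 0, 1])

        def run(theta, alpha, n_iter=4):
            for _ in range(n_iter):
                s = estep(ref, alt, theta, rho_in, alpha, 0.01)
                theta = np.clip(
                    np.where(s["den"] > 0, s["num"] / np.maximum(s["den"], 1e-300), theta),
                    THETA_MIN,
                    1 - THETA_MIN,
                )
                alpha = s["adoption"] / s["adoption"].sum()
            out = estep(ref, alt, theta, rho_in, alpha, 0.01, want_outputs=True)
            return theta, out["dosage"], out["loglik"]

        th_a, dos_a, ll_a = run(theta0.copy(), np.full(K, 1 / K))
        th_b, dos_b, ll_b = run(theta0[perm].copy(), np.full(K, 1 / K))
        np.testing.assert_allclose(dos_a, dos_b, atol=1e-10)
        np.testing.assert_allclose(ll_a, ll_b, atol=1e-8)
        np.testing.assert_allclose(th_a[perm], th_b, atol=1e-10)

    def test_empty_cohort_rejected(self):
        gm = make_genome_map(1, 1_000_000, 10, 2.0, 1)
        with pytest.raises(ValueError):
            run_em(np.empty((0, 10)), np.empty((0, 10)), gm, HMMParams(K=2, n_iterations=1))


class TestInfoScore:
    def test_certain_polymorphic_calls_score_one(self):
        gp = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        assert info_score(gp) == pytest.approx(1.0)

    def test_monomorphic_frequency_is_undefined(self):
        gp = np.array([[1, 0, 0], [1, 0, 0]], dtype=float)
        assert np.isnan(info_score(gp))

    def test_three_sample_case_matches_direct_formula(self):
        gp = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        e = gp[:, 1] + 2 * gp[:, 2]
        var = gp[:, 1] + 4 * gp[:, 2] - e**2
        f = e.mean() / 2
        expected = 1 - var.mean() / (2 * f * (1 - f))
        assert info_score(gp) == pytest.approx(expected, abs=1e-12)


class TestHaplotypeImputer:
    def test_fit_exposes_sklearn_style_attributes(self, small_cohort):
        _, cohort = small_cohort
        imp = HaplotypeImputer(K=4, n_iterations=3, random_state=1)
        assert imp.get_params()["K"] == 4
        imp.fit(cohort)
        assert imp.theta_.shape == (4, cohort.genome_map.n_sites)
        assert imp.dosage_.shape == (cohort.n_samples, cohort.genome_map.n_sites)
        assert np.all(imp.dosage_ >= 0) and np.all(imp.dosage_ <= 2)

    def test_predict_reproduces_training_dosage(self, small_cohort):
        _, cohort = small_cohort
        imp = HaplotypeImputer(K=4, n_iterations=3, random_state=1).fit(cohort)
        np.testing.assert_allclose(imp.predict(cohort), imp.dosage_, atol=1e-10)

    def test_clone_compatible(self, small_cohort):
        from sklearn.base import clone

        imp = HaplotypeImputer(K=2, n_iterations=2)
        assert clone(imp).get_params() == imp.get_params()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_posteriors_normalized_property(seed):
    """Every (sample, site) posterior over haplotype pairs sums to one."""
    rng = np.random.default_rng(seed)
    K = int(rng.integers(1, 4))
    T = int(rng.integers(2, 8))
    gm, theta, alpha, reads = random_instance(rng, K=K, T=T)
    sched = transition_schedule(gm, 2, 2.0)
    post, ll = forward_backward_diploid(reads, theta, sched, alpha, 0.01)
    np.testing.assert_allclose(post.sum(axis=(1, 2)), 1.0, atol=1e-8)
    assert np.isfinite(ll)
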