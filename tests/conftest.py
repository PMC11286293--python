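import itertools

import numpy as np
import pytest

from f2impute import (
    HMMParams,
    emission_likelihood,
    make_genome_map,
    run_em,
    simulate_cohort,
)
from f2impute.simdata import CrossDesign


def enumerate_paths(reads, theta, rho_in, alpha, eps):
    """Brute-force posterior and log-likelihood by summing over all state paths.

    Independent oracle for the forward-backward recursion: the hidden state
    at each site is an ordered haplotype pair; each chain jumps across an
    interval with probability rho and lands on haplotype k with weight
    alpha[k] (self-landing allowed).
    """
    T = reads.shape[0]
    K = theta.shape[0]
    states = list(itertools.product(range(K), repeat=2))
    post = np.zeros((T, K, K))
    total = 0.0
    for path in itertools.product(states, repeat=T):
        p = 1.0
        for t, (k1, k2) in enumerate(path):
            if t == 0 or rho_in[t] >= 1.0:
                p *= alpha[k1] * alpha[k2]
            else:
                pk1, pk2 = path[t - 1]
                r = rho_in[t]
                p *= ((1 - r) * (k1 == pk1) + r * alpha[k1]) * ((1 - r) * (k2 == pk2) + r * alpha[k2])
            p_alt = 0.5 * (theta[k1, t] + theta[k2, t])
            p *= emission_likelihood(reads[t, 0], reads[t, 1], p_alt, eps)
        total += p
        for t, (k1, k2) in enumerate(path):
            post[t, k1, k2] += p
    return post / total, np.log(total)


def random_instance(rng, K=2, T=3, max_reads=3):
    """A small random HMM instance on a random genome map."""
    gm = make_genome_map(1, 3_000_000, T, 2.0, rng.integers(2**31))
    theta = rng.uniform(0.05, 0.95, (K, T))
    alpha = rng.dirichlet(np.ones(K))
    reads = rng.integers(0, max_reads + 1, (T, 2))
    return gm, theta, alpha, reads


SINGLE_CROSS = CrossDesign(crosses=(("72-2", "55-2", 400),))


@pytest.fixture(scope="session")
def single_cross_cohort():
    """400 F2 from one cross of two fully inbred lines, 2000 SNPs, 1x depth.

    The SNP set is polymorphic across the full eight-line panel (as when a
    study-wide site list is applied to one cross), so roughly half the sites
    are monomorphic within the cross.
    """
    from f2impute.simdata import MEDAKA_LINES

    panel, cohort = simulate_cohort(
        design=SINGLE_CROSS,
        n_chrom=1,
        chrom_len=5_000_000,
        n_sites=2000,
        residual_het=0.0,
        mean_depth=1.0,
        base_error=0.01,
        seed=11,
        panel_lines=MEDAKA_LINES,
    )
    return panel, cohort


@pytest.fixture(scope="session")
def single_cross_em(single_cross_cohort):
    """Full EM imputation of the single-cross cohort at K=4."""
    _, cohort = single_cross_cohort
    return run_em(
        cohort.ref_counts,
        cohort.alt_counts,
        cohort.genome_map,
        HMMParams(K=4, n_gen=2, exp_rate=2.0, n_iterations=100, seed=7),
        base_error=cohort.base_error,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Compact two-line cohort for fast EM-based tests (120 F2, 300 SNPs)."""
    design = CrossDesign(crosses=(("A", "B", 120),))
    panel, cohort = simulate_cohort(
        design=design,
        n_chrom=1,
        chrom_len=5_000_000,
        n_sites=300,
        residual_het=0.01,
        mean_depth=1.0,
        base_error=0.01,
        seed=5,
    )
    return panel, cohort
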