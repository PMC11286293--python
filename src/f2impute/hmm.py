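"""Reference-free diploid Li–Stephens imputation with EM-learned ancestral haplotypes.

The sample's two chromosomes are modelled as independent mosaic copies of K
latent ancestral haplotypes. The hidden state at SNP t is the ordered pair
(k1, k2) of haplotypes being copied; across the interval between adjacent
SNPs each copying chain jumps with probability

    rho_t = 1 - exp(-n_gen * exp_rate * d_Mb / 100)

and, when it jumps, re-samples its haplotype from weights alpha (the current
haplotype may be re-adopted). Emissions are the observed allelic read counts:
a read reports the alternate allele with probability p(1-e) + (1-p)e, where
p = (theta[k1, t] + theta[k2, t]) / 2 and theta[k, t] in [0, 1] is ancestral
haplotype k's alternate-allele dosage. EM alternates exact forward-backward
posteriors with closed-form updates of theta and alpha, reconstructing the
founder haplotypes and the per-sample genotype posteriors simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .simdata import GenomeMap, SimCohort

__all__ = [
    "HMMParams",
    "TransitionSchedule",
    "ImputationResult",
    "transition_schedule",
    "emission_likelihood",
    "forward_backward_diploid",
    "em_update",
    "run_em",
    "info_score",
    "HaplotypeImputer",
]

THETA_MIN = 1e-4  # clip for ancestral dosages; avoids degenerate emissions


@dataclass(frozen=True)
class HMMParams:
    """Hyperparameters of the copying model.

    K: number of ancestral haplotypes; n_gen: generations since founding
    (2 for an F2 cross: two meioses separate F2 haplotypes from the founders);
    exp_rate: recombination rate in cM/Mb; n_iterations: EM rounds.

    ``relabel_every`` controls the label-switch repair: every that many EM
    iterations (during the first three quarters of the run) the engine
    proposes swapping two haplotypes' tails at the interval carrying the
    most expected recombination jumps, accepting the move only if the exact
    log-likelihood improves. This greedy ascent escapes the classic
    ancestral-label-switching local optima without breaking EM monotonicity;
    0 disables it.
    """

    K: int = 16
    n_gen: int = 2
    exp_rate: float = 2.0
    n_iterations: int = 100
    seed: int = 0
    refill_enabled: bool = False
    relabel_every: int = 10
    n_starts: int = 3  # independent initializations; best by log-likelihood after a short burn-in

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_gen < 1 or self.n_iterations < 1:
            raise ValueError("K, n_gen and n_iterations must all be >= 1")


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-interval jump probabilities, chromosome boundaries forced to 1."""

    rho: np.ndarray  # length T - 1

    def __post_init__(self) -> None:
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("rho must lie in [0, 1]")

    def rho_in(self) -> np.ndarray:
        """Jump probability *into* each site; index 0 is a full reset."""
        return np.concatenate([[1.0], self.rho])


@dataclass
class ImputationResult:
    """Output of one EM imputation run."""

    dosage: np.ndarray  # (N, T) expected alternate-allele count in [0, 2]
    genotype_probs: np.ndarray  # (N, T, 3)
    info: np.ndarray  # (T,) info score, NaN where undefined
    loglik_trace: np.ndarray  # total log-likelihood per EM iteration (+ final pass)
    theta: np.ndarray  # (K, T) final ancestral haplotype dosages
    alpha: np.ndarray  # (K,) final haplotype weights
    usage: np.ndarray = field(default=None)  # (K,) mean posterior copying usage


def transition_schedule(genome_map: GenomeMap, n_gen: int = 2, exp_rate: float | None = None) -> TransitionSchedule:
    """Haldane-style map from physical distance to chain-jump probability.

    rho_t = 1 - exp(-n_gen * exp_rate * d_Mb / 100); intervals that span a
    chromosome boundary get rho = 1 so the chains reset.
    """
    if exp_rate is None:
        exp_rate = genome_map.exp_rate
    d_mb = np.diff(genome_map.pos).astype(float) / 1e6
    rho = 1.0 - np.exp(-n_gen * exp_rate * d_mb / 100.0)
    rho[np.diff(genome_map.chrom_index) != 0] = 1.0
    return TransitionSchedule(np.clip(rho, 0.0, 1.0))


def emission_likelihood(ref_count, alt_count, p_alt, base_error: float):
    """Probability of the observed reads given alternate-allele dosage ``p_alt``.

    Product over reads; an alt read has probability p(1-e) + (1-p)e, a ref
    read the complement. Vectorises over numpy inputs.
    """
    p_alt = np.asarray(p_alt, dtype=float)
    q = p_alt * (1 - base_error) + (1 - p_alt) * base_error
    return q**alt_count * (1 - q) ** ref_count


def _q_alt(theta_col: np.ndarray, eps: float) -> np.ndarray:
    """Per-haplotype probability that a read is alt, given copying that haplotype."""
    return theta_col * (1 - eps) + (1 - theta_col) * eps


def _apply_transition(v: np.ndarray, r: float, alpha: np.ndarray) -> np.ndarray:
    """Forward transition operator on (N, K, K) mass: each chain jumps w.p. r."""
    if r == 0.0:
        return v
    v1 = (1 - r) * v + r * alpha[None, :, None] * v.sum(axis=1, keepdims=True)
    return (1 - r) * v1 + r * v1.sum(axis=2, keepdims=True) * alpha[None, None, :]


def _apply_transition_T(u: np.ndarray, r: float, alpha: np.ndarray) -> np.ndarray:
    """Transpose operator, used in the backward recursion."""
    if r == 0.0:
        return u
    u1 = (1 - r) * u + r * np.einsum("j,ijk->ik", alpha, u)[:, None, :]
    return (1 - r) * u1 + r * np.einsum("k,ijk->ij", alpha, u1)[:, :, None]


def _site_emission(alt_t, ref_t, theta_col, eps):
    """(N, K, K) read likelihood at one site."""
    qa = _q_alt(theta_col, eps)
    q = 0.5 * (qa[:, None] + qa[None, :])  # pair alt-read probability
    logE = alt_t[:, None, None] * np.log(q) + ref_t[:, None, None] * np.log1p(-q)
    return np.exp(logE)


def _site_weights(theta: np.ndarray, eps: float):
    """Per-site log-emission terms and read-responsibility weights, (T, K, K)."""
    qa_all = _q_alt(theta, eps)  # (K, T)
    qr_all = 1.0 - qa_all
    q_pair = 0.5 * (qa_all[:, None, :] + qa_all[None, :, :])  # (K, K, T)
    lq = np.ascontiguousarray(np.log(q_pair).transpose(2, 0, 1))
    l1q = np.ascontiguousarray(np.log1p(-q_pair).transpose(2, 0, 1))
    Da = (qa_all[:, None, :] + qa_all[None, :, :]).transpose(2, 0, 1)
    Dr = (qr_all[:, None, :] + qr_all[None, :, :]).transpose(2, 0, 1)
    th_col = theta.T[:, :, None]  # (T, K, 1)
    Wa = np.ascontiguousarray(th_col * (1 - eps) / Da)
    Wr = np.ascontiguousarray(th_col * eps / Dr)
    Ua = np.ascontiguousarray(qa_all.T[:, :, None] / Da)
    Ur = np.ascontiguousarray(qr_all.T[:, :, None] / Dr)
    return lq, l1q, Wa, Wr, Ua, Ur


def _e_step(
    ref: np.ndarray,
    alt: np.ndarray,
    theta: np.ndarray,
    rho_in: np.ndarray,
    alpha: np.ndarray,
    eps: float,
    want_outputs: bool = False,
):
    """One exact forward-backward pass over all samples (compiled inner loop).

    Returns the EM sufficient statistics; see :func:`_e_step_numpy` for the
    reference implementation of the identical computation.
    """
    from ._kernels import fb_all

    a = np.ascontiguousarray(alt, dtype=np.float64)
    r_ = np.ascontiguousarray(ref, dtype=np.float64)
    lq, l1q, Wa, Wr, Ua, Ur = _site_weights(theta, eps)
    num, den, adoption, usage, loglik, dosage, gp, jumps = fb_all(
        a, r_, lq, l1q, np.asarray(rho_in, dtype=np.float64), np.asarray(alpha, dtype=np.float64),
        np.ascontiguousarray(theta), Wa, Wr, Ua, Ur, want_outputs,
    )
    return {
        "num": num,
        "den": den,
        "adoption": adoption,
        "usage": usage,
        "loglik": loglik,
        "jumps": jumps,
        "dosage": dosage if want_outputs else None,
        "genotype_probs": gp if want_outputs else None,
    }


def _total_loglik(ref, alt, theta, rho_in, alpha, eps) -> float:
    """Exact total log-likelihood under fixed parameters (forward pass only)."""
    from ._kernels import loglik_all

    lq, l1q, *_ = _site_weights(theta, eps)
    return float(
        loglik_all(
            np.ascontiguousarray(alt, dtype=np.float64),
            np.ascontiguousarray(ref, dtype=np.float64),
            lq,
            l1q,
            np.asarray(rho_in, dtype=np.float64),
            np.asarray(alpha, dtype=np.float64),
        )
    )


def _e_step_numpy(
    ref: np.ndarray,
    alt: np.ndarray,
    theta: np.ndarray,
    rho_in: np.ndarray,
    alpha: np.ndarray,
    eps: float,
    want_outputs: bool = False,
    block_elems: int = 40_000_000,
):
    """One exact forward-backward pass over all samples.

    Returns the sufficient statistics of the EM M-step (per-site alt/total
    read evidence attributed to each haplotype, expected haplotype adoption
    counts), the per-sample log-likelihood, the mean copying usage, and,
    when ``want_outputs``, dosages and genotype posteriors.

    Samples are processed in blocks so the stored messages stay bounded in
    memory; within a block only the sequential recursions run site by site,
    everything else is batched over sites.
    """
    N, T = ref.shape
    K = theta.shape[0]
    num = np.zeros((K, T))
    den = np.zeros((K, T))
    adoption = np.zeros(K)
    usage = np.zeros(K)
    loglik = np.zeros(N)
    jumps = np.zeros((K, T))
    dosage = np.empty((N, T)) if want_outputs else None
    gp = np.empty((N, T, 3)) if want_outputs else None

    # per-site theta-derived quantities shared by all blocks
    qa_all = _q_alt(theta, eps)  # (K, T)
    q_pair = 0.5 * (qa_all[:, None, :] + qa_all[None, :, :])  # (K, K, T)
    lq = np.log(q_pair).transpose(2, 0, 1)  # (T, K, K)
    l1q = np.log1p(-q_pair).transpose(2, 0, 1)
    # read-responsibility weights of the theta M-step, (T, K, K)
    qr_all = 1.0 - qa_all
    Da = (qa_all[:, None, :] + qa_all[None, :, :]).transpose(2, 0, 1)
    Dr = (qr_all[:, None, :] + qr_all[None, :, :]).transpose(2, 0, 1)
    th_col = theta.T[:, :, None]  # (T, K, 1)
    Wa = th_col * (1 - eps) / Da
    Wr = th_col * eps / Dr
    Ua = qa_all.T[:, :, None] / Da
    Ur = qr_all.T[:, :, None] / Dr
    init = np.outer(alpha, alpha)
    reset = rho_in >= 1.0

    block = max(1, int(block_elems // (T * K * K)))
    for lo in range(0, N, block):
        hi = min(N, lo + block)
        a = alt[lo:hi].astype(float)
        r_ = ref[lo:hi].astype(float)
        B = hi - lo
        # emissions for the whole block, (B, T, K, K)
        E_all = a[:, :, None, None] * lq[None]
        E_all += r_[:, :, None, None] * l1q[None]
        np.exp(E_all, out=E_all)
        fwd = np.empty((B, T, K, K))
        c = np.empty((B, T))

        # forward
        prev = None
        for t in range(T):
            if reset[t] or prev is None:
                pred = np.broadcast_to(init[None], (B, K, K))
            else:
                pred = _apply_transition(prev, rho_in[t], alpha)
            f = pred * E_all[:, t]
            ct = np.maximum(f.sum(axis=(1, 2)), 1e-300)
            f /= ct[:, None, None]
            fwd[:, t] = f
            c[:, t] = ct
            prev = f
        loglik[lo:hi] = np.log(c).sum(axis=1)

        # backward; fwd[:, t] is overwritten in place with the posterior
        b = np.ones((B, K, K))
        inv_c = 1.0 / c
        for t in range(T - 1, -1, -1):
            u = E_all[:, t] * b
            rr = rho_in[t]
            if 0.0 < rr < 1.0:
                # expected recombination-jump landings (exact alpha M-step)
                F2 = fwd[:, t - 1].sum(axis=1) * inv_c[:, t, None]
                term_stay = np.einsum("ik,ijk->j", F2, u)
                term_jump = np.einsum("i,k,ijk->j", inv_c[:, t], alpha, u)
                la = 2.0 * rr * alpha * ((1 - rr) * term_stay + rr * term_jump)
                adoption += la
                jumps[:, t] += la
            fwd[:, t] *= b  # now the (unnormalized) posterior at t
            if t > 0:
                if reset[t]:
                    tot = np.einsum("jk,ijk->i", init, u)
                    b = np.broadcast_to((tot * inv_c[:, t])[:, None, None], (B, K, K)).copy()
                else:
                    b = _apply_transition_T(u, rr, alpha)
                    b *= inv_c[:, t, None, None]

        post = fwd  # (B, T, K, K), already ~normalized; renormalize for safety
        post /= np.maximum(post.sum(axis=(2, 3)), 1e-300)[:, :, None, None]
        gamma = post.sum(axis=3)  # (B, T, K) chain marginal (symmetric)
        usage += gamma.sum(axis=(0, 1))
        adoption += 2.0 * gamma[:, reset[:T]].sum(axis=(0, 1))

        # theta statistics: attribute each read's alt responsibility to the
        # chains that may have produced it
        Sa = np.einsum("it,itkl->tkl", a, post)
        Sr = np.einsum("it,itkl->tkl", r_, post)
        Sa += Sa.transpose(0, 2, 1)
        Sr += Sr.transpose(0, 2, 1)
        num += (Sa * Wa + Sr * Wr).sum(axis=2).T
        den += (Sa * Ua + Sr * Ur).sum(axis=2).T

        if want_outputs:
            omt = 1.0 - theta
            p0 = np.einsum("itkl,kt,lt->it", post, omt, omt)
            p2 = np.einsum("itkl,kt,lt->it", post, theta, theta)
            p1 = np.clip(1.0 - p0 - p2, 0.0, 1.0)
            gp[lo:hi, :, 0] = p0
            gp[lo:hi, :, 1] = p1
            gp[lo:hi, :, 2] = p2
            dosage[lo:hi] = p1 + 2.0 * p2

    usage /= usage.sum()
    return {
        "num": num,
        "den": den,
        "adoption": adoption,
        "usage": usage,
        "loglik": loglik,
        "jumps": jumps,
        "dosage": dosage,
        "genotype_probs": gp,
    }


def forward_backward_diploid(
    reads_i: np.ndarray,
    theta: np.ndarray,
    schedule: TransitionSchedule,
    alpha: np.ndarray,
    base_error: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Exact per-site posteriors over ordered haplotype pairs for one sample.

    ``reads_i`` is (T, 2) with columns (ref_count, alt_count). Returns the
    (T, K, K) posterior array (each site sums to 1) and the log-likelihood.
    """
    reads_i = np.asarray(reads_i)
    T = reads_i.shape[0]
    if T == 0:
        raise ValueError("no sites")
    K = theta.shape[0]
    if theta.shape[1] != T or schedule.rho.shape[0] != T - 1:
        raise ValueError("theta / schedule dimensioned inconsistently with the reads")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (K,) or not np.isclose(alpha.sum(), 1.0, atol=1e-8):
        raise ValueError("alpha must be a normalized K-vector")

    ref = reads_i[None, :, 0]
    alt = reads_i[None, :, 1]
    rho_in = schedule.rho_in()
    # dedicated small-scale recursion (keeps the batched path honest in tests)
    a = alt[0].astype(float)
    r_ = ref[0].astype(float)
    fwd = np.empty((T, K, K))
    c = np.empty(T)
    init = np.outer(alpha, alpha)
    prev = None
    for t in range(T):
        E = _site_emission(a[t : t + 1], r_[t : t + 1], theta[:, t], base_error)[0]
        rr = rho_in[t]
        pred = init if (rr >= 1.0 or prev is None) else _apply_transition(prev[None], rr, alpha)[0]
        f = pred * E
        ct = max(f.sum(), 1e-300)
        fwd[t] = f / ct
        c[t] = ct
        prev = fwd[t]
    post = np.empty((T, K, K))
    b = np.ones((K, K))
    for t in range(T - 1, -1, -1):
        pt = fwd[t] * b
        post[t] = pt / max(pt.sum(), 1e-300)
        if t > 0:
            E = _site_emission(a[t : t + 1], r_[t : t + 1], theta[:, t], base_error)[0]
            u = E * b
            rr = rho_in[t]
            if rr >= 1.0:
                b = np.full((K, K), float((init * u).sum()) / c[t])
            else:
                b = _apply_transition_T(u[None], rr, alpha)[0] / c[t]
    return post, float(np.log(c).sum())


def em_update(
    theta: np.ndarray,
    posteriors: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    base_error: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form M-step from per-sample pair posteriors.

    ``posteriors`` is (N, T, K, K). Each chain's marginal posterior of copying
    haplotype k contributes its read-consistent alternate-allele
    responsibility to theta'[k, t]; sites with no assigned evidence keep their
    previous value; theta' is clipped away from {0, 1}. alpha' is the
    normalized average marginal haplotype usage.
    """
    N, T, K, _ = posteriors.shape
    eps = base_error
    num = np.zeros((K, T))
    den = np.zeros((K, T))
    qa_all = _q_alt(theta, eps)
    for t in range(T):
        post = posteriors[:, t]
        qa = qa_all[:, t]
        qr = 1.0 - qa
        Da = qa[:, None] + qa[None, :]
        Dr = qr[:, None] + qr[None, :]
        Wa = theta[:, t, None] * (1 - eps) / Da
        Wr = theta[:, t, None] * eps / Dr
        Ua = qa[:, None] / Da
        Ur = qr[:, None] / Dr
        Sa = np.einsum("i,ikl->kl", alt[:, t].astype(float), post)
        Sr = np.einsum("i,ikl->kl", ref[:, t].astype(float), post)
        Sa = Sa + Sa.T
        Sr = Sr + Sr.T
        num[:, t] = (Sa * Wa + Sr * Wr).sum(axis=1)
        den[:, t] = (Sa * Ua + Sr * Ur).sum(axis=1)
    theta_new = np.where(den > 0, num / np.maximum(den, 1e-300), theta)
    theta_new = np.clip(theta_new, THETA_MIN, 1 - THETA_MIN)
    gamma = posteriors.sum(axis=3)  # (N, T, K) chain-1 marginal
    alpha_new = gamma.sum(axis=(0, 1))
    alpha_new = alpha_new / alpha_new.sum()
    return theta_new, alpha_new


def info_score(genotype_probs: np.ndarray) -> np.ndarray:
    """IMPUTE-style per-site certainty measure.

    info = 1 - mean(Var[g]) / (2 f(1-f)), with f the mean dosage / 2; NaN
    where the estimated frequency is 0 or 1. Accepts (N, 3) for one site or
    (N, T, 3) for many.
    """
    gp = np.asarray(genotype_probs, dtype=float)
    single = gp.ndim == 2
    if single:
        gp = gp[:, None, :]
    e_g = gp[..., 1] + 2.0 * gp[..., 2]
    e_g2 = gp[..., 1] + 4.0 * gp[..., 2]
    var = np.maximum(e_g2 - e_g**2, 0.0)
    f = e_g.mean(axis=0) / 2.0
    denom = 2.0 * f * (1.0 - f)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = 1.0 - var.mean(axis=0) / denom
    info = np.where(denom > 0, info, np.nan)
    return float(info[0]) if single else info


def run_em(
    ref: np.ndarray,
    alt: np.ndarray,
    genome_map: GenomeMap,
    params: HMMParams,
    base_error: float = 0.01,
) -> ImputationResult:
    """Full EM imputation: alternate forward-backward with theta/alpha updates.

    theta is initialized Uniform(0.1, 0.9) from ``params.seed`` and alpha
    uniform; each iteration runs the exact E-step over all samples and the
    closed-form M-step (alpha re-estimated from expected haplotype adoption
    events, so the likelihood is non-decreasing). ``n_starts`` independent
    initializations are burnt in for a few iterations and the one with the
    highest log-likelihood is continued — the standard guard against poor EM
    basins. A final E-pass produces the genotype posteriors, dosages, and
    info scores on the last theta.
    """
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    if ref.ndim != 2 or ref.shape[0] < 1 or ref.shape[1] < 2:
        raise ValueError("need at least 1 sample and 2 sites")
    N, T = ref.shape
    K = params.K
    rng = np.random.default_rng(params.seed)
    rho_in = transition_schedule(genome_map, params.n_gen, params.exp_rate).rho_in()

    refill_at = {params.n_iterations // 4, params.n_iterations // 2} if params.refill_enabled else set()
    relabel_at = (
        set(range(params.relabel_every, int(0.75 * params.n_iterations) + 1, params.relabel_every))
        if params.relabel_every
        else set()
    )

    def iterate(theta, alpha, trace, start, stop):
        for it in range(start, stop):
            stats = _e_step(ref, alt, theta, rho_in, alpha, base_error)
            trace.append(stats["loglik"].sum())
            theta = np.where(stats["den"] > 0, stats["num"] / np.maximum(stats["den"], 1e-300), theta)
            theta = np.clip(theta, THETA_MIN, 1 - THETA_MIN)
            alpha = stats["adoption"] / stats["adoption"].sum()
            if it + 1 in relabel_at:
                theta = _relabel_repair(ref, alt, theta, rho_in, alpha, base_error, stats["jumps"])
            if it in refill_at:
                theta = _refill(theta, stats["usage"], rng)
        return theta, alpha, trace

    n_starts = max(1, params.n_starts)
    n_burn = min(10, params.n_iterations) if n_starts > 1 else 0
    candidates = []
    for _ in range(n_starts):
        theta0 = rng.uniform(0.1, 0.9, size=(K, T))
        alpha0 = np.full(K, 1.0 / K)
        th, al, tr = iterate(theta0, alpha0, [], 0, n_burn)
        if n_starts > 1:
            ll = _total_loglik(ref, alt, th, rho_in, al, base_error)
        else:
            ll = 0.0
        candidates.append((ll, th, al, tr))
        if n_starts == 1:
            break
    _, theta, alpha, trace = max(candidates, key=lambda c: c[0])
    theta, alpha, trace = iterate(theta, alpha, trace, n_burn, params.n_iterations)
    final = _e_step(ref, alt, theta, rho_in, alpha, base_error, want_outputs=True)
    trace.append(final["loglik"].sum())
    info = info_score(final["genotype_probs"])
    return ImputationResult(
        dosage=final["dosage"],
        genotype_probs=final["genotype_probs"],
        info=info,
        loglik_trace=np.array(trace),
        theta=theta,
        alpha=alpha,
        usage=final["usage"],
    )


def _relabel_repair(
    ref: np.ndarray,
    alt: np.ndarray,
    theta: np.ndarray,
    rho_in: np.ndarray,
    alpha: np.ndarray,
    eps: float,
    jumps: np.ndarray,
    max_swaps: int = 3,
    min_gain: float = 1e-6,
) -> np.ndarray:
    """Greedy likelihood-ascent repair of ancestral-label switching.

    A converged EM solution often represents each founder as complementary
    mosaics of two latent haplotypes; every copying chain then pays a jump
    penalty at the mosaic boundary, which shows up as a sharp peak in the
    expected-jump profile. At each of up to ``max_swaps`` peaks, tail swaps
    are proposed among the haplotypes carrying the most jump landings there,
    and the best proposal is accepted only when the exact total
    log-likelihood increases, so EM monotonicity is preserved.

    ``jumps`` is the (K, T) expected-jump-landing profile from the E-step.
    """
    K, T = theta.shape
    jumps = jumps.copy()
    jumps[:, rho_in >= 1.0] = 0.0
    profile = jumps.sum(axis=0)
    base_ll = None
    for _ in range(max_swaps):
        t_star = int(np.argmax(profile))
        if profile[t_star] <= 0:
            break
        if base_ll is None:
            base_ll = _total_loglik(ref, alt, theta, rho_in, alpha, eps)
        top = np.argsort(jumps[:, t_star])[::-1][: min(3, K)]
        best = None
        for a_i in range(len(top)):
            for b_i in range(a_i + 1, len(top)):
                j, k = int(top[a_i]), int(top[b_i])
                cand = theta.copy()
                cand[j, t_star:], cand[k, t_star:] = theta[k, t_star:].copy(), theta[j, t_star:].copy()
                ll = _total_loglik(ref, alt, cand, rho_in, alpha, eps)
                if ll > base_ll + min_gain and (best is None or ll > best[0]):
                    best = (ll, cand)
        if best is not None:
            base_ll, theta = best
        # mask this breakpoint's neighbourhood and try the next-highest peak
        lo = max(0, t_star - 5)
        profile[lo : t_star + 6] = 0.0
    return theta


def _refill(theta: np.ndarray, usage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Re-seed rarely used haplotypes near the most-used one (optional heuristic)."""
    K = theta.shape[0]
    rare = usage < 1.0 / (4 * K)
    if not rare.any():
        return theta
    best = int(np.argmax(usage))
    theta = theta.copy()
    for k in np.flatnonzero(rare):
        theta[k] = np.clip(theta[best] + rng.uniform(-0.1, 0.1, size=theta.shape[1]), THETA_MIN, 1 - THETA_MIN)
    return theta


class HaplotypeImputer(BaseEstimator):
    """Scikit-learn style front end for the EM imputation engine.

    Parameters mirror :class:`HMMParams`. ``fit`` learns the ancestral
    haplotypes from a cohort's allelic read counts and stores the imputation
    of the training cohort; ``predict`` imputes dosages for further samples
    under the fitted haplotypes (one E-pass, no re-estimation).

    Examples
    --------
    >>> imp = HaplotypeImputer(K=4, n_iterations=30, random_state=1)
    >>> imp.fit(cohort)                      # doctest: +SKIP
    >>> imp.dosage_.shape                    # doctest: +SKIP
    (400, 2000)
    """

    def __init__(
        self,
        K: int = 16,
        n_gen: int = 2,
        exp_rate: float = 2.0,
        n_iterations: int = 100,
        base_error: float = 0.01,
        refill: bool = False,
        relabel_every: int = 10,
        n_starts: int = 3,
        random_state: int = 0,
    ):
        self.K = K
        self.n_gen = n_gen
        self.exp_rate = exp_rate
        self.n_iterations = n_iterations
        self.base_error = base_error
        self.refill = refill
        self.relabel_every = relabel_every
        self.n_starts = n_starts
        self.random_state = random_state

    def _params(self) -> HMMParams:
        return HMMParams(
            K=self.K,
            n_gen=self.n_gen,
            exp_rate=self.exp_rate,
            n_iterations=self.n_iterations,
            seed=self.random_state,
            refill_enabled=self.refill,
            relabel_every=self.relabel_every,
            n_starts=self.n_starts,
        )

    @staticmethod
    def _unpack(X, genome_map):
        if isinstance(X, SimCohort):
            if X.ref_counts is None:
                raise ValueError("cohort has no simulated reads")
            return X.ref_counts, X.alt_counts, X.genome_map
        ref, alt = X
        if genome_map is None:
            raise ValueError("genome_map is required when X is a (ref, alt) pair")
        return np.asarray(ref), np.asarray(alt), genome_map

    def fit(self, X, y=None, genome_map: GenomeMap | None = None):
        """Run EM on a cohort (``SimCohort`` or ``(ref_counts, alt_counts)``)."""
        ref, alt, gm = self._unpack(X, genome_map)
        res = run_em(ref, alt, gm, self._params(), base_error=self.base_error)
        self.result_ = res
        self.theta_ = res.theta
        self.alpha_ = res.alpha
        self.dosage_ = res.dosage
        self.genotype_probs_ = res.genotype_probs
        self.info_ = res.info
        self.loglik_trace_ = res.loglik_trace
        self.genome_map_ = gm
        self.n_features_in_ = ref.shape[1]
        return self

    def predict(self, X, genome_map: GenomeMap | None = None) -> np.ndarray:
        """Dosages for new samples under the fitted haplotypes."""
        ref, alt, gm = self._unpack(X, genome_map or getattr(self, "genome_map_", None))
        rho_in = transition_schedule(gm, self.n_gen, self.exp_rate).rho_in()
        out = _e_step(ref, alt, self.theta_, rho_in, self.alpha_, self.base_error, want_outputs=True)
        return out["dosage"]

    def score(self, X, y, genome_map: GenomeMap | None = None) -> float:
        """Mean per-sample squared Pearson correlation against true genotypes."""
        from .evaluate import per_sample_concordance

        dosage = self.predict(X, genome_map)
        return per_sample_concordance(dosage, np.asarray(y)).mean_per_sample_r2
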