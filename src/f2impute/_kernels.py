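"""Compiled inner loops of the diploid copying-model E-step.

One tight per-sample forward-backward recursion over the K x K ordered
haplotype-pair states, accumulating the EM sufficient statistics in place.
Semantics are identical to the pure-numpy reference path in
``f2impute.hmm._e_step_numpy`` (asserted in the test suite); this version
exists because the E-step runs thousands of times in refinement loops and
design sweeps.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def fb_all(a, r, lq, l1q, rho_in, alpha, theta, Wa, Wr, Ua, Ur, want_outputs):
    """Forward-backward + M-step statistics for all samples.

    a, r: (N, T) float alt/ref read counts; lq, l1q: (T, K, K) log emission
    terms; rho_in: (T,) jump probability into each site (1 = chain reset);
    Wa/Wr/Ua/Ur: (T, K, K) read-responsibility weights of the theta update.

    Returns (num, den, adoption, usage, loglik, dosage, gp); dosage/gp are
    empty unless ``want_outputs``.
    """
    N, T = a.shape
    K = alpha.shape[0]
    num = np.zeros((K, T))
    den = np.zeros((K, T))
    adoption = np.zeros(K)
    usage = np.zeros(K)
    loglik = np.zeros(N)
    jumps = np.zeros((K, T))  # expected jump landings per haplotype and interval
    if want_outputs:
        dosage = np.zeros((N, T))
        gp = np.zeros((N, T, 3))
    else:
        dosage = np.zeros((0, 0))
        gp = np.zeros((0, 0, 0))

    fwd = np.empty((T, K, K))
    c = np.empty(T)
    E = np.empty((K, K))
    pred = np.empty((K, K))
    b = np.empty((K, K))
    u = np.empty((K, K))
    tmp = np.empty((K, K))
    post = np.empty((K, K))
    colsum = np.empty(K)
    rowsum = np.empty(K)

    for i in range(N):
        # ---------------- forward ----------------
        ll = 0.0
        for t in range(T):
            rr = rho_in[t]
            if t == 0 or rr >= 1.0:
                for k in range(K):
                    for l in range(K):
                        pred[k, l] = alpha[k] * alpha[l]
            else:
                # chain 1 jumps with prob rr, then chain 2
                for l in range(K):
                    s = 0.0
                    for k in range(K):
                        s += fwd[t - 1, k, l]
                    colsum[l] = s
                for k in range(K):
                    for l in range(K):
                        tmp[k, l] = (1.0 - rr) * fwd[t - 1, k, l] + rr * alpha[k] * colsum[l]
                for k in range(K):
                    s = 0.0
                    for l in range(K):
                        s += tmp[k, l]
                    rowsum[k] = s
                for k in range(K):
                    for l in range(K):
                        pred[k, l] = (1.0 - rr) * tmp[k, l] + rr * rowsum[k] * alpha[l]
            at = a[i, t]
            rt = r[i, t]
            ct = 0.0
            if at > 0.0 or rt > 0.0:
                for k in range(K):
                    for l in range(K):
                        v = pred[k, l] * np.exp(at * lq[t, k, l] + rt * l1q[t, k, l])
                        fwd[t, k, l] = v
                        ct += v
            else:
                for k in range(K):
                    for l in range(K):
                        fwd[t, k, l] = pred[k, l]
                        ct += pred[k, l]
            if ct < 1e-300:
                ct = 1e-300
            inv = 1.0 / ct
            for k in range(K):
                for l in range(K):
                    fwd[t, k, l] *= inv
            c[t] = ct
            ll += np.log(ct)
        loglik[i] = ll

        # ---------------- backward ----------------
        for k in range(K):
            for l in range(K):
                b[k, l] = 1.0
        for t in range(T - 1, -1, -1):
            at = a[i, t]
            rt = r[i, t]
            rr = rho_in[t]
            if at > 0.0 or rt > 0.0:
                for k in range(K):
                    for l in range(K):
                        u[k, l] = np.exp(at * lq[t, k, l] + rt * l1q[t, k, l]) * b[k, l]
            else:
                for k in range(K):
                    for l in range(K):
                        u[k, l] = b[k, l]

            # expected recombination-jump landings (alpha M-step)
            if t > 0 and 0.0 < rr < 1.0:
                inv = 1.0 / c[t]
                for l in range(K):
                    s = 0.0
                    for k in range(K):
                        s += fwd[t - 1, k, l]
                    colsum[l] = s  # other-chain marginal of f_{t-1}
                for j in range(K):
                    stay = 0.0
                    jump = 0.0
                    for l in range(K):
                        stay += colsum[l] * u[j, l]
                        jump += alpha[l] * u[j, l]
                    la = 2.0 * rr * alpha[j] * ((1.0 - rr) * stay + rr * jump) * inv
                    adoption[j] += la
                    jumps[j, t] += la

            # posterior at t
            psum = 0.0
            for k in range(K):
                for l in range(K):
                    v = fwd[t, k, l] * b[k, l]
                    post[k, l] = v
                    psum += v
            if psum < 1e-300:
                psum = 1e-300
            inv = 1.0 / psum
            for k in range(K):
                gam = 0.0
                for l in range(K):
                    post[k, l] *= inv
                    gam += post[k, l]
                rowsum[k] = gam  # chain-1 marginal
                usage[k] += gam
            if rr >= 1.0 or t == 0:
                for k in range(K):
                    adoption[k] += 2.0 * rowsum[k]

            # theta statistics
            if at > 0.0 or rt > 0.0:
                for k in range(K):
                    for l in range(K):
                        s = post[k, l] + post[l, k]
                        num[k, t] += at * s * Wa[t, k, l] + rt * s * Wr[t, k, l]
                        den[k, t] += at * s * Ua[t, k, l] + rt * s * Ur[t, k, l]

            if want_outputs:
                p0 = 0.0
                p2 = 0.0
                for k in range(K):
                    for l in range(K):
                        p0 += post[k, l] * (1.0 - theta[k, t]) * (1.0 - theta[l, t])
                        p2 += post[k, l] * theta[k, t] * theta[l, t]
                p1 = 1.0 - p0 - p2
                if p1 < 0.0:
                    p1 = 0.0
                elif p1 > 1.0:
                    p1 = 1.0
                gp[i, t, 0] = p0
                gp[i, t, 1] = p1
                gp[i, t, 2] = p2
                dosage[i, t] = p1 + 2.0 * p2

            # recurse b to t-1
            if t > 0:
                if rr >= 1.0:
                    tot = 0.0
                    for k in range(K):
                        for l in range(K):
                            tot += alpha[k] * alpha[l] * u[k, l]
                    tot /= c[t]
                    for k in range(K):
                        for l in range(K):
                            b[k, l] = tot
                else:
                    inv = 1.0 / c[t]
                    for l in range(K):
                        s = 0.0
                        for k in range(K):
                            s += alpha[k] * u[k, l]
                        colsum[l] = s
                    for k in range(K):
                        for l in range(K):
                            tmp[k, l] = (1.0 - rr) * u[k, l] + rr * colsum[l]
                    for k in range(K):
                        s = 0.0
                        for l in range(K):
                            s += alpha[l] * tmp[k, l]
                        rowsum[k] = s
                    for k in range(K):
                        for l in range(K):
                            b[k, l] = ((1.0 - rr) * tmp[k, l] + rr * rowsum[k]) * inv

    total = usage.sum()
    if total > 0:
        usage = usage / total
    return num, den, adoption, usage, loglik, dosage, gp, jumps


@njit(cache=True)
def loglik_all(a, r, lq, l1q, rho_in, alpha):
    """Total log-likelihood only (forward pass); used to score candidate
    haplotype-relabeling moves."""
    N, T = a.shape
    K = alpha.shape[0]
    pred = np.empty((K, K))
    f = np.empty((K, K))
    tmp = np.empty((K, K))
    colsum = np.empty(K)
    rowsum = np.empty(K)
    total = 0.0
    for i in range(N):
        for t in range(T):
            rr = rho_in[t]
            if t == 0 or rr >= 1.0:
                for k in range(K):
                    for l in range(K):
                        pred[k, l] = alpha[k] * alpha[l]
            else:
                for l in range(K):
                    s = 0.0
                    for k in range(K):
                        s += f[k, l]
                    colsum[l] = s
                for k in range(K):
                    for l in range(K):
                        tmp[k, l] = (1.0 - rr) * f[k, l] + rr * alpha[k] * colsum[l]
                for k in range(K):
                    s = 0.0
                    for l in range(K):
                        s += tmp[k, l]
                    rowsum[k] = s
                for k in range(K):
                    for l in range(K):
                        pred[k, l] = (1.0 - rr) * tmp[k, l] + rr * rowsum[k] * alpha[l]
            at = a[i, t]
            rt = r[i, t]
            ct = 0.0
            if at > 0.0 or rt > 0.0:
                for k in range(K):
                    for l in range(K):
                        v = pred[k, l] * np.exp(at * lq[t, k, l] + rt * l1q[t, k, l])
                        f[k, l] = v
                        ct += v
            else:
                for k in range(K):
                    for l in range(K):
                        f[k, l] = pred[k, l]
                        ct += pred[k, l]
            if ct < 1e-300:
                ct = 1e-300
            inv = 1.0 / ct
            for k in range(K):
                for l in range(K):
                    f[k, l] *= inv
            total += np.log(ct)
    return total
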