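"""Compiled inner loops for the variational HMM: the VBEM E-step (scaled
forward-backward with fused Gaussian-step emissions and sufficient-statistic
reduction) and Viterbi decoding over ragged batches of step sequences.

Sequences are padded to a common length T; ``lengths`` gives the true number
of steps per sequence. Emissions are isotropic zero-mean 2-D Gaussians over
squared step norms ``sq``: ln B_tk = e_lnlam_k − ln 2π − e_lam_k·sq_t/2,
evaluated under expected log-parameters.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def e_step(sq, lengths, e_lam, e_lnlam, A, pi):
    """One VBEM E-step over all sequences.

    Parameters: sq (n_seq, T) padded squared step norms; lengths (n_seq,);
    e_lam, e_lnlam (K,) expected precision and log-precision per state;
    A (K, K), pi (K,) sub-normalized expected-log transition/initial weights.

    Returns (loglik, Nk, Sk, xi, gamma0): total log-normalizer, expected
    step counts per state, expected sum of squared norms per state (for the
    gamma-rate update, i.e. Σ γ·sq), transition counts (K, K) and summed
    first-step posteriors (K,).
    """
    n_seq, T = sq.shape
    K = e_lam.shape[0]
    ln2pi = np.log(2.0 * np.pi)
    Nk = np.zeros(K)
    Sk = np.zeros(K)
    xi = np.zeros((K, K))
    gamma0 = np.zeros(K)
    loglik = 0.0
    B = np.empty((T, K))
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    for s in range(n_seq):
        L = lengths[s]
        # emission weights, shifted per step for stability
        for t in range(L):
            m = -np.inf
            for k in range(K):
                v = e_lnlam[k] - ln2pi - 0.5 * e_lam[k] * sq[s, t]
                B[t, k] = v
                if v > m:
                    m = v
            for k in range(K):
                B[t, k] = np.exp(B[t, k] - m)
            loglik += m
        # forward
        tot = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * B[0, k]
            tot += alpha[0, k]
        c[0] = tot
        for k in range(K):
            alpha[0, k] /= tot
        for t in range(1, L):
            tot = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[t, j]
                tot += alpha[t, j]
            c[t] = tot
            for j in range(K):
                alpha[t, j] /= tot
        for t in range(L):
            loglik += np.log(c[t])
        # backward, accumulating posteriors on the fly
        for k in range(K):
            beta[L - 1, k] = 1.0
        for t in range(L - 2, -1, -1):
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]
        for t in range(L):
            for k in range(K):
                g = alpha[t, k] * beta[t, k]
                Nk[k] += g
                Sk[k] += g * sq[s, t]
                if t == 0:
                    gamma0[k] += g
        for t in range(L - 1):
            for i in range(K):
                ai = alpha[t, i]
                for j in range(K):
                    xi[i, j] += ai * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
    return loglik, Nk, Sk, xi, gamma0


@njit(cache=True)
def viterbi(lnB, lengths, lnA, lnpi):
    """Most probable state path per sequence; returns (n_seq, T) labels
    (entries beyond each sequence length are -1)."""
    n_seq, T, K = lnB.shape
    paths = -np.ones((n_seq, T), dtype=np.int64)
    delta = np.empty((T, K))
    back = np.empty((T, K), dtype=np.int64)
    for s in range(n_seq):
        L = lengths[s]
        for k in range(K):
            delta[0, k] = lnpi[k] + lnB[s, 0, k]
            back[0, k] = 0
        for t in range(1, L):
            for j in range(K):
                best = -np.inf
                arg = 0
                for i in range(K):
                    v = delta[t - 1, i] + lnA[i, j]
                    if v > best:
                        best = v
                        arg = i
                delta[t, j] = best + lnB[s, t, j]
                back[t, j] = arg
        best = -np.inf
        arg = 0
        for k in range(K):
            if delta[L - 1, k] > best:
                best = delta[L - 1, k]
                arg = k
        paths[s, L - 1] = arg
        for t in range(L - 2, -1, -1):
            paths[s, t] = back[t + 1, paths[s, t + 1]]
    return paths
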