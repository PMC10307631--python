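"""Numba collapsed-Gibbs kernel for the spatial topic model."""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _collapsed_joint(n_dk, n_kg, n_k, n_d, alpha, beta):
    """Collapsed joint log p(w, z) up to assignment-independent constants."""
    D, K = n_dk.shape
    G = n_kg.shape[1]
    ll = 0.0
    for k in range(K):
        for g in range(G):
            if n_kg[k, g] > 0:
                ll += math.lgamma(n_kg[k, g] + beta) - math.lgamma(beta)
        ll -= math.lgamma(n_k[k] + G * beta) - math.lgamma(G * beta)
    for d in range(D):
        for k in range(K):
            if n_dk[d, k] > 0:
                ll += math.lgamma(n_dk[d, k] + alpha) - math.lgamma(alpha)
        ll -= math.lgamma(n_d[d] + K * alpha) - math.lgamma(K * alpha)
    return ll


@njit(cache=True)
def gibbs(token_spot, token_gene, K, D, G, alpha, beta, n_sweeps, burn_in, thin, seed):
    """Collapsed Gibbs sampling of token-topic assignments.

    Returns (theta_mean (K,G), omega_mean (D,K), trace (n_sweeps,), n_samples).
    Posterior means average the per-sample conditional estimates of theta and
    omega over post-burn-in sweeps at the given thinning interval.
    """
    np.random.seed(seed)
    T = token_spot.shape[0]
    z = np.empty(T, dtype=np.int32)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kg = np.zeros((K, G), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    n_d = np.zeros(D, dtype=np.int64)
    for t in range(T):
        k = np.random.randint(0, K)
        z[t] = k
        n_dk[token_spot[t], k] += 1
        n_kg[k, token_gene[t]] += 1
        n_k[k] += 1
        n_d[token_spot[t]] += 1

    probs = np.empty(K)
    theta_acc = np.zeros((K, G))
    omega_acc = np.zeros((D, K))
    n_samples = 0
    trace = np.empty(n_sweeps)
    gb = G * beta

    for sweep in range(n_sweeps):
        for t in range(T):
            d = token_spot[t]
            g = token_gene[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_kg[k, g] -= 1
            n_k[k] -= 1
            tot = 0.0
            for kk in range(K):
                p = (n_dk[d, kk] + alpha) * (n_kg[kk, g] + beta) / (n_k[kk] + gb)
                probs[kk] = p
                tot += p
            u = np.random.random() * tot
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += probs[kk]
                if u < acc:
                    knew = kk
                    break
            z[t] = knew
            n_dk[d, knew] += 1
            n_kg[knew, g] += 1
            n_k[knew] += 1

        trace[sweep] = _collapsed_joint(n_dk, n_kg, n_k, n_d, alpha, beta)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            for k in range(K):
                denom = n_k[k] + gb
                for g in range(G):
                    theta_acc[k, g] += (n_kg[k, g] + beta) / denom
            for d in range(D):
                denom = n_d[d] + K * alpha
                for k in range(K):
                    omega_acc[d, k] += (n_dk[d, k] + alpha) / denom
            n_samples += 1

    if n_samples == 0:  # all sweeps inside burn-in: use final state
        for k in range(K):
            denom = n_k[k] + gb
            for g in range(G):
                theta_acc[k, g] += (n_kg[k, g] + beta) / denom
        for d in range(D):
            denom = n_d[d] + K * alpha
            for k in range(K):
                omega_acc[d, k] += (n_dk[d, k] + alpha) / denom
        n_samples = 1

    return theta_acc / n_samples, omega_acc / n_samples, trace, n_samples
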