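"""Grade-of-membership (LDA) topic models for spatial spot counts.

Each capture spot is modelled as a mixture over K latent topics (cell types /
tissue programs): spot d draws its topic proportions omega_d from a Dirichlet
and every molecule draws a topic k, then a gene from the topic's gene
distribution theta_k.  Fitting is by collapsed Gibbs sampling on the raw
counts; the number of topics is selected by a penalised log-likelihood
approximation of the Bayes factor against the single-multinomial null; and
per-topic marker genes are extracted with a Poisson Kullback-Leibler
discrimination score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import jensenshannon

from . import _lda
from ._utils import child_seeds
from .scoring import ExpressionMatrix


@dataclass
class TopicModel:
    theta: np.ndarray  # topics x genes, rows on the simplex
    omega: np.ndarray  # spots x topics, rows on the simplex
    K: int
    loglik: float
    seed: int
    trace: np.ndarray | None = None
    gene_ids: list | None = None
    spot_ids: list | None = None

    def __post_init__(self):
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.omega.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("omega rows must sum to 1")
        if (self.theta < 0).any() or (self.omega < 0).any():
            raise ValueError("negative probabilities")


@dataclass
class TopicMarkers:
    """Per-topic ranked marker genes with KL discrimination scores."""

    per_topic: dict[int, pd.DataFrame]  # topic -> DataFrame(gene, score), descending


def _counts_to_array(counts):
    if isinstance(counts, ExpressionMatrix):
        return counts.dense(), list(counts.gene_ids), list(counts.obs.index)
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(), list(counts.columns), list(counts.index)
    if sp.issparse(counts):
        return np.asarray(counts.todense()), None, None
    return np.asarray(counts), None, None


def filter_spot_genes(counts, min_spots: int = 10, max_frac: float = 0.95):
    """Drop genes detected in fewer than ``min_spots`` spots or in more than
    ``max_frac`` of spots.

    Boundary semantics: a gene detected in exactly ``min_spots`` spots is
    kept; one detected in exactly ``max_frac`` of spots is kept.  Returns the
    filtered object (same type as input) and a report of removals per rule.
    """
    arr, genes, spots = _counts_to_array(counts)
    n_spots = arr.shape[0]
    det = (arr > 0).sum(axis=0)
    too_rare = det < min_spots
    too_common = det > max_frac * n_spots
    keep = ~(too_rare | too_common)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive the spot-detection filter")
    report = {
        "n_input_genes": int(arr.shape[1]),
        "n_removed_rare": int(too_rare.sum()),
        "n_removed_common": int(too_common.sum()),
        "n_kept": int(keep.sum()),
    }
    if isinstance(counts, ExpressionMatrix):
        out = ExpressionMatrix(
            values=counts.values[:, keep],
            obs=counts.obs,
            gene_ids=counts.gene_ids[keep],
            kind=counts.kind,
            scale_factor=counts.scale_factor,
        )
    elif isinstance(counts, pd.DataFrame):
        out = counts.loc[:, keep]
    else:
        out = arr[:, keep]
    return out, report


def fit_topic_model(
    counts,
    K: int,
    seed: int = 0,
    n_iter: int = 1000,
    burn_in: int | None = None,
    thin: int = 10,
    alpha: float | None = None,
    beta: float = 0.1,
) -> TopicModel:
    """Fit the K-topic model by collapsed Gibbs sampling on raw counts.

    ``alpha`` defaults to the symmetric 1/K prior on spot proportions, ``beta``
    to 0.1 on topic gene distributions.  theta and omega are posterior means
    over post-burn-in samples at the given thinning interval; ``loglik`` is
    the training log likelihood of the counts under the point estimates.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    arr, genes, spots = _counts_to_array(counts)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    D, G = arr.shape
    if alpha is None:
        alpha = 1.0 / K
    if burn_in is None:
        burn_in = n_iter // 2

    coo = sp.coo_matrix(arr)
    reps = coo.data.astype(np.int64)
    token_spot = np.repeat(coo.row.astype(np.int32), reps)
    token_gene = np.repeat(coo.col.astype(np.int32), reps)
    if token_spot.size == 0:
        raise ValueError("no counts to model")

    theta, omega, trace, n_samples = _lda.gibbs(
        token_spot,
        token_gene,
        K,
        D,
        G,
        float(alpha),
        float(beta),
        int(n_iter),
        int(burn_in),
        int(thin),
        int(seed) % (2**31 - 1),
    )
    bad = np.where(~np.isfinite(trace))[0]
    if bad.size:
        raise FloatingPointError(f"non-finite likelihood at sweep {int(bad[0])}")

    theta = theta / theta.sum(axis=1, keepdims=True)
    omega = omega / omega.sum(axis=1, keepdims=True)
    mix = omega @ theta
    ll = float((arr * np.log(np.clip(mix, 1e-300, None))).sum())
    return TopicModel(
        theta=theta,
        omega=omega,
        K=K,
        loglik=ll,
        seed=seed,
        trace=trace,
        gene_ids=genes,
        spot_ids=spots,
    )


def _null_loglik(arr: np.ndarray) -> float:
    """Log likelihood of the K=1 (single multinomial) null."""
    tot = arr.sum(axis=0).astype(float)
    T = tot.sum()
    p = tot / T
    nz = tot > 0
    return float((tot[nz] * np.log(p[nz])).sum())


def select_K(
    counts,
    K_range,
    seed: int = 0,
    n_iter: int = 300,
    **fit_kw,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of topics by maximum approximate log Bayes factor.

    For each K the log Bayes factor against the single-multinomial null is
    approximated by the BIC-style penalised deviance
    ``2*(loglik_K - loglik_1) - (df_K - df_1) * ln(n_tokens)`` with
    ``df_K = K*(G-1) + D*(K-1)``.  K* is the argmax; ties go to the smallest
    K (recorded in the table).
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range or min(K_range) < 2 or max(K_range) > 20:
        raise ValueError("K_range must lie within [2, 20]")
    arr, _, _ = _counts_to_array(counts)
    D, G = arr.shape
    n_tokens = float(arr.sum())
    ll1 = _null_loglik(arr)
    seeds = child_seeds(seed, len(K_range))

    rows = []
    for K, s in zip(K_range, seeds):
        tm = fit_topic_model(arr, K=K, seed=s, n_iter=n_iter, **fit_kw)
        df_k = K * (G - 1) + D * (K - 1)
        lbf = 2.0 * (tm.loglik - ll1) - (df_k - (G - 1)) * np.log(n_tokens)
        rows.append({"K": K, "loglik": tm.loglik, "df": df_k, "log_bf": lbf})
    table = pd.DataFrame(rows).set_index("K", drop=False)
    best = table["log_bf"].to_numpy()
    k_star = int(table["K"].iloc[int(np.argmax(best))])  # argmax; first (smallest K) wins ties
    return k_star, table


def extract_top_genes(tm: TopicModel, n_top: int = 30, eps: float = 1e-12) -> TopicMarkers:
    """Per-topic marker genes by the Poisson-KL discrimination score.

    The score of gene g for topic k is the smallest, over competing topics
    k', of KL(Poisson(theta_kg) || Poisson(theta_k'g)) =
    theta_k'g - theta_kg + theta_kg * ln(theta_kg / theta_k'g): how well the
    gene separates the topic from its nearest competitor.  Scores are
    nonnegative; genes are ranked descending within each topic.
    """
    if tm.K < 2:
        raise ValueError("marker extraction needs K >= 2")
    theta = np.clip(tm.theta, eps, None)
    K, G = theta.shape
    genes = tm.gene_ids if tm.gene_ids is not None else list(range(G))
    per_topic = {}
    for k in range(K):
        others = [kk for kk in range(K) if kk != k]
        kl = np.stack(
            [
                theta[kk] - theta[k] + theta[k] * np.log(theta[k] / theta[kk])
                for kk in others
            ]
        )
        score = np.clip(kl.min(axis=0), 0.0, None)
        order = np.argsort(-score, kind="stable")[:n_top]
        per_topic[k] = pd.DataFrame(
            {"gene": [genes[i] for i in order], "score": score[order]}
        ).reset_index(drop=True)
    return TopicMarkers(per_topic=per_topic)


# -- topic alignment utilities (label switching) ----------------------------


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2, in [0, 1])."""
    return float(jensenshannon(p, q, base=2) ** 2)


def match_topics(theta_hat: np.ndarray, theta_true: np.ndarray) -> np.ndarray:
    """Hungarian assignment of estimated topics to true topics by JSD cost.

    Returns ``perm`` such that ``theta_hat[perm[k]]`` corresponds to
    ``theta_true[k]``.
    """
    K = theta_true.shape[0]
    cost = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = jsd(theta_true[i], theta_hat[j])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm
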