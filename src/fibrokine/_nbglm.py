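"""Vectorised negative-binomial GLM machinery for two-group Wald tests.

All fits share the design ``[intercept, group indicator]`` with a log link and
per-sample log size-factor offsets, which permits closed-form 2x2 IRLS solves
vectorised across all genes at once.  The NB is parameterised by mean mu and
dispersion alpha with Var = mu + alpha * mu**2.

Gene-wise dispersions are maximum (Cox-Reid adjusted) likelihood estimates,
shrunk toward a parametric mean-dispersion trend a/mu + b through a log-normal
prior whose width is estimated from the spread of the gene-wise estimates
around the trend.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, polygamma

ALPHA_MIN = 1e-8
ALPHA_MAX = 50.0
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


def irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    ridge: float = 0.0,
    n_iter: int = 30,
    tol: float = 1e-9,
):
    """Fit ``log mu = b0 + b1*x + offset`` per gene by IRLS.

    Parameters
    ----------
    y : (G, S) counts; x : (S,) 0/1 indicator; offset : (S,) log size factors;
    alpha : (G,) dispersions; ridge : precision of a zero-mean normal prior on
    b1 (0 = plain MLE).

    Returns
    -------
    b0, b1, se1, mu, converged — arrays of shape (G,) except mu (G, S).
    """
    y = np.asarray(y, dtype=float)
    G, S = y.shape
    x = np.asarray(x, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,))

    # moment initialisation on group means
    eps = 0.1
    m0 = (y[:, x == 0] / np.exp(offset[x == 0])).mean(axis=1) + eps
    m1 = (y[:, x == 1] / np.exp(offset[x == 1])).mean(axis=1) + eps
    b0 = np.log(m0)
    b1 = np.log(m1) - np.log(m0)

    converged = np.zeros(G, dtype=bool)
    for _ in range(n_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        a11 = w.sum(axis=1)
        a12 = (w * x).sum(axis=1)
        a22 = (w * x * x).sum(axis=1) + ridge
        r1 = (w * z).sum(axis=1)
        r2 = (w * x * z).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        nb0 = (a22 * r1 - a12 * r2) / det
        nb1 = (a11 * r2 - a12 * r1) / det
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, np.clip(nb1, -15, 15))
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        newly = step < tol
        converged |= newly
        b0, b1 = nb0, np.clip(nb1, -15, 15)
        if converged.all():
            break

    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    a11 = w.sum(axis=1)
    a12 = (w * x).sum(axis=1)
    a22 = (w * x * x).sum(axis=1) + ridge
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(a11 / det)
    return b0, b1, se1, mu, converged


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log likelihood, summed over samples.  Shapes (G,S),(G,S),(G,)."""
    a = np.clip(alpha, ALPHA_MIN, None)[:, None]
    inv = 1.0 / a
    mu = np.clip(mu, 1e-10, None)
    ll = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - inv * np.log1p(a * mu)
    )
    return ll.sum(axis=1)


def _cox_reid(mu: np.ndarray, x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """-0.5 * log det(X' W X) adjustment for the 2-column design."""
    w = mu / (1.0 + alpha[:, None] * mu)
    a11 = w.sum(axis=1)
    a12 = (w * x).sum(axis=1)
    a22 = (w * x * x).sum(axis=1)
    det = np.clip(a11 * a22 - a12 * a12, 1e-30, None)
    return -0.5 * np.log(det)


def _objective(y, x, offset, log_alpha, prior_mean=None, prior_var=None):
    """Cox-Reid adjusted profile log likelihood of log-dispersion (optionally MAP)."""
    alpha = np.exp(log_alpha)
    _, _, _, mu, _ = irls_two_group(y, x, offset, alpha, n_iter=12)
    obj = nb_loglik(y, mu, alpha) + _cox_reid(mu, x, alpha)
    if prior_mean is not None:
        obj = obj - (log_alpha - prior_mean) ** 2 / (2.0 * prior_var)
    return obj


def estimate_dispersions_mle(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    prior_mean: np.ndarray | None = None,
    prior_var: float | np.ndarray | None = None,
    n_golden: int = 35,
) -> np.ndarray:
    """Per-gene dispersion by vectorised golden-section search in log-alpha.

    With ``prior_mean``/``prior_var`` given, maximises the posterior instead
    (log-normal prior on alpha) — this is the trend-shrinkage step.
    """
    G = y.shape[0]
    lo = np.full(G, np.log(ALPHA_MIN))
    hi = np.full(G, np.log(ALPHA_MAX))
    c = hi - _GOLD * (hi - lo)
    d = lo + _GOLD * (hi - lo)
    fc = _objective(y, x, offset, c, prior_mean, prior_var)
    fd = _objective(y, x, offset, d, prior_mean, prior_var)
    for _ in range(n_golden):
        take_left = fc > fd
        hi = np.where(take_left, d, hi)
        lo = np.where(take_left, lo, c)
        c = hi - _GOLD * (hi - lo)
        d = lo + _GOLD * (hi - lo)
        fc = _objective(y, x, offset, c, prior_mean, prior_var)
        fd = _objective(y, x, offset, d, prior_mean, prior_var)
    return np.exp((lo + hi) / 2.0)


def fit_dispersion_trend(alpha_mle: np.ndarray, base_mean: np.ndarray):
    """Parametric trend alpha(mu) = a/mu + b fitted to gene-wise estimates.

    Iteratively reweighted least squares with outlier exclusion; falls back to
    the median dispersion (flat trend) when the fit degenerates.
    Returns (a, b, trend_fn).
    """
    ok = (
        np.isfinite(alpha_mle)
        & (alpha_mle > ALPHA_MIN * 10)
        & (alpha_mle < ALPHA_MAX * 0.9)
        & (base_mean > 0.5)
    )
    if ok.sum() < 20:
        b = float(np.nanmedian(alpha_mle[np.isfinite(alpha_mle)])) if np.isfinite(
            alpha_mle
        ).any() else 0.1
        b = max(b, 1e-6)
        return 0.0, b, lambda mu: np.full_like(np.asarray(mu, float), b)

    al = alpha_mle[ok]
    mu = base_mean[ok]
    X = np.column_stack([1.0 / mu, np.ones_like(mu)])
    w = np.ones_like(al)
    a_c, b_c = 0.0, float(np.median(al))
    for _ in range(15):
        fit = np.clip(X @ np.array([a_c, b_c]), 1e-8, None)
        # gamma-family weights: Var ~ fit^2
        w = 1.0 / fit**2
        WX = X * w[:, None]
        try:
            coef, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ al, rcond=None)
        except np.linalg.LinAlgError:
            break
        a_c = max(float(coef[0]), 0.0)
        b_c = max(float(coef[1]), 1e-6)
        # drop gross outliers once the trend stabilises
        ratio = al / np.clip(X @ np.array([a_c, b_c]), 1e-8, None)
        keep = (ratio < 15) & (ratio > 1 / 15)
        if keep.sum() > 20 and keep.sum() < keep.size:
            al, mu = al[keep], mu[keep]
            X = np.column_stack([1.0 / mu, np.ones_like(mu)])

    a_f, b_f = a_c, b_c

    def trend(m):
        m = np.clip(np.asarray(m, dtype=float), 1e-8, None)
        return np.clip(a_f / m + b_f, ALPHA_MIN, ALPHA_MAX)

    return a_f, b_f, trend


def dispersion_prior_var(log_resid: np.ndarray, n_samples: int, n_coef: int = 2) -> float:
    """Width of the log-normal dispersion prior.

    The spread of gene-wise log-dispersion MLEs around the trend mixes true
    biological spread with sampling noise; the expected sampling variance of a
    log-dispersion MLE is approximately trigamma((m - p)/2), which is
    subtracted, with a floor of 0.25.
    """
    from ._utils import mad_sd

    slr = mad_sd(log_resid)
    samp = float(polygamma(1, max(n_samples - n_coef, 1) / 2.0))
    return float(max(slr**2 - samp, 0.25))
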