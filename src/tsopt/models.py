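"""Genomic prediction models: GBLUP with REML variances, and BayesB.

GBLUP fits y = 1 mu + g + eps with g ~ N(0, sigma2_g K) for a genomic
relationship matrix K.  Variance components are estimated by restricted
maximum likelihood on the eigendecomposition of K (a single dense
decomposition followed by a 1-D profile-likelihood search in the variance
ratio), and the narrow-sense heritability h2 = sigma2_g / (sigma2_g +
sigma2_e) carries a delta-method standard error from the observed
information at the optimum.

BayesB fits y = 1 mu + M beta + eps by Gibbs sampling with a
point-mass-at-zero mixture prior on marker effects: with probability
(1 - pi_in) an effect is exactly zero, otherwise it is normal with a
marker-specific variance carrying a scaled-inverse-chi-square prior (so
the marginal slab is a scaled t).  pi_in has a beta prior and is updated;
the hyperparameters are solved from a prior proportion of variance
explained, mirroring the conventions of common Bayesian-alphabet
software.  The sampler core is compiled with numba.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix
from .pheno import AdjustedMeans

__all__ = [
    "VarianceComponents",
    "GblupFit",
    "BayesBFit",
    "BayesBSettings",
    "reml_fit",
    "heritability",
    "gblup_fit",
    "gblup_predict",
    "bayesb_fit",
    "bayesb_predict",
]

JITTER = 1e-8  # single diagonal jitter allowed on K; never silently more


@dataclasses.dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    covariance: np.ndarray  # 2x2 asymptotic covariance of (sigma2_g, sigma2_e)
    converged: bool
    n_iterations: int
    boundary: bool = False

    @property
    def ratio(self) -> float:
        """sigma2_e / sigma2_g, the shrinkage ratio of the mixed model."""
        return self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else np.inf


@dataclasses.dataclass
class GblupFit:
    mu_hat: float
    g_hat: np.ndarray
    vc: VarianceComponents
    pev_diag: np.ndarray
    individual_ids: list[str]


@dataclasses.dataclass
class BayesBSettings:
    """Chain and prior settings for the BayesB Gibbs sampler.

    ``r2`` is the prior proportion of variance attributed to markers,
    ``nu`` the slab degrees of freedom, and ``pi_counts`` the beta prior
    pseudo-counts (in, out) for the marker inclusion probability — the
    defaults make inclusion sparse a priori (prior mean 0.2).
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    nu: float = 5.0
    r2: float = 0.5
    pi_counts: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")


@dataclasses.dataclass
class BayesBFit:
    mu_hat: float
    beta_mean: np.ndarray
    inclusion: np.ndarray
    sigma2_e_mean: float
    settings: BayesBSettings
    locus_ids: list[str]
    col_means: np.ndarray  # centering used at fit time, needed to predict


# ----------------------------------------------------------------------
# REML
# ----------------------------------------------------------------------

def _as_y(y) -> np.ndarray:
    if isinstance(y, AdjustedMeans):
        return np.asarray(y.values, dtype=float)
    return np.asarray(y, dtype=float)


def _as_k(K) -> np.ndarray:
    if isinstance(K, KinshipMatrix):
        return K.G
    return np.asarray(K, dtype=float)


def _neg2_reml(lam: np.ndarray, yt: np.ndarray, xt: np.ndarray, s2g: float, s2e: float) -> float:
    v = s2g * lam + s2e
    if np.any(v <= 0):
        return np.inf
    w = 1.0 / v
    xwx = np.sum(w * xt * xt)
    mu = np.sum(w * xt * yt) / xwx
    r = yt - xt * mu
    return float(np.sum(np.log(v)) + np.log(xwx) + np.sum(w * r * r))


def reml_fit(y, K, tol: float = 1e-10) -> VarianceComponents:
    """REML variance components for y = 1 mu + g + eps, g ~ N(0, s2g K).

    The profile restricted likelihood is maximized over the log variance
    ratio after one eigendecomposition of K; the asymptotic covariance of
    (sigma2_g, sigma2_e) comes from finite-difference observed information
    at the optimum.  A boundary solution (sigma2_g ~ 0 or sigma2_e ~ 0) is
    flagged, not raised.
    """
    yv, G = _as_y(y), _as_k(K)
    n = yv.size
    if n < 10:
        raise ValueError("REML needs at least 10 individuals")
    if G.shape != (n, n):
        raise ValueError("K misaligned with y")
    lam, U = np.linalg.eigh(G)
    if lam.min() < -1e-6:
        lam = lam + JITTER
        if lam.min() < -1e-6:
            raise ValueError("K is indefinite beyond the jitter policy")
    lam = np.maximum(lam, 0.0)
    yt, xt = U.T @ yv, U.T @ np.ones(n)

    def profiled(log_delta: float) -> tuple[float, float]:
        """(-2 restricted loglik, profiled sigma2_g) at delta = s2e/s2g."""
        delta = np.exp(log_delta)
        v = lam + delta
        w = 1.0 / v
        xwx = np.sum(w * xt * xt)
        mu = np.sum(w * xt * yt) / xwx
        r = yt - xt * mu
        s2g = float(np.sum(w * r * r) / (n - 1))
        if s2g <= 0:
            return np.inf, s2g
        ll = np.sum(np.log(v)) + np.log(xwx) + (n - 1) * np.log(s2g) + (n - 1)
        return float(ll), s2g

    lo, hi = -14.0, 14.0
    res = minimize_scalar(
        lambda t: profiled(t)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9},
    )
    log_delta = float(res.x)
    _, s2g = profiled(log_delta)
    delta = np.exp(log_delta)
    s2e = s2g * delta
    boundary = log_delta < lo + 0.5 or log_delta > hi - 0.5

    cov = _information_covariance(lam, yt, xt, s2g, s2e)
    return VarianceComponents(
        sigma2_g=s2g,
        sigma2_e=s2e,
        covariance=cov,
        converged=bool(res.success),
        n_iterations=int(res.nfev),
        boundary=boundary,
    )


def _information_covariance(lam, yt, xt, s2g, s2e) -> np.ndarray:
    """Observed-information covariance by central finite differences."""
    scale = max(s2g + s2e, 1e-12)
    h = 1e-4 * scale

    def f(a: float, b: float) -> float:
        return 0.5 * _neg2_reml(lam, yt, xt, max(a, 1e-12 * scale), max(b, 1e-12 * scale))

    H = np.empty((2, 2))
    p = np.array([s2g, s2e])
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            H[i, j] = (
                f(*(p + ei + ej)) - f(*(p + ei - ej)) - f(*(p - ei + ej)) + f(*(p - ei - ej))
            ) / (4 * h * h)
    H = (H + H.T) / 2
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((2, 2), np.nan)
    if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
        return np.full((2, 2), np.nan)
    return cov


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """Narrow-sense h2 = s2g / (s2g + s2e) with delta-method SE.

    The gradient of h2 in (s2g, s2e) is (s2e, -s2g) / (s2g + s2e)^2; the
    SE is sqrt(grad' Cov grad) with the REML asymptotic covariance.
    """
    total = vc.sigma2_g + vc.sigma2_e
    if total <= 0:
        raise ValueError("zero total variance")
    h2 = vc.sigma2_g / total
    grad = np.array([vc.sigma2_e, -vc.sigma2_g]) / total**2
    cov = vc.covariance
    se = float(np.sqrt(grad @ cov @ grad)) if np.all(np.isfinite(cov)) else float("nan")
    return float(h2), se


# ----------------------------------------------------------------------
# GBLUP
# ----------------------------------------------------------------------

def gblup_fit(y, K, vc: VarianceComponents | None = None) -> GblupFit:
    """Fit GBLUP on all phenotyped individuals.

    Solves the mixed-model equations with REML variances (estimated here
    unless supplied), returning the intercept, genomic breeding values
    and their prediction-error variances (from the inverse coefficient
    matrix).
    """
    yv, G = _as_y(y), _as_k(K)
    n = yv.size
    if vc is None:
        vc = reml_fit(yv, G)
    ids = K.individual_ids if isinstance(K, KinshipMatrix) else [str(i) for i in range(n)]
    delta = vc.ratio
    if not np.isfinite(delta):  # total shrinkage
        mu = float(np.mean(yv))
        return GblupFit(mu, np.zeros(n), vc, np.full(n, vc.sigma2_g), ids)
    C = G + delta * np.eye(n)
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Ci = np.linalg.inv(C + JITTER * np.eye(n))
    one = np.ones(n)
    # GLS intercept under V = s2g G + s2e I  (proportional to C)
    w = Ci @ one
    mu = float(w @ yv / (w @ one))
    g_hat = G @ Ci @ (yv - mu)
    # PEV of g_hat: Var(g - g_hat) = s2g (G - G Ci G) for known mu
    pev = vc.sigma2_g * np.diag(G - G @ Ci @ G)
    return GblupFit(mu, g_hat, vc, np.maximum(pev, 0.0), ids)


def gblup_predict(
    y_train,
    K,
    train_idx,
    test_idx,
    vc: VarianceComponents | None = None,
) -> np.ndarray:
    """Predict test individuals from training phenotypes via GBLUP.

    ``y_train`` holds one value per training individual, aligned to
    ``train_idx`` rows of K.  Predictions are

        yhat = mu + K_ts,tr (K_tr,tr + delta I)^-1 (y - mu 1),

    with delta = sigma2_e / sigma2_g from REML on the training block
    unless variance components are supplied.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test sets overlap")
    G = _as_k(K)
    yv = _as_y(y_train)
    if yv.size != train_idx.size:
        raise ValueError("y_train length must match train_idx")
    Ktt = G[np.ix_(train_idx, train_idx)]
    if vc is None:
        vc = reml_fit(yv, Ktt)
    delta = vc.ratio
    if not np.isfinite(delta):
        return np.full(test_idx.size, float(np.mean(yv)))
    C = Ktt + delta * np.eye(train_idx.size)
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Ci = np.linalg.inv(C + JITTER * np.eye(train_idx.size))
    one = np.ones(train_idx.size)
    w = Ci @ one
    mu = float(w @ yv / (w @ one))
    Kst = G[np.ix_(test_idx, train_idx)]
    return mu + Kst @ Ci @ (yv - mu)


# ----------------------------------------------------------------------
# BayesB
# ----------------------------------------------------------------------

@njit(cache=True)
def _bayesb_gibbs(
    y, X, n_iter, burn_in, thin, nu, s2_beta0, nu_e, s2_e0, pi_in0, c_in, c_out, seed
):  # pragma: no cover - exercised via bayesb_fit
    np.random.seed(seed)
    n, J = X.shape
    xx = np.empty(J)
    for j in range(J):
        xx[j] = np.dot(X[:, j], X[:, j])
    beta = np.zeros(J)
    inb = np.zeros(J, dtype=np.bool_)
    s2b = np.full(J, s2_beta0)
    mu = np.mean(y)
    e = y - mu
    s2e = np.var(y) * 0.5 + 1e-8
    pi_in = pi_in0

    n_keep = (n_iter - burn_in) // thin
    beta_sum = np.zeros(J)
    incl_sum = np.zeros(J)
    mu_sum = 0.0
    s2e_sum = 0.0
    kept = 0

    for it in range(n_iter):
        # intercept
        e += mu
        mu = np.sum(e) / n + np.sqrt(s2e / n) * np.random.normal()
        e -= mu
        # marker effects
        n_in = 0
        for j in range(J):
            if xx[j] <= 0.0:
                continue
            rhs = np.dot(X[:, j], e)
            if inb[j]:
                rhs += xx[j] * beta[j]
            c = xx[j] + s2e / s2b[j]
            # log Bayes factor of inclusion vs exclusion (beta integrated out)
            log_odds = (
                np.log(pi_in / (1.0 - pi_in))
                - 0.5 * np.log(s2b[j] * xx[j] / s2e + 1.0)
                + 0.5 * rhs * rhs / (s2e * c)
            )
            p_in = 1.0 / (1.0 + np.exp(-log_odds))
            old = beta[j] if inb[j] else 0.0
            if np.random.random() < p_in:
                newb = rhs / c + np.sqrt(s2e / c) * np.random.normal()
                beta[j] = newb
                inb[j] = True
                n_in += 1
            else:
                beta[j] = 0.0
                inb[j] = False
                newb = 0.0
            if newb != old:
                e += X[:, j] * (old - newb)
            # marker variance: scaled-inv-chi2 update (prior draw when out)
            if inb[j]:
                s2b[j] = (nu * s2_beta0 + beta[j] * beta[j]) / np.random.chisquare(nu + 1.0)
            else:
                s2b[j] = nu * s2_beta0 / np.random.chisquare(nu)
            if not np.isfinite(beta[j]):
                raise FloatingPointError("divergent BayesB chain")
        # inclusion probability
        pi_in = np.random.beta(c_in + n_in, c_out + (J - n_in))
        pi_in = min(max(pi_in, 1e-4), 1.0 - 1e-4)
        # residual variance
        sse = np.dot(e, e)
        s2e = (sse + nu_e * s2_e0) / np.random.chisquare(nu_e + n)
        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_sum += beta
            for j in range(J):
                if inb[j]:
                    incl_sum[j] += 1.0
            mu_sum += mu
            s2e_sum += s2e
            kept += 1
    return beta_sum / kept, incl_sum / kept, mu_sum / kept, s2e_sum / kept


def bayesb_fit(
    y_train, M: GenotypeMatrix | np.ndarray, settings: BayesBSettings | None = None
) -> BayesBFit:
    """Fit the BayesB marker-effect model by Gibbs sampling.

    ``M`` is a complete dosage matrix (or raw array) for the training
    individuals; columns are centered internally.  Returns posterior mean
    effects, per-marker inclusion proportions and the posterior mean
    intercept.  The chain is deterministic for a fixed ``settings.seed``.
    """
    settings = settings or BayesBSettings()
    yv = _as_y(y_train)
    if isinstance(M, GenotypeMatrix):
        M._require_complete()
        X = M.dosage.astype(np.float64)
        loci = list(M.locus_ids)
    else:
        X = np.asarray(M, dtype=np.float64)
        loci = [f"m{j}" for j in range(X.shape[1])]
    if X.shape[0] != yv.size:
        raise ValueError("marker matrix misaligned with y")
    col_means = X.mean(axis=0)
    Xc = np.asfortranarray(X - col_means)  # column-contiguous for the sampler

    var_y = float(np.var(yv))
    if var_y <= 0:
        # degenerate response: nothing to explain
        return BayesBFit(float(yv[0]), np.zeros(X.shape[1]), np.zeros(X.shape[1]),
                         0.0, settings, loci, col_means)
    msx = float(np.sum(Xc.var(axis=0)))
    c_in, c_out = settings.pi_counts
    pi_prior = c_in / (c_in + c_out)
    nu = settings.nu
    # prior slab scale solved from the prior marker R2 given expected inclusion
    s2_beta0 = var_y * settings.r2 * (nu + 2.0) / nu / max(msx * pi_prior, 1e-12)
    nu_e = 5.0
    s2_e0 = var_y * (1.0 - settings.r2) * (nu_e + 2.0) / nu_e

    try:
        beta_mean, incl, mu_mean, s2e_mean = _bayesb_gibbs(
            yv.astype(np.float64), Xc, settings.n_iter, settings.burn_in,
            settings.thin, nu, s2_beta0, nu_e, s2_e0, pi_prior,
            c_in, c_out, settings.seed & 0x7FFFFFFF,
        )
    except FloatingPointError as err:
        raise RuntimeError(f"BayesB chain diverged: {err}") from err
    return BayesBFit(
        mu_hat=float(mu_mean),
        beta_mean=beta_mean,
        inclusion=incl,
        sigma2_e_mean=float(s2e_mean),
        settings=settings,
        locus_ids=loci,
        col_means=col_means,
    )


def bayesb_predict(fit: BayesBFit, M_test: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Predict new individuals: mu + (M - centering) @ posterior mean beta."""
    if isinstance(M_test, GenotypeMatrix):
        M_test._require_complete()
        X = M_test.dosage.astype(np.float64)
    else:
        X = np.asarray(M_test, dtype=np.float64)
    return fit.mu_hat + (X - fit.col_means) @ fit.beta_mean
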