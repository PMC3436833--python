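"""Joint SNP-set association test: supervised reduction, GLM, permutation.

The test statistic is the GLM likelihood-ratio (deviance difference)
between ``trait ~ covariates`` and ``trait ~ covariates + sufficient
predictors`` — ordinary linear regression for quantitative traits, logistic
regression for case-control status.  Because the reduction is supervised,
its directions must be refit inside every permutation; the kernel matrix
itself is label-free, so a permutation only permutes the genotype side
(simultaneous row/column permutation of the kernel) against the intact
(trait, covariate) pairs, and the per-permutation eigenproblem is solved
in a fixed reduced eigenbasis of the centered kernel computed once per
dataset.

The public :func:`glm_statistic` goes through statsmodels; the permutation
loop uses an equivalent vectorized Newton/IRLS routine (checked against
the statsmodels route in the test suite) so that tens of thousands of
refits stay cheap.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import norm

from . import classic_kernels, wf_kernel as wf
from .dimred import (DEFAULT_KSIR_RIDGE_FACTOR, _slice_weight_matrix,
                     fit_pca, slice_response)
from .genotypes import CovariateMatrix, GenotypeMatrix, TraitVector, recode

__all__ = [
    "AssocResult",
    "beta_to_odds_ratio",
    "glm_statistic",
    "permutation_test",
    "build_kernel",
]

DEFAULT_REDUCED_BASIS = 150


@dataclass
class AssocResult:
    """Permutation-test outcome for one SNP set."""

    statistic_obs: float
    perm_stats: np.ndarray
    B: int
    p_empirical: float
    config_digest: str = ""
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.perm_stats = np.asarray(self.perm_stats, dtype=float)
        if len(self.perm_stats) != self.B:
            raise ValueError("perm_stats length must equal B")
        if not 0.0 < self.p_empirical <= 1.0:
            raise ValueError("empirical p must lie in (0, 1]")


def beta_to_odds_ratio(beta: float) -> float:
    """Odds ratio implied by a linear trait coefficient ``beta`` for a
    half-affected, half-control sample: ``(1 - Phi(-beta)) / Phi(-beta)``
    with ``Phi`` the standard normal CDF.  Equals 1 at beta = 0 and is
    strictly increasing."""
    phi = norm.cdf(-beta)
    return float((1.0 - phi) / phi)


# ---------------------------------------------------------------------------
# GLM likelihood-ratio statistic
# ---------------------------------------------------------------------------

def _as_array(c: CovariateMatrix | np.ndarray | None) -> np.ndarray | None:
    if c is None:
        return None
    vals = c.values if isinstance(c, CovariateMatrix) else np.atleast_2d(np.asarray(c, float))
    return vals if vals.size else None


def glm_statistic(s: np.ndarray, y: TraitVector,
                  c: CovariateMatrix | np.ndarray | None = None) -> float:
    """Deviance-difference (likelihood-ratio) statistic for adding the
    sufficient predictors ``s`` to the null GLM ``y ~ covariates``.

    Gaussian/identity for quantitative traits (equal to
    ``n log(RSS_null / RSS_full)``), binomial/logit for binary traits.
    Non-negative up to numerical tolerance.  A perfectly separated
    logistic fit falls back to a ridge-stabilized Newton fit with a
    warning.
    """
    import statsmodels.api as sm

    s = np.atleast_2d(np.asarray(s, dtype=float))
    if s.shape[0] == 1 and len(y) > 1:
        s = s.T
    n = len(y)
    cov = _as_array(c)
    X0 = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    X1 = np.column_stack([X0, s])
    if y.kind == "quantitative":
        ll0 = sm.OLS(y.values, X0).fit().llf
        ll1 = sm.OLS(y.values, X1).fit().llf
        return max(2.0 * (ll1 - ll0), 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll0 = sm.Logit(y.values, X0).fit(disp=0).llf
            ll1 = sm.Logit(y.values, X1).fit(disp=0).llf
        if not (np.isfinite(ll0) and np.isfinite(ll1)):
            raise ValueError("non-finite logistic log-likelihood")
    except Exception:
        warnings.warn("logistic fit unstable (separation?); using "
                      "ridge-stabilized Newton fit", stacklevel=2)
        ll0 = _logistic_loglik(y.values, X0, penalty=1e-4)
        ll1 = _logistic_loglik(y.values, X1, penalty=1e-4)
    return max(2.0 * (ll1 - ll0), 0.0)


def _logistic_loglik(y: np.ndarray, X: np.ndarray, penalty: float = 0.0,
                     max_iter: int = 50) -> float:
    """Newton/IRLS logistic log-likelihood (optionally ridge-penalized)."""
    n, k = X.shape
    beta = np.zeros(k)
    pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    beta[0] = np.log(pbar / (1.0 - pbar))
    eye = np.eye(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wd = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - penalty * beta
        hess = (X * wd[:, None]).T @ X + (penalty + 1e-10) * eye
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < 1e-9:
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


# --- vectorized permutation-loop statistics --------------------------------

def _gaussian_lr_batch(y: np.ndarray, S: np.ndarray, X0: np.ndarray) -> np.ndarray:
    """n log(RSS0/RSS1) for each predictor block S[b] (shape B x n x d),
    with the null design X0 projected out."""
    n = len(y)
    Q, _ = np.linalg.qr(X0)
    yr = y - Q @ (Q.T @ y)
    rss0 = float(yr @ yr)
    Sr = S - np.einsum("ij,bjd->bid", Q @ Q.T, S)
    StS = np.einsum("bid,bie->bde", Sr, Sr)
    Sty = np.einsum("bid,i->bd", Sr, yr)
    d = S.shape[2]
    StS = StS + 1e-12 * np.trace(StS, axis1=1, axis2=2)[:, None, None] * np.eye(d)
    coef = np.linalg.solve(StS, Sty[..., None])[..., 0]
    explained = np.einsum("bd,bd->b", Sty, coef)
    rss1 = np.maximum(rss0 - explained, 1e-300)
    return n * np.log(rss0 / rss1)


def _logistic_lr_batch(y: np.ndarray, S: np.ndarray, X0: np.ndarray,
                       max_iter: int = 30) -> np.ndarray:
    """Logistic LR statistic for each predictor block S[b] vs the common
    null design X0, by batched Newton iteration with warm start at the
    null fit."""
    n = len(y)
    B, _, d = S.shape
    k0 = X0.shape[1]
    beta0 = np.zeros(k0)
    pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    beta0[0] = np.log(pbar / (1.0 - pbar))
    for _ in range(max_iter):  # null fit (shared)
        eta = np.clip(X0 @ beta0, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wd = np.maximum(mu * (1.0 - mu), 1e-12)
        step = np.linalg.solve((X0 * wd[:, None]).T @ X0 + 1e-10 * np.eye(k0),
                               X0.T @ (y - mu))
        beta0 += step
        if np.abs(step).max() < 1e-10:
            break
    eta0 = np.clip(X0 @ beta0, -30, 30)
    ll0 = float(np.sum(y * eta0 - np.log1p(np.exp(eta0))))

    k = k0 + d
    beta = np.zeros((B, k))
    beta[:, :k0] = beta0
    eye = np.eye(k)
    for _ in range(max_iter):
        eta = X0 @ beta[:, :k0].T  # n x B
        eta = eta.T + np.einsum("bnd,bd->bn", S, beta[:, k0:])
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wd = np.maximum(mu * (1.0 - mu), 1e-12)
        resid = y[None, :] - mu
        grad = np.empty((B, k))
        grad[:, :k0] = resid @ X0
        grad[:, k0:] = np.einsum("bn,bnd->bd", resid, S)
        hess = np.empty((B, k, k))
        XW = X0[None, :, :] * wd[:, :, None]
        hess[:, :k0, :k0] = np.einsum("bni,nj->bij", XW, X0)
        cross = np.einsum("bni,bnd->bid", XW, S)
        hess[:, :k0, k0:] = cross
        hess[:, k0:, :k0] = cross.transpose(0, 2, 1)
        hess[:, k0:, k0:] = np.einsum("bnd,bn,bne->bde", S, wd, S)
        hess += 1e-10 * eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        beta += step
        if np.abs(step).max() < 1e-9:
            break
    eta = X0 @ beta[:, :k0].T
    eta = np.clip(eta.T + np.einsum("bnd,bd->bn", S, beta[:, k0:]), -30, 30)
    ll1 = np.sum(y[None, :] * eta - np.log1p(np.exp(eta)), axis=1)
    return np.maximum(2.0 * (ll1 - ll0), 0.0)


def _lr_batch(y: TraitVector, S: np.ndarray, X0: np.ndarray) -> np.ndarray:
    if y.kind == "binary":
        return _logistic_lr_batch(y.values, S, X0)
    return _gaussian_lr_batch(y.values, S, X0)


# ---------------------------------------------------------------------------
# Kernel dispatch
# ---------------------------------------------------------------------------

def build_kernel(g: GenotypeMatrix, kernel_spec: dict | str) -> wf.KernelMatrix:
    """Build a symmetric kernel from a spec like ``{"name": "wf", ...}``.

    Names: ``wf`` (extra keys ``symmetrization``, ``dm``), ``ibs``,
    ``wibs`` (``weights``), ``gaussian`` (``bandwidth``), ``linear``.
    Each kernel recodes the genotypes to its required convention itself.
    """
    spec = {"name": kernel_spec} if isinstance(kernel_spec, str) else dict(kernel_spec)
    name = spec.pop("name", "wf")
    if name == "precomputed":
        K = spec.pop("kernel")
        return K if isinstance(K, wf.KernelMatrix) else wf.KernelMatrix(
            np.asarray(K, float), symmetric=True)
    if name == "wf":
        return wf.wf_kernel(g, dm=spec.pop("dm", None),
                            symmetrization=spec.pop("symmetrization",
                                                    "multiplicative"))
    if name == "ibs":
        return classic_kernels.ibs_kernel(g)
    if name == "wibs":
        return classic_kernels.weighted_ibs_kernel(
            g, weights=spec.pop("weights", "maf-default"))
    if name == "gaussian":
        return classic_kernels.gaussian_kernel(
            g, bandwidth=spec.pop("bandwidth", "median-heuristic"))
    if name == "linear":
        return classic_kernels.linear_kernel(g)
    raise ValueError(f"unknown kernel {name!r}")


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _digest(obj: dict) -> str:
    return hashlib.sha1(json.dumps(obj, sort_keys=True, default=str)
                        .encode()).hexdigest()[:12]


class _KsirEngine:
    """Per-dataset kSIR machinery: eigenbasis of the centered kernel is
    computed once; each permutation costs O(n m) plus an H x H eigensolve."""

    def __init__(self, K: np.ndarray, y: TraitVector, H: int, d: int,
                 ridge: float | None, m: int | None):
        n = K.shape[0]
        col_mean = K.mean(axis=0)
        Kbar = K - col_mean[None, :] - col_mean[:, None] + K.mean()
        w, U = np.linalg.eigh(Kbar)
        idx = np.argsort(w)[::-1]
        lam_all = np.maximum(w[idx], 0.0)
        if ridge is None:
            ridge = DEFAULT_KSIR_RIDGE_FACTOR * float((lam_all ** 2).sum()) / n
        m = n if m is None else min(m, n)
        self.lam = lam_all[:m]
        self.U = np.ascontiguousarray(U[:, idx[:m]])
        self.ridge = ridge
        self.sl = slice_response(y, H)
        self.d = min(d, self.sl.H - 1)
        self.Z = _slice_weight_matrix(self.sl, n)
        self.sqrtB = np.sqrt(self.lam ** 2 + self.ridge)
        self.filt = self.lam / self.sqrtB
        # row indices per slice, for segment sums
        self.slice_rows = [np.flatnonzero(self.sl.labels == h)
                           for h in range(self.sl.H)]
        self.zw = 1.0 / np.sqrt(n * np.maximum(self.sl.counts, 1))

    def predictors(self, perm: np.ndarray | None) -> np.ndarray:
        """In-sample sufficient predictors after permuting the genotype
        side by ``perm`` (None = observed ordering)."""
        rows = self.U if perm is None else self.U[perm]
        V = np.empty((self.U.shape[1], self.sl.H))
        for h, ridx in enumerate(self.slice_rows):
            V[:, h] = rows[ridx].sum(axis=0) * self.zw[h]
        V *= self.filt[:, None]
        G = V.T @ V
        gw, gv = np.linalg.eigh(G)
        idx = np.argsort(gw)[::-1][:self.d]
        S = np.empty((self.U.shape[0], len(idx)))
        for k, j in enumerate(idx):
            b = V @ gv[:, j]
            nb = np.linalg.norm(b)
            if nb > 0:
                b /= nb
            S[:, k] = rows @ ((self.lam / self.sqrtB) * b)
        return S


class _SirEngine:
    """Linear-SIR analogue: covariance whitening is permutation-invariant,
    so each permutation needs only fresh slice means."""

    def __init__(self, X: np.ndarray, y: TraitVector, H: int, d: int,
                 ridge: float):
        n, p = X.shape
        self.Xc = X - X.mean(axis=0)
        Sigma = (self.Xc.T @ self.Xc) / n + ridge * np.eye(p)
        try:
            self.L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            raise ValueError("singular SNP covariance; pass dr ridge > 0") from None
        self.sl = slice_response(y, H)
        self.d = min(d, self.sl.H - 1)
        self.Z = _slice_weight_matrix(self.sl, n)
        self.slice_rows = [np.flatnonzero(self.sl.labels == h)
                           for h in range(self.sl.H)]
        self.zw = 1.0 / np.sqrt(n * np.maximum(self.sl.counts, 1))

    def predictors(self, perm: np.ndarray | None) -> np.ndarray:
        rows = self.Xc if perm is None else self.Xc[perm]
        D = np.empty((self.Xc.shape[1], self.sl.H))
        for h, ridx in enumerate(self.slice_rows):
            D[:, h] = rows[ridx].sum(axis=0) * self.zw[h]
        W = scipy.linalg.solve_triangular(self.L, D, lower=True)
        G = W.T @ W
        gw, gv = np.linalg.eigh(G)
        idx = np.argsort(gw)[::-1][:self.d]
        S = np.empty((self.Xc.shape[0], len(idx)))
        for k, j in enumerate(idx):
            b = W @ gv[:, j]
            nb = np.linalg.norm(b)
            if nb > 0:
                b /= nb
            eta = scipy.linalg.solve_triangular(self.L, b, lower=True,
                                                trans="T")
            S[:, k] = rows @ eta
        return S


def permutation_test(
    g: GenotypeMatrix,
    y: TraitVector,
    c: CovariateMatrix | np.ndarray | None = None,
    kernel_spec: dict | str = "wf",
    dr_spec: dict | None = None,
    B: int = 1000,
    seed: int = 0,
) -> AssocResult:
    """Joint SNP-set association test with a permutation null.

    The kernel (label-free) is computed once; the observed statistic comes
    from reduction -> projection -> GLM, and each of ``B`` permutations
    permutes the genotype side against the intact (trait, covariate) pairs
    and refits the supervised reduction before recomputing the statistic.
    Returns the empirical p-value ``(1 + #{perm >= obs}) / (1 + B)``.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    n = g.n_samples
    if len(y) != n:
        raise ValueError("trait length does not match genotype rows")
    cov = _as_array(c)
    if cov is not None and cov.shape[0] != n:
        raise ValueError("covariate rows do not match genotype rows")
    dr = {"method": "ksir", "d": 1, "H": None, "ridge": None,
          "reduced_basis_m": DEFAULT_REDUCED_BASIS}
    dr.update(dr_spec or {})
    H = dr["H"] or (2 if y.kind == "binary" else 10)

    config = {"kernel": kernel_spec, "dr": dr, "B": B, "seed": seed,
              "trait_kind": y.kind}
    rng = np.random.default_rng(seed)
    X0 = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])

    method = dr["method"]
    if method == "ksir":
        K = build_kernel(g, kernel_spec)
        engine = _KsirEngine(K.values, y, H, dr["d"], dr["ridge"],
                             dr["reduced_basis_m"])
        get_S = engine.predictors
    elif method == "sir":
        X = recode(g, "minor").values.astype(float)
        engine = _SirEngine(X, y, H, dr["d"], dr["ridge"] or 0.0)
        get_S = engine.predictors
    elif method == "pca":
        fit = fit_pca(g, dr["d"])
        X = recode(g, "minor").values.astype(float)
        S_fixed = (X - X.mean(axis=0)) @ fit.dual_coefs

        def get_S(perm):
            return S_fixed if perm is None else S_fixed[perm]
    elif method == "none":
        X = recode(g, "minor").values.astype(float)
        Xc = X - X.mean(axis=0)

        def get_S(perm):
            return Xc if perm is None else Xc[perm]
    else:
        raise ValueError(f"unknown reduction method {method!r}")

    S_obs = get_S(None)
    d_eff = S_obs.shape[1]
    S_all = np.empty((B + 1, n, d_eff))
    S_all[0] = S_obs
    for b in range(B):
        S_all[b + 1] = get_S(rng.permutation(n))
    stats = _lr_batch(y, S_all, X0)
    obs, perm_stats = float(stats[0]), stats[1:]
    p_emp = (1.0 + float((perm_stats >= obs).sum())) / (1.0 + B)
    return AssocResult(obs, perm_stats, B, p_emp,
                       config_digest=_digest(config), config=config)
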