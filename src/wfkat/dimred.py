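"""Supervised dimension reduction: PCA, sliced inverse regression (SIR)
and kernel SIR (kSIR).

SIR estimates the central subspace of a regression from the generalized
eigenproblem ``Omega eta = lambda Sigma eta`` where ``Omega`` is the
between-slice covariance of predictor means, ``Cov{E(X|Y) - E(X)}``.  kSIR
carries the same estimation into a kernel feature space through the dual
problem on the centered Gram matrix

    Kbar J Kbar a = lambda (Kbar Kbar + ridge I) a,

with ``J_ij = 1/(n n_h)`` for samples sharing slice ``h`` (0 otherwise),
so only an ``n x n`` decomposition is needed and ``p >> n`` is fine.  The
nonlinear sufficient predictor of a sample is the kernel expansion
``sum_i a_ji k(x_i, x)`` after the training centering transform.

All solvers reduce the generalized problem to an ordinary symmetric one in
the eigenbasis of ``Kbar`` (the right operator is diagonal there), which
is also what makes the permutation engine in :mod:`wfkat.assoc` cheap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .classic_kernels import center_kernel
from .genotypes import GenotypeMatrix, TraitVector, recode
from .wf_kernel import KernelMatrix, _jsonable

__all__ = [
    "SliceAssignment",
    "ReductionFit",
    "slice_response",
    "fit_pca",
    "fit_sir",
    "fit_ksir",
    "project",
    "DEFAULT_KSIR_RIDGE_FACTOR",
]

#: kSIR ridge defaults to this factor times trace(Kbar Kbar)/n (the mean
#: squared eigenvalue).  A vanishing ridge lets the leading predictor
#: interpolate the slice labels through the numerically full-rank kernel;
#: the mean-squared-eigenvalue scale shrinks the weak tail of the spectrum
#: while keeping the strong components, sitting between interpolation and
#: the pure quadratic-form regime.
DEFAULT_KSIR_RIDGE_FACTOR = 1.0


@dataclass
class SliceAssignment:
    """Slice labels in ``{0, ..., H-1}`` and per-slice counts."""

    labels: np.ndarray
    counts: np.ndarray

    @property
    def H(self) -> int:
        return len(self.counts)


@dataclass
class ReductionFit:
    """A fitted reduction: dual/loading vectors, eigenvalues and the
    training references needed to evaluate predictors on new samples.

    For ``ksir`` the columns of ``dual_coefs`` are kernel-expansion weight
    vectors ``a_j``; for ``pca``/``sir`` they are loading vectors in
    predictor space.
    """

    method: str
    dual_coefs: np.ndarray
    eigenvalues: np.ndarray
    train_ref: dict = field(default_factory=dict)
    d: int = 1

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if len(ev) > 1 and (np.diff(ev) > 1e-8).any():
            raise ValueError("eigenvalues must be non-increasing")

    def to_json(self, path: str) -> None:
        payload = {
            "method": self.method,
            "d": self.d,
            "eigenvalues": self.eigenvalues.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "train_ref": _jsonable(self.train_ref),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str) -> "ReductionFit":
        payload = json.loads(Path(path).read_text())
        ref = {k: (np.asarray(v) if isinstance(v, list) else v)
               for k, v in payload["train_ref"].items()}
        return cls(payload["method"], np.asarray(payload["dual_coefs"]),
                   np.asarray(payload["eigenvalues"]), ref, payload["d"])


def slice_response(y: TraitVector, H: int = 10) -> SliceAssignment:
    """Partition the response into slices: binary traits by class (H forced
    to 2), quantitative traits into ``H`` near-equal-count slices by sorted
    order (stable ties); counts differ by at most one."""
    n = len(y)
    if y.kind == "binary":
        labels = y.values.astype(int)
        counts = np.bincount(labels, minlength=2)
        return SliceAssignment(labels, counts)
    if H < 2:
        raise ValueError("need at least two slices")
    if H > n:
        raise ValueError(f"cannot form {H} slices from {n} samples")
    order = np.argsort(y.values, kind="stable")
    labels = np.empty(n, dtype=int)
    for h, chunk in enumerate(np.array_split(order, H)):
        labels[chunk] = h
    return SliceAssignment(labels, np.bincount(labels, minlength=H))


# ---------------------------------------------------------------------------
# Linear reductions
# ---------------------------------------------------------------------------

def _predictor_matrix(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(g, GenotypeMatrix):
        return recode(g, "minor").values.astype(float)
    return np.asarray(g, dtype=float)


def fit_pca(g: GenotypeMatrix | np.ndarray, d: int) -> ReductionFit:
    """Unsupervised baseline: leading eigenvectors of the sample covariance
    of the SNP codes; component variances equal the eigenvalues."""
    X = _predictor_matrix(g)
    n, p = X.shape
    if not 1 <= d <= min(n - 1, p):
        raise ValueError(f"d must be in [1, {min(n - 1, p)}], got {d}")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(np.atleast_2d(cov))
    idx = np.argsort(w)[::-1][:d]
    loadings = V[:, idx]
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(d):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    return ReductionFit("pca", loadings, w[idx], {"mean": mean}, d)


def fit_sir(g: GenotypeMatrix | np.ndarray, y: TraitVector, H: int = 10,
            d: int = 1, ridge: float = 0.0) -> ReductionFit:
    """Linear SIR: solve ``Omega eta = lambda (Sigma + ridge I) eta`` with
    ``Omega = sum_h (n_h/n)(xbar_h - xbar)(xbar_h - xbar)^T``.

    Directions are normalized to unit Sigma-length and signed so the
    in-sample predictor correlates non-negatively with the response;
    eigenvalues lie in [0, 1] up to tolerance.  At most ``H - 1``
    directions exist; a larger request is capped with a warning.
    """
    X = _predictor_matrix(g)
    n, p = X.shape
    sl = slice_response(y, H)
    d_max = sl.H - 1
    if d > d_max:
        warnings.warn(f"SIR supports at most H-1={d_max} directions; capping d",
                      stacklevel=2)
        d = d_max
    xbar = X.mean(axis=0)
    Xc = X - xbar
    Sigma = (Xc.T @ Xc) / n + ridge * np.eye(p)
    Omega = np.zeros((p, p))
    for h in range(sl.H):
        dh = Xc[sl.labels == h].mean(axis=0)
        Omega += (sl.counts[h] / n) * np.outer(dh, dh)
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            "sample covariance is singular (p >= n or collinear SNPs); "
            "pass ridge > 0"
        ) from None
    w, V = scipy.linalg.eigh(Omega, Sigma)
    idx = np.argsort(w)[::-1][:d]
    eta = V[:, idx]  # Sigma-orthonormal, i.e. unit Sigma-length
    lam = np.clip(w[idx], 0.0, 1.0 + 1e-8)
    s = Xc @ eta
    for j in range(d):
        if np.corrcoef(s[:, j], y.values)[0, 1] < 0:
            eta[:, j] *= -1
    return ReductionFit("sir", eta, lam, {"mean": xbar}, d)


# ---------------------------------------------------------------------------
# Kernel SIR
# ---------------------------------------------------------------------------

def _slice_weight_matrix(sl: SliceAssignment, n: int) -> np.ndarray:
    """Columns ``1_h / sqrt(n n_h)``: J = Z Z^T for the kSIR J matrix."""
    Z = np.zeros((n, sl.H))
    Z[np.arange(n), sl.labels] = 1.0
    return Z / np.sqrt(n * np.maximum(sl.counts, 1))


def _ksir_in_basis(lam: np.ndarray, U: np.ndarray, Z: np.ndarray, d: int,
                   ridge: float):
    """Solve the kSIR generalized eigenproblem in the eigenbasis of Kbar.

    ``lam, U`` are (non-negative) eigenvalues/vectors of the centered
    kernel, ``Z`` the slice-weight matrix with ``J = Z Z^T``.  Returns
    ``(dual coefficient columns a_j, eigenvalues, in-sample predictors)``;
    eigenvalues are reported on the SIR scale (times n, in [0, 1]).
    """
    n = U.shape[0]
    B = lam ** 2 + ridge
    V = (lam / np.sqrt(B))[:, None] * (U.T @ Z)   # m x H
    G = V.T @ V                                   # H x H Gram of rank-H operator
    gw, gv = np.linalg.eigh(G)
    idx = np.argsort(gw)[::-1][:d]
    lam_out = np.maximum(gw[idx], 0.0) * n
    coefs = np.empty((n, len(idx)))
    preds = np.empty((n, len(idx)))
    for k, j in enumerate(idx):
        b = V @ gv[:, j]
        nb = np.linalg.norm(b)
        if nb > 0:
            b = b / nb
        c = b / np.sqrt(B)
        coefs[:, k] = U @ c
        preds[:, k] = U @ (lam * c)
    return coefs, lam_out, preds


def fit_ksir(K: KernelMatrix | np.ndarray, y: TraitVector, H: int = 10,
             d: int = 1, ridge: float | None = None) -> ReductionFit:
    """Kernel SIR on an uncentered symmetric kernel.

    Centers the kernel, forms the slice matrix ``J`` and solves the dual
    generalized eigenproblem.  The ridge defaults to
    ``DEFAULT_KSIR_RIDGE_FACTOR * trace(Kbar Kbar) / n``.  Dual vectors are
    scaled to unit-norm in-sample predictors and signed so each predictor
    correlates non-negatively with the response; centering statistics are
    stored for out-of-sample projection.
    """
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("fit_ksir requires a symmetric kernel matrix")
    n = values.shape[0]
    if len(y) != n:
        raise ValueError("trait length does not match kernel size")
    sl = slice_response(y, H)
    d_max = sl.H - 1
    if d > d_max:
        warnings.warn(f"kSIR supports at most H-1={d_max} directions; capping d",
                      stacklevel=2)
        d = d_max
    Kc = center_kernel(values)
    Kbar = Kc.values
    w, U = np.linalg.eigh(Kbar)
    idx = np.argsort(w)[::-1]
    lam = np.maximum(w[idx], 0.0)
    U = U[:, idx]
    if ridge is None:
        ridge = DEFAULT_KSIR_RIDGE_FACTOR * float((lam ** 2).sum()) / n
    Z = _slice_weight_matrix(sl, n)
    coefs, lam_out, preds = _ksir_in_basis(lam, U, Z, d, ridge)
    if lam_out.max(initial=0.0) < 1e-12:
        warnings.warn("all kSIR eigenvalues are ~0: no supervised signal",
                      stacklevel=2)
    for j in range(coefs.shape[1]):
        if np.corrcoef(preds[:, j], y.values)[0, 1] < 0:
            coefs[:, j] *= -1
            preds[:, j] *= -1
    train_ref = {
        "col_mean": values.mean(axis=0),
        "grand_mean": float(values.mean()),
        "predictors": preds,
        "ridge": float(ridge),
        "n": n,
    }
    return ReductionFit("ksir", coefs, lam_out, train_ref, coefs.shape[1])


def project(fit: ReductionFit, k_new: np.ndarray | None = None,
            g_new: GenotypeMatrix | np.ndarray | None = None) -> np.ndarray:
    """Sufficient predictors for new samples.

    For ``ksir``, ``k_new`` has one row per new sample holding its kernel
    evaluations against the ``n`` training samples (same kernel, coding and
    symmetrization as training); the training centering transform is
    applied and the rows multiplied by the dual coefficients.  Projecting
    the training kernel itself reproduces the in-sample predictors.  For
    ``pca``/``sir``, pass ``g_new`` instead.
    """
    if fit.method == "ksir":
        if k_new is None:
            raise ValueError("ksir projection requires k_new")
        k_new = np.atleast_2d(np.asarray(k_new, dtype=float))
        n = fit.train_ref["n"]
        if k_new.shape[1] != n:
            raise ValueError(
                f"k_new must have {n} columns (one per training sample), "
                f"got {k_new.shape[1]}"
            )
        col_mean = np.asarray(fit.train_ref["col_mean"], dtype=float)
        grand = float(fit.train_ref["grand_mean"])
        centered = (k_new - k_new.mean(axis=1, keepdims=True)
                    - col_mean[None, :] + grand)
        return centered @ fit.dual_coefs
    if g_new is None:
        raise ValueError(f"{fit.method} projection requires g_new")
    X = _predictor_matrix(g_new)
    mean = np.asarray(fit.train_ref["mean"], dtype=float)
    return (X - mean) @ fit.dual_coefs
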