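"""The Wright-Fisher Mercer kernel for genotype vectors.

A SNP set of ``p`` loci, coded by major-allele counts, is viewed as a draw
from a Dirichlet-multinomial distribution over ``p + 1`` categories: the
``p`` per-locus major-allele counts plus a slack category absorbing the
remaining ``N - sum_t x_t`` of the ``N = 2p`` allele slots (i.e. the total
minor-allele burden).  The Wright-Fisher resampling chain with Dirichlet
mutation mass ``alpha`` moves from genotype ``x`` to ``x'`` with the
multinomial probability of the augmented target vector under sampling
probabilities

    pi_t(x) = (x_t + alpha_t) / (N + |alpha|).

The resulting (asymmetric) transition matrix between the observed
individuals, after column l2 scaling and additive or multiplicative
symmetrization, is a Mercer kernel: positivity is inherited from the
chain's positive spectrum via the symmetrization facts below.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln

from .genotypes import GenotypeMatrix, recode

__all__ = [
    "DirichletParams",
    "KernelMatrix",
    "estimate_dm_params",
    "fit_dm_counts",
    "dm_loglik",
    "wf_cross_kernel",
    "wf_transition",
    "wf_closed_form_eigenvalue",
    "build_wf_kernel",
    "column_l2_normalize",
    "symmetrize",
    "wf_kernel",
    "additive_symmetrization",
    "multiplicative_symmetrization",
    "gram_symmetrization",
    "has_positive_spectrum",
    "full_state_space",
    "full_transition_matrix",
    "simulate_wf_chain",
]

#: Concentration ceiling, as a multiple of N: beyond |alpha| = 100 N the
#: transition law is within ~1% of its multinomial limit and the DM
#: likelihood is flat; the fixed-point iteration stops there and flags
#: boundary convergence (the MLE diverges for under-dispersed counts).
ALPHA_TOTAL_CEILING_FACTOR = 100.0

_ALPHA_FLOOR = 1e-6


@dataclass
class DirichletParams:
    """Dirichlet-multinomial parameters for the augmented genotype counts.

    ``alpha`` holds the ``p`` per-locus components, ``alpha_slack`` the
    component of the slack (minor-allele burden) category; ``alpha_total``
    is their sum.  ``boundary`` records whether estimation stopped at the
    concentration ceiling (multinomial limit) rather than an interior MLE.
    """

    alpha: np.ndarray
    alpha_slack: float
    boundary: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if (self.alpha <= 0).any() or self.alpha_slack <= 0:
            raise ValueError("all Dirichlet components must be positive")

    @property
    def alpha_total(self) -> float:
        return float(self.alpha.sum() + self.alpha_slack)

    @property
    def augmented(self) -> np.ndarray:
        """All ``p + 1`` components, slack last."""
        return np.append(self.alpha, self.alpha_slack)


@dataclass
class KernelMatrix:
    """An ``n x n`` kernel with bookkeeping flags and optional metadata."""

    values: np.ndarray
    symmetric: bool = False
    centered: bool = False
    psd_checked: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if self.symmetric and not np.allclose(self.values, self.values.T,
                                              atol=1e-8):
            raise ValueError("kernel flagged symmetric but is not")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str, sample_ids: list[str] | None = None) -> None:
        """Write as dense TSV with a sample-id header plus a JSON sidecar
        recording the construction metadata."""
        ids = sample_ids or [f"s{i + 1}" for i in range(self.n)]
        header = "\t".join(ids)
        np.savetxt(path, self.values, delimiter="\t", header=header, comments="")
        sidecar = {
            "symmetric": self.symmetric,
            "centered": self.centered,
            "psd_checked": self.psd_checked,
            "meta": _jsonable(self.meta),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str) -> "KernelMatrix":
        values = np.loadtxt(path, delimiter="\t", skiprows=1)
        sidecar_path = Path(str(path) + ".json")
        flags = {"symmetric": False, "centered": False, "psd_checked": False,
                 "meta": {}}
        if sidecar_path.exists():
            flags.update(json.loads(sidecar_path.read_text()))
        return cls(values, **flags)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Dirichlet-multinomial estimation
# ---------------------------------------------------------------------------

def _augmented_counts(g: GenotypeMatrix) -> tuple[np.ndarray, int]:
    gm = recode(g, "major")
    p = gm.n_snps
    N = 2 * p
    slack = N - gm.values.sum(axis=1)
    return np.column_stack([gm.values, slack]).astype(float), N


def dm_loglik(alpha: np.ndarray, counts: np.ndarray, N: int) -> float:
    """Dirichlet-multinomial log-likelihood of ``counts`` (rows sum to N)."""
    alpha = np.asarray(alpha, dtype=float)
    n = counts.shape[0]
    A = alpha.sum()
    ll = (gammaln(counts + alpha).sum()
          - n * gammaln(alpha).sum()
          + n * (gammaln(A) - gammaln(N + A))
          + (gammaln(N + 1) - gammaln(counts + 1).sum(axis=1)).sum())
    return float(ll)


def estimate_dm_params(
    g: GenotypeMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
    alpha_total_max: float | None = None,
) -> DirichletParams:
    """Maximum-likelihood Dirichlet-multinomial fit to the augmented counts.

    Uses the standard digamma fixed-point update, initialised by method of
    moments.  Categories with zero total count are pinned to a small floor
    with a warning.  For under-dispersed counts (e.g. independent loci in
    Hardy-Weinberg equilibrium) the likelihood increases monotonically
    toward the multinomial boundary; the iteration then stops at the
    concentration ceiling ``alpha_total_max`` (default ``100 N``) and the
    result is flagged ``boundary=True``.
    """
    counts, N = _augmented_counts(g)
    if counts.shape[0] < 2:
        raise ValueError("at least two individuals are required")
    alpha, boundary = fit_dm_counts(counts, N, tol=tol, max_iter=max_iter,
                                    alpha_total_max=alpha_total_max)
    return DirichletParams(alpha[:-1], float(alpha[-1]), boundary=boundary)


def fit_dm_counts(
    counts: np.ndarray,
    N: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
    alpha_total_max: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Digamma fixed-point DM MLE on raw count rows (each summing to N).

    Returns ``(alpha, boundary)`` where ``boundary`` flags that the
    iteration stopped at the concentration ceiling.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if alpha_total_max is None:
        alpha_total_max = ALPHA_TOTAL_CEILING_FACTOR * N

    totals = counts.sum(axis=0)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} categorie(s) with zero total count; "
            f"pinning those components to {_ALPHA_FLOOR}", stacklevel=2,
        )
    mean_prop = np.maximum(counts.mean(axis=0) / N, _ALPHA_FLOOR / N)
    alpha = 10.0 * mean_prop  # moment-style start at moderate concentration
    boundary = False
    converged = False
    grad_norm = np.inf
    for _ in range(max_iter):
        A = alpha.sum()
        num = (digamma(counts + alpha) - digamma(alpha)).sum(axis=0)
        den = n * (digamma(N + A) - digamma(A))
        new = alpha * num / den
        new = np.maximum(new, _ALPHA_FLOOR)
        if new.sum() > alpha_total_max:
            new *= alpha_total_max / new.sum()
            boundary = True
        step = np.abs(new - alpha).max()
        alpha = new
        if step < tol or (boundary and step < 1e-3):
            converged = True
            break
        grad_norm = step
    if boundary:
        warnings.warn(
            "Dirichlet-multinomial MLE diverged toward the multinomial limit "
            f"(under-dispersed counts); stopped at |alpha| = {alpha.sum():.1f}",
            stacklevel=2,
        )
    elif not converged:
        raise RuntimeError(
            f"DM fixed-point iteration did not converge in {max_iter} "
            f"iterations (last parameter change {grad_norm:.3e})"
        )
    alpha[totals == 0] = _ALPHA_FLOOR
    return alpha, boundary


# ---------------------------------------------------------------------------
# Transition kernel
# ---------------------------------------------------------------------------

def _log_pi(x_from: np.ndarray, dm: DirichletParams, N: int) -> np.ndarray:
    """Log sampling probabilities over the p+1 categories given parent x."""
    aug = np.append(x_from, N - np.sum(x_from)).astype(float)
    return np.log((aug + dm.augmented) / (N + dm.alpha_total))


def wf_transition(x_from, x_to, dm: DirichletParams, N: int | None = None) -> float:
    """One-step WF transition probability from genotype ``x_from`` to the
    target count vector ``x_to``.

    ``x_from`` must be a genotype vector (entries in {0,1,2}); ``x_to`` may
    be any non-negative count vector (the multinomial support), so that the
    probabilities over all augmented compositions of ``N`` sum to one.
    Returns 0 when ``sum(x_to) > N``.
    """
    x_from = np.asarray(x_from)
    x_to = np.asarray(x_to)
    if x_from.shape != x_to.shape:
        raise ValueError("genotype vectors must have equal length")
    if not np.isin(x_from, (0, 1, 2)).all():
        raise ValueError("x_from entries must be in {0, 1, 2}")
    if (x_to < 0).any() or not np.issubdtype(np.asarray(x_to).dtype, np.integer):
        raise ValueError("x_to entries must be non-negative integers")
    p = len(x_from)
    if N is None:
        N = 2 * p
    if len(dm.alpha) != p:
        raise ValueError("Dirichlet parameter length does not match p")
    slack_to = N - int(np.sum(x_to))
    if slack_to < 0:
        return 0.0
    target = np.append(x_to, slack_to).astype(float)
    logpmf = (gammaln(N + 1) - gammaln(target + 1).sum()
              + float(target @ _log_pi(x_from, dm, N)))
    return float(np.exp(logpmf))


def wf_closed_form_eigenvalue(i: int, p: int) -> float:
    """Falling-factorial eigenvalue ratio ``(2p)_[i] / (2p)^i`` of the
    resampling chain, for ``i = 0, ..., 2p - 1``.

    Equals 1 at i = 0 and i = 1, then decreases strictly; all values are
    positive, which is what licenses the Mercer construction.
    """
    N = 2 * p
    if not 0 <= i <= N - 1:
        raise ValueError(f"index i must be in [0, {N - 1}], got {i}")
    out = 1.0
    for k in range(i):
        out *= (N - k) / N
    return out


def build_wf_kernel(g: GenotypeMatrix, dm: DirichletParams | None = None) -> KernelMatrix:
    """Raw (asymmetric) WF transition matrix between individuals.

    ``K[i, j]`` is the transition probability out of individual ``j`` into
    individual ``i``, so column ``j`` holds j's outgoing transition profile.
    Evaluated in log space (log-gamma) to survive large ``p``, then
    exponentiated after subtracting the global maximum (a harmless common
    scale, removed anyway by column scaling).
    """
    counts, N = _augmented_counts(g)
    if dm is None:
        dm = estimate_dm_params(g)
    if len(dm.alpha) != g.n_snps:
        raise ValueError("Dirichlet parameter length does not match SNP count")
    log_pi = np.log((counts + dm.augmented) / (N + dm.alpha_total))  # n x (p+1)
    log_coef = gammaln(N + 1) - gammaln(counts + 1).sum(axis=1)      # per target
    logK = log_coef[:, None] + counts @ log_pi.T
    logK -= logK.max()
    K = np.exp(logK)
    return KernelMatrix(K, symmetric=False, meta={
        "kernel": "wf", "raw": True, "alpha_total": dm.alpha_total,
        "alpha_boundary": dm.boundary, "coding": "major",
    })


def column_l2_normalize(K: KernelMatrix | np.ndarray) -> KernelMatrix:
    """Scale each column to unit l2 norm (right-multiplication by a positive
    diagonal, which preserves spectrum positivity)."""
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    norms = np.linalg.norm(values, axis=0)
    if (norms == 0).any():
        raise ValueError("cannot column-normalize: zero column present")
    meta = dict(K.meta) if isinstance(K, KernelMatrix) else {}
    meta["column_scaled"] = True
    return KernelMatrix(values / norms, symmetric=False, meta=meta)


def symmetrize(K: KernelMatrix | np.ndarray, mode: str = "multiplicative",
               psd_tol: float = 1e-10) -> KernelMatrix:
    """Symmetrize via ``(K + K^T)/2`` (additive) or the Hadamard product
    ``K o K^T`` (multiplicative); both preserve spectrum positivity.  The
    result is PSD-checked (smallest eigenvalue >= -tol * largest)."""
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("symmetrize requires a square matrix")
    if mode == "additive":
        sym = 0.5 * (values + values.T)
    elif mode == "multiplicative":
        sym = values * values.T
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    meta = dict(K.meta) if isinstance(K, KernelMatrix) else {}
    meta["symmetrization"] = mode
    out = KernelMatrix(sym, symmetric=True, meta=meta)
    out.psd_checked = has_positive_spectrum(sym, tol=psd_tol, strict=False)
    return out


def wf_kernel(g: GenotypeMatrix, dm: DirichletParams | None = None,
              symmetrization: str = "multiplicative") -> KernelMatrix:
    """Full WF kernel pipeline: transition matrix, column l2 scaling, then
    symmetrization (multiplicative by default)."""
    if dm is None:
        dm = estimate_dm_params(g)
    K = build_wf_kernel(g, dm)
    return symmetrize(column_l2_normalize(K), mode=symmetrization)


def wf_cross_kernel(g_train: GenotypeMatrix, g_new: GenotypeMatrix,
                    dm: DirichletParams,
                    symmetrization: str = "multiplicative") -> np.ndarray:
    """Kernel evaluations of new samples against the training panel,
    consistent with :func:`wf_kernel` on the training panel.

    Row ``a`` holds the symmetrized, column-scaled similarity of new
    individual ``a`` to each training individual: training columns are
    scaled by the training column norms, and the new individual's outgoing
    transition column is scaled by its l2 norm over transitions into the
    ``n`` training individuals.
    """
    counts_tr, N = _augmented_counts(g_train)
    counts_new, N2 = _augmented_counts(g_new)
    if N2 != N:
        raise ValueError("train and new panels must share the SNP set")
    stacked = np.vstack([counts_tr, counts_new])
    log_pi = np.log((stacked + dm.augmented) / (N + dm.alpha_total))
    log_coef = gammaln(N + 1) - gammaln(stacked + 1).sum(axis=1)
    logK = log_coef[:, None] + stacked @ log_pi.T   # K[i, j] = P(j -> i)
    logK -= logK.max()
    K = np.exp(logK)
    n = counts_tr.shape[0]
    train_norms = np.linalg.norm(K[:n, :n], axis=0)
    into_new = K[n:, :n] / train_norms[None, :]      # P(train j -> new a), scaled
    new_norms = np.linalg.norm(K[:n, n:], axis=0)    # outgoing column of new a
    out_of_new = (K[:n, n:] / new_norms[None, :]).T  # scaled P(new a -> train i)
    if symmetrization == "multiplicative":
        return into_new * out_of_new
    if symmetrization == "additive":
        return 0.5 * (into_new + out_of_new)
    raise ValueError(f"unknown symmetrization mode {symmetrization!r}")


# ---------------------------------------------------------------------------
# Mercer-construction algebra
# ---------------------------------------------------------------------------

def additive_symmetrization(M: np.ndarray) -> np.ndarray:
    """``(M + M^T) / 2``; positive definite whenever M's spectrum is positive."""
    M = np.asarray(M, float)
    return 0.5 * (M + M.T)


def multiplicative_symmetrization(M: np.ndarray) -> np.ndarray:
    """Hadamard product ``M o M^T``; positive definite whenever M's spectrum
    is positive (Schur product argument)."""
    M = np.asarray(M, float)
    return M * M.T


def gram_symmetrization(M: np.ndarray) -> np.ndarray:
    """``M M^T``; symmetric positive definite for nonsingular M."""
    M = np.asarray(M, float)
    return M @ M.T


def has_positive_spectrum(M: np.ndarray, tol: float = 1e-10,
                          strict: bool = True) -> bool:
    """True when all eigenvalues exceed ``-tol * max(|eigenvalue|)`` (and are
    positive beyond tolerance when ``strict``).  Uses the symmetric solver
    for symmetric inputs, the general one otherwise (real parts checked)."""
    M = np.asarray(M, float)
    if np.allclose(M, M.T, atol=1e-12):
        ev = np.linalg.eigvalsh(M)
    else:
        ev = np.linalg.eigvals(M).real
    scale = max(np.abs(ev).max(), 1e-300)
    if strict:
        return bool(ev.min() > -tol * scale)
    return bool(ev.min() >= -tol * scale)


# ---------------------------------------------------------------------------
# Full-chain utilities (small p diagnostics)
# ---------------------------------------------------------------------------

def full_state_space(p: int, lattice: bool = False) -> np.ndarray:
    """All augmented compositions of ``N = 2p`` into ``p + 1`` parts, as the
    leading ``p`` coordinates.  With ``lattice=True`` the per-locus counts
    are restricted to the genotype values {0, 1, 2}."""
    N = 2 * p
    rng = range(3) if lattice else range(N + 1)
    states = [s for s in itertools.product(rng, repeat=p) if sum(s) <= N]
    return np.asarray(states, dtype=int)


def full_transition_matrix(dm: DirichletParams, p: int,
                           lattice: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Dense transition matrix over the full augmented state space (or the
    genotype lattice), ``T[a, b] = P(state_a -> state_b)``.

    On the full composition space each row sums to one; on the genotype
    lattice the rows sum to less than one (the multinomial support extends
    beyond per-locus counts of 2), which perturbs the spectrum relative to
    the closed-form falling-factorial eigenvalues.
    """
    states = full_state_space(p, lattice=lattice)
    N = 2 * p
    aug = np.column_stack([states, N - states.sum(axis=1)]).astype(float)
    log_pi = np.log((aug + dm.augmented) / (N + dm.alpha_total))
    log_coef = gammaln(N + 1) - gammaln(aug + 1).sum(axis=1)
    T = np.exp(log_coef[None, :] + log_pi @ aug.T)
    return T, states


def simulate_wf_chain(dm: DirichletParams, p: int, steps: int,
                      seed: int = 0) -> np.ndarray:
    """Simulate the augmented WF chain; returns the visited states
    (first ``p`` coordinates), starting from the all-heterozygote state."""
    N = 2 * p
    rng = np.random.default_rng(seed)
    x = np.ones(p, dtype=int)
    out = np.empty((steps, p), dtype=int)
    for t in range(steps):
        pi = np.exp(_log_pi(x, dm, N))
        draw = rng.multinomial(N, pi)
        x = draw[:p]
        out[t] = x
    return out
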