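"""Synthetic-genotype and trait simulation for power and type-I studies.

The generator emulates the gene panels the method is aimed at (a
TG/COL6A3-like mix: ~10 common variants with MAF 0.32-0.43 and ~140 rare
variants with MAF 0.005-0.0086 over n = 697 individuals, mostly low
pairwise LD), and the experimental design: a quantitative trait

    Q1 = f(X) + eps,   eps ~ N(0, 1)       (Q0 = eps under the null),

whose top half defines affected status, with the genetic effect ``f``
drawn from a library of scenarios (additive common/rare, with or without
protective variants, main + epistasis, pure epistasis, common-rare
epistasis) and its magnitude controlled by the signal-to-noise ratio
``SNR = var(f(X)) / var(eps)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .assoc import permutation_test
from .genotypes import GenotypeMatrix, TraitVector

__all__ = [
    "Term",
    "ScenarioSpec",
    "PowerResult",
    "simulate_genotypes",
    "make_trait",
    "scale_to_snr",
    "scenario_library",
    "run_power_experiment",
    "TG_LIKE_PANEL",
]

#: (count, MAF range) pairs mimicking the TG gene: 10 common variants and
#: 140 rare ones.
TG_LIKE_PANEL = ((10, (0.32, 0.43)), (140, (0.005, 0.0086)))


@dataclass(frozen=True)
class Term:
    """One multiplicative term of the genetic effect: the product of the
    SNP codes addressed by ``variables`` times ``coef``.

    Each variable is a ``(stratum, rank)`` pair: stratum ``"common"``,
    ``"rare"`` or ``"all"``, rank 1-based in descending-MAF order within
    the stratum (the X_{j} convention).
    """

    variables: tuple[tuple[str, int], ...]
    coef: float = 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A genetic-effect scenario.

    ``snr`` is the target signal-to-noise ratio; when set, coefficients
    are rescaled on the realized genotype panel so that
    ``var(f(X)) = snr`` exactly (the error variance is 1).  Interaction
    terms multiply raw allele-count codes by default;
    ``center_interactions`` switches to mean-centered codes.
    """

    name: str
    terms: tuple[Term, ...] = ()
    snr: float | None = None
    center_interactions: bool = False
    trait_kind: str = "binary"

    @property
    def is_null(self) -> bool:
        return len(self.terms) == 0

    def causal_snps(self, g: GenotypeMatrix) -> np.ndarray:
        cols = set()
        resolver = _StratumResolver(g)
        for term in self.terms:
            for v in term.variables:
                cols.add(resolver(v))
        return np.array(sorted(cols), dtype=int)

    def evaluate(self, g: GenotypeMatrix) -> np.ndarray:
        """The genetic effect f(X) on the given panel (before any SNR
        rescaling)."""
        X = g.values.astype(float)
        resolver = _StratumResolver(g)
        f = np.zeros(g.n_samples)
        for term in self.terms:
            cols = [resolver(v) for v in term.variables]
            part = np.full(g.n_samples, term.coef)
            for j in cols:
                col = X[:, j]
                if self.center_interactions and len(cols) > 1:
                    col = col - col.mean()
                part = part * col
            f += part
        return f


class _StratumResolver:
    """Map (stratum, rank) variables to genotype columns by MAF rank,
    preferring low-LD common variants (greedy pairwise r^2 filter)."""

    def __init__(self, g: GenotypeMatrix, common_thresh: float = 0.10,
                 rare_thresh: float = 0.01, r2_max: float = 0.3):
        self.g = g
        order = np.argsort(-g.maf, kind="stable")
        self.strata = {
            "all": list(order),
            "common": self._low_ld([j for j in order if g.maf[j] > common_thresh],
                                   r2_max),
            "rare": [j for j in order if g.maf[j] < rare_thresh],
        }

    def _low_ld(self, cols: list[int], r2_max: float) -> list[int]:
        X = self.g.values.astype(float)
        kept: list[int] = []
        for j in cols:
            ok = True
            for k in kept:
                r = np.corrcoef(X[:, j], X[:, k])[0, 1]
                if r * r > r2_max:
                    ok = False
                    break
            if ok:
                kept.append(j)
        return kept

    def __call__(self, variable: tuple[str, int]) -> int:
        stratum, rank = variable
        cols = self.strata.get(stratum)
        if cols is None:
            raise ValueError(f"unknown stratum {stratum!r}")
        if rank < 1 or rank > len(cols):
            raise ValueError(
                f"rank {rank} unavailable in stratum {stratum!r} "
                f"({len(cols)} candidates)"
            )
        return cols[rank - 1]


@dataclass
class PowerResult:
    """Empirical power (or type-I error) over replicated datasets."""

    scenario: str
    replicates: int
    rejections: int
    power_hat: float
    alpha: float
    mc_se: float
    pvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "scenario": self.scenario, "replicates": self.replicates,
            "rejections": self.rejections, "power_hat": self.power_hat,
            "alpha": self.alpha, "mc_se": self.mc_se,
        }])


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------

def _latent_corr_for_allele_corr(q1: float, q2: float, rho: float) -> float:
    """Latent-normal correlation reproducing a target correlation between
    threshold allele indicators with frequencies q1, q2."""
    z1, z2 = norm.ppf(q1), norm.ppf(q2)
    denom = np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))

    def gap(r):
        p11 = multivariate_normal.cdf([z1, z2], mean=[0, 0],
                                      cov=[[1, r], [r, 1]])
        return (p11 - q1 * q2) / denom - rho

    lo, hi = -0.999, 0.999
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"allele correlation {rho} infeasible for "
                         f"frequencies {q1:.3g}, {q2:.3g}")
    return brentq(gap, lo, hi, xtol=1e-6)


def simulate_genotypes(
    n: int,
    maf_spec=TG_LIKE_PANEL,
    ld: str = "independent",
    seed: int = 0,
    ld_blocks: list[tuple[list[int], float]] | None = None,
) -> GenotypeMatrix:
    """Simulate a genotype panel under Hardy-Weinberg equilibrium.

    Each SNP's MAF is drawn uniformly in its declared range.  With
    ``ld="independent"`` genotypes are sums of two independent Bernoulli
    allele draws.  With ``ld="block-copula"``, ``ld_blocks`` declares
    ``(column indices, target r^2)`` blocks whose allele draws come from a
    thresholded equicorrelated latent normal (positive allele correlation
    ``sqrt(r^2)``); loci outside blocks stay independent.
    """
    for _, (lo, hi) in maf_spec:
        if not 0.0 < lo <= hi < 0.5:
            raise ValueError(f"MAF range ({lo}, {hi}) must lie inside (0, 0.5)")
    rng = np.random.default_rng(seed)
    maf = np.concatenate([rng.uniform(lo, hi, size=count)
                          for count, (lo, hi) in maf_spec])
    p = len(maf)
    if ld == "independent":
        values = rng.binomial(2, maf, size=(n, p))
    elif ld == "block-copula":
        values = rng.binomial(2, maf, size=(n, p))
        for cols, r2 in (ld_blocks or []):
            cols = list(cols)
            if not 0 < r2 <= 1:
                raise ValueError("target r^2 must be in (0, 1]")
            rho_allele = float(np.sqrt(r2))
            k = len(cols)
            C = np.eye(k)
            for a in range(k):
                for b in range(a + 1, k):
                    r = _latent_corr_for_allele_corr(maf[cols[a]], maf[cols[b]],
                                                     rho_allele)
                    C[a, b] = C[b, a] = r
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"infeasible LD targets for block {cols}: latent "
                    "correlation matrix is not positive definite"
                ) from None
            thr = norm.ppf(maf[cols])
            geno = np.zeros((n, k), dtype=int)
            for _ in range(2):  # two allele draws per individual
                Z = rng.standard_normal((n, k)) @ L.T
                geno += (Z < thr[None, :]).astype(int)
            values[:, cols] = geno
    else:
        raise ValueError(f"unknown ld mode {ld!r}")
    return GenotypeMatrix(values, coding="minor")


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def scale_to_snr(g: GenotypeMatrix, spec: ScenarioSpec,
                 target_snr: float) -> ScenarioSpec:
    """Rescale the scenario's coefficients so the realized sample variance
    of f(X) on ``g`` equals ``target_snr`` exactly (error variance 1)."""
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    base = dataclasses.replace(spec, snr=None)
    f = base.evaluate(g)
    v = float(f.var(ddof=0))
    if v == 0.0:
        raise ValueError("genetic effect has zero variance on this panel")
    c = float(np.sqrt(target_snr / v))
    terms = tuple(dataclasses.replace(t, coef=t.coef * c) for t in spec.terms)
    return dataclasses.replace(spec, terms=terms, snr=None)


def make_trait(g: GenotypeMatrix, spec: ScenarioSpec,
               seed: int = 0) -> tuple[TraitVector, TraitVector]:
    """Quantitative and dichotomized traits under the scenario.

    The quantitative trait is ``f(X) + eps`` with standard normal noise
    (pure noise for the null scenario).  The binary trait declares the top
    ``ceil(n/2)`` of the realized quantitative values affected (stable
    ties), so exactly half the sample (rounded up) is affected.
    """
    rng = np.random.default_rng(seed)
    resolved = scale_to_snr(g, spec, spec.snr) if spec.snr is not None else spec
    f = resolved.evaluate(g)
    q = f + rng.standard_normal(g.n_samples)
    if np.ptp(q) == 0.0:
        raise ValueError("degenerate trait: constant values cannot be split")
    n = g.n_samples
    order = np.argsort(-q, kind="stable")
    affected = np.zeros(n)
    affected[order[: (n + 1) // 2]] = 1.0
    return TraitVector(q, "quantitative"), TraitVector(affected, "binary")


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

def _mains(stratum: str, coefs: list[float]) -> tuple[Term, ...]:
    return tuple(Term(((stratum, j + 1),), c) for j, c in enumerate(coefs))


def scenario_library() -> list[ScenarioSpec]:
    """The null plus nine genetic-effect scenarios.

    1-2: additive on the 10 common variants (all deleterious; two
    protective).  3-4: additive on 10 rare variants (likewise).  5: main
    effects plus an interaction between two common variants.  6-7: pure
    epistasis among three low-LD common variants (pairwise products;
    three-way product).  8-9: common-rare interactions (all positive; one
    protective).  Effect magnitudes are set through the target SNR, 0.1
    for main-effect models and 0.12 for interaction models.
    """
    ten = [1.0] * 10
    ten_prot = [-1.0, -1.0] + [1.0] * 8
    cc = ("common", 1), ("common", 2), ("common", 3)
    return [
        ScenarioSpec("null"),
        ScenarioSpec("sim1_common_deleterious", _mains("common", ten), snr=0.1),
        ScenarioSpec("sim2_common_protective", _mains("common", ten_prot), snr=0.1),
        ScenarioSpec("sim3_rare_deleterious", _mains("rare", ten), snr=0.1),
        ScenarioSpec("sim4_rare_protective", _mains("rare", ten_prot), snr=0.1),
        ScenarioSpec("sim5_main_plus_epistasis",
                     _mains("common", [1.0, 1.0]) + (Term((cc[0], cc[1]), 1.0),),
                     snr=0.12),
        ScenarioSpec("sim6_pure_epistasis_pairwise",
                     (Term((cc[0], cc[1]), 1.0), Term((cc[0], cc[2]), 1.0),
                      Term((cc[1], cc[2]), 1.0)), snr=0.12),
        ScenarioSpec("sim7_pure_epistasis_threeway",
                     (Term(cc, 1.0),), snr=0.12),
        ScenarioSpec("sim8_common_rare_epistasis",
                     (Term((("common", 1), ("rare", 1)), 1.0),
                      Term((("common", 2), ("rare", 2)), 1.0)), snr=0.12),
        ScenarioSpec("sim9_common_rare_protective",
                     (Term((("common", 1), ("rare", 1)), 1.0),
                      Term((("common", 2), ("rare", 2)), -1.0)), snr=0.12),
    ]


# ---------------------------------------------------------------------------
# Replicate driver
# ---------------------------------------------------------------------------

def run_power_experiment(
    spec: ScenarioSpec,
    method: dict | None = None,
    R: int = 200,
    B: int = 500,
    alpha: float = 0.05,
    n: int = 400,
    seed: int = 0,
    maf_spec=TG_LIKE_PANEL,
    panel: str = "fixed",
    ld: str = "independent",
    ld_blocks=None,
) -> PowerResult:
    """Estimate empirical power (or type-I error for the null scenario).

    By default one genotype panel is simulated and reused across all ``R``
    replicates with fresh traits (mirroring a design conditioned on real
    genotypes); ``panel="fresh"`` draws new genotypes each replicate.  Each
    replicate runs the full permutation test with ``B`` permutations;
    power is the fraction of empirical p-values below ``alpha``.
    Deterministic given ``seed``.
    """
    if R < 1 or B < 1:
        raise ValueError("R and B must be at least 1")
    method = method or {}
    kernel_spec = method.get("kernel", "wf")
    dr_spec = method.get("dr", {"method": "ksir", "d": 1})
    trait_kind = method.get("trait", spec.trait_kind)

    rng = np.random.default_rng(seed)
    g = simulate_genotypes(n, maf_spec, ld=ld, seed=int(rng.integers(2 ** 31)),
                           ld_blocks=ld_blocks)
    if panel == "fixed" and (dr_spec or {}).get("method", "ksir") == "ksir":
        # the kernel is label-free: with a fixed panel it can be built once
        from .assoc import build_kernel
        kernel_spec = {"name": "precomputed",
                       "kernel": build_kernel(g, kernel_spec)}
    pvals = np.empty(R)
    for r in range(R):
        if panel == "fresh":
            g = simulate_genotypes(n, maf_spec, ld=ld,
                                   seed=int(rng.integers(2 ** 31)),
                                   ld_blocks=ld_blocks)
        quant, binary = make_trait(g, spec, seed=int(rng.integers(2 ** 31)))
        y = binary if trait_kind == "binary" else quant
        res = permutation_test(g, y, kernel_spec=kernel_spec, dr_spec=dr_spec,
                               B=B, seed=int(rng.integers(2 ** 31)))
        pvals[r] = res.p_empirical
    rej = int((pvals < alpha).sum())
    phat = rej / R
    return PowerResult(spec.name, R, rej, phat, alpha,
                       float(np.sqrt(phat * (1 - phat) / R)), pvals)
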