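"""Baseline genotype kernels (IBS, weighted IBS, Gaussian, linear) and
kernel centering.

The IBS family counts shared alleles per locus: two diploid counts ``a, b``
share ``2 - |a - b|`` alleles.  Equivalently, with threshold indicators
``I(x >= 1)`` and ``I(x >= 2)``, the per-locus match is a dot product of
binary features, which is how the kernels are computed here (matrix
products instead of an ``O(n^2 p)`` loop).
"""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix, recode
from .wf_kernel import KernelMatrix

__all__ = [
    "ibs_kernel",
    "weighted_ibs_kernel",
    "gaussian_kernel",
    "linear_kernel",
    "center_kernel",
]


def _minor_values(g: GenotypeMatrix) -> np.ndarray:
    return recode(g, "minor").values.astype(float)


def _ibs_match_gram(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sum over loci of w_s * (2 - |x_is - x_js|) via threshold features."""
    out = np.zeros((x.shape[0], x.shape[0]))
    for k in (1, 2):
        b = (x >= k).astype(float)
        bw = b * w
        out += bw @ b.T + (w - bw) @ (1.0 - b).T
    return out


def ibs_kernel(g: GenotypeMatrix) -> KernelMatrix:
    """Identity-by-state kernel ``K_ij = sum_s (2 - |x_is - x_js|) / (2p)``
    on minor-allele counts; symmetric with unit diagonal, values in [0, 1]."""
    x = _minor_values(g)
    p = x.shape[1]
    K = _ibs_match_gram(x, np.ones(p)) / (2.0 * p)
    return KernelMatrix(K, symmetric=True, meta={"kernel": "ibs"})


def weighted_ibs_kernel(g: GenotypeMatrix,
                        weights: np.ndarray | str = "maf-default") -> KernelMatrix:
    """IBS kernel with positive per-variant weights,
    ``K_ij = sum_s w_s (2 - |x_is - x_js|) / (2 sum_s w_s)``.

    The default up-weights rare variants with ``w_s = 1 / sqrt(f_s)``, the
    MAF floored at ``1 / (2n)`` so monomorphic columns stay finite.
    """
    x = _minor_values(g)
    n, p = x.shape
    if isinstance(weights, str):
        if weights != "maf-default":
            raise ValueError(f"unknown weight rule {weights!r}")
        f = np.maximum(g.maf, 1.0 / (2.0 * n))
        w = 1.0 / np.sqrt(f)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if len(w) != p:
            raise ValueError("weights length does not match SNP count")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    K = _ibs_match_gram(x, w) / (2.0 * w.sum())
    return KernelMatrix(K, symmetric=True, meta={"kernel": "weighted_ibs"})


def gaussian_kernel(g: GenotypeMatrix,
                    bandwidth: float | str = "median-heuristic") -> KernelMatrix:
    """Gaussian RBF kernel ``exp(-||x_i - x_j||^2 / (2 sigma^2))`` on the
    genotype codes; ``sigma`` defaults to the median pairwise distance."""
    x = _minor_values(g)
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    if isinstance(bandwidth, str):
        if bandwidth != "median-heuristic":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        off = d2[~np.eye(len(d2), dtype=bool)]
        sigma = float(np.sqrt(np.median(off)))
        if sigma == 0.0:
            raise ValueError(
                "median pairwise distance is zero (identical samples); "
                "pass an explicit bandwidth"
            )
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValueError("bandwidth must be positive")
    K = np.exp(-d2 / (2.0 * sigma ** 2))
    return KernelMatrix(K, symmetric=True,
                        meta={"kernel": "gaussian", "bandwidth": sigma})


def linear_kernel(g: GenotypeMatrix) -> KernelMatrix:
    """Linear kernel ``G G^T`` on column-centered genotype codes (the
    kernelization of linear SIR)."""
    x = _minor_values(g)
    xc = x - x.mean(axis=0)
    return KernelMatrix(xc @ xc.T, symmetric=True, meta={"kernel": "linear"})


def center_kernel(K: KernelMatrix | np.ndarray) -> KernelMatrix:
    """Double centering ``H K H`` with ``H = I - 11^T/n``: row and column
    sums become zero; idempotent."""
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("center_kernel requires a symmetric kernel")
    col_mean = values.mean(axis=0)
    grand = values.mean()
    centered = values - col_mean[None, :] - col_mean[:, None] + grand
    meta = dict(K.meta) if isinstance(K, KernelMatrix) else {}
    meta["centering"] = {"col_mean": col_mean, "grand_mean": grand}
    return KernelMatrix(centered, symmetric=True, centered=True, meta=meta)
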