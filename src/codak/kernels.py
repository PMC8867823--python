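"""Similarity kernels for compositions and predictors.

Two routes turn a distance matrix into a kernel: the double-centering
identity K = -1/2 H D^2 H (exact for Euclidean-embeddable distances such as
the Aitchison distance) and the Gaussian form k_ij = exp(-d_ij / gamma) with
the bandwidth gamma conventionally set to the median pairwise distance.
Predictors get a linear kernel (continuous) or a Hamming-distance kernel
(binary).  The stratified kernel zeroes similarity between samples in
different covariate strata, the categorical-covariate adjustment route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "KernelMatrix",
    "centering_matrix",
    "distance_induced_kernel",
    "gaussian_kernel",
    "predictor_kernel",
    "stratified_kernel",
    "psd_clip",
]

#: relative eigenvalue threshold below which negativity is clipped, not round-off
_CLIP_REL_TOL = 1e-10


@dataclass
class KernelMatrix:
    """Symmetric n x n similarity matrix with provenance tags."""

    values: np.ndarray
    kernel: str
    psd_clipped: bool = False
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("kernel matrix must be square")
        if np.any(np.abs(self.values - self.values.T) > 1e-10):
            raise ValueError("kernel matrix must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def centering_matrix(n: int) -> np.ndarray:
    """H = I_n - 1 1^T / n."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def distance_induced_kernel(D: DistanceMatrix) -> KernelMatrix:
    """K = -1/2 H D^2 H (D^2 elementwise); row sums are zero by construction."""
    d2 = D.values**2
    # H A H = A - row means - col means + grand mean
    rm = d2.mean(axis=1, keepdims=True)
    cm = d2.mean(axis=0, keepdims=True)
    K = -0.5 * (d2 - rm - cm + d2.mean())
    return KernelMatrix(K, f"distance_induced[{D.metric}]", sample_ids=D.sample_ids)


def resolve_bandwidth(D: DistanceMatrix, gamma: float | str = "median") -> float:
    """Resolve a Gaussian bandwidth; "median" = median off-diagonal distance."""
    if isinstance(gamma, str):
        if gamma != "median":
            raise ValueError("gamma must be a positive number or 'median'")
        med = float(np.median(D.offdiagonal()))
        if med <= 0:
            raise ValueError("all pairwise distances are 0; median bandwidth is degenerate")
        return med
    gamma = float(gamma)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return gamma


def gaussian_kernel(D: DistanceMatrix, gamma: float | str = "median") -> KernelMatrix:
    """k_ij = exp(-d_ij / gamma); unit diagonal, entries in (0, 1]."""
    g = resolve_bandwidth(D, gamma)
    return KernelMatrix(np.exp(-D.values / g), f"gaussian[{D.metric}]", sample_ids=D.sample_ids)


def recode_binary(x: np.ndarray) -> np.ndarray:
    """Map an arbitrary two-level vector to {0, 1} (levels in sorted order)."""
    x = np.asarray(x)
    levels = np.unique(x)
    if len(levels) > 2:
        raise ValueError(
            f"binary predictor has {len(levels)} levels; one-hot encode or use "
            "stratification for multi-level factors"
        )
    return (x == levels[-1]).astype(float) if len(levels) == 2 else np.zeros(len(x))


def predictor_kernel(
    x: np.ndarray, kind: str = "auto", scale: bool = True
) -> KernelMatrix:
    """Kernel on the predictor side.

    binary     l_ij = exp(-|x_i - x_j|) with x recoded to {0, 1}
               (a Gaussian kernel on the Hamming distance, hence PSD)
    continuous l_ij = x_i x_j after mean-centering (and unit-scaling by
               default: the statistic is scale-invariant after normalization
               but centering/scaling keeps the permutation test numerically
               stable)
    """
    x = np.asarray(x)
    if kind == "auto":
        kind = "binary" if len(np.unique(x)) <= 2 else "continuous"
    if kind == "binary":
        xb = recode_binary(x)
        return KernelMatrix(np.exp(-np.abs(xb[:, None] - xb[None, :])), "hamming")
    if kind != "continuous":
        raise ValueError("kind must be 'binary', 'continuous' or 'auto'")
    xc = x.astype(float) - float(np.mean(x))
    if scale:
        sd = float(np.std(xc))
        if sd > 0:
            xc = xc / sd
    return KernelMatrix(np.outer(xc, xc), "linear")


def stratified_kernel(K: KernelMatrix, strata: np.ndarray) -> KernelMatrix:
    """Zero out similarity between samples in different strata.

    Intended for kernels of the exponential (Gaussian) form, for which the
    masked matrix stays strictly positive definite.  Singleton strata
    contribute no between-sample information and trigger a warning.
    """
    strata = np.asarray(strata)
    if len(strata) != K.n_samples:
        raise ValueError("one stratum label per sample required")
    labels, counts = np.unique(strata, return_counts=True)
    if np.any(counts == 1):
        singles = labels[counts == 1].tolist()
        warnings.warn(
            f"strata {singles} contain a single sample and contribute no "
            "between-sample information",
            UserWarning,
            stacklevel=2,
        )
    mask = strata[:, None] == strata[None, :]
    return KernelMatrix(
        np.where(mask, K.values, 0.0), f"stratified[{K.kernel}]", K.psd_clipped, K.sample_ids
    )


def psd_clip(K: KernelMatrix) -> KernelMatrix:
    """Project onto the PSD cone by zeroing negative eigenvalues.

    Eigenvalues below ``-1e-10 * max eigenvalue`` are clipped; smaller
    negativity is round-off and left alone.  This is the nearest PSD matrix
    in Frobenius norm.
    """
    vals, vecs = np.linalg.eigh(K.values)
    lo = -_CLIP_REL_TOL * max(vals.max(), 0.0)
    if vals.min() >= lo:
        return KernelMatrix(K.values, K.kernel, psd_clipped=False, sample_ids=K.sample_ids)
    clipped = np.clip(vals, 0.0, None)
    out = (vecs * clipped) @ vecs.T
    return KernelMatrix(out, K.kernel, psd_clipped=True, sample_ids=K.sample_ids)
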