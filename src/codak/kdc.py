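"""The kernel distance covariance (KDC) statistic and permutation test.

Given kernel matrices K (compositions) and L (predictor) on n samples, the
statistic is

    KDC_n = trace(K H L H) / n^2,      H = I - 1 1^T / n,

a sample estimate of the Hilbert-Schmidt independence criterion.  The
normalized version

    dcor = KDC(K, L) / sqrt(KDC(K, K) * KDC(L, L))

lies in [0, 1] for PSD kernels and serves as an effect size; with
double-centering kernels of Euclidean distances on both sides it equals the
squared distance correlation of Szekely et al.  Significance comes from a
permutation test that jointly permutes the rows and columns of L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np

from .compositions import CompositionMatrix
from .distances import (
    aitchison_distance,
    bray_curtis_distance,
    euclidean_distance,
)
from .kernels import (
    KernelMatrix,
    distance_induced_kernel,
    gaussian_kernel,
    predictor_kernel,
    psd_clip,
)

__all__ = [
    "TestResult",
    "kdc_statistic",
    "dcor",
    "permutation_test",
    "codak_test",
    "build_composition_kernel",
    "COMPOSITION_KERNELS",
]

COMPOSITION_KERNELS = ("ad-gaussian", "ad-linear", "bc", "euclidean")

#: above this, permutations are sampled; at or below, enumerated exactly
_EXACT_ENUMERATION_LIMIT = 10_000


@dataclass
class TestResult:
    """Outcome of a KDC association test."""

    statistic: float
    dcor: float
    p_value: float
    n_permutations: int
    seed: int | None
    kernel_tags: tuple[str, str]
    adjustment: str = "none"
    exact: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "dcor": self.dcor,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "composition_kernel": self.kernel_tags[0],
            "predictor_kernel": self.kernel_tags[1],
            "adjustment": self.adjustment,
            "exact_enumeration": self.exact,
            **self.extras,
        }


def _as_array(K: KernelMatrix | np.ndarray) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def _double_center(A: np.ndarray) -> np.ndarray:
    """H A H without forming H."""
    rm = A.mean(axis=1, keepdims=True)
    cm = A.mean(axis=0, keepdims=True)
    return A - rm - cm + A.mean()


def kdc_statistic(K: KernelMatrix | np.ndarray, L: KernelMatrix | np.ndarray) -> float:
    """trace(K H L H) / n^2."""
    Ka, La = _as_array(K), _as_array(L)
    if Ka.shape != La.shape:
        raise ValueError(f"kernel dimensions differ: {Ka.shape} vs {La.shape}")
    n = Ka.shape[0]
    return float(np.sum(_double_center(Ka) * La)) / n**2


def dcor(K: KernelMatrix | np.ndarray, L: KernelMatrix | np.ndarray) -> float:
    """Normalized KDC effect size in [0, 1] for PSD kernels."""
    Ka, La = _as_array(K), _as_array(L)
    kk = kdc_statistic(Ka, Ka)
    ll = kdc_statistic(La, La)
    if kk <= 0:
        raise ValueError("degenerate composition kernel: KDC(K, K) is not positive")
    if ll <= 0:
        raise ValueError("degenerate predictor kernel: KDC(L, L) is not positive")
    return kdc_statistic(Ka, La) / math.sqrt(kk * ll)


def draw_permutations(
    rng: np.random.Generator, n: int, B: int, strata: np.ndarray | None = None
) -> np.ndarray:
    """B uniform permutations of 0..n-1, restricted within strata if given."""
    if strata is None:
        return np.argsort(rng.random((B, n)), axis=1)
    perms = np.tile(np.arange(n), (B, 1))
    for label in np.unique(strata):
        idx = np.flatnonzero(np.asarray(strata) == label)
        if len(idx) < 2:
            continue
        sub = np.argsort(rng.random((B, len(idx))), axis=1)
        perms[:, idx] = idx[sub]
    return perms


def permuted_statistics(
    K: KernelMatrix | np.ndarray,
    L: KernelMatrix | np.ndarray,
    perms: np.ndarray,
    block: int = 512,
) -> np.ndarray:
    """KDC statistics for L jointly row/column permuted by each row of perms."""
    A = _double_center(_as_array(K))
    La = _as_array(L)
    n = A.shape[0]
    out = np.empty(len(perms))
    for start in range(0, len(perms), block):
        p = perms[start : start + block]
        Lp = La[p[:, :, None], p[:, None, :]]
        out[start : start + block] = np.einsum("ij,bij->b", A, Lp)
    return out / n**2


def permutation_test(
    K: KernelMatrix | np.ndarray,
    L: KernelMatrix | np.ndarray,
    B: int = 10_000,
    seed: int | None = 0,
    strata: np.ndarray | None = None,
    adjustment: str = "none",
) -> TestResult:
    """Permutation test of independence based on the KDC statistic.

    The indexing of L is permuted B times (within strata when supplied) and
    the p-value is (1 + #{permuted >= observed}) / (B + 1); ties count toward
    the numerator, which keeps the test valid.  When n! <= 10,000 and there
    are no strata the permutation group is enumerated exactly instead.
    """
    Ka, La = _as_array(K), _as_array(L)
    n = Ka.shape[0]
    if n < 3:
        raise ValueError("permutation test requires at least 3 samples")
    if B < 1:
        raise ValueError("B must be at least 1")
    obs = kdc_statistic(Ka, La)

    exact = strata is None and math.factorial(n) <= _EXACT_ENUMERATION_LIMIT
    if exact:
        perms = np.array(list(_iter_permutations(range(n))))
        stats = permuted_statistics(Ka, La, perms)
        p = float(np.mean(stats >= obs - 1e-12))  # identity permutation included
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = draw_permutations(rng, n, B, strata)
        stats = permuted_statistics(Ka, La, perms)
        p = (1.0 + int(np.sum(stats >= obs - 1e-12))) / (B + 1.0)
        n_perm = B

    tags = (
        K.kernel if isinstance(K, KernelMatrix) else "raw",
        L.kernel if isinstance(L, KernelMatrix) else "raw",
    )
    try:
        effect = dcor(Ka, La)
    except ValueError:
        effect = float("nan")  # degenerate (constant) kernel: p is still valid
    return TestResult(
        statistic=obs,
        dcor=effect,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        kernel_tags=tags,
        adjustment=adjustment,
        exact=exact,
    )


def build_composition_kernel(
    P: CompositionMatrix, kernel: str = "ad-gaussian", gamma: float | str = "median"
) -> KernelMatrix:
    """Build the composition-side kernel K.

    ad-gaussian  exp(-AD/gamma), gamma = median pairwise Aitchison distance
    ad-linear    -1/2 H AD^2 H (double-centering kernel on AD)
    bc           double-centering kernel on Bray-Curtis, PSD-clipped
    euclidean    exp(-ED/gamma) on plain Euclidean distance (comparison)
    """
    if kernel == "ad-gaussian":
        return gaussian_kernel(aitchison_distance(P), gamma)
    if kernel == "ad-linear":
        return distance_induced_kernel(aitchison_distance(P))
    if kernel == "bc":
        return psd_clip(distance_induced_kernel(bray_curtis_distance(P)))
    if kernel == "euclidean":
        return gaussian_kernel(euclidean_distance(P), gamma)
    raise ValueError(f"unknown composition kernel {kernel!r}; choose from {COMPOSITION_KERNELS}")


def codak_test(
    P: CompositionMatrix,
    x: np.ndarray,
    kernel: str = "ad-gaussian",
    predictor_kind: str = "auto",
    gamma: float | str = "median",
    B: int = 10_000,
    seed: int | None = 0,
) -> TestResult:
    """End-to-end CODAK association test between compositions and a predictor."""
    x = np.asarray(x)
    if len(x) != P.n_samples:
        raise ValueError("predictor length must match the number of samples")
    K = build_composition_kernel(P, kernel, gamma)
    L = predictor_kernel(x, predictor_kind)
    return permutation_test(K, L, B=B, seed=seed)
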