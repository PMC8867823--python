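"""Pairwise distances on the simplex.

The Aitchison distance — the Euclidean distance between clr-transformed
compositions — is the default geometry for cell-type abundance profiles: it
is scale-, permutation- and perturbation-invariant and subcompositionally
dominant, none of which hold for the plain Euclidean distance.  Bray-Curtis
and Euclidean distances are provided for comparison and for zero-containing
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .compositions import CompositionMatrix, clr

__all__ = [
    "DistanceMatrix",
    "aitchison_distance",
    "weighted_aitchison_distance",
    "bray_curtis_distance",
    "euclidean_distance",
]


@dataclass
class DistanceMatrix:
    """Symmetric n x n pairwise distance matrix with a metric tag."""

    values: np.ndarray
    metric: str
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("distance matrix must be square")
        if np.any(np.abs(self.values - self.values.T) > 1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0) or np.any(self.values < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        """Strictly-upper-triangle entries (the n(n-1)/2 pairwise distances)."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]


def aitchison_distance(P: CompositionMatrix) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance between clr rows."""
    y = clr(P).values
    return DistanceMatrix(squareform(pdist(y)), "aitchison", list(P.sample_ids))


def weighted_aitchison_distance(P: CompositionMatrix, weights: np.ndarray) -> DistanceMatrix:
    """Weighted Aitchison distance.

    d_w(i, j)^2 = sum_r w_r { ln(P_ir / g_w(P_i)) - ln(P_jr / g_w(P_j)) }^2
    with g_w the weighted geometric mean, log g_w(P_i) = (1/s_w) sum_k w_k ln P_ik
    and s_w = sum_k w_k.  With all weights equal to one this reduces exactly to
    the unweighted Aitchison distance.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (P.n_components,):
        raise ValueError("need one weight per component")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    logp = np.log(P.values)
    log_gw = (logp * w).sum(axis=1, keepdims=True) / w.sum()
    y = np.sqrt(w) * (logp - log_gw)
    return DistanceMatrix(squareform(pdist(y)), "weighted_aitchison", list(P.sample_ids))


def bray_curtis_distance(M: CompositionMatrix | np.ndarray) -> DistanceMatrix:
    """Bray-Curtis dissimilarity; tolerates zeros (not a proper metric)."""
    if isinstance(M, CompositionMatrix):
        values, ids = M.values, list(M.sample_ids)
    else:
        values, ids = np.asarray(M, dtype=float), None
        if np.any(values < 0) or np.any(values.sum(axis=1) <= 0):
            raise ValueError("Bray-Curtis requires nonnegative rows with positive sums")
    return DistanceMatrix(squareform(pdist(values, metric="braycurtis")), "bray_curtis", ids)


def euclidean_distance(M: CompositionMatrix | np.ndarray) -> DistanceMatrix:
    """Plain L2 pairwise distance (comparison baseline; ignores the simplex)."""
    if isinstance(M, CompositionMatrix):
        values, ids = M.values, list(M.sample_ids)
    else:
        values, ids = np.asarray(M, dtype=float), None
    return DistanceMatrix(squareform(pdist(values)), "euclidean", ids)
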