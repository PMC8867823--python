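"""Compositional abundance data: closure, log-ratio transforms, zero handling.

Cell-type abundance profiles are compositional: each sample is a vector of
q nonnegative parts carrying only relative information, constrained to the
unit simplex S^q.  All downstream distance and kernel machinery in this
package operates on log-ratio coordinates, which require strictly positive
parts; zeros in raw counts are handled by a pseudocount applied on the
count scale before closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionMatrix",
    "CountMatrix",
    "LogRatioMatrix",
    "closure",
    "counts_to_composition",
    "alr",
    "alr_inverse",
    "clr",
    "clr_inverse",
]

_ROW_SUM_TOL = 1e-10
#: tolerance for accepting user-supplied proportion tables before re-closure;
#: generous enough for files rounded to 3 decimals (rows summing to 0.999)
INPUT_ROW_SUM_TOL = 1e-2


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def closure(v: np.ndarray) -> np.ndarray:
    """Rescale nonnegative vector(s) to unit sum (the closure operator C).

    Accepts a single vector or a matrix (closure applied row-wise).

    Raises
    ------
    ValueError
        If any entry is negative or any row sums to zero.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("closure requires nonnegative entries")
    s = v.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("closure of an all-zero vector is undefined")
    return v / s


@dataclass
class CountMatrix:
    """Raw per-sample cell counts (n samples x q cell types)."""

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    component_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if np.any(self.values < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded):
                raise ValueError("counts must be integers")
            self.values = rounded
        self.values = self.values.astype(np.int64)
        if np.any(self.values.sum(axis=1) <= 0):
            raise ValueError("every sample must contain at least one cell")
        n, q = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = _default_ids("sample", n)
        if self.component_ids is None:
            self.component_ids = _default_ids("component", q)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.component_ids)


@dataclass
class CompositionMatrix:
    """Strictly positive compositions on the simplex, one sample per row.

    Rows sum to one; entries are strictly positive so that log-ratio
    transforms are defined.  Proportion tables whose rows sum to one only
    approximately (within ``1e-6``, e.g. rounded input files) are re-closed
    on construction.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    component_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("composition matrix must be 2-dimensional")
        n, q = self.values.shape
        if q < 2 or n < 2:
            raise ValueError("need at least 2 samples and 2 components")
        if np.any(self.values <= 0):
            bad = np.argwhere(self.values <= 0)
            raise ValueError(
                "compositions must be strictly positive; zero/negative entries at "
                f"(sample, component) indices {bad[:5].tolist()}. For count data with "
                "zeros use counts_to_composition with a positive pseudocount, or the "
                "Bray-Curtis kernel which tolerates zeros."
            )
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > INPUT_ROW_SUM_TOL):
            bad = np.where(np.abs(sums - 1.0) > INPUT_ROW_SUM_TOL)[0]
            raise ValueError(f"rows {bad[:5].tolist()} do not sum to 1 (tolerance {INPUT_ROW_SUM_TOL})")
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            self.values = self.values / sums[:, None]
        if self.sample_ids is None:
            self.sample_ids = _default_ids("sample", n)
        if self.component_ids is None:
            self.component_ids = _default_ids("component", q)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.component_ids)


@dataclass
class LogRatioMatrix:
    """Log-ratio coordinates of a composition matrix.

    ``transform`` is ``"alr"`` (q-1 columns, one reference part) or ``"clr"``
    (q columns, rows sum to zero).  ``reference_index`` records the alr
    reference component's position in the original column order so that the
    inverse transform can restore it.
    """

    values: np.ndarray
    transform: str
    reference_index: int | None = None
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    component_ids: list[str] = field(default=None)  # type: ignore[assignment]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.transform not in ("alr", "clr"):
            raise ValueError("transform must be 'alr' or 'clr'")
        if self.transform == "clr":
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums) > 1e-8):
                raise ValueError("clr rows must sum to 0")
        if self.sample_ids is None:
            self.sample_ids = _default_ids("sample", self.values.shape[0])
        if self.component_ids is None:
            self.component_ids = _default_ids("component", self.values.shape[1])


def counts_to_composition(counts: CountMatrix, pseudocount: float = 1.0) -> CompositionMatrix:
    """Convert raw counts to compositions, resolving zeros with a pseudocount.

    When any row contains a zero, ``pseudocount`` is added to *every* cell of
    the matrix (not only the zero cells) before row-wise closure.  A global
    additive shift preserves the within-row ordering of counts, avoids rank
    inversions between zero and near-zero cells, and keeps samples comparable.
    A matrix with no zeros is closed as-is.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    values = counts.values.astype(float)
    if np.any(values == 0):
        if pseudocount == 0:
            zr, zc = np.nonzero(values == 0)
            offenders = [
                f"(sample={counts.sample_ids[i]}, component={counts.component_ids[j]})"
                for i, j in zip(zr[:5], zc[:5])
            ]
            raise ValueError(
                "zero counts present but pseudocount is 0; offending cells include "
                + ", ".join(offenders)
            )
        values = values + pseudocount
    return CompositionMatrix(closure(values), list(counts.sample_ids), list(counts.component_ids))


def alr(P: CompositionMatrix, ref: int = -1) -> LogRatioMatrix:
    """Additive log-ratio transform: ln(P_k / P_ref) for non-reference parts.

    The reference defaults to the last component.  Output columns are the
    non-reference components in their original order.
    """
    q = P.n_components
    ref = int(ref) % q
    logp = np.log(P.values)
    keep = [k for k in range(q) if k != ref]
    values = logp[:, keep] - logp[:, [ref]]
    return LogRatioMatrix(
        values,
        "alr",
        reference_index=ref,
        sample_ids=list(P.sample_ids),
        component_ids=[P.component_ids[k] for k in keep],
        reference_id=P.component_ids[ref],
    )


def alr_inverse(Y: LogRatioMatrix) -> CompositionMatrix:
    """Invert the alr transform: closure of (exp(Y_1) ... exp(Y_{q-1}), 1).

    The exponentials are computed after subtracting the per-row maximum, so
    arbitrarily large coordinates do not overflow; closure removes the shift.
    The reference component is restored at its original column position.
    """
    if Y.transform != "alr":
        raise ValueError("alr_inverse requires an alr-transformed matrix")
    n, m = Y.values.shape
    ext = np.concatenate([Y.values, np.zeros((n, 1))], axis=1)
    # subtract the row max so exp cannot overflow; floor so it cannot
    # underflow to an exact zero either
    ext = np.clip(ext - ext.max(axis=1, keepdims=True), -700.0, 0.0)
    comp = closure(np.exp(ext))
    ref = Y.reference_index if Y.reference_index is not None else m
    order = list(range(m))
    order.insert(ref, m)  # order[i] = source column for destination i
    comp = comp[:, order]
    ids = list(Y.component_ids)
    ids.insert(ref, Y.reference_id if Y.reference_id is not None else "reference")
    return CompositionMatrix(comp, list(Y.sample_ids), ids)


def clr(P: CompositionMatrix) -> LogRatioMatrix:
    """Centered log-ratio transform: ln(P_k / g(P)), g the row geometric mean."""
    logp = np.log(P.values)
    values = logp - logp.mean(axis=1, keepdims=True)
    return LogRatioMatrix(
        values, "clr", sample_ids=list(P.sample_ids), component_ids=list(P.component_ids)
    )


def clr_inverse(Y: LogRatioMatrix) -> CompositionMatrix:
    """Invert the clr transform: closure of exp(Y), overflow-guarded."""
    if Y.transform != "clr":
        raise ValueError("clr_inverse requires a clr-transformed matrix")
    shifted = np.clip(Y.values - Y.values.max(axis=1, keepdims=True), -700.0, 0.0)
    return CompositionMatrix(closure(np.exp(shifted)), list(Y.sample_ids), list(Y.component_ids))
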