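"""Covariate adjustment for KDC tests.

Two routes are provided.  The log-ratio route transforms compositions to alr
coordinates, removes the covariates by linear projection, Y(Z) = (I - H_Z) Y,
maps the residuals back to the simplex, and residualizes the predictor the
same way; the permutation scheme is either Kennedy-Cade (permute the
residualized predictor's kernel directly) or Freedman-Lane (permute the
reduced-model residuals and re-residualize before each permuted statistic),
the latter giving tighter type-I error control.  The stratified-kernel route
handles a categorical covariate by zeroing similarity between samples in
different strata on both kernel sides and permuting within strata.

The projection is invariant to the choice of log-ratio basis: the alr and
clr routes yield identical Aitchison geometry on the adjusted compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositions import (
    CompositionMatrix,
    alr,
    alr_inverse,
    clr,
    clr_inverse,
)
from .distances import aitchison_distance
from .kdc import (
    TestResult,
    dcor,
    kdc_statistic,
    draw_permutations,
    permutation_test,
)
from .kernels import (
    gaussian_kernel,
    predictor_kernel,
    resolve_bandwidth,
    stratified_kernel,
)

__all__ = [
    "CovariateMatrix",
    "residualize",
    "adjust_composition",
    "codak_alr",
    "codak_sk",
]


@dataclass
class CovariateMatrix:
    """Covariates expanded into a full-rank design matrix with intercept.

    Continuous covariates enter as-is; categorical covariates are
    dummy-coded against a first-level reference.
    """

    design: np.ndarray
    column_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-dimensional")
        if self.column_names is None:
            self.column_names = [f"x{j}" for j in range(self.design.shape[1])]
        rank = np.linalg.matrix_rank(self.design)
        if rank < self.design.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{self.design.shape[1]} columns); collinear columns among: "
                + ", ".join(self._suspect_columns())
            )

    def _suspect_columns(self) -> list[str]:
        from scipy.linalg import qr

        _, r, piv = qr(self.design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(self.design.shape) * np.finfo(float).eps
        return [self.column_names[j] for j in piv[diag <= tol]]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kinds: dict[str, str] | None = None) -> "CovariateMatrix":
        """Build from a covariate table; non-numeric columns are categorical."""
        kinds = kinds or {}
        n = len(df)
        blocks = [np.ones((n, 1))]
        names = ["intercept"]
        for col in df.columns:
            kind = kinds.get(col)
            if kind is None:
                kind = "continuous" if pd.api.types.is_numeric_dtype(df[col]) else "categorical"
            if kind == "continuous":
                blocks.append(df[col].to_numpy(dtype=float)[:, None])
                names.append(col)
            elif kind == "categorical":
                dummies = pd.get_dummies(df[col].astype("category"), prefix=col, drop_first=True)
                blocks.append(dummies.to_numpy(dtype=float))
                names.extend(dummies.columns.tolist())
            else:
                raise ValueError(f"unknown covariate kind {kind!r} for column {col!r}")
        return cls(np.hstack(blocks), names)

    @classmethod
    def from_array(cls, values: np.ndarray, kind: str = "continuous", name: str = "z") -> "CovariateMatrix":
        """Convenience constructor for a single covariate vector or matrix."""
        values = np.asarray(values)
        if values.ndim == 1:
            values = values[:, None]
        df = pd.DataFrame({f"{name}{j}" if values.shape[1] > 1 else name: values[:, j] for j in range(values.shape[1])})
        return cls.from_dataframe(df, {c: kind for c in df.columns})

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]


def residualize(M: np.ndarray, Z: CovariateMatrix) -> np.ndarray:
    """(I - H_Z) M: residuals of each column of M on the covariate design."""
    M = np.asarray(M, dtype=float)
    one_d = M.ndim == 1
    if one_d:
        M = M[:, None]
    if M.shape[0] != Z.n_samples:
        raise ValueError("row count of M must match the covariate design")
    beta, *_ = np.linalg.lstsq(Z.design, M, rcond=None)
    resid = M - Z.design @ beta
    return resid[:, 0] if one_d else resid


def adjust_composition(
    P: CompositionMatrix, Z: CovariateMatrix, transform: str = "alr", ref: int = -1
) -> CompositionMatrix:
    """Remove covariate effects from compositions via log-ratio projection.

    alr(P) (or clr(P)) is residualized on the design and mapped back to the
    simplex.  Either basis yields the same Aitchison distances downstream.
    """
    if transform == "alr":
        Y = alr(P, ref=ref)
        Y.values = residualize(Y.values, Z)
        return alr_inverse(Y)
    if transform == "clr":
        Y = clr(P)
        resid = residualize(Y.values, Z)
        # re-center rows: projection acts column-wise, so row sums can drift
        Y.values = resid - resid.mean(axis=1, keepdims=True)
        return clr_inverse(Y)
    raise ValueError("transform must be 'alr' or 'clr'")


def codak_alr(
    P: CompositionMatrix,
    x: np.ndarray,
    Z: CovariateMatrix,
    scheme: str = "kennedy_cade",
    gamma: float | str = "median",
    B: int = 10_000,
    seed: int | None = 0,
    ref: int = -1,
) -> TestResult:
    """Covariate-adjusted CODAK test via alr residualization.

    Both schemes share the observed statistic (AD-Gaussian kernel on the
    adjusted compositions against the linear kernel on the residualized
    predictor); they differ only in how the null distribution is resampled.
    """
    x = np.asarray(x, dtype=float)
    if scheme not in ("kennedy_cade", "freedman_lane"):
        raise ValueError("scheme must be 'kennedy_cade' or 'freedman_lane'")
    Y = alr(P, ref=ref)
    E = residualize(Y.values, Z)
    Yr = alr(P, ref=ref)
    Yr.values = E
    P_adj = alr_inverse(Yr)
    x_r = residualize(x, Z)
    K = gaussian_kernel(aitchison_distance(P_adj), gamma)
    L = predictor_kernel(x_r, kind="continuous")

    if scheme == "kennedy_cade":
        res = permutation_test(K, L, B=B, seed=seed, adjustment="alr_kc")
        return res

    # Freedman-Lane: permute reduced-model residuals, re-residualize on Z,
    # rebuild the composition kernel, test against the fixed x-residual kernel
    obs = kdc_statistic(K, L)
    rng = np.random.default_rng(seed)
    n = P.n_samples
    perms = draw_permutations(rng, n, B)
    count = 0
    for b in range(B):
        Eb = residualize(E[perms[b]], Z)
        Yb = alr(P, ref=ref)
        Yb.values = Eb
        Kb = gaussian_kernel(aitchison_distance(alr_inverse(Yb)), gamma)
        if kdc_statistic(Kb, L) >= obs - 1e-12:
            count += 1
    return TestResult(
        statistic=obs,
        dcor=dcor(K, L),
        p_value=(1.0 + count) / (B + 1.0),
        n_permutations=B,
        seed=seed,
        kernel_tags=(K.kernel, L.kernel),
        adjustment="alr_fl",
    )


def codak_sk(
    P: CompositionMatrix,
    x: np.ndarray,
    strata: np.ndarray,
    predictor_kind: str = "auto",
    gamma: float | str = "median",
    B: int = 10_000,
    seed: int | None = 0,
) -> TestResult:
    """Covariate-adjusted CODAK test via the stratified kernel.

    The Gaussian AD kernel and the predictor kernel are both zeroed between
    samples from different covariate strata, and permutations are restricted
    within strata.  The bandwidth is the median of *all* pairwise Aitchison
    distances, so within-stratum similarities equal the unadjusted kernel's.
    Multiple categorical covariates should be crossed into a single stratum
    label beforehand (at a cost in effective sample size).
    """
    strata = np.asarray(strata)
    if len(strata) != P.n_samples:
        raise ValueError("one stratum label per sample required")
    D = aitchison_distance(P)
    g = resolve_bandwidth(D, gamma)
    K = stratified_kernel(gaussian_kernel(D, g), strata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # singleton warning already raised for K
        L = stratified_kernel(predictor_kernel(x, predictor_kind), strata)
    return permutation_test(K, L, B=B, seed=seed, strata=strata, adjustment="stratified")
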