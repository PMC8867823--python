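"""Synthetic CyTOF-like cell-type count data and the validation studies.

The generator emulates clustered mass-cytometry output for a two-group
comparison: each sample contributes 30,000-50,000 cells allocated to 20
named cell types (plus an "other" remainder category) by a multinomial
logit model.  Baseline cell-type probabilities span 0.002-0.15
(log-spaced); overdispersion beyond the multinomial is induced by an
observation-level random effect (OLRE, sd 0.2) on every logit.  Group
effects are percentage-point shifts on a documented subset of components:

    null           no shift (size simulations)
    all_small      0.2 pp on all 20 named components
    half_small     0.2 pp on every other component (10 of 20)
    quarter_large  0.4 pp on every fourth component (5 of 20)

Signs alternate +/- along the affected components so the shifts nearly
cancel; any residual mass is absorbed by the "other" category.  An optional
binary covariate shifts compositions like the all-small pattern, and a
repeated-measures design adds a subject-level random effect shared across a
subject's two condition rows to probe robustness to correlated samples.

The study runners estimate test size/power over a grid of nominal levels
and ranking-recovery metrics (Spearman correlation with true log odds
ratios, top-5 overlap), all reproducible from a single master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adjust import CovariateMatrix, codak_alr, codak_sk
from .compositions import CompositionMatrix, CountMatrix, counts_to_composition
from .distances import aitchison_distance, bray_curtis_distance, euclidean_distance
from .followup import evaluate_ranking, log_or_baseline, loo_dcor, weighted_dcor_rank
from .kdc import TestResult, permutation_test
from .kernels import distance_induced_kernel, gaussian_kernel, predictor_kernel, psd_clip

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "SimulationSummary",
    "default_baseline_probs",
    "make_group_probs",
    "simulate_dataset",
    "run_size_power_study",
    "run_ranking_study",
    "true_effect_summary",
    "SIZE_POWER_METHODS",
]

EFFECT_PATTERNS = ("null", "all_small", "half_small", "quarter_large")
SIZE_POWER_METHODS = (
    "codak_ad",
    "codak_ad_linear",
    "codak_bc",
    "codak_ed",
    "codak_alr_kc",
    "codak_alr_fl",
    "codak_sk",
)
RANKING_METHODS = ("loo", "weighted_dcor", "log_or")


def default_baseline_probs(q: int = 20) -> np.ndarray:
    """Log-spaced baseline cell-type probabilities from 0.002 to 0.15."""
    return np.geomspace(0.002, 0.15, q)


@dataclass
class SimulationConfig:
    """Generative parameters for one simulation scenario.

    Defaults are the study conditions: 12 samples per group, 20 named cell
    types, 30,000-50,000 cells per sample, OLRE sd 0.2, and
    percentage-point effects of 0.2 (small) / 0.4 (large).
    """

    n_per_group: int = 12
    n_components: int = 20
    cells_min: int = 30_000
    cells_max: int = 50_000
    baseline_probs: np.ndarray | None = None
    olre_sd: float = 0.2
    effect_pattern: str = "null"
    small_effect: float = 0.2  # percentage points
    large_effect: float = 0.4
    with_covariate: bool = False
    repeated_measures: bool = False
    subject_re_sd: float = 0.0

    def resolved_baseline(self) -> np.ndarray:
        if self.baseline_probs is not None:
            p = np.asarray(self.baseline_probs, dtype=float)
        else:
            p = default_baseline_probs(self.n_components)
        if np.any(p <= 0) or p.sum() > 1:
            raise ValueError("baseline probabilities must be positive and sum to at most 1")
        return p


@dataclass
class SimulatedDataset:
    """One simulated dataset plus its generating truth."""

    counts: CountMatrix
    x: np.ndarray
    z: np.ndarray | None
    subject_ids: np.ndarray | None
    probs_group0: np.ndarray
    probs_group1: np.ndarray
    true_log_or: np.ndarray

    def composition(self, pseudocount: float = 1.0) -> CompositionMatrix:
        return counts_to_composition(self.counts, pseudocount)


@dataclass
class SimulationSummary:
    """Tabular output of a size/power or ranking study."""

    table: pd.DataFrame
    per_replicate: pd.DataFrame | None = None
    config: SimulationConfig | None = None


def _effect_delta(pattern: str, q: int, small: float, large: float) -> np.ndarray:
    """Percentage-point shifts on the named components for one pattern."""
    delta = np.zeros(q)
    if pattern == "null":
        return delta
    if pattern == "all_small":
        affected, eff = np.arange(q), small
    elif pattern == "half_small":
        affected, eff = np.arange(0, q, 2), small
    elif pattern == "quarter_large":
        affected, eff = np.arange(0, q, 4), large
    else:
        raise ValueError(f"unknown effect pattern {pattern!r}; choose from {EFFECT_PATTERNS}")
    signs = np.where(np.arange(len(affected)) % 2 == 0, 1.0, -1.0)
    delta[affected] = signs * eff / 100.0
    return delta


def _apply_delta(probs: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Shift the named components; the 'other' category absorbs the remainder."""
    named = probs[:-1] + delta
    other = 1.0 - named.sum()
    out = np.concatenate([named, [other]])
    if np.any(out <= 0):
        bad = np.where(out <= 0)[0].tolist()
        raise ValueError(
            f"effect too large for the baseline: probabilities at indices {bad} "
            "would become nonpositive"
        )
    return out


def _log_odds_ratio(p1: np.ndarray, p0: np.ndarray) -> np.ndarray:
    return np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))


def make_group_probs(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True cell-type probability vectors for the two groups and the log ORs.

    Both returned vectors have q+1 entries (named components plus "other")
    and sum to one exactly.
    """
    named = config.resolved_baseline()
    q = len(named)
    p0 = np.concatenate([named, [1.0 - named.sum()]])
    if p0[-1] <= 0:
        raise ValueError("baseline probabilities leave no mass for the reference category")
    delta = _effect_delta(config.effect_pattern, q, config.small_effect, config.large_effect)
    p1 = _apply_delta(p0, delta)
    return p0, p1, _log_odds_ratio(p1, p0)


def component_names(config: SimulationConfig) -> list[str]:
    q = config.n_components
    return [f"ct{k + 1:02d}" for k in range(q)] + ["other"]


def simulate_dataset(
    config: SimulationConfig, seed: int | np.random.Generator | None = 0
) -> SimulatedDataset:
    """Draw one dataset from the multinomial-logit OLRE model.

    Per sample i: total cells N_i ~ uniform on [cells_min, cells_max];
    logits eta_ik = ln(p_k,group(i)) + b_ik with b_ik ~ N(0, olre_sd^2)
    independently per sample and component (plus a subject-level
    N(0, subject_re_sd^2) term shared across a subject's repeated rows);
    counts_i ~ Multinomial(N_i, softmax(eta_i)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0, p1, true_lor = make_group_probs(config)
    qq = len(p0)
    n = config.n_per_group

    if config.repeated_measures:
        # two condition rows (z = 0, 1) per subject, disease constant within subject
        n_subj = 2 * n
        subject_ids = np.repeat(np.arange(n_subj), 2)
        x = np.repeat(np.concatenate([np.zeros(n), np.ones(n)]), 2)
        z = np.tile([0.0, 1.0], n_subj)
    else:
        n_subj = 2 * n
        subject_ids = None
        x = np.concatenate([np.zeros(n), np.ones(n)])
        if config.with_covariate:
            # balanced within groups
            half = np.tile([0.0, 1.0], (n + 1) // 2)[:n]
            z = np.concatenate([half, half])
        else:
            z = None

    n_rows = len(x)
    cov_delta = _effect_delta(
        "all_small", config.n_components, config.small_effect, config.large_effect
    )

    base = np.empty((n_rows, qq))
    for i in range(n_rows):
        p = p1 if x[i] == 1 else p0
        if z is not None and z[i] == 1:
            p = _apply_delta(p, cov_delta)
        base[i] = p

    eta = np.log(base) + rng.normal(0.0, config.olre_sd, size=(n_rows, qq))
    if config.repeated_measures and config.subject_re_sd > 0:
        a = rng.normal(0.0, config.subject_re_sd, size=(n_subj, qq))
        eta += a[np.repeat(np.arange(n_subj), 2)]
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)

    totals = rng.integers(config.cells_min, config.cells_max + 1, size=n_rows)
    counts = np.empty((n_rows, qq), dtype=np.int64)
    for i in range(n_rows):
        counts[i] = rng.multinomial(totals[i], probs[i])

    return SimulatedDataset(
        counts=CountMatrix(counts, component_ids=component_names(config)),
        x=x,
        z=z,
        subject_ids=subject_ids,
        probs_group0=p0,
        probs_group1=p1,
        true_log_or=true_lor,
    )


def _run_method(method: str, data: SimulatedDataset, B: int, seed: int) -> TestResult:
    """One test on one simulated dataset, sharing distance work across kernels."""
    P = data.composition()
    L = predictor_kernel(data.x, "binary")
    if method == "codak_ad":
        K = gaussian_kernel(aitchison_distance(P))
        return permutation_test(K, L, B=B, seed=seed)
    if method == "codak_ad_linear":
        K = distance_induced_kernel(aitchison_distance(P))
        return permutation_test(K, L, B=B, seed=seed)
    if method == "codak_bc":
        K = psd_clip(distance_induced_kernel(bray_curtis_distance(P)))
        return permutation_test(K, L, B=B, seed=seed)
    if method == "codak_ed":
        K = gaussian_kernel(euclidean_distance(P))
        return permutation_test(K, L, B=B, seed=seed)
    if data.z is None:
        raise ValueError(f"method {method!r} requires a covariate scenario")
    if method == "codak_alr_kc":
        return codak_alr(P, data.x, CovariateMatrix.from_array(data.z), "kennedy_cade", B=B, seed=seed)
    if method == "codak_alr_fl":
        return codak_alr(P, data.x, CovariateMatrix.from_array(data.z), "freedman_lane", B=B, seed=seed)
    if method == "codak_sk":
        return codak_sk(P, data.x, data.z, predictor_kind="binary", B=B, seed=seed)
    raise ValueError(f"unknown method {method!r}; choose from {SIZE_POWER_METHODS}")


def _child_seeds(master_seed: int, n: int, streams: int = 1) -> np.ndarray:
    """Independent 31-bit integer seeds derived from one master seed.

    Returns a (streams, n) array so that, e.g., data generation and
    permutation drawing never share a random stream within a replicate.
    """
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=(streams, n))


def run_size_power_study(
    config: SimulationConfig,
    methods: tuple[str, ...] = ("codak_ad",),
    n_sims: int = 2_000,
    n_perms: int = 1_000,
    alpha_grid: tuple[float, ...] = (0.01, 0.05, 0.1),
    seed: int = 0,
) -> SimulationSummary:
    """Estimate rejection rates for the requested methods under ``config``.

    Each replicate draws a fresh dataset and runs every method on it with a
    replicate-specific permutation seed.  Rates come with Monte-Carlo
    standard errors sqrt(p(1-p)/n_sims).
    """
    data_seeds, perm_seeds = _child_seeds(seed, n_sims, streams=2)
    records = []
    for r in range(n_sims):
        data = simulate_dataset(config, int(data_seeds[r]))
        for method in methods:
            res = _run_method(method, data, n_perms, int(perm_seeds[r]))
            records.append({"replicate": r, "method": method, "p_value": res.p_value})
    per_rep = pd.DataFrame.from_records(records)
    rows = []
    for method in methods:
        p = per_rep.loc[per_rep["method"] == method, "p_value"].to_numpy()
        for alpha in alpha_grid:
            rate = float(np.mean(p <= alpha))
            rows.append(
                {
                    "method": method,
                    "case": config.effect_pattern,
                    "alpha": alpha,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / n_sims)),
                    "n_sims": n_sims,
                }
            )
    return SimulationSummary(pd.DataFrame(rows), per_rep, config)


def run_ranking_study(
    config: SimulationConfig,
    cases: tuple[str, ...] = ("all_small", "half_small", "quarter_large"),
    n_sims: int = 2_000,
    top_m: int = 5,
    seed: int = 0,
) -> SimulationSummary:
    """Ranking-recovery study pooled over non-null effect patterns.

    Replicates are split evenly over ``cases``; each is ranked by the LOO
    dcor, weighted dcor and estimated-log-OR methods and scored against the
    true log odds ratios of its generating case.  The summary reports median
    Spearman correlation and median top-m overlap per method, pooled.
    """
    if "null" in cases:
        raise ValueError("ranking recovery is undefined under the null pattern")
    (seeds,) = _child_seeds(seed, n_sims)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for r in range(n_sims):
            case = cases[r % len(cases)]
            cfg = replace(config, effect_pattern=case)
            data = simulate_dataset(cfg, int(seeds[r]))
            P = data.composition()
            rankings = {
                "loo": loo_dcor(P, data.x),
                "weighted_dcor": weighted_dcor_rank(P, data.x)[1],
                "log_or": log_or_baseline(P, data.x),
            }
            # evaluate over the named cell types; the "other" remainder
            # category is part of the analysis but not a ranked target
            named = data.counts.component_ids[:-1]
            truth = data.true_log_or[:-1]
            for method, ranking in rankings.items():
                rho, overlap = evaluate_ranking(ranking.subset(named), truth, top_m)
                records.append(
                    {
                        "replicate": r,
                        "case": case,
                        "method": method,
                        "spearman": rho,
                        "top_overlap": overlap,
                    }
                )
    per_rep = pd.DataFrame.from_records(records)
    rows = []
    for method in RANKING_METHODS:
        sub = per_rep[per_rep["method"] == method]
        rows.append(
            {
                "method": method,
                "median_spearman": float(sub["spearman"].median()),
                "median_top_overlap": float(sub["top_overlap"].median()),
                "n_sims": len(sub),
            }
        )
    return SimulationSummary(pd.DataFrame(rows), per_rep, config)


def true_effect_summary(p0: np.ndarray, p1: np.ndarray) -> tuple[float, float]:
    """(Aitchison distance between the group probability vectors, max |log OR|)."""
    P = CompositionMatrix(np.vstack([p0, p1]))
    ad = float(aitchison_distance(P).values[0, 1])
    return ad, float(np.max(np.abs(_log_odds_ratio(p1, p0))))
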