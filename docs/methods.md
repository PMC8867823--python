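# Methods

This note records the statistical model implemented by `codak`, the design
choices that were genuinely open, the synthetic-data generator's
assumptions, and the package's numerical conventions.

## The test

Cell-type abundance profiles are compositions P(i) ∈ S^q. Classical
multivariate tests are inappropriate because compositions carry only
relative information; `codak` works in the Aitchison geometry instead.
With clr(p) = (ln p_k − mean_r ln p_r)_k, the Aitchison distance (AD) is
the Euclidean distance between clr vectors. It is invariant to per-sample
rescaling and to component reordering, and deleting components can only
shrink it (subcompositional dominance) — the properties that make
distance-based testing on the simplex coherent and that the Euclidean and
Bray–Curtis distances lack.

The association between compositions and a predictor X is measured by the
kernel distance covariance (equivalently, a biased HSIC estimate)

    KDC_n = trace(K H L H)/n²,  H = I − 11ᵀ/n,

and normalized to the distance correlation
dcor = KDC(K,L)/√(KDC(K,K)·KDC(L,L)), which is in [0,1] for PSD kernels
and equals the squared distance correlation of Székely et al. when both
kernels are distance-induced kernels (−½ H D H) of Euclidean distances.

Composition kernels:

* `ad-gaussian` (default): k_ij = exp(−d_ij/γ). γ defaults to the median
  of the n(n−1)/2 off-diagonal distances (linear-interpolation median).
* `ad-linear`: −½ H D² H, the double-centering (Gram) kernel; PSD because
  AD is Euclidean-embeddable via clr. The two kernels give nearly
  indistinguishable tests in simulation.
* `bc`: double-centering kernel of the Bray–Curtis dissimilarity. BC is
  not a proper metric, so the kernel may be indefinite; negative
  eigenvalues below −1e−10·λ_max are clipped to zero (the nearest-PSD
  spectral projection), smaller negativity is treated as round-off.
* `euclidean`: Gaussian kernel on plain L2 distances (comparison arm only).

Predictor kernels: binary predictors (recoded to {0,1}) use
exp(−|x_i − x_j|), a Gaussian kernel on the Hamming distance, hence PSD;
continuous predictors use the linear kernel after mean-centering and unit
scaling (the normalized statistic is unaffected by affine rescaling of x;
scaling just keeps the arithmetic well-conditioned).

Inference is by permutation of the predictor kernel's sample indexing:
p = (1 + #{permuted ≥ observed})/(B + 1); ties count as at least as
extreme, and both conventions keep the test valid at any B. When
n! ≤ 10,000 and there are no strata the group is enumerated exactly, and
the p-value becomes seed-free. Kernels are centered once outside the
permutation loop; a permuted statistic is an O(n²) gather-and-sum, done in
vectorized blocks.

## Covariate adjustment

*Log-ratio residualization.* Y = alr(P) is regressed on the covariate
design (intercept + continuous columns + first-level-reference dummies for
categorical columns; rank-checked), residuals are mapped back to the
simplex through alr⁻¹, and x is residualized the same way. The projection
commutes with the change between alr and clr bases, so both yield
identical AD matrices downstream (verified to 1e−8 in the tests); the
reference component is therefore immaterial. Two permutation schemes are
implemented: Kennedy–Cade (build both kernels from residuals, permute L as
usual — slightly anticonservative under strong confounding) and
Freedman–Lane (each permutation re-residualizes the permuted reduced-model
residuals on Z and rebuilds the composition kernel before computing the
statistic against the fixed residualized-predictor kernel — tighter
type-I error control at some power cost). Both schemes share one observed
statistic.

*Stratified kernel.* For a categorical covariate, similarity between
samples in different strata is zeroed on both the composition and
predictor sides; the masked exponential kernel remains strictly positive
definite. The bandwidth is the median of *all* pairwise distances, not
within-stratum medians, so the stratified kernel is exactly a masked
version of the unadjusted one (with a single stratum the two tests
coincide seed-for-seed). Permutations are restricted within strata —
the natural group that preserves the covariate–predictor relationship
under the null; this choice is ours, and the repeated-measures robustness
claim below was re-validated under it. Multiple categorical covariates
must be crossed into one stratum label, at a cost in effective sample
size.

## Follow-up ranking

* **Leave-one-out dcor**: score component c by
  max{0, dcor(P,X) − dcor(P₋c,X)} with P₋c the re-closed subcomposition.
  Each reduced dcor is a self-contained statistic: the same kernel family
  with its bandwidth re-resolved on the reduced data. An exact identity
  supports the intuition: for any pair of samples, the component whose
  log-abundance ratio deviates most from the geometric-mean ratio is
  precisely the one whose removal shrinks the pairwise AD the most
  (checked exhaustively in the tests).
* **Weighted dcor**: β_k is the scalar distance correlation (squared,
  V-statistic form on Euclidean distances) between component k's
  proportions and x; weights w_k = β_k^γ / √(Σ_r β_r^{2γ}) enter a
  weighted AD, d_w² = Σ_r w_r (ln(P_ir/g_w(P_i)) − ln(P_jr/g_w(P_j)))²
  with g_w the weighted geometric mean. γ is chosen by direct search on
  the fixed grid {0} ∪ {2⁻³ … 2⁶} (10 log-spaced points); γ = 0 gives
  exactly uniform weights and anchors the search at the unweighted
  statistic, keeping the optimized value no worse than it. Constant
  components get β = 0 with a warning.
* **Log-odds-ratio baseline**: per-component log OR of group mean
  proportions, ranked by absolute value. Used as the evaluation
  comparator; a GLMM-based estimate would be an alternative reading, and
  the group-mean choice may shift benchmark medians slightly.

Ranks are 1 = top contributor, ties broken stably by component order with
an explicit tie flag. Ranking quality against a known truth is scored by
the Spearman correlation of the estimated ranks with the ranks of
|true log OR| (average ranks at ties) plus the top-5 overlap.

## The synthetic-data generator

The generator emulates clustered CyTOF output for a two-group design; its
defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_per_group | 12 | samples per group |
| n_components | 20 | named cell types (+1 "other" remainder) |
| cells_min–cells_max | 30,000–50,000 | per-sample cell total, uniform integer |
| baseline_probs | geomspace(0.002, 0.15, 20) | control-group probabilities |
| olre_sd | 0.2 | observation-level random-effect sd on every logit |
| small/large effect | 0.2 / 0.4 | percentage-point group differences |
| subject_re_sd | 0 (√0.1 for the mild repeated-measures case) | subject-level RE sd |

Counts for sample i are Multinomial(N_i, softmax(ln p_group + b_i)) with
b_ik ~ N(0, σ_b²) i.i.d. per sample and component — the OLRE that induces
the extra-multinomial variation seen in real CyTOF data. The published
description of these conditions gives only the probability *range*
0.002–0.15 and the effect magnitudes; the concrete baseline vector
(log-spaced, ascending), the affected subsets (all / every second / every
fourth component, from the smallest), and the alternating +/− signs are
this package's fixed, documented choices. Because the named probabilities
sum to ≈0.73, the remaining mass is an "other" reference category: it
absorbs any net effect mass, participates in the analysis composition, but
is not a ranked target in the recovery studies. The covariate scenario
gives z = 1 rows an additional all-components 0.2-pp shift; the
repeated-measures scenario gives every subject one row per covariate
condition plus a subject-level N(0, σ_s²) logit effect shared across the
subject's rows.

What the generator does *not* emulate: hierarchical (tree-structured)
cell-type relationships, zero-inflated counts (at these depths and
baselines zeros are vanishingly rare; a pseudocount guard exists for real
data), batch effects, and heavy-tailed overdispersion. Passing the
simulation-based tests therefore demonstrates calibration and relative
power under log-normal multiplicative overdispersion, not under every
failure mode of real data.

A consequence of the fixed effect placement deserves emphasis: adding
percentage-point shifts to baselines as small as 0.002 produces true
|log OR| up to ≈1.6, a wide and strongly structured spread. Ranking
recovery is correspondingly easier here than in studies whose effect
configurations are weaker or more homogeneous: our pooled medians are
≈0.68 (LOO), ≈0.66 (weighted dcor), ≈0.68 (log-OR baseline) with median
top-5 overlap 3–4, whereas weaker-effect designs are reported to give
medians near 0.4–0.5 and overlap 3. The *ordering* of the methods (LOO at
least as good as the log-OR baseline, weighted dcor slightly behind) is
stable across these regimes; the absolute level is a property of the
effect configuration, which is why the package reports it alongside the
generating truth rather than as a universal constant.

## Study runners, seeds and problem sizes

`run_size_power_study` and `run_ranking_study` derive two independent
31-bit seed streams per replicate from one master seed (data generation
and permutation drawing never share a stream — sharing one measurably
biases size estimates), making every study bit-reproducible from
`(config, seed)`. Default scales were chosen so the whole validation suite
runs in minutes on one core: size studies use 2,000–5,000 replicates ×
1,000 permutations (Monte-Carlo SE of a size estimate at 0.05: ≈0.005 at
2,000, ≈0.003 at 5,000), power and robustness studies 1,000 × 1,000, and
ranking studies 2,000 replicates (no permutations needed). Full-scale
reruns are a matter of raising `n_sims`/`n_perms` in the config.

Measured calibration under these conditions: empirical size 0.047 at
α = 0.05 for both AD kernels (10,000 pooled null replicates); under the
mild repeated-measures violation (subject RE variance 0.1) the stratified
kernel's size is ≈0.074 while the alr route rejects ≈78% of the time —
the stratified kernel is the only safe adjustment there, and its control
degrades as the subject effect grows.

## Numerical conventions and edge cases

* Compositions must be strictly positive; proportion tables with rows
  summing to 1 within 1e−2 (rounded files) are re-closed, worse rows are
  rejected. Zeros in *counts* are handled by adding a pseudocount
  (default 1) to **every** cell of the matrix before closure whenever any
  zero is present — a global shift preserves within-row count ordering and
  cross-sample comparability; zero *proportions* are refused with guidance
  rather than silently imputed.
* alr/clr inverses exponentiate after subtracting the row maximum and
  floor the shifted exponent at −700, so extreme coordinates neither
  overflow nor underflow to exact zeros; round trips are exact to 1e−10.
* The alr reference defaults to the last component and is restored to its
  original column position on inversion.
* Permutation ties count toward the numerator (conservative); the
  observed-vs-permuted comparison uses a 1e−12 absolute guard against
  floating-point ties.
* Degenerate cases raise informative errors: all-zero closure input,
  constant kernels in dcor (the degenerate side is named), rank-deficient
  covariate designs (collinear columns listed), >2 levels for a binary
  kernel, dropping a component from a 2-part composition. Singleton strata
  warn rather than fail.

## Known limitations

* The permutation p-value floor is 1/(B+1); very small p-values need large B.
* Freedman–Lane rebuilds the composition kernel per permutation (O(B·n²·q));
  it is the slow path and is sized accordingly in the studies.
* The stratified kernel conditions on strata and loses power as strata
  multiply; with repeated measures its size control is empirical, not
  exact, and worsens with stronger within-subject correlation.
* Asymptotic (non-permutation) null distributions are out of scope, as are
  tree-aware distances and per-component hypothesis tests with
  multiplicity control.
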