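# Methods

This note documents the models implemented in `radpipe`, the choices
made where the methodology left room, what the synthetic-data
generators emulate, and the known limitations.

## Spline time-course differential expression

The treated-vs-control comparison uses a gene-wise linear model

    y_s = β₀ + Σₖ βₖ Bₖ(t_s) + x_s (γ₀ + Σₖ γₖ Bₖ(t_s)) + ε_s,

where B is a natural cubic spline basis with K = 3 degrees of freedom
and x indicates the irradiated condition. The basis is built in-house
(`radpipe.splines`): boundary knots at the min/max design time,
interior knots at evenly spaced quantiles of the distinct times, and
the reduced truncated-power construction that enforces zero second
derivative beyond the boundary knots exactly. Times are internally
rescaled to the boundary interval so basis values are O(1); tests
verify the span against an independent truncated-power plus
natural-constraint null-space construction.

The default tested null is γ₀ = … = γ_K = 0 (q = K + 1 = 4), i.e. the
treated time course may differ from control by level as well as shape.
A shape-only test (q = K, the offset absorbed into the null model) is
available via `test="shape"`; which coefficients the original
spline-time-course methodology tests is ambiguous, so both are exposed
with the inclusive variant as default.

Variance moderation follows the classic empirical-Bayes scheme for a
scaled-inverse-chi-square prior: with e_g = log s_g² − ψ(d_g/2) +
log(d_g/2), the prior df d₀ solves ψ′(d₀/2) = Var(e) − mean ψ′(d_g/2)
via a Newton inversion of the trigamma function, and s₀² follows from
the mean of e. When the observed variance of e falls below the
sampling-noise term, d₀ = ∞ and all gene variances pool to s₀² (the
F statistic then reduces to a chi-square test); d₀ forced to 0 recovers
the ordinary per-gene F-test, an equality the tests check to 1e−10.
With fewer than two genes no prior is estimable and the code falls back
to the unmoderated test.

The early/late classification uses per-time-point fold changes on
replicate means: FC(t) = 2^(mean treated − mean control). Strict
inequalities at 2.0 and 0.5 apply, the 24 h sample counts as day 1, and
fitted spline values are deliberately not used (replicate means keep
the rule transparent and replicate-permutation invariant). The static
contrast flags a gene only when both |log2FC| > 0.5 and FDR < 0.05
hold, with the fold-change threshold read as a magnitude because
down-regulated genes must qualify symmetrically.

## Gene association networks

The network stage treats each gene's replicate-averaged trajectory as a
functional observation. Time points receive trapezoid quadrature
weights w_k ∝ (t_{k+1} − t_{k−1})/2 (half-intervals at the ends),
normalised to sum to one, so the irregular sampling grid does not
over-weight the densely sampled first day.

Correlation shrinkage uses the identity-target analytic form
λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij², clipped to [0, 1], with
R* = (1 − λ*) R + λ* I. The per-correlation variance is estimated from
the weighted empirical variance of standardized cross-products,
Var̂(r_ij) = sw/(1 − sw) · Σ_k w_k (c_kij − r_ij)² with sw = Σ w_k²,
which reduces to the textbook squared standard error of a mean for
uniform weights; alternative scalings of the same estimator differ
only at O(1/n). λ* = 0 on a singular correlation matrix raises rather
than silently regularizing; all-zero off-diagonals give λ* = 1.

Partial correlations are p_ij = −Ω_ij/√(Ω_ii Ω_jj), Ω = (R*)⁻¹. The
exact inverse map (negate off-diagonals, invert, rescale) is provided
as `partial_to_correlation`; the round trip is an identity to machine
precision. Note that applying the forward map twice is *not* an
identity — the inverse requires the sign flip.

Edge significance uses a two-component mixture over all off-diagonal
partial correlations: f(p) = η₀ f₀(p; κ) + (1 − η₀)·½, where f₀ is the
null distribution of a sample correlation with effective degrees of
freedom κ (constrained > 3) and the alternative is uniform on [−1, 1].
The uniform alternative replaces the nonparametric (Grenander) estimate
used elsewhere because it is deterministic and testable; κ is estimated
by maximum likelihood rather than fixed from the nominal sample size,
since weighting, averaging and shrinkage make the nominal n
inappropriate. (η₀, κ) are fit by bounded quasi-Newton from three
starts; the per-edge posterior is (1 − η₀)·½ / f(p), monotone in |p|.
Edges with posterior ≥ 0.95 (closed threshold, ties included) enter the
network; isolated nodes are retained with a flag so both node counts
are reportable.

Which condition feeds the network is configurable
(`condition="treated"` by default, the irradiated trajectories of the
temporally DE genes); the methodology does not pin this down, so the
switch is explicit.

## Centrality and selection

Degree, unnormalized shortest-path betweenness (Brandes pair
dependencies, each unordered pair counted once) and harmonic closeness
Σ 1/d(u, v) are computed on the unweighted graph. Harmonic closeness is
a deliberate choice: reconstructed networks are typically disconnected
and classical closeness is undefined there, while the harmonic form
handles 1/∞ = 0 gracefully. Each measure is ranked descending with
average ranks on ties (preserving Σ ranks = N(N+1)/2); the consensus is
the mean of the three ranks. The top fraction selects
k = round(0.05·N) rounded half away from zero with a floor of one —
the only rounding convention consistent with all three published
network sizes (6256→313, 5709→285, 6859→343) — with boundary ties
broken by (consensus, gene id) for determinism.

## Enrichment

Gene sets are intersected with the analysis universe *first*, then the
20 ≤ |set ∩ universe| ≤ 600 filter applies (inclusive); this makes the
size filter data-relative. The universe defaults to all detected genes
of the experiment, not the full annotation. p-values are upper
hypergeometric tails P(X ≥ hits) and BH-adjusted across the tested
sets; the default reporting threshold is FDR < 0.1.

## Copy-number integration and qPCR

Genes are assigned to segments by midpoint containment in half-open
[start, end) intervals (midpoint = start inside, midpoint = end
outside); genes outside all segments are neutral with an explicit flag.
Concordance statuses partition the joined genes into gain_up,
loss_down, discordant and neutral. ΔΔCt combines multiple reference
genes by the arithmetic mean of their Ct values (the geometric mean of
expression is equivalent on the Ct scale up to this choice);
RQ = 2^(−ΔΔCt) is invariant to per-sample constant Ct offsets.
Platform validation passes only for Spearman ρ strictly above 0.5.

## Clonogenic survival

Colony counts are modelled as Poisson — colony formation is a thinned
counting process, making Poisson the natural likelihood where the
original description says only "maximum likelihood". For fixed (α, β)
the per-experiment plating efficiencies have the closed-form ML
solution PE_e = Σ k / Σ cells·S(D), so the optimizer works on the
2-parameter profile likelihood with α, β ≥ 0 bounds (L-BFGS-B,
initialized from log-linear least squares on observed surviving
fractions with a half-count continuity floor). Fits pinned at the
boundary are flagged. Curve comparison fits a joint model sharing
(α, β) across the two lines (separate PEs) and computes the
extra-sum-of-squares F on Poisson deviance with (2, n − p_sep) degrees
of freedom; an exact likelihood-ratio chi-square is available via
`method="lr"`. Simulation tests confirm the F variant holds its nominal
5 % size at moderate counts and detects an α difference of 0.3 /Gy with
power ~1 at 10⁴ cells per dish.

## Synthetic data

The generators emulate the study design: two conditions × the 0.25–96 h
grid × 3 replicates, gene variances drawn from the
scaled-inverse-chi-square prior (d₀ = 4, s₀² = 0.05 log2² by default)
so the moderation stage faces a correctly specified target, treatment
effects as 3-df spline deviations with N(0, effect_sd²) coefficients in
a prop_de fraction of genes, and baseline trajectories with intercept
~ N(7, 1) and spline coefficients ~ N(0, 0.5²) — typical log2
microarray scale and curvature, chosen once. Network data are i.i.d.
draws from a Gaussian graphical model whose precision matrix has unit
diagonal and −pcor entries on a random edge set, giving every true edge
partial correlation exactly +pcor; positive definiteness is verified on
the smallest eigenvalue and infeasible density/magnitude combinations
raise with that eigenvalue. i.i.d. sampling (rather than an
autoregressive process) keeps an exact analytic truth for the
conditional-independence structure. Colony counts are Poisson under the
LQ law with per-experiment plating efficiencies; copy-number profiles
tile each chromosome with non-overlapping half-open segments.

Each generator owns an RNG stream seeded from `seed` plus a fixed
per-generator offset, so outputs are byte-identical across runs and
adding a generator never perturbs the others.

What the simulations do *not* model: probe-level microarray artefacts,
normalization, batch effects, autocorrelated dynamics, heavy-tailed
noise, or linkage between copy number and expression levels. Passing
tests therefore demonstrate correctness and calibration of the
statistical machinery under its own assumptions, not robustness to
real-data violations of them.

## Problem sizes and numerics

The bundled test and acceptance computations use deliberately modest
sizes — 1000–2000 genes, 100-node networks with 200 samples, 400–500
simulation replicates for test calibration — which are sufficient for
the binomial/recovery tolerances being checked. Optimizers: L-BFGS-B
with analytic profile likelihoods (LQ) or vectorized objectives
(mixture); Newton for the trigamma inversion (60-digit agreement not
claimed, 1e−10 relative). Degenerate inputs are defined behaviour:
zero-variance genes get zero correlations with a warning, empty
queries give p = 1, single-gene BH returns the raw p, d₀ = ∞ pools
variances, λ* is clipped to [0, 1].

## The demo pipeline

`run_pipeline` chains simulate → DE → early/late → network →
centrality → enrichment → integration on one simulated dataset. Two
pragmatic choices: the network stage keeps the top `max_network_genes`
(default 300) DE genes by F so the matrix inversion stays small, and —
because the simulation has a single cell line — the static contrast for
copy-number integration compares treated vs control samples as two
groups. Both are config-visible and exist to exercise the code paths
end-to-end with ground truth, not to mimic a second subclone.
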