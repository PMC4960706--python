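# radpipe

Analysis pipeline for radiation-response experiments on cultured tumour
cell lines: time-course transcriptomics after irradiation, gene
association networks, and clonogenic survival. The typical experiment
compares irradiated (e.g. 8 Gy) against sham-irradiated cells sampled at
several time points (default grid 0.25, 2, 7, 12, 24, 48, 72, 96 h)
with a few independent replicates, complemented by colony-formation
assays, copy-number profiles and qPCR validation.

Every stage can be exercised on synthetic data with recorded ground
truth, so the statistical behaviour of the whole stack (power, FDR
control, edge recovery, parameter recovery) is testable without any
external data.

## What it computes

**Time-course differential expression.** Each gene's log2 expression is
regressed on a natural cubic spline in time (K = 3 df) with a treatment
interaction:

    y = β₀ + Σₖ βₖ Bₖ(t) + x·(γ₀ + Σₖ γₖ Bₖ(t)) + ε,   x = 1 for treated

and the null γ₀ = … = γ_K = 0 is tested with a moderated F statistic:
gene-wise residual variances s_g² are shrunk toward an
inverse-chi-square prior (d₀, s₀²) estimated across genes by the
standard moment-matching on log s_g², giving
s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) and F̃ ~ F(q, d₀ + d_g).
p-values are Benjamini–Hochberg adjusted; genes with FDR < 0.05 are
temporally differentially expressed. Genes crossing fold-change 2.0 (or
0.5) at any time point within the first day are early responders;
within days 2–4, late responders. A static two-group contrast
(moderated t, |log2FC| > 0.5 and FDR < 0.05) handles clone-vs-parental
comparisons.

**Gene association networks.** Replicate trajectories are averaged,
time points weighted by the trapezoid rule, and the weighted correlation
matrix shrunk toward the identity with the analytic intensity
λ* = Σ Var̂(r_ij) / Σ r_ij². Partial correlations come from the inverse
of the shrunken matrix, p_ij = −Ω_ij/√(Ω_ii Ω_jj), and a two-component
mixture — null density (1−p²)^((κ−3)/2)·Γ(κ/2)/(√π Γ((κ−1)/2)) versus a
uniform alternative — converts each p_ij into a posterior edge
probability. Edges with posterior ≥ 0.95 form the network; nodes are
ranked by the consensus (mean) of their degree, shortest-path
betweenness and harmonic closeness ranks, and the top 5 % are the
candidate key genes.

**Enrichment and integration.** Gene lists are tested for
over-representation in GMT gene sets (one-sided Fisher's exact test,
sets restricted to 20–600 universe genes, BH-adjusted). Copy-number
calls (−1/0/+1 per segment) are mapped to genes by midpoint containment
and intersected with the static DE results to report concordant genes
(gain∧up, loss∧down). ΔΔCt relative quantification and a Spearman
ρ > 0.5 criterion validate array fold changes against qPCR.

**Clonogenic survival.** Colony counts are Poisson with mean
cells·PE_e·S(D), S(D) = exp(−(αD + βD²)). (α, β) are fit by maximum
likelihood with per-experiment plating efficiencies profiled out in
closed form; curves are compared with a deviance-based F-test (or
likelihood ratio). Doubling times come from semi-log regression in the
exponential growth window, T_d = ln 2 / slope.

## Worked example

```python
import numpy as np
from radpipe import (SimulationConfig, gen_timecourse, timecourse_de,
                     classify_early_late, reconstruct_network,
                     compute_centralities, top_fraction, fit_lq)
from radpipe.synthetic import gen_colony_counts

cfg = SimulationConfig(n_genes=1000, prop_de=0.2, effect_sd=1.0, seed=42)
expr, design, truth = gen_timecourse(cfg)

de = timecourse_de(expr, design, fdr_threshold=0.05)
called = set(de.index[de["de"]])
resp = classify_early_late(expr, design, sorted(called))

top_de = de[de["de"]].sort_values("F", ascending=False).index[:200]
G, P, lam, model = reconstruct_network(expr.loc[top_de], design, condition="treated")
cent = compute_centralities(G)
top = top_fraction(cent, 0.05)

counts = gen_colony_counts(0.30, 0.03, 0.5, [0, 1, 2, 4, 6, 8],
                           [100, 200, 400], 3, seed=7)
fit = fit_lq(counts)
```

Output:

```
temporally DE genes: 189 / 1000  (sensitivity 0.925, empirical FDR 0.021)
variance prior: d0 = 3.94, s0^2 = 0.0514
early responders: 103, late responders: 120
network: 189 nodes, 30 edges (lambda* = 0.489, eta0 = 0.996)
top 5% consensus genes: 9 (G0574, G0820, G0718, G0358, ...)
LQ fit: alpha = 0.312 /Gy, beta = 0.0288 /Gy^2, PE = 0.513
```

189 of the 1000 genes are called temporally DE at FDR < 0.05; 185 of
the 200 simulated true responders are among them and only 4 calls are
false (empirical FDR 0.021, below the nominal 0.05). The estimated
variance prior (d₀ ≈ 3.9, s₀² ≈ 0.051) recovers the simulation's
hyperparameters (4, 0.05). The network stage keeps only edges with
posterior ≥ 0.95 under an estimated null proportion η₀ ≈ 1, and the
linear-quadratic fit recovers the simulated α = 0.30 /Gy, β = 0.03 /Gy²
and plating efficiency 0.5 from Poisson counts.

The same stages are available from the shell via the `radpipe` console
script (`radpipe simulate`, `radpipe de timecourse`, `radpipe gan
build`, `radpipe centrality rank`, `radpipe enrich`, `radpipe integrate
cna`, `radpipe clonogenic fit`, `radpipe pipeline run`), and
`radpipe pipeline run --config config.yaml` executes the full chain
(simulate → DE → early/late → network → centrality → enrichment →
copy-number integration) with a checksummed run manifest.

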