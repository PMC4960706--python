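"""Synthetic data generators with recorded ground truth.

Every input the pipeline consumes can be simulated here: a two-condition
(sham vs 8 Gy) time-course expression experiment on the 0.25–96 h grid
with three replicates, i.i.d. draws from a sparse Gaussian graphical
model for network reconstruction, gene-set collections with spiked
enrichment, segmented copy-number profiles, and Poisson colony counts
under the linear-quadratic survival law.

Each generator owns an RNG stream seeded from ``seed`` plus a fixed
per-generator offset, so adding or re-running one generator never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .splines import natural_spline_basis

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_timecourse",
    "gen_network_timeseries",
    "gen_gene_sets",
    "gen_cna_profile",
    "gen_colony_counts",
    "expected_colonies",
    "lq_survival",
]

DEFAULT_TIMEPOINTS = (0.25, 2.0, 7.0, 12.0, 24.0, 48.0, 72.0, 96.0)

# fixed per-generator seed offsets (independent streams per generator)
_OFF_TIMECOURSE = 101
_OFF_NETWORK = 211
_OFF_GENESETS = 307
_OFF_CNA = 401
_OFF_COLONY = 503


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters for the simulators.

    Defaults mirror the emulated experiment: 8 sampling times between
    0.25 and 96 h post irradiation, 3 independent replicates, and an
    inverse-chi-square hyperprior on gene variances (d0=4, s0_sq=0.05
    log2^2) so that the variance-moderation stage faces a correctly
    specified target.
    """

    n_genes: int = 2000
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    prop_de: float = 0.2
    effect_sd: float = 1.0
    d0: float = 4.0
    s0_sq: float = 0.05
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    baseline_coef_sd: float = 0.5
    network_n_nodes: int = 100
    network_n_edges: int = 40
    pcor_magnitude: float = 0.35
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("timepoints must be strictly increasing and positive")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if not 0.0 <= self.prop_de <= 1.0:
            raise ValueError("prop_de must lie in [0, 1]")
        if self.effect_sd < 0 or self.d0 <= 0 or self.s0_sq <= 0:
            raise ValueError("effect_sd >= 0 and d0, s0_sq > 0 required")
        max_edges = self.network_n_nodes * (self.network_n_nodes - 1) // 2
        if not 0 <= self.network_n_edges <= max_edges:
            raise ValueError(f"network_n_edges must lie in [0, {max_edges}]")
        if not 0.0 < self.pcor_magnitude < 1.0:
            raise ValueError("pcor_magnitude must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Recorded truth for a simulated dataset."""

    de_genes: set = field(default_factory=set)
    true_edges: set = field(default_factory=set)
    enriched_sets: set = field(default_factory=set)
    cna_truth: dict = field(default_factory=dict)
    lq_truth: tuple | None = None


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def gen_timecourse(config: SimulationConfig):
    """Simulate a two-condition spline time course on the log2 scale.

    Per gene g the control mean trajectory is ``mu_g(t) = b0 + B(t) @ beta``
    with a 3-df natural cubic spline basis B; treated samples add
    ``delta_g(t) = g0 + B(t) @ gamma`` with all treatment coefficients
    drawn N(0, effect_sd^2) iff g is a DE gene, else delta = 0.
    Residual noise is N(0, sigma_g^2) with
    sigma_g^2 ~ s0_sq * d0 / ChiSq(d0).

    Returns ``(expr, design, truth)``: genes x samples DataFrame, sample
    design table (index sample; columns condition, time_h, replicate),
    and the GroundTruth with ``de_genes`` recorded.
    """
    rng = np.random.default_rng(config.seed + _OFF_TIMECOURSE)
    times = np.asarray(config.timepoints, dtype=float)
    basis = natural_spline_basis(times, df=3)
    B = basis.basis  # T x 3

    genes = _gene_ids(config.n_genes)
    n_de = int(round(config.prop_de * config.n_genes))
    de_idx = rng.permutation(config.n_genes)[:n_de]
    de_mask = np.zeros(config.n_genes, dtype=bool)
    de_mask[de_idx] = True

    b0 = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    beta = rng.normal(0.0, config.baseline_coef_sd, (config.n_genes, 3))
    gamma0 = np.zeros(config.n_genes)
    gamma = np.zeros((config.n_genes, 3))
    if n_de and config.effect_sd > 0:
        gamma0[de_mask] = rng.normal(0.0, config.effect_sd, n_de)
        gamma[de_mask] = rng.normal(0.0, config.effect_sd, (n_de, 3))
    sigma2 = config.s0_sq * config.d0 / rng.chisquare(config.d0, config.n_genes)

    control_mean = b0[:, None] + beta @ B.T                      # G x T
    treated_mean = control_mean + gamma0[:, None] + gamma @ B.T  # G x T

    rows = []
    for cond in ("control", "treated"):
        for ti, t in enumerate(times):
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{cond}_t{ti}_r{r}", cond, t, r))
    design = pd.DataFrame(rows, columns=["sample", "condition", "time_h", "replicate"])
    design = design.set_index("sample")

    n_samples = len(design)
    mean = np.empty((config.n_genes, n_samples))
    for j, (_, row) in enumerate(design.iterrows()):
        ti = int(np.searchsorted(times, row["time_h"]))
        mean[:, j] = treated_mean[:, ti] if row["condition"] == "treated" else control_mean[:, ti]
    noise = rng.standard_normal((config.n_genes, n_samples)) * np.sqrt(sigma2)[:, None]
    expr = pd.DataFrame(mean + noise, index=genes, columns=design.index)

    truth = GroundTruth(de_genes={genes[i] for i in np.flatnonzero(de_mask)})
    return expr, design, truth


class InfeasibleNetworkError(ValueError):
    """Requested partial-correlation magnitude/density yields a non-PD precision."""


def gen_network_timeseries(config: SimulationConfig, n_samples: int | None = None):
    """Draw i.i.d. samples from a sparse Gaussian graphical model.

    A random graph with ``network_n_edges`` edges over
    ``network_n_nodes`` nodes defines the off-diagonal pattern of a
    precision matrix with unit diagonal and entries ``-pcor_magnitude``
    on edges, so that every true edge has partial correlation exactly
    ``+pcor_magnitude``.  Positive definiteness is verified on the
    smallest eigenvalue; infeasible settings raise
    :class:`InfeasibleNetworkError` naming that eigenvalue.

    ``n_samples`` defaults to ``len(timepoints) * n_replicates``.
    Returns ``(expr, truth)`` with expr genes x samples and
    ``truth.true_edges`` a set of sorted gene-id pairs.
    """
    rng = np.random.default_rng(config.seed + _OFF_NETWORK)
    p = config.network_n_nodes
    n = n_samples if n_samples is not None else len(config.timepoints) * config.n_replicates
    genes = _gene_ids(p, prefix="N")

    pairs = list(combinations(range(p), 2))
    edge_idx = rng.choice(len(pairs), size=config.network_n_edges, replace=False)
    edges = [pairs[i] for i in sorted(edge_idx)]

    omega = np.eye(p)
    for i, j in edges:
        omega[i, j] = omega[j, i] = -config.pcor_magnitude
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin <= 1e-8:
        raise InfeasibleNetworkError(
            f"precision matrix not positive definite for pcor_magnitude="
            f"{config.pcor_magnitude} at {config.network_n_edges} edges; "
            f"smallest eigenvalue {eigmin:.4g}"
        )
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)
    samples = rng.standard_normal((n, p)) @ chol.T

    expr = pd.DataFrame(
        samples.T, index=genes, columns=[f"s{k + 1:03d}" for k in range(n)]
    )
    truth = GroundTruth(true_edges={tuple(sorted((genes[i], genes[j]))) for i, j in edges})
    return expr, truth


def gen_gene_sets(
    universe,
    n_sets: int,
    size_range: tuple[int, int],
    enriched_in,
    seed: int,
    n_enriched_sets: int = 3,
    enriched_frac: float = 0.75,
):
    """Random gene sets plus designated sets oversampled from ``enriched_in``.

    Returns ``(collection, truth)`` where collection maps set name to
    ``(description, member list)`` (GMT-serializable) and
    ``truth.enriched_sets`` names the spiked sets.  With an empty
    ``enriched_in`` no set is flagged enriched.
    """
    rng = np.random.default_rng(seed + _OFF_GENESETS)
    universe = list(universe)
    enriched_in = [g for g in enriched_in if g in set(universe)]
    lo, hi = size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ValueError(f"size_range {size_range} outside [1, {len(universe)}]")

    collection: dict[str, tuple[str, list[str]]] = {}
    truth = GroundTruth()
    if not enriched_in:
        n_enriched_sets = 0
    others = [g for g in universe if g not in set(enriched_in)]
    for k in range(n_enriched_sets):
        size = int(rng.integers(lo, hi + 1))
        n_spike = min(len(enriched_in), max(1, int(round(enriched_frac * size))))
        members = list(rng.choice(enriched_in, size=n_spike, replace=False))
        n_fill = min(size - n_spike, len(others))
        if n_fill > 0:
            members += list(rng.choice(others, size=n_fill, replace=False))
        name = f"ENR{k + 1:03d}"
        collection[name] = ("spiked enriched set", members)
        truth.enriched_sets.add(name)
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        collection[f"SET{k + 1:03d}"] = ("random set", members)
    return collection, truth


def gen_cna_profile(genes_with_coords: pd.DataFrame, n_segments: int, seed: int):
    """Segmented copy-number profile covering each chromosome.

    ``genes_with_coords`` needs columns gene, chrom, midpoint.  Each
    chromosome is split into ``n_segments`` non-overlapping half-open
    segments [start, end) tiling [0, chrom span], each with a call in
    {-1, 0, +1}.  Returns ``(segments, truth)``: a segment table
    (chrom, start, end, call) and per-gene truth calls (the call of the
    segment containing the gene midpoint).
    """
    required = {"gene", "chrom", "midpoint"}
    if not required.issubset(genes_with_coords.columns):
        raise ValueError(f"genes_with_coords must have columns {sorted(required)}")
    rng = np.random.default_rng(seed + _OFF_CNA)
    seg_rows = []
    truth = GroundTruth()
    for chrom, grp in genes_with_coords.groupby("chrom", sort=True):
        length = int(grp["midpoint"].max()) + 1000
        if n_segments > 1:
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_segments - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [length]])
        calls = rng.choice([-1, 0, 1], size=n_segments)
        for s, e, c in zip(bounds[:-1], bounds[1:], calls):
            seg_rows.append((chrom, int(s), int(e), int(c)))
        # half-open containment: segment k covers [bounds[k], bounds[k+1])
        idx = np.searchsorted(bounds, grp["midpoint"].to_numpy(), side="right") - 1
        for gene, k in zip(grp["gene"], idx):
            truth.cna_truth[gene] = int(calls[min(k, n_segments - 1)])
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "call"])
    return segments, truth


def lq_survival(dose, alpha: float, beta: float):
    """Linear-quadratic surviving fraction S(D) = exp(-(alpha*D + beta*D^2))."""
    d = np.asarray(dose, dtype=float)
    return np.exp(-(alpha * d + beta * d * d))


def expected_colonies(alpha, beta, pe, dose, cells):
    """Expected colony count: cells * PE * S(dose)."""
    return np.asarray(cells, float) * pe * lq_survival(dose, alpha, beta)


def gen_colony_counts(
    alpha: float,
    beta: float,
    plating_efficiency,
    doses,
    cells_seeded,
    n_experiments: int,
    seed: int,
) -> pd.DataFrame:
    """Poisson colony counts under the linear-quadratic survival law.

    ``plating_efficiency`` may be a scalar (shared) or a sequence of
    per-experiment values in (0, 1].  One dish per (experiment, dose,
    seeding density).  Returns a table with columns experiment, dose,
    cells, colonies.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    pe = np.broadcast_to(np.asarray(plating_efficiency, dtype=float), (n_experiments,))
    if np.any((pe <= 0) | (pe > 1)):
        raise ValueError("plating efficiencies must lie in (0, 1]")
    rng = np.random.default_rng(seed + _OFF_COLONY)
    rows = []
    for e in range(n_experiments):
        for d in doses:
            for cells in np.atleast_1d(cells_seeded):
                mu = float(expected_colonies(alpha, beta, pe[e], d, cells))
                rows.append((f"exp{e + 1}", float(d), int(cells), int(rng.poisson(mu))))
    table = pd.DataFrame(rows, columns=["experiment", "dose", "cells", "colonies"])
    return table


def default_gene_annotation(genes, n_chromosomes: int = 5, spacing: int = 10_000) -> pd.DataFrame:
    """Synthetic gene coordinates: genes dealt round-robin onto chromosomes."""
    genes = list(genes)
    rows = []
    per_chrom = {c: 0 for c in range(n_chromosomes)}
    for i, g in enumerate(genes):
        c = i % n_chromosomes
        rows.append((g, f"chr{c + 1}", per_chrom[c] * spacing + spacing // 2))
        per_chrom[c] += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "midpoint"])
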