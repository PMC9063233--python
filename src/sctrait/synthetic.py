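"""Seeded synthetic data with known ground truth.

Two generators make every downstream stage testable without any external
download:

* :func:`generate_gwas` draws genome-ordered signed marker effects with
  block-wise correlation (an LD proxy) and optional variance inflation
  inside designated gene windows, together with a marker-aligned gene
  annotation and gene-set catalog on the simulated genome.
* :func:`generate_sc` draws negative-binomial count matrices with cell-type
  structure, a designated cycling subpopulation with elevated expression of
  a cell-cycle panel, and gene modules whose per-time-point means follow
  configurable trajectories (rising-and-falling "peaked" versus
  rising-and-holding "sustained" shapes of an LPS-style time course).

All randomness flows from the config seed through named SeedSequence
substreams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cellstate import GenePanel
from .mapping import GeneSetCatalog, MarkerEffects

__all__ = [
    "GwasSimConfig",
    "ScSimConfig",
    "SimulatedGwas",
    "SimulatedSc",
    "generate_gwas",
    "generate_sc",
    "default_panels",
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_TRAJECTORIES",
]

DEFAULT_TIMEPOINTS = ["Control", "LPS_2h", "LPS_4h", "LPS_8h"]

# Qualitative shapes of the three LPS-response programs: antiviral and peaked
# inflammatory rise to an interior maximum and return to baseline by the last
# time point; sustained inflammatory rises and holds (slight late decrease).
DEFAULT_TRAJECTORIES: dict[str, list[float]] = {
    "core_antiviral": [1.0, 2.2, 3.0, 1.1],
    "peaked_inflammatory": [1.0, 3.0, 3.5, 1.0],
    "sustained_inflammatory": [1.0, 2.0, 3.0, 2.7],
}


@dataclass
class GwasSimConfig:
    """Parameters of the synthetic GWAS summary-statistic genome.

    Markers sit every ``marker_spacing_bp`` on each chromosome.  Effects are
    drawn from an equicorrelated factor model: within each block of
    ``ld_block_size`` consecutive markers,
    ``b = sd * (sqrt(ld_rho) * z_block + sqrt(1 - ld_rho) * z_marker)``,
    giving exact pairwise correlation ``ld_rho`` — a stand-in for LD used
    for calibration testing, not a model of any real panel.  Markers inside
    enriched gene bodies have ``sd`` multiplied by ``enrichment_lambda``.
    """

    n_chromosomes: int = 3
    markers_per_chromosome: int = 400
    marker_spacing_bp: int = 10_000
    effect_sd: float = 1.0
    ld_block_size: int = 10
    ld_rho: float = 0.5
    enrichment_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.markers_per_chromosome, self.ld_block_size) < 1:
            raise ValueError("counts must be >= 1")
        if self.marker_spacing_bp < 1:
            raise ValueError("marker_spacing_bp must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be positive")
        if self.enrichment_lambda < 1.0:
            raise ValueError("enrichment_lambda must be >= 1")


@dataclass
class SimulatedGwas:
    """Generator output: effects plus the genome they live on."""

    effects: MarkerEffects
    annotation: pd.DataFrame
    catalog: GeneSetCatalog
    enriched_marker_index: np.ndarray  # truth: markers whose SD was inflated


def _fabricate_genome(
    config: GwasSimConfig,
    rng: np.random.Generator,
    n_sets: int,
    genes_per_set: int,
    gene_span_markers: int,
) -> tuple[pd.DataFrame, GeneSetCatalog]:
    """Place marker-aligned, non-overlapping genes and group them into sets.

    Candidate slots are spaced so that even 20-kb windows of neighbouring
    genes stay disjoint at the default marker spacing; each gene covers
    ``gene_span_markers`` consecutive markers.
    """
    spacing = config.marker_spacing_bp
    per_chrom = config.markers_per_chromosome
    step = gene_span_markers + 5
    slots = [
        (c, s)
        for c in range(1, config.n_chromosomes + 1)
        for s in range(0, per_chrom - gene_span_markers + 1, step)
    ]
    n_genes = n_sets * genes_per_set
    if n_genes > len(slots):
        raise ValueError(
            f"genome too small: {n_genes} genes requested, {len(slots)} slots available"
        )
    chosen = rng.choice(len(slots), size=n_genes, replace=False)
    chosen = np.sort(chosen)
    rows = []
    for gi, si in enumerate(chosen):
        c, s = slots[si]
        first_pos = (s + 1) * spacing          # 1-based position of first marker
        last_pos = (s + gene_span_markers) * spacing
        rows.append((f"gene{gi:04d}", str(c), first_pos - 1, last_pos, "+"))
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    perm = rng.permutation(n_genes)
    sets = {
        f"set{k:02d}": [f"gene{perm[k * genes_per_set + j]:04d}" for j in range(genes_per_set)]
        for k in range(n_sets)
    }
    return annotation, GeneSetCatalog(sets, provenance="synthetic")


def generate_gwas(
    config: GwasSimConfig,
    enriched_sets: GeneSetCatalog | None = None,
    *,
    annotation: pd.DataFrame | None = None,
    catalog: GeneSetCatalog | None = None,
    n_sets: int = 8,
    genes_per_set: int = 10,
    gene_span_markers: int = 4,
    trait_id: str = "trait",
) -> SimulatedGwas:
    """Simulate genome-ordered marker effects with optional set enrichment.

    When ``annotation``/``catalog`` are not supplied, genes and gene sets
    are fabricated on the simulated genome.  ``enriched_sets`` names the
    sets whose genes get their effect SD multiplied by
    ``config.enrichment_lambda`` (markers inside the gene bodies); its genes
    must exist in the annotation.
    """
    ss = np.random.SeedSequence([int(config.seed), 0x67776173])  # "gwas" stream
    rng_genome, rng_effects = (np.random.default_rng(s) for s in ss.spawn(2))

    if annotation is None or catalog is None:
        annotation, catalog = _fabricate_genome(
            config, rng_genome, n_sets, genes_per_set, gene_span_markers
        )

    spacing = config.marker_spacing_bp
    per_chrom = config.markers_per_chromosome
    chroms = np.repeat(
        [str(c) for c in range(1, config.n_chromosomes + 1)], per_chrom
    ).astype(object)
    pos = np.tile(np.arange(1, per_chrom + 1) * spacing, config.n_chromosomes)
    m = len(pos)
    marker_id = np.array([f"m{c}_{p}" for c, p in zip(chroms, pos)], dtype=object)

    sd = np.full(m, config.effect_sd)
    enriched_idx = np.empty(0, dtype=np.int64)
    if enriched_sets is not None and len(enriched_sets) > 0:
        known = set(annotation["gene_id"])
        ann = annotation.set_index("gene_id")
        pos0 = pos - 1
        hit = np.zeros(m, dtype=bool)
        for set_id, genes in enriched_sets:
            for g in genes:
                if g not in known:
                    raise ValueError(f"enriched gene {g!r} not on the simulated genome")
                row = ann.loc[g]
                on_chrom = chroms == str(row["chrom"])
                hit |= on_chrom & (pos0 >= row["start"]) & (pos0 < row["end"])
        enriched_idx = np.flatnonzero(hit)
        sd[enriched_idx] *= config.enrichment_lambda

    n_blocks = -(-m // config.ld_block_size)
    z_block = np.repeat(rng_effects.standard_normal(n_blocks), config.ld_block_size)[:m]
    z_marker = rng_effects.standard_normal(m)
    b = sd * (
        np.sqrt(config.ld_rho) * z_block + np.sqrt(1.0 - config.ld_rho) * z_marker
    )

    effects = MarkerEffects(
        marker_id=marker_id, chrom=chroms, pos=pos, b=b, trait_id=trait_id,
        chrom_order=[str(c) for c in range(1, config.n_chromosomes + 1)],
    )
    return SimulatedGwas(effects, annotation, catalog, enriched_idx)


@dataclass
class ScSimConfig:
    """Parameters of the synthetic single-cell count matrix.

    ``n_cells_per_group`` cells are drawn for every (cluster, time point)
    pair.  Counts are negative binomial with mean ``mu`` and inverse
    dispersion ``nb_dispersion`` (variance ``mu + mu^2 / nb_dispersion``).
    Per cluster, ``cycling_fraction_per_cluster`` of cells have the
    cell-cycle panel means multiplied by ``cycle_effect``; module genes have
    per-time-point means scaled by ``module_trajectories``.
    """

    n_genes: int = 1000
    n_cells_per_group: int = 200
    cluster_labels: list[str] = field(
        default_factory=lambda: ["monocytes", "CD4_T", "B_cells"]
    )
    timepoint_labels: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    cycling_fraction_per_cluster: dict[str, float] = field(default_factory=dict)
    cycle_effect: float = 5.0
    module_trajectories: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TRAJECTORIES.items()}
    )
    nb_dispersion: float = 2.0
    baseline_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_group < 1:
            raise ValueError("counts must be >= 1")
        if not self.cluster_labels:
            raise ValueError("at least one cluster label is required")
        if not self.timepoint_labels:
            raise ValueError("timepoint_labels must be non-empty")
        for cl, f in self.cycling_fraction_per_cluster.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"cycling fraction for {cl!r} must be in [0, 1]")
            if cl not in self.cluster_labels:
                raise ValueError(f"unknown cluster {cl!r} in cycling fractions")
        for mod, traj in self.module_trajectories.items():
            if len(traj) != len(self.timepoint_labels):
                raise ValueError(
                    f"trajectory for {mod!r} must have one multiplier per time point"
                )
            if any(t <= 0 for t in traj):
                raise ValueError("trajectory multipliers must be > 0")
        if self.cycle_effect <= 1:
            raise ValueError("cycle_effect must be > 1")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion and baseline_mean must be positive")


@dataclass
class SimulatedSc:
    """Generator output: counts plus the mean model that produced them.

    ``adata.obs`` carries cluster, timepoint and the true cycling flag;
    ``expected_mean`` exposes the exact negative-binomial mean vector of any
    (cluster, timepoint, cycling) stratum for law-of-large-numbers checks.
    """

    adata: ad.AnnData
    config: ScSimConfig
    _means: np.ndarray  # (n_clusters, n_timepoints, 2, n_genes)

    def expected_mean(self, cluster: str, timepoint: str, cycling: bool) -> np.ndarray:
        ci = self.config.cluster_labels.index(cluster)
        ti = self.config.timepoint_labels.index(timepoint)
        return self._means[ci, ti, int(cycling)]


def default_panels(
    n_genes: int,
    module_ids: Sequence[str] = tuple(DEFAULT_TRAJECTORIES),
    module_size: int = 30,
) -> tuple[list[GenePanel], list[GenePanel]]:
    """Disjoint cell-cycle (43 G1/S + 55 G2/M) and module panels on g#### ids."""
    need = 98 + module_size * len(module_ids)
    if n_genes < need:
        raise ValueError(f"need at least {need} genes for the default panels")
    ids = [f"g{i:04d}" for i in range(n_genes)]
    cycle = [GenePanel("G1S", ids[:43]), GenePanel("G2M", ids[43:98])]
    modules = [
        GenePanel(mid, ids[98 + k * module_size : 98 + (k + 1) * module_size])
        for k, mid in enumerate(module_ids)
    ]
    return cycle, modules


def _panel_index(genes: Sequence[str], var_names: pd.Index) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(var_names)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise ValueError(f"panel genes outside the simulated matrix: {missing[:5]}")
    return np.array([lookup[g] for g in genes], dtype=np.int64)


def generate_sc(
    config: ScSimConfig,
    cycle_panels: GenePanel | Sequence[GenePanel],
    module_panels: Sequence[GenePanel] = (),
) -> SimulatedSc:
    """Simulate a counts matrix with cycling cells and module trajectories.

    All panels must be pairwise disjoint; the true cycling status of every
    cell is returned in ``obs["true_cycling"]`` so recovery tests need no
    side channel.
    """
    if isinstance(cycle_panels, GenePanel):
        cycle_panels = [cycle_panels]
    all_panels = list(cycle_panels) + list(module_panels)
    seen: dict[str, str] = {}
    for p in all_panels:
        for g in p.genes:
            if g in seen:
                raise ValueError(
                    f"gene {g!r} appears in panels {seen[g]!r} and {p.panel_id!r}"
                )
            seen[g] = p.panel_id

    ss = np.random.SeedSequence([int(config.seed), 0x73696D73])  # "sims" stream
    rng_model, rng_flags, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    var_names = pd.Index([f"g{i:04d}" for i in range(config.n_genes)], name="gene_id")
    cycle_idx = np.concatenate([_panel_index(p.genes, var_names) for p in cycle_panels])
    module_idx = {p.panel_id: _panel_index(p.genes, var_names) for p in module_panels}
    unknown = set(module_idx) - set(config.module_trajectories)
    if unknown:
        raise ValueError(f"no trajectory configured for modules: {sorted(unknown)}")

    G = config.n_genes
    clusters, tps = config.cluster_labels, config.timepoint_labels

    # gene baselines: lognormal spread around baseline_mean (unit expectation)
    sigma = 0.4
    base = config.baseline_mean * rng_model.lognormal(-0.5 * sigma**2, sigma, size=G)
    # cluster signatures on non-panel genes only, so panel scores compare
    # cleanly across clusters
    panel_mask = np.zeros(G, dtype=bool)
    panel_mask[cycle_idx] = True
    for idx in module_idx.values():
        panel_mask[idx] = True
    cluster_fold = np.ones((len(clusters), G))
    free = np.flatnonzero(~panel_mask)
    for ci in range(len(clusters)):
        sig = rng_model.choice(free, size=max(1, len(free) // 10), replace=False)
        cluster_fold[ci, sig] = rng_model.lognormal(0.0, 0.5, size=len(sig))

    means = np.ones((len(clusters), len(tps), 2, G))
    for ci in range(len(clusters)):
        for ti, tp in enumerate(tps):
            mu = base * cluster_fold[ci]
            mu = mu.copy()
            for mod, idx in module_idx.items():
                mu[idx] = mu[idx] * config.module_trajectories[mod][ti]
            means[ci, ti, 0] = mu
            cyc = mu.copy()
            cyc[cycle_idx] *= config.cycle_effect
            means[ci, ti, 1] = cyc

    n_per = config.n_cells_per_group
    theta = config.nb_dispersion
    blocks, obs_rows = [], []
    for ci, cl in enumerate(clusters):
        frac = config.cycling_fraction_per_cluster.get(cl, 0.0)
        for ti, tp in enumerate(tps):
            n_cyc = int(round(frac * n_per))
            flags = np.zeros(n_per, dtype=bool)
            flags[rng_flags.choice(n_per, size=n_cyc, replace=False)] = True
            mu_cells = means[ci, ti, flags.astype(int)]  # (n_per, G)
            counts = rng_counts.negative_binomial(theta, theta / (theta + mu_cells))
            blocks.append(counts)
            for j in range(n_per):
                obs_rows.append((f"{cl}_{tp}_c{j}", cl, tp, bool(flags[j])))

    X = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "cluster", "timepoint", "true_cycling"]
    ).set_index("cell_id")
    obs["cluster"] = pd.Categorical(obs["cluster"], categories=clusters)
    obs["timepoint"] = pd.Categorical(obs["timepoint"], categories=tps, ordered=True)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=var_names))
    return SimulatedSc(adata, config, means)
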