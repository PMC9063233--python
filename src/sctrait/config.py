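"""Run configuration and the end-to-end synthetic driver.

``RunConfig`` mirrors the CLI flags in one YAML-editable structure; defaults
follow the analysis conventions of the pipeline (20-kb gene windows, 10,000
rotations, FDR 0.05).  :func:`run_all` executes
simulate -> map -> enrich -> cellcycle -> module-score -> pseudocell and
writes a JSON manifest (versions, seeds, parameters, output hashes) so a
re-run with the same config can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cellstate import (
    classify_proliferating,
    classify_trajectory,
    cycle_index,
    cycle_score,
    module_score,
    normalize,
    pseudocell_aggregate,
)
from .enrichment import run_grid
from .mapping import GeneSetCatalog
from .synthetic import (
    GwasSimConfig,
    ScSimConfig,
    default_panels,
    generate_gwas,
    generate_sc,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    With ``synthetic=True`` (default) all inputs are generated under the run
    seed; otherwise the ``*_path`` fields must point at existing files.
    """

    seed: int = 0
    outdir: str = "sctrait_run"
    synthetic: bool = True
    # enrichment conventions
    window_bp: int = 20_000
    n_perm: int = 10_000
    alpha_fdr: float = 0.05
    proliferation_threshold: str = "cluster_mean"  # or "grand_mean"
    # synthetic-mode scale
    n_traits: int = 3
    n_sets: int = 8
    genes_per_set: int = 10
    enriched_set: str | None = "set00"  # enriched in the first trait
    gwas: dict = field(default_factory=dict)  # GwasSimConfig overrides
    sc: dict = field(default_factory=dict)    # ScSimConfig overrides
    # file-mode inputs
    gwas_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    genesets_path: str | None = None
    mtx_dir: str | None = None
    panels_path: str | None = None
    # cell-state parameters
    pseudocell_size: int = 100
    n_pseudocells: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(data) - known:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(value, name: str):
    if not value:
        raise ValueError(f"config field {name!r} is required when synthetic=false")
    return value


def _load_inputs(config: RunConfig, outdir: Path):
    """Produce (traits, annotation, catalog, adata, cycle_panels, module_panels)."""
    if config.synthetic:
        gw_cfg = GwasSimConfig(seed=config.seed, **config.gwas)
        base = generate_gwas(
            gw_cfg, n_sets=config.n_sets, genes_per_set=config.genes_per_set,
            trait_id="trait00",
        )
        annotation, catalog = base.annotation, base.catalog
        traits = []
        for t in range(config.n_traits):
            enriched = None
            cfg_t = dataclasses.replace(
                gw_cfg,
                seed=int(np.random.SeedSequence([config.seed, 101, t]).generate_state(1)[0] % (2**31)),
            )
            if t == 0 and config.enriched_set and gw_cfg.enrichment_lambda > 1:
                enriched = GeneSetCatalog(
                    {config.enriched_set: catalog.sets[config.enriched_set]}
                )
            sim = generate_gwas(
                cfg_t, enriched, annotation=annotation, catalog=catalog,
                trait_id=f"trait{t:02d}",
            )
            traits.append(sim.effects)
        sc_cfg = ScSimConfig(seed=config.seed, **config.sc)
        cycle_panels, module_panels = default_panels(sc_cfg.n_genes)
        adata = generate_sc(sc_cfg, cycle_panels, module_panels).adata

        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        for eff in traits:
            io.write_gwas_tsv(eff, inputs / f"{eff.trait_id}.gwas.tsv")
        io.write_bed(annotation, inputs / "genes.bed")
        io.write_gene_sets(catalog, inputs / "gene_sets.tsv")
        io.write_panels(cycle_panels + module_panels, inputs / "panels.tsv")
        io.write_mtx_bundle(adata, inputs / "counts")
    else:
        traits = [io.read_gwas_tsv(p) for p in _require(config.gwas_paths, "gwas_paths")]
        annotation = io.read_annotation(_require(config.annotation_path, "annotation_path"))
        catalog = io.read_gene_sets(_require(config.genesets_path, "genesets_path"))
        adata = io.read_mtx_bundle(_require(config.mtx_dir, "mtx_dir"))
        panels = io.read_panels(_require(config.panels_path, "panels_path"))
        cycle_panels = [p for p in panels if p.panel_id in ("G1S", "G2M")]
        module_panels = [p for p in panels if p.panel_id not in ("G1S", "G2M")]
        if not cycle_panels:
            raise ValueError("panels file contains no G1S/G2M cell-cycle panel")
    return traits, annotation, catalog, adata, cycle_panels, module_panels


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate" if config.synthetic else "load-inputs"
    try:
        traits, annotation, catalog, adata, cycle_panels, module_panels = _load_inputs(
            config, outdir
        )

        stage = "enrich"
        grid = run_grid(
            traits, catalog, annotation,
            window_bp=config.window_bp, n_perm=config.n_perm, seed=config.seed,
        )
        grid.to_csv(outdir / "enrichment_grid.tsv", sep="\t", index=False)

        stage = "cellcycle"
        norm = normalize(adata)
        scores = cycle_score(norm, cycle_panels)
        flags, tau = classify_proliferating(
            scores, norm.obs["cluster"], threshold=config.proliferation_threshold
        )
        flags.to_frame().assign(cycle_score=scores).to_csv(
            outdir / "proliferation_flags.tsv", sep="\t"
        )
        idx = cycle_index(flags, norm.obs[["cluster", "timepoint"]])
        idx.reset_index().to_csv(outdir / "cycle_index.tsv", sep="\t", index=False)

        stage = "module-score"
        if module_panels:
            ms = module_score(norm, module_panels, group_key="timepoint")
            ms.to_csv(outdir / "module_scores.tsv", sep="\t")
            labels = {mod: classify_trajectory(ms.loc[mod].to_numpy()) for mod in ms.index}
            pd.Series(labels, name="pattern").rename_axis("module").reset_index().to_csv(
                outdir / "module_patterns.tsv", sep="\t", index=False
            )

        stage = "pseudocell"
        pcs = pseudocell_aggregate(
            norm, cluster_key="cluster", size=config.pseudocell_size,
            n_pseudocells=config.n_pseudocells, seed=config.seed,
        )
        pc_frame = pd.DataFrame(pcs.X, index=pcs.obs_names, columns=pcs.var_names)
        pc_frame.to_csv(outdir / "pseudocells.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "sctrait",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "proliferation_threshold_value": tau,
        "outputs": {rel: _sha256(outdir / rel) for rel in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
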