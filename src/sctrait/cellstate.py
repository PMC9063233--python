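"""Cell-state scoring on a single-cell expression matrix.

Three analyses share this module: the cell-cycle proliferation index (the
fraction of cells in a group whose mean expression of a G1/S + G2/M gene
panel exceeds the across-cluster average), time-course scoring of gene
modules (e.g. the core antiviral, peaked inflammatory and sustained
inflammatory LPS-response programs), and pseudocell aggregation (averages of
fixed-size random cell samples within a cluster, used to stabilise
co-expression estimation).

The in-memory container is :class:`anndata.AnnData` with cells as
observations.  ``normalize`` must run before any scoring operation: it
scales each cell to the median total count and applies log1p, keeping the
raw counts in ``layers["counts"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GenePanel",
    "normalize",
    "cycle_score",
    "classify_proliferating",
    "cycle_index",
    "module_score",
    "classify_trajectory",
    "pseudocell_aggregate",
]


@dataclass
class GenePanel:
    """A named gene list (cell-cycle phase panel or response module)."""

    panel_id: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise ValueError(f"panel {self.panel_id!r} is empty")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Median-depth scaling followed by log1p.

    Cells with zero total count are dropped (and counted in the provenance
    record).  Raw counts are preserved in ``layers["counts"]``; ``X`` holds
    the normalized values afterwards.  Returns a new AnnData.
    """
    import scanpy as sc

    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("normalize: dropped %d zero-count cells", n_dropped)
    out = adata[keep].copy()
    out.layers["counts"] = out.X.copy()
    median_total = float(np.median(totals[keep]))
    sc.pp.normalize_total(out, target_sum=None)  # scanpy's None = median depth
    sc.pp.log1p(out)
    out.uns["normalization"] = {
        "method": "median_depth_log1p",
        "median_total": median_total,
        "n_cells_dropped": n_dropped,
    }
    return out


def _require_normalized(adata: ad.AnnData) -> None:
    if "normalization" not in adata.uns:
        raise ValueError("matrix is not normalized; call normalize() first")


def _present_genes(adata: ad.AnnData, panel: GenePanel) -> list[str]:
    present = [g for g in panel.genes if g in adata.var_names]
    n_missing = len(panel.genes) - len(present)
    if n_missing:
        logger.info("panel %s: %d genes absent from matrix", panel.panel_id, n_missing)
    if not present:
        raise ValueError(f"no gene of panel {panel.panel_id!r} is present in the matrix")
    return present


def cycle_score(
    adata: ad.AnnData,
    panels: GenePanel | Sequence[GenePanel],
    statistic: str = "mean",
) -> pd.Series:
    """Per-cell cell-cycle score over the (G1/S + G2/M) panel.

    The score is the per-cell mean of normalized expression over the panel
    genes present in the matrix (``statistic="total"`` gives the unscaled
    sum instead; the two orderings of cells are identical when no panel gene
    is missing).
    """
    _require_normalized(adata)
    if isinstance(panels, GenePanel):
        panels = [panels]
    combined = GenePanel(
        "+".join(p.panel_id for p in panels),
        [g for p in panels for g in p.genes],
    )
    present = _present_genes(adata, combined)
    X = _dense(adata[:, present].X)
    vals = X.sum(axis=1) if statistic == "total" else X.mean(axis=1)
    return pd.Series(vals, index=adata.obs_names, name="cycle_score")


def classify_proliferating(
    scores: pd.Series,
    clusters: pd.Series,
    threshold: str = "cluster_mean",
) -> tuple[pd.Series, float]:
    """Flag cells scoring strictly above the across-cluster average.

    ``threshold="cluster_mean"`` (default) uses the unweighted mean of
    per-cluster mean scores, so small clusters weigh as much as large ones;
    ``"grand_mean"`` uses the mean over all cells.  Returns the boolean
    flags and the threshold used.
    """
    scores, clusters = scores.align(clusters, join="inner")
    if threshold == "cluster_mean":
        tau = float(scores.groupby(clusters, observed=True).mean().mean())
    elif threshold == "grand_mean":
        tau = float(scores.mean())
    else:
        raise ValueError(f"unknown threshold flavor {threshold!r}")
    flags = scores > tau  # strict: a cell at exactly the average is not proliferating
    return flags.rename("proliferating"), tau


def cycle_index(flags: pd.Series, groups: pd.Series | pd.DataFrame) -> pd.Series:
    """Fraction of proliferating cells per group (the cell-cycle index).

    ``groups`` may be a single label series (cluster or time point) or a
    DataFrame of several label columns, whose cross defines the groups.
    Groups with no cells simply do not appear.
    """
    if isinstance(groups, pd.DataFrame):
        keys = [groups[c] for c in groups.columns]
    else:
        keys = groups
    idx = flags.groupby(keys, observed=True).mean()
    return idx.rename("cycle_index")


def _group_order(labels: pd.Series, order: Sequence[str] | None) -> list[str]:
    if order is not None:
        return list(order)
    if isinstance(labels.dtype, pd.CategoricalDtype):
        return [c for c in labels.cat.categories if c in set(labels)]
    return list(pd.unique(labels))


def module_score(
    adata: ad.AnnData,
    panels: Sequence[GenePanel],
    group_key: str,
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Scaled module expression per group (module x group table).

    Per gene, the mean normalized expression is computed per group and
    z-scaled across groups (population SD); a module's score in a group is
    the mean of these scaled values over its genes.  Genes with zero
    variance across groups contribute 0.  Group order follows ``order``, a
    categorical ordering on the obs column, or first appearance.
    """
    _require_normalized(adata)
    labels = adata.obs[group_key]
    groups = _group_order(labels, order)
    if isinstance(panels, GenePanel):
        panels = [panels]

    rows = {}
    for panel in panels:
        present = _present_genes(adata, panel)
        X = _dense(adata[:, present].X).astype(np.float64)
        means = np.vstack([X[np.asarray(labels == g)].mean(axis=0) for g in groups])
        mu = means.mean(axis=0)
        sd = means.std(axis=0)  # population SD across groups
        scaled = np.zeros_like(means)
        nz = sd > 0
        scaled[:, nz] = (means[:, nz] - mu[nz]) / sd[nz]
        rows[panel.panel_id] = scaled.mean(axis=1)
    return pd.DataFrame(rows, index=pd.Index(groups, name=group_key)).T


def classify_trajectory(scores: Sequence[float], tolerance: float = 0.25) -> str:
    """Label an ordered time-course as sustained, peaked or flat.

    sustained: the maximum is after the first time point and the final value
    stays more than ``tolerance`` above the first (rise and hold).
    peaked: the maximum is at an interior time point and the final value
    returns to within ``tolerance`` of the first (rise and fall back).
    flat: anything else.  ``tolerance`` is in the scaled-score units of
    :func:`module_score`.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        raise ValueError("trajectory classification needs at least 3 time points")
    imax = int(np.argmax(s))
    if imax > 0 and s[-1] > s[0] + tolerance:
        return "sustained"
    if 0 < imax < s.size - 1 and abs(s[-1] - s[0]) <= tolerance:
        return "peaked"
    return "flat"


def pseudocell_aggregate(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    size: int = 100,
    n_pseudocells: int = 50,
    seed: int | np.random.Generator = 0,
) -> ad.AnnData:
    """Average expression of random fixed-size cell samples per cluster.

    For each cluster with at least ``size`` cells, draws ``n_pseudocells``
    samples of ``size`` cells without replacement (independent draws, so a
    cell can recur across draws) and averages ``X`` per gene.  Clusters
    smaller than ``size`` are skipped with a warning, mirroring the usual
    exclusion of tiny clusters from co-expression analysis.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = adata.obs[cluster_key]
    profiles, meta = [], []
    for cl in _group_order(labels, None):
        cells = np.flatnonzero(np.asarray(labels == cl))
        if cells.size < size:
            logger.warning(
                "pseudocell: skipping cluster %r (%d cells < size %d)",
                cl, cells.size, size,
            )
            continue
        X = _dense(adata.X[cells])
        for d in range(n_pseudocells):
            take = rng.choice(cells.size, size=size, replace=False)
            profiles.append(X[take].mean(axis=0))
            meta.append((f"{cl}_pc{d}", cl, d))
    if not profiles:
        raise ValueError(f"no cluster has at least {size} cells")
    obs = pd.DataFrame(meta, columns=["pseudocell_id", cluster_key, "draw"]).set_index(
        "pseudocell_id"
    )
    out = ad.AnnData(X=np.vstack(profiles), obs=obs, var=adata.var.copy())
    out.uns["pseudocell"] = {"size": size, "n_pseudocells": n_pseudocells}
    return out
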