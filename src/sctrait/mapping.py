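"""Gene-set window resolution and marker-to-set mapping.

Marker-set association tests need two things from the genome: a single fixed
ordering of all markers (the rotation null rotates one genome-wide vector),
and, per gene set, the indices of markers that fall inside windows around the
set's genes.  This module provides both.

Coordinate conventions
----------------------
All internal intervals are 0-based half-open, as in BED.  GWAS marker
positions are 1-based on input and converted once (``pos - 1``) at the
membership test.  A GFF3 1-based inclusive interval ``[a, b]`` becomes
``[a-1, b)`` on read.  Membership is ``start <= pos0 < end``.

Chromosome order is the natural sort (1, 2, ..., 10, ..., X) unless an
explicit order is supplied; markers and annotation use the same order, which
is what makes the rotation null well defined.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerEffects",
    "GeneSetCatalog",
    "SetWindows",
    "natural_chrom_order",
    "resolve_windows",
    "markers_in_set",
]


def natural_chrom_order(labels: Iterable[str]) -> list[str]:
    """Return chromosome labels in natural order (1, 2, ..., 10, ..., X, Y)."""

    def key(lab: str):
        s = str(lab)
        s = s[3:] if s.lower().startswith("chr") else s
        return (0, int(s)) if s.isdigit() else (1, s)

    return sorted({str(x) for x in labels}, key=key)


@dataclass
class MarkerEffects:
    """Genome-ordered signed marker effects for one trait.

    Parameters
    ----------
    marker_id, chrom, pos, b
        Equal-length arrays; ``pos`` is 1-based.  Construction sorts the
        arrays by (chromosome order, position) so that the stored vector is
        the genome-ordered substrate of the rotation null.
    trait_id
        Label of the trait the single-marker effects belong to.
    chrom_order
        Declared chromosome order; defaults to the natural sort of the
        chromosomes present.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    b: np.ndarray
    trait_id: str = "trait"
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object).astype(str).astype(object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.b = np.asarray(self.b, dtype=np.float64)
        n = len(self.marker_id)
        if not (len(self.chrom) == len(self.pos) == len(self.b) == n):
            raise ValueError("marker_id, chrom, pos and b must have equal length")
        if n < 1:
            raise ValueError("at least one marker is required")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("marker effects b must be finite")
        if not self.chrom_order:
            self.chrom_order = natural_chrom_order(self.chrom)
        missing = set(map(str, self.chrom)) - set(self.chrom_order)
        if missing:
            raise ValueError(f"chromosomes not in declared order: {sorted(missing)}")
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        order = np.lexsort((self.pos, np.array([rank[c] for c in self.chrom])))
        for name in ("marker_id", "chrom", "pos", "b"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def m(self) -> int:
        """Total number of markers."""
        return len(self.b)

    @property
    def b2(self) -> np.ndarray:
        """Genome-ordered squared effects, the vector the null rotates."""
        return self.b**2

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        trait_id: str = "trait",
        chrom_order: Sequence[str] | None = None,
    ) -> "MarkerEffects":
        """Build from a data frame with columns marker, chrom, pos, b."""
        return cls(
            marker_id=df["marker"].to_numpy(),
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            b=df["b"].to_numpy(),
            trait_id=trait_id,
            chrom_order=list(chrom_order) if chrom_order else [],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_id, "chrom": self.chrom, "pos": self.pos, "b": self.b}
        )


@dataclass
class GeneSetCatalog:
    """Named gene lists (cluster marker genes or DEG sets).

    ``sets`` maps set_id to a list of gene ids; ``provenance`` is a free-text
    label (e.g. ``"cell_type_markers"`` or ``"pairwise_degs"``).
    """

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {sid!r} is empty")
        self.sets = {str(k): [str(g) for g in v] for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].astype(str)
    ann["start"] = ann["start"].astype(np.int64)
    ann["end"] = ann["end"].astype(np.int64)
    if (ann["start"] < 0).any() or (ann["start"] >= ann["end"]).any():
        raise ValueError("annotation requires 0 <= start < end")
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dups[:5]}")
    return ann


@dataclass
class SetWindows:
    """Resolved genomic windows for one catalog.

    ``windows`` maps set_id to a frame (chrom, start, end) of per-gene windows
    (unmerged; the membership test de-duplicates markers).  Sets whose genes
    are all absent from the annotation appear in ``excluded`` with a reason
    and are not tested.
    """

    windows: dict[str, pd.DataFrame]
    n_genes_resolved: dict[str, int]
    n_genes_dropped: dict[str, int]
    excluded: dict[str, str]
    window_bp: int


def resolve_windows(
    catalog: GeneSetCatalog,
    annotation: pd.DataFrame,
    window_bp: int = 20_000,
) -> SetWindows:
    """Extend each set's genes by ``window_bp`` on both sides, clipped at 0.

    Genes absent from the annotation are dropped and counted; a set with no
    resolvable gene is excluded (recorded, not an error).  The default 20 kb
    flank targets potential cis-regulatory variants near the gene body.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    ann = _validate_annotation(annotation).set_index("gene_id")

    windows: dict[str, pd.DataFrame] = {}
    n_resolved: dict[str, int] = {}
    n_dropped: dict[str, int] = {}
    excluded: dict[str, str] = {}
    for set_id, genes in catalog:
        present = [g for g in genes if g in ann.index]
        n_resolved[set_id] = len(present)
        n_dropped[set_id] = len(genes) - len(present)
        if n_dropped[set_id]:
            logger.info(
                "set %s: dropped %d of %d genes absent from annotation",
                set_id, n_dropped[set_id], len(genes),
            )
        if not present:
            excluded[set_id] = "no_resolvable_genes"
            continue
        sub = ann.loc[present]
        windows[set_id] = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": np.maximum(sub["start"].to_numpy() - window_bp, 0),
                "end": sub["end"].to_numpy() + window_bp,
            }
        )
    return SetWindows(windows, n_resolved, n_dropped, excluded, window_bp)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals into disjoint ones."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def markers_in_set(
    effects: MarkerEffects,
    windows: Mapping[str, pd.DataFrame] | SetWindows,
) -> dict[str, np.ndarray]:
    """Indices (into the genome-ordered vector) of markers inside each set.

    A marker covered by several windows of the same set counts once, so the
    cardinality of each returned index array is the set's marker count m_f.
    """
    if isinstance(windows, SetWindows):
        windows = windows.windows
    pos0 = effects.pos - 1  # membership test uses 0-based positions
    chrom = effects.chrom
    by_chrom: dict[str, np.ndarray] = {
        c: np.flatnonzero(chrom == c) for c in effects.chrom_order
    }
    out: dict[str, np.ndarray] = {}
    for set_id, win in windows.items():
        hits: list[np.ndarray] = []
        for c, grp in win.groupby("chrom", sort=False):
            idx_c = by_chrom.get(str(c))
            if idx_c is None or len(idx_c) == 0:
                continue
            ms, me = _merge_intervals(
                grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
            )
            p = pos0[idx_c]
            j = np.searchsorted(ms, p, side="right") - 1
            inside = (j >= 0) & (p < me[np.clip(j, 0, len(me) - 1)])
            hits.append(idx_c[inside])
        out[set_id] = (
            np.sort(np.concatenate(hits)) if hits else np.empty(0, dtype=np.int64)
        )
    return out


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a minimal GFF3 into the annotation frame.

    Only rows whose type column is ``gene`` are kept; the gene id is the
    ``ID=`` (or ``gene_id=``) attribute.  1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == "gene"].copy()
    ids = df["attributes"].str.extract(_GFF_ID_RE, expand=False)
    if ids.isna().any():
        raise ValueError("GFF3 gene feature without an ID attribute")
    return pd.DataFrame(
        {
            "gene_id": ids.to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(np.int64) - 1,
            "end": df["end"].to_numpy(np.int64),
            "strand": df["strand"].to_numpy(),
        }
    )


def read_bed_genes(path) -> pd.DataFrame:
    """Read a BED4+ gene annotation (0-based half-open, kept as is)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError("BED gene annotation needs at least 4 columns")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0],
            "start": df.iloc[:, 1].astype(np.int64),
            "end": df.iloc[:, 2].astype(np.int64),
            "strand": df.iloc[:, 5] if df.shape[1] > 5 else ".",
        }
    )
    return out
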