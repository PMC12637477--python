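"""Count normalization and marker-based cell-type assignment.

Cell types are called per cell from canonical marker panels: each cell is
scored for every type as the mean log-normalized expression of that type's
markers, and labeled with the best-scoring type when its margin over the
runner-up clears ``min_margin`` (default 0, i.e. assign everything).  This is
the per-cell form of the usual cluster-level canonical-marker annotation;
genes outside the panel never influence the scores.

The default panel anchors each type to its standard cytometry identity:
CD8 T cells via Cd3e/Cd8a (CD3+CD8+), conventional dendritic cells via
Itgax/H2-Ab1 (CD11c+MHCII+), plus broad myeloid, tumor-epithelial and
stromal/endothelial markers.  Panels are replaceable: real analyses should
supply the marker lists matching their tissue and platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .formats import ChronotimeError, SpatialSection, UNASSIGNED

DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "tumor": ["Epcam", "Krt8"],
    "myeloid": ["Lyz2", "Cd68"],
    "CD8_T": ["Cd3e", "Cd8a"],
    "cDC": ["Itgax", "H2-Ab1"],
    "other": ["Col1a2", "Pecam1"],
}


@dataclass
class MarkerPanel:
    """Mapping cell type -> canonical marker genes.

    Lists must be non-empty and a gene may serve at most one type.
    """

    types: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.types:
            raise ChronotimeError("marker panel is empty")
        seen: dict[str, str] = {}
        for cell_type, genes in self.types.items():
            if not genes:
                raise ChronotimeError(f"type {cell_type!r} has no markers")
            for g in genes:
                if g in seen:
                    raise ChronotimeError(
                        f"gene {g!r} assigned to both {seen[g]!r} and {cell_type!r}"
                    )
                seen[g] = cell_type

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        """Two-column TSV (type, gene), no header."""
        df = pd.read_csv(path, sep="\t", header=None, names=["type", "gene"])
        types: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            types.setdefault(str(row["type"]), []).append(str(row["gene"]))
        return cls(types)

    @property
    def all_genes(self) -> list[str]:
        return [g for genes in self.types.values() for g in genes]


@dataclass
class TypeScores:
    """Per-cell marker scores with the best call and its margin."""

    scores: pd.DataFrame  # cells x types
    best: pd.Series
    margin: pd.Series  # best minus runner-up, >= 0


def lognorm(counts, scale: float = 1e4):
    """Depth-normalize then log-transform a genes x cells count matrix.

    Each non-empty cell's counts are scaled to sum to ``scale`` and mapped
    through ln(1 + x); zero-depth cells become all-zero columns (no NaN).
    Sparse input yields sparse output.
    """
    if scale <= 0:
        raise ChronotimeError("scale must be positive")
    if sp.issparse(counts):
        counts = sp.csr_matrix(counts)
        if counts.nnz and counts.data.min() < 0:
            raise ChronotimeError("counts must be non-negative")
        depth = np.asarray(counts.sum(axis=0)).ravel()
        factor = np.divide(scale, depth, out=np.zeros_like(depth, dtype=float),
                           where=depth > 0)
        out = counts.astype(float) @ sp.diags(factor)
        out.data = np.log1p(out.data)
        return sp.csr_matrix(out)
    counts = np.asarray(counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ChronotimeError("counts must be non-negative")
    depth = counts.sum(axis=0)
    factor = np.divide(scale, depth, out=np.zeros_like(depth), where=depth > 0)
    return np.log1p(counts * factor)


def marker_scores(section: SpatialSection, panel: MarkerPanel) -> TypeScores:
    """Score every cell for every panel type.

    score(cell, type) = mean over the type's markers of the cell's
    log-normalized expression.  All panel genes must be present in the
    section (the error lists any that are not).
    """
    missing = [g for g in panel.all_genes if g not in section.gene_names]
    if missing:
        raise ChronotimeError(f"marker genes missing from section: {missing}")
    ln = lognorm(section.counts)
    cols = {}
    for cell_type, genes in panel.types.items():
        rows = section.gene_index(genes)
        block = ln[rows]
        mean = np.asarray(block.mean(axis=0)).ravel()
        cols[cell_type] = mean
    scores = pd.DataFrame(cols, index=section.cells["cell_id"].to_numpy())
    vals = scores.to_numpy()
    order = np.argsort(-vals, axis=1, kind="stable")
    best_idx = order[:, 0]
    best = pd.Series(scores.columns.to_numpy()[best_idx], index=scores.index)
    if vals.shape[1] > 1:
        runner = vals[np.arange(len(vals)), order[:, 1]]
        margin = vals[np.arange(len(vals)), best_idx] - runner
    else:
        margin = np.full(len(vals), np.inf)
    return TypeScores(scores=scores, best=best,
                      margin=pd.Series(margin, index=scores.index))


def assign_types(scores: TypeScores, min_margin: float = 0.0) -> pd.Series:
    """Label each cell with its best type, abstaining on small margins.

    Cells whose margin over the runner-up falls below ``min_margin`` get the
    :data:`chronotime.UNASSIGNED` sentinel; raising ``min_margin`` can only
    move labels to unassigned, never flip them between types.
    """
    if min_margin < 0:
        raise ChronotimeError("min_margin must be >= 0")
    labels = scores.best.copy()
    labels[scores.margin < min_margin] = UNASSIGNED
    return labels


def annotate_section(
    section: SpatialSection,
    panel: MarkerPanel,
    min_margin: float = 0.0,
) -> SpatialSection:
    """Return a copy of the section with cell_type filled from marker calls."""
    labels = assign_types(marker_scores(section, panel), min_margin)
    cells = section.cells.copy()
    cells["cell_type"] = labels.to_numpy()
    return SpatialSection(
        section_id=section.section_id,
        condition=section.condition,
        cells=cells,
        counts=section.counts,
        gene_names=list(section.gene_names),
    )
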