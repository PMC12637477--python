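"""File formats, core containers, configuration and logging.

The on-disk representation of a spatial section is the most interoperable
dialect of the 10x-style bundle: a flat cells TSV (one row per cell), a
genes x cells integer count matrix in MatrixMarket triplet format, and a
features TSV (one gene per row).  MatrixMarket itself is orientation
agnostic, so the genes-in-rows / cells-in-columns convention is part of this
module's contract and is asserted on read.

Promoter sequences travel as plain FASTA over the A,C,G,T,N alphabet and
motif hits as BED6 with 0-based half-open coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__version__ = "0.1.0"

#: Sentinel label for cells without a type call; never the empty string.
UNASSIGNED = "unassigned"

#: Valid nucleotide alphabet for promoter sequences.
DNA_ALPHABET = frozenset("ACGTN")

CELL_COLUMNS = ["cell_id", "x_um", "y_um", "cell_type", "section_id", "condition"]

logger = logging.getLogger("chronotime")


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


class ChronotimeError(ValueError):
    """Base class for all contract violations raised by this package."""


class FormatError(ChronotimeError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class SpatialSection:
    """One tumor section: cell coordinates/labels plus a count matrix.

    Parameters
    ----------
    section_id, condition
        Identifiers shared by every cell of the section.
    cells
        One row per cell with columns ``cell_id, x_um, y_um, cell_type``;
        coordinates in micrometers, ``cell_type`` may be :data:`UNASSIGNED`.
    counts
        genes x cells non-negative integer matrix (CSR); column *j* belongs
        to row *j* of ``cells``.
    gene_names
        Ordered unique gene names, one per matrix row.
    """

    section_id: str
    condition: str
    cells: pd.DataFrame
    counts: sp.csr_matrix
    gene_names: list[str]

    def __post_init__(self) -> None:
        required = {"cell_id", "x_um", "y_um", "cell_type"}
        missing = required - set(self.cells.columns)
        if missing:
            raise FormatError(f"cells table missing columns: {sorted(missing)}")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_names), len(self.cells)):
            raise FormatError(
                f"count matrix is {self.counts.shape[0]} genes x "
                f"{self.counts.shape[1]} cells but features file lists "
                f"{len(self.gene_names)} genes and cells table lists "
                f"{len(self.cells)} cells"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            dupes = pd.Series(self.gene_names)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate gene names: {dupes}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts in matrix")
        coords = self.cells[["x_um", "y_um"]].to_numpy(float)
        if coords.size and not np.isfinite(coords).all():
            raise FormatError("non-finite cell coordinates")
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, genes: list[str] | str) -> np.ndarray:
        """Row indices for ``genes``; raises naming any that are absent."""
        if isinstance(genes, str):
            genes = [genes]
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ChronotimeError(f"genes not in section: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def type_mask(self, cell_type: str) -> np.ndarray:
        return (self.cells["cell_type"] == cell_type).to_numpy()

    def coords(self, cell_type: str | None = None) -> np.ndarray:
        """(n, 2) array of coordinates, optionally restricted to one type."""
        df = self.cells if cell_type is None else self.cells[self.type_mask(cell_type)]
        return df[["x_um", "y_um"]].to_numpy(float)


def sections_equal(a: SpatialSection, b: SpatialSection) -> bool:
    """Value equality of two sections (ids, cells, genes, counts)."""
    return (
        a.section_id == b.section_id
        and a.condition == b.condition
        and a.gene_names == b.gene_names
        and a.cells[["cell_id", "x_um", "y_um", "cell_type"]].equals(
            b.cells[["cell_id", "x_um", "y_um", "cell_type"]]
        )
        and (a.counts != b.counts).nnz == 0
    )


@dataclass
class RunMetadata:
    """Provenance sidecar written next to every output bundle."""

    seed: int | None = None
    config: dict | None = None
    tool: str = "chronotime"
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Section IO
# ---------------------------------------------------------------------------


def write_section(
    section: SpatialSection,
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write a section bundle (cells.tsv, matrix.mtx, features.tsv, metadata.json).

    Field order in cells.tsv is fixed (:data:`CELL_COLUMNS`) so identical
    sections serialize to identical bytes; metadata.json carries a wall-clock
    timestamp and is excluded from byte-identity contracts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out_dir / "cells.tsv",
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "metadata": out_dir / "metadata.json",
    }
    table = section.cells[["cell_id", "x_um", "y_um", "cell_type"]].copy()
    table["section_id"] = section.section_id
    table["condition"] = section.condition
    table[CELL_COLUMNS].to_csv(paths["cells"], sep="\t", index=False)
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(section.counts), field="integer")
    pd.DataFrame({"gene": section.gene_names}).to_csv(
        paths["features"], sep="\t", index=False, header=False
    )
    meta = RunMetadata(seed=seed, config=config)
    meta.checksums = {
        name: _sha256(p) for name, p in paths.items() if name != "metadata"
    }
    paths["metadata"].write_text(meta.to_json())
    logger.info("wrote section %s (%d cells) to %s", section.section_id,
                section.n_cells, out_dir)
    return paths


def read_section(
    cells_path: str | Path,
    matrix_path: str | Path,
    features_path: str | Path,
) -> SpatialSection:
    """Read a section bundle back into a :class:`SpatialSection`.

    Cells keep file order; matrix column ``j`` is aligned positionally to
    cell row ``j``; gene order comes from the features file.
    """
    cells = pd.read_csv(
        cells_path, sep="\t", dtype={"cell_id": str, "cell_type": str},
        float_precision="round_trip",
    )
    for col in ("cell_id", "x_um", "y_um", "cell_type"):
        if col not in cells.columns:
            raise FormatError(f"cells file missing column {col!r}")
    features = pd.read_csv(features_path, sep="\t", header=None)
    gene_names = features.iloc[:, 0].astype(str).tolist()
    mat = scipy.io.mmread(matrix_path)
    if not np.issubdtype(np.asarray(mat.data if sp.issparse(mat) else mat).dtype,
                         np.integer):
        data = mat.data if sp.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise FormatError("matrix contains non-integer counts")
    counts = sp.csr_matrix(mat).astype(np.int64)
    if counts.nnz and counts.data.min() < 0:
        raise FormatError("negative counts in matrix")
    if counts.shape[1] != len(cells):
        raise FormatError(
            f"matrix has {counts.shape[1]} columns but cells file has "
            f"{len(cells)} records"
        )
    if counts.shape[0] != len(gene_names):
        raise FormatError(
            f"matrix has {counts.shape[0]} rows but features file has "
            f"{len(gene_names)} genes"
        )
    section_id = str(cells["section_id"].iloc[0]) if len(cells) else ""
    condition = str(cells["condition"].iloc[0]) if len(cells) else ""
    if len(cells):
        if cells["section_id"].nunique() > 1 or cells["condition"].nunique() > 1:
            raise FormatError("cells file mixes multiple sections or conditions")
    return SpatialSection(
        section_id=section_id,
        condition=condition,
        cells=cells[["cell_id", "x_um", "y_um", "cell_type"]],
        counts=counts,
        gene_names=gene_names,
    )


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences upcased and validated."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise FormatError(
                    f"invalid character {ch!r} at position {pos} of {rec.id!r}"
                )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
    return path


def write_bed(hits, path: str | Path) -> Path:
    """Write motif hits as BED6: seq_id, start, end, motif, 0, strand."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif}\t0\t{h.strand}\n")
    return path


# ---------------------------------------------------------------------------
# Flat dotted-key config files
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file; '#' starts a comment.

    Keys use dots for nesting (e.g. ``attract_prob_by_condition.ZT2``); values
    stay strings and are coerced by the consumer. CLI flags win over file
    values when both are given.
    """
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def coerce_scalar(text: str):
    """Best-effort string -> int/float/bool/str coercion for config values."""
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        f = float(text)
        return f if math.isfinite(f) else text
    except ValueError:
        return text
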