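"""Cross-type nearest-partner distances and distance-quantile expression.

The core spatial statistic: for every cell of a source type (e.g. each
T cell), the Euclidean distance in micrometers to the nearest cell of a
target type (e.g. the nearest myeloid cell) in the same section.  Pooled
profiles are split into equal-count distance quantiles (10 by default) and
gene expression is averaged per quantile, producing the genes x quantiles
matrix whose near-to-far gradient quantifies proximity-dependent expression
of chemokines (measured in myeloid cells) and effector cytokines (measured
in T cells).

Distances are centroid-to-centroid with a single nearest neighbor (k=1) and
no edge correction; cells near the section border can only appear farther
from partners, a limitation shared with the synthetic generator so planted
effects remain internally consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .annotate import lognorm
from .formats import ChronotimeError, SpatialSection

# below this many source*target pairs the exact brute-force path is used,
# which also yields lowest-index tie-breaking for free
_BRUTE_FORCE_LIMIT = 4_000_000

PROFILE_COLUMNS = [
    "cell_id", "section_id", "condition", "distance_um", "partner_cell_id",
]


@dataclass
class DistanceProfile:
    """Per-source-cell nearest-partner distances for one type pair."""

    source_type: str
    target_type: str
    records: pd.DataFrame  # PROFILE_COLUMNS, one row per source cell

    def __post_init__(self) -> None:
        missing = set(PROFILE_COLUMNS) - set(self.records.columns)
        if missing:
            raise ChronotimeError(f"profile missing columns: {sorted(missing)}")
        if len(self.records) and (self.records["distance_um"] < 0).any():
            raise ChronotimeError("negative distances")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def distances(self) -> np.ndarray:
        return self.records["distance_um"].to_numpy(float)

    def to_tsv(self, path) -> None:
        out = self.records.copy()
        out.insert(0, "source_type", self.source_type)
        out.insert(1, "target_type", self.target_type)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class QuantileStrata:
    """Assignment of profile records to equal-count distance quantiles."""

    source_type: str
    target_type: str
    n_quantiles: int
    records: pd.DataFrame  # profile columns + 'quantile' in 1..n
    boundaries: np.ndarray  # max distance per quantile, non-decreasing

    def sizes(self) -> np.ndarray:
        return (
            self.records["quantile"].value_counts().reindex(
                range(1, self.n_quantiles + 1), fill_value=0
            ).to_numpy()
        )


@dataclass
class QuantileExpressionMatrix:
    """Mean expression per gene per distance quantile (near -> far).

    Rows are (gene, measured_in_type) pairs; ``values`` holds mean
    log-normalized expression, ``cell_counts`` how many cells entered each
    mean.  ``raw_values`` preserves the unscaled matrix after row z-scoring.
    """

    values: pd.DataFrame  # MultiIndex (gene, measured_in_type) x quantiles 1..n
    cell_counts: pd.DataFrame
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    raw_values: pd.DataFrame | None = None

    @property
    def n_quantiles(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"q{c}" for c in out.columns]
        out.reset_index().to_csv(path, sep="\t", index=False)


def nearest_partner_distances(
    section: SpatialSection,
    source_type: str,
    target_type: str,
) -> DistanceProfile:
    """Distance from every source-type cell to its nearest target-type cell.

    Exactly equals the all-pairs brute-force minimum; ties go to the
    lowest-index target cell.  Cross-type only: asking for a type against
    itself is refused rather than returning all zeros.
    """
    if source_type == target_type:
        raise ChronotimeError("source and target types must differ (cross-type only)")
    src_mask = section.type_mask(source_type)
    tgt_mask = section.type_mask(target_type)
    src = section.cells[src_mask]
    tgt = section.cells[tgt_mask]
    if len(tgt) == 0:
        raise ChronotimeError("no target cells")
    if len(src) == 0:
        warnings.warn(
            f"no source cells of type {source_type!r} in {section.section_id}",
            stacklevel=2,
        )
        return DistanceProfile(
            source_type, target_type,
            pd.DataFrame(columns=PROFILE_COLUMNS),
        )
    src_xy = src[["x_um", "y_um"]].to_numpy(float)
    tgt_xy = tgt[["x_um", "y_um"]].to_numpy(float)
    if len(src_xy) * len(tgt_xy) <= _BRUTE_FORCE_LIMIT:
        dmat = cdist(src_xy, tgt_xy)
        idx = dmat.argmin(axis=1)  # argmin takes the lowest index on ties
        dist = dmat[np.arange(len(src_xy)), idx]
    else:
        tree = cKDTree(tgt_xy)
        dist, idx = tree.query(src_xy, k=1)
        # enforce lowest-index tie-breaking
        for i, (x, d) in enumerate(zip(src_xy, dist)):
            cands = tree.query_ball_point(x, d * (1 + 1e-12) + 1e-12)
            exact = [j for j in cands
                     if np.hypot(*(tgt_xy[j] - x)) == d]
            if exact:
                idx[i] = min(exact)
    return DistanceProfile(
        source_type,
        target_type,
        pd.DataFrame(
            {
                "cell_id": src["cell_id"].to_numpy(),
                "section_id": section.section_id,
                "condition": section.condition,
                "distance_um": dist,
                "partner_cell_id": tgt["cell_id"].to_numpy()[idx],
            }
        ),
    )


def pool_profiles(profiles: list[DistanceProfile]) -> DistanceProfile:
    """Concatenate profiles of the same type pair across sections."""
    if not profiles:
        raise ChronotimeError("no profiles to pool")
    pairs = {(p.source_type, p.target_type) for p in profiles}
    if len(pairs) > 1:
        raise ChronotimeError(f"mixed type pairs: {sorted(pairs)}")
    records = pd.concat([p.records for p in profiles], ignore_index=True)
    dup = records.duplicated(subset=["section_id", "cell_id"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate cell ids after pooling", stacklevel=2
        )
    src, tgt = next(iter(pairs))
    return DistanceProfile(src, tgt, records)


def assign_quantiles(
    profile: DistanceProfile, n_quantiles: int = 10
) -> QuantileStrata:
    """Split a profile into ``n_quantiles`` equal-count distance strata.

    Records are ordered by (distance, original index) and cut into
    contiguous groups whose sizes differ by at most one (the first
    N mod n groups take the extra record).  Quantile 1 is nearest.
    """
    n = len(profile)
    if n < n_quantiles:
        raise ChronotimeError(
            f"cannot form {n_quantiles} quantiles from {n} records"
        )
    records = profile.records.copy()
    order = np.lexsort((np.arange(n), records["distance_um"].to_numpy()))
    records = records.iloc[order].reset_index(drop=True)
    quantile = np.empty(n, dtype=int)
    start = 0
    boundaries = np.empty(n_quantiles)
    for q, chunk in enumerate(np.array_split(np.arange(n), n_quantiles), start=1):
        quantile[chunk] = q
        boundaries[q - 1] = records["distance_um"].iloc[chunk[-1]]
        start += len(chunk)
    records["quantile"] = quantile
    return QuantileStrata(
        source_type=profile.source_type,
        target_type=profile.target_type,
        n_quantiles=n_quantiles,
        records=records,
        boundaries=boundaries,
    )


def quantile_expression_matrix(
    sections: list[SpatialSection],
    strata_by_source: dict[str, QuantileStrata],
    gene_rows: list[tuple[str, str]],
) -> QuantileExpressionMatrix:
    """Mean log-normalized expression per (gene, type) row per quantile.

    ``strata_by_source`` maps the measured type to its distance strata
    (chemokine rows measured in myeloid cells use myeloid->T distances;
    effector rows measured in T cells use T->myeloid distances).
    """
    if not gene_rows:
        raise ChronotimeError("no gene rows requested")
    if not strata_by_source:
        raise ChronotimeError("no strata provided")
    n_quantiles = {s.n_quantiles for s in strata_by_source.values()}
    if len(n_quantiles) != 1:
        raise ChronotimeError("strata disagree on n_quantiles")
    nq = n_quantiles.pop()
    ln_by_section = {s.section_id: (s, lognorm(s.counts)) for s in sections}
    pos_by_section = {
        sid: pd.Series(range(sec.n_cells), index=sec.cells["cell_id"])
        for sid, (sec, _) in ln_by_section.items()
    }
    index = pd.MultiIndex.from_tuples(gene_rows, names=["gene", "measured_in_type"])
    values = np.full((len(gene_rows), nq), np.nan)
    counts = np.zeros((len(gene_rows), nq), dtype=int)
    for r, (gene, mtype) in enumerate(gene_rows):
        if mtype not in strata_by_source:
            raise ChronotimeError(f"no strata for measured type {mtype!r}")
        strata = strata_by_source[mtype]
        if strata.source_type != mtype:
            raise ChronotimeError(
                f"strata for {mtype!r} were computed with source type "
                f"{strata.source_type!r}"
            )
        # expression value for every record of the strata, section by section
        expr = np.empty(len(strata.records))
        for section_id, group in strata.records.groupby("section_id"):
            if section_id not in ln_by_section:
                raise ChronotimeError(f"section {section_id!r} not provided")
            section, ln = ln_by_section[section_id]
            row = section.gene_index(gene)[0]
            pos = pos_by_section[section_id].loc[group["cell_id"]].to_numpy()
            dense = np.asarray(ln[row].todense()).ravel()
            expr[group.index.to_numpy()] = dense[pos]
        quantiles = strata.records["quantile"].to_numpy()
        for q in range(1, nq + 1):
            sample = expr[quantiles == q]
            counts[r, q - 1] = len(sample)
            values[r, q - 1] = sample.mean() if len(sample) else np.nan
    boundaries = {
        t: s.boundaries.copy() for t, s in strata_by_source.items()
    }
    return QuantileExpressionMatrix(
        values=pd.DataFrame(values, index=index, columns=range(1, nq + 1)),
        cell_counts=pd.DataFrame(counts, index=index, columns=range(1, nq + 1)),
        boundaries=boundaries,
    )


def zscore_rows(qem: QuantileExpressionMatrix) -> QuantileExpressionMatrix:
    """Center/scale each row to mean 0, sd 1 across quantiles.

    Constant rows map to all-zero; the raw matrix is retained in
    ``raw_values`` so display scaling never destroys the measurement.
    """
    raw = qem.values.copy()
    vals = raw.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    centered = vals - mean
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return QuantileExpressionMatrix(
        values=pd.DataFrame(z, index=raw.index, columns=raw.columns),
        cell_counts=qem.cell_counts.copy(),
        boundaries={t: b.copy() for t, b in qem.boundaries.items()},
        raw_values=raw,
    )
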