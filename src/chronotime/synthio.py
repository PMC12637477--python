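"""Synthetic spatial sections, two-condition experiments and promoter sequences.

The generator emulates the structure of a time-of-day spatial-transcriptomics
contrast in a mouse tumor: two harvest times (ZT2, early light/inactive phase;
ZT18, mid dark/active phase) that differ in

* immune infiltration — myeloid and T-cell counts are scaled per condition;
* T-cell/myeloid co-localization — myeloid cells form a Thomas cluster
  process (Poisson parents, Gaussian offspring) and each T cell is, with a
  per-condition probability, placed at a Gaussian offset from a random
  myeloid cell;
* proximity-dependent expression — chemokine genes in myeloid cells and
  effector-cytokine genes in T cells get a mean multiplier
  ``1 + beta * exp(-d / tau) * gain``, where ``d`` is the distance to the
  nearest partner-type cell and ``gain`` applies only in the peak condition.

Counts are negative binomial (variance = mu + mu^2/theta).  Every planted
quantity — true type, per-cell proximity multiplier, per-condition
parameters, promoter motif positions — is recorded in a GroundTruth object
so downstream recovery can be tested.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .formats import ChronotimeError, SpatialSection, logger
from .motifs import DEFAULT_MOTIFS, revcomp, scan_motifs

# Roles a gene can play in the panel.
ROLE_CHEMOKINE = "chemokine"
ROLE_EFFECTOR = "effector"
ROLE_BACKGROUND = "background"
MARKER_PREFIX = "marker:"

#: Default gene panel: canonical markers for the four simulated types, the
#: chemokine and effector-cytokine sets measured in the proximity analysis,
#: and housekeeping background genes.
DEFAULT_GENE_PANEL: list[tuple[str, str]] = [
    ("Epcam", "marker:tumor"),
    ("Krt8", "marker:tumor"),
    ("Lyz2", "marker:myeloid"),
    ("Cd68", "marker:myeloid"),
    ("Cd3e", "marker:T"),
    ("Cd8a", "marker:T"),
    ("Col1a2", "marker:other"),
    ("Pecam1", "marker:other"),
    ("Cxcl9", ROLE_CHEMOKINE),
    ("Cxcl10", ROLE_CHEMOKINE),
    ("Cxcl16", ROLE_CHEMOKINE),
    ("Ccl4", ROLE_CHEMOKINE),
    ("Ccl5", ROLE_CHEMOKINE),
    ("Xcl1", ROLE_CHEMOKINE),
    ("Ifng", ROLE_EFFECTOR),
    ("Gzmb", ROLE_EFFECTOR),
    ("Tnf", ROLE_EFFECTOR),
    ("Prf1", ROLE_EFFECTOR),
    ("Actb", ROLE_BACKGROUND),
    ("Gapdh", ROLE_BACKGROUND),
    ("B2m", ROLE_BACKGROUND),
    ("Rplp0", ROLE_BACKGROUND),
    ("Hprt", ROLE_BACKGROUND),
    ("Tbp", ROLE_BACKGROUND),
]


@dataclass
class SimConfig:
    """Full parameterization of one synthetic experiment.

    Defaults encode the study conditions: a 1 x 1 mm window, a 1.5x immune
    infiltration excess at ZT2, strong/tight T-cell attraction to myeloid
    cells at ZT2 (p=0.7, sd=30 um) versus weak/loose at ZT18 (p=0.2,
    sd=80 um), a proximity expression effect beta=2 decaying over tau=50 um,
    and a 1.5x chemokine/effector gain in the peak (ZT2) condition.
    """

    window_width_um: float = 1000.0
    window_height_um: float = 1000.0
    n_tumor: int = 1000
    n_myeloid: int = 400
    n_t: int = 350
    n_other: int = 250
    infiltration_factor_by_condition: dict[str, float] = field(
        default_factory=lambda: {"ZT2": 1.5, "ZT18": 1.0}
    )
    cluster_parent_intensity: float = 5e-5  # parents per um^2
    cluster_sd_um: float = 50.0
    attract_prob_by_condition: dict[str, float] = field(
        default_factory=lambda: {"ZT2": 0.7, "ZT18": 0.2}
    )
    attract_sd_um_by_condition: dict[str, float] = field(
        default_factory=lambda: {"ZT2": 30.0, "ZT18": 80.0}
    )
    proximity_effect_beta: float = 2.0
    proximity_scale_tau_um: float = 50.0
    condition_gain: float = 1.5
    peak_condition: str = "ZT2"
    marker_fold: float = 20.0
    mean_depth: float = 2000.0
    nb_dispersion: float = 2.0
    gene_panel: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_GENE_PANEL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.window_width_um <= 0 or self.window_height_um <= 0:
            raise ChronotimeError("window dimensions must be positive")
        for name in ("n_tumor", "n_myeloid", "n_t", "n_other"):
            if getattr(self, name) < 0:
                raise ChronotimeError(f"{name} must be non-negative")
        for cond, p in self.attract_prob_by_condition.items():
            if not 0.0 <= p <= 1.0:
                raise ChronotimeError(f"attract_prob[{cond}]={p} outside [0,1]")
        for cond, s in self.attract_sd_um_by_condition.items():
            if s <= 0:
                raise ChronotimeError(f"attract_sd_um[{cond}] must be positive")
        for cond, f in self.infiltration_factor_by_condition.items():
            if f <= 0:
                raise ChronotimeError(f"infiltration_factor[{cond}] must be positive")
        if self.cluster_sd_um <= 0 or self.proximity_scale_tau_um <= 0:
            raise ChronotimeError("spatial scales must be strictly positive")
        if self.cluster_parent_intensity <= 0:
            raise ChronotimeError("cluster_parent_intensity must be positive")
        if self.proximity_effect_beta < 0:
            raise ChronotimeError("proximity_effect_beta must be >= 0")
        if self.condition_gain < 1:
            raise ChronotimeError("condition_gain must be >= 1")
        if self.marker_fold < 1:
            raise ChronotimeError("marker_fold must be >= 1")
        if self.mean_depth <= 0 or self.nb_dispersion <= 0:
            raise ChronotimeError("mean_depth and nb_dispersion must be positive")
        genes = [g for g, _ in self.gene_panel]
        if len(set(genes)) != len(genes):
            raise ChronotimeError("gene names in panel must be unique")
        for g, role in self.gene_panel:
            if role not in (ROLE_CHEMOKINE, ROLE_EFFECTOR, ROLE_BACKGROUND) and not (
                role.startswith(MARKER_PREFIX) and len(role) > len(MARKER_PREFIX)
            ):
                raise ChronotimeError(f"unknown role {role!r} for gene {g!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.infiltration_factor_by_condition)

    def to_dict(self) -> dict:
        return asdict(self)

    def marker_panel(self) -> dict[str, list[str]]:
        """type -> marker genes mapping implied by the panel roles."""
        panel: dict[str, list[str]] = {}
        for gene, role in self.gene_panel:
            if role.startswith(MARKER_PREFIX):
                panel.setdefault(role[len(MARKER_PREFIX):], []).append(gene)
        return panel


@dataclass
class GroundTruth:
    """Planted truth for one generated object.

    For a section, ``cells`` has one row per cell (cell_id, true_type,
    proximity_multiplier) and ``params`` snapshots the condition-specific
    parameters used.  For promoters, ``motifs`` lists one
    (position, strand, motif) triple per planted site, per sequence.
    """

    cells: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)
    motifs: list[list[tuple[int, str, str]]] | None = None

    def to_jsonable(self) -> dict:
        out: dict = {"params": self.params}
        if self.cells is not None:
            out["cells"] = self.cells.to_dict(orient="list")
        if self.motifs is not None:
            out["motifs"] = [
                [[p, s, m] for p, s, m in per_seq] for per_seq in self.motifs
            ]
        return out


def derive_seed(master_seed: int, *parts) -> int:
    """Stable 31-bit sub-seed from the master seed and arbitrary labels.

    Hash-based (splitmix-style) so that adding sections or conditions never
    reshuffles the streams of earlier ones.
    """
    key = ":".join(str(p) for p in (master_seed, *parts))
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def _round_even(x: float) -> int:
    # nearest integer, ties to even (numpy banker's rounding)
    return int(np.round(x))


def _uniform_points(rng, n, width, height) -> np.ndarray:
    pts = rng.uniform(0.0, 1.0, size=(n, 2))
    pts[:, 0] *= width
    pts[:, 1] *= height
    return pts


def _thomas_points(rng, n, width, height, parent_intensity, sd) -> np.ndarray:
    """Thomas-type cluster process with an exact offspring total.

    Parents are Poisson over the window (at least one when offspring are
    requested); each offspring picks a uniform parent and a Gaussian offset,
    resampled until it lands inside the window (no boundary pile-up).
    """
    if n == 0:
        return np.empty((0, 2))
    n_parents = max(1, rng.poisson(parent_intensity * width * height))
    parents = _uniform_points(rng, n_parents, width, height)
    assignment = rng.integers(0, n_parents, size=n)
    return _gaussian_near(rng, parents[assignment], sd, width, height)


def _gaussian_near(rng, centers, sd, width, height) -> np.ndarray:
    """Gaussian offsets from ``centers``, resampling any point off-window."""
    pts = centers + rng.normal(0.0, sd, size=centers.shape)
    for _ in range(1000):
        bad = ~(
            (pts[:, 0] >= 0) & (pts[:, 0] <= width)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= height)
        )
        if not bad.any():
            return pts
        pts[bad] = centers[bad] + rng.normal(0.0, sd, size=(bad.sum(), 2))
    raise ChronotimeError("failed to place points inside the window")


def _nearest_distance(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """For each row of src, Euclidean distance to the nearest row of tgt."""
    if len(src) == 0:
        return np.empty(0)
    if len(tgt) == 0:
        return np.full(len(src), np.inf)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(tgt).query(src, k=1)
    return np.asarray(d, float)


def simulate_section(
    config: SimConfig,
    condition: str,
    seed: int,
    section_id: str | None = None,
) -> tuple[SpatialSection, GroundTruth]:
    """Generate one section under ``condition`` with its planted truth."""
    config.validate()
    for mapping, name in (
        (config.infiltration_factor_by_condition, "infiltration_factor"),
        (config.attract_prob_by_condition, "attract_prob"),
        (config.attract_sd_um_by_condition, "attract_sd_um"),
    ):
        if condition not in mapping:
            raise ChronotimeError(f"condition {condition!r} missing from {name}")
    width, height = config.window_width_um, config.window_height_um
    infil = config.infiltration_factor_by_condition[condition]
    attract_p = config.attract_prob_by_condition[condition]
    attract_sd = config.attract_sd_um_by_condition[condition]
    n_mye = _round_even(config.n_myeloid * infil)
    n_t = _round_even(config.n_t * infil)
    if n_t > 0 and attract_p > 0 and n_mye == 0:
        raise ChronotimeError(
            "no attractors: zero myeloid cells with T cells and attract_prob > 0"
        )
    rng = np.random.default_rng(seed)

    tumor = _uniform_points(rng, config.n_tumor, width, height)
    myeloid = _thomas_points(
        rng, n_mye, width, height, config.cluster_parent_intensity,
        config.cluster_sd_um,
    )
    # T cells: attracted to a uniformly chosen myeloid cell, else uniform
    t_pts = np.empty((n_t, 2))
    attracted = rng.uniform(size=n_t) < attract_p
    n_att = int(attracted.sum())
    if n_att:
        centers = myeloid[rng.integers(0, len(myeloid), size=n_att)]
        t_pts[attracted] = _gaussian_near(rng, centers, attract_sd, width, height)
    t_pts[~attracted] = _uniform_points(rng, n_t - n_att, width, height)
    other = _uniform_points(rng, config.n_other, width, height)

    coords = np.vstack([tumor, myeloid, t_pts, other])
    types = np.array(
        ["tumor"] * config.n_tumor + ["myeloid"] * n_mye
        + ["T"] * n_t + ["other"] * config.n_other
    )
    if section_id is None:
        section_id = condition
    cell_ids = np.array([f"{section_id}_c{i:05d}" for i in range(len(coords))])

    # proximity multiplier per cell: chemokines respond in myeloid cells to
    # the nearest T cell, effectors in T cells to the nearest myeloid cell
    gain = config.condition_gain if condition == config.peak_condition else 1.0
    beta, tau = config.proximity_effect_beta, config.proximity_scale_tau_um
    mult = np.ones(len(coords))
    mye_mask = types == "myeloid"
    t_mask = types == "T"
    d_mye = _nearest_distance(coords[mye_mask], coords[t_mask])
    d_t = _nearest_distance(coords[t_mask], coords[mye_mask])
    with np.errstate(over="ignore"):
        mult[mye_mask] = 1.0 + beta * np.exp(-d_mye / tau) * gain
        mult[t_mask] = 1.0 + beta * np.exp(-d_t / tau) * gain

    genes = [g for g, _ in config.gene_panel]
    base = config.mean_depth / len(genes)
    mean = np.full((len(genes), len(coords)), base)
    for row, (gene, role) in enumerate(config.gene_panel):
        if role.startswith(MARKER_PREFIX):
            own = types == role[len(MARKER_PREFIX):]
            mean[row, own] *= config.marker_fold
        elif role == ROLE_CHEMOKINE:
            mean[row, mye_mask] *= mult[mye_mask]
        elif role == ROLE_EFFECTOR:
            mean[row, t_mask] *= mult[t_mask]

    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    section = SpatialSection(
        section_id=section_id,
        condition=condition,
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "x_um": coords[:, 0],
                "y_um": coords[:, 1],
                "cell_type": types,
            }
        ),
        counts=sp.csr_matrix(counts),
        gene_names=genes,
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {"cell_id": cell_ids, "true_type": types, "proximity_multiplier": mult}
        ),
        params={
            "condition": condition,
            "seed": seed,
            "infiltration_factor": infil,
            "attract_prob": attract_p,
            "attract_sd_um": attract_sd,
            "proximity_effect_beta": beta,
            "proximity_scale_tau_um": tau,
            "condition_gain_applied": gain,
            "n_by_type": {
                "tumor": config.n_tumor,
                "myeloid": n_mye,
                "T": n_t,
                "other": config.n_other,
            },
        },
    )
    return section, truth


def simulate_experiment(
    config: SimConfig,
    sections_per_condition: int,
    seed: int,
) -> list[tuple[SpatialSection, GroundTruth]]:
    """Balanced multi-section two-arm (or multi-arm) experiment.

    Each section gets a sub-seed derived from (seed, condition, index) so
    the output is reproducible and insensitive to the number of sections
    generated after it.
    """
    if sections_per_condition < 1:
        raise ChronotimeError("sections_per_condition must be >= 1")
    if len(config.conditions) < 2:
        raise ChronotimeError("experiment requires at least two conditions")
    out = []
    for cond, i in itertools.product(
        config.conditions, range(sections_per_condition)
    ):
        sub = derive_seed(seed, cond, i)
        out.append(
            simulate_section(config, cond, sub, section_id=f"{cond}_s{i + 1}")
        )
    logger.info(
        "simulated %d sections (%d per condition x %d conditions)",
        len(out), sections_per_condition, len(config.conditions),
    )
    return out


def simulate_promoters(
    n_sequences: int,
    length: int,
    gc_fraction: float,
    planted: list[list[tuple[str, int, str]]] | None,
    reject_accidental: bool,
    seed: int,
    motif_set: tuple[str, ...] = DEFAULT_MOTIFS,
    max_retries: int = 1000,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Promoter sequences with motifs planted at known positions/strands.

    Background bases are i.i.d. with the given GC fraction; each planted
    (motif, position, strand) is written over the background (the reverse
    complement is written for strand '-').  With ``reject_accidental`` the
    background is resampled until scanning recovers exactly the planted
    sites and nothing else.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ChronotimeError("gc_fraction must be in [0,1]")
    if planted is None:
        planted = [[] for _ in range(n_sequences)]
    if len(planted) != n_sequences:
        raise ChronotimeError(
            f"planted lists ({len(planted)}) != n_sequences ({n_sequences})"
        )
    for per_seq in planted:
        spans = []
        for motif, pos, strand in per_seq:
            if strand not in "+-":
                raise ChronotimeError(f"strand must be + or -, got {strand!r}")
            if pos < 0 or pos + len(motif) > length:
                raise ChronotimeError(
                    f"planted motif {motif!r} at {pos} exceeds length {length}"
                )
            spans.append((pos, pos + len(motif)))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ChronotimeError("planted motifs overlap")

    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
         (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    truth_motifs: list[list[tuple[int, str, str]]] = []
    for idx in range(n_sequences):
        seq_id = f"p{idx + 1}"
        # expected hits after palindrome normalization ('-' palindrome -> '+')
        expected = []
        for motif, pos, strand in planted[idx]:
            if strand == "-" and revcomp(motif) == motif:
                strand = "+"
            expected.append((pos, strand, motif))
        expected_sorted = sorted(expected)
        for attempt in range(max_retries):
            seq = rng.choice(bases, size=length, p=probs)
            for motif, pos, strand in planted[idx]:
                word = motif if strand == "+" else revcomp(motif)
                seq[pos:pos + len(motif)] = list(word)
            text = "".join(seq)
            if not reject_accidental:
                break
            hits = scan_motifs([(seq_id, text)], motif_set=motif_set)
            got = sorted((h.start, h.strand, h.motif) for h in hits)
            if got == expected_sorted:
                break
        else:
            raise ChronotimeError(
                f"rejection sampling budget exhausted for sequence {seq_id}"
            )
        records.append((seq_id, text))
        truth_motifs.append(expected)
    truth = GroundTruth(
        params={
            "n_sequences": n_sequences,
            "length": length,
            "gc_fraction": gc_fraction,
            "reject_accidental": reject_accidental,
            "motif_set": list(motif_set),
            "seed": seed,
        },
        motifs=truth_motifs,
    )
    return records, truth
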