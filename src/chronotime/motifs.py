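"""E-box promoter motif scanning.

BMAL1:CLOCK binds hexameric E-box elements in promoters; the canonical site
is CACGTG with CACGTT as the common non-canonical variant.  This module does
exact-word scanning of both strands of promoter sequences, reporting hits in
forward-strand 0-based half-open coordinates.  The motif set is a plain list
of literal words (no position-weight matrices).

The canonical E-box is its own reverse complement, so every forward match is
also a reverse-strand match at the same coordinates; those duplicates are
collapsed to a single '+' hit by default so per-promoter counts are not
doubled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formats import ChronotimeError, DNA_ALPHABET, write_bed

DEFAULT_MOTIFS: tuple[str, ...] = ("CACGTG", "CACGTT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement over A,C,G,T,N (N maps to N)."""
    bad = set(sequence.upper()) - DNA_ALPHABET
    if bad:
        raise ChronotimeError(f"invalid characters for revcomp: {sorted(bad)}")
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence in forward-strand coordinates.

    ``motif`` is the motif-set word that matched; for strand '-' the forward
    strand of the sequence shows its reverse complement over [start, end).
    """

    seq_id: str
    start: int
    end: int
    motif: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ChronotimeError("hit coordinates must satisfy 0 <= start < end")
        if self.end - self.start != len(self.motif):
            raise ChronotimeError("hit span must equal motif length")
        if self.strand not in "+-":
            raise ChronotimeError("strand must be '+' or '-'")


def _occurrences(haystack: str, needle: str):
    """All (possibly overlapping) start positions of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _as_records(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, str):
        return [("seq", sequences)]
    if isinstance(sequences, dict):
        return list(sequences.items())
    return list(sequences)


def scan_motifs(
    sequences,
    motif_set: tuple[str, ...] = DEFAULT_MOTIFS,
    both_strands: bool = True,
    dedupe_palindrome: bool = True,
) -> list[MotifHit]:
    """Exact occurrences of each motif on one or both strands.

    Parameters
    ----------
    sequences
        A single sequence string, a dict id -> sequence, or an iterable of
        (id, sequence) pairs (as produced by :func:`chronotime.read_fasta`).
    motif_set
        Literal words over A,C,G,T.  N in the sequence never matches.
    both_strands
        Also report occurrences of each motif's reverse complement, in
        forward coordinates with strand '-'.
    dedupe_palindrome
        Collapse the double report a palindromic motif would produce at
        each site into a single '+' hit.

    Returns hits sorted by (seq_id, start, motif).
    """
    for motif in motif_set:
        if not motif or set(motif) - set("ACGT"):
            raise ChronotimeError(f"motif {motif!r} must be non-empty over A,C,G,T")
    hits: set[MotifHit] = set()
    for seq_id, seq in _as_records(sequences):
        seq = seq.upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ChronotimeError(
                f"sequence {seq_id!r} has invalid characters: {sorted(bad)}"
            )
        for motif in motif_set:
            for start in _occurrences(seq, motif):
                hits.add(MotifHit(seq_id, start, start + len(motif), motif, "+"))
            if both_strands:
                rc = revcomp(motif)
                palindrome = rc == motif
                for start in _occurrences(seq, rc):
                    strand = "+" if (palindrome and dedupe_palindrome) else "-"
                    hit = MotifHit(seq_id, start, start + len(motif), motif, strand)
                    hits.add(hit)
    return sorted(hits, key=lambda h: (h.seq_id, h.start, h.motif, h.strand))


def summarize_promoter(
    hits: list[MotifHit],
    per_sequence: bool = True,
    bed_path=None,
) -> pd.DataFrame:
    """Count hits by motif and strand, per sequence or overall.

    Returns a tidy table with a ``count`` column; total count always equals
    the number of hits.  If ``bed_path`` is given the hits are also written
    as BED6 through the formats module.
    """
    rows = [
        {"seq_id": h.seq_id, "motif": h.motif, "strand": h.strand} for h in hits
    ]
    keys = (["seq_id"] if per_sequence else []) + ["motif", "strand"]
    if rows:
        table = (
            pd.DataFrame(rows).groupby(keys).size().reset_index(name="count")
        )
    else:
        table = pd.DataFrame(columns=keys + ["count"])
    if bed_path is not None:
        write_bed(hits, bed_path)
    return table
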