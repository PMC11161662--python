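"""Cross-species conserved A / m6A site detection in ortholog pairs.

One-to-one ortholog transcripts (rice vs Arabidopsis in the motivating
setting) are globally aligned at the spliced-mRNA level; an aligned column
is a *conserved A site* when both rows carry an A and the +/-1 nt flanks
are gap-free and identical across species.  A conserved A that carries a
passed m6A site in both species is a *conserved m6A pair*.  Motif classes
follow the field's trinucleotide grouping: RAC (R = A or G, followed by
C), GAT, and other.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

__all__ = [
    "OrthologPair",
    "ConservedASite",
    "OrthologSitePair",
    "pair_orthologs",
    "align_pair",
    "conserved_a_sites",
    "conserved_m6a_pairs",
    "classify_motif",
]

_VALID = set("ACGTUN")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    transcript_a: str
    transcript_b: str


@dataclass(frozen=True)
class ConservedASite:
    """An aligned A column with consistent +/-1 nt flanks in both species."""

    column: int
    pos_a: int  # transcript-relative, 0-based
    pos_b: int
    flank_left: str
    flank_right: str


@dataclass(frozen=True)
class OrthologSitePair:
    column: int
    pos_a: int
    pos_b: int
    flank_left: str
    flank_right: str
    fraction_a: float | None
    fraction_b: float | None
    conserved_m6a: bool
    motif_class: str
    same_motif_5mer: bool | None = None


def pair_orthologs(
    ortholog_table: pd.DataFrame,
    canonical_a: dict[str, str],
    canonical_b: dict[str, str],
) -> list[OrthologPair]:
    """Build ortholog pairs from a (gene_a, gene_b) table.

    The table must be one-to-one: a gene repeated in either column is an
    error.  Pairs whose gene lacks a canonical transcript in either
    annotation are dropped (logged via the return-size difference).
    """
    for col in ("gene_a", "gene_b"):
        dup = ortholog_table[col][ortholog_table[col].duplicated()]
        if len(dup):
            raise ValueError(f"ortholog table not one-to-one: {col} repeats {dup.iloc[0]!r}")
    pairs = []
    for rec in ortholog_table.itertuples(index=False):
        ta = canonical_a.get(rec.gene_a)
        tb = canonical_b.get(rec.gene_b)
        if ta is None or tb is None:
            continue
        pairs.append(OrthologPair(rec.gene_a, rec.gene_b, ta, tb))
    return pairs


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)}")
    return seq


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> tuple[str, str]:
    """Global affine-gap alignment of two transcript sequences.

    Returns the two gapped rows (T/U merged to T).  The first optimal
    alignment in Biopython's deterministic enumeration order is used, so
    ties break reproducibly.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """
    sa, sb = _check_seq(seq_a, "seq_a"), _check_seq(seq_b, "seq_b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(sa, sb)[0]
    # str(aln) wraps long alignments; rebuild the rows from coordinates.
    return _gapped_rows(aln, sa, sb)


def _gapped_rows(aln, sa: str, sb: str) -> tuple[str, str]:
    a_parts, b_parts = [], []
    coords = aln.coordinates
    for k in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, k]), int(coords[0, k + 1])
        b0, b1 = int(coords[1, k]), int(coords[1, k + 1])
        if a1 > a0 and b1 > b0:
            a_parts.append(sa[a0:a1])
            b_parts.append(sb[b0:b1])
        elif a1 > a0:
            a_parts.append(sa[a0:a1])
            b_parts.append("-" * (a1 - a0))
        else:
            a_parts.append("-" * (b1 - b0))
            b_parts.append(sb[b0:b1])
    return "".join(a_parts), "".join(b_parts)


def conserved_a_sites(row_a: str, row_b: str) -> list[ConservedASite]:
    """Conserved A columns of a gapped alignment.

    Column c qualifies iff both rows carry A at c, columns c-1 and c+1
    exist and are gap-free in both rows, and the -1 bases match across rows
    as do the +1 bases.
    """
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    ra = row_a.upper().replace("U", "T")
    rb = row_b.upper().replace("U", "T")
    out = []
    pos_a = pos_b = 0
    for c, (ca, cb) in enumerate(zip(ra, rb)):
        if (
            ca == "A"
            and cb == "A"
            and 0 < c < len(ra) - 1
            and "-" not in (ra[c - 1], ra[c + 1], rb[c - 1], rb[c + 1])
            and ra[c - 1] == rb[c - 1]
            and ra[c + 1] == rb[c + 1]
        ):
            out.append(ConservedASite(c, pos_a, pos_b, ra[c - 1], ra[c + 1]))
        if ca != "-":
            pos_a += 1
        if cb != "-":
            pos_b += 1
    return out


def classify_motif(flank_left: str, flank_right: str) -> str:
    """Trinucleotide motif class of a conserved A: RAC, GAT or other."""
    right = flank_right.upper().replace("U", "T")
    left = flank_left.upper()
    if left in ("A", "G") and right == "C":
        return "RAC"
    if left == "G" and right == "T":
        return "GAT"
    return "other"


def conserved_m6a_pairs(
    conserved: list[ConservedASite],
    sites_a: dict[int, float],
    sites_b: dict[int, float],
    seq_a: str | None = None,
    seq_b: str | None = None,
) -> list[OrthologSitePair]:
    """Join conserved A columns with per-species m6A calls.

    ``sites_a``/``sites_b`` map transcript-relative positions of *passed*
    sites to calibrated fractions.  ``conserved_m6a`` is true iff both
    species carry a passed site at the column's positions.  When the
    ungapped sequences are supplied, pairs whose full 5-mer contexts match
    are additionally flagged (``same_motif_5mer``).
    """
    out = []
    for site in conserved:
        fa = sites_a.get(site.pos_a)
        fb = sites_b.get(site.pos_b)
        same5 = None
        if seq_a is not None and seq_b is not None:
            ka = _context5(seq_a, site.pos_a)
            kb = _context5(seq_b, site.pos_b)
            same5 = ka is not None and ka == kb
        out.append(
            OrthologSitePair(
                column=site.column,
                pos_a=site.pos_a,
                pos_b=site.pos_b,
                flank_left=site.flank_left,
                flank_right=site.flank_right,
                fraction_a=fa,
                fraction_b=fb,
                conserved_m6a=fa is not None and fb is not None,
                motif_class=classify_motif(site.flank_left, site.flank_right),
                same_motif_5mer=same5,
            )
        )
    return out


def _context5(seq: str, pos: int) -> str | None:
    seq = seq.upper().replace("U", "T")
    if pos - 2 < 0 or pos + 3 > len(seq):
        return None
    return seq[pos - 2 : pos + 3]
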