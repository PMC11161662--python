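"""Transcript models from genome annotation.

Parses GFF3 + genome FASTA into :class:`TranscriptModel` objects — the
coordinate backbone for every positional statistic in the package: region
assignment (5'UTR / CDS / 3'UTR / intron), exon classification
(first / internal / last / single) and metagene coordinates.

Conventions
-----------
* Internal coordinates are 0-based half-open genomic intervals; emitted
  tables are 1-based (the field's "Chr3: 29172686" style).
* Exons are stored 5'->3' in *transcript* orientation (reversed genomic
  order on the minus strand).
* The stop codon counts as CDS; the first base after ``cds_end`` opens the
  3'UTR.
* One canonical transcript per gene: longest CDS, then longest transcript,
  then lexicographically smallest ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import gffutils
from pyfaidx import Fasta

__all__ = [
    "Region",
    "TranscriptModel",
    "ExonRecord",
    "load_annotation",
    "classify_exons",
    "assign_region",
    "metagene_coordinate",
    "region_percentages",
    "canonical_transcripts",
    "write_gff3",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Region(str, Enum):
    """Transcript region label for a single site."""

    UTR5 = "5UTR"
    CDS = "CDS"
    UTR3 = "3UTR"
    INTRON = "intron"
    NONCODING_EXON = "noncoding_exon"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


class NotOnTranscript(ValueError):
    """Raised when a genomic position falls outside a transcript's span."""


@dataclass
class TranscriptModel:
    """A spliced transcript: exon structure, CDS boundaries and sequence.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation.  ``cds_start``/``cds_end`` are transcript-relative
    offsets (half-open, stop codon included in the CDS); ``None`` for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise AnnotationError(
                f"{self.transcript_id}: exons not ordered 5'->3' in transcript orientation"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.transcript_id}: partial CDS annotation")
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.length:
                raise AnnotationError(f"{self.transcript_id}: CDS outside transcript")

    # -- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def genomic_span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def utr5_length(self) -> int:
        return self.cds_start if self.is_coding else 0

    @property
    def cds_length(self) -> int:
        return (self.cds_end - self.cds_start) if self.is_coding else 0

    @property
    def utr3_length(self) -> int:
        return (self.length - self.cds_end) if self.is_coding else 0

    # -- coordinate mapping ---------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Transcript-relative offset of genomic ``pos``; None if intronic/outside."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
            off += e - s
        return None

    def transcript_to_genomic(self, offset: int) -> int:
        if not 0 <= offset < self.length:
            raise IndexError(f"offset {offset} out of range for {self.transcript_id}")
        for s, e in self.exons:
            n = e - s
            if offset < n:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= n
        raise AssertionError("unreachable")

    def exon_transcript_intervals(self) -> list[tuple[int, int]]:
        """Transcript-relative half-open interval of each exon, 5'->3'."""
        out, off = [], 0
        for s, e in self.exons:
            out.append((off, off + (e - s)))
            off += e - s
        return out


@dataclass(frozen=True)
class ExonRecord:
    """One exon with its structural class (first / internal / last / single)."""

    transcript_id: str
    index: int  # 1-based, 5'->3'
    klass: str
    length: int
    chrom: str
    strand: str
    genomic_interval: tuple[int, int]
    transcript_interval: tuple[int, int]


def classify_exons(t: TranscriptModel) -> list[ExonRecord]:
    """Classify each exon of ``t`` by position in the transcript.

    Single-exon transcripts yield one ``single`` record; internal/last-exon
    analyses skip those downstream.
    """
    n = t.n_exons
    tx_ivals = t.exon_transcript_intervals()
    records = []
    for i, ((gs, ge), tiv) in enumerate(zip(t.exons, tx_ivals), start=1):
        if n == 1:
            klass = "single"
        elif i == 1:
            klass = "first"
        elif i == n:
            klass = "last"
        else:
            klass = "internal"
        records.append(
            ExonRecord(t.transcript_id, i, klass, ge - gs, t.chrom, t.strand, (gs, ge), tiv)
        )
    return records


def assign_region(pos: int, t: TranscriptModel) -> Region:
    """Region label of genomic position ``pos`` on transcript ``t``.

    Exonic positions get 5UTR/CDS/3UTR (or noncoding_exon for non-coding
    transcripts); positions inside the genomic span but not exonic are
    intronic.  The stop-codon boundary is assigned 3'-ward: offset ==
    cds_end is the first 3'UTR base.
    """
    off = t.genomic_to_transcript(pos)
    if off is None:
        lo, hi = t.genomic_span
        if lo <= pos < hi:
            return Region.INTRON
        raise NotOnTranscript(f"position {pos} not on transcript {t.transcript_id}")
    if not t.is_coding:
        return Region.NONCODING_EXON
    if off < t.cds_start:
        return Region.UTR5
    if off < t.cds_end:
        return Region.CDS
    return Region.UTR3


def metagene_coordinate(
    pos: int, t: TranscriptModel, bins_per_region: int = 100
) -> tuple[Region, int] | None:
    """Metagene bin of an exonic site: (region, bin index in [0, bins)).

    The site's transcript offset is scaled to [0,1) within its region and
    discretized.  Returns None (with a warning) if the region has zero
    length, which cannot occur for well-formed coding transcripts.
    """
    region = assign_region(pos, t)
    if region in (Region.INTRON,):
        raise ValueError("metagene coordinates are defined for exonic sites only")
    off = t.genomic_to_transcript(pos)
    if region is Region.NONCODING_EXON:
        start, size = 0, t.length
    elif region is Region.UTR5:
        start, size = 0, t.cds_start
    elif region is Region.CDS:
        start, size = t.cds_start, t.cds_end - t.cds_start
    else:
        start, size = t.cds_end, t.length - t.cds_end
    if size <= 0:
        warnings.warn(f"zero-length {region} on {t.transcript_id}; site skipped")
        return None
    rel = (off - start) / size
    return region, min(int(rel * bins_per_region), bins_per_region - 1)


def region_percentages(labels: Iterable[Region]) -> dict[str, float]:
    """Percentage of sites per region over a label collection (sums to 100)."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels")
    out: dict[str, float] = {}
    n = len(labels)
    for lab in labels:
        out[str(lab.value)] = out.get(str(lab.value), 0.0) + 100.0 / n
    return out


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------


def load_annotation(
    gff_path: str,
    fasta_path: str | None = None,
    *,
    id_attr: str = "ID",
    parent_attr: str = "Parent",
) -> dict[str, TranscriptModel]:
    """Parse GFF3 (+ optional genome FASTA) into transcript models.

    One :class:`TranscriptModel` per mRNA feature; UTRs are derived from
    exons minus CDS.  When ``fasta_path`` is given the spliced sense-strand
    sequence is attached to each model.

    Raises :class:`AnnotationError` for orphan exons/CDS (missing mRNA
    parent), CDS segments outside exons, or chromosomes absent from the
    FASTA.
    """
    db = gffutils.create_db(
        gff_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        id_spec=id_attr,
    )
    mrna_ids = set()
    mrna_gene: dict[str, str] = {}
    mrnas = {}
    for feat in db.features_of_type(("mRNA", "transcript")):
        tid = feat.attributes.get(id_attr, [feat.id])[0]
        mrna_ids.add(tid)
        mrnas[tid] = feat
        mrna_gene[tid] = feat.attributes.get(parent_attr, [tid])[0]

    exons_by_tx: dict[str, list[tuple[int, int]]] = {tid: [] for tid in mrna_ids}
    cds_by_tx: dict[str, list[tuple[int, int]]] = {tid: [] for tid in mrna_ids}
    for ftype, store, label in (("exon", exons_by_tx, "exon"), ("CDS", cds_by_tx, "CDS")):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get(parent_attr, [])
            hits = [p for p in parents if p in mrna_ids]
            if not hits:
                raise AnnotationError(
                    f"orphan {label} at {feat.seqid}:{feat.start}-{feat.end}: "
                    f"no mRNA parent among {parents or '(none)'}"
                )
            for p in hits:
                store[p].append((feat.start - 1, feat.end))  # GFF3 is 1-based closed

    fasta = Fasta(fasta_path, as_raw=True, sequence_always_upper=True) if fasta_path else None

    models: dict[str, TranscriptModel] = {}
    for tid, feat in mrnas.items():
        strand = feat.strand
        chrom = feat.seqid
        exons = sorted(exons_by_tx[tid])
        if not exons:
            raise AnnotationError(f"mRNA {tid} has no exons")
        if strand == "-":
            exons = exons[::-1]
        cds_start = cds_end = None
        if cds_by_tx[tid]:
            cds = sorted(cds_by_tx[tid])
            for cs, ce in cds:
                if not any(s <= cs and ce <= e for s, e in exons):
                    raise AnnotationError(f"CDS [{cs},{ce}) of {tid} outside exons")
            model_noseq = TranscriptModel(tid, mrna_gene[tid], chrom, strand, exons)
            first = cds[0][0] if strand == "+" else cds[-1][1] - 1
            last = cds[-1][1] - 1 if strand == "+" else cds[0][0]
            cds_start = model_noseq.genomic_to_transcript(first)
            cds_end = model_noseq.genomic_to_transcript(last) + 1
        seq = None
        if fasta is not None:
            if chrom not in fasta:
                raise AnnotationError(f"chromosome {chrom!r} absent from FASTA")
            parts = [str(fasta[chrom][s:e]) for s, e in sorted(exons)]
            seq = "".join(parts)
            if strand == "-":
                seq = reverse_complement(seq)
        models[tid] = TranscriptModel(
            tid, mrna_gene[tid], chrom, strand, exons, cds_start, cds_end, seq
        )
    return models


def canonical_transcripts(models: Mapping[str, TranscriptModel]) -> dict[str, str]:
    """Pick one canonical transcript per gene.

    Longest CDS, tie -> longest transcript, tie -> lexicographically
    smallest transcript ID.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in models.values():
        by_gene.setdefault(t.gene_id, []).append(t)
    return {
        g: min(ts, key=lambda t: (-t.cds_length, -t.length, t.transcript_id)).transcript_id
        for g, ts in by_gene.items()
    }


def write_gff3(models: Mapping[str, TranscriptModel] | Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models back to GFF3 (gene/mRNA/exon/CDS features)."""
    if isinstance(models, Mapping):
        models = list(models.values())
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene):
            ts = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
            lo = min(t.genomic_span[0] for t in ts)
            hi = max(t.genomic_span[1] for t in ts)
            chrom, strand = ts[0].chrom, ts[0].strand
            fh.write(
                f"{chrom}\tm6abasemap\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tID={gene_id}\n"
            )
            for t in ts:
                s0, e0 = t.genomic_span
                fh.write(
                    f"{chrom}\tm6abasemap\tmRNA\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for s, e in sorted(t.exons):
                    fh.write(
                        f"{chrom}\tm6abasemap\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                if t.is_coding:
                    g1 = t.transcript_to_genomic(t.cds_start)
                    g2 = t.transcript_to_genomic(t.cds_end - 1)
                    clo, chi = min(g1, g2), max(g1, g2) + 1
                    for s, e in sorted(t.exons):
                        cs, ce = max(s, clo), min(e, chi)
                        if cs < ce:
                            fh.write(
                                f"{chrom}\tm6abasemap\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t"
                                f"Parent={t.transcript_id}\n"
                            )


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    """Write a plain-text FASTA."""
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
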