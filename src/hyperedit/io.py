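"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally; BED output uses the same
convention natively. FASTA/FASTQ parsing is delegated to Biopython; the BED
dialect used here (chrom, start, end, [strand], [label]) is read and written
directly so that round-trips are byte-exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class SiteRecord:
    """A unique genomic editing site aggregated over reads.

    ``mismatch_type`` is an ordered (ref, alt) pair on the edited strand,
    e.g. ("A", "G"); ``strand`` is the inferred edited strand.
    """

    chrom: str
    pos: int  # 0-based
    mismatch_type: tuple[str, str]
    support: int
    strand: str = "."
    strand_resolved: bool = False

    def __post_init__(self) -> None:
        ref, alt = self.mismatch_type
        if ref == alt or ref not in "ACGT" or alt not in "ACGT":
            raise ValueError(f"invalid mismatch type {self.mismatch_type}")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class Genome:
    """Named sequences plus optional interval annotations.

    Sequences are stored uppercase; soft-masking is dropped on read (masking
    belongs in the ``repeats`` annotation, not in case).
    """

    sequences: dict[str, str]
    repeats: list[Interval] = field(default_factory=list)
    coding: list[Interval] = field(default_factory=list)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][max(0, start) : end]


@dataclass
class Read:
    """A sequencing read (FASTQ record) with Phred+33 qualities."""

    id: str
    seq: str
    qual: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


class ParseError(ValueError):
    """Malformed record in an input file, annotated with its line number."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> Genome:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return Genome(sequences=seqs)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTQ file (Sanger / Phred+33). Empty file is fine."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(id=rec.id, seq=str(rec.seq).upper(), qual=qual)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "?" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED-like file: chrom, start, end, [strand], [label].

    Both the 4-column (strand in column 4) and 6-column (name, score, strand)
    dialects are accepted; mixed line endings are tolerated.
    """
    out: list[Interval] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand, label = ".", ""
            rest = fields[3:]
            if len(rest) >= 3 and rest[2] in "+-.":  # BED6: name score strand
                label, strand = rest[0], rest[2]
            elif rest and rest[0] in "+-.":
                strand = rest[0]
                if len(rest) > 1:
                    label = rest[1]
            elif rest:
                label = rest[0]
            try:
                out.append(Interval(fields[0], start, end, strand, label))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write intervals as chrom, start, end, [strand], [label] (tab-separated)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.strand != "." or iv.label:
                fields.append(iv.strand)
            if iv.label:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Site tables and summaries


def write_sites(sites: Sequence[SiteRecord], path: str | Path) -> None:
    """Write unique sites as a BED-like table with type and support columns."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmismatch_type\tsupport\tstrand\n")
        for s in sites:
            ref, alt = s.mismatch_type
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{ref}>{alt}\t{s.support}\t{s.strand}\n")


def read_sites(path: str | Path) -> list[SiteRecord]:
    out: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            ref, alt = f[3].split(">")
            out.append(
                SiteRecord(f[0], int(f[1]), (ref, alt), int(f[4]), f[5], strand_resolved=f[5] != ".")
            )
    return out


SUMMARY_COLUMNS = [
    "dataset",
    "source_reads",
    "pct_aligned",
    "hyper_reads",
    "editing_events",
    "unique_sites",
    "pct_a_to_g_of_all_types",
    "pct_in_coding",
    "pct_in_repeats",
]


def write_summary(rows: Sequence[dict], path: str | Path) -> None:
    """Tab-delimited per-dataset summary (source reads, % aligned, hyper-editing
    reads, editing events, unique sites with % A-to-G, % coding, % repeats)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in SUMMARY_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# SAM emission (optional output of hyper-edited read placements)


def write_sam(alignments, genome: Genome, path: str | Path) -> None:
    """Write gapless placements as SAM (flags 0/16 only, NM and MD populated).

    ``alignments`` is an iterable of objects with read_id, chrom, start,
    strand, seq (as-sequenced), and a native mismatch list.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()],
    }
    chrom_ids = {name: i for i, name in enumerate(genome.sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            seq = aln.seq if aln.strand == "+" else revcomp(aln.seq)
            a.query_sequence = seq
            a.flag = 0 if aln.strand == "+" else 16
            a.reference_id = chrom_ids[aln.chrom]
            a.reference_start = aln.start
            a.mapping_quality = 60 if aln.unique else 0
            a.cigarstring = f"{len(seq)}M"
            nm = len(aln.mismatches)
            md = _md_tag(genome[aln.chrom][aln.start : aln.start + len(seq)], aln.mismatches)
            a.set_tags([("NM", nm, "i"), ("MD", md, "Z")])
            fh.write(a)


def _md_tag(ref_window: str, mismatches) -> str:
    """MD string for a gapless alignment given (window_offset, ref, alt) triples."""
    parts: list[str] = []
    prev = 0
    for off, ref_base, _alt in sorted(mismatches, key=lambda m: m[0]):
        parts.append(str(off - prev))
        parts.append(ref_base)
        prev = off + 1
    parts.append(str(len(ref_window) - prev))
    return "".join(parts)
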