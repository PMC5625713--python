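"""Hyper-edited read detection: the four-step rescue-and-cluster screen.

The screen proceeds per ordered mismatch type X→Y:

1. collect the reads the initial (native-alphabet) alignment could not place;
2. transform X to Y in both the unmapped reads and the reference;
3. realign in the collapsed alphabet;
4. recover the native-alphabet mismatches at the placement and keep reads
   whose X→Y mismatch count forms a dense cluster — at least 5% of the read
   length (four sites for 80-bp reads).

Running the identical screen for all 12 ordered mismatch types gauges
specificity: true A-to-I editing produces A→G clusters (and T→C clusters in
unstranded libraries, where minus-strand transcripts are sequenced on the
opposite strand), while artifacts spread over all types.

A detected read's ``mismatch_type`` is reported on the read's own strand:
a minus-strand placement under scheme X→Y masks mismatches reading
complement(X)→complement(Y) on the read, and is recorded as that type. With
this convention stranded libraries yield virtually only A→G clusters, while
unstranded libraries split the signal between A→G and T→C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import (
    ALL_SCHEMES,
    AlignmentResult,
    KmerIndex,
    TransformScheme,
    align_read,
)
from .io import Genome, Interval, Read, SiteRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def min_sites(read_length: int, frac: float = 0.05, strict: bool = False) -> int:
    """Minimum candidate-mismatch count for a read to qualify as hyper-edited.

    The calling rule requires the candidate-type mismatch count to reach 5%
    of the read length — four sites for 80-bp reads. By default the threshold
    is ``ceil(frac * L)``, which reproduces that worked value; ``strict=True``
    instead uses the smallest integer strictly greater than ``frac * L``
    (5 for 80-bp reads), the literal "exceeds 5%" reading.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    x = frac * read_length
    if strict:
        return math.floor(x) + 1
    return math.ceil(x)


@dataclass
class DetectConfig:
    """Tunable knobs of the cluster-calling screen."""

    min_frac: float = 0.05  # candidate sites must reach this fraction of L
    strict_threshold: bool = False
    k: int = 16  # seed length for the transformed realignment
    #: budget for transformed-space (non-candidate) mismatches during realignment
    #: and cap on recovered non-candidate mismatches, as a fraction of L
    max_other_frac: float = 0.025
    #: reject reads whose candidate sites all sit in the first or last
    #: ``edge_frac`` of the read (junction / end-of-read artifacts)
    edge_frac: float = 0.10
    #: minimum mean Phred quality over candidate sites (applied when
    #: qualities are informative, i.e. not constant)
    min_mean_qual: float = 25.0
    #: trim reads to this common length (from the start, keeping the 3' end)
    #: before detection; None disables trimming
    trim_to: int | None = None
    require_unique: bool = True

    def max_other(self, read_length: int) -> int:
        return max(1, math.floor(self.max_other_frac * read_length))


@dataclass
class HyperEditedRead:
    """A read passing the dense-cluster rule for one mismatch type."""

    read_id: str
    mismatch_type: tuple[str, str]  # on the read's own strand
    chrom: str
    start: int
    strand: str  # placement strand
    seq: str
    candidate_read_offsets: list[int]
    candidate_positions: list[int]  # genomic, 0-based, ascending
    other_mismatches: int
    cluster_span: Interval = field(init=False)
    alignment: AlignmentResult | None = None

    def __post_init__(self) -> None:
        pos = self.candidate_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("candidate positions must be strictly increasing")
        # span carries the edited strand (relevant for motif background)
        self.cluster_span = Interval(self.chrom, pos[0], pos[-1] + 1, self.site_strand)

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_positions)

    @property
    def site_strand(self) -> str:
        """Genomic strand of the edited adenosines, assuming A→G editing.

        For an A→G read-strand type the edited base lies on the placement
        strand; for T→C it lies on the opposite strand.
        """
        if self.mismatch_type == ("T", "C"):
            return "-" if self.strand == "+" else "+"
        return self.strand


@dataclass
class TypeScreenReport:
    """Per-mismatch-type tallies of the 12-type specificity screen."""

    reads: dict[tuple[str, str], int]
    events: dict[tuple[str, str], int]
    unique_sites: dict[tuple[str, str], int]

    @classmethod
    def from_detections(
        cls, per_type: dict[tuple[str, str], list[HyperEditedRead]]
    ) -> "TypeScreenReport":
        reads, events, sites = {}, {}, {}
        for t, dets in per_type.items():
            reads[t] = len(dets)
            events[t] = sum(d.n_candidates for d in dets)
            sites[t] = len({(d.chrom, p) for d in dets for p in d.candidate_positions})
        return cls(reads=reads, events=events, unique_sites=sites)

    def total(self, field_name: str = "unique_sites") -> int:
        return sum(getattr(self, field_name).values())


def _passes_filters(
    candidates: list,
    others: int,
    read_len: int,
    qual: str | None,
    cfg: DetectConfig,
) -> bool:
    """Clean-read filters: other-mismatch cap, edge concentration, quality."""
    if others > cfg.max_other(read_len):
        return False
    edge = cfg.edge_frac * read_len
    offsets = [m.read_offset for m in candidates]
    if max(offsets) < edge or min(offsets) >= read_len - edge:
        return False
    if qual is not None and len(set(qual)) > 1:
        mean_q = sum(ord(qual[o]) - 33 for o in offsets) / len(offsets)
        if mean_q < cfg.min_mean_qual:
            return False
    return True


def _trim(read: Read, trim_to: int | None) -> Read:
    if trim_to is None or len(read.seq) <= trim_to:
        return read
    # longer reads are trimmed from the start, keeping the 3' end
    return Read(read.id, read.seq[-trim_to:], read.qual[-trim_to:] if read.qual else None)


def _scheme_run(
    reads: Sequence[Read],
    genome: Genome,
    scheme: TransformScheme,
    cfg: DetectConfig,
    index_cache: dict | None = None,
) -> list[HyperEditedRead]:
    """Realign reads under one transform scheme and call dense clusters.

    Returns detections from both placement strands; each detection's
    ``mismatch_type`` is the scheme pair for '+' placements and the
    complemented pair for '−' placements.
    """
    key = scheme.pair
    if index_cache is not None and key in index_cache:
        index = index_cache[key]
    else:
        index = KmerIndex(genome, k=cfg.k, scheme=scheme)
        if index_cache is not None:
            index_cache[key] = index
    out: list[HyperEditedRead] = []
    for raw in reads:
        read = _trim(raw, cfg.trim_to)
        L = len(read.seq)
        if L < 20:
            continue
        budget = cfg.max_other(L)
        res = align_read(read, index, max_mm=budget, phase="transformed")
        if res is None or (cfg.require_unique and not res.unique):
            continue
        # classify native mismatches in the compared-copy (forward window)
        # orientation: candidates are scheme.from→scheme.to there
        cand = [m for m in res.mismatches if (m.ref, m.alt) == scheme.pair]
        others = len(res.mismatches) - len(cand)
        if len(cand) < min_sites(L, cfg.min_frac, cfg.strict_threshold):
            continue
        if not _passes_filters(cand, others, L, read.qual, cfg):
            continue
        if res.strand == "+":
            mtype = scheme.pair
        else:
            mtype = (_COMP[scheme.from_base], _COMP[scheme.to_base])
        positions = sorted(res.start + m.offset for m in cand)
        out.append(
            HyperEditedRead(
                read_id=read.id,
                mismatch_type=mtype,
                chrom=res.chrom,
                start=res.start,
                strand=res.strand,
                seq=read.seq,
                candidate_read_offsets=sorted(m.read_offset for m in cand),
                candidate_positions=positions,
                other_mismatches=others,
                alignment=res,
            )
        )
    return out


def detect_type(
    reads: Sequence[Read],
    genome: Genome,
    mismatch_type: tuple[str, str],
    cfg: DetectConfig | None = None,
    index_cache: dict | None = None,
) -> list[HyperEditedRead]:
    """Detect hyper-edited reads of one read-strand mismatch type.

    A read whose own-strand mismatches are X→Y is rescued either by scheme
    X→Y on a plus-strand placement or by the complemented scheme on a
    minus-strand placement; both routes are searched.
    """
    cfg = cfg or DetectConfig()
    scheme = TransformScheme(*mismatch_type)
    hits = [d for d in _scheme_run(reads, genome, scheme, cfg, index_cache) if d.strand == "+"]
    hits += [
        d
        for d in _scheme_run(reads, genome, scheme.complement(), cfg, index_cache)
        if d.strand == "-"
    ]
    return hits


def run_all_types(
    reads: Sequence[Read],
    genome: Genome,
    cfg: DetectConfig | None = None,
) -> tuple[dict[tuple[str, str], list[HyperEditedRead]], TypeScreenReport]:
    """Run the screen for all 12 ordered mismatch types with one parameter set.

    Each scheme is realigned once; detections are bucketed by their
    strand-resolved mismatch type. A read rescued under more than one screen
    keeps only its best explanation — the placement with the fewest total
    native mismatches, then the fewest non-candidate mismatches (a
    hyper-edited read from a repeat can otherwise also be "rescued" at a
    paralogous copy, where its edits line up with conserved adenosines and
    are masked again, planting spurious sites).
    """
    cfg = cfg or DetectConfig()
    cache: dict = {}
    by_read: dict[str, tuple[tuple[int, int, int], HyperEditedRead]] = {}
    for order, scheme in enumerate(ALL_SCHEMES):
        for det in _scheme_run(reads, genome, scheme, cfg, cache):
            key = (det.n_candidates + det.other_mismatches, det.other_mismatches, order)
            prev = by_read.get(det.read_id)
            if prev is None or key < prev[0]:
                by_read[det.read_id] = (key, det)
    per_type: dict[tuple[str, str], list[HyperEditedRead]] = {s.pair: [] for s in ALL_SCHEMES}
    for _, det in by_read.values():
        per_type[det.mismatch_type].append(det)
    return per_type, TypeScreenReport.from_detections(per_type)


def collapse_sites(
    detections: Iterable[HyperEditedRead],
    stranded: bool = False,
) -> list[SiteRecord]:
    """Collapse per-read candidate sites to unique genomic sites with support.

    In unstranded mode a T→C cluster is the minus-strand appearance of A→G
    editing: its sites are reported as A→G on the inferred (opposite) strand
    and merged by genomic position with plus-strand support. Other mismatch
    types collapse within type, keeping the placement strand.
    """
    counts: dict[tuple[str, int, tuple[str, str]], int] = {}
    strands: dict[tuple[str, int, tuple[str, str]], str] = {}
    resolved: dict[tuple[str, int, tuple[str, str]], bool] = {}
    for det in detections:
        mtype = det.mismatch_type
        if not stranded and mtype == ("T", "C"):
            report_type = ("A", "G")
            strand = det.site_strand
            was_inferred = True
        else:
            report_type = mtype
            strand = det.strand
            was_inferred = False
        for pos in det.candidate_positions:
            key = (det.chrom, pos, report_type)
            counts[key] = counts.get(key, 0) + 1
            if key in strands:
                if strands[key] != strand:
                    strands[key] = "."  # conflicting orientation evidence
            else:
                strands[key] = strand
            resolved[key] = resolved.get(key, False) or not was_inferred or stranded
    out = [
        SiteRecord(
            chrom=chrom,
            pos=pos,
            mismatch_type=mtype,
            support=n,
            strand=strands[(chrom, pos, mtype)],
            strand_resolved=True,
        )
        for (chrom, pos, mtype), n in counts.items()
    ]
    out.sort(key=lambda s: (s.chrom, s.pos, s.mismatch_type))
    return out
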