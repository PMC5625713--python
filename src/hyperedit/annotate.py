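"""Annotation overlap and expression context of hyper-edited loci.

Two questions about the detected sites: where do they fall (coding sequence
vs repeats — clustered editing is expected to concentrate in repeats and be
rare in coding sequence), and do the loci also express unedited transcripts
(most hyper-edited loci support no reads other than the hyper-edited ones)?
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .align import AlignmentResult
from .detect import HyperEditedRead
from .io import Interval, SiteRecord


def _trees(intervals: list[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.label)
    return trees


def overlap_fraction(
    sites: list[SiteRecord], intervals: list[Interval]
) -> tuple[float, dict[str, int]]:
    """Fraction of unique sites inside ≥1 interval, with per-label counts.

    A site overlaps an annotation if its position falls inside the interval
    regardless of strand or reading frame (table overlap, not codon logic).
    Returns (0.0, {}) for empty site or interval lists.
    """
    if not sites or not intervals:
        return 0.0, {}
    trees = _trees(intervals)
    n_in = 0
    per_label: dict[str, int] = {}
    for s in sites:
        hits = trees[s.chrom][s.pos] if s.chrom in trees else set()
        if hits:
            n_in += 1
            for h in hits:
                label = h.data or "(unlabeled)"
                per_label[label] = per_label.get(label, 0) + 1
    return n_in / len(sites), per_label


@dataclass
class LocusExpression:
    locus: Interval
    n_hyper_reads: int
    n_initial_reads: int

    @property
    def edited_only(self) -> bool:
        return self.n_initial_reads == 0


@dataclass
class SiteLevel:
    chrom: str
    pos: int
    edited_reads: int
    total_reads: int

    @property
    def level(self) -> float:
        return self.edited_reads / self.total_reads

    @property
    def tier(self) -> str:
        """Editing-level tier: strong (>30%), moderate (1–30%), low (<1%)."""
        lv = self.level
        if lv > 0.30:
            return "strong"
        if lv >= 0.01:
            return "moderate"
        return "low"


@dataclass
class ExpressionReport:
    loci: list[LocusExpression]
    site_levels: list[SiteLevel]

    @property
    def fraction_edited_only_loci(self) -> float:
        if not self.loci:
            return float("nan")
        return sum(l.edited_only for l in self.loci) / len(self.loci)

    @property
    def fraction_edited_only_sites(self) -> float:
        """Same question counted per site (sites in edited-only loci)."""
        if not self.site_levels:
            return float("nan")
        return sum(s.level >= 1.0 for s in self.site_levels) / len(self.site_levels)


def _merge_spans(spans: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in sorted(spans, key=lambda x: (x.chrom, x.start)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out.pop()
            out.append(Interval(prev.chrom, prev.start, max(prev.end, iv.end)))
        else:
            out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


def unedited_expression(
    detections: list[HyperEditedRead],
    initial_alignments: list[AlignmentResult],
    sites: list[SiteRecord] | None = None,
) -> ExpressionReport:
    """Expression context of hyper-edited loci.

    Loci are the merged cluster spans of the detected reads. A locus is
    "edited-only" when no initially-mapped read overlaps it. Per-site editing
    level = hyper-edited support / all covering reads (rescued + initial);
    duplicate read ids at a site count once.
    """
    loci = _merge_spans([d.cluster_span for d in detections])
    init_trees: dict[str, IntervalTree] = {}
    for aln in initial_alignments:
        init_trees.setdefault(aln.chrom, IntervalTree()).addi(
            aln.start, aln.end, aln.read_id
        )
    locus_rows: list[LocusExpression] = []
    for locus in loci:
        n_init = (
            len({h.data for h in init_trees[locus.chrom][locus.start : locus.end]})
            if locus.chrom in init_trees
            else 0
        )
        n_hyper = len(
            {d.read_id for d in detections if d.cluster_span.overlaps(locus)}
        )
        locus_rows.append(LocusExpression(locus, n_hyper, n_init))

    site_rows: list[SiteLevel] = []
    site_support: dict[tuple[str, int], set[str]] = {}
    for d in detections:
        for pos in d.candidate_positions:
            site_support.setdefault((d.chrom, pos), set()).add(d.read_id)
    keys = (
        [(s.chrom, s.pos) for s in sites]
        if sites is not None
        else sorted(site_support)
    )
    for chrom, pos in keys:
        edited_ids = site_support.get((chrom, pos), set())
        init_ids = (
            {h.data for h in init_trees[chrom][pos]} if chrom in init_trees else set()
        )
        total = len(edited_ids | init_ids)
        if total == 0:
            continue
        site_rows.append(SiteLevel(chrom, pos, len(edited_ids), total))
    return ExpressionReport(loci=locus_rows, site_levels=site_rows)


def min_edited_fraction(
    read_length: int, min_sites: int, double_strand: bool = True
) -> float:
    """Lower bound on the fraction of edited base pairs in a hyper-edited
    dsRNA region implied by the per-read site threshold.

    Each qualifying read carries at least ``min_sites`` edits, and a similar
    number is expected on the complementary strand of the duplex, doubling
    the count per substrate; dividing by the read length gives the bound
    (10% for 80-bp reads at the four-site threshold).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return min_sites * (2 if double_strand else 1) / read_length
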