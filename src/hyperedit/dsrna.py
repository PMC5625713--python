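"""Reverse-complement structure search linking editing clusters to dsRNA.

ADAR requires double-stranded RNA. A transcript forms long intramolecular
dsRNA when it carries two reverse-complementary segments — typically two
inverted copies of the same repeat within a short genomic distance — or a
palindromic repeat that folds on itself. This module asks, for each
hyper-edited cluster (and for randomly sampled genomic windows), whether a
reverse-oriented near-copy exists within a ±2 kb flank, using gapped local
alignment with bl2seq-style scoring (match +2, mismatch −3, gap open 5,
gap extend 2, word size 7, no low-complexity filter). A same-strand search
over the identical region provides the non-dsRNA-forming control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import Genome, Interval, SiteRecord, revcomp


@dataclass(frozen=True)
class LocalAlignParams:
    """bl2seq-style local-alignment scoring (reward +2 regime)."""

    match: int = 2
    mismatch: int = -3
    word_size: int = 7  # seeding granularity of the original tool; exact DP here
    gap_open: int = 5  # charged as -(gap_open + gap_extend) for the first gap base
    gap_extend: int = 2
    low_complexity_filter: bool = False

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match reward > 0 > mismatch penalty")


DEFAULT_PARAMS = LocalAlignParams()


@dataclass
class LocalAlignment:
    """Best gapped local alignment between two sequences."""

    score: float
    identity: float  # matches / aligned columns, gaps counted as mismatches
    n_matches: int
    aligned_length: int  # alignment columns including gaps
    query_span: tuple[int, int]  # 0-based half-open, on the query
    subject_span: tuple[int, int]


@dataclass
class DsRNAHit:
    """A reverse-orientation (or same-strand control) partner for a locus."""

    query: Interval
    partner: Interval
    orientation: str  # "reverse" | "same-strand-control"
    identity: float
    aligned_length: int
    coverage_of_query: float  # ungapped query-span coverage of the query length
    score: float


def _aligner(params: LocalAlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def local_align(
    query: str, subject: str, params: LocalAlignParams = DEFAULT_PARAMS
) -> LocalAlignment | None:
    """Best local alignment of query vs subject (Smith–Waterman with gaps).

    Returns None when no positive-scoring alignment exists. Ties between
    co-optimal alignments are broken deterministically by the aligner's
    traceback order. N never matches anything (it scores as a mismatch).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(params)
    score = aligner.score(subject, query)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(subject, query)))
    s_blocks, q_blocks = aln.aligned
    n_match = 0
    aligned_cols = 0
    prev_s = prev_q = None
    for (ss, se), (qs, qe) in zip(s_blocks, q_blocks):
        if prev_s is not None:
            aligned_cols += max(ss - prev_s, qs - prev_q)  # gap columns
        block_s = subject[ss:se]
        block_q = query[qs:qe]
        n_match += sum(a == b and a != "N" for a, b in zip(block_s, block_q))
        aligned_cols += se - ss
        prev_s, prev_q = se, qe
    if aligned_cols == 0:
        return None
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return LocalAlignment(
        score=float(score),
        identity=n_match / aligned_cols,
        n_matches=n_match,
        aligned_length=aligned_cols,
        query_span=q_span,
        subject_span=s_span,
    )


def _flank_region(genome: Genome, cluster: Interval, flank: int) -> tuple[int, int, str]:
    start = max(0, cluster.start - flank)
    end = min(genome.length(cluster.chrom), cluster.end + flank)
    return start, end, genome.fetch(cluster.chrom, start, end)


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / max(1, a[1] - a[0])


def find_dsrna_partner(
    cluster: Interval,
    genome: Genome,
    flank: int = 2000,
    min_identity: float = 0.65,
    min_cov: float = 0.80,
    params: LocalAlignParams = DEFAULT_PARAMS,
) -> DsRNAHit | None:
    """Search the reverse complement of the ±flank region for a duplex partner.

    A hit requires identity ≥ min_identity over an alignment covering
    ≥ min_cov of the cluster length (ungapped query-span coverage). The
    cluster's own locus stays in the subject: a palindromic cluster
    legitimately partners with itself in reverse orientation.
    """
    qseq = genome.fetch(cluster.chrom, cluster.start, cluster.end)
    rstart, rend, region = _flank_region(genome, cluster, flank)
    aln = local_align(qseq, revcomp(region), params)
    if aln is None:
        return None
    coverage = (aln.query_span[1] - aln.query_span[0]) / len(cluster)
    if aln.identity < min_identity or coverage < min_cov:
        return None
    # map subject span from reverse-complement coordinates back to forward
    s0, s1 = aln.subject_span
    p_start, p_end = rend - s1, rend - s0
    return DsRNAHit(
        query=cluster,
        partner=Interval(cluster.chrom, p_start, p_end, "-"),
        orientation="reverse",
        identity=aln.identity,
        aligned_length=aln.aligned_length,
        coverage_of_query=coverage,
        score=aln.score,
    )


def control_same_strand(
    cluster: Interval,
    genome: Genome,
    flank: int = 2000,
    min_identity: float = 0.65,
    min_cov: float = 0.80,
    params: LocalAlignParams = DEFAULT_PARAMS,
) -> DsRNAHit | None:
    """Same search without reverse-complementing: similar sequence on the
    same strand cannot base-pair, so this rate is the structural control.

    The cluster's own span is masked with N in the subject so the trivial
    self-identity never counts.
    """
    qseq = genome.fetch(cluster.chrom, cluster.start, cluster.end)
    rstart, rend, region = _flank_region(genome, cluster, flank)
    masked = (
        region[: cluster.start - rstart]
        + "N" * len(cluster)
        + region[cluster.end - rstart :]
    )
    aln = local_align(qseq, masked, params)
    if aln is None:
        return None
    coverage = (aln.query_span[1] - aln.query_span[0]) / len(cluster)
    if aln.identity < min_identity or coverage < min_cov:
        return None
    s0, s1 = aln.subject_span
    partner = Interval(cluster.chrom, rstart + s0, rstart + s1, "+")
    if _overlap_frac((partner.start, partner.end), (cluster.start, cluster.end)) > 0.5:
        return None  # residual self-hit
    return DsRNAHit(
        query=cluster,
        partner=partner,
        orientation="same-strand-control",
        identity=aln.identity,
        aligned_length=aln.aligned_length,
        coverage_of_query=coverage,
        score=aln.score,
    )


def genomic_dsrna_potential(
    genome: Genome,
    n_windows: int,
    window: int = 50,
    flank: int = 2000,
    min_identity: float = 0.95,
    min_len: int = 40,
    seed: int = 0,
    params: LocalAlignParams = DEFAULT_PARAMS,
    max_n_frac: float = 0.10,
) -> float:
    """Fraction of random genomic windows with a reverse-oriented near-copy.

    Samples ``n_windows`` windows of ``window`` bp (length-weighted across
    chromosomes), resampling windows whose N content exceeds ``max_n_frac``,
    and scores a window as dsRNA-capable when the reverse complement of its
    ±flank region contains an alignment of ≥ min_len columns at
    ≥ min_identity. Deterministic given the seed.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    chroms = [c for c in genome.chroms if genome.length(c) >= window]
    if not chroms:
        raise ValueError("window longer than every chromosome")
    lengths = np.array([genome.length(c) - window + 1 for c in chroms], dtype=float)
    rng = np.random.default_rng(seed)
    hits = 0
    sampled = 0
    attempts = 0
    while sampled < n_windows and attempts < 50 * n_windows:
        attempts += 1
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        start = int(rng.integers(0, genome.length(chrom) - window + 1))
        wseq = genome.fetch(chrom, start, start + window)
        if wseq.count("N") > max_n_frac * window:
            continue
        sampled += 1
        iv = Interval(chrom, start, start + window)
        rstart, rend, region = _flank_region(genome, iv, flank)
        aln = local_align(wseq, revcomp(region), params)
        if aln is not None and aln.identity >= min_identity and aln.aligned_length >= min_len:
            hits += 1
    if sampled == 0:
        raise ValueError("could not sample any N-free window")
    return hits / sampled


def dsrna_editing_enrichment(
    hits: list[DsRNAHit],
    sites: list[SiteRecord],
    genome: Genome,
) -> float:
    """Fold-change of editing-site density inside vs outside predicted dsRNA.

    Predicted dsRNA regions are the union of query and partner intervals of
    the reverse-orientation hits. Returns NaN (flagged undefined) when there
    are no sites or the outside density is zero.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.orientation != "reverse":
            continue
        for iv in (h.query, h.partner):
            spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    inside_bases = 0
    for chrom, ivs in spans.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
        inside_bases += sum(e - s for s, e in out)
    total_bases = genome.total_length()
    outside_bases = total_bases - inside_bases
    if not sites or outside_bases <= 0 or inside_bases == 0:
        return float("nan")
    inside_sites = 0
    for s in sites:
        for lo, hi in merged.get(s.chrom, []):
            if lo <= s.pos < hi:
                inside_sites += 1
                break
    outside_sites = len(sites) - inside_sites
    density_in = inside_sites / inside_bases
    density_out = outside_sites / outside_bases
    if density_out == 0:
        return float("inf")
    return density_in / density_out
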