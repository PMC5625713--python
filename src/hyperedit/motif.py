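"""ADAR neighbor-preference profiles and their cross-species clustering.

ADAR deaminates adenosines in dsRNA with a sequence bias at the immediately
flanking positions: G is depleted one base upstream of the edited A in all
ADARs characterized so far, while the downstream (+1) preference differs
between lineages (G in one group, A in the other). The profile here is a
4 (base) × 2 (position −1/+1) enrichment matrix over unique edited sites,
computed on the edited strand against a background of unedited adenosines,
and species-level profiles are compared by hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .io import Genome, Interval, SiteRecord, revcomp

BASES = "ACGT"
POSITIONS = (-1, +1)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MotifProfile:
    """Neighbor-base counts and enrichments around edited adenosines.

    ``counts[b, p]`` and ``background[b, p]`` are occurrence counts of base
    ``BASES[b]`` at position ``POSITIONS[p]`` relative to edited sites and to
    background (unedited) adenosines respectively; ``enrichment`` is the
    ratio of the corresponding frequency fractions. Entries with zero
    background frequency have undefined enrichment (NaN).
    """

    counts: np.ndarray  # (4, 2) ints
    background: np.ndarray  # (4, 2) ints
    n_sites: int
    low_confidence: bool = False
    enrichment: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore", invalid="ignore"):
            fg = self.counts / self.counts.sum(axis=0, keepdims=True)
            bg = self.background / self.background.sum(axis=0, keepdims=True)
            self.enrichment = np.where(bg > 0, fg / bg, np.nan)

    def get(self, base: str, position: int) -> float:
        return float(self.enrichment[BASES.index(base), POSITIONS.index(position)])

    def vector(self) -> np.ndarray:
        """Flattened 8-dimensional enrichment vector (base-major, −1 then +1)."""
        return np.nan_to_num(self.enrichment, nan=1.0).ravel()

    def to_rows(self) -> list[dict]:
        rows = []
        for bi, b in enumerate(BASES):
            for pi, p in enumerate(POSITIONS):
                rows.append(
                    {
                        "base": b,
                        "position": p,
                        "site_count": int(self.counts[bi, pi]),
                        "background_count": int(self.background[bi, pi]),
                        "enrichment": float(self.enrichment[bi, pi]),
                    }
                )
        return rows


def _context(genome: Genome, chrom: str, pos: int, strand: str) -> tuple[str, str] | None:
    """(−1, +1) bases on the edited strand, or None at sequence boundaries."""
    seq = genome[chrom]
    if pos - 1 < 0 or pos + 1 >= len(seq):
        return None
    if strand == "-":
        return _COMP[seq[pos + 1]], _COMP[seq[pos - 1]]
    return seq[pos - 1], seq[pos + 1]


def build_profile(
    sites: list[SiteRecord],
    genome: Genome,
    cluster_spans: list[Interval] | None = None,
    background: str = "local",
    min_sites_confident: int = 50,
) -> MotifProfile:
    """Tally −1/+1 contexts of edited sites against a background of adenosines.

    ``background="local"`` uses adenosines inside the detected cluster spans
    (on each span's strand) that are not edited sites — this controls for the
    base composition of the edited regions themselves. ``background="genome"``
    uses every adenosine on both strands of the genome.
    """
    ag = [s for s in sites if s.mismatch_type == ("A", "G") and s.strand in "+-"]
    counts = np.zeros((4, 2), dtype=np.int64)
    for s in ag:
        ctx = _context(genome, s.chrom, s.pos, s.strand)
        if ctx is None:
            continue
        counts[BASES.index(ctx[0]), 0] += 1
        counts[BASES.index(ctx[1]), 1] += 1

    edited = {(s.chrom, s.pos, s.strand) for s in ag}
    bg = np.zeros((4, 2), dtype=np.int64)
    if background == "local" and cluster_spans:
        for span in cluster_spans:
            seq = genome[span.chrom]
            strand = span.strand if span.strand in "+-" else "+"
            target = "A" if strand == "+" else "T"
            for pos in range(span.start, span.end):
                if seq[pos] != target or (span.chrom, pos, strand) in edited:
                    continue
                ctx = _context(genome, span.chrom, pos, strand)
                if ctx is None:
                    continue
                bg[BASES.index(ctx[0]), 0] += 1
                bg[BASES.index(ctx[1]), 1] += 1
    else:
        for chrom, seq in genome.sequences.items():
            for strand, target in (("+", "A"), ("-", "T")):
                for pos in range(1, len(seq) - 1):
                    if seq[pos] != target or (chrom, pos, strand) in edited:
                        continue
                    ctx = _context(genome, chrom, pos, strand)
                    bg[BASES.index(ctx[0]), 0] += 1
                    bg[BASES.index(ctx[1]), 1] += 1
    n_usable = int(counts[:, 0].sum())
    return MotifProfile(
        counts=counts,
        background=bg,
        n_sites=n_usable,
        low_confidence=n_usable < min_sites_confident,
    )


def upstream_depletion(profile: MotifProfile) -> float:
    """Enrichment of G at the −1 position; < 1 for ADAR-like editing.

    NaN (flagged undefined) when the background contains no G at −1.
    """
    return profile.get("G", -1)


def cluster_profiles(
    labeled_profiles: list[tuple[str, MotifProfile]],
    k: int = 2,
) -> tuple[dict[str, int], np.ndarray]:
    """Agglomerative clustering of species motif profiles.

    Average-linkage hierarchical clustering on Euclidean distance between
    8-dimensional enrichment vectors, cut into ``k`` groups. Returns a
    label→group mapping (groups renumbered 0.. by first appearance in input
    order, which makes ties deterministic under label order) and the scipy
    linkage matrix.
    """
    if len(labeled_profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = [lab for lab, _ in labeled_profiles]
    X = np.vstack([p.vector() for _, p in labeled_profiles])
    Z = linkage(X, method="average", metric="euclidean")
    raw = fcluster(Z, t=min(k, len(labels)), criterion="maxclust")
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for lab, g in zip(labels, raw):
        if g not in remap:
            remap[g] = len(remap)
        assignment[lab] = remap[g]
    return assignment, Z
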