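"""A small deterministic gapless read aligner with a transformed-alphabet mode.

Hyper-edited reads carry so many A→G mismatches that a mismatch-limited
aligner rejects them. The rescue trick is to collapse the edited base pair
away: substitute every A with G (or any other ordered base pair) in *both*
the reads and the reference, realign in the reduced alphabet, then recover
the native-alphabet mismatches from the placement. This module provides the
aligner used for both the initial (native) pass and the transformed pass.

Alignment is gapless and end-to-end: the best placement by mismatch count is
found via non-overlapping seed tiling (pigeonhole: a read with ≤ max_mm
mismatches has at least one exact seed among max_mm + 1 tiles).

Strand handling: the read's reverse complement is aligned against the forward
reference; the transform is applied to the read copy being compared, after
strand resolution. A minus-strand placement under scheme X→Y therefore masks
mismatches that read complement(X)→complement(Y) on the read's own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import Genome, Read, revcomp

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TransformScheme:
    """The alphabet-collapsing substitution applied to reads and reference."""

    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("transform must change the base")
        for b in (self.from_base, self.to_base):
            if b not in _BASES:
                raise ValueError(f"invalid base {b!r}")

    def apply(self, seq: str) -> str:
        return seq.replace(self.from_base, self.to_base)

    def complement(self) -> "TransformScheme":
        return TransformScheme(_COMP[self.from_base], _COMP[self.to_base])

    @property
    def pair(self) -> tuple[str, str]:
        return (self.from_base, self.to_base)


#: All 12 ordered mismatch types, as transform schemes.
ALL_SCHEMES: tuple[TransformScheme, ...] = tuple(
    TransformScheme(a, b) for a in _BASES for b in _BASES if a != b
)


@dataclass
class Mismatch:
    """A native-alphabet mismatch within a gapless placement.

    ``offset`` indexes the forward-reference window (== genomic position −
    alignment start); ``read_offset`` indexes the read as sequenced.
    """

    offset: int
    ref: str
    alt: str
    read_offset: int


@dataclass
class AlignmentResult:
    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str  # placement strand of the read on the reference
    n_mm: int  # mismatch count in the (possibly transformed) comparison space
    mismatches: list[Mismatch]  # native-alphabet mismatches at this placement
    unique: bool
    phase: str  # "initial" | "transformed"
    seq: str = ""  # read sequence as sequenced
    read_length: int = 0

    @property
    def end(self) -> int:
        return self.start + self.read_length


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class KmerIndex:
    """Exact-match k-mer seed index over a (optionally transformed) genome.

    The index holds only the forward strand of each reference sequence;
    reverse-strand placements are found by querying with the reverse
    complement of the read.
    """

    def __init__(self, genome: Genome, k: int = 16, scheme: TransformScheme | None = None):
        if k < 1:
            raise ValueError("k must be positive")
        shortest = min((len(s) for s in genome.sequences.values()), default=0)
        if shortest and k > shortest:
            raise ValueError(f"k={k} exceeds shortest reference sequence ({shortest} bp)")
        self.k = k
        self.scheme = scheme
        self.genome = genome
        self.chroms = list(genome.sequences)
        # native and transformed byte arrays per chromosome
        self._native = {c: _encode(genome[c]) for c in self.chroms}
        self._transformed = {
            c: _encode(scheme.apply(genome[c]) if scheme else genome[c]) for c in self.chroms
        }
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for c in self.chroms:
            seq = scheme.apply(genome[c]) if scheme else genome[c]
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i : i + k], []).append((c, i))

    def query(self, kmer: str) -> list[tuple[str, int]]:
        """Positions of an exact (transformed-alphabet) k-mer, forward strand."""
        return self._kmers.get(kmer, [])

    def transformed_window(self, chrom: str, start: int, length: int) -> np.ndarray:
        return self._transformed[chrom][start : start + length]

    def native_window(self, chrom: str, start: int, length: int) -> np.ndarray:
        return self._native[chrom][start : start + length]


def build_index(genome: Genome, scheme: TransformScheme | None = None, k: int = 16) -> KmerIndex:
    return KmerIndex(genome, k=k, scheme=scheme)


def _tile_starts(read_len: int, k: int, n_tiles: int) -> list[int]:
    """Starts of up to n_tiles non-overlapping k-length tiles spread over the read."""
    n = min(n_tiles, max(1, read_len // k))
    if n == 1:
        return [0]
    span = read_len - k
    return sorted({round(i * span / (n - 1)) for i in range(n)})


def align_read(
    read: Read,
    index: KmerIndex,
    max_mm: int = 3,
    phase: str = "initial",
) -> AlignmentResult | None:
    """Best gapless end-to-end placement of a read, or None if unmapped.

    Searches both strands via seed tiling. The returned mismatch list is in
    the native alphabet regardless of the index's transform scheme; ``n_mm``
    is the mismatch count in the comparison (transformed) space used for the
    mapping decision. ``unique`` is False on a tie for best.
    """
    L = len(read.seq)
    k = index.k
    if L < k:
        return None
    scheme = index.scheme
    best: tuple[int, str, int, str] | None = None  # (mm, chrom, start, strand)
    second_mm = None
    seen: set[tuple[str, int, str]] = set()
    queries = {"+": read.seq, "-": revcomp(read.seq)}
    for strand, native_query in queries.items():
        compared = scheme.apply(native_query) if scheme else native_query
        cmp_arr = _encode(compared)
        for s in _tile_starts(L, k, max_mm + 1):
            for chrom, hit in index.query(compared[s : s + k]):
                start = hit - s
                if start < 0 or start + L > len(index._transformed[chrom]):
                    continue
                key = (chrom, start, strand)
                if key in seen:
                    continue
                seen.add(key)
                window = index.transformed_window(chrom, start, L)
                mm = int(np.count_nonzero(window != cmp_arr))
                if best is None or mm < best[0]:
                    second_mm = best[0] if best else None
                    best = (mm, chrom, start, strand)
                elif second_mm is None or mm < second_mm:
                    second_mm = mm
    if best is None or best[0] > max_mm:
        return None
    mm, chrom, start, strand = best
    native_query = queries[strand]
    q_arr = _encode(native_query)
    ref_win = index.native_window(chrom, start, L)
    diff = np.nonzero(ref_win != q_arr)[0]
    mismatches = [
        Mismatch(
            offset=int(j),
            ref=chr(ref_win[j]),
            alt=chr(q_arr[j]),
            read_offset=int(j) if strand == "+" else L - 1 - int(j),
        )
        for j in diff
    ]
    return AlignmentResult(
        read_id=read.id,
        chrom=chrom,
        start=start,
        strand=strand,
        n_mm=mm,
        mismatches=mismatches,
        unique=(second_mm is None or mm < second_mm),
        phase=phase,
        seq=read.seq,
        read_length=L,
    )


@dataclass
class BatchResult:
    mapped: list[AlignmentResult]
    unmapped: list[Read]
    mapped_bases: int = 0

    def __iter__(self):
        return iter((self.mapped, self.unmapped, self.mapped_bases))


def align_batch(
    reads: Iterable[Read],
    genome: Genome,
    max_mm: int = 3,
    k: int = 16,
    index: KmerIndex | None = None,
) -> BatchResult:
    """Partition reads into mapped / unmapped under the native-alphabet pass.

    ``mapped_bases`` sums read lengths over mapped reads and feeds the
    per-million-mapped-bases normalization downstream.
    """
    if index is None:
        index = KmerIndex(genome, k=k)
    mapped: list[AlignmentResult] = []
    unmapped: list[Read] = []
    bases = 0
    for read in reads:
        res = align_read(read, index, max_mm=max_mm, phase="initial")
        if res is None:
            unmapped.append(read)
        else:
            mapped.append(res)
            bases += len(read.seq)
    return BatchResult(mapped=mapped, unmapped=unmapped, mapped_bases=bases)
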