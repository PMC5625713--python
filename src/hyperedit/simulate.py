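"""Synthetic genomes and RNA-seq reads with planted ADAR hyper-editing.

The generator emulates the statistical structure the detection screen
assumes: a genome carrying repeat families (inverted near-copies within a
short flank, a palindromic self-folding family, dispersed non-pairing
fragments), transcripts tiled over the genome on both strands, and reads in
which a fraction of transcript molecules are hyper-edited — every adenosine
inside a dsRNA-forming span converted to G with a per-site probability
modulated by a planted neighbor motif. Sequencing errors and homozygous
SNPs are layered on afterwards, and every planted feature is recorded in a
ground-truth table.

dsRNA-forming spans are the union of (a) both members of an inverted repeat
pair plus the intervening sequence, and (b) palindromic-family copies —
the two substrates on which ADAR acts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Genome, Interval, Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class RepeatFamilySpec:
    """One repeat family to plant in the genome.

    ``divergence`` is the expected per-base substitution fraction between a
    copy and the family consensus; ``palindromic`` families have a consensus
    that equals its own reverse complement (a self-folding hairpin repeat);
    ``inverted_pair_fraction`` of the copies are placed as reverse-complement
    pairs separated by at most ``pair_gap_max`` bases.
    """

    name: str
    consensus_length: int = 300
    copy_number: int = 4
    divergence: float = 0.05
    palindromic: bool = False
    inverted_pair_fraction: float = 0.0
    pair_gap_max: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.divergence <= 0.35):
            raise ValueError("divergence must be in [0, 0.35]")
        if not (0 <= self.inverted_pair_fraction <= 1):
            raise ValueError("inverted_pair_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    genome_length: int = 50_000
    gc_content: float = 0.42
    repeat_families: list[RepeatFamilySpec] = field(default_factory=lambda: default_families())
    n_reads: int = 20_000
    read_length: int = 80
    #: marginal per-adenosine editing probability inside dsRNA spans of edited
    #: molecules; ~0.3 makes edited duplexes carry the observed ~6–7 sites per
    #: 80-bp read, well over the ~10% edited-base floor
    edit_rate_per_A: float = 0.3
    #: probability a sampled transcript molecule is hyper-edited
    p_transcript_edited: float = 0.8
    motif_group: str = "downstream_G"  # or "downstream_A": planted +1 preference
    #: ADAR site preference is a property of the site, not the molecule: each
    #: adenosine is marked editable once per genome with these probabilities,
    #: and per-molecule editing is then confined to the editable set (keeping
    #: edit_rate_per_A as the marginal per-A rate)
    editable_prob_preferred: float = 0.9  # when the +1 base matches motif_group
    editable_prob_other: float = 0.25
    upstream_G_depletion: float = 0.3  # editability multiplier when −1 is G
    seq_error_rate: float = 0.0
    snp_rate: float = 0.0
    stranded: bool = False
    transcript_min: int = 1000
    transcript_max: int = 3000
    coding_fraction: float = 0.3  # fraction of transcripts contributing a coding interval
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.gc_content,
            self.edit_rate_per_A,
            self.p_transcript_edited,
            self.upstream_G_depletion,
            self.seq_error_rate,
            self.snp_rate,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be >= 10 x read_length")
        if self.motif_group not in ("downstream_G", "downstream_A"):
            raise ValueError("motif_group must be downstream_G or downstream_A")


def default_families() -> list[RepeatFamilySpec]:
    """Default repeat content: an inverted-pairing family, a palindromic
    (self-folding) family, and dispersed non-pairing fragments."""
    return [
        RepeatFamilySpec(
            "IRpair", consensus_length=300, copy_number=8, divergence=0.08,
            inverted_pair_fraction=1.0,
        ),
        RepeatFamilySpec(
            "Palindrome", consensus_length=300, copy_number=3, divergence=0.06,
            palindromic=True,
        ),
        RepeatFamilySpec(
            "Dispersed", consensus_length=200, copy_number=5, divergence=0.12,
        ),
    ]


@dataclass
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    chrom: str
    transcript_strand: str
    frag_start: int  # genomic, 0-based
    flipped: bool  # read reported on the strand opposite the transcript
    edited: bool
    edited_genomic_positions: list[int] = field(default_factory=list)
    edited_read_offsets: list[int] = field(default_factory=list)  # as-sequenced coords
    error_offsets: list[int] = field(default_factory=list)

    @property
    def read_strand(self) -> str:
        """Strand of the reported read sequence on the genome."""
        flip = {"+": "-", "-": "+"}
        return flip[self.transcript_strand] if self.flipped else self.transcript_strand


@dataclass
class TruthTable:
    """Everything planted into a synthetic dataset."""

    repeats: list[Interval] = field(default_factory=list)
    dsrna_spans: list[Interval] = field(default_factory=list)
    transcripts: list[Interval] = field(default_factory=list)
    coding: list[Interval] = field(default_factory=list)
    snp_positions: list[int] = field(default_factory=list)
    donor_sequences: dict[str, str] = field(default_factory=dict)
    reads: list[ReadTruth] = field(default_factory=list)

    def edited_sites(self) -> set[tuple[str, int]]:
        return {
            (r.chrom, p) for r in self.reads if r.edited for p in r.edited_genomic_positions
        }


class GenomeSizingError(ValueError):
    """Requested repeats do not fit in the requested genome length."""


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(rng.choice(_BASES, size=n, p=probs)).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute exactly round(rate * L) distinct positions.

    The deterministic count keeps every palindromic copy within the
    1 − 2·divergence reverse-complement self-similarity bound (each
    substitution can break at most two mirrored positions).
    """
    n_sub = int(round(rate * len(seq)))
    if n_sub == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.choice(len(arr), size=n_sub, replace=False)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return bytes(arr).decode()


def _palindromic_consensus(rng: np.random.Generator, length: int, gc: float) -> str:
    half = _random_seq(rng, length // 2, gc)
    pal = half + revcomp(half)
    return pal if len(pal) == length else pal[:length]


def build_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[Genome, TruthTable]:
    """Build the reference genome, plant repeats and SNPs, define transcripts.

    The returned genome is the *reference* handed to the aligner; the truth
    table carries the donor sequence (reference + homozygous SNPs) that reads
    are actually sampled from, so SNPs appear in every read of a locus while
    editing stays per-molecule.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    chrom = "chr1"
    glen = cfg.genome_length
    seq = list(_random_seq(rng, glen, cfg.gc_content))
    truth = TruthTable()

    total_repeat = sum(f.consensus_length * f.copy_number for f in cfg.repeat_families)
    if total_repeat > 0.6 * glen:
        raise GenomeSizingError(
            f"repeats need {total_repeat} bp but genome is only {glen} bp"
        )

    occupied: list[tuple[int, int]] = []

    def place(length: int, near: tuple[int, int] | None = None, max_gap: int = 0) -> int | None:
        for _ in range(200):
            if near is None:
                p = int(rng.integers(0, glen - length + 1))
            else:
                lo = near[1] + 50
                hi = min(near[1] + max_gap, glen - length)
                if hi <= lo:
                    return None
                p = int(rng.integers(lo, hi + 1))
            if all(p + length + 20 <= s or p >= e + 20 for s, e in occupied):
                occupied.append((p, p + length))
                return p
        return None

    for fam in cfg.repeat_families:
        if fam.consensus_length > glen:
            raise GenomeSizingError(f"consensus of {fam.name} longer than genome")
        consensus = (
            _palindromic_consensus(rng, fam.consensus_length, cfg.gc_content)
            if fam.palindromic
            else _random_seq(rng, fam.consensus_length, cfg.gc_content)
        )
        n_inverted = int(round(fam.copy_number * fam.inverted_pair_fraction))
        n_pairs = n_inverted // 2
        n_single = fam.copy_number - 2 * n_pairs
        for _ in range(n_pairs):
            copy1 = _mutate(rng, consensus, fam.divergence)
            copy2 = _mutate(rng, consensus, fam.divergence)
            p1 = place(len(copy1))
            if p1 is None:
                raise GenomeSizingError(f"cannot place copies of {fam.name}")
            gap_cap = min(fam.pair_gap_max, 2000)
            p2 = place(len(copy2), near=(p1, p1 + len(copy1)), max_gap=gap_cap)
            if p2 is None:
                p2 = place(len(copy2))
                if p2 is None:
                    raise GenomeSizingError(f"cannot place partner copy of {fam.name}")
                paired = False
            else:
                paired = True
            seq[p1 : p1 + len(copy1)] = copy1
            seq[p2 : p2 + len(copy2)] = revcomp(copy2)
            truth.repeats.append(Interval(chrom, p1, p1 + len(copy1), "+", fam.name))
            truth.repeats.append(Interval(chrom, p2, p2 + len(copy2), "-", fam.name))
            if paired:
                span = Interval(chrom, min(p1, p2), max(p1 + len(copy1), p2 + len(copy2)))
                truth.dsrna_spans.append(span)
        for _ in range(n_single):
            copy = _mutate(rng, consensus, fam.divergence)
            p = place(len(copy))
            if p is None:
                raise GenomeSizingError(f"cannot place copies of {fam.name}")
            strand = "+" if rng.random() < 0.5 else "-"
            seq[p : p + len(copy)] = copy if strand == "+" else revcomp(copy)
            truth.repeats.append(Interval(chrom, p, p + len(copy), strand, fam.name))
            if fam.palindromic:
                truth.dsrna_spans.append(Interval(chrom, p, p + len(copy)))

    reference = "".join(seq)

    # homozygous SNPs: the donor the reads come from differs from the reference
    donor = reference
    if cfg.snp_rate > 0:
        arr = np.frombuffer(reference.encode(), dtype=np.uint8).copy()
        snp_pos = np.nonzero(rng.random(glen) < cfg.snp_rate)[0]
        for i in snp_pos:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
        donor = bytes(arr).decode()
        truth.snp_positions = [int(i) for i in snp_pos]
    truth.donor_sequences = {chrom: donor}

    # transcripts tile the whole genome (1-3 kb), alternating random strands
    pos = 0
    while pos < glen:
        tlen = int(rng.integers(cfg.transcript_min, cfg.transcript_max + 1))
        end = min(pos + tlen, glen)
        strand = "+" if rng.random() < 0.5 else "-"
        truth.transcripts.append(Interval(chrom, pos, end, strand, f"tx{len(truth.transcripts)}"))
        if rng.random() < cfg.coding_fraction:
            mid = (end - pos) // 5
            if end - mid > pos + mid:
                truth.coding.append(Interval(chrom, pos + mid, end - mid, strand, "CDS"))
        pos = end

    genome = Genome(
        sequences={chrom: reference},
        repeats=list(truth.repeats),
        coding=list(truth.coding),
    )
    return genome, truth


def _span_mask(truth: TruthTable, glen: int) -> np.ndarray:
    mask = np.zeros(glen, dtype=bool)
    for iv in truth.dsrna_spans:
        mask[iv.start : iv.end] = True
    return mask


def simulate_reads(
    genome: Genome,
    truth: TruthTable,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Read], TruthTable]:
    """Sample reads from the donor genome's transcripts and plant editing.

    The editing model has two levels, mirroring ADAR's site-consistent
    preference. Once per genome, each transcript-strand adenosine inside a
    dsRNA-forming span is marked *editable* with a context-dependent
    probability (``editable_prob_preferred`` when its +1 base matches the
    planted motif group, ``editable_prob_other`` otherwise, scaled by
    ``upstream_G_depletion`` when the −1 base is G). A molecule sampled from
    a transcript overlapping a span is then hyper-edited with probability
    ``p_transcript_edited``, and in edited molecules each *editable*
    adenosine is deaminated with probability ``edit_rate_per_A`` divided by
    the editable fraction — so ``edit_rate_per_A`` stays the marginal per-A
    rate while site identity carries the motif. Sequencing errors and the
    read-strand flip of unstranded libraries are applied after editing.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    chrom = genome.chroms[0]
    donor = truth.donor_sequences.get(chrom, genome[chrom])
    glen = len(donor)
    L = cfg.read_length
    mask = _span_mask(truth, glen)
    transcripts = [t for t in truth.transcripts if len(t) >= L]
    if not transcripts:
        warnings.warn("no transcribed region can host a read; returning empty set")
        return [], truth
    weights = np.array([len(t) - L + 1 for t in transcripts], dtype=float)
    weights /= weights.sum()
    preferred = "G" if cfg.motif_group == "downstream_G" else "A"

    # per-genome editability map: which span adenosines ADAR would act on
    editable: dict[str, np.ndarray] = {}
    n_A = n_editable = 0
    draws = {"+": rng.random(glen), "-": rng.random(glen)}
    for strand in "+-":
        ed = np.zeros(glen, dtype=bool)
        target = "A" if strand == "+" else "T"
        for p in range(1, glen - 1):
            if not mask[p] or donor[p] != target:
                continue
            n_A += 1
            if strand == "+":
                down, up = donor[p + 1], donor[p - 1]
            else:
                down, up = _COMP[donor[p - 1]], _COMP[donor[p + 1]]
            q = cfg.editable_prob_preferred if down == preferred else cfg.editable_prob_other
            if up == "G":
                q *= cfg.upstream_G_depletion
            if draws[strand][p] < q:
                ed[p] = True
                n_editable += 1
        editable[strand] = ed
    frac_editable = n_editable / n_A if n_A else 0.0
    rate_e = min(1.0, cfg.edit_rate_per_A / frac_editable) if frac_editable > 0 else 0.0

    reads: list[Read] = []
    for i in range(cfg.n_reads):
        t = transcripts[int(rng.choice(len(transcripts), p=weights))]
        fstart = int(rng.integers(t.start, t.end - L + 1))
        frag_fwd = donor[fstart : fstart + L]
        span_overlap = bool(mask[fstart : fstart + L].any())
        edited = span_overlap and (rng.random() < cfg.p_transcript_edited)
        # work on the transcript strand
        tseq = frag_fwd if t.strand == "+" else revcomp(frag_fwd)
        tlist = list(tseq)
        edited_gpos: list[int] = []
        edited_toff: list[int] = []
        if edited and rate_e > 0:
            for off in range(L):
                gpos = fstart + off if t.strand == "+" else fstart + L - 1 - off
                if not editable[t.strand][gpos] or tlist[off] != "A":
                    continue
                if rng.random() < rate_e:
                    tlist[off] = "G"
                    edited_gpos.append(gpos)
                    edited_toff.append(off)
        molecule = "".join(tlist)
        flipped = (not cfg.stranded) and rng.random() < 0.5
        read_seq = revcomp(molecule) if flipped else molecule
        err_offsets: list[int] = []
        if cfg.seq_error_rate > 0:
            arr = np.frombuffer(read_seq.encode(), dtype=np.uint8).copy()
            hit = np.nonzero(rng.random(L) < cfg.seq_error_rate)[0]
            for j in hit:
                choices = _BASES[_BASES != arr[j]]
                arr[j] = rng.choice(choices)
            read_seq = bytes(arr).decode()
            err_offsets = [int(j) for j in hit]
        rid = f"r{i:06d}"
        reads.append(Read(id=rid, seq=read_seq, qual="?" * L))  # constant Q30
        truth.reads.append(
            ReadTruth(
                read_id=rid,
                chrom=chrom,
                transcript_strand=t.strand,
                frag_start=fstart,
                flipped=flipped,
                edited=edited,  # molecule-level flag; realized edits may be fewer
                edited_genomic_positions=sorted(edited_gpos),
                edited_read_offsets=sorted(
                    o if not flipped else L - 1 - o for o in edited_toff
                ),
                error_offsets=err_offsets,
            )
        )
    return reads, truth


def simulate_dataset(cfg: SimConfig) -> tuple[Genome, list[Read], TruthTable]:
    """Convenience: build the genome and sample reads with one seed lineage."""
    rng = np.random.default_rng(cfg.seed)
    genome, truth = build_genome(cfg, rng)
    reads, truth = simulate_reads(genome, truth, cfg, rng)
    return genome, reads, truth


def adar_null_control(cfg: SimConfig) -> tuple[Genome, list[Read], TruthTable]:
    """The identical generative process with editing switched off.

    Emulates an ADAR-lacking control species: downstream A→G cluster counts
    should be statistically indistinguishable from the other mismatch types.
    """
    return simulate_dataset(replace(cfg, edit_rate_per_A=0.0, p_transcript_edited=0.0))


# ---------------------------------------------------------------------------
# truth-table text serialization (tab-delimited)


def write_truth(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#section\tfields...\n")
        for iv in truth.repeats:
            fh.write(f"repeat\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{iv.label}\n")
        for iv in truth.dsrna_spans:
            fh.write(f"dsrna\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        for iv in truth.transcripts:
            fh.write(f"transcript\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{iv.label}\n")
        for p in truth.snp_positions:
            fh.write(f"snp\t{p}\n")
        for r in truth.reads:
            fh.write(
                "read\t{}\t{}\t{}\t{}\t{}\t{}\t{}\t{}\t{}\n".format(
                    r.read_id,
                    r.chrom,
                    r.transcript_strand,
                    r.frag_start,
                    int(r.flipped),
                    int(r.edited),
                    ",".join(map(str, r.edited_genomic_positions)) or ".",
                    ",".join(map(str, r.edited_read_offsets)) or ".",
                    ",".join(map(str, r.error_offsets)) or ".",
                )
            )
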