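"""dsRNA structure search: local alignment, partner search, genomic potential.

The independent oracle for the gapped local aligner is a plain Gotoh
(affine-gap Smith–Waterman) dynamic program implemented here in numpy.
"""

import numpy as np
import pytest

import hyperedit as he
from hyperedit.dsrna import (
    DEFAULT_PARAMS,
    LocalAlignParams,
    control_same_strand,
    dsrna_editing_enrichment,
    find_dsrna_partner,
    genomic_dsrna_potential,
    local_align,
)
from hyperedit.io import Genome, Interval, SiteRecord, revcomp

from conftest import random_genome

NEG = -(10**9)


def gotoh_local_score(a: str, b: str, p: LocalAlignParams = DEFAULT_PARAMS) -> float:
    """Affine-gap Smith–Waterman score by full dynamic programming.

    First gap base costs gap_open + gap_extend; each further base gap_extend,
    matching the scoring of the package aligner.
    """
    n, m = len(a), len(b)
    open_cost = p.gap_open + p.gap_extend
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - p.gap_extend)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - p.gap_extend)
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=100))
        aln = local_align(s, s)
        assert aln.identity == 1.0
        assert aln.aligned_length == 100
        assert aln.query_span == (0, 100) and aln.subject_span == (0, 100)

    def test_query_vs_reverse_complement_of_itself(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=80))
        aln = local_align(s, revcomp(revcomp(s)))
        assert aln.identity == 1.0

    def test_substituted_copy_identity_near_the_planted_rate(self, rng):
        idents = []
        for _ in range(20):
            s = list("".join(rng.choice(list("ACGT"), size=200)))
            mutant = s[:]
            for i in rng.choice(200, size=60, replace=False):
                mutant[i] = "ACGT"[(("ACGT".index(mutant[i])) + 1 + int(rng.integers(3))) % 4]
            aln = local_align("".join(s), "".join(mutant))
            idents.append(aln.identity)
        assert abs(np.mean(idents) - 0.70) < 0.05

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_score_matches_dp_oracle_on_random_pairs(self, rng):
        for trial in range(12):
            n = int(rng.integers(30, 140))
            a = "".join(rng.choice(list("ACGT"), size=n))
            if trial % 3 == 0:
                b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 500))))
            else:  # related pair: mutated / partially deleted copy
                bl = list(a)
                for i in rng.choice(n, size=n // 10, replace=False):
                    bl[i] = "ACGT"[int(rng.integers(4))]
                del bl[n // 3 : n // 3 + int(rng.integers(0, 6))]
                b = "".join(bl)
            aln = local_align(a, b)
            oracle = gotoh_local_score(a, b)
            got = aln.score if aln else 0.0
            assert got == pytest.approx(oracle), f"trial {trial}"

    def test_scoring_params_validated(self):
        with pytest.raises(ValueError):
            LocalAlignParams(match=-1, mismatch=-3)


def _genome_with_inverted_pair(rng, gap=600, div=0.0, size=12_000):
    seq = list("".join(rng.choice(list("ACGT"), size=size)))
    core = "".join(rng.choice(list("ACGT"), size=300))
    copy2 = list(core)
    for i in rng.choice(300, size=int(div * 300), replace=False):
        copy2[i] = "ACGT"[int(rng.integers(4))]
    p1 = 4000
    p2 = p1 + 300 + gap
    seq[p1 : p1 + 300] = core
    seq[p2 : p2 + 300] = revcomp("".join(copy2))
    return Genome(sequences={"chr1": "".join(seq)}), p1, p2


class TestPartnerSearch:
    def test_cluster_in_perfect_inverted_pair_finds_partner(self, rng):
        genome, p1, p2 = _genome_with_inverted_pair(rng)
        cluster = Interval("chr1", p1 + 50, p1 + 250)
        hit = find_dsrna_partner(cluster, genome)
        assert hit is not None
        assert hit.identity == pytest.approx(1.0)
        assert hit.coverage_of_query >= 0.99
        # partner is the mirrored window inside the second copy
        assert p2 <= hit.partner.start < hit.partner.end <= p2 + 300

    def test_reciprocal_search_finds_the_first_copy(self, rng):
        genome, p1, p2 = _genome_with_inverted_pair(rng)
        hit = find_dsrna_partner(Interval("chr1", p1 + 50, p1 + 250), genome)
        back = find_dsrna_partner(hit.partner, genome)
        assert back is not None
        assert back.partner.overlaps(Interval("chr1", p1 + 50, p1 + 250))
        assert back.identity == pytest.approx(hit.identity, abs=0.01)

    def test_diverged_pair_identity_tracks_divergence(self, rng):
        genome, p1, p2 = _genome_with_inverted_pair(rng, div=0.2)
        hit = find_dsrna_partner(Interval("chr1", p1 + 20, p1 + 280), genome)
        assert hit is not None
        assert 0.65 <= hit.identity <= 0.9

    def test_cluster_in_unique_sequence_has_no_partner(self, rng):
        genome = random_genome(rng, 10_000)
        assert find_dsrna_partner(Interval("chr1", 5000, 5200), genome) is None

    def test_palindrome_partners_with_itself(self, rng):
        seq = list("".join(rng.choice(list("ACGT"), size=8000)))
        half = "".join(rng.choice(list("ACGT"), size=150))
        pal = half + revcomp(half)
        seq[3000:3300] = pal
        genome = Genome(sequences={"chr1": "".join(seq)})
        hit = find_dsrna_partner(Interval("chr1", 3000, 3300), genome)
        assert hit is not None
        assert hit.identity == pytest.approx(1.0)
        assert hit.partner.overlaps(Interval("chr1", 3000, 3300))

    def test_direct_repeat_hits_control_not_reverse(self, rng):
        seq = list("".join(rng.choice(list("ACGT"), size=12_000)))
        core = "".join(rng.choice(list("ACGT"), size=300))
        seq[4000:4300] = core
        seq[5000:5300] = core  # same orientation
        genome = Genome(sequences={"chr1": "".join(seq)})
        cluster = Interval("chr1", 4050, 4250)
        assert find_dsrna_partner(cluster, genome) is None
        ctrl = control_same_strand(cluster, genome)
        assert ctrl is not None and ctrl.orientation == "same-strand-control"
        assert 5000 <= ctrl.partner.start < ctrl.partner.end <= 5300

    def test_inverted_pair_has_no_same_strand_control_hit(self, rng):
        genome, p1, _ = _genome_with_inverted_pair(rng)
        assert control_same_strand(Interval("chr1", p1 + 50, p1 + 250), genome) is None


class TestGenomicPotential:
    def test_random_genome_has_negligible_potential(self, rng):
        genome = random_genome(rng, 30_000)
        assert genomic_dsrna_potential(genome, 300, seed=2) < 1e-3

    def test_planted_inverted_fraction_recovered(self, rng):
        # perfect inverted pairs covering ~8% of the genome
        seq = list("".join(rng.choice(list("ACGT"), size=30_000)))
        for start in (2000, 10_000, 20_000):
            core = "".join(rng.choice(list("ACGT"), size=600))
            seq[start : start + 600] = core
            seq[start + 800 : start + 1400] = revcomp(core)
        genome = Genome(sequences={"chr1": "".join(seq)})
        frac = genomic_dsrna_potential(genome, 400, seed=2)
        covered = 3 * 1200 / 30_000
        assert abs(frac - covered) < 3 * np.sqrt(covered * (1 - covered) / 400) + 0.02

    def test_zero_windows_is_an_error(self, rng):
        with pytest.raises(ValueError):
            genomic_dsrna_potential(random_genome(rng, 5000), 0, seed=1)

    def test_window_longer_than_chromosomes_is_an_error(self):
        genome = Genome(sequences={"c": "ACGT" * 5})
        with pytest.raises(ValueError):
            genomic_dsrna_potential(genome, 10, window=50, seed=1)

    def test_determinism_under_seed(self, rng):
        genome = random_genome(rng, 20_000)
        a = genomic_dsrna_potential(genome, 100, seed=7)
        b = genomic_dsrna_potential(genome, 100, seed=7)
        assert a == b


class TestEditingEnrichment:
    def test_editing_confined_to_dsrna_gives_large_fold_change(self, rng):
        genome, p1, p2 = _genome_with_inverted_pair(rng)
        hit = find_dsrna_partner(Interval("chr1", p1 + 50, p1 + 250), genome)
        sites = [SiteRecord("chr1", p, ("A", "G"), 1, "+", True)
                 for p in range(p1 + 60, p1 + 240, 12)]
        sites.append(SiteRecord("chr1", 100, ("A", "G"), 1, "+", True))  # one stray
        fold = dsrna_editing_enrichment([hit], sites, genome)
        assert fold > 5

    def test_uniform_sites_give_fold_change_near_one(self, rng):
        genome = random_genome(rng, 20_000)
        hits = [he.DsRNAHit(Interval("chr1", 0, 10_000), Interval("chr1", 0, 10_000),
                            "reverse", 1.0, 10_000, 1.0, 0.0)]
        sites = [SiteRecord("chr1", int(p), ("A", "G"), 1, "+", True)
                 for p in rng.choice(20_000, size=400, replace=False)]
        fold = dsrna_editing_enrichment(hits, sites, genome)
        assert 0.7 < fold < 1.4

    def test_no_sites_is_flagged_undefined(self, rng):
        genome = random_genome(rng, 5000)
        assert np.isnan(dsrna_editing_enrichment([], [], genome))
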