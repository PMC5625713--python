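"""Cluster calling: threshold rule, type specificity, filters, site collapsing."""

import numpy as np
import pytest
from scipy import stats

import hyperedit as he
from hyperedit.detect import DetectConfig, min_sites
from hyperedit.io import Genome, Read, revcomp

from conftest import random_genome


class TestMinSites:
    def test_printed_worked_value_for_80bp(self):
        assert min_sites(80) == 4

    @pytest.mark.parametrize("L,expected", [(100, 5), (20, 1), (60, 3), (101, 6)])
    def test_default_is_ceiling_of_five_percent(self, L, expected):
        assert min_sites(L) == expected

    @pytest.mark.parametrize("L,expected", [(80, 5), (100, 6), (20, 2)])
    def test_strict_reading_is_smallest_integer_exceeding(self, L, expected):
        assert min_sites(L, strict=True) == expected

    def test_short_reads_rejected(self):
        with pytest.raises(ValueError):
            min_sites(19)


def _edited_read(genome: Genome, start: int, n_edits: int, rng, extra_mm: int = 0,
                 length: int = 80) -> Read:
    src = list(genome["chr1"][start : start + length])
    a_pos = [i for i, b in enumerate(src) if b == "A"]
    assert len(a_pos) >= n_edits
    # spread edits over the read so the edge filter is not triggered
    chosen = [a_pos[int(i)] for i in np.linspace(0, len(a_pos) - 1, n_edits)]
    for i in chosen:
        src[i] = "G"
    non_a = [i for i, b in enumerate(src) if b not in "AG" and i not in chosen]
    for i in non_a[:extra_mm]:
        src[i] = {"C": "T", "T": "C", "G": "C"}[src[i]]
    return Read("e", "".join(src))


def test_planted_read_detected_only_under_its_own_type(rng):
    genome = random_genome(rng, 6000)
    read = _edited_read(genome, 700, 6, rng)
    for t in [(a, b) for a in "ACGT" for b in "ACGT" if a != b]:
        dets = he.detect_type([read], genome, t)
        if t == ("A", "G"):
            assert len(dets) == 1
            assert dets[0].n_candidates == 6
            assert dets[0].mismatch_type == ("A", "G")
        else:
            assert dets == []


def test_flipped_read_detected_as_t_to_c_and_inferred_back(rng):
    genome = random_genome(rng, 6000)
    read = _edited_read(genome, 700, 6, rng)
    flipped = Read("f", revcomp(read.seq))
    dets = he.detect_type([flipped], genome, ("T", "C"))
    assert len(dets) == 1 and dets[0].strand == "-"
    assert dets[0].mismatch_type == ("T", "C")
    # unstranded collapse reports the sites as A→G on the opposite strand
    sites = he.collapse_sites(dets, stranded=False)
    assert all(s.mismatch_type == ("A", "G") and s.strand == "+" for s in sites)


def test_read_below_threshold_rejected(rng):
    genome = random_genome(rng, 6000)
    read = _edited_read(genome, 700, 3, rng)  # threshold at L=80 is 4
    assert he.detect_type([read], genome, ("A", "G")) == []


def test_clean_read_filter_rejects_many_other_mismatches(rng):
    genome = random_genome(rng, 6000)
    # 6 candidate edits plus 5 non-candidate mismatches: exceeds the 2.5% cap
    read = _edited_read(genome, 700, 6, rng, extra_mm=5)
    assert he.detect_type([read], genome, ("A", "G")) == []


def test_edge_concentration_filter(rng):
    genome = random_genome(rng, 6000)
    src = list(genome["chr1"][700:780])
    early_a = [i for i, b in enumerate(src) if b == "A" and i < 8]
    if len(early_a) >= 4:
        for i in early_a[:4]:
            src[i] = "G"
        dets = he.detect_type([Read("edge", "".join(src))], genome, ("A", "G"))
        assert dets == []


def test_raising_threshold_never_increases_detections(noisy_run):
    genome, batch = noisy_run["genome"], noisy_run["batch"]
    reads = batch.unmapped[:400]
    counts = []
    for frac in (0.05, 0.0751, 0.10):
        dets = he.detect_type(reads, genome, ("A", "G"), DetectConfig(min_frac=frac))
        counts.append(len(dets))
    assert counts[0] >= counts[1] >= counts[2]


def test_collapse_support_counts_and_empty(rng):
    genome = random_genome(rng, 6000)
    seq = genome["chr1"]
    # edit the same genomic adenosines in two overlapping reads
    gpos = [p for p in range(760, 810) if seq[p] == "A"][:5]
    assert len(gpos) == 5
    dets = []
    for rid, start in (("r1", 740), ("r2", 752)):
        src = list(seq[start : start + 80])
        for p in gpos:
            src[p - start] = "G"
        dets.extend(he.detect_type([Read(rid, "".join(src))], genome, ("A", "G")))
    assert len(dets) == 2
    sites = he.collapse_sites(dets)
    assert {s.pos for s in sites if s.support == 2} == set(gpos)
    assert he.collapse_sites([]) == []


def test_noiseless_recovery_and_site_purity(noiseless_run):
    """Every truth read with enough edits is rescued, and every called site is
    a planted site, in the error-free, SNP-free limit."""
    truth, per_type = noiseless_run["truth"], noiseless_run["per_type"]
    dets = per_type[("A", "G")] + per_type[("T", "C")]
    det_ids = {d.read_id for d in dets}
    k = min_sites(80)
    hyper = [r for r in truth.reads if len(r.edited_genomic_positions) >= k]
    assert hyper
    assert all(r.read_id in det_ids for r in hyper)
    truth_sites = truth.edited_sites()
    called = {(d.chrom, p) for d in dets for p in d.candidate_positions}
    assert called <= truth_sites
    # per-read candidate positions match the truth exactly
    by_id = {r.read_id: r for r in truth.reads}
    for d in dets:
        assert d.candidate_positions == by_id[d.read_id].edited_genomic_positions


def test_signal_concentrated_in_a_to_g_and_t_to_c(noisy_run):
    screen = noisy_run["screen"]
    ag = screen.unique_sites[("A", "G")] + screen.unique_sites[("T", "C")]
    assert ag > 0
    for t, n in screen.unique_sites.items():
        if t not in (("A", "G"), ("T", "C")):
            assert n <= 0.05 * ag


def test_stranded_library_shows_only_a_to_g():
    cfg = he.SimConfig(genome_length=30_000, n_reads=8_000, stranded=True, seed=9)
    genome, reads, _ = he.simulate_dataset(cfg)
    batch = he.align_batch(reads, genome)
    _, screen = he.run_all_types(batch.unmapped, genome)
    assert screen.reads[("A", "G")] > 0
    assert screen.reads[("T", "C")] == 0


def test_candidate_sites_uniform_across_read_positions(noiseless_run):
    """Edits planted uniformly should be recovered roughly uniformly across
    read positions (the interior; the edge filter shapes the extremes)."""
    per_type = noiseless_run["per_type"]
    offsets = [o for d in per_type[("A", "G")] for o in d.candidate_read_offsets
               if 8 <= o < 72]
    hist, _ = np.histogram(offsets, bins=8, range=(8, 72))
    p = stats.chisquare(hist).pvalue
    assert p > 1e-4


def test_cluster_span_runs_first_to_last_candidate(noiseless_run):
    for d in noiseless_run["per_type"][("A", "G")][:50]:
        assert d.cluster_span.start == d.candidate_positions[0]
        assert d.cluster_span.end == d.candidate_positions[-1] + 1
        assert d.cluster_span.start >= d.start
        assert d.cluster_span.end <= d.start + len(d.seq)
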