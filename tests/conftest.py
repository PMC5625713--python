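"""Shared fixtures: simulated datasets are expensive, so the standard study
conditions are generated once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import hyperedit as he


@pytest.fixture(scope="session")
def noiseless_run():
    """50 kb genome, 20k error-free reads: the clean-recovery regime."""
    cfg = he.SimConfig(genome_length=50_000, n_reads=20_000, seq_error_rate=0.0,
                       snp_rate=0.0, seed=11)
    genome, reads, truth = he.simulate_dataset(cfg)
    batch = he.align_batch(reads, genome)
    per_type, screen = he.run_all_types(batch.unmapped, genome)
    return {
        "cfg": cfg, "genome": genome, "reads": reads, "truth": truth,
        "batch": batch, "per_type": per_type, "screen": screen,
    }


@pytest.fixture(scope="session")
def noisy_run():
    """Same conditions with 1% per-base sequencing error, unstranded."""
    cfg = he.SimConfig(genome_length=50_000, n_reads=20_000, seq_error_rate=0.01,
                       seed=3)
    genome, reads, truth = he.simulate_dataset(cfg)
    batch = he.align_batch(reads, genome)
    per_type, screen = he.run_all_types(batch.unmapped, genome)
    return {
        "cfg": cfg, "genome": genome, "reads": reads, "truth": truth,
        "batch": batch, "per_type": per_type, "screen": screen,
    }


@pytest.fixture(scope="session")
def null_run():
    """ADAR-null control under the same noise conditions."""
    cfg = he.SimConfig(genome_length=50_000, n_reads=20_000, seq_error_rate=0.01,
                       seed=3)
    genome, reads, truth = he.adar_null_control(cfg)
    batch = he.align_batch(reads, genome)
    per_type, screen = he.run_all_types(batch.unmapped, genome)
    return {"genome": genome, "truth": truth, "batch": batch,
            "per_type": per_type, "screen": screen}


def _species_profile(seed: int, group: str) -> he.MotifProfile:
    cfg = he.SimConfig(genome_length=15_000, n_reads=5_000, motif_group=group,
                       seed=seed)
    genome, reads, _ = he.simulate_dataset(cfg)
    batch = he.align_batch(reads, genome)
    per_type, _ = he.run_all_types(batch.unmapped, genome)
    dets = per_type[("A", "G")] + per_type[("T", "C")]
    sites = [s for s in he.collapse_sites(dets) if s.mismatch_type == ("A", "G")]
    return he.build_profile(sites, genome, cluster_spans=[d.cluster_span for d in dets])


@pytest.fixture(scope="session")
def species_profiles():
    """Eight synthetic species: four per planted downstream-preference group."""
    profiles = [(f"Gsp{i}", _species_profile(100 + i, "downstream_G")) for i in range(4)]
    profiles += [(f"Asp{i}", _species_profile(200 + i, "downstream_A")) for i in range(4)]
    return profiles


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_genome(rng: np.random.Generator, n: int, name: str = "chr1") -> he.Genome:
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return he.Genome(sequences={name: seq})
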