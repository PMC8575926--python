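import gzip

import numpy as np
import pytest

import prewell


def write_fastq_plain(records, path):
    """Write (id, seq) records as gzip FASTQ for handcrafted fixtures."""
    with gzip.open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """Error-free simulation shared across tests: 300 cells, 4 conditions."""
    out = tmp_path_factory.mktemp("sim_clean")
    cfg = prewell.SimConfig(
        n_cells=300,
        n_conditions=4,
        n_wells=100,
        n_genes=20,
        mean_molecules_per_cell=30.0,
        error_rate=0.0,
        seed=11,
    )
    return prewell.simulate_experiment(cfg, out_dir=out)


@pytest.fixture(scope="session")
def sim_noisy(tmp_path_factory):
    """Simulation with 1% per-base substitution errors."""
    out = tmp_path_factory.mktemp("sim_noisy")
    cfg = prewell.SimConfig(
        n_cells=300,
        n_conditions=4,
        n_wells=100,
        n_genes=20,
        mean_molecules_per_cell=30.0,
        error_rate=0.01,
        seed=12,
    )
    return prewell.simulate_experiment(cfg, out_dir=out)


def run_demux(sim, **options):
    idx = prewell.build_reference_index(sim.transcriptome)
    assigned, stats = prewell.demultiplex(
        sim.paths["r1_fastq"],
        sim.paths["r2_fastq"],
        sim.config.layout,
        sim.wl_round1,
        sim.wl_round2,
        idx,
        **options,
    )
    return assigned, stats, idx


@pytest.fixture(scope="session")
def demuxed_clean(sim_clean):
    assigned, stats, idx = run_demux(sim_clean)
    return assigned, stats, prewell.count_matrix(assigned)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
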