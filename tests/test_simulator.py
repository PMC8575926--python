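"""Simulator: transcriptome, well loading, expression model, read emission."""

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import prewell
from prewell.simulate import sample_molecule_counts

# --------------------------------------------------------------------------
# toy transcriptome


def test_transcriptome_requires_genes():
    with pytest.raises(ValueError):
        prewell.make_toy_transcriptome(0)


def test_transcriptome_rejects_short_transcripts():
    with pytest.raises(ValueError):
        prewell.make_toy_transcriptome(5, length=50, window=100)


def test_transcriptome_deterministic_and_windows_unique(tmp_path):
    t1 = prewell.make_toy_transcriptome(50, length=500, seed=3)
    t2 = prewell.make_toy_transcriptome(50, length=500, seed=3)
    f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
    t1.write_fasta(f1)
    t2.write_fasta(f2)
    assert f1.read_bytes() == f2.read_bytes()
    windows = {t1.three_prime_window(g, 100) for g in t1.genes}
    assert len(windows) == 50


def test_transcriptome_species_split():
    t = prewell.make_toy_transcriptome(10, species_labels=("human", "mouse"), seed=1)
    assert len(t.genes_of_species("human")) == 5
    assert len(t.genes_of_species("mouse")) == 5


# --------------------------------------------------------------------------
# well loading


def test_single_well_takes_all(rng):
    wells, occ = prewell.assign_cells_to_wells(5, 1, rng)
    assert (wells == 0).all() and occ[0] == 5


def test_no_cells(rng):
    wells, occ = prewell.assign_cells_to_wells(0, 10, rng)
    assert len(wells) == 0 and occ.sum() == 0


def test_occupancy_matches_poisson_limit(rng):
    """10^4 cells in 10^3 wells: empty-well fraction ~ e^-10 (Poisson limit)."""
    n_cells, n_wells = 10_000, 1_000
    _, occ = prewell.assign_cells_to_wells(n_cells, n_wells, rng)
    assert occ.sum() == n_cells
    p_empty = (1 - 1 / n_wells) ** n_cells  # ~ e^-10
    se = np.sqrt(n_wells * p_empty * (1 - p_empty))
    assert abs((occ == 0).sum() - n_wells * p_empty) <= 3 * se + 1e-9


# --------------------------------------------------------------------------
# expression model


def test_zero_mean_gives_zero_molecules(rng):
    t = prewell.make_toy_transcriptome(5, seed=0)
    assert prewell.sample_cell_expression(t, 0.0, 2.0, rng) == []


def test_gamma_poisson_variance():
    """Law of total variance: Var/mean = 1 + mean/dispersion; the
    dispersion -> infinity limit recovers Poisson (ratio -> 1)."""
    n, mean = 10_000, 20.0
    for disp, expect in ((1e9, 1.0), (2.0, 1 + mean / 2.0)):
        counts = sample_molecule_counts(n, mean, disp, np.random.default_rng(5))
        ratio = counts.var(ddof=1) / counts.mean()
        # SE of the variance/mean ratio, normal approximation
        se = expect * np.sqrt(2.0 / n) * 3
        assert abs(ratio - expect) < max(4 * se, 0.05 * expect)


def test_umis_unique_within_cell_gene(rng):
    t = prewell.make_toy_transcriptome(3, seed=2)
    mols = prewell.sample_cell_expression(t, 200.0, 5.0, rng, umi_len=4)
    assert len(set(mols)) == len(mols)


def test_species_restriction(sim_two_species=None):
    cfg = prewell.SimConfig(
        n_cells=200, n_wells=50, n_genes=20, mean_molecules_per_cell=10,
        species_mix={"human": 0.5, "mouse": 0.5}, seed=21,
    )
    res = prewell.simulate_experiment(cfg)
    truth = res.truth
    merged = truth.molecules.merge(truth.cells, on="cell_id")
    gene_species = merged["gene"].map(res.transcriptome.species)
    assert (gene_species == merged["species"]).all()


def test_species_mix_binomial():
    """50/50 mix over 2000 cells: per-species counts within 3 binomial SE."""
    cfg = prewell.SimConfig(
        n_cells=2000, n_wells=500, n_genes=10, mean_molecules_per_cell=2,
        reads_per_molecule=0.5, species_mix={"human": 0.5, "mouse": 0.5}, seed=22,
    )
    res = prewell.simulate_experiment(cfg)
    n_human = (res.truth.cells["species"] == "human").sum()
    se = np.sqrt(2000 * 0.25)
    assert abs(n_human - 1000) <= 3 * se


# --------------------------------------------------------------------------
# read emission


def test_error_free_reads_reconstruct_barcodes(sim_clean):
    """With error_rate=0 every R1 carries its cell's true barcodes and UMI."""
    layout = sim_clean.config.layout
    truth = sim_clean.truth
    mol_info = truth.molecules.merge(truth.cells, on="cell_id").set_index("molecule_id")
    reads = truth.reads.set_index("read_id")
    import pysam

    with pysam.FastxFile(sim_clean.paths["r1_fastq"]) as fh:
        for i, rec in enumerate(fh):
            if i >= 500:
                break
            mol = mol_info.loc[reads.loc[rec.name, "molecule_id"]]
            parsed = prewell.parse_barcode_read(rec.sequence, layout)
            assert parsed.round1_obs == mol["round1"]
            assert parsed.round2_obs == mol["round2"]
            assert parsed.umi == mol["umi"]


def test_read_count_poisson_sum(sim_clean):
    """Total reads ~ Poisson(mean * n_molecules) within 3 sqrt."""
    n_mol = len(sim_clean.truth.molecules)
    mean = sim_clean.config.reads_per_molecule
    n_reads = len(sim_clean.truth.reads)
    assert abs(n_reads - mean * n_mol) <= 3 * np.sqrt(mean * n_mol)


def test_conservation(sim_clean):
    """FASTQ records == read-table rows; molecule table covers all reads."""
    with gzip.open(sim_clean.paths["r1_fastq"], "rt") as fh:
        n_fastq = sum(1 for _ in fh) // 4
    assert n_fastq == len(sim_clean.truth.reads)
    assert set(sim_clean.truth.reads["molecule_id"]) <= set(
        sim_clean.truth.molecules["molecule_id"]
    )
    assert set(sim_clean.truth.molecules["cell_id"]) <= set(
        sim_clean.truth.cells["cell_id"]
    )


def test_truth_consistency(sim_clean):
    """Grouping error-free reads by (r1, r2, UMI, gene) equals the molecule
    table's aggregation by cell identity."""
    truth = sim_clean.truth
    info = truth.reads.merge(truth.molecules, on="molecule_id").merge(
        truth.cells, on="cell_id"
    )
    by_reads = (
        info.drop_duplicates(["round1", "round2", "umi", "gene"])
        .groupby(["round1", "round2"])
        .size()
    )
    expected = sim_clean.truth.expected_matrix()
    by_matrix = pd.Series(
        expected.umi_per_cell(), index=[c for c in expected.cells]
    )
    # identical totals per identity (UMI collisions across merged cells dedup)
    assert sorted(by_reads.values) == sorted(by_matrix.values)


def test_shared_key_only_for_same_well_same_preindex(sim_clean):
    cells = sim_clean.truth.cells
    grp = cells.groupby(["round1", "round2"])
    for (_, _), sub in grp:
        if len(sub) > 1:
            assert sub["well"].nunique() == 1
            assert sub["round1"].nunique() == 1


# --------------------------------------------------------------------------
# full experiment


def test_empty_experiment(tmp_path):
    cfg = prewell.SimConfig(n_cells=0, n_wells=10, n_genes=5, seed=1)
    res = prewell.simulate_experiment(cfg, out_dir=tmp_path)
    assert len(res.truth.cells) == 0
    assert len(res.truth.reads) == 0
    with gzip.open(res.paths["r1_fastq"], "rt") as fh:
        assert fh.read() == ""
    manifest = json.loads(Path(res.paths["manifest"]).read_text())
    assert manifest["n_reads"] == 0


def test_same_seed_byte_identity(tmp_path):
    cfg = prewell.SimConfig(
        n_cells=100, n_wells=30, n_genes=10, mean_molecules_per_cell=10, seed=9
    )
    a = prewell.simulate_experiment(cfg, out_dir=tmp_path / "a")
    b = prewell.simulate_experiment(cfg, out_dir=tmp_path / "b")
    for name in ("r1_fastq", "r2_fastq", "transcriptome", "cells", "molecules", "reads"):
        assert Path(a.paths[name]).read_bytes() == Path(b.paths[name]).read_bytes()
    assert a.manifest["manifest_hash"] == b.manifest["manifest_hash"]


def test_config_validation_errors():
    from prewell.errors import ConfigError

    with pytest.raises(ConfigError):
        prewell.SimConfig(n_cells=-1).validate()
    with pytest.raises(ConfigError):
        prewell.SimConfig(error_rate=1.0).validate()
    with pytest.raises(ConfigError):
        prewell.SimConfig(species_mix={"a": 0.6, "b": 0.6}).validate()
    with pytest.raises(ConfigError):
        prewell.SimConfig(n_conditions=10, whitelist1_size=5).validate()
    with pytest.raises(ConfigError):
        prewell.SimConfig.from_dict({"no_such_key": 1})
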