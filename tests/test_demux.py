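"""Gene assignment, demultiplexing fate partition, UMI counting, MTX I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prewell
from prewell import CellKey
from prewell.demux import AssignedRead, ReferenceIndex
from prewell.errors import DataError, MatrixFormatError
from prewell.matrix import CellGeneMatrix

from conftest import run_demux, write_fastq_plain

# --------------------------------------------------------------------------
# reference index / gene assignment


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_index_posting_count(rng):
    t = prewell.make_toy_transcriptome(1, length=200, seed=1)
    idx = prewell.build_reference_index(t, window=100, k=21)
    assert idx.n_postings == 80  # 100 - 21 + 1


def test_index_short_transcript_errors():
    t = prewell.make_toy_transcriptome(2, length=120, seed=1, window=100)
    with pytest.raises(DataError):
        prewell.build_reference_index(t, window=150)


def test_assign_exact_window(rng):
    t = prewell.make_toy_transcriptome(5, length=300, seed=4)
    idx = prewell.build_reference_index(t)
    for g in t.genes:
        assert prewell.assign_gene(t.three_prime_window(g, 100), idx) == g


def test_assign_identical_windows_ambiguous():
    w = "".join("ACGT"[i % 4] for i in range(100))
    # duplicate windows build fine; reads hitting them are ambiguous
    idx = ReferenceIndex({"gA": w, "gB": w}, window=100, k=21)
    assert prewell.assign_gene(w, idx) == "ambiguous"


def test_assign_unassigned_verified_by_scan(rng):
    t = prewell.make_toy_transcriptome(5, length=300, seed=4)
    idx = prewell.build_reference_index(t)
    while True:
        probe = _random_seq(rng, 100)
        # oracle: brute-force scan confirms no window shares a seed k-mer
        hit = any(
            probe[s : s + 21] in t.sequences[g][-100:]
            for g in t.genes
            for s in (0, 10, 20)
        )
        if not hit:
            break
    assert prewell.assign_gene(probe, idx) == "unassigned"


def test_assign_tolerates_mismatches(rng):
    t = prewell.make_toy_transcriptome(5, length=300, seed=4)
    idx = prewell.build_reference_index(t)
    g = t.genes[0]
    read = list(t.three_prime_window(g, 100))
    read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[50]]
    assert prewell.assign_gene("".join(read), idx, max_mismatch=4) == g
    assert prewell.assign_gene("".join(read), idx, max_mismatch=0) == "unassigned"


# --------------------------------------------------------------------------
# demultiplexing


def test_error_free_all_assigned(sim_clean, demuxed_clean):
    _, stats, _ = demuxed_clean[0], demuxed_clean[1], demuxed_clean[2]
    assert stats.assigned == stats.total == len(sim_clean.truth.reads)
    for f in prewell.DemuxStats.__dataclass_fields__:
        if f not in ("total", "assigned"):
            assert getattr(stats, f) == 0


def test_planted_single_substitution_corrected(sim_clean, tmp_path):
    """Mutating exactly one barcode base per R1 read yields status corrected
    for that round on every read, with everything still assigned."""
    import pysam

    layout = sim_clean.config.layout
    rng = np.random.default_rng(77)
    mutated = []
    with pysam.FastxFile(sim_clean.paths["r1_fastq"]) as fh:
        for rec in fh:
            seq = list(rec.sequence)
            pos = int(rng.integers(0, layout.round2_len))  # inside round-2
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            mutated.append((rec.name, "".join(seq)))
    r1 = tmp_path / "R1.fastq.gz"
    write_fastq_plain(mutated, r1)
    idx = prewell.build_reference_index(sim_clean.transcriptome)
    assigned, stats = prewell.demultiplex(
        r1, sim_clean.paths["r2_fastq"], layout,
        sim_clean.wl_round1, sim_clean.wl_round2, idx,
    )
    assert stats.assigned == stats.total
    assert stats.r2_corrected == stats.total
    assert all(r.r2_status == "corrected" for r in assigned)
    # corrected identities match the truth aggregation exactly
    m = prewell.count_matrix(assigned)
    assert m.to_dict() == sim_clean.truth.expected_matrix().to_dict()


def test_empty_fastq(tmp_path):
    r1, r2 = tmp_path / "R1.fastq.gz", tmp_path / "R2.fastq.gz"
    write_fastq_plain([], r1)
    write_fastq_plain([], r2)
    wl1 = prewell.Whitelist.from_iterable(["A" * 10, "C" * 10])
    wl2 = prewell.Whitelist.from_iterable(["A" * 18, "C" * 18])
    assigned, stats = prewell.demultiplex(r1, r2, prewell.ReadLayout(), wl1, wl2, None)
    assert assigned == [] and stats.total == 0


def test_id_mismatch_errors(tmp_path):
    r1, r2 = tmp_path / "R1.fastq.gz", tmp_path / "R2.fastq.gz"
    write_fastq_plain([("a", "A" * 50)], r1)
    write_fastq_plain([("b", "A" * 50)], r2)
    wl1 = prewell.Whitelist.from_iterable(["A" * 10])
    wl2 = prewell.Whitelist.from_iterable(["A" * 18])
    with pytest.raises(DataError, match="mismatch"):
        prewell.demultiplex(r1, r2, prewell.ReadLayout(), wl1, wl2, None)


def test_monotonic_in_correction_and_mismatch_budget(sim_noisy):
    """Loosening max_dist or max_mismatch never loses assigned reads."""
    prev = -1
    for max_dist in (0, 1):
        _, stats, _ = run_demux(sim_noisy, max_dist=max_dist)
        assert stats.assigned >= prev
        prev = stats.assigned
    prev = -1
    for mm in (0, 2, 4):
        _, stats, _ = run_demux(sim_noisy, max_mismatch=mm)
        assert stats.assigned >= prev
        prev = stats.assigned


def test_partition_invariant_noisy(sim_noisy):
    _, stats, _ = run_demux(sim_noisy)
    stats.check_partition()
    assert stats.total == len(sim_noisy.truth.reads)


# --------------------------------------------------------------------------
# counting


def _ar(cell, umi, gene):
    return AssignedRead("r", CellKey(*cell), umi, gene, "exact", "exact")


def test_umi_dedup_same_umi_counts_once():
    reads = [_ar(("AA", "CC"), "ACGT", "g1"), _ar(("AA", "CC"), "ACGT", "g1")]
    m = prewell.count_matrix(reads)
    assert m.to_dict() == {("AA-CC", "g1"): 1}
    assert m.cell_reads[0] == 2


def test_umi_distinct_counts_two():
    reads = [_ar(("AA", "CC"), "ACGT", "g1"), _ar(("AA", "CC"), "TTTT", "g1")]
    assert prewell.count_matrix(reads).to_dict() == {("AA-CC", "g1"): 2}


def test_matrix_entries_bounded_by_reads(demuxed_clean):
    assigned, _, m = demuxed_clean
    reads_per = {}
    for r in assigned:
        key = (str(r.cell), r.gene)
        reads_per[key] = reads_per.get(key, 0) + 1
    for key, umis in m.to_dict().items():
        assert umis <= reads_per[key]


def test_pipeline_matrix_equals_truth(sim_clean, demuxed_clean):
    _, _, m = demuxed_clean
    exp = sim_clean.truth.expected_matrix()
    assert m.to_dict() == exp.to_dict()
    assert np.array_equal(m.cell_reads, exp.cell_reads)


# --------------------------------------------------------------------------
# MTX round trip


def test_mtx_header_shape(tmp_path):
    m = CellGeneMatrix.from_counts(
        {("A-A", "g1"): 1, ("A-C", "g1"): 2, ("A-C", "g2"): 3, ("A-G", "g2"): 4}
    )
    prewell.write_matrix(m, tmp_path)
    header = [
        line
        for line in (tmp_path / "matrix.mtx").read_text().splitlines()
        if not line.startswith("%")
    ][0]
    assert header.split() == ["3", "2", "4"]


def test_mtx_roundtrip_empty(tmp_path):
    m = CellGeneMatrix.from_counts({})
    prewell.write_matrix(m, tmp_path)
    assert prewell.read_matrix(tmp_path) == m


@given(st.integers(0, 10**6))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_mtx_roundtrip_random(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    n_c, n_g = int(rng.integers(1, 8)), int(rng.integers(1, 6))
    counts = {}
    for i in range(n_c):
        for j in range(n_g):
            if rng.random() < 0.4:
                counts[(f"A{i}-B{i}", f"g{j}")] = int(rng.integers(1, 50))
    reads = {c: int(rng.integers(1, 100)) for c, _ in counts}
    m = CellGeneMatrix.from_counts(counts, cell_reads=reads)
    out = tmp_path_factory.mktemp("mtx")
    prewell.write_matrix(m, out)
    assert prewell.read_matrix(out) == m


def test_mtx_malformed_header(tmp_path):
    m = CellGeneMatrix.from_counts({("A-A", "g"): 1})
    prewell.write_matrix(m, tmp_path)
    mtx = tmp_path / "matrix.mtx"
    lines = mtx.read_text().splitlines()
    lines[0] = "not a banner"
    mtx.write_text("\n".join(lines) + "\n")
    with pytest.raises(MatrixFormatError, match="line 1"):
        prewell.read_matrix(tmp_path)


def test_matrix_rejects_negative_and_duplicates():
    import scipy.sparse as sp

    with pytest.raises(ValueError):
        CellGeneMatrix(sp.csr_matrix(np.array([[-1]])), ["A-A"], ["g"])
    with pytest.raises(ValueError):
        CellGeneMatrix(sp.csr_matrix(np.eye(2)), ["A-A", "A-A"], ["g1", "g2"])
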