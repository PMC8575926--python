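"""Demultiplexing and UMI quantification.

Turns paired FASTQ (R1 = barcodes/UMI, R2 = 3' cDNA) into a
UMI-deduplicated cell x gene matrix. Each read is parsed against the
layout, both barcode rounds are corrected against their whitelists, the
cDNA is assigned to a gene by seed-and-extend against the transcripts'
3'-terminal windows, and reads sharing a (round-1, round-2) combination are
combined into one cell.

Read fates partition exactly: every read is counted once in
:class:`DemuxStats` under a fixed rejection precedence
(too_short -> polyT_fail -> round-2 -> round-1 -> gene), so stats are
reproducible and sum to the input total by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

from .barcode import (
    BarcodeCorrector,
    CellKey,
    ReadLayout,
    Whitelist,
    parse_barcode_read,
)
from .errors import DataError
from .matrix import CellGeneMatrix
from .simulate import ToyTranscriptome

#: Reject counters in precedence order.
REJECT_FIELDS = (
    "too_short",
    "polyT_fail",
    "r2_unmatched",
    "r2_ambiguous",
    "r1_unmatched",
    "r1_ambiguous",
    "gene_unassigned",
    "gene_ambiguous",
)


@dataclass
class DemuxStats:
    """Exhaustive partition of read fates."""

    total: int = 0
    assigned: int = 0
    too_short: int = 0
    polyT_fail: int = 0
    r2_unmatched: int = 0
    r2_ambiguous: int = 0
    r1_unmatched: int = 0
    r1_ambiguous: int = 0
    gene_unassigned: int = 0
    gene_ambiguous: int = 0
    r1_corrected: int = 0
    r2_corrected: int = 0

    def rejected(self) -> int:
        return sum(getattr(self, f) for f in REJECT_FIELDS)

    def check_partition(self) -> None:
        if self.assigned + self.rejected() != self.total:
            raise AssertionError(
                f"stats do not partition: assigned {self.assigned} + rejected "
                f"{self.rejected()} != total {self.total}"
            )

    def as_dict(self) -> dict:
        d = {"total": self.total, "assigned": self.assigned}
        d.update({f: getattr(self, f) for f in REJECT_FIELDS})
        d["r1_corrected"] = self.r1_corrected
        d["r2_corrected"] = self.r2_corrected
        return d

    def write_json(self, path) -> None:
        self.check_partition()
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)


class AssignedRead(NamedTuple):
    """One read that survived both barcode rounds and gene assignment."""

    read_id: str
    cell: CellKey
    umi: str
    gene: str
    r1_status: str
    r2_status: str


# ---------------------------------------------------------------------------
# reference index


class ReferenceIndex:
    """k-mer index over the 3'-terminal windows of a small transcriptome.

    Because the library sequences the linear 3' ends of transcripts, the
    last ``window`` bases of each transcript are the only mappable target;
    the index stores every k-mer of each window with its (gene, offset).
    """

    def __init__(self, windows: dict, window: int, k: int = 21):
        if k < 1 or k > window:
            raise ValueError(f"k must be in [1, window], got k={k}, window={window}")
        self.window = window
        self.k = k
        self.windows = dict(windows)
        self.genes = sorted(self.windows)
        self.kmers: dict = {}
        for gene in self.genes:
            w = self.windows[gene]
            if len(w) != window:
                raise ValueError(
                    f"gene {gene}: window length {len(w)} != {window}"
                )
            for off in range(window - k + 1):
                self.kmers.setdefault(w[off : off + k], []).append((gene, off))
        # exact-window fast path: full-window sequence -> gene list
        self._exact: dict = {}
        for gene in self.genes:
            self._exact.setdefault(self.windows[gene], []).append(gene)

    @property
    def n_postings(self) -> int:
        return sum(len(v) for v in self.kmers.values())


def build_reference_index(
    transcriptome, gene_table=None, window: int = 100, k: int = 21
) -> ReferenceIndex:
    """Index a transcriptome's 3' windows.

    ``transcriptome`` is a :class:`ToyTranscriptome` or a FASTA path
    (optionally with a gene table TSV). Transcripts shorter than the window
    and duplicate gene ids are errors.
    """
    if not isinstance(transcriptome, ToyTranscriptome):
        from .simulate import load_transcriptome

        transcriptome = load_transcriptome(transcriptome, gene_table, window=window)
    seen: set = set()
    windows = {}
    for gene in transcriptome.genes:
        if gene in seen:
            raise DataError(f"duplicate gene id {gene}")
        seen.add(gene)
        seq = transcriptome.sequences[gene]
        if len(seq) < window:
            raise DataError(
                f"transcript {gene} length {len(seq)} shorter than 3' window {window}"
            )
        windows[gene] = seq[-window:]
    return ReferenceIndex(windows, window=window, k=k)


def assign_gene(
    cdna: str,
    idx: ReferenceIndex,
    min_match: int = 50,
    max_mismatch: int = 4,
) -> str:
    """Assign a cDNA read to a gene by 3'-window seed-and-extend.

    Seeds with the read's first k-mer, falling back to offsets 10 and 20;
    each candidate (gene, offset) is extended over the full overlap between
    read and window, counting mismatches. Candidates with aligned length >=
    ``min_match`` and mismatches <= ``max_mismatch`` survive. Returns the
    gene id, ``"ambiguous"`` (several distinct genes survive) or
    ``"unassigned"`` (none).
    """
    if not cdna:
        raise ValueError("cdna must be nonempty")
    cdna = cdna.upper()
    # fast path: read is exactly a full window
    if len(cdna) == idx.window:
        exact = idx._exact.get(cdna)
        if exact is not None:
            return exact[0] if len(exact) == 1 else "ambiguous"
    k = idx.k
    candidates = []
    for seed_off in (0, 10, 20):
        if seed_off + k > len(cdna):
            break
        hits = idx.kmers.get(cdna[seed_off : seed_off + k])
        if hits:
            candidates = [(gene, off - seed_off) for gene, off in hits]
            break
    survivors: set = set()
    for gene, start in candidates:
        # read position p aligns to window position p + start
        w = idx.windows[gene]
        lo = max(0, -start)
        hi = min(len(cdna), idx.window - start)
        aligned = hi - lo
        if aligned < min_match:
            continue
        mism = sum(
            1 for p in range(lo, hi) if cdna[p] != w[p + start]
        )
        if mism <= max_mismatch:
            survivors.add(gene)
    if not survivors:
        return "unassigned"
    if len(survivors) > 1:
        return "ambiguous"
    return survivors.pop()


# ---------------------------------------------------------------------------
# demultiplexing


def _fastq_pairs(r1_path, r2_path) -> Iterator:
    import pysam

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        it1, it2 = iter(f1), iter(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise DataError("R1/R2 FASTQ have different read counts")
            n1 = rec1.name.split("/")[0]
            n2 = rec2.name.split("/")[0]
            if n1 != n2:
                raise DataError(f"R1/R2 id mismatch: {rec1.name!r} vs {rec2.name!r}")
            yield n1, rec1.sequence, rec2.sequence


def iter_demultiplex(
    fastq_pair: tuple,
    layout: ReadLayout,
    wl1: Whitelist,
    wl2: Whitelist,
    idx: ReferenceIndex | None,
    stats: DemuxStats,
    max_dist: int = 1,
    min_match: int = 50,
    max_mismatch: int = 4,
    require_polyT: bool | None = None,
) -> Iterator[AssignedRead]:
    """Stream AssignedReads from a FASTQ pair, filling ``stats`` in place.

    Memory is bounded in the number of reads; only whitelist/index state is
    held. Rejection precedence: too_short, polyT_fail, round-2
    (unmatched/ambiguous), round-1, gene.
    """
    if wl1.length != layout.round1_len:
        raise DataError(
            f"round-1 whitelist length {wl1.length} != layout round1_len {layout.round1_len}"
        )
    if wl2.length != layout.round2_len:
        raise DataError(
            f"round-2 whitelist length {wl2.length} != layout round2_len {layout.round2_len}"
        )
    if require_polyT is not None and require_polyT != layout.require_polyT:
        import dataclasses

        layout = dataclasses.replace(layout, require_polyT=require_polyT)
    corr1 = BarcodeCorrector(wl1, max_dist)
    corr2 = BarcodeCorrector(wl2, max_dist)
    for read_id, seq1, seq2 in _fastq_pairs(*fastq_pair):
        stats.total += 1
        parsed = parse_barcode_read(seq1, layout)
        if "too_short" in parsed.qc_flags:
            stats.too_short += 1
            continue
        if "polyT_fail" in parsed.qc_flags:
            stats.polyT_fail += 1
            continue
        res2 = corr2.correct(parsed.round2_obs)
        if not res2.resolved:
            if res2.status == "unmatched":
                stats.r2_unmatched += 1
            else:
                stats.r2_ambiguous += 1
            continue
        res1 = corr1.correct(parsed.round1_obs)
        if not res1.resolved:
            if res1.status == "unmatched":
                stats.r1_unmatched += 1
            else:
                stats.r1_ambiguous += 1
            continue
        if idx is None:
            gene = "unassigned"
        else:
            gene = assign_gene(seq2, idx, min_match=min_match, max_mismatch=max_mismatch)
        if gene == "unassigned":
            stats.gene_unassigned += 1
            continue
        if gene == "ambiguous":
            stats.gene_ambiguous += 1
            continue
        stats.assigned += 1
        if res1.status == "corrected":
            stats.r1_corrected += 1
        if res2.status == "corrected":
            stats.r2_corrected += 1
        yield AssignedRead(
            read_id=read_id,
            cell=CellKey(res1.barcode, res2.barcode),
            umi=parsed.umi,
            gene=gene,
            r1_status=res1.status,
            r2_status=res2.status,
        )


def demultiplex(
    r1_path,
    r2_path,
    layout: ReadLayout,
    wl1: Whitelist,
    wl2: Whitelist,
    idx: ReferenceIndex | None,
    **options,
) -> tuple:
    """Demultiplex a FASTQ pair; returns (assigned reads list, DemuxStats)."""
    stats = DemuxStats()
    assigned = list(
        iter_demultiplex((r1_path, r2_path), layout, wl1, wl2, idx, stats, **options)
    )
    stats.check_partition()
    return assigned, stats


def read_gene_assignments(path) -> Iterator:
    """Ingestion path for pre-aligned data: TSV of read_id<TAB>gene_id.

    Stands in for the gene-assignment step when reads were already mapped by
    an external aligner; yields (read_id, gene) pairs.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}: line {lineno}: expected read_id<TAB>gene_id")
            yield parts[0], parts[1]


# ---------------------------------------------------------------------------
# counting


def count_matrix(
    reads: Iterable[AssignedRead], genes: Iterable[str] | None = None
) -> CellGeneMatrix:
    """UMI-deduplicated counts: distinct UMIs per (cell, gene).

    Exact distinct-UMI counting (no Hamming-collapse of near-duplicate
    UMIs): the verifiable baseline. Per-cell assigned-read totals are kept
    as matrix metadata. Deterministic for any input order.
    """
    umis: dict = {}
    cell_reads: dict = {}
    for r in reads:
        cid = str(r.cell)
        umis.setdefault((cid, r.gene), set()).add(r.umi)
        cell_reads[cid] = cell_reads.get(cid, 0) + 1
    counts = {key: len(s) for key, s in umis.items()}
    return CellGeneMatrix.from_counts(counts, cell_reads=cell_reads, genes=genes)
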