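"""Ground-truth read simulator for pre-indexed microwell scRNA-seq.

The simulated experiment mirrors the wet workflow: cells sit in sample wells
where in-cell RT attaches a well-specific round-1 barcode (one barcode per
perturbation condition); all cells are pooled and spun into an array of
microwells, several cells per well; each microwell holds one barcoded bead
whose round-2 barcode is ligated onto every cDNA captured in that well; the
3' end of each molecule is sequenced together with the barcodes and a UMI.

Two cells that share both the pre-index and the microwell collapse into one
cell identity — the collision mode the pre-index is designed to dilute — and
the simulator lets this happen naturally rather than injecting doublets.

Expression is gamma-Poisson (negative binomial) per cell over a small
synthetic transcriptome with lognormal gene abundance weights, optionally
split across two species for barnyard experiments, with per-base sequencing
substitution errors. Every random draw is recorded in truth tables so the
demultiplexer can be checked read-for-read.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import ReadLayout, Whitelist, random_whitelist, write_whitelist
from .errors import ConfigError
from .matrix import CellGeneMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# toy transcriptome


@dataclass
class ToyTranscriptome:
    """A small synthetic transcriptome: one transcript per gene.

    3'-terminal windows (the sequenced part) are guaranteed pairwise
    distinct so gene assignment has an unambiguous truth.
    """

    genes: list
    sequences: dict
    species: dict
    weights: dict
    window: int = 100

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")

    def three_prime_window(self, gene: str, n: int | None = None) -> str:
        n = n or self.window
        return self.sequences[gene][-n:]

    def species_labels(self) -> list:
        return sorted(set(self.species.values()))

    def genes_of_species(self, label: str) -> list:
        return [g for g in self.genes if self.species[g] == label]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f">{g} species={self.species[g]}\n{self.sequences[g]}\n")

    def write_gene_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tspecies\tweight\n")
            for g in self.genes:
                fh.write(f"{g}\t{self.species[g]}\t{self.weights[g]:.8g}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def make_toy_transcriptome(
    n_genes: int,
    length: int = 500,
    species_labels: Sequence[str] = ("human",),
    seed: int | np.random.Generator = 0,
    window: int = 100,
) -> ToyTranscriptome:
    """Generate ``n_genes`` random transcripts split evenly across species.

    Deterministic for a fixed seed; 3' windows that collide are regenerated.
    Gene abundance weights are lognormal (sigma = 1), the conventional
    skewed-abundance model for transcript frequencies.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if length < window:
        raise ValueError(f"transcript length {length} < 3' window {window}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes, seqs, species_of = [], {}, {}
    seen_windows: set = set()
    n_species = len(species_labels)
    for i in range(n_genes):
        label = species_labels[i % n_species]
        gid = f"{label}_g{i:04d}"
        while True:
            s = _random_seq(rng, length)
            if s[-window:] not in seen_windows:
                break
        seen_windows.add(s[-window:])
        genes.append(gid)
        seqs[gid] = s
        species_of[gid] = label
    weights = {g: float(w) for g, w in zip(genes, rng.lognormal(0.0, 1.0, n_genes))}
    return ToyTranscriptome(genes, seqs, species_of, weights, window=window)


def load_transcriptome(fasta_path, gene_table_path=None, window: int = 100) -> ToyTranscriptome:
    """Read a transcriptome FASTA (+ optional gene table with species/weights)."""
    import pysam

    genes, seqs, species_of, weights = [], {}, {}, {}
    with pysam.FastxFile(str(fasta_path)) as fh:
        for rec in fh:
            genes.append(rec.name)
            seqs[rec.name] = rec.sequence.upper()
            sp = "unknown"
            if rec.comment:
                for tok in rec.comment.split():
                    if tok.startswith("species="):
                        sp = tok.split("=", 1)[1]
            species_of[rec.name] = sp
            weights[rec.name] = 1.0
    if gene_table_path is not None:
        tab = pd.read_csv(gene_table_path, sep="\t")
        for _, row in tab.iterrows():
            species_of[row["gene_id"]] = row["species"]
            if "weight" in tab.columns:
                weights[row["gene_id"]] = float(row["weight"])
    return ToyTranscriptome(genes, seqs, species_of, weights, window=window)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults describe a desk-scale run: 2,000 cells over 4 conditions loaded
    into 500 microwells, 50 genes, ~100 molecules per cell with moderate
    overdispersion and ~1.5 sequenced reads per molecule.
    """

    n_cells: int = 2000
    n_conditions: int = 4
    n_wells: int = 500
    cells_per_condition: Sequence[int] | None = None
    n_genes: int = 50
    transcript_length: int = 500
    mean_molecules_per_cell: float = 100.0
    dispersion: float = 2.0
    reads_per_molecule: float = 1.5
    error_rate: float = 0.0
    species_mix: Mapping[str, float] | None = None
    condition_labels: Sequence[str] | None = None
    condition_effects: Mapping[str, Mapping[str, float]] | None = None
    cdna_read_len: int = 100
    polyT_tail_len: int = 15
    layout: ReadLayout = field(default_factory=ReadLayout)
    whitelist1_size: int | None = None
    whitelist2_size: int | None = None
    whitelist_min_dist: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if self.n_conditions < 1:
            raise ConfigError("n_conditions must be >= 1")
        if self.n_wells < 1:
            raise ConfigError("n_wells must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.mean_molecules_per_cell < 0:
            raise ConfigError("mean_molecules_per_cell must be >= 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.reads_per_molecule < 0:
            raise ConfigError("reads_per_molecule must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be in [0, 1)")
        if self.transcript_length < self.cdna_read_len:
            raise ConfigError("transcript_length must be >= cdna_read_len")
        if self.species_mix is not None:
            fr = list(self.species_mix.values())
            if len(self.species_mix) < 1 or any(f < 0 for f in fr):
                raise ConfigError("species_mix fractions must be nonnegative")
            if abs(sum(fr) - 1.0) > 1e-8:
                raise ConfigError("species_mix fractions must sum to 1")
        if self.cells_per_condition is not None:
            if len(self.cells_per_condition) != self.n_conditions:
                raise ConfigError("cells_per_condition length must equal n_conditions")
            if sum(self.cells_per_condition) != self.n_cells:
                raise ConfigError("cells_per_condition must sum to n_cells")
        if self.condition_labels is not None and len(self.condition_labels) != self.n_conditions:
            raise ConfigError("condition_labels length must equal n_conditions")
        wl1 = self.whitelist1_size or self.n_conditions
        wl2 = self.whitelist2_size or self.n_wells
        if wl1 < self.n_conditions:
            raise ConfigError("round-1 whitelist smaller than n_conditions")
        if wl2 < self.n_wells:
            raise ConfigError("round-2 whitelist smaller than n_wells (one bead per well)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layout"] = dataclasses.asdict(self.layout)
        if self.cells_per_condition is not None:
            d["cells_per_condition"] = list(self.cells_per_condition)
        if self.condition_labels is not None:
            d["condition_labels"] = list(self.condition_labels)
        if self.species_mix is not None:
            d["species_mix"] = dict(self.species_mix)
        if self.condition_effects is not None:
            d["condition_effects"] = {c: dict(v) for c, v in self.condition_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulate config keys: {sorted(unknown)}")
        if "layout" in d and not isinstance(d["layout"], ReadLayout):
            lay = dict(d["layout"])
            if "segment_order" in lay:
                lay["segment_order"] = tuple(lay["segment_order"])
            d["layout"] = ReadLayout(**lay)
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# truth tables


@dataclass
class TruthTables:
    """Exhaustive ground truth of one simulation.

    ``cells``: cell_id, condition, species, well, round1, round2.
    ``molecules``: molecule_id, cell_id, gene, umi.
    ``reads``: read_id, molecule_id, r1_errors, r2_errors (comma-joined
    0-based substituted positions, empty when error-free).
    """

    cells: pd.DataFrame
    molecules: pd.DataFrame
    reads: pd.DataFrame

    def expected_matrix(self) -> CellGeneMatrix:
        """Aggregate the truth by two-barcode cell identity.

        Counts distinct UMIs per (CellKey, gene) — exactly what a perfect
        demultiplexer would report. Cells merged by a barcode collision are
        aggregated into one identity, as they would be in real assembly.
        """
        mols = self.molecules.merge(
            self.cells[["cell_id", "round1", "round2"]], on="cell_id"
        )
        mols["key"] = mols["round1"] + "-" + mols["round2"]
        # molecules that drew zero reads were never sequenced
        reads_per_mol = self.reads.groupby("molecule_id").size()
        mols = mols[mols["molecule_id"].isin(reads_per_mol.index)].copy()
        dedup = mols.drop_duplicates(["key", "gene", "umi"])
        counts = dedup.groupby(["key", "gene"]).size()
        mols["n_reads"] = mols["molecule_id"].map(reads_per_mol).astype(int)
        cell_reads = mols.groupby("key")["n_reads"].sum().to_dict()
        return CellGeneMatrix.from_counts(
            {(k, g): int(v) for (k, g), v in counts.items()}, cell_reads=cell_reads
        )

    def identity_table(self) -> pd.DataFrame:
        """Per cell identity (round1-round2): member cells and species set."""
        cells = self.cells.copy()
        cells["key"] = cells["round1"] + "-" + cells["round2"]
        return cells.groupby("key").agg(
            n_cells=("cell_id", "size"),
            species=("species", lambda s: tuple(sorted(set(s)))),
            condition=("condition", "first"),
        )


# ---------------------------------------------------------------------------
# elementary operations


def assign_cells_to_wells(
    n_cells: int, n_wells: int, rng: np.random.Generator
) -> tuple:
    """Place cells into wells uniformly and independently (multinomial loading).

    Returns (well index per cell, occupancy histogram of length n_wells).
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    wells = rng.integers(0, n_wells, size=n_cells)
    occupancy = np.bincount(wells, minlength=n_wells)
    return wells, occupancy


def _int_to_umi(x: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[x & 3])
        x >>= 2
    return "".join(out)


def sample_molecule_counts(
    n_cells: int,
    mean_molecules: float,
    dispersion: float,
    rng: np.random.Generator,
    mean_scale: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Per-cell molecule counts, gamma-Poisson (negative binomial).

    Marginal mean is ``mean_molecules * mean_scale``; variance is
    mean + mean^2 / dispersion (dispersion -> inf recovers Poisson).
    """
    means = np.broadcast_to(np.asarray(mean_scale, dtype=float), (n_cells,)) * mean_molecules
    if mean_molecules == 0:
        return np.zeros(n_cells, dtype=np.int64)
    lam = rng.gamma(shape=dispersion, scale=means / dispersion)
    return rng.poisson(lam).astype(np.int64)


def sample_cell_expression(
    transcriptome: ToyTranscriptome,
    mean_molecules: float,
    dispersion: float,
    rng: np.random.Generator,
    species: str | None = None,
    umi_len: int = 8,
    gene_weights: Mapping[str, float] | None = None,
) -> list:
    """Draw one cell's molecules: list of (gene_id, umi).

    Molecule count is gamma-Poisson; genes are categorical by abundance
    weight restricted to the cell's species; UMIs are uniform over 4^umi_len
    with resampling on within-(cell, gene) collisions so every molecule of a
    gene in a cell carries a distinct UMI.
    """
    if mean_molecules < 0 or dispersion <= 0:
        raise ValueError("mean_molecules must be >= 0 and dispersion > 0")
    genes = (
        transcriptome.genes_of_species(species) if species else list(transcriptome.genes)
    )
    if not genes:
        raise ValueError(f"no genes for species {species!r}")
    w = np.array(
        [(gene_weights or transcriptome.weights)[g] for g in genes], dtype=float
    )
    p = w / w.sum()
    n = int(sample_molecule_counts(1, mean_molecules, dispersion, rng)[0])
    if n == 0:
        return []
    gene_idx = rng.choice(len(genes), size=n, p=p)
    umis = rng.integers(0, 4**umi_len, size=n)
    seen: set = set()
    for i in range(n):
        while (gene_idx[i], int(umis[i])) in seen:
            umis[i] = rng.integers(0, 4**umi_len)
        seen.add((gene_idx[i], int(umis[i])))
    return [(genes[int(g)], _int_to_umi(int(u), umi_len)) for g, u in zip(gene_idx, umis)]


def _apply_errors(
    seq: str, n_err: int, rng: np.random.Generator
) -> tuple:
    """Substitute ``n_err`` random positions with a uniformly different base."""
    if n_err == 0:
        return seq, ()
    L = len(seq)
    pos = rng.choice(L, size=min(n_err, L), replace=False)
    pos.sort()
    chars = list(seq)
    for pidx in pos:
        old = chars[pidx]
        choices = [b for b in "ACGT" if b != old]
        chars[pidx] = choices[rng.integers(0, len(choices))]
    return "".join(chars), tuple(int(x) for x in pos)


def emit_reads(
    cells: pd.DataFrame,
    molecules: pd.DataFrame,
    transcriptome: ToyTranscriptome,
    layout: ReadLayout,
    reads_per_molecule: float,
    error_rate: float,
    rng: np.random.Generator,
    cdna_read_len: int = 100,
    polyT_tail_len: int = 15,
) -> tuple:
    """Sequence the molecules: paired reads plus the read truth table.

    R1 carries the barcodes/UMI per the layout followed by a poly-T tail;
    R2 is the exact 3'-terminal window of the molecule's transcript. Each
    base is substituted independently with probability ``error_rate``.
    Reads per molecule are Poisson; molecules drawn zero times are dropped
    (unsequenced), as in a real library.
    """
    n_mol = len(molecules)
    cell_info = cells.set_index("cell_id")
    r1_parts_by_cell = {}
    for cid, row in cell_info.iterrows():
        r1_parts_by_cell[cid] = (row["round2"], row["round1"])
    reads_per_mol = rng.poisson(reads_per_molecule, size=n_mol)
    n_reads = int(reads_per_mol.sum())
    r1_len = layout.barcode_span + polyT_tail_len
    n_err1 = rng.binomial(r1_len, error_rate, size=n_reads) if error_rate > 0 else np.zeros(n_reads, dtype=int)
    n_err2 = rng.binomial(cdna_read_len, error_rate, size=n_reads) if error_rate > 0 else np.zeros(n_reads, dtype=int)

    offsets = layout.offsets()
    order = [s for s in layout.segment_order if s != "polyT"]

    r1_records, r2_records = [], []
    read_rows = []
    ridx = 0
    mol_ids = molecules["molecule_id"].to_numpy()
    mol_cells = molecules["cell_id"].to_numpy()
    mol_genes = molecules["gene"].to_numpy()
    mol_umis = molecules["umi"].to_numpy()
    tail = "T" * polyT_tail_len
    window_cache = {
        g: transcriptome.three_prime_window(g, cdna_read_len) for g in transcriptome.genes
    }
    for m in range(n_mol):
        k = int(reads_per_mol[m])
        if k == 0:
            continue
        r2bc, r1bc = r1_parts_by_cell[mol_cells[m]]
        segs = {"round2": r2bc, "round1": r1bc, "umi": mol_umis[m]}
        r1_seq = "".join(segs[s] for s in order) + tail
        r2_seq = window_cache[mol_genes[m]]
        for _ in range(k):
            rid = f"read{ridx:08d}"
            s1, e1 = _apply_errors(r1_seq, int(n_err1[ridx]), rng)
            s2, e2 = _apply_errors(r2_seq, int(n_err2[ridx]), rng)
            r1_records.append((rid, s1))
            r2_records.append((rid, s2))
            read_rows.append(
                (
                    rid,
                    mol_ids[m],
                    ",".join(map(str, e1)),
                    ",".join(map(str, e2)),
                )
            )
            ridx += 1
    reads = pd.DataFrame(
        read_rows, columns=["read_id", "molecule_id", "r1_errors", "r2_errors"]
    )
    return r1_records, r2_records, reads


def write_fastq(records, path) -> None:
    """Write (id, seq) records as gzip FASTQ with constant quality.

    gzip mtime is pinned to 0 so identical content gives identical bytes.
    """
    buf = []
    for rid, seq in records:
        buf.append(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    data = "".join(buf).encode("ascii")
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(data)


# ---------------------------------------------------------------------------
# full experiment


@dataclass
class SimulationResult:
    config: SimConfig
    wl_round1: Whitelist
    wl_round2: Whitelist
    transcriptome: ToyTranscriptome
    truth: TruthTables
    manifest: dict
    paths: dict


def _condition_weight_tables(
    cfg: SimConfig, transcriptome: ToyTranscriptome, conditions: Sequence[str]
):
    """Per (species, condition): gene list, probabilities, and mean scaling.

    A condition effect of fold f on gene g multiplies g's absolute expected
    molecule count by f: the gene's weight is scaled by f and the cell's
    expected total by the same renormalizer, leaving unmarked genes'
    absolute expectations untouched.
    """
    species_labels = transcriptome.species_labels()
    tables = {}
    for sp in species_labels:
        genes = transcriptome.genes_of_species(sp)
        base = np.array([transcriptome.weights[g] for g in genes])
        base_sum = base.sum()
        for cond in set(conditions):
            w = base.copy()
            effects = (cfg.condition_effects or {}).get(cond, {})
            for g, fold in effects.items():
                if g in genes:
                    w[genes.index(g)] *= fold
            tables[(sp, cond)] = (genes, w / w.sum(), w.sum() / base_sum)
    return tables


def simulate_experiment(config: SimConfig, out_dir=None) -> SimulationResult:
    """Run the full simulation; optionally write all artifacts to ``out_dir``.

    Outputs: paired gzip FASTQ, transcriptome FASTA + gene table, truth
    tables (TSV), both whitelists, a plate map skeleton, a gene -> species
    map, and a JSON manifest echoing the config with content hashes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    umi_len = layout.umi_len

    wl1 = random_whitelist(
        config.whitelist1_size or config.n_conditions,
        layout.round1_len,
        rng,
        config.whitelist_min_dist,
    )
    wl2 = random_whitelist(
        config.whitelist2_size or config.n_wells,
        layout.round2_len,
        rng,
        config.whitelist_min_dist,
    )
    r1_codes = sorted(wl1.barcodes)
    r2_codes = sorted(wl2.barcodes)

    if config.species_mix is not None:
        species_labels = sorted(config.species_mix)
    else:
        species_labels = ["human"]
    transcriptome = make_toy_transcriptome(
        config.n_genes,
        config.transcript_length,
        species_labels,
        rng,
        window=config.cdna_read_len,
    )

    cond_labels = (
        list(config.condition_labels)
        if config.condition_labels is not None
        else [f"cond{i:02d}" for i in range(config.n_conditions)]
    )

    n = config.n_cells
    if config.cells_per_condition is not None:
        cond_idx = np.repeat(np.arange(config.n_conditions), config.cells_per_condition)
    else:
        cond_idx = np.arange(n) % config.n_conditions
    if config.species_mix is not None:
        probs = [config.species_mix[s] for s in species_labels]
        species = rng.choice(species_labels, size=n, p=probs)
    else:
        species = np.array(["human"] * n)
    wells, occupancy = assign_cells_to_wells(n, config.n_wells, rng)

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n)],
            "condition": [cond_labels[c] for c in cond_idx],
            "species": species,
            "well": wells,
            "round1": [r1_codes[c] for c in cond_idx],
            "round2": [r2_codes[w] for w in wells],
        }
    )

    tables = _condition_weight_tables(config, transcriptome, cond_labels)
    mean_scale = np.array(
        [tables[(sp, cond)][2] for sp, cond in zip(cells["species"], cells["condition"])]
    ) if n else np.zeros(0)
    counts = sample_molecule_counts(
        n, config.mean_molecules_per_cell, config.dispersion, rng, mean_scale
    )

    mol_rows = []
    mol_id = 0
    for i in range(n):
        c = int(counts[i])
        if c == 0:
            continue
        genes, p, _ = tables[(species[i], cells["condition"].iat[i])]
        gidx = rng.choice(len(genes), size=c, p=p)
        umis = rng.integers(0, 4**umi_len, size=c)
        seen: set = set()
        for j in range(c):
            while (int(gidx[j]), int(umis[j])) in seen:
                umis[j] = rng.integers(0, 4**umi_len)
            seen.add((int(gidx[j]), int(umis[j])))
            mol_rows.append(
                (
                    f"mol{mol_id:08d}",
                    cells["cell_id"].iat[i],
                    genes[int(gidx[j])],
                    _int_to_umi(int(umis[j]), umi_len),
                )
            )
            mol_id += 1
    molecules = pd.DataFrame(
        mol_rows, columns=["molecule_id", "cell_id", "gene", "umi"]
    )

    r1_records, r2_records, reads = emit_reads(
        cells,
        molecules,
        transcriptome,
        layout,
        config.reads_per_molecule,
        config.error_rate,
        rng,
        cdna_read_len=config.cdna_read_len,
        polyT_tail_len=config.polyT_tail_len,
    )
    truth = TruthTables(cells=cells, molecules=molecules, reads=reads)

    manifest = {
        "tool": "prewell",
        "config": config.to_dict(),
        "seed": config.seed,
        "n_cells": n,
        "n_molecules": len(molecules),
        "n_reads": len(reads),
        "occupancy_nonempty_wells": int((occupancy > 0).sum()),
    }

    paths = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1_fastq": out / "R1.fastq.gz",
            "r2_fastq": out / "R2.fastq.gz",
            "transcriptome": out / "transcriptome.fa",
            "gene_table": out / "genes.tsv",
            "cells": out / "cells.tsv",
            "molecules": out / "molecules.tsv",
            "reads": out / "reads.tsv",
            "whitelist1": out / "whitelist_round1.txt",
            "whitelist2": out / "whitelist_round2.txt",
            "platemap": out / "platemap.tsv",
            "species_map": out / "species_map.tsv",
            "manifest": out / "manifest.json",
        }
        write_fastq(r1_records, paths["r1_fastq"])
        write_fastq(r2_records, paths["r2_fastq"])
        transcriptome.write_fasta(paths["transcriptome"])
        transcriptome.write_gene_table(paths["gene_table"])
        cells.to_csv(paths["cells"], sep="\t", index=False)
        molecules.to_csv(paths["molecules"], sep="\t", index=False)
        reads.to_csv(paths["reads"], sep="\t", index=False)
        write_whitelist(wl1, paths["whitelist1"])
        write_whitelist(wl2, paths["whitelist2"])
        _write_platemap_skeleton(paths["platemap"], r1_codes, cond_labels)
        with open(paths["species_map"], "w") as fh:
            fh.write("gene_id\tspecies\n")
            for g in transcriptome.genes:
                fh.write(f"{g}\t{transcriptome.species[g]}\n")
        hashes = {
            name: _sha256(p) for name, p in paths.items() if name != "manifest"
        }
        manifest["output_sha256"] = hashes
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        paths = {k: str(v) for k, v in paths.items()}

    return SimulationResult(
        config=config,
        wl_round1=wl1,
        wl_round2=wl2,
        transcriptome=transcriptome,
        truth=truth,
        manifest=manifest,
        paths=paths,
    )


def _write_platemap_skeleton(path, r1_codes, cond_labels) -> None:
    """Plate map mapping each used round-1 barcode to its condition.

    Replicate ids count repeated condition labels (duplicate wells of the
    same perturbation get replicate 1, 2, ...).
    """
    seen: dict = {}
    with open(path, "w") as fh:
        fh.write("barcode\twell\tcondition\treplicate\tcomponents\n")
        for i, (bc, cond) in enumerate(zip(r1_codes, cond_labels)):
            seen[cond] = seen.get(cond, 0) + 1
            comps = "+".join(cond.split("+"))
            fh.write(f"{bc}\tW{i + 1:03d}\t{cond}\t{seen[cond]}\t{comps}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
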