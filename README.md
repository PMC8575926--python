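# prewell

Simulator, demultiplexer and QC toolkit for **pre-indexed microwell
single-cell RNA-seq** — split-pool experiments in which every cell carries
two combinatorial barcodes:

1. a **round-1 pre-index** attached by well-specific primers during in-cell
   reverse transcription, before pooling (it encodes the sample or
   perturbation condition), and
2. a **round-2 bead barcode** ligated onto the cDNA by the single barcoded
   bead of the microwell the cell lands in.

A cell's transcriptome is assembled by combining all reads that share the
same two-barcode combination `(round1, round2)`. Because several cells
occupy one microwell, the pre-index is what keeps co-trapped cells
distinguishable: with *K* pre-indexes and *w* wells there are *K·w*
distinguishable identity slots instead of *w*. The package is for method
developers and analysts who need a fully ground-truthed sandbox for this
design: read-level simulation, exact demultiplexing statistics, barnyard
(two-species) doublet readouts, and the closed-form collision/capacity
model behind the plate-loading math.

## The model at the core

Cells are loaded uniformly and independently into wells (multinomial
loading) and pre-indexes are assigned per condition. Two cells **merge**
into one identity iff they share both barcodes. Under uniform placement
into the *s = K·w* slots:

- expected colliding pairs: `C(n,2) / s`
- expected occupied slots: `s · (1 − (1 − 1/s)^n)`
- merged-identity fraction: `1 − occupied/n`
- plate capacity at a merge budget *r*: the largest *n* whose merged
  fraction stays ≤ *r* (found by bisection).

A two-species mixing experiment reads this out empirically: an identity
whose UMIs are split across species (purity < 0.9 by default) is a
collision. Expression is simulated as gamma-Poisson (negative binomial)
per cell over a small synthetic transcriptome with lognormal abundance
weights; reads carry per-base substitution errors and are demultiplexed
with whitelist-based Hamming correction and 3′-window seed-and-extend gene
assignment.

## Worked example

```python
import prewell

cfg = prewell.SimConfig(
    n_cells=2000, n_conditions=48, n_wells=500, n_genes=50,
    mean_molecules_per_cell=100.0, reads_per_molecule=1.5,
    error_rate=0.005, species_mix={"human": 0.5, "mouse": 0.5}, seed=1,
)
res = prewell.simulate_experiment(cfg, out_dir="run")
idx = prewell.build_reference_index(res.transcriptome)
assigned, stats = prewell.demultiplex(
    res.paths["r1_fastq"], res.paths["r2_fastq"], cfg.layout,
    res.wl_round1, res.wl_round2, idx,
)
m = prewell.count_matrix(assigned, genes=idx.genes)
called = prewell.call_cells(dict(zip(m.cells, m.umi_per_cell())),
                            method="threshold", min_umi=1)
print(prewell.qc_summary(m, called))
print("mixed:", prewell.barnyard_classify(
    m, res.transcriptome.species, called).mixed_fraction)
print("model merged fraction:",
      prewell.expected_collisions(2000, 48, 500).merged_fraction)
```

prints (seed 1):

```
QCReport(n_cells_called=1913, mean_umi=84.58..., median_umi=81.0,
         mean_genes=17.87..., median_genes=18.0, mean_reads=152.83...,
         reads_in_cells_frac=1.0)
mixed: 0.0183...
model merged fraction: 0.04051...
```

1913 identities observed from 2000 loaded cells — ~4% of cells merged into
shared identities, matching the closed form; 1.8% of identities are
cross-species mixed (each merge is cross-species with probability
2·p·(1−p) = 0.5 here); mean UMI ≈ 85 because a Poisson(1.5) read depth
leaves ~78% of the ~108 molecules per cell sequenced.

The same pipeline is available from the shell:

```sh
prewell run --config run.yaml --out outdir       # simulate→demux→qc→annotate
prewell simulate / demux / qc / annotate ...     # individual stages
```

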