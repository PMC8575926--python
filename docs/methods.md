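# Methods

## The experiment being modeled

Pre-indexed microwell scRNA-seq labels every cell twice. In round 1, cells
sit in sample wells (one per condition) where in-cell reverse transcription
with well-specific primers attaches a pre-index barcode next to the poly-T
priming site. Cells are then pooled and centrifuged into an agarose
microwell array at several cells per well. Each microwell holds one
barcoded magnetic bead; bead oligonucleotides capture the barcoded cDNA by
hybridization and are ligated on, contributing the round-2 barcode 5′ of
the RT product. Only the 3′ ends of transcripts are sequenced. A cell
identity is the `(round1, round2)` pair; all reads sharing it are combined
into one transcriptome.

The design's central trade-off is capacity versus collisions: co-trapped
cells that also share a pre-index are indistinguishable. The package
implements this trade-off analytically (collision model), generatively
(simulator) and empirically (barnyard classification).

## Read layout and barcode correction

The chemistry fixes the order of elements on the barcode read — bead
barcode, then UMI, then RT pre-index, then the poly-T stretch — but not
their lengths, which are configuration. Defaults: round-2 = 18 nt,
UMI = 8 nt, round-1 = 10 nt, poly-T tail 15 nt, cDNA read 100 nt. The
optional poly-T filter (off by default) requires ≥ 80% T over a 10-nt
window after the barcodes.

Correction is substitution-only Hamming matching against a whitelist with
`max_dist ∈ {0,1,2}`, default 1: the fixed-position layout makes
substitutions the dominant recoverable error, and whitelists generated with
pairwise distance ≥ 3 (the simulator's default) make single-substitution
correction unambiguous. A read corrects iff exactly one whitelist entry
lies within `max_dist`; two or more give `ambiguous`, none `unmatched`.
Non-ACGT characters mismatch every base, so a barcode with more than
`max_dist` N's can never match. The production corrector precomputes the
1-mutant neighborhood for O(1) lookups and falls back to a vectorized scan
for `max_dist = 2` or reads containing N; both paths are tested against an
exhaustive brute-force scan.

## Simulator

The generator draws, in order: whitelists (rejection sampling to pairwise
distance ≥ 3), a transcriptome, per-cell condition / species / well
assignments, per-cell molecules, and reads.

- **Transcriptome**: random ACGT transcripts (default 50 genes × 500 nt),
  split evenly across species labels; 3′-terminal 100-mers are regenerated
  on collision so gene assignment has an unambiguous truth. Gene abundance
  weights are lognormal(σ = 1), the conventional skewed-abundance model.
- **Loading**: wells are drawn uniformly and independently per cell
  (multinomial). Doublets are *emergent*: two cells with the same pre-index
  in the same well simply share a CellKey — nothing is injected.
- **Expression**: molecule counts are gamma-Poisson with mean 100 and shape
  (dispersion) 2 by default, i.e. negative binomial with variance
  m + m²/2 — strong overdispersion typical of per-cell total counts. Genes
  are categorical by abundance weight restricted to the cell's species;
  UMIs are uniform over 4⁸ and resampled on within-(cell, gene) collision.
- **Condition effects**: a fold change *f* on a marked gene multiplies that
  gene's *absolute* expected molecule count by *f*: the gene's weight is
  scaled by *f* and the cell's expected total by the same renormalizer.
  Plain weight renormalization would depress the marked genes' ratio below
  *f* and perturb unmarked genes; this parameterization keeps pseudo-bulk
  ratio expectations exactly *f* for marked and 1 for unmarked genes.
- **Reads**: each molecule is sequenced Poisson(1.5) times by default;
  molecules drawn zero times are unsequenced, as in a real library. R1 is
  the exact concatenation of barcodes/UMI plus a poly-T tail; R2 is the
  exact 3′-terminal window of the transcript (no fragmentation model — a
  fixed window suffices to exercise gene assignment). Each base is
  substituted independently with probability `error_rate` (default 0 for
  oracle work; 0.005 in the headline run) to a uniformly random different
  base, with positions logged per read.

Everything is recorded in truth tables (cells, molecules, reads), and
`TruthTables.expected_matrix()` aggregates them exactly as a perfect
demultiplexer would — the oracle used throughout the tests.

**What the simulator does not emulate**: ambient RNA and empty-well
background, PCR duplication bias, quality-score structure (constant Q),
indels, doublet-specific library-size effects, fragmentation, and any
non-uniform well-loading bias. Passing tests therefore demonstrate the
correctness of the pipeline's bookkeeping and the internal consistency of
the collision model, not robustness to these real-data artifacts.

## Demultiplexing and quantification

Per read: parse at fixed offsets → correct round 2, then round 1 → assign
a gene. Gene assignment is seed-and-extend over an index of each gene's
3′-terminal 100-mer window (k = 21 seeds at read offsets 0, 10, 20;
candidates extended over the full read/window overlap; accepted at aligned
length ≥ 50 and ≤ 4 mismatches). A unique surviving gene is assigned;
several distinct survivors are `ambiguous`. A TSV ingestion path
(`read_gene_assignments`) accepts externally aligned read→gene tables for
real data.

Read fates partition exactly under the fixed precedence `too_short →
polyT_fail → round-2 → round-1 → gene`, so `DemuxStats` is reproducible
and always sums to the input total. UMI counting is exact distinct-UMI per
(cell, gene) — no Hamming-collapse of near-duplicate UMIs, which keeps the
count verifiable against truth. Matrices are MatrixMarket coordinate
integer files (cells × genes) beside `barcodes.tsv` / `genes.tsv`, with
per-cell read totals in `cell_reads.tsv`; an AnnData export is provided
for downstream toolkits.

## Cell calling

Two rules. `threshold` calls identities with ≥ `min_umi` total UMIs — the
right rule for background-free simulations. `knee` ranks totals, takes
log10 of rank and total, and calls everything above the point of maximum
perpendicular distance to the chord from the first to the last point.
Because sampling spread tilts the upper plateau, the literal argmax can
land one or two ranks above the cliff; the cutoff therefore extends down
the ranked list while totals remain within 2-fold of the knee value. Real
cell/background cliffs span orders of magnitude, so the 2-fold shoulder
never crosses them; the planted-cell recovery test exercises exactly this
geometry. All-equal totals defeat the construction and fall back to the
threshold rule with a warning.

## Barnyard classification and the collision model

For two species, a called identity's purity is the larger species' UMI
share (∈ [0.5, 1]); it is `mixed` iff purity < 0.9 (default — the
published scatter classifications rarely state their rule; the threshold
is explicit here so the readout is reproducible). "Collision" throughout
means an *identity merge* (shared CellKey), not a droplet-style biological
doublet.

With *n* cells over *s = K·w* uniform slots: expected colliding pairs
`C(n,2)/s`, expected occupied slots `s(1−(1−1/s)^n)`, merged fraction
`1 − occupied/n`, and capacity at budget *r* by bisection (the merged
fraction is nondecreasing in *n*). At a 50/50 species mix a pairwise merge
is cross-species with probability 2p(1−p); at low per-slot load the
identity-level mixed fraction is ≈ 2p(1−p) × merged fraction, which the
20-seed barnyard test verifies end-to-end against binomial error, and the
K = 1 → K = 48 contrast shows the pre-index diluting collisions.

## Condition annotation and summaries

The plate map (TSV: barcode, well, condition, replicate, components) maps
each round-1 barcode to its condition; replicate structure is the
multiplicity of a condition label. Annotation is total — cells with
unlisted barcodes are labeled `unlisted_barcode`, never dropped. Pseudo-bulk
is the plain per-condition UMI sum; the optional normalized mean is
counts-per-10⁴ → log1p → per-condition average. Differential-expression
testing is deliberately out of scope; exports feed standard toolkits.

## Determinism and numerics

All randomness flows through one `numpy` Generator seeded from the config;
fixed iteration order makes simulation outputs byte-identical across runs,
and gzip members are written with `mtime=0` so FASTQ files are bit-exact
too. Matrix axes are sorted lexicographically; rejection precedence and
tie handling (ties at the knee cutoff included; `ambiguous` on any ≥ 2
whitelist hits) are fixed. Capacity bisection is integer-exact.

## Problem sizes

The test suite and acceptance script run desk-scale configurations chosen
to give tight statistical checks in minutes on one CPU: 2,000-cell
experiments for oracle equivalence and the headline run, 10⁴-replicate
placement simulations for the collision grid, 20 seeded 500-cell
replicates for the barnyard check, and 1,000-cell runs for planted-effect
recovery. Statistical assertions use 3-SE bands around closed-form or
truth-table expectations.

## Known limitations

Gene assignment is a desk-scale stand-in for genome alignment (no splicing,
no multi-mappers beyond `ambiguous`, no indels); correction is
substitution-only; the analytic model assumes uniform loading, whereas
real arrays fill unevenly (the simulator, not the formula, is the place to
study such deviations); and UMI counting does not collapse sequencing-error
UMI duplicates, which slightly inflates counts at high error rates.
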