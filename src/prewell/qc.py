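"""Cell calling, QC summaries, barnyard doublet classification, and the
analytic pre-index x microwell collision/capacity model.

"Collision" here means an identity merge: two cells sharing both the
round-1 pre-index and the microwell (hence the bead barcode) are one
indistinguishable (round-1, round-2) identity after assembly. This is the
quantity the pre-index multiplies away — with K pre-indexes and w wells
there are K*w distinguishable slots — and it is what a barnyard
(two-species mixing) experiment reads out as mixed cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import CellGeneMatrix


# ---------------------------------------------------------------------------
# cell calling


def call_cells(
    totals: Mapping[str, int] | pd.Series,
    method: str = "knee",
    min_umi: int = 1,
) -> set:
    """Call real cells from per-identity UMI totals.

    ``knee``: rank identities by descending total, take log10 of both rank
    and total, and call everything above the point of maximum perpendicular
    distance to the chord joining the first and last points of the curve
    (ties at the knee total included). Because sampling noise tilts the
    upper plateau, the raw max-distance point can sit a rank or two above
    the cliff; the cutoff therefore extends down the ranked list while
    totals stay within 2-fold of the knee value — the cell/background cliff
    spans orders of magnitude, so the tolerance never crosses it.
    ``threshold``: call totals >= ``min_umi``. All-equal totals defeat the
    knee construction; the threshold fallback is used with a warning.
    """
    if isinstance(totals, pd.Series):
        totals = totals.to_dict()
    if not totals:
        raise DataError("call_cells: empty UMI totals")
    if method == "threshold":
        return {k for k, v in totals.items() if v >= min_umi}
    if method != "knee":
        raise ValueError(f"unknown cell-calling method {method!r}")
    keys = sorted(totals, key=lambda k: (-totals[k], k))
    vals = np.array([totals[k] for k in keys], dtype=float)
    if vals.min() == vals.max():
        warnings.warn(
            "all UMI totals equal; knee undefined, falling back to threshold",
            stacklevel=2,
        )
        return {k for k, v in totals.items() if v >= min_umi}
    x = np.log10(np.arange(1, len(vals) + 1))
    y = np.log10(np.maximum(vals, 1.0))
    # perpendicular distance from each point to the first->last chord
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    knee = int(np.argmax(dist))
    i = knee
    while i + 1 < len(vals) and vals[i + 1] >= 0.5 * vals[knee]:
        i += 1
    cutoff = vals[i]
    return {k for k, v in totals.items() if v >= cutoff}


# ---------------------------------------------------------------------------
# QC summary


@dataclass
class QCReport:
    """Per-run QC over called cells (means over called cells only)."""

    n_cells_called: int
    mean_umi: float | None
    median_umi: float | None
    mean_genes: float | None
    median_genes: float | None
    mean_reads: float | None
    reads_in_cells_frac: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)


def qc_summary(m: CellGeneMatrix, called: Iterable[str]) -> QCReport:
    """Summarize UMI/gene/read depth over the called cells.

    ``reads_in_cells_frac`` is the fraction of assigned reads that fall in
    called cells (requires the matrix's per-cell read metadata).
    """
    called = set(called)
    unknown = called - set(m.cells)
    if unknown:
        raise DataError(f"called keys not in matrix: {sorted(unknown)[:5]}")
    if not called:
        return QCReport(0, None, None, None, None, None, None)
    mask = np.array([c in called for c in m.cells])
    umi = m.umi_per_cell()[mask]
    genes = m.genes_per_cell()[mask]
    mean_reads = None
    frac = None
    if m.cell_reads is not None:
        total_reads = int(m.cell_reads.sum())
        in_cells = int(m.cell_reads[mask].sum())
        mean_reads = float(in_cells / mask.sum())
        frac = float(in_cells / total_reads) if total_reads else None
    return QCReport(
        n_cells_called=int(mask.sum()),
        mean_umi=float(umi.mean()),
        median_umi=float(np.median(umi)),
        mean_genes=float(genes.mean()),
        median_genes=float(np.median(genes)),
        mean_reads=mean_reads,
        reads_in_cells_frac=frac,
    )


# ---------------------------------------------------------------------------
# barnyard classification


@dataclass
class BarnyardResult:
    """Species-mixing readout.

    ``per_cell`` has one row per called identity: UMIs per species, purity
    (max species share of UMIs) and class (majority species label, or
    ``mixed`` when purity < threshold). ``mixed_fraction`` = mixed / called.
    """

    per_cell: pd.DataFrame
    species: tuple
    purity_threshold: float
    mixed_fraction: float

    @property
    def n_mixed(self) -> int:
        return int((self.per_cell["class"] == "mixed").sum())


def barnyard_classify(
    m: CellGeneMatrix,
    gene_species: Mapping[str, str],
    called: Iterable[str],
    purity_threshold: float = 0.9,
) -> BarnyardResult:
    """Classify called identities as one species or mixed.

    Purity is the larger species' share of the cell's UMIs, so it lies in
    [0.5, 1] for two species; a cell is mixed iff purity < threshold. The
    mixed fraction estimates the identity-collision (doublet) rate.
    """
    species = sorted(set(gene_species.values()))
    if len(species) != 2:
        raise DataError(f"barnyard requires exactly 2 species, got {species}")
    unmapped = [g for g in m.genes if g not in gene_species]
    if unmapped:
        raise DataError(f"genes missing from species map: {unmapped[:5]}")
    if not (0.5 < purity_threshold <= 1.0):
        raise ValueError("purity_threshold must be in (0.5, 1]")
    called = sorted(set(called))
    unknown = set(called) - set(m.cells)
    if unknown:
        raise DataError(f"called keys not in matrix: {sorted(unknown)[:5]}")
    sp_mask = np.array([gene_species[g] == species[0] for g in m.genes])
    umi_a = np.asarray(m.X[:, sp_mask].sum(axis=1)).ravel()
    umi_b = np.asarray(m.X[:, ~sp_mask].sum(axis=1)).ravel()
    idx = m.cell_index()
    rows = []
    for c in called:
        a = int(umi_a[idx[c]])
        b = int(umi_b[idx[c]])
        total = a + b
        if total == 0:
            purity, cls = float("nan"), "mixed"
        else:
            purity = max(a, b) / total
            if purity < purity_threshold:
                cls = "mixed"
            else:
                cls = species[0] if a >= b else species[1]
        rows.append((c, a, b, purity, cls))
    per_cell = pd.DataFrame(
        rows, columns=["cell_id", f"umi_{species[0]}", f"umi_{species[1]}", "purity", "class"]
    )
    mixed_fraction = float((per_cell["class"] == "mixed").mean()) if len(per_cell) else 0.0
    return BarnyardResult(
        per_cell=per_cell,
        species=tuple(species),
        purity_threshold=purity_threshold,
        mixed_fraction=mixed_fraction,
    )


# ---------------------------------------------------------------------------
# analytic collision / capacity model


@dataclass(frozen=True)
class CollisionModel:
    """Closed-form collision expectations for n cells, K pre-indexes, w wells.

    Under uniform independent placement into wells and uniform pre-index
    assignment there are K*w distinguishable (pre-index, well) slots:

    - expected colliding pairs  = C(n, 2) / (K*w)
    - expected occupied slots   = K*w * (1 - (1 - 1/(K*w))^n)
    - merged-identity fraction  = 1 - occupied/n   (cells lost to merging)
    """

    n: int
    K: int
    w: int

    def __post_init__(self):
        if self.n < 0 or self.K < 1 or self.w < 1:
            raise ValueError("need n >= 0, K >= 1, w >= 1")

    @property
    def slots(self) -> int:
        return self.K * self.w

    @property
    def expected_colliding_pairs(self) -> float:
        return self.n * (self.n - 1) / 2.0 / self.slots

    @property
    def expected_occupied_slots(self) -> float:
        if self.n == 0:
            return 0.0
        s = self.slots
        return float(s * -np.expm1(self.n * np.log1p(-1.0 / s))) if s > 1 else 1.0

    @property
    def merged_fraction(self) -> float:
        if self.n <= 1:
            return 0.0
        return 1.0 - self.expected_occupied_slots / self.n


def expected_collisions(n: int, K: int, w: int) -> CollisionModel:
    """Build the analytic collision model for a loading configuration."""
    return CollisionModel(n=n, K=K, w=w)


def capacity(K: int, w: int, target_merged_fraction: float, n_max: int = 10**9) -> int:
    """Largest cell load n with merged-identity fraction <= target.

    The merged fraction is nondecreasing in n, so bisection applies.
    """
    if not (0.0 < target_merged_fraction < 1.0):
        raise ValueError("target_merged_fraction must be in (0, 1)")
    lo, hi = 1, 2
    while CollisionModel(hi, K, w).merged_fraction <= target_merged_fraction:
        if hi >= n_max:
            return n_max
        lo, hi = hi, min(hi * 2, n_max)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if CollisionModel(mid, K, w).merged_fraction <= target_merged_fraction:
            lo = mid
        else:
            hi = mid
    return lo


def simulate_merged_fraction(
    n: int, K: int, w: int, n_replicates: int, rng: np.random.Generator
) -> tuple:
    """Monte-Carlo oracle for the placement model.

    Each replicate throws n cells uniformly into K*w slots. Returns
    (mean merged fraction, SE of the mean, mean colliding pairs, its SE).
    """
    s = K * w
    merged = np.empty(n_replicates)
    pairs = np.empty(n_replicates)
    for r in range(n_replicates):
        slots = rng.integers(0, s, size=n)
        occ = np.bincount(slots, minlength=s)
        merged[r] = 1.0 - (occ > 0).sum() / n if n else 0.0
        pairs[r] = (occ * (occ - 1) / 2.0).sum()
    return (
        float(merged.mean()),
        float(merged.std(ddof=1) / np.sqrt(n_replicates)),
        float(pairs.mean()),
        float(pairs.std(ddof=1) / np.sqrt(n_replicates)),
    )
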