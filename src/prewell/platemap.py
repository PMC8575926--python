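"""Plate-map annotation of pre-indexed cells and per-condition summaries.

The round-1 pre-index barcode is attached in a specific sample well before
pooling, so it encodes the experimental condition (e.g. a small-molecule
combination) of every cell that carries it. A plate map — a TSV of
(barcode, well, condition, replicate, components) rows — turns demultiplexed
cell identities into condition-annotated cells, and pseudo-bulk summaries
aggregate the annotated matrix per condition for downstream tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .barcode import CellKey, Whitelist
from .errors import DataError
from .matrix import CellGeneMatrix

REQUIRED_COLUMNS = ("barcode", "well", "condition", "replicate")

#: Condition label given to cells whose round-1 barcode is not in the map.
UNLISTED = "unlisted_barcode"


@dataclass
class PlateMap:
    """Validated plate map: one row per round-1 barcode."""

    table: pd.DataFrame

    def __post_init__(self):
        dup = self.table["barcode"][self.table["barcode"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate plate-map barcode(s): {sorted(set(dup))}")
        if (self.table["condition"].astype(str).str.len() == 0).any():
            raise DataError("empty condition label in plate map")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def conditions(self) -> list:
        return sorted(self.table["condition"].unique())

    def by_barcode(self) -> dict:
        return {row.barcode: row for row in self.table.itertuples(index=False)}

    def replicate_structure(self) -> pd.Series:
        """Number of replicate wells per condition label."""
        return self.table.groupby("condition").size()


def load_plate_map(path, whitelist: Whitelist | None = None) -> PlateMap:
    """Read and validate a plate-map TSV.

    Requires a header with barcode/well/condition/replicate columns
    (``components`` optional, free-form, '+'-separated by convention).
    When a round-1 whitelist is given, every barcode must belong to it.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: plate map is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {missing}")
    if len(table) == 0:
        raise DataError(f"{path}: plate map has no rows")
    if "components" not in table.columns:
        table["components"] = ""
    table["barcode"] = table["barcode"].str.upper()
    if whitelist is not None:
        offenders = sorted(set(table["barcode"]) - whitelist.barcodes)
        if offenders:
            raise DataError(
                f"{path}: barcode(s) not in round-1 whitelist: {offenders}"
            )
    return PlateMap(table=table.reset_index(drop=True))


@dataclass
class AnnotatedMatrix:
    """A count matrix plus per-cell condition metadata.

    ``obs`` has one row per matrix cell (same order): round1, round2,
    condition, replicate, well. Cells whose round-1 barcode is absent from
    the plate map carry condition ``unlisted_barcode``.
    """

    matrix: CellGeneMatrix
    obs: pd.DataFrame

    def __post_init__(self):
        if list(self.obs["cell_id"]) != list(self.matrix.cells):
            raise ValueError("obs rows must match matrix cells in order")

    @property
    def n_unlisted(self) -> int:
        return int((self.obs["condition"] == UNLISTED).sum())

    @property
    def n_annotated(self) -> int:
        return len(self.obs) - self.n_unlisted

    def to_anndata(self):
        ad = self.matrix.to_anndata()
        for col in ("condition", "replicate", "well"):
            ad.obs[col] = self.obs[col].to_numpy()
        return ad

    def write(self, out_dir) -> None:
        from .matrix import write_matrix

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.matrix, out)
        self.obs.to_csv(out / "cell_metadata.tsv", sep="\t", index=False)


def annotate_cells(m: CellGeneMatrix, pm: PlateMap) -> AnnotatedMatrix:
    """Annotate every matrix cell by its round-1 barcode's plate-map row.

    Annotation is total: annotated + unlisted == number of cells, always.
    """
    by_bc = pm.by_barcode()
    rows = []
    for cid in m.cells:
        key = CellKey.from_string(cid)
        row = by_bc.get(key.round1)
        if row is None:
            rows.append((cid, key.round1, key.round2, UNLISTED, "", ""))
        else:
            rows.append(
                (cid, key.round1, key.round2, row.condition, str(row.replicate), row.well)
            )
    obs = pd.DataFrame(
        rows, columns=["cell_id", "round1", "round2", "condition", "replicate", "well"]
    )
    return AnnotatedMatrix(matrix=m, obs=obs)


@dataclass
class ConditionSummary:
    """Per-condition aggregates of an annotated matrix.

    ``summary``: n_cells and mean UMI per condition. ``pseudobulk``: genes x
    conditions raw UMI sums. ``normalized_mean`` (optional): per-cell counts
    scaled to 10^4 total, log1p-transformed, averaged per condition.
    """

    summary: pd.DataFrame
    pseudobulk: pd.DataFrame
    normalized_mean: pd.DataFrame | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "condition_summary.tsv", sep="\t")
        self.pseudobulk.to_csv(out / "condition_pseudobulk.tsv", sep="\t")
        if self.normalized_mean is not None:
            self.normalized_mean.to_csv(out / "condition_lognorm_mean.tsv", sep="\t")


def condition_summaries(
    am: AnnotatedMatrix, normalize: bool = False, scale: float = 1e4
) -> ConditionSummary:
    """Aggregate an annotated matrix per condition.

    Pseudo-bulk is the plain sum of UMI counts over each condition's cells;
    unlisted-barcode cells are excluded. The optional normalized mean is
    counts-per-``scale`` then log1p then the per-condition average —
    the fixed, documented formula. Results are invariant to cell order.
    """
    listed = am.obs["condition"] != UNLISTED
    if not listed.any():
        raise DataError("no annotated cells (all barcodes unlisted)")
    X = am.matrix.X
    genes = am.matrix.genes
    conds = sorted(am.obs.loc[listed, "condition"].unique())
    sum_rows, n_cells, mean_umi, norm_rows = {}, {}, {}, {}
    umi_tot = am.matrix.umi_per_cell().astype(float)
    for cond in conds:
        mask = (am.obs["condition"] == cond).to_numpy()
        sub = X[mask]
        sum_rows[cond] = np.asarray(sub.sum(axis=0)).ravel()
        n_cells[cond] = int(mask.sum())
        mean_umi[cond] = float(umi_tot[mask].mean())
        if normalize:
            tot = umi_tot[mask]
            tot[tot == 0] = 1.0
            scaled = sub.multiply(scale / tot[:, None]).tocsr()
            scaled.data = np.log1p(scaled.data)
            norm_rows[cond] = np.asarray(scaled.mean(axis=0)).ravel()
    summary = pd.DataFrame(
        {"n_cells": pd.Series(n_cells), "mean_umi": pd.Series(mean_umi)}
    )
    summary.index.name = "condition"
    pseudobulk = pd.DataFrame(sum_rows, index=pd.Index(genes, name="gene_id"))
    normalized = (
        pd.DataFrame(norm_rows, index=pd.Index(genes, name="gene_id"))
        if normalize
        else None
    )
    assert int(summary["n_cells"].sum()) == am.n_annotated
    return ConditionSummary(
        summary=summary, pseudobulk=pseudobulk, normalized_mean=normalized
    )
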