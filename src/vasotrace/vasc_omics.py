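"""Vessel transcriptome set algebra: DEG filtering, sex Venn counts, atlas overlap.

The module consumes DEG tables (gene, log2 fold change, FDR, contrast) —
differential testing itself is upstream territory — and computes:

* FDR filtering at a strict ``fdr < 0.05`` cut with optional direction
  (up/down by the sign of log2FC);
* sex-stratified Venn counts between the male and female contrasts,
  including a check for genes with opposing fold-change signs;
* per-cell-type overlap with a marker atlas (a gene in several marker sets
  is reported under every matching type; the per-type counts are not
  mutually exclusive);
* the two-stage cross-species overlap: mouse per-cell-type DEGs against
  the healthy-human top-100 atlas, then against human AD DEG lists.

Gene symbols are case-normalized (uppercased) before any comparison, which
doubles as the mouse-to-human mapping rule (Mmp2 -> MMP2); an explicit
orthology table can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "MarkerAtlas",
    "VennCounts",
    "filter_deg",
    "sex_stratified_venn",
    "map_to_atlas",
    "cross_species_overlap",
    "atlas_from_table",
]

_REQUIRED_DEG_COLS = {"gene", "log2fc", "fdr"}


@dataclass
class MarkerAtlas:
    """Cell type -> ordered marker gene list, with a provenance tag."""

    markers: dict
    provenance: str = ""
    max_depth: int | None = None  # e.g. 500 for mouse, 100 for human atlases

    def __post_init__(self):
        norm = {}
        for ct, genes in self.markers.items():
            up = [str(g).upper() for g in genes]
            if len(up) != len(set(up)):
                raise SchemaError(f"duplicate genes in marker set '{ct}'")
            if self.max_depth is not None and len(up) > self.max_depth:
                raise SchemaError(
                    f"marker set '{ct}' exceeds atlas depth {self.max_depth}")
            norm[ct] = up
        self.markers = norm

    def cell_types(self):
        return list(self.markers)

    def gene_set(self, cell_type):
        return set(self.markers[cell_type])


@dataclass
class VennCounts:
    n_male_only: int
    n_female_only: int
    n_common: int
    opposing_sign_genes: list = field(default_factory=list)


def _check_schema(table: pd.DataFrame):
    missing = _REQUIRED_DEG_COLS - set(table.columns)
    if missing:
        raise SchemaError(f"DEG table missing columns: {sorted(missing)}")


def _normalized(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["gene"] = out["gene"].astype(str).str.upper()
    return out


def filter_deg(table: pd.DataFrame, fdr_max: float = 0.05,
               direction: str = "both") -> pd.DataFrame:
    """Rows with FDR strictly below ``fdr_max``, optionally by fold-change sign."""
    _check_schema(table)
    if direction not in ("up", "down", "both"):
        raise SchemaError("direction must be 'up', 'down' or 'both'")
    out = _normalized(table)
    out = out[out["fdr"] < fdr_max]
    if direction == "up":
        out = out[out["log2fc"] > 0]
    elif direction == "down":
        out = out[out["log2fc"] < 0]
    return out.reset_index(drop=True)


def sex_stratified_venn(table_m: pd.DataFrame, table_f: pd.DataFrame,
                        direction: str = "both") -> VennCounts:
    """Venn counts of DEG sets between the male and female contrasts.

    Inputs should already be FDR-filtered; the direction filter is applied
    here for convenience.  Genes present in both contrasts with opposing
    log2FC signs are counted as common and reported separately.
    """
    m = filter_deg(table_m, fdr_max=np.inf, direction=direction)
    f = filter_deg(table_f, fdr_max=np.inf, direction=direction)
    set_m = set(m["gene"])
    set_f = set(f["gene"])
    common = set_m & set_f
    sign_m = dict(zip(m["gene"], np.sign(m["log2fc"])))
    sign_f = dict(zip(f["gene"], np.sign(f["log2fc"])))
    opposing = sorted(g for g in common
                      if sign_m[g] != 0 and sign_f[g] != 0 and sign_m[g] != sign_f[g])
    return VennCounts(
        n_male_only=len(set_m - set_f),
        n_female_only=len(set_f - set_m),
        n_common=len(common),
        opposing_sign_genes=opposing,
    )


def map_to_atlas(filtered: pd.DataFrame, atlas: MarkerAtlas) -> pd.DataFrame:
    """Per-cell-type overlap of filtered DEGs with the marker atlas.

    Returns one row per cell type with the overlap count and gene list; a
    gene matching several cell types appears under each.
    """
    _check_schema(filtered)
    if not atlas.markers:
        raise SchemaError("empty marker atlas")
    genes = set(filtered["gene"].astype(str).str.upper())
    rows = []
    for ct in atlas.cell_types():
        hit = sorted(genes & atlas.gene_set(ct))
        rows.append((ct, len(hit), hit))
    return pd.DataFrame(rows, columns=["cell_type", "n_overlap", "genes"])


def cross_species_overlap(mouse_mapped: pd.DataFrame, human_atlas: MarkerAtlas,
                          human_ad_degs: MarkerAtlas):
    """Two-stage species translation of per-cell-type gene lists.

    Stage 1 intersects each mouse cell type's genes with the healthy human
    atlas list for the same cell type; stage 2 intersects the stage-1
    survivors with the human AD DEG list for that type.  Cell types absent
    from an atlas are reported in ``unmatched`` rather than dropped.
    Returns ``(stage_table, unmatched)``.
    """
    if not human_atlas.markers:
        raise SchemaError("empty human atlas")
    rows, unmatched = [], []
    for _, rec in mouse_mapped.iterrows():
        ct = rec["cell_type"]
        genes = {str(g).upper() for g in rec["genes"]}
        if ct not in human_atlas.markers:
            unmatched.append(ct)
            continue
        stage1 = sorted(genes & human_atlas.gene_set(ct))
        if ct in human_ad_degs.markers:
            stage2 = sorted(set(stage1) & human_ad_degs.gene_set(ct))
        else:
            stage2 = []
            if stage1 and ct not in human_ad_degs.markers:
                unmatched.append(f"{ct} (AD DEG list)")
        rows.append((ct, len(stage1), stage1, len(stage2), stage2))
    table = pd.DataFrame(rows, columns=[
        "cell_type", "n_stage1", "stage1_genes", "n_stage2", "stage2_genes"])
    return table, unmatched


def atlas_from_table(table: pd.DataFrame, provenance: str = "",
                     max_depth: int | None = None) -> MarkerAtlas:
    """Build a MarkerAtlas from a two-column (cell_type, gene) table."""
    if not {"cell_type", "gene"} <= set(table.columns):
        raise SchemaError("atlas table needs 'cell_type' and 'gene' columns")
    markers = {}
    for ct, g in table.groupby("cell_type", observed=True):
        markers[ct] = list(dict.fromkeys(g["gene"].astype(str)))
    return MarkerAtlas(markers=markers, provenance=provenance, max_depth=max_depth)
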