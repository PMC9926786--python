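"""DEG filtering and direction-matched DMR→DEG linkage.

Genes are classified up/down/ns by corrected p ≤ 0.05 and absolute fold
change ≥ 2 (both inclusive).  When the input table lacks corrected
values, Benjamini–Hochberg q-values are computed over all raw p-values;
when q is present it is used as-is.

Linkage keeps only the direction-matched pairs — promoter (or gene-body)
hypo-DMRs on up-regulated genes and hyper-DMRs on down-regulated genes —
the logically coherent pattern where promoter demethylation accompanies
activation.  Flip genes are regenerative DEGs whose promoters carry an
early-aging DMR synchronous with the expression direction and a
mid-to-late-aging DMR inverse to it (the Sox9/Kif4 pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome_annotation import GeneDMRMap
from .io_tables import DEGTable

__all__ = [
    "DEGParams",
    "DEGRecord",
    "LinkedGene",
    "FlipGene",
    "filter_degs",
    "link_dmrs_to_degs",
    "find_flip_genes",
]

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass(frozen=True)
class DEGParams:
    q_threshold: float = 0.05
    min_abs_fc: float = 2.0
    adjust_if_missing: str = "bh"  # or "none"

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.min_abs_fc < 1:
            raise ValueError("min_abs_fc must be >= 1")
        if self.adjust_if_missing not in ("bh", "none"):
            raise ValueError("adjust_if_missing must be 'bh' or 'none'")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    p_raw: float
    q: float
    direction: str  # up | down | ns


@dataclass(frozen=True)
class LinkedGene:
    gene_id: str
    deg_direction: str
    dmr_id: str
    dmr_direction: str
    contrast: str
    zone: str


@dataclass
class FlipGene:
    gene_id: str
    deg_direction: str
    early_dmr_ids: list[str] = field(default_factory=list)
    late_dmr_ids: list[str] = field(default_factory=list)


def filter_degs(table: DEGTable, params: DEGParams = DEGParams()) -> list[DEGRecord]:
    """Classify every gene up/down/ns; thresholds are inclusive.

    Rows with non-finite log2fc are rejected with a warning count in the
    return path (they simply do not appear).
    """
    df = table.df.copy()
    finite = np.isfinite(df["log2fc"].to_numpy(float))
    df = df[finite].reset_index(drop=True)
    if table.has_q:
        q = df["q"].to_numpy(float)
    elif params.adjust_if_missing == "bh":
        q = multipletests(df["p_raw"].to_numpy(float), method="fdr_bh")[1]
    else:
        q = df["p_raw"].to_numpy(float)
    min_log2 = math.log2(params.min_abs_fc)
    records: list[DEGRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        direction = NS
        if q[i] <= params.q_threshold:
            if row.log2fc >= min_log2:
                direction = UP
            elif -row.log2fc >= min_log2:
                direction = DOWN
        records.append(
            DEGRecord(
                gene_id=row.gene_id,
                log2fc=float(row.log2fc),
                p_raw=float(row.p_raw),
                q=float(q[i]),
                direction=direction,
            )
        )
    return records


_MATCH = {("hypo", UP), ("hyper", DOWN)}


def link_dmrs_to_degs(
    genemap: GeneDMRMap,
    degs: list[DEGRecord],
    zone_filter: str = "promoter",
) -> list[LinkedGene]:
    """Direction-matched linkage: hypo-DMR↔up-DEG, hyper-DMR↔down-DEG.

    ``zone_filter`` is ``"promoter"`` or ``"promoter+gBody"``.  Genes
    absent from the DEG list are dropped; a DEG may collect several DMRs
    (DMR-level vs gene-level counting is up to the caller).
    """
    if zone_filter not in ("promoter", "promoter+gBody"):
        raise ValueError("zone_filter must be 'promoter' or 'promoter+gBody'")
    zones = {"promoter"} if zone_filter == "promoter" else {"promoter", "gBody"}
    deg_by_gene = {d.gene_id: d for d in degs}
    out: list[LinkedGene] = []
    seen: set[tuple[str, str, str]] = set()
    for row in genemap.df.itertuples(index=False):
        if row.zone not in zones:
            continue
        deg = deg_by_gene.get(row.gene_id)
        if deg is None or deg.direction == NS:
            continue
        if (row.direction, deg.direction) not in _MATCH:
            continue
        key = (row.gene_id, row.dmr_id, row.zone)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            LinkedGene(
                gene_id=row.gene_id,
                deg_direction=deg.direction,
                dmr_id=row.dmr_id,
                dmr_direction=row.direction,
                contrast=row.contrast,
                zone=row.zone,
            )
        )
    return out


def linked_counts(links: list[LinkedGene]) -> dict[str, int]:
    """DMR-level and gene-level summary counts of a linkage result."""
    return {
        "n_links": len(links),
        "n_dmrs": len({(l.dmr_id, l.contrast) for l in links}),
        "n_genes": len({l.gene_id for l in links}),
        "n_up_genes": len({l.gene_id for l in links if l.deg_direction == UP}),
        "n_down_genes": len({l.gene_id for l in links if l.deg_direction == DOWN}),
    }


def find_flip_genes(
    early_map: GeneDMRMap,
    late_map: GeneDMRMap,
    degs: list[DEGRecord],
) -> list[FlipGene]:
    """Find DEGs with promoter DMRs synchronous in early aging and inverse
    in mid-to-late aging.

    Up-DEGs need >= 1 early hypo-DMR and >= 1 late hyper-DMR in the
    promoter; down-DEGs the mirror pattern.  Maps are restricted to the
    promoter zone internally.
    """
    def promoter_hits(gmap: GeneDMRMap, gene: str, direction: str) -> list[str]:
        sel = gmap.df[
            (gmap.df.gene_id == gene)
            & (gmap.df.zone == "promoter")
            & (gmap.df.direction == direction)
        ]
        return sorted(set(sel.dmr_id))

    flips: list[FlipGene] = []
    for deg in degs:
        if deg.direction == UP:
            early_dir, late_dir = "hypo", "hyper"
        elif deg.direction == DOWN:
            early_dir, late_dir = "hyper", "hypo"
        else:
            continue
        early_hits = promoter_hits(early_map, deg.gene_id, early_dir)
        late_hits = promoter_hits(late_map, deg.gene_id, late_dir)
        if early_hits and late_hits:
            flips.append(
                FlipGene(
                    gene_id=deg.gene_id,
                    deg_direction=deg.direction,
                    early_dmr_ids=early_hits,
                    late_dmr_ids=late_hits,
                )
            )
    return flips
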