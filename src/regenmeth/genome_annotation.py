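"""Hotspot region vocabulary, DMR genomic distributions, and DMR→gene maps.

The hotspot vocabulary is derived from gene models (strand-aware) plus
pass-through repeat/CGI tracks:

====================  =======================================================
Track                 Definition (0-based half-open; ``-`` genes mirrored)
====================  =======================================================
Gene                  transcript span
ExtGene               transcript span ± 1 kb
Genf                  start of 1st exon to start of 2nd exon
ExtGenf               Genf ± 1 kb
1stExon / 1stIntron   first exon / first intron (strand-aware "first")
Exon / Intron         all exons / all introns
FpUTR / TpUTR         5'/3' untranslated regions (require CDS coordinates)
Prom1k                TSS ± 1 kb (= TSSup1k ∪ TSSdn1k)
TSSup1k / TSSdn1k     1 kb upstream / downstream of the TSS
TTS1k                 TTS ± 1 kb (= TTSup1k ∪ TTSdn1k)
TTSup1k / TTSdn1k     1 kb upstream / downstream of the TTS
Center30ct            central 60% of the transcript span
TSS-7k                7 kb upstream of the TSS
====================  =======================================================

For ``-`` genes the TSS is the transcript end and "upstream" means larger
coordinates.  A DMR counts toward a region when it overlaps any interval
of the track by at least 1 bp; region classes are not mutually exclusive.

DMR→gene mapping uses the promoter window −7 kb/+3 kb around the TSS
(strand-aware) and/or the gene body.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .catalog_compare import CompareParams
from .dmc_dmr import DMRCatalog
from .io_tables import GeneModel, RegionTrack

__all__ = [
    "GeneMapParams",
    "HotspotReport",
    "GeneDMRMap",
    "derive_region_tracks",
    "hotspot_report",
    "map_dmrs_to_genes",
    "promoter_window",
]

log = logging.getLogger(__name__)

PASS_THROUGH = ("rmsk", "cgi", "SINE", "LINE", "LTR", "Simple_repeat")


@dataclass(frozen=True)
class GeneMapParams:
    promoter_upstream_bp: int = 7000
    promoter_downstream_bp: int = 3000

    def __post_init__(self) -> None:
        if self.promoter_upstream_bp < 0 or self.promoter_downstream_bp < 0:
            raise ValueError("promoter window extents must be >= 0")


@dataclass
class HotspotReport:
    """Per (direction, region) DMR counts and percentages of direction total."""

    df: pd.DataFrame  # columns: direction, region, count, percent
    direction_totals: dict[str, int]

    def percent(self, direction: str, region: str) -> float:
        sel = self.df[(self.df.direction == direction) & (self.df.region == region)]
        return float(sel["percent"].iloc[0]) if len(sel) else 0.0

    def count(self, direction: str, region: str) -> int:
        sel = self.df[(self.df.direction == direction) & (self.df.region == region)]
        return int(sel["count"].iloc[0]) if len(sel) else 0


@dataclass
class GeneDMRMap:
    """Rows: gene_id, dmr_id, zone (promoter|gBody), direction, contrast."""

    df: pd.DataFrame

    def genes(self, zone: str | None = None, direction: str | None = None) -> set[str]:
        sel = self.df
        if zone is not None:
            sel = sel[sel.zone == zone]
        if direction is not None:
            sel = sel[sel.direction == direction]
        return set(sel.gene_id)

    def __len__(self) -> int:
        return len(self.df)


def _clip(start: int, end: int, chrom: str, sizes: dict[str, int] | None):
    lo = max(start, 0)
    hi = end if sizes is None or chrom not in sizes else min(end, sizes[chrom])
    if lo >= hi:
        return None
    return lo, hi


def _gene_tracks(g: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Raw (unclipped) per-gene intervals for every derived track name."""
    out: dict[str, list[tuple[int, int]]] = {}
    plus = g.strand == "+"
    tss, tts = g.tss, g.tts

    out["Gene"] = [(g.tx_start, g.tx_end)]
    out["ExtGene"] = [(g.tx_start - 1000, g.tx_end + 1000)]

    exons = list(zip(g.exon_starts, g.exon_ends))
    introns = [
        (e0_end, e1_start)
        for (_, e0_end), (e1_start, _) in zip(exons, exons[1:])
        if e0_end < e1_start
    ]
    out["Exon"] = exons
    out["Intron"] = introns

    # strand-aware "first": rightmost exon/intron for '-' genes
    first_exon = exons[0] if plus else exons[-1]
    out["1stExon"] = [first_exon]
    if introns:
        out["1stIntron"] = [introns[0] if plus else introns[-1]]
    else:
        out["1stIntron"] = []

    # Genf: start of 1st exon to start of 2nd exon (strand-aware); a
    # single-exon gene's Genf spans the sole exon
    if len(exons) >= 2:
        if plus:
            genf = (exons[0][0], exons[1][0])
        else:
            genf = (exons[-2][1], exons[-1][1])
    else:
        genf = first_exon
    out["Genf"] = [genf]
    out["ExtGenf"] = [(genf[0] - 1000, genf[1] + 1000)]

    if plus:
        out["TSSup1k"] = [(tss - 1000, tss)]
        out["TSSdn1k"] = [(tss, tss + 1000)]
        out["TTSup1k"] = [(tts - 1000, tts)]
        out["TTSdn1k"] = [(tts, tts + 1000)]
        out["TSS-7k"] = [(tss - 7000, tss)]
    else:
        out["TSSup1k"] = [(tss, tss + 1000)]
        out["TSSdn1k"] = [(tss - 1000, tss)]
        out["TTSup1k"] = [(tts, tts + 1000)]
        out["TTSdn1k"] = [(tts - 1000, tts)]
        out["TSS-7k"] = [(tss, tss + 7000)]
    out["Prom1k"] = [(tss - 1000, tss + 1000)]
    out["TTS1k"] = [(tts - 1000, tts + 1000)]

    # central 60% of tx span, boundaries rounded toward the center
    span = g.tx_end - g.tx_start
    left = g.tx_start + math.ceil(0.2 * span)
    right = g.tx_end - math.ceil(0.2 * span)
    out["Center30ct"] = [(left, right)] if left < right else []

    # UTRs require CDS coordinates
    if g.cds_start is not None and g.cds_end is not None and g.cds_start < g.cds_end:
        utr_left = [
            (max(s, g.tx_start), min(e, g.cds_start))
            for s, e in exons
            if s < g.cds_start
        ]
        utr_left = [(s, e) for s, e in utr_left if s < e]
        utr_right = [
            (max(s, g.cds_end), e) for s, e in exons if e > g.cds_end
        ]
        utr_right = [(s, e) for s, e in utr_right if s < e]
        out["FpUTR"] = utr_left if plus else utr_right
        out["TpUTR"] = utr_right if plus else utr_left
    else:
        out["FpUTR"] = []
        out["TpUTR"] = []
    return out


def derive_region_tracks(
    genes: list[GeneModel],
    repeats: list[RegionTrack] | None = None,
    cgi: RegionTrack | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, RegionTrack]:
    """Build the full hotspot track vocabulary from gene models.

    Repeat tracks and the CGI track are passed through under their own
    names; an aggregate ``rmsk`` track is formed from all repeat classes
    if not already provided.  Windows are clipped to [0, chrom length)
    when sizes are given, else left at >= 0 with a log warning.
    """
    if chrom_sizes is None:
        log.warning("derive_region_tracks: no chromosome sizes; windows unclipped")
    acc: dict[str, list[tuple[str, int, int]]] = {}
    empty_utr = False
    for g in genes:
        for name, ivs in _gene_tracks(g).items():
            if name in ("FpUTR", "TpUTR") and not ivs and g.cds_start is None:
                empty_utr = True
            for s, e in ivs:
                clipped = _clip(s, e, g.chrom, chrom_sizes)
                if clipped:
                    acc.setdefault(name, []).append((g.chrom, *clipped))
    if empty_utr:
        log.warning("FpUTR/TpUTR empty for genes lacking CDS coordinates")
    tracks = {
        name: RegionTrack(name=name, intervals=ivs) for name, ivs in acc.items()
    }
    for name in (
        "Gene", "ExtGene", "Genf", "ExtGenf", "1stExon", "1stIntron", "Exon",
        "Intron", "FpUTR", "TpUTR", "Prom1k", "TSSup1k", "TSSdn1k", "TTS1k",
        "TTSup1k", "TTSdn1k", "Center30ct", "TSS-7k",
    ):
        tracks.setdefault(name, RegionTrack(name=name, intervals=[]))

    rmsk_ivs: list[tuple[str, int, int]] = []
    for tr in repeats or []:
        tracks[tr.name] = tr
        rmsk_ivs.extend(tr.intervals)
    if "rmsk" not in tracks:
        tracks["rmsk"] = RegionTrack(name="rmsk", intervals=rmsk_ivs)
    if cgi is not None:
        tracks["cgi"] = RegionTrack(name="cgi", intervals=list(cgi.intervals))
    return tracks


def _track_trees(track: RegionTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in track.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def hotspot_report(
    catalog: DMRCatalog,
    tracks: dict[str, RegionTrack],
    params: CompareParams = CompareParams(),
) -> HotspotReport:
    """Count DMRs overlapping each track, per direction, with percentages.

    Regions are not mutually exclusive: one DMR may count toward many.
    Percent = 100 × count / total DMRs of that direction (0 when empty).
    """
    totals = {
        "hyper": len(catalog.by_direction("hyper")),
        "hypo": len(catalog.by_direction("hypo")),
    }
    trees_by_track = {name: _track_trees(tr) for name, tr in tracks.items()}
    rows = []
    for name in sorted(tracks):
        trees = trees_by_track[name]
        counts = {"hyper": 0, "hypo": 0}
        for dmr in catalog.dmrs:
            tree = trees.get(dmr.chrom)
            if tree is None:
                continue
            hit = any(
                min(iv.end, dmr.end) - max(iv.begin, dmr.start)
                >= params.min_overlap_bp
                for iv in tree.overlap(dmr.start, dmr.end)
            )
            if hit:
                counts[dmr.direction] += 1
        for direction in ("hyper", "hypo"):
            total = totals[direction]
            rows.append(
                {
                    "direction": direction,
                    "region": name,
                    "count": counts[direction],
                    "percent": 100.0 * counts[direction] / total if total else 0.0,
                }
            )
    return HotspotReport(df=pd.DataFrame(rows), direction_totals=totals)


def promoter_window(
    gene: GeneModel, params: GeneMapParams = GeneMapParams()
) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS (−up, +down); unclipped."""
    up, down = params.promoter_upstream_bp, params.promoter_downstream_bp
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down, gene.tss + up


def map_dmrs_to_genes(
    catalog: DMRCatalog,
    genes: list[GeneModel],
    map_params: GeneMapParams = GeneMapParams(),
    params: CompareParams = CompareParams(),
) -> GeneDMRMap:
    """Map DMRs to genes via promoter (−7k/+3k of TSS) and gene-body zones.

    One row per (gene, dmr, zone) with >= 1 bp overlap; a pair may appear
    with both zones.  DMR identifiers are ``chrom:start-end:direction``.
    """
    rows = []
    zone_ivs: list[tuple[str, int, int, str, str]] = []  # chrom,s,e,gene,zone
    for g in genes:
        ps, pe = promoter_window(g, map_params)
        ps = max(ps, 0)
        if ps < pe:
            zone_ivs.append((g.chrom, ps, pe, g.gene_id, "promoter"))
        zone_ivs.append((g.chrom, g.tx_start, g.tx_end, g.gene_id, "gBody"))
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, gid, zone in zone_ivs:
        trees.setdefault(chrom, IntervalTree()).addi(s, e, (gid, zone))
    for dmr in catalog.dmrs:
        tree = trees.get(dmr.chrom)
        if tree is None:
            continue
        dmr_id = f"{dmr.chrom}:{dmr.start}-{dmr.end}:{dmr.direction}"
        seen: set[tuple[str, str]] = set()
        for iv in tree.overlap(dmr.start, dmr.end):
            if min(iv.end, dmr.end) - max(iv.begin, dmr.start) < params.min_overlap_bp:
                continue
            gid, zone = iv.data
            if (gid, zone) in seen:  # dedupe multi-isoform repeats by gene_id
                continue
            seen.add((gid, zone))
            rows.append(
                {
                    "gene_id": gid,
                    "dmr_id": dmr_id,
                    "zone": zone,
                    "direction": dmr.direction,
                    "contrast": catalog.contrast_label,
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "dmr_id", "zone", "direction", "contrast"])
    df = df.sort_values(["gene_id", "dmr_id", "zone"], ignore_index=True)
    return GeneDMRMap(df=df)
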