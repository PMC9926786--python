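"""Seeded synthetic methylomes with planted ground truth.

The generator emulates the statistical structure of replicate liver WGBS
count data: CpG positions are irregular (uniform without replacement on
even coordinates, so dyads never collide), per-CpG baseline methylation
is U-shaped Beta-distributed (default Beta(0.7, 0.25), mean ≈ 74%
matching the bulk-liver global methylation level), per-sample coverage is
Poisson (default mean 10×), and methylated counts are Binomial in the
condition-level methylation fraction.

Six conditions are produced: three baseline ages (A2R0, A8R0, A16R0) and
three post-hepatectomy time points of the young liver (A2R1, A2R2, A2R4),
four replicates each by default.  Condition fractions are built
cumulatively — A8 adds the early-aging shift to A2, A16 adds the
mid-to-late shift to A8, and each regeneration time point adds its own
shift to the shared A2R0 baseline — so a region planted only for the
early contrast persists into A16 (an "early single" event) rather than
reverting.  Shifted fractions are clipped to [0.02, 0.98].

Planted truth (region coordinates, per-contrast directions, effect sizes,
DEG directions and promoter patterns) is returned as a table so every
downstream call can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dmc_dmr import DMRCatalog
from .genome_annotation import GeneMapParams, promoter_window
from .io_tables import (
    CpGCountTable,
    DEGTable,
    GeneModel,
    RegionTrack,
    write_chrom_sizes,
    write_cpg_table,
    write_dmr_bed,
    write_gene_models,
)

__all__ = [
    "SimConfig",
    "PlantedRegion",
    "PlantedDEG",
    "SimResult",
    "default_config",
    "simulate",
    "simulate_tables",
    "score_recovery",
]

CONDITIONS = ("A2R0", "A8R0", "A16R0", "A2R1", "A2R2", "A2R4")

#: contrast label -> (test condition, reference condition)
CONTRASTS = {
    "A8:A2": ("A8R0", "A2R0"),
    "A16:A8": ("A16R0", "A8R0"),
    "A16:A2": ("A16R0", "A2R0"),
    "R1:R0": ("A2R1", "A2R0"),
    "R2:R0": ("A2R2", "A2R0"),
    "R4:R0": ("A2R4", "A2R0"),
}

CLIP_LO, CLIP_HI = 0.02, 0.98


@dataclass(frozen=True)
class PlantedRegion:
    """A contiguous run of CpGs shifted in one or two contrasts."""

    chrom: str
    start: int
    end: int  # half-open; CpGs are placed in [start, end)
    n_cpgs: int = 10
    #: contrast label -> 'hyper' | 'hypo' (direction of the test condition)
    effects: dict = field(default_factory=dict)
    effect_size: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cpgs < 3:
            raise ValueError("planted region needs >= 3 CpGs")
        if self.end - self.start < 2 * self.n_cpgs:
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end}: too short for "
                f"{self.n_cpgs} CpG dyads"
            )
        for contrast, direction in self.effects.items():
            if contrast not in CONTRASTS:
                raise ValueError(f"unknown contrast {contrast!r}")
            if direction not in ("hyper", "hypo"):
                raise ValueError(f"bad direction {direction!r}")


@dataclass(frozen=True)
class PlantedDEG:
    gene_id: str
    direction: str  # up | down
    log2fc: float = 1.5
    promoter_dmr_pattern: str = "none"  # early_sync_late_inverse | sync_only | none

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.promoter_dmr_pattern not in (
            "early_sync_late_inverse",
            "sync_only",
            "none",
        ):
            raise ValueError(f"bad pattern {self.promoter_dmr_pattern!r}")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_200_000
    n_cpgs: int = 30_000  # background CpGs, genome-wide
    n_genes: int = 60
    n_repeats: int = 120
    n_replicates: int = 4
    mean_coverage: float = 10.0
    coverage_model: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 2.0
    baseline_beta: tuple[float, float] = (0.7, 0.25)
    planted_regions: tuple[PlantedRegion, ...] = ()
    planted_degs: tuple[PlantedDEG, ...] = ()

    def __post_init__(self) -> None:
        if self.coverage_model not in ("poisson", "negbin"):
            raise ValueError("coverage_model must be 'poisson' or 'negbin'")


@dataclass
class SimResult:
    config: SimConfig
    samples: dict  # condition -> list[CpGCountTable]
    genes: list[GeneModel]
    repeat_tracks: list[RegionTrack]
    cgi: RegionTrack
    chrom_sizes: dict[str, int]
    degs: DEGTable
    truth: pd.DataFrame  # planted regions and DEGs
    baseline: dict = field(default_factory=dict)  # chrom -> latent per-CpG beta

    def truth_regions(self, contrast: str | None = None) -> pd.DataFrame:
        t = self.truth[self.truth.kind == "region"]
        if contrast is not None:
            t = t[t.contrast == contrast]
        return t


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _make_genes(cfg: SimConfig) -> list[GeneModel]:
    """Tile genes across chromosomes, alternating strands, 2-3 exons."""
    chroms = _chrom_names(cfg.n_chroms)
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    pitch = cfg.chrom_length_bp // (per_chrom + 1)
    genes: list[GeneModel] = []
    gi = 0
    for chrom in chroms:
        for slot in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            tx_start = 20_000 + slot * pitch
            tx_end = tx_start + 8_000
            strand = "+" if gi % 2 == 0 else "-"
            n_ex = 2 + gi % 2
            if n_ex == 2:
                starts = (tx_start, tx_start + 5_000)
                ends = (tx_start + 1_000, tx_end)
            else:
                starts = (tx_start, tx_start + 3_000, tx_start + 6_000)
                ends = (tx_start + 800, tx_start + 3_900, tx_end)
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:03d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exon_starts=starts,
                    exon_ends=ends,
                    cds_start=tx_start + 400,
                    cds_end=tx_end - 400,
                )
            )
            gi += 1
    return genes


def _make_repeats(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[RegionTrack], RegionTrack]:
    classes = ("SINE", "LINE", "LTR", "Simple_repeat")
    chroms = _chrom_names(cfg.n_chroms)
    per_class: dict[str, list[tuple[str, int, int]]] = {c: [] for c in classes}
    for _ in range(cfg.n_repeats):
        cls = classes[int(rng.integers(len(classes)))]
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        length = int(rng.integers(150, 1200))
        start = int(rng.integers(0, cfg.chrom_length_bp - length))
        per_class[cls].append((chrom, start, start + length))
    tracks = [RegionTrack(name=c, intervals=ivs) for c, ivs in per_class.items()]
    cgi_ivs = []
    n_cgi = max(cfg.n_genes // 2, 1)
    for _ in range(n_cgi):
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        length = int(rng.integers(300, 1500))
        start = int(rng.integers(0, cfg.chrom_length_bp - length))
        cgi_ivs.append((chrom, start, start + length))
    return tracks, RegionTrack(name="cgi", intervals=cgi_ivs)


def _condition_offsets(region: PlantedRegion) -> dict[str, float]:
    """Cumulative per-condition shifts implied by a region's contrasts."""
    e = region.effect_size
    sgn = {"hyper": +e, "hypo": -e}
    off = {c: 0.0 for c in CONDITIONS}
    if "A8:A2" in region.effects:
        d = sgn[region.effects["A8:A2"]]
        off["A8R0"] += d
        off["A16R0"] += d  # persists unless the late contrast says otherwise
    if "A16:A8" in region.effects:
        off["A16R0"] += sgn[region.effects["A16:A8"]]
    if "A16:A2" in region.effects and "A8:A2" not in region.effects and "A16:A8" not in region.effects:
        off["A16R0"] += sgn[region.effects["A16:A2"]]
    for contrast, cond in (("R1:R0", "A2R1"), ("R2:R0", "A2R2"), ("R4:R0", "A2R4")):
        if contrast in region.effects:
            off[cond] += sgn[region.effects[contrast]]
    return off


def simulate_tables(cfg: SimConfig) -> SimResult:
    """Run the generator in memory.  Deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    chroms = _chrom_names(cfg.n_chroms)
    sizes = {c: cfg.chrom_length_bp for c in chroms}
    genes = _make_genes(cfg)
    repeat_tracks, cgi = _make_repeats(cfg, rng)

    # --- CpG positions (even coordinates; planted first, background after)
    planted_pos: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    region_meta: list[tuple[PlantedRegion, np.ndarray]] = []
    for region in cfg.planted_regions:
        half = np.arange(region.start // 2 + (region.start % 2), region.end // 2)
        if len(half) < region.n_cpgs:
            raise ValueError(
                f"planted region {region.chrom}:{region.start}-{region.end}: "
                f"not enough CpG positions"
            )
        pos = np.sort(rng.choice(half, size=region.n_cpgs, replace=False)) * 2
        planted_pos[region.chrom].append(pos)
        region_meta.append((region, pos))

    per_chrom_bg = -(-cfg.n_cpgs // cfg.n_chroms)
    all_pos: dict[str, np.ndarray] = {}
    for chrom in chroms:
        taken = (
            np.concatenate(planted_pos[chrom]) if planted_pos[chrom] else np.array([], int)
        )
        bg = rng.choice(cfg.chrom_length_bp // 2, size=per_chrom_bg, replace=False) * 2
        bg = np.setdiff1d(bg, taken)
        all_pos[chrom] = np.sort(np.concatenate([taken, bg]))

    # --- baseline fractions; planted CpGs get a headroom-aware baseline
    a, b = cfg.baseline_beta
    base: dict[str, np.ndarray] = {
        chrom: rng.beta(a, b, size=len(all_pos[chrom])) for chrom in chroms
    }
    offsets: dict[str, dict[str, np.ndarray]] = {
        cond: {chrom: np.zeros(len(all_pos[chrom])) for chrom in chroms}
        for cond in CONDITIONS
    }
    for region, pos in region_meta:
        chrom = region.chrom
        idx = np.searchsorted(all_pos[chrom], pos)
        off = _condition_offsets(region)
        omin = min(off.values())
        omax = max(off.values())
        lo, hi = 0.05 - omin, 0.95 - omax  # keep every condition inside (0.05, 0.95)
        if lo >= hi:
            raise ValueError(
                f"planted region {chrom}:{region.start}-{region.end}: "
                f"cumulative shifts leave no baseline headroom"
            )
        base[chrom][idx] = rng.uniform(lo, hi, size=len(idx))
        for cond, val in off.items():
            if val:
                offsets[cond][chrom][idx] += val

    # --- per-sample counts
    samples: dict[str, list[CpGCountTable]] = {}
    for cond in CONDITIONS:
        tables = []
        for rep in range(cfg.n_replicates):
            frames = []
            for chrom in chroms:
                off = offsets[cond][chrom]
                # only shifted fractions are clipped; the untouched baseline
                # keeps the Beta-distributed global methylation level
                beta_cond = np.where(
                    off != 0.0, np.clip(base[chrom] + off, CLIP_LO, CLIP_HI), base[chrom]
                )
                n = len(all_pos[chrom])
                if cfg.coverage_model == "poisson":
                    cov = rng.poisson(cfg.mean_coverage, size=n)
                else:
                    r = cfg.negbin_dispersion
                    p = r / (r + cfg.mean_coverage)
                    cov = rng.negative_binomial(r, p, size=n)
                meth = rng.binomial(cov, beta_cond)
                frames.append(
                    pd.DataFrame(
                        {"chrom": chrom, "pos": all_pos[chrom], "meth": meth, "total": cov}
                    )
                )
            df = pd.concat(frames, ignore_index=True)
            tables.append(CpGCountTable(sample_id=f"{cond}_rep{rep + 1}", df=df))
        samples[cond] = tables

    # --- DEG table: planted DEGs plus null background genes
    planted_by_gene = {d.gene_id: d for d in cfg.planted_degs}
    deg_rows = []
    for g in genes:
        planted = planted_by_gene.get(g.gene_id)
        if planted is not None:
            sign = 1.0 if planted.direction == "up" else -1.0
            lfc = sign * abs(planted.log2fc)
            p = float(rng.uniform(1e-8, 1e-5))  # survives BH at any sane table size
        else:
            lfc = float(rng.normal(0.0, 0.3))
            p = float(rng.uniform(0.0, 1.0))
        deg_rows.append({"gene_id": g.gene_id, "log2fc": lfc, "p_raw": p})
    degs = DEGTable(df=pd.DataFrame(deg_rows))

    # --- truth table
    truth_rows = []
    for region, pos in region_meta:
        for contrast, direction in sorted(region.effects.items()):
            truth_rows.append(
                {
                    "kind": "region",
                    "chrom": region.chrom,
                    "start": int(pos[0]),
                    "end": int(pos[-1]) + 1,
                    "contrast": contrast,
                    "direction": direction,
                    "effect": region.effect_size,
                    "n_cpgs": region.n_cpgs,
                    "gene_id": "",
                    "pattern": "",
                }
            )
    for d in cfg.planted_degs:
        truth_rows.append(
            {
                "kind": "deg",
                "chrom": "",
                "start": -1,
                "end": -1,
                "contrast": "",
                "direction": d.direction,
                "effect": d.log2fc,
                "n_cpgs": 0,
                "gene_id": d.gene_id,
                "pattern": d.promoter_dmr_pattern,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "kind", "chrom", "start", "end", "contrast", "direction",
            "effect", "n_cpgs", "gene_id", "pattern",
        ],
    )
    return SimResult(
        config=cfg,
        samples=samples,
        genes=genes,
        repeat_tracks=repeat_tracks,
        cgi=cgi,
        chrom_sizes=sizes,
        degs=degs,
        truth=truth,
        baseline=base,
    )


def simulate(cfg: SimConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run the generator and write every artifact under ``out_dir``.

    Writes per-sample CpG TSVs, the gene-model TSV, repeat/CGI BEDs, a
    chrom-sizes file, the DEG TSV, and truth.tsv.  Returns the truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = simulate_tables(cfg)
    for cond, tables in res.samples.items():
        for t in tables:
            write_cpg_table(t, out / f"{t.sample_id}.tsv")
    write_gene_models(res.genes, out / "genes.tsv")
    with open(out / "repeats.bed", "w") as fh:
        for tr in res.repeat_tracks:
            for chrom, s, e in tr.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{tr.name}\n")
    with open(out / "cgi.bed", "w") as fh:
        for chrom, s, e in res.cgi.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\tcgi\n")
    write_chrom_sizes(res.chrom_sizes, out / "chrom.sizes")
    res.degs.df.to_csv(out / "degs.tsv", sep="\t", index=False, header=True)
    res.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return res.truth


# -- default study-condition configuration ------------------------------------

def default_config(
    seed: int = 0,
    n_single_per_contrast_direction: int = 12,
    n_progressive: int = 20,
    n_inverse: int = 20,
    n_cross_sync: int = 6,
    n_cross_inverse: int = 6,
    region_span: int = 280,
    cpgs_per_region: int = 10,
    effect: float = 0.3,
) -> SimConfig:
    """The default planted layout used by the end-to-end suites.

    Plants single-contrast regions for each of the five called contrasts
    in both directions, progressive and inverse aging regions (split
    evenly between the two direction patterns), regeneration promoter
    regions on the planted DEGs, and four flip genes (two up, two down).
    """
    cfg0 = SimConfig(seed=seed)
    chroms = _chrom_names(cfg0.n_chroms)
    genes = _make_genes(cfg0)

    regions: list[PlantedRegion] = []
    # intergenic slots: gene pitch leaves [tx_end, next tx_start) free; walk
    # a deterministic cursor through each chromosome away from promoters
    slot_pitch = 3_000
    cursors = {c: 30_500 for c in chroms}  # odd offset, clear of gene starts
    gene_keepout = []
    pw = GeneMapParams()
    for g in genes:
        ps, pe = promoter_window(g, pw)
        gene_keepout.append((g.chrom, min(ps, g.tx_start) - 400, max(pe, g.tx_end) + 400))

    def next_slot(chrom: str) -> int:
        cur = cursors[chrom]
        while True:
            blocked = any(
                kc == chrom and cur < ke and cur + region_span > ks
                for kc, ks, ke in gene_keepout
            )
            if not blocked:
                break
            cur += slot_pitch
        cursors[chrom] = cur + slot_pitch
        return cur

    def plant(effects: dict) -> None:
        chrom = chroms[len(regions) % len(chroms)]
        start = next_slot(chrom)
        regions.append(
            PlantedRegion(
                chrom=chrom,
                start=start,
                end=start + region_span,
                n_cpgs=cpgs_per_region,
                effects=effects,
                effect_size=effect,
            )
        )

    for contrast in ("A8:A2", "A16:A8", "R1:R0", "R2:R0", "R4:R0"):
        for direction in ("hyper", "hypo"):
            for _ in range(n_single_per_contrast_direction):
                plant({contrast: direction})
    for i in range(n_progressive):
        d = "hyper" if i % 2 == 0 else "hypo"
        plant({"A8:A2": d, "A16:A8": d})
    for i in range(n_inverse):
        d, o = ("hyper", "hypo") if i % 2 == 0 else ("hypo", "hyper")
        plant({"A8:A2": d, "A16:A8": o})
    # aging x regeneration shared regions: synchronous changes concentrate
    # in early aging, inverse changes in mid-to-late aging, as in the liver
    for i in range(n_cross_sync):
        d = "hyper" if i % 2 == 0 else "hypo"
        plant({"A8:A2": d, "R2:R0": d})
    for i in range(n_cross_inverse):
        d, o = ("hyper", "hypo") if i % 2 == 0 else ("hypo", "hyper")
        plant({"A16:A8": d, "R1:R0": o})

    # flip genes: early-sync + late-inverse promoter regions; sync-only pair;
    # plus plain DEGs carrying a matched R2:R0 promoter region
    planted_degs: list[PlantedDEG] = []
    flip_specs = [
        ("g004", "up", "early_sync_late_inverse"),
        ("g010", "up", "early_sync_late_inverse"),
        ("g016", "down", "early_sync_late_inverse"),
        ("g022", "down", "early_sync_late_inverse"),
        ("g028", "up", "sync_only"),
        ("g034", "down", "sync_only"),
        ("g040", "up", "none"),
        ("g046", "down", "none"),
    ]
    gene_by_id = {g.gene_id: g for g in genes}
    for gene_id, direction, pattern in flip_specs:
        planted_degs.append(
            PlantedDEG(gene_id=gene_id, direction=direction, promoter_dmr_pattern=pattern)
        )
        g = gene_by_id[gene_id]
        ps, pe = promoter_window(g, pw)
        ps, pe = ps + 20, pe - 20
        early_dir = "hypo" if direction == "up" else "hyper"
        late_dir = "hyper" if direction == "up" else "hypo"
        if pattern in ("early_sync_late_inverse", "sync_only"):
            regions.append(
                PlantedRegion(
                    chrom=g.chrom,
                    start=ps,
                    end=ps + region_span,
                    n_cpgs=cpgs_per_region,
                    effects={"A8:A2": early_dir},
                    effect_size=effect,
                )
            )
        if pattern == "early_sync_late_inverse":
            regions.append(
                PlantedRegion(
                    chrom=g.chrom,
                    start=ps + region_span + 200,
                    end=ps + 2 * region_span + 200,
                    n_cpgs=cpgs_per_region,
                    effects={"A16:A8": late_dir},
                    effect_size=effect,
                )
            )
        # a direction-matched regenerative promoter region (links the DEG)
        regen_dir = "hypo" if direction == "up" else "hyper"
        regions.append(
            PlantedRegion(
                chrom=g.chrom,
                start=pe - region_span,
                end=pe,
                n_cpgs=cpgs_per_region,
                effects={"R2:R0": regen_dir},
                effect_size=effect,
            )
        )

    return SimConfig(
        seed=seed,
        planted_regions=tuple(regions),
        planted_degs=tuple(planted_degs),
    )


def planted_temporal_regions(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted regions affected by BOTH aging contrasts, with their implied
    temporal category (progressive when directions agree, inverse otherwise)."""
    regions = truth[truth.kind == "region"]
    aging = regions[regions.contrast.isin(("A8:A2", "A16:A8"))]
    rows = []
    for (chrom, start, end), grp in aging.groupby(["chrom", "start", "end"]):
        by_contrast = dict(zip(grp.contrast, grp.direction))
        if len(by_contrast) != 2:
            continue
        category = (
            "progressive"
            if by_contrast["A8:A2"] == by_contrast["A16:A8"]
            else "inverse"
        )
        rows.append(
            {
                "chrom": chrom, "start": start, "end": end,
                "category": category,
                "early_direction": by_contrast["A8:A2"],
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "early_direction"])


def score_temporal_recovery(truth: pd.DataFrame, temporal_calls) -> dict:
    """Fraction of planted progressive/inverse aging regions whose temporal
    classification was recovered (an early-contrast DMR of the planted
    category overlaps the planted span by >= 1 bp)."""
    planted = planted_temporal_regions(truth)
    recovered = 0
    for r in planted.itertuples(index=False):
        hit = any(
            c.category == r.category
            and c.dmr.chrom == r.chrom
            and min(c.dmr.end, r.end) - max(c.dmr.start, r.start) >= 1
            for c in temporal_calls
        )
        recovered += hit
    return {
        "n_planted": len(planted),
        "recovered": recovered,
        "fraction": recovered / len(planted) if len(planted) else float("nan"),
    }


def score_flip_recovery(truth: pd.DataFrame, flip_genes) -> dict:
    """Planted flip genes (early-sync + late-inverse promoter pattern)
    versus the flip genes the pipeline reports."""
    planted = set(
        truth[(truth.kind == "deg") & (truth.pattern == "early_sync_late_inverse")].gene_id
    )
    called = {f.gene_id for f in flip_genes}
    return {
        "n_planted": len(planted),
        "recovered": len(planted & called),
        "spurious": len(called - planted),
        "fraction": len(planted & called) / len(planted) if planted else float("nan"),
    }


def score_recovery(
    truth: pd.DataFrame, catalogs: dict[str, DMRCatalog]
) -> pd.DataFrame:
    """Score called catalogs against planted truth, per contrast.

    A planted region is recovered when a called DMR of the same contrast
    and direction overlaps it by >= 1 bp; a called DMR is a true positive
    when it overlaps any such planted region.  Returns one row per
    contrast plus an 'overall' row, with sensitivity, precision, and the
    mean recovered-overlap fraction of planted spans.
    """
    rows = []
    tot_rec = tot_planted = tot_tp = tot_called = 0
    all_fracs: list[float] = []
    regions = truth[truth.kind == "region"]
    for contrast, catalog in sorted(catalogs.items()):
        t = regions[regions.contrast == contrast]
        recovered = 0
        fracs = []
        for r in t.itertuples(index=False):
            best = 0.0
            for dmr in catalog.dmrs:
                if dmr.direction != r.direction or dmr.chrom != r.chrom:
                    continue
                ov = min(dmr.end, r.end) - max(dmr.start, r.start)
                if ov >= 1:
                    best = max(best, ov / (r.end - r.start))
            if best > 0:
                recovered += 1
                fracs.append(best)
        tp = 0
        for dmr in catalog.dmrs:
            hit = any(
                r.chrom == dmr.chrom
                and r.direction == dmr.direction
                and min(dmr.end, r.end) - max(dmr.start, r.start) >= 1
                for r in t.itertuples(index=False)
            )
            tp += hit
        n_planted, n_called = len(t), len(catalog.dmrs)
        rows.append(
            {
                "contrast": contrast,
                "n_planted": n_planted,
                "n_called": n_called,
                "recovered": recovered,
                "true_positive": tp,
                "sensitivity": recovered / n_planted if n_planted else float("nan"),
                "precision": tp / n_called if n_called else float("nan"),
                "mean_overlap_fraction": float(np.mean(fracs)) if fracs else 0.0,
            }
        )
        tot_rec += recovered
        tot_planted += n_planted
        tot_tp += tp
        tot_called += n_called
        all_fracs.extend(fracs)
    rows.append(
        {
            "contrast": "overall",
            "n_planted": tot_planted,
            "n_called": tot_called,
            "recovered": tot_rec,
            "true_positive": tot_tp,
            "sensitivity": tot_rec / tot_planted if tot_planted else float("nan"),
            "precision": tot_tp / tot_called if tot_called else float("nan"),
            "mean_overlap_fraction": float(np.mean(all_fracs)) if all_fracs else 0.0,
        }
    )
    return pd.DataFrame(rows)
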