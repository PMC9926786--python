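"""End-to-end orchestration: simulate → call → classify → annotate → link.

A single flat YAML config drives a run; every stage output lands under
the output directory with a manifest, and a machine-readable JSON summary
echoes parameters and all counts.  Reruns at the same seed are identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog_compare import (
    CompareParams,
    classify_temporal,
    cross_regeneration,
    venn_summary,
)
from .deg_link import DEGParams, filter_degs, find_flip_genes, link_dmrs_to_degs, linked_counts
from .dmc_dmr import DMCParams, DMRCatalog, DMRParams, call_contrast
from .genome_annotation import (
    GeneMapParams,
    derive_region_tracks,
    hotspot_report,
    map_dmrs_to_genes,
)
from .io_tables import write_dmr_bed
from .synthetic_data import (
    default_config,
    score_flip_recovery,
    score_recovery,
    score_temporal_recovery,
    simulate_tables,
)

log = logging.getLogger(__name__)

AGING_CONTRASTS = ("A8:A2", "A16:A8")
REGEN_CONTRASTS = ("R1:R0", "R2:R0", "R4:R0")
DEFAULT_CONTRASTS = AGING_CONTRASTS + REGEN_CONTRASTS


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage; returns (and writes) the run summary dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    dmc_params = DMCParams(**config.get("dmc", {}))
    dmr_params = DMRParams(**config.get("dmr", {}))
    cmp_params = CompareParams(**config.get("compare", {}))
    map_params = GeneMapParams(**config.get("genemap", {}))
    deg_params = DEGParams(**config.get("deg", {}))
    contrasts = tuple(config.get("contrasts", DEFAULT_CONTRASTS))

    # --- stage: simulate ------------------------------------------------
    sim_kwargs = dict(config.get("sim", {}))
    sim_cfg = default_config(seed=seed, **sim_kwargs)
    sim = simulate_tables(sim_cfg)
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = ["truth.tsv"]

    # --- stage: DMC/DMR calling per contrast ----------------------------
    from .synthetic_data import CONTRASTS as CONTRAST_CONDS

    catalogs: dict[str, DMRCatalog] = {}
    dmr_counts: dict[str, dict[str, int]] = {}
    for label in contrasts:
        cond_a, cond_b = CONTRAST_CONDS[label]
        _, catalog = call_contrast(
            sim.samples[cond_a], sim.samples[cond_b], label, dmc_params, dmr_params
        )
        catalogs[label] = catalog
        fname = f"dmrs_{label.replace(':', '_')}.bed"
        write_dmr_bed(catalog, out / fname)
        manifest.append(fname)
        dmr_counts[label] = {
            "hyper": len(catalog.by_direction("hyper")),
            "hypo": len(catalog.by_direction("hypo")),
        }

    # --- stage: temporal aging classification ---------------------------
    temporal_counts: dict[str, int] = {}
    temporal_calls = []
    if all(c in catalogs for c in AGING_CONTRASTS):
        calls = classify_temporal(catalogs["A8:A2"], catalogs["A16:A8"], cmp_params)
        temporal_calls = calls
        tdf = pd.DataFrame(
            {
                "chrom": c.dmr.chrom,
                "start": c.dmr.start,
                "end": c.dmr.end,
                "direction": c.dmr.direction,
                "category": c.category,
                "n_partners": len(c.partner_ids),
            }
            for c in calls
        )
        tdf.to_csv(out / "temporal.tsv", sep="\t", index=False)
        manifest.append("temporal.tsv")
        temporal_counts = tdf["category"].value_counts().to_dict()

    # --- stage: aging x regeneration cross-classification ---------------
    cross_counts = {"synchronous": 0, "inverse": 0}
    cross_rows = []
    for regen_label in REGEN_CONTRASTS:
        if regen_label not in catalogs:
            continue
        for aging_label in AGING_CONTRASTS:
            if aging_label not in catalogs:
                continue
            for rec in cross_regeneration(
                catalogs[regen_label], catalogs[aging_label], cmp_params
            ):
                cross_counts[rec.relation] += 1
                cross_rows.append(
                    {
                        "regen_contrast": rec.regen_contrast,
                        "aging_contrast": rec.aging_contrast,
                        "regen_dmr": f"{rec.regen_dmr.chrom}:{rec.regen_dmr.start}-{rec.regen_dmr.end}",
                        "aging_dmr": f"{rec.aging_dmr.chrom}:{rec.aging_dmr.start}-{rec.aging_dmr.end}",
                        "relation": rec.relation,
                    }
                )
    pd.DataFrame(
        cross_rows,
        columns=["regen_contrast", "aging_contrast", "regen_dmr", "aging_dmr", "relation"],
    ).to_csv(out / "cross.tsv", sep="\t", index=False)
    manifest.append("cross.tsv")

    # --- stage: regeneration Venn per direction -------------------------
    venns: dict[str, dict] = {}
    if all(c in catalogs for c in REGEN_CONTRASTS):
        for direction in ("hyper", "hypo"):
            sub = [
                DMRCatalog(
                    contrast_label=lbl,
                    dmrs=list(catalogs[lbl].by_direction(direction)),
                )
                for lbl in REGEN_CONTRASTS
            ]
            vs = venn_summary(sub, cmp_params)
            venns[direction] = {
                "set_sizes": vs.set_sizes,
                "pair_intersections": {
                    "|".join(sorted(k)): v for k, v in vs.pair_intersections.items()
                },
                "triple_intersection": vs.triple_intersection,
                "union_size": vs.union_size,
                "exclusive_counts": {
                    "|".join(sorted(k)): v for k, v in vs.exclusive_counts.items()
                },
            }
        (out / "venn.json").write_text(json.dumps(venns, indent=2, sort_keys=True))
        manifest.append("venn.json")

    # --- stage: annotation ----------------------------------------------
    tracks = derive_region_tracks(
        sim.genes, sim.repeat_tracks, sim.cgi, sim.chrom_sizes
    )
    genemaps = {}
    for label, catalog in catalogs.items():
        rep = hotspot_report(catalog, tracks, cmp_params)
        fname = f"hotspot_{label.replace(':', '_')}.tsv"
        rep.df.to_csv(out / fname, sep="\t", index=False)
        manifest.append(fname)
        gmap = map_dmrs_to_genes(catalog, sim.genes, map_params, cmp_params)
        genemaps[label] = gmap
        fname = f"genemap_{label.replace(':', '_')}.tsv"
        gmap.df.to_csv(out / fname, sep="\t", index=False)
        manifest.append(fname)

    # --- stage: DEG linkage and flip genes ------------------------------
    degs = filter_degs(sim.degs, deg_params)
    link_summaries = {}
    for label in REGEN_CONTRASTS:
        if label not in genemaps:
            continue
        links = link_dmrs_to_degs(genemaps[label], degs, zone_filter="promoter")
        link_summaries[label] = linked_counts(links)
    flips = []
    if all(c in genemaps for c in AGING_CONTRASTS):
        flips = find_flip_genes(genemaps["A8:A2"], genemaps["A16:A8"], degs)
        pd.DataFrame(
            {
                "gene_id": f.gene_id,
                "deg_direction": f.deg_direction,
                "early_dmrs": ",".join(f.early_dmr_ids),
                "late_dmrs": ",".join(f.late_dmr_ids),
            }
            for f in flips
        ).to_csv(out / "flip_genes.tsv", sep="\t", index=False)
        manifest.append("flip_genes.tsv")

    # --- stage: planted-truth recovery ----------------------------------
    recovery = score_recovery(sim.truth, catalogs)
    recovery.to_csv(out / "recovery.tsv", sep="\t", index=False)
    manifest.append("recovery.tsv")

    summary = {
        "tool_version": __version__,
        "seed": seed,
        "params": {
            "dmc": asdict(dmc_params),
            "dmr": asdict(dmr_params),
            "compare": asdict(cmp_params),
            "genemap": asdict(map_params),
            "deg": asdict(deg_params),
        },
        "contrasts": list(contrasts),
        "dmr_counts": dmr_counts,
        "temporal_counts": temporal_counts,
        "cross_counts": cross_counts,
        "venn": venns,
        "deg_counts": {
            "up": sum(d.direction == "up" for d in degs),
            "down": sum(d.direction == "down" for d in degs),
            "ns": sum(d.direction == "ns" for d in degs),
        },
        "linked": link_summaries,
        "flip_genes": sorted(f.gene_id for f in flips),
        "recovery": recovery.to_dict(orient="records"),
        "temporal_recovery": score_temporal_recovery(sim.truth, temporal_calls),
        "flip_recovery": score_flip_recovery(sim.truth, flips),
        "manifest": sorted(manifest),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete: %d contrasts, outputs in %s", len(contrasts), out)
    return summary
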