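"""Hotspot track derivation, DMR genomic distribution, and gene mapping."""

import pytest

from regenmeth.catalog_compare import CompareParams
from regenmeth.dmc_dmr import DMRCatalog, DMRRecord
from regenmeth.genome_annotation import (
    GeneMapParams,
    derive_region_tracks,
    hotspot_report,
    map_dmrs_to_genes,
    promoter_window,
)
from regenmeth.io_tables import GeneModel, RegionTrack


def _gene(gene_id="g1", chrom="chr1", strand="+", tx=(10_000, 20_000),
          exons=((10_000, 11_000), (15_000, 20_000)), cds=None):
    starts = tuple(s for s, _ in exons)
    ends = tuple(e for _, e in exons)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tx_start=tx[0], tx_end=tx[1], exon_starts=starts, exon_ends=ends,
        cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None,
    )


def _dmr(start, end, direction="hyper", chrom="chr1"):
    delta = 0.3 if direction == "hyper" else -0.3
    return DMRRecord(chrom, start, end, direction, 3, delta, 0.01)


def _ivs(tracks, name):
    return tracks[name].intervals


class TestDeriveRegionTracks:
    def test_plus_gene_tss_windows(self):
        tracks = derive_region_tracks([_gene()])
        assert _ivs(tracks, "TSSup1k") == [("chr1", 9_000, 10_000)]
        assert _ivs(tracks, "TSSdn1k") == [("chr1", 10_000, 11_000)]
        assert _ivs(tracks, "Prom1k") == [("chr1", 9_000, 11_000)]
        assert _ivs(tracks, "TSS-7k") == [("chr1", 3_000, 10_000)]

    def test_minus_gene_upstream_is_rightward(self):
        tracks = derive_region_tracks([_gene(strand="-")])
        assert _ivs(tracks, "TSSup1k") == [("chr1", 20_000, 21_000)]
        assert _ivs(tracks, "TSSdn1k") == [("chr1", 19_000, 20_000)]
        assert _ivs(tracks, "TTSup1k") == [("chr1", 10_000, 11_000)]

    def test_strand_mirror_oracle(self):
        """Reflecting all coordinates about a point and flipping strand
        yields mirrored tracks."""
        L = 100_000
        plus = _gene(strand="+")
        minus = _gene(
            strand="-",
            tx=(L - 20_000, L - 10_000),
            exons=((L - 20_000, L - 15_000), (L - 11_000, L - 10_000)),
        )
        t_plus = derive_region_tracks([plus])
        t_minus = derive_region_tracks([minus])
        for name in ("TSSup1k", "TSSdn1k", "Prom1k", "TTS1k", "TSS-7k",
                     "1stExon", "Genf", "Gene", "Center30ct"):
            mirrored = sorted(
                ("chr1", L - e, L - s) for _, s, e in t_plus[name].intervals
            )
            assert mirrored == t_minus[name].intervals, name

    def test_window_clipped_at_chromosome_start(self):
        g = _gene(tx=(500, 2_000), exons=((500, 2_000),))
        tracks = derive_region_tracks([g], chrom_sizes={"chr1": 10_000})
        assert _ivs(tracks, "TSSup1k") == [("chr1", 0, 500)]
        assert _ivs(tracks, "TSS-7k") == [("chr1", 0, 500)]

    def test_single_exon_gene_genf_spans_exon_no_first_intron(self):
        g = _gene(tx=(1_000, 2_000), exons=((1_000, 2_000),))
        tracks = derive_region_tracks([g])
        assert _ivs(tracks, "Genf") == [("chr1", 1_000, 2_000)]
        assert _ivs(tracks, "1stIntron") == []

    def test_containment_invariants(self):
        g = _gene(cds=(10_400, 19_600))
        tracks = derive_region_tracks([g])

        def covered(inner, outer):
            return all(
                any(oc == ic and os <= s and e <= oe for oc, os, oe in outer)
                for ic, s, e in inner
            )

        assert covered(_ivs(tracks, "1stExon"), _ivs(tracks, "Exon"))
        assert covered(_ivs(tracks, "Exon"), _ivs(tracks, "Gene"))
        assert covered(_ivs(tracks, "Gene"), _ivs(tracks, "ExtGene"))
        assert covered(_ivs(tracks, "Genf"), _ivs(tracks, "Gene"))
        assert covered(_ivs(tracks, "FpUTR"), _ivs(tracks, "Exon"))
        # TSSup1k and TSSdn1k tile Prom1k exactly
        up, dn = _ivs(tracks, "TSSup1k")[0], _ivs(tracks, "TSSdn1k")[0]
        prom = _ivs(tracks, "Prom1k")[0]
        assert min(up[1], dn[1]) == prom[1] and max(up[2], dn[2]) == prom[2]

    def test_utrs_require_cds(self):
        tracks = derive_region_tracks([_gene()])
        assert _ivs(tracks, "FpUTR") == [] and _ivs(tracks, "TpUTR") == []
        with_cds = derive_region_tracks([_gene(cds=(10_400, 19_600))])
        assert _ivs(with_cds, "FpUTR") == [("chr1", 10_000, 10_400)]
        assert _ivs(with_cds, "TpUTR") == [("chr1", 19_600, 20_000)]


class TestHotspotReport:
    def test_multi_membership_and_percentages(self):
        tracks = derive_region_tracks(
            [_gene()],
            repeats=[RegionTrack("SINE", [("chr1", 15_100, 15_400)])],
        )
        catalog = DMRCatalog(
            contrast_label="A8:A2",
            dmrs=[
                _dmr(15_200, 15_300, "hyper"),  # in gene body and SINE
                _dmr(50_000, 50_100, "hypo"),
                _dmr(60_000, 60_100, "hypo"),
                _dmr(9_500, 9_600, "hypo"),  # promoter only
                _dmr(70_000, 70_100, "hypo"),
            ],
        )
        rep = hotspot_report(catalog, tracks)
        assert rep.count("hyper", "Gene") == 1
        assert rep.count("hyper", "SINE") == 1
        assert rep.count("hyper", "rmsk") == 1
        assert rep.percent("hyper", "Gene") == 100.0
        assert rep.percent("hypo", "Prom1k") == 25.0

    def test_empty_catalog_percent_defined_zero(self):
        tracks = derive_region_tracks([_gene()])
        rep = hotspot_report(DMRCatalog(contrast_label="x"), tracks)
        assert (rep.df["count"] == 0).all() and (rep.df["percent"] == 0).all()

    def test_matches_quadratic_overlap_oracle(self, rng):
        intervals = []
        for _ in range(30):
            s = int(rng.integers(0, 50_000))
            intervals.append(("chr1", s, s + int(rng.integers(50, 2_000))))
        track = RegionTrack("rmsk", intervals)
        dmrs = []
        for _ in range(40):
            s = int(rng.integers(0, 50_000))
            dmrs.append(_dmr(s, s + int(rng.integers(30, 500)),
                             "hyper" if rng.random() < 0.5 else "hypo"))
        catalog = DMRCatalog(contrast_label="x", dmrs=dmrs)
        rep = hotspot_report(catalog, {"rmsk": track})
        for direction in ("hyper", "hypo"):
            expected = sum(
                any(
                    c == d.chrom and min(e, d.end) - max(s, d.start) >= 1
                    for c, s, e in intervals
                )
                for d in catalog.by_direction(direction)
            )
            assert rep.count(direction, "rmsk") == expected

    def test_invariant_to_splitting_track_intervals(self):
        whole = {"t": RegionTrack("t", [("chr1", 100, 500)])}
        split = {"t": RegionTrack("t", [("chr1", 100, 300), ("chr1", 300, 500)])}
        catalog = DMRCatalog(contrast_label="x", dmrs=[_dmr(250, 350)])
        assert (
            hotspot_report(catalog, whole).count("hyper", "t")
            == hotspot_report(catalog, split).count("hyper", "t")
            == 1
        )


class TestMapDmrsToGenes:
    def test_promoter_window_boundaries_plus_strand(self):
        g = _gene()  # '+' TSS at 10_000; promoter = [3_000, 13_000)
        hit = map_dmrs_to_genes(
            DMRCatalog(contrast_label="x", dmrs=[_dmr(2_990, 3_100)]), [g]
        )
        assert set(hit.df.zone) == {"promoter"}
        miss = map_dmrs_to_genes(
            DMRCatalog(contrast_label="x", dmrs=[_dmr(2_900, 3_000)]), [g]
        )
        assert len(miss) == 0

    def test_minus_strand_promoter_around_tx_end(self):
        g = _gene(strand="-")  # TSS 20_000; promoter = [17_000, 27_000)
        hit = map_dmrs_to_genes(
            DMRCatalog(contrast_label="x", dmrs=[_dmr(26_900, 27_100)]), [g]
        )
        assert set(hit.df.zone) == {"promoter"}
        assert promoter_window(g) == (17_000, 27_000)

    def test_intronic_dmr_maps_to_gbody_only(self):
        g = _gene()  # intron [11_000, 15_000); promoter ends at 13_000
        res = map_dmrs_to_genes(
            DMRCatalog(contrast_label="x", dmrs=[_dmr(13_500, 13_600)]), [g]
        )
        assert list(res.df.zone) == ["gBody"]

    def test_pair_can_carry_both_zones(self):
        g = _gene()
        res = map_dmrs_to_genes(
            DMRCatalog(contrast_label="x", dmrs=[_dmr(12_000, 12_100)]), [g]
        )
        assert sorted(res.df.zone) == ["gBody", "promoter"]

    def test_rows_verified_by_direct_interval_arithmetic(self, rng):
        genes = [
            _gene(gene_id=f"g{i}", tx=(s, s + 5_000), exons=((s, s + 5_000),),
                  strand="+" if i % 2 == 0 else "-")
            for i, s in enumerate(range(10_000, 110_000, 20_000))
        ]
        dmrs = []
        for _ in range(50):
            s = int(rng.integers(0, 120_000))
            dmrs.append(_dmr(s, s + int(rng.integers(50, 800))))
        res = map_dmrs_to_genes(DMRCatalog(contrast_label="x", dmrs=dmrs), genes)
        params = GeneMapParams()
        expected = set()
        for g in genes:
            pw = promoter_window(g, params)
            for d in dmrs:
                did = f"{d.chrom}:{d.start}-{d.end}:{d.direction}"
                if min(pw[1], d.end) - max(pw[0], d.start) >= 1:
                    expected.add((g.gene_id, did, "promoter"))
                if min(g.tx_end, d.end) - max(g.tx_start, d.start) >= 1:
                    expected.add((g.gene_id, did, "gBody"))
        got = set(zip(res.df.gene_id, res.df.dmr_id, res.df.zone))
        assert got == expected
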