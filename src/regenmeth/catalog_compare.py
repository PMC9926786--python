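"""Cross-contrast DMR classification.

Three comparisons drive the biology here:

* **Temporal aging categories** — each DMR from the early aging contrast
  (8 vs 2 months) is classified against the late contrast (16 vs 8 months)
  as early-single, progressive (same-direction overlap), or inverse
  (opposite-direction overlap); late DMRs with no early partner are
  late-single.
* **Aging × regeneration cross-classification** — overlapping pairs of a
  regenerative and an aging DMR are labelled synchronous (same direction)
  or inverse (opposite), the headline signal that mid-to-late aging
  opposes the regenerative methylation program.
* **Three-way Venn accounting** — DMR sharing across the 1/2/4-day
  regeneration catalogs, counted over overlap-connected components so the
  three-set inclusion–exclusion identity holds exactly.

"Shared" always means an interval overlap of at least ``min_overlap_bp``
(default 1 bp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .dmc_dmr import DMRCatalog, DMRRecord

__all__ = [
    "CompareParams",
    "TemporalCall",
    "CrossRecord",
    "VennSummary",
    "overlaps",
    "classify_temporal",
    "cross_regeneration",
    "venn_summary",
    "build_venn_catalogs",
]

EARLY_SINGLE = "early_single"
LATE_SINGLE = "late_single"
PROGRESSIVE = "progressive"
INVERSE = "inverse"
SYNCHRONOUS = "synchronous"


@dataclass(frozen=True)
class CompareParams:
    min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")


@dataclass
class TemporalCall:
    dmr: DMRRecord
    category: str  # early_single | late_single | progressive | inverse
    partner_ids: list[int] = field(default_factory=list)  # indices in other catalog


@dataclass
class CrossRecord:
    regen_dmr: DMRRecord
    aging_dmr: DMRRecord
    regen_contrast: str
    aging_contrast: str
    relation: str  # synchronous | inverse


@dataclass
class VennSummary:
    labels: tuple[str, str, str]
    set_sizes: dict[str, int]
    pair_intersections: dict[frozenset, int]  # include triple members
    triple_intersection: int
    union_size: int
    exclusive_counts: dict[frozenset, int]  # counts per exact Venn cell

    def only_in(self, *labels: str) -> int:
        """Components found in exactly this label combination."""
        return self.exclusive_counts.get(frozenset(labels), 0)

    def in_any_of(self, *labels: str) -> int:
        """Components found in at least one of the given labels and no other."""
        want = set(labels)
        return sum(
            n for cell, n in self.exclusive_counts.items() if set(cell) <= want
        )

    def check_inclusion_exclusion(self) -> bool:
        total = (
            sum(self.set_sizes.values())
            - sum(self.pair_intersections.values())
            + self.triple_intersection
        )
        return total == self.union_size


def overlaps(a: DMRRecord, b: DMRRecord, params: CompareParams = CompareParams()) -> bool:
    """True iff a and b share >= min_overlap_bp on the same chromosome."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= params.min_overlap_bp


def _build_trees(catalog: DMRCatalog) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, dmr in enumerate(catalog.dmrs):
        trees.setdefault(dmr.chrom, IntervalTree()).addi(dmr.start, dmr.end, i)
    return trees


def _query(
    trees: dict[str, IntervalTree], dmr: DMRRecord, min_overlap: int
) -> list[int]:
    tree = trees.get(dmr.chrom)
    if tree is None:
        return []
    hits = []
    for iv in tree.overlap(dmr.start, dmr.end):
        if min(iv.end, dmr.end) - max(iv.begin, dmr.start) >= min_overlap:
            hits.append(iv.data)
    return sorted(hits)


def classify_temporal(
    early: DMRCatalog, late: DMRCatalog, params: CompareParams = CompareParams()
) -> list[TemporalCall]:
    """Classify aging DMRs into the four temporal categories.

    Every early DMR gets exactly one category (inverse takes precedence
    over progressive when partners of both directions exist); late DMRs
    overlapped by an early DMR are reported through the early DMR's
    partner list, so category counts partition |early| + |late-single|.
    """
    late_trees = _build_trees(late)
    calls: list[TemporalCall] = []
    partnered_late: set[int] = set()
    for dmr in early.dmrs:
        hits = _query(late_trees, dmr, params.min_overlap_bp)
        partnered_late.update(hits)
        if not hits:
            calls.append(TemporalCall(dmr=dmr, category=EARLY_SINGLE))
            continue
        dirs = {late.dmrs[i].direction for i in hits}
        if dirs - {dmr.direction}:
            category = INVERSE  # any opposite-direction partner wins
        else:
            category = PROGRESSIVE
        calls.append(TemporalCall(dmr=dmr, category=category, partner_ids=hits))
    for i, dmr in enumerate(late.dmrs):
        if i not in partnered_late:
            calls.append(TemporalCall(dmr=dmr, category=LATE_SINGLE))
    return calls


def cross_regeneration(
    regen: DMRCatalog, aging: DMRCatalog, params: CompareParams = CompareParams()
) -> list[CrossRecord]:
    """One record per overlapping (regenerative, aging) DMR pair.

    The relation depends only on direction equality: hyper/hyper and
    hypo/hypo pairs are synchronous, mixed pairs inverse.
    """
    aging_trees = _build_trees(aging)
    out: list[CrossRecord] = []
    for dmr in regen.dmrs:
        for i in _query(aging_trees, dmr, params.min_overlap_bp):
            partner = aging.dmrs[i]
            out.append(
                CrossRecord(
                    regen_dmr=dmr,
                    aging_dmr=partner,
                    regen_contrast=regen.contrast_label,
                    aging_contrast=aging.contrast_label,
                    relation=SYNCHRONOUS
                    if dmr.direction == partner.direction
                    else INVERSE,
                )
            )
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def venn_summary(
    catalogs: list[DMRCatalog], params: CompareParams = CompareParams()
) -> VennSummary:
    """Three-set Venn accounting over overlap-connected components.

    DMRs from the three catalogs (all one direction) are clustered into
    connected components by pairwise cross-catalog overlap; a component
    belongs to every catalog contributing a DMR to it.  Counting
    components (rather than raw records) makes the inclusion–exclusion
    identity exact even when one DMR overlaps several partners.
    """
    if len(catalogs) != 3:
        raise ValueError("venn_summary requires exactly three catalogs")
    directions = {d.direction for c in catalogs for d in c.dmrs}
    if len(directions) > 1:
        raise ValueError("catalogs must be single-direction and share it")
    labels = tuple(c.contrast_label for c in catalogs)
    if len(set(labels)) != 3:
        raise ValueError("catalog contrast labels must be distinct")

    entries: list[tuple[DMRRecord, str]] = []
    for cat in catalogs:
        for dmr in cat.dmrs:
            entries.append((dmr, cat.contrast_label))
    uf = _UnionFind(len(entries))
    trees: dict[str, IntervalTree] = {}
    for i, (dmr, _) in enumerate(entries):
        trees.setdefault(dmr.chrom, IntervalTree()).addi(dmr.start, dmr.end, i)
    for i, (dmr, label) in enumerate(entries):
        for iv in trees.get(dmr.chrom, IntervalTree()).overlap(dmr.start, dmr.end):
            j = iv.data
            if j <= i or entries[j][1] == label:
                continue
            if min(iv.end, dmr.end) - max(iv.begin, dmr.start) >= params.min_overlap_bp:
                uf.union(i, j)

    members: dict[int, set[str]] = {}
    for i, (_, label) in enumerate(entries):
        members.setdefault(uf.find(i), set()).add(label)

    cells: dict[frozenset, int] = {}
    for labelset in members.values():
        cells[frozenset(labelset)] = cells.get(frozenset(labelset), 0) + 1

    def in_label(lbl: str) -> int:
        return sum(n for cell, n in cells.items() if lbl in cell)

    set_sizes = {lbl: in_label(lbl) for lbl in labels}
    pair_intersections = {
        frozenset(p): sum(n for cell, n in cells.items() if set(p) <= cell)
        for p in itertools.combinations(labels, 2)
    }
    triple = cells.get(frozenset(labels), 0)
    union = sum(cells.values())
    return VennSummary(
        labels=labels,
        set_sizes=set_sizes,
        pair_intersections=pair_intersections,
        triple_intersection=triple,
        union_size=union,
        exclusive_counts=cells,
    )


def build_venn_catalogs(
    cell_counts: dict[frozenset, int],
    direction: str = "hyper",
    chrom: str = "chrV",
    spacing: int = 1000,
) -> list[DMRCatalog]:
    """Construct three catalogs realizing prescribed Venn cell counts.

    Each component of a cell gets its own disjoint coordinate block; every
    catalog named in the cell contributes one DMR overlapping the block.
    Useful for arithmetic checks of :func:`venn_summary` against published
    set sizes and intersections.
    """
    labels = sorted({lbl for cell in cell_counts for lbl in cell})
    if len(labels) != 3:
        raise ValueError("cell_counts must mention exactly three labels")
    per_label: dict[str, list[DMRRecord]] = {lbl: [] for lbl in labels}
    cursor = 1000
    for cell in sorted(cell_counts, key=lambda c: sorted(c)):
        for _ in range(cell_counts[cell]):
            for k, lbl in enumerate(sorted(cell)):
                # stagger member intervals so they overlap within the block
                per_label[lbl].append(
                    DMRRecord(
                        chrom=chrom,
                        start=cursor + 10 * k,
                        end=cursor + 100 + 10 * k,
                        direction=direction,
                        dmc_count=3,
                        mean_delta=0.3 if direction == "hyper" else -0.3,
                        min_p=0.01,
                    )
                )
            cursor += spacing
    return [DMRCatalog(contrast_label=lbl, dmrs=per_label[lbl]) for lbl in labels]
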