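"""Readers and writers for the on-disk formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open
``[start, end)``.  CpG count tables are read from 1-based TSV files
(bedGraph/CX-report style) and converted on input; report writers restore
1-based inclusive coordinates so printed ranges match genome-browser style.

Strand handling for CpG input follows symmetric-CpG pooling: a record on
the ``-`` strand refers to the paired cytosine one base left of the
``+``-strand cytosine of the same CpG dyad, so it is mapped to that
position and merged by summing counts.  One record per dyad results.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CpGCountTable",
    "GeneModel",
    "RegionTrack",
    "DEGTable",
    "ValidationError",
    "read_cpg_table",
    "read_gene_models",
    "read_region_track",
    "read_deg_table",
    "read_dmr_bed",
    "write_dmr_bed",
    "write_cpg_table",
]

CPG_COLUMNS = ("chrom", "pos", "strand", "meth", "total")


class ValidationError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass
class CpGCountTable:
    """Per-sample CpG methylation counts.

    ``df`` has columns chrom (str), pos (int, 0-based internal position of
    the +-strand cytosine), meth, total; sorted by (chrom, pos); one row
    per CpG dyad.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if (df["meth"] > df["total"]).any():
            bad = df[df["meth"] > df["total"]].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id}: meth > total at "
                f"{bad['chrom']}:{bad['pos'] + 1}"
            )
        if (df["meth"] < 0).any() or (df["total"] < 0).any():
            raise ValidationError(f"sample {self.sample_id}: negative count")
        if df.duplicated(["chrom", "pos"]).any():
            bad = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id}: duplicate CpG "
                f"{bad['chrom']}:{bad['pos'] + 1}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.df)


@dataclass
class GeneModel:
    """One gene model row (refFlat-like, 0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValidationError(f"gene {self.gene_id}: tx_start >= tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValidationError(
                f"gene {self.gene_id}: exonStarts/exonEnds length mismatch"
            )
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not s < e:
                raise ValidationError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside tx bounds"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons overlap/unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (the last coordinate for '-' genes)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)


@dataclass
class RegionTrack:
    """A named set of genomic intervals (repeat class, CGI, derived track)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValidationError(
                    f"track {self.name}: empty interval {chrom}:[{start},{end})"
                )
        self.intervals.sort()

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class DEGTable:
    """Gene-level differential expression input: gene_id, log2fc, p_raw[, q]."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df["gene_id"].duplicated().any():
            dup = df[df["gene_id"].duplicated()]["gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r} in DEG table")
        if df["p_raw"].isna().any():
            raise ValidationError("p_raw missing for some DEG rows")
        if ((df["p_raw"] < 0) | (df["p_raw"] > 1)).any():
            raise ValidationError("p_raw outside [0, 1]")
        if "q" in df.columns:
            q = df["q"].dropna()
            if ((q < 0) | (q > 1)).any():
                raise ValidationError("q outside [0, 1]")

    @property
    def has_q(self) -> bool:
        return "q" in self.df.columns and self.df["q"].notna().all()


def _read_tsv(path: str | Path, names: Sequence[str], dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=list(names),
            dtype=dtypes,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: malformed TSV: {exc}") from exc
    return df


def read_cpg_table(path: str | Path, sample_id: str) -> CpGCountTable:
    """Read a 5-column CpG count TSV (chrom, 1-based pos, strand, meth, total).

    Minus-strand records are folded onto the +-strand cytosine of the dyad
    (1-based pos − 1) and counts are summed.  Output is 0-based and sorted.
    """
    df = _read_tsv(path, CPG_COLUMNS, {"chrom": str, "strand": str})
    _validate_cpg_frame(df, path)
    # fold '-' records onto the + cytosine of the dyad, then 1-based -> 0-based
    pos1 = df["pos"].to_numpy(copy=True)
    minus = (df["strand"] == "-").to_numpy()
    pos1[minus] -= 1
    if (pos1 < 1).any():
        raise ValidationError(f"{path}: position < 1 after strand folding")
    out = pd.DataFrame(
        {"chrom": df["chrom"], "pos": pos1 - 1, "meth": df["meth"], "total": df["total"]}
    )
    out = (
        out.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    )
    # duplicates of the same (chrom, pos, strand) are an input error; dyad
    # merging above is the only legitimate source of repeated positions
    dup = df.assign(pos_folded=pos1).duplicated(["chrom", "pos_folded", "strand"])
    if dup.any():
        i = int(dup.idxmax())
        raise ValidationError(
            f"{path}: duplicate CpG record at line {i + 1} "
            f"({df['chrom'].iloc[i]}:{df['pos'].iloc[i]})"
        )
    return CpGCountTable(sample_id=sample_id, df=out)


def _validate_cpg_frame(df: pd.DataFrame, path) -> None:
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in ("+", "-", "."):
            raise ValidationError(f"{path}: line {line_no}: bad strand {row.strand!r}")
    for col in ("pos", "meth", "total"):
        try:
            df[col] = df[col].astype(int)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-integer {col}: {exc}") from exc
    if (df["pos"] < 1).any():
        i = int((df["pos"] < 1).idxmax())
        raise ValidationError(f"{path}: line {i + 1}: pos < 1")
    if (df["meth"] > df["total"]).any():
        i = int((df["meth"] > df["total"]).idxmax())
        raise ValidationError(f"{path}: line {i + 1}: meth > total")
    if (df["meth"] < 0).any() or (df["total"] < 0).any():
        raise ValidationError(f"{path}: negative count")


def write_cpg_table(table: CpGCountTable, path: str | Path) -> None:
    """Write a CpG count table as 1-based, +-strand TSV (inverse of read)."""
    df = table.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "strand": "+",
            "meth": df["meth"],
            "total": df["total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read refFlat-like gene TSV: gene_id, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds [, cdsStart, cdsEnd]; coordinates 0-based half-open,
    exon lists comma-separated."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (7, 9):
                raise ValidationError(
                    f"{path}: line {line_no}: expected 7 or 9 columns, got {len(parts)}"
                )
            try:
                starts = tuple(int(x) for x in parts[5].strip(",").split(",") if x)
                ends = tuple(int(x) for x in parts[6].strip(",").split(",") if x)
                cds_s = int(parts[7]) if len(parts) == 9 else None
                cds_e = int(parts[8]) if len(parts) == 9 else None
                gene = GeneModel(
                    gene_id=parts[0],
                    chrom=parts[1],
                    strand=parts[2],
                    tx_start=int(parts[3]),
                    tx_end=int(parts[4]),
                    exon_starts=starts,
                    exon_ends=ends,
                    cds_start=cds_s,
                    cds_end=cds_e,
                )
            except ValidationError:
                raise
            except ValueError as exc:
                raise ValidationError(f"{path}: line {line_no}: {exc}") from exc
            genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cols = [
                g.gene_id,
                g.chrom,
                g.strand,
                str(g.tx_start),
                str(g.tx_end),
                ",".join(map(str, g.exon_starts)),
                ",".join(map(str, g.exon_ends)),
            ]
            if g.cds_start is not None and g.cds_end is not None:
                cols += [str(g.cds_start), str(g.cds_end)]
            fh.write("\t".join(cols) + "\n")


def read_region_track(path: str | Path, name: str | None = None) -> RegionTrack:
    """Read a BED4 track; column 4 carries the track class name.

    If ``name`` is given, only rows of that class are kept (and the track
    takes that name); otherwise all rows must share one class.
    """
    intervals: list[tuple[str, int, int]] = []
    seen_names: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}: line {line_no}: expected >=4 columns")
            chrom, start_s, end_s, cls = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValidationError(f"{path}: line {line_no}: {exc}") from exc
            if name is not None and cls != name:
                continue
            seen_names.add(cls)
            intervals.append((chrom, start, end))
    if name is None:
        if len(seen_names) > 1:
            raise ValidationError(
                f"{path}: multiple track classes {sorted(seen_names)}; pass name="
            )
        name = next(iter(seen_names)) if seen_names else Path(path).stem
    return RegionTrack(name=name, intervals=intervals)


def read_deg_table(path: str | Path) -> DEGTable:
    """Read a DEG TSV: gene_id, log2fc, p_raw and optionally q.

    A header line starting with 'gene_id' is accepted and skipped.
    """
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("gene_id") else 0
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, skiprows=skip)
    if raw.shape[1] not in (3, 4):
        raise ValidationError(f"{path}: expected 3 or 4 columns, got {raw.shape[1]}")
    cols = ["gene_id", "log2fc", "p_raw"] + (["q"] if raw.shape[1] == 4 else [])
    raw.columns = cols
    raw["gene_id"] = raw["gene_id"].astype(str)
    for col in cols[1:]:
        raw[col] = pd.to_numeric(raw[col], errors="raise")
    return DEGTable(df=raw)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# -- DMR BED6+3 ---------------------------------------------------------------

def write_dmr_bed(catalog, path: str | Path) -> None:
    """Write a DMR catalog as BED6+3: chrom, start, end, contrast label,
    score = DMC count, strand '.', direction, mean delta, min p."""
    buf = io.StringIO()
    for dmr in sorted(catalog.dmrs, key=lambda d: (d.chrom, d.start, d.end, d.direction)):
        buf.write(
            "\t".join(
                [
                    dmr.chrom,
                    str(dmr.start),
                    str(dmr.end),
                    catalog.contrast_label,
                    str(dmr.dmc_count),
                    ".",
                    dmr.direction,
                    f"{dmr.mean_delta:.6g}",
                    f"{dmr.min_p:.6g}",
                ]
            )
            + "\n"
        )
    Path(path).write_text(buf.getvalue())


def read_dmr_bed(path: str | Path):
    """Read a BED6+3 DMR file back into a DMRCatalog (round-trip of
    :func:`write_dmr_bed`)."""
    from .dmc_dmr import DMRCatalog, DMRRecord  # local import, avoids cycle

    dmrs: list[DMRRecord] = []
    label: str | None = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path}: line {line_no}: expected 9 columns")
            chrom, start, end, name, score, _strand, direction, mean_d, min_p = parts
            if label is None:
                label = name
            elif name != label:
                raise ValidationError(
                    f"{path}: line {line_no}: mixed contrast labels {label!r}/{name!r}"
                )
            dmrs.append(
                DMRRecord(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    direction=direction,
                    dmc_count=int(score),
                    mean_delta=float(mean_d),
                    min_p=float(min_p),
                )
            )
    return DMRCatalog(contrast_label=label or Path(path).stem, dmrs=dmrs)


def validate_file(path: str | Path, kind: str, sample_id: str = "sample") -> str:
    """Validate one file of a given kind; returns a one-line summary.

    kind is one of cpg, genes, track, deg, dmr.
    """
    if kind == "cpg":
        t = read_cpg_table(path, sample_id)
        return f"{path}: OK cpg table, {t.n_sites} CpGs"
    if kind == "genes":
        genes = read_gene_models(path)
        return f"{path}: OK gene models, {len(genes)} rows"
    if kind == "track":
        tr = read_region_track(path)
        return f"{path}: OK region track '{tr.name}', {len(tr)} intervals"
    if kind == "deg":
        d = read_deg_table(path)
        return f"{path}: OK DEG table, {len(d.df)} genes"
    if kind == "dmr":
        c = read_dmr_bed(path)
        return f"{path}: OK DMR catalog '{c.contrast_label}', {len(c.dmrs)} DMRs"
    raise ValueError(f"unknown kind {kind!r}")
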