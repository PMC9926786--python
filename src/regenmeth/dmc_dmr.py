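"""Single-CpG differential methylation calls and sliding-window DMR assembly.

A DMC (differentially methylated cytosine) is a CpG whose pooled
methylation fraction differs between two condition groups by more than a
threshold (default |Δβ| > 0.2) with Fisher exact support (p < 0.05) at a
minimum per-group coverage (default 3 reads).  A DMR (differentially
methylated region) is assembled from ≥3 consecutive same-direction DMCs
whose positional span fits within a 300-bp window slid at 1-nt steps;
windows sharing a DMC merge transitively into one region.

Replicates are pooled (counts summed) before testing.  The optional
``credible`` statistic replaces the raw |Δβ| with the distance from zero
to the nearer endpoint of the central 95% posterior interval of
β_a − β_b under independent Jeffreys Beta posteriors (zero when the
interval spans zero), discounting sampling noise at low coverage; the
p-value is still the Fisher one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CpGCountTable

__all__ = [
    "DMCParams",
    "DMCRecord",
    "DMRParams",
    "DMRRecord",
    "DMRCatalog",
    "pool_group",
    "call_dmcs",
    "assemble_dmrs",
    "credible_difference",
]

log = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"


@dataclass(frozen=True)
class DMCParams:
    delta_threshold: float = 0.2
    p_threshold: float = 0.05
    min_coverage: int = 3
    statistic: str = "fisher"  # or "credible"

    def __post_init__(self) -> None:
        if not 0 < self.delta_threshold < 1:
            raise ValueError("delta_threshold must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.statistic not in ("fisher", "credible"):
            raise ValueError("statistic must be 'fisher' or 'credible'")


@dataclass(frozen=True)
class DMCRecord:
    chrom: str
    pos: int  # 0-based internal
    beta_a: float
    beta_b: float
    delta: float  # beta_a - beta_b
    p_value: float
    direction: str  # hyper | hypo

    def __post_init__(self) -> None:
        expected = HYPER if self.delta > 0 else HYPO
        if self.direction != expected:
            raise ValueError(f"direction {self.direction!r} inconsistent with delta")


@dataclass(frozen=True)
class DMRParams:
    window_bp: int = 300
    min_dmcs: int = 3
    step_nt: int = 1

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.min_dmcs < 2:
            raise ValueError("min_dmcs must be >= 2")


@dataclass(frozen=True)
class DMRRecord:
    chrom: str
    start: int  # 0-based
    end: int  # half-open; last member DMC position + 1
    direction: str
    dmc_count: int
    mean_delta: float
    min_p: float

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("DMR must span >= 1 bp")
        if self.direction not in (HYPER, HYPO):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class DMRCatalog:
    contrast_label: str
    dmrs: list[DMRRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dmrs.sort(key=lambda d: (d.chrom, d.start, d.end, d.direction))

    def by_direction(self, direction: str) -> list[DMRRecord]:
        return [d for d in self.dmrs if d.direction == direction]

    def __len__(self) -> int:
        return len(self.dmrs)

    def __iter__(self):
        return iter(self.dmrs)


def pool_group(tables: list[CpGCountTable]) -> pd.DataFrame:
    """Sum meth/total counts across replicate samples, per CpG.

    The coordinate universe is the union across samples; the pooled
    fraction at each CpG equals the coverage-weighted mean of the
    per-sample fractions.  Returns a DataFrame (chrom, pos, meth, total)
    sorted by (chrom, pos).
    """
    if not tables:
        raise ValueError("pool_group requires at least one sample")
    cat = pd.concat([t.df for t in tables], ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    )
    return pooled


def _fisher_pvalues(ma, ua, mb, ub) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables [[ma, ua], [mb, ub]] row-wise."""
    out = np.empty(len(ma))
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in range(len(ma)):
        key = (int(ma[i]), int(ua[i]), int(mb[i]), int(ub[i]))
        p = cache.get(key)
        if p is None:
            p = stats.fisher_exact(
                [[key[0], key[1]], [key[2], key[3]]], alternative="two-sided"
            )[1]
            cache[key] = p
        out[i] = p
    return out


def credible_difference(
    meth_a: int, total_a: int, meth_b: int, total_b: int, *,
    level: float = 0.95, grid: int = 512,
) -> float:
    """Credible (noise-discounted) methylation difference magnitude.

    The central ``level`` posterior interval of β_a − β_b is formed under
    independent Beta(meth + 1/2, unmeth + 1/2) (Jeffreys) posteriors; the
    statistic is the distance from zero to the nearer interval endpoint,
    or zero when the interval spans zero.  It never exceeds the raw
    |pooled delta| and shrinks toward zero at low coverage.  Computed
    deterministically from the product of ``grid`` posterior quantiles
    per group (no sampling).
    """
    u = (np.arange(grid) + 0.5) / grid
    qa = stats.beta.ppf(u, meth_a + 0.5, total_a - meth_a + 0.5)
    qb = stats.beta.ppf(u, meth_b + 0.5, total_b - meth_b + 0.5)
    diffs = (qa[:, None] - qb[None, :]).ravel()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    if lo <= 0.0 <= hi:
        return 0.0
    return float(min(abs(lo), abs(hi)))


def call_dmcs(
    group_a: pd.DataFrame, group_b: pd.DataFrame, params: DMCParams = DMCParams()
) -> list[DMCRecord]:
    """Call DMCs between pooled group A (test) and group B (reference).

    Only CpGs with total >= min_coverage in BOTH groups are tested.  A CpG
    is a DMC iff its effect statistic exceeds delta_threshold (strictly)
    and the two-sided Fisher exact p is strictly below p_threshold.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    for g in (group_a, group_b):
        if (g["meth"].to_numpy() < 0).any() or (g["total"].to_numpy() < 0).any():
            raise ValueError("negative counts")
    merged = group_a.merge(
        group_b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner"
    )
    covered = merged[
        (merged["total_a"] >= params.min_coverage)
        & (merged["total_b"] >= params.min_coverage)
    ]
    n_tested = len(covered)
    ta = covered["total_a"].to_numpy(float)
    tb = covered["total_b"].to_numpy(float)
    ma = covered["meth_a"].to_numpy(float)
    mb = covered["meth_b"].to_numpy(float)
    beta_a = ma / ta
    beta_b = mb / tb
    delta = beta_a - beta_b
    # Fisher p is only needed where the raw effect can still pass; for the
    # credible statistic the effect is never larger than |delta| so the
    # same pre-filter is valid.
    cand = np.abs(delta) > params.delta_threshold
    idx = np.flatnonzero(cand)
    pvals = np.ones(len(covered))
    if len(idx):
        pvals[idx] = _fisher_pvalues(
            ma[idx].astype(int),
            (ta[idx] - ma[idx]).astype(int),
            mb[idx].astype(int),
            (tb[idx] - mb[idx]).astype(int),
        )
    records: list[DMCRecord] = []
    chroms = covered["chrom"].to_numpy()
    poss = covered["pos"].to_numpy()
    for i in idx:
        effect = abs(delta[i])
        if params.statistic == "credible":
            effect = credible_difference(
                int(ma[i]), int(ta[i]), int(mb[i]), int(tb[i])
            )
        if effect > params.delta_threshold and pvals[i] < params.p_threshold:
            records.append(
                DMCRecord(
                    chrom=str(chroms[i]),
                    pos=int(poss[i]),
                    beta_a=float(beta_a[i]),
                    beta_b=float(beta_b[i]),
                    delta=float(delta[i]),
                    p_value=float(pvals[i]),
                    direction=HYPER if delta[i] > 0 else HYPO,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    log.info(
        "call_dmcs: %d sites tested, %d DMCs (%d hyper, %d hypo); "
        "p-values are raw (no multiplicity adjustment at the DMC stage)",
        n_tested,
        len(records),
        sum(r.direction == HYPER for r in records),
        sum(r.direction == HYPO for r in records),
    )
    return records


def _assemble_one(
    dmcs: list[DMCRecord], params: DMRParams
) -> list[DMRRecord]:
    """Assemble DMRs from one chromosome's same-direction, sorted DMC list.

    A seed is any run of ``min_dmcs`` consecutive DMCs whose span
    (last.pos − first.pos) is <= window_bp (inclusive).  Seeds sharing a
    DMC merge transitively; each merged component becomes one DMR.
    """
    k = params.min_dmcs
    n = len(dmcs)
    if n < k:
        return []
    pos = np.array([d.pos for d in dmcs])
    out: list[DMRRecord] = []
    comp_start = comp_end = None  # index range of current merged component
    for i in range(n - k + 1):
        if pos[i + k - 1] - pos[i] <= params.window_bp:
            if comp_end is not None and i <= comp_end:
                comp_end = i + k - 1  # shares a DMC with the open component
            else:
                if comp_start is not None:
                    out.append(_make_dmr(dmcs[comp_start : comp_end + 1]))
                comp_start, comp_end = i, i + k - 1
    if comp_start is not None:
        out.append(_make_dmr(dmcs[comp_start : comp_end + 1]))
    return out


def _make_dmr(members: list[DMCRecord]) -> DMRRecord:
    return DMRRecord(
        chrom=members[0].chrom,
        start=members[0].pos,
        end=members[-1].pos + 1,
        direction=members[0].direction,
        dmc_count=len(members),
        mean_delta=float(np.mean([m.delta for m in members])),
        min_p=float(min(m.p_value for m in members)),
    )


def assemble_dmrs(
    dmcs: list[DMCRecord],
    params: DMRParams = DMRParams(),
    contrast_label: str = "",
) -> DMRCatalog:
    """Assemble a DMR catalog from a sorted DMC list.

    Hyper- and hypo-DMCs are processed independently: an intervening
    opposite-direction DMC does not break a run.  Raises on unsorted input.
    """
    for prev, cur in zip(dmcs, dmcs[1:]):
        if (cur.chrom, cur.pos) < (prev.chrom, prev.pos):
            raise ValueError("DMC list must be sorted by (chrom, pos)")
    dmrs: list[DMRRecord] = []
    for direction in (HYPER, HYPO):
        subset = [d for d in dmcs if d.direction == direction]
        by_chrom: dict[str, list[DMCRecord]] = {}
        for d in subset:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom_dmcs in by_chrom.values():
            dmrs.extend(_assemble_one(chrom_dmcs, params))
    return DMRCatalog(contrast_label=contrast_label, dmrs=dmrs)


def call_contrast(
    samples_a: list[CpGCountTable],
    samples_b: list[CpGCountTable],
    contrast_label: str,
    dmc_params: DMCParams = DMCParams(),
    dmr_params: DMRParams = DMRParams(),
) -> tuple[list[DMCRecord], DMRCatalog]:
    """Pool each group, call DMCs, assemble DMRs — one contrast end to end."""
    pooled_a = pool_group(samples_a)
    pooled_b = pool_group(samples_b)
    dmcs = call_dmcs(pooled_a, pooled_b, dmc_params)
    catalog = assemble_dmrs(dmcs, dmr_params, contrast_label=contrast_label)
    log.info(
        "contrast %s: %d DMRs (%d hyper, %d hypo)",
        contrast_label,
        len(catalog),
        len(catalog.by_direction(HYPER)),
        len(catalog.by_direction(HYPO)),
    )
    return dmcs, catalog
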