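"""DMC calling and sliding-window DMR assembly, checked against
independent enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from regenmeth.dmc_dmr import (
    DMCParams,
    DMCRecord,
    DMRParams,
    assemble_dmrs,
    call_dmcs,
    credible_difference,
    pool_group,
)
from regenmeth.io_tables import CpGCountTable


def _pooled(records):
    """records: list of (chrom, pos, meth, total)"""
    return pd.DataFrame(records, columns=["chrom", "pos", "meth", "total"])


def _table(sample_id, records):
    return CpGCountTable(sample_id=sample_id, df=_pooled(records))


def _dmc(pos, direction, chrom="chr1", p=0.001):
    delta = 0.4 if direction == "hyper" else -0.4
    beta_a = 0.7 if direction == "hyper" else 0.3
    return DMCRecord(chrom, pos, beta_a, beta_a - delta, delta, p, direction)


# ---------------------------------------------------------------- pooling

class TestPoolGroup:
    def test_counts_sum_across_samples(self):
        a = _table("s1", [("chr1", 999, 5, 10)])
        b = _table("s2", [("chr1", 999, 4, 10)])
        pooled = pool_group([a, b])
        assert (pooled.iloc[0].meth, pooled.iloc[0].total) == (9, 20)

    def test_union_of_coordinates(self):
        a = _table("s1", [("chr1", 10, 1, 5)])
        b = _table("s2", [("chr1", 20, 2, 6)])
        pooled = pool_group([a, b])
        assert list(pooled.pos) == [10, 20]
        assert list(pooled.total) == [5, 6]

    def test_pooled_fraction_is_coverage_weighted_mean(self, rng):
        tables = []
        positions = np.sort(rng.choice(10_000, size=50, replace=False))
        for s in range(3):
            total = rng.integers(1, 30, size=50)
            meth = rng.binomial(total, 0.4)
            tables.append(
                _table(f"s{s}", [("chr1", int(p), int(m), int(t))
                                 for p, m, t in zip(positions, meth, total)])
            )
        pooled = pool_group(tables)
        for i, pos in enumerate(positions):
            fracs, weights = [], []
            for t in tables:
                row = t.df[t.df.pos == pos].iloc[0]
                fracs.append(row.meth / row.total)
                weights.append(row.total)
            expected = np.average(fracs, weights=weights)
            got = pooled.iloc[i].meth / pooled.iloc[i].total
            assert got == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pool_group([])


# ---------------------------------------------------------------- DMC calls

def _hypergeom_two_sided(ma, ua, mb, ub):
    """Oracle: full enumeration of the 2x2 margin distribution."""
    n1, n2 = ma + ua, mb + ub
    k = ma + mb
    lo, hi = max(0, k - n2), min(n1, k)
    pmf = {x: stats.hypergeom.pmf(x, n1 + n2, k, n1) for x in range(lo, hi + 1)}
    p_obs = pmf[ma]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestCallDmcs:
    def test_matches_exact_hypergeometric_oracle(self):
        a = _pooled([("chr1", 100, 19, 20)])
        b = _pooled([("chr1", 100, 5, 20)])
        (rec,) = call_dmcs(a, b)
        assert rec.direction == "hyper"
        assert rec.delta == pytest.approx(0.70)
        assert rec.p_value == pytest.approx(_hypergeom_two_sided(19, 1, 5, 15), rel=1e-8)

    def test_equal_fractions_not_called(self):
        a = _pooled([("chr1", 100, 10, 20)])
        b = _pooled([("chr1", 100, 10, 20)])
        assert call_dmcs(a, b) == []

    def test_delta_threshold_is_strict(self):
        # delta exactly 0.2 must not pass, however small the p-value
        a = _pooled([("chr1", 100, 120, 200)])
        b = _pooled([("chr1", 100, 80, 200)])
        assert abs(120 / 200 - 80 / 200) == pytest.approx(0.2)
        assert call_dmcs(a, b) == []

    def test_low_coverage_site_not_tested(self):
        a = _pooled([("chr1", 100, 2, 2)])
        b = _pooled([("chr1", 100, 0, 2)])
        assert call_dmcs(a, b, DMCParams(min_coverage=3)) == []

    def test_raising_delta_threshold_never_adds_dmcs(self, rng):
        n = 200
        pos = np.arange(n) * 10
        a = _pooled([("chr1", int(p), int(m), 30)
                     for p, m in zip(pos, rng.binomial(30, 0.6, n))])
        b = _pooled([("chr1", int(p), int(m), 30)
                     for p, m in zip(pos, rng.binomial(30, 0.4, n))])
        counts = [
            len(call_dmcs(a, b, DMCParams(delta_threshold=t)))
            for t in (0.1, 0.2, 0.3, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCredibleDifference:
    @given(
        st.integers(min_value=3, max_value=60).flatmap(
            lambda ta: st.tuples(
                st.just(ta),
                st.integers(min_value=0, max_value=ta),
                st.integers(min_value=3, max_value=60),
            )
        ).flatmap(
            lambda x: st.tuples(
                st.just(x[0]), st.just(x[1]), st.just(x[2]),
                st.integers(min_value=0, max_value=x[2]),
            )
        )
    )
    def test_never_exceeds_pooled_delta(self, counts):
        ta, ma, tb, mb = counts
        cred = credible_difference(ma, ta, mb, tb)
        delta = abs(ma / ta - mb / tb)
        assert cred <= delta + 1e-9

    def test_shrinks_low_coverage_effect(self):
        # same fractions, very different coverage: the credible effect is
        # heavily discounted at 4 reads but close to raw at 400 reads
        low = credible_difference(3, 4, 1, 4)
        high = credible_difference(300, 400, 100, 400)
        assert low < 0.1 < 0.40 < high <= 0.5

    def test_credible_statistic_filters_noisy_site(self):
        a = _pooled([("chr1", 100, 4, 5)])
        b = _pooled([("chr1", 100, 2, 5)])
        fisher_called = call_dmcs(a, b, DMCParams(statistic="fisher"))
        credible_called = call_dmcs(a, b, DMCParams(statistic="credible"))
        # raw delta 0.4 passes the effect cutoff; the posterior bound does not
        assert len(fisher_called) <= 1
        assert credible_called == []


# ---------------------------------------------------------------- DMR assembly

def brute_force_dmrs(positions, window=300, min_dmcs=3):
    """Oracle: enumerate every window [s, s+window] at 1-nt steps, mark
    windows holding >= min_dmcs DMCs, union marked sets into components."""
    import networkx as nx

    positions = sorted(positions)
    if not positions:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    marked_any = set()
    for s in range(positions[0] - window, positions[-1] + 1):
        members = [i for i, p in enumerate(positions) if s <= p <= s + window]
        if len(members) >= min_dmcs:
            marked_any.update(members)
            for i, j in zip(members, members[1:]):
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if comp[0] in marked_any:
            out.append((positions[comp[0]], positions[comp[-1]] + 1, len(comp)))
    return sorted(out)


class TestAssembleDmrs:
    def test_minimal_three_dmc_region(self):
        dmcs = [_dmc(p, "hyper") for p in (100, 200, 300)]
        cat = assemble_dmrs(dmcs)
        (dmr,) = cat.dmrs
        assert (dmr.start, dmr.end, dmr.dmc_count) == (100, 301, 3)

    def test_two_dmcs_insufficient(self):
        assert len(assemble_dmrs([_dmc(100, "hyper"), _dmc(200, "hyper")])) == 0

    def test_chain_merge_of_overlapping_windows(self):
        dmcs = [_dmc(p, "hyper") for p in (100, 200, 350, 500, 650)]
        cat = assemble_dmrs(dmcs)
        (dmr,) = cat.dmrs
        assert (dmr.start, dmr.end, dmr.dmc_count) == (100, 651, 5)
        assert brute_force_dmrs([100, 200, 350, 500, 650]) == [(100, 651, 5)]

    def test_directions_processed_independently(self):
        dmcs = sorted(
            [_dmc(p, "hyper") for p in (100, 200, 300)]
            + [_dmc(p, "hypo") for p in (150, 250, 290)],
            key=lambda d: d.pos,
        )
        cat = assemble_dmrs(dmcs)
        assert {(d.direction, d.start, d.end) for d in cat.dmrs} == {
            ("hyper", 100, 301),
            ("hypo", 150, 291),
        }

    def test_span_boundary_inclusive(self):
        # span exactly window_bp qualifies; window_bp + 1 does not
        assert len(assemble_dmrs([_dmc(p, "hyper") for p in (0, 150, 300)])) == 1
        assert len(assemble_dmrs([_dmc(p, "hyper") for p in (0, 150, 301)])) == 0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            assemble_dmrs([_dmc(200, "hyper"), _dmc(100, "hyper")])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(0, 60))
            positions = np.sort(rng.choice(2500, size=n, replace=False))
            dmcs = [_dmc(int(p), "hyper") for p in positions]
            got = sorted((d.start, d.end, d.dmc_count) for d in assemble_dmrs(dmcs))
            assert got == brute_force_dmrs([int(p) for p in positions])

    def test_widening_window_never_uncovers_dmcs(self, rng):
        positions = np.sort(rng.choice(3000, size=50, replace=False))
        dmcs = [_dmc(int(p), "hyper") for p in positions]
        covered = [
            sum(d.dmc_count for d in assemble_dmrs(dmcs, DMRParams(window_bp=w)).dmrs)
            for w in (100, 200, 300, 500)
        ]
        assert covered == sorted(covered)
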