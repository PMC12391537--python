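"""Junction parsing, filtering, clustering and usage-ratio arithmetic."""

import numpy as np
import pandas as pd
import pytest

from spliceqtl.junctions import (
    JunctionTable,
    cluster_introns,
    compute_iur,
    filter_junctions,
    read_junc,
    write_junc,
)

from conftest import make_table


def brute_force_clusters(table, min_cluster_reads=50, min_intron_frac=0.001):
    """Independent O(n^2) reference: pairwise adjacency + BFS components,
    with the same iterative low-fraction refinement and final filters."""
    totals = table.counts.sum(axis=1)
    meta = table.meta.copy()

    def strand_key(s):
        return s if s in ("+", "-") else "?"

    def components(ids):
        ids = list(ids)
        adj = {i: set() for i in ids}
        for a in ids:
            for b in ids:
                if a >= b:
                    continue
                ra, rb = meta.loc[a], meta.loc[b]
                if ra["chrom"] != rb["chrom"]:
                    continue
                if strand_key(ra["strand"]) != strand_key(rb["strand"]):
                    continue
                if ra["start"] == rb["start"] or ra["end"] == rb["end"]:
                    adj[a].add(b)
                    adj[b].add(a)
        seen, comps = set(), []
        for i in ids:
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(sorted(comp))
        return comps

    alive = list(meta.index)
    while True:
        drop = []
        for comp in components(alive):
            tot = totals.loc[comp].sum()
            if tot <= 0:
                drop.extend(comp)
                continue
            drop.extend(j for j in comp if totals.loc[j] / tot < min_intron_frac)
        if not drop:
            break
        alive = [j for j in alive if j not in set(drop)]
    out = []
    for comp in components(alive):
        if len(comp) >= 2 and totals.loc[comp].sum() >= min_cluster_reads:
            out.append(frozenset(comp))
    return set(out)


class TestReadJunc:
    def test_intron_coordinates_from_block_sizes(self, tmp_path):
        # record spanning [100, 300) with anchors 20 and 30 -> intron [120, 270)
        line = "chr1\t100\t300\tJ1\t7\t+\t100\t300\t255,0,0\t2\t20,30\t0,170\n"
        p = tmp_path / "a.junc"
        p.write_text(line)
        tab = read_junc(p, sample="s1")
        (jid,) = tab.meta.index
        assert tab.meta.loc[jid, "start"] == 120
        assert tab.meta.loc[jid, "end"] == 270
        assert tab.counts.loc[jid, "s1"] == 7
        assert tab.meta.loc[jid, "anchor_len"] == 20

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.junc"
        p.write_text("")
        tab = read_junc(p, sample="s1")
        assert len(tab.meta) == 0

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t100\t300\tJ\t-3\t+\t.\t.\t.\t2\t20,30\t0,170\n",  # negative score
            "chr1\t100\t300\tJ\t5\t+\t.\t.\t.\t2\n",  # too few fields
            "chr1\tX\t300\tJ\t5\t+\t.\t.\t.\t2\t20,30\t0,170\n",  # non-numeric
        ],
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.junc"
        p.write_text(line)
        with pytest.raises(ValueError, match=":1"):
            read_junc(p)

    def test_variant_ambiguous_flag_column_drops_record(self, tmp_path):
        lines = (
            "chr1\t100\t300\tJ1\t7\t+\t.\t.\t.\t2\t20,30\t0,170\t1\n"
            "chr1\t100\t400\tJ2\t9\t+\t.\t.\t.\t2\t20,30\t0,270\t0\n"
        )
        p = tmp_path / "w.junc"
        p.write_text(lines)
        tab = read_junc(p, sample="s1")
        assert list(tab.counts["s1"]) == [9]

    def test_roundtrip_through_writer(self, tmp_path):
        tab = make_table([("chr1", 120, 270, "+", (7,)), ("chr1", 120, 500, "+", (3,))])
        p = tmp_path / "rt.junc"
        write_junc(tab, p, "s1")
        back = read_junc(p, sample="s1")
        assert set(back.meta.index) == set(tab.meta.index)
        assert back.counts["s1"].to_dict() == tab.counts["s1"].to_dict()


class TestFilterJunctions:
    @pytest.mark.parametrize("length,kept", [(49, False), (50, True), (500_000, True), (500_001, False)])
    def test_length_bounds_inclusive(self, length, kept):
        tab = make_table([("chr1", 1000, 1000 + length, "+", (10,))])
        out = filter_junctions(tab)
        assert (len(out.meta) == 1) == kept

    def test_anchor_filter(self):
        tab = make_table([("chr1", 100, 200, "+", (10,))])
        tab.meta.loc[:, "anchor_len"] = 7
        assert len(filter_junctions(tab).meta) == 0

    def test_within_bounds_unchanged(self):
        tab = make_table([("chr1", 100, 200, "+", (1,)), ("chr1", 100, 300, "+", (2,))])
        out = filter_junctions(tab)
        pd.testing.assert_frame_equal(out.meta, tab.meta)


class TestClusterIntrons:
    def test_shared_start_forms_cluster(self):
        tab = make_table([("c", 100, 200, "+", (30,)), ("c", 100, 300, "+", (30,))])
        cs = cluster_introns(tab)
        assert len(cs) == 1
        assert cs.totals[next(iter(cs.members))] == 60

    def test_transitive_chain_single_cluster(self):
        # A shares start with B; B shares end with C; A and C share nothing
        tab = make_table(
            [("c", 100, 200, "+", (30,)), ("c", 100, 300, "+", (30,)), ("c", 150, 300, "+", (30,))]
        )
        cs = cluster_introns(tab)
        assert len(cs) == 1
        assert len(next(iter(cs.members.values()))) == 3

    def test_lone_intron_discarded(self):
        tab = make_table([("c", 100, 200, "+", (1000,))])
        assert len(cluster_introns(tab)) == 0

    def test_low_total_cluster_discarded(self):
        tab = make_table([("c", 100, 200, "+", (20,)), ("c", 100, 300, "+", (20,))])
        assert len(cluster_introns(tab, min_cluster_reads=50)) == 0

    def test_low_fraction_intron_refined_away(self):
        tab = make_table(
            [("c", 100, 200, "+", (5000,)), ("c", 100, 300, "+", (5000,)), ("c", 300, 400, "-", (0,)),
             ("c", 100, 400, "+", (2,))]
        )
        cs = cluster_introns(tab, min_intron_frac=0.01)
        members = next(iter(cs.members.values()))
        assert len(members) == 2
        assert all("400" not in m for m in members)

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 30))
            rows = []
            for _i in range(n):
                start = int(rng.choice([100, 150, 200, 250, 300]))
                end = start + int(rng.choice([60, 110, 160, 210]))
                rows.append(("c", start, end, "+", (int(rng.integers(0, 120)),)))
            tab = make_table(list(dict.fromkeys(rows)))
            got = {frozenset(v) for v in cluster_introns(tab, 50, 0.01).members.values()}
            want = brute_force_clusters(tab, 50, 0.01)
            assert got == want


class TestComputeIur:
    def test_simple_ratios(self):
        tab = make_table([("c", 100, 200, "+", (2,)), ("c", 100, 300, "+", (3,)), ("c", 100, 400, "+", (5,))])
        cs = cluster_introns(tab, min_cluster_reads=5)
        usage = compute_iur(cs, tab)
        assert sorted(usage.values["s1"].round(6)) == [0.2, 0.3, 0.5]

    def test_zero_total_sample_missing(self):
        tab = make_table(
            [("c", 100, 200, "+", (30, 0)), ("c", 100, 300, "+", (30, 0))], samples=("s1", "s2")
        )
        usage = compute_iur(cluster_introns(tab), tab)
        assert usage.values["s2"].isna().all()
        assert not usage.values["s1"].isna().any()

    def test_cluster_rows_sum_to_one(self, tiny_normalized):
        raw = tiny_normalized["raw"]
        sums = raw.values.groupby(raw.cluster_of).sum()
        obs = sums.to_numpy()
        assert np.allclose(obs[~np.isnan(obs)], 1.0, atol=1e-9)

    def test_order_invariance(self):
        tab = make_table([("c", 100, 200, "+", (2,)), ("c", 100, 300, "+", (8,))])
        cs = cluster_introns(tab, min_cluster_reads=5)
        u1 = compute_iur(cs, tab)
        flipped = JunctionTable(meta=tab.meta.iloc[::-1], counts=tab.counts.iloc[::-1])
        u2 = compute_iur(cluster_introns(flipped, min_cluster_reads=5), flipped)
        assert u1.values.sort_index().equals(u2.values.sort_index())
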