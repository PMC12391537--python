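"""Split-read junction handling: parsing, filtering, intron-excision clustering
and intron usage ratios.

A *junction* is an intron observed through reads aligned across it.  Junction
files follow the regtools ``.junc`` dialect of BED12: the record spans the two
anchoring read segments, so the intron itself is ``[chromStart + blockSizes[0],
chromEnd - blockSizes[-1])`` in 0-based half-open coordinates, and the BED
``score`` column carries the split-read count.

Junctions sharing a splice site (a start or an end coordinate, on the same
chromosome and compatible strand) are grouped into *intron clusters* by graph
connectivity, and the usage ratio of intron k in its cluster is

    R_k = X_k / sum_i X_i

where X_i are the split-read counts of the cluster's introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "JunctionTable",
    "IntronClusterSet",
    "UsageMatrix",
    "read_junc",
    "read_junc_files",
    "filter_junctions",
    "cluster_introns",
    "compute_iur",
]


def junction_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}:{end}:{strand}"


@dataclass
class JunctionTable:
    """Per-sample split-read counts keyed by (chrom, start, end, strand).

    ``meta`` is indexed by junction id with columns chrom, start, end, strand,
    anchor_len; ``counts`` shares the index and has one integer column per
    sample.  ``start``/``end`` are 0-based half-open intron coordinates.
    """

    meta: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.counts.index):
            raise ValueError("meta and counts must share a junction index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative junction counts")
        bad = self.meta["end"] <= self.meta["start"]
        if bad.any():
            raise ValueError(f"junctions with end <= start: {list(self.meta.index[bad])}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lengths(self) -> pd.Series:
        return self.meta["end"] - self.meta["start"]

    def total_counts(self) -> pd.Series:
        """Split-read count per junction summed across samples."""
        return self.counts.sum(axis=1)

    def merge(self, other: "JunctionTable") -> "JunctionTable":
        """Outer-join two tables (union of junctions and of samples)."""
        meta = pd.concat([self.meta, other.meta[~other.meta.index.isin(self.meta.index)]])
        counts = (
            self.counts.reindex(meta.index)
            .combine_first(other.counts.reindex(meta.index))
            .fillna(0.0)
        )
        counts = counts.reindex(meta.index).astype(np.int64)
        return JunctionTable(meta=meta, counts=counts)

    @staticmethod
    def empty(samples: list[str] | None = None) -> "JunctionTable":
        meta = pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str),
             "anchor_len": pd.Series(dtype=np.int64)}
        )
        counts = pd.DataFrame(index=meta.index, columns=samples or [], dtype=np.int64)
        return JunctionTable(meta=meta, counts=counts)


@dataclass
class IntronClusterSet:
    """Connected groups of junctions sharing splice sites.

    ``members`` maps cluster id (``chrom:index:strand``) to the junction ids in
    the cluster; ``totals`` carries each cluster's split-read total across
    samples (the usage-ratio denominator summed over samples).
    """

    members: dict[str, list[str]]
    totals: dict[str, int]

    def cluster_of(self) -> pd.Series:
        pairs = [(j, c) for c, js in self.members.items() for j in js]
        return pd.Series({j: c for j, c in pairs}, name="cluster_id")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class UsageMatrix:
    """Intron usage ratios (introns x samples) with cluster membership.

    ``stage`` is ``"raw"`` (ratios in [0, 1], NaN where the cluster total is
    zero in a sample) or ``"normalized"`` (after quantile normalisation and
    rank-based inverse normal transform).
    """

    values: pd.DataFrame
    cluster_of: pd.Series
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = self.values.index.difference(self.cluster_of.index)
        if len(missing):
            raise ValueError(f"introns without cluster assignment: {list(missing)[:3]}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "cluster_id", self.cluster_of.reindex(out.index))
        out.index.name = "intron_id"
        with open(path, "w") as fh:
            fh.write(f"# spliceqtl usage matrix stage={self.stage}\n")
            out.to_csv(fh, sep="\t")

    @staticmethod
    def from_tsv(path) -> "UsageMatrix":
        with open(path) as fh:
            header = fh.readline()
            stage = "raw"
            if header.startswith("#"):
                for tok in header.split():
                    if tok.startswith("stage="):
                        stage = tok.split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        cluster_of = df.pop("cluster_id")
        return UsageMatrix(values=df, cluster_of=cluster_of, stage=stage)


# ---------------------------------------------------------------------------
# Parsing


def _parse_junc_line(line: str, lineno: int, path: str) -> tuple:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"{path}:{lineno}: expected >=12 BED12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        chrom_end = int(fields[2])
        score = int(float(fields[4]))
        strand = fields[5] if fields[5] in ("+", "-") else "?"
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from exc
    if score < 0:
        raise ValueError(f"{path}:{lineno}: negative score {score}")
    if len(block_sizes) < 2:
        raise ValueError(f"{path}:{lineno}: junction needs >=2 blocks")
    start = chrom_start + block_sizes[0]
    end = chrom_end - block_sizes[-1]
    if end <= start:
        raise ValueError(f"{path}:{lineno}: inferred intron empty ({start}, {end})")
    anchor = min(block_sizes[0], block_sizes[-1])
    flagged = len(fields) > 12 and fields[12] not in ("", "0", ".", "False", "false")
    return chrom, start, end, strand, score, anchor, flagged


def read_junc(path, sample: str | None = None) -> JunctionTable:
    """Read one regtools-style ``.junc`` file into a single-sample table.

    Junction coordinates are converted from the BED12 record span to intron
    coordinates (chromStart + first block size, chromEnd - last block size).
    Records carrying a truthy 13th column (variant-ambiguous mapping flag) are
    dropped.  Duplicate introns have their counts summed; the anchor length
    kept is the maximum observed.
    """
    sample = sample if sample is not None else str(path)
    rows: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, strand, score, anchor, flagged = _parse_junc_line(
                line, lineno, str(path)
            )
            if flagged:
                continue
            jid = junction_id(chrom, start, end, strand)
            if jid in rows:
                rows[jid][4] += score
                rows[jid][5] = max(rows[jid][5], anchor)
            else:
                rows[jid] = [chrom, start, end, strand, score, anchor]
    if not rows:
        return JunctionTable.empty(samples=[sample])
    meta = pd.DataFrame(
        {jid: r[:4] + [r[5]] for jid, r in rows.items()},
        index=["chrom", "start", "end", "strand", "anchor_len"],
    ).T
    meta["start"] = meta["start"].astype(np.int64)
    meta["end"] = meta["end"].astype(np.int64)
    meta["anchor_len"] = meta["anchor_len"].astype(np.int64)
    counts = pd.DataFrame({sample: {jid: r[4] for jid, r in rows.items()}}, dtype=np.int64)
    counts = counts.reindex(meta.index)
    return JunctionTable(meta=meta, counts=counts)


def read_junc_files(paths: dict[str, str]) -> JunctionTable:
    """Read several per-sample ``.junc`` files into one multi-sample table."""
    tables = [read_junc(p, sample=s) for s, p in paths.items()]
    if not tables:
        return JunctionTable.empty()
    out = tables[0]
    for t in tables[1:]:
        out = out.merge(t)
    return out


def write_junc(table: JunctionTable, path, sample: str, anchor: int = 8) -> None:
    """Write one sample's junctions in the BED12 ``.junc`` dialect."""
    with open(path, "w") as fh:
        for i, (jid, row) in enumerate(table.meta.iterrows()):
            count = int(table.counts.loc[jid, sample])
            if count == 0:
                continue
            a = max(anchor, int(row["anchor_len"]))
            chrom_start = row["start"] - a
            chrom_end = row["end"] + a
            block_starts = f"0,{row['end'] - chrom_start}"
            strand = row["strand"] if row["strand"] in ("+", "-") else "?"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        row["chrom"], chrom_start, chrom_end, f"JUNC{i:08d}", count,
                        strand, chrom_start, chrom_end, "255,0,0", 2, f"{a},{a}",
                        block_starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering and clustering


def filter_junctions(
    table: JunctionTable,
    min_len: int = 50,
    max_len: int = 500_000,
    min_anchor: int = 8,
) -> JunctionTable:
    """Drop junctions outside [min_len, max_len] (inclusive) or with a short anchor."""
    lengths = table.lengths
    keep = (lengths >= min_len) & (lengths <= max_len) & (table.meta["anchor_len"] >= min_anchor)
    return JunctionTable(meta=table.meta.loc[keep].copy(), counts=table.counts.loc[keep].copy())


def _strand_key(strand: str) -> str:
    return strand if strand in ("+", "-") else "?"


def _components(meta: pd.DataFrame) -> list[list[str]]:
    """Connected components linking junctions on one (chrom, strand) stratum
    that share a start or an end coordinate."""
    g = nx.Graph()
    g.add_nodes_from(meta.index)
    for side in ("start", "end"):
        for _, group in meta.groupby(["chrom", meta["strand"].map(_strand_key), side]):
            ids = list(group.index)
            g.add_edges_from(zip(ids[:-1], ids[1:]))
    return [sorted(c) for c in nx.connected_components(g)]


def cluster_introns(
    table: JunctionTable,
    min_cluster_reads: int = 50,
    min_intron_frac: float = 0.001,
) -> IntronClusterSet:
    """Group junctions into intron-excision clusters.

    Clusters are connected components of the graph joining junctions on the
    same chromosome and strand that share a start or an end coordinate
    (unknown-strand junctions form their own stratum, so unstranded input
    clusters purely by coordinates).  Introns carrying less than
    ``min_intron_frac`` of their component's total reads are dropped
    iteratively, recomputing components until stable.  Components with fewer
    than two introns or with a read total below ``min_cluster_reads`` are
    discarded — a lone intron has a degenerate usage ratio of 1.
    """
    totals = table.total_counts()
    meta = table.meta
    while True:
        comps = _components(meta)
        drop: list[str] = []
        for comp in comps:
            comp_total = totals.loc[comp].sum()
            if comp_total <= 0:
                drop.extend(comp)
                continue
            frac = totals.loc[comp] / comp_total
            drop.extend(frac.index[frac < min_intron_frac])
        if not drop:
            break
        meta = meta.drop(index=drop)

    members: dict[str, list[str]] = {}
    cluster_totals: dict[str, int] = {}
    comps = _components(meta)
    comps.sort(key=lambda c: (meta.loc[c[0], "chrom"], int(meta.loc[c, "start"].min())))
    idx = 0
    for comp in comps:
        total = int(totals.loc[comp].sum())
        if len(comp) < 2 or total < min_cluster_reads:
            continue
        idx += 1
        chrom = meta.loc[comp[0], "chrom"]
        strand = _strand_key(meta.loc[comp[0], "strand"])
        cid = f"{chrom}:{idx}:{strand}"
        members[cid] = comp
        cluster_totals[cid] = total
    return IntronClusterSet(members=members, totals=cluster_totals)


def compute_iur(clusters: IntronClusterSet, table: JunctionTable) -> UsageMatrix:
    """Raw intron usage ratios R_k = X_k / sum_i X_i per cluster and sample.

    Samples in which a cluster has zero total reads get missing (NaN) ratios
    for all that cluster's introns.
    """
    cluster_of = clusters.cluster_of()
    introns = list(cluster_of.index)
    counts = table.counts.loc[introns].astype(float)
    denom = counts.groupby(cluster_of).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = counts / denom
    values[denom == 0] = np.nan
    return UsageMatrix(values=values, cluster_of=cluster_of, stage="raw")
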