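"""Characterisation of (colocalised) splice junctions.

Three orthogonal views of a junction:

* usage — the *high-genotype IUR*: mean raw usage ratio among samples
  homozygous for the usage-increasing allele; below 0.1 the junction is
  called low-usage;
* annotation — against reference introns derived from a GTF, each junction is
  DA (known donor-acceptor pair), NDA (both sites known, pairing novel),
  A (known acceptor, novel donor), D (known donor, novel acceptor) or
  N (neither known), with a canonical flag for GT..AG splice-site
  dinucleotides on the transcribed strand;
* replication — exact intron-chain matching against long-read isoforms,
  optionally restricted to a cell group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = [
    "JunctionAnnotation",
    "UsageClassification",
    "ReferenceIntrons",
    "reference_introns_from_gtf",
    "genome_from_fasta",
    "high_genotype_iur",
    "classify_low_usage",
    "annotate_junction",
    "usage_enrichment_test",
    "replicate_junctions",
]

CATEGORIES = ("DA", "NDA", "A", "D", "N")


@dataclass
class JunctionAnnotation:
    junction_id: str
    category: str  # DA | NDA | A | D | N
    canonical: bool

    @property
    def annotated(self) -> bool:
        return self.category == "DA"


@dataclass
class UsageClassification:
    junction_id: str
    high_genotype_iur: float
    low_usage: bool
    extrapolated: bool
    n_samples_supporting: int


@dataclass
class ReferenceIntrons:
    """Reference intron chains indexed for annotation queries.

    ``exact`` holds (chrom, strand, start, end) tuples in 0-based half-open
    coordinates; donor sites are intron starts on '+' and intron ends on '-',
    acceptors the opposite.
    """

    exact: set[tuple[str, str, int, int]]
    donors: set[tuple[str, str, int]]
    acceptors: set[tuple[str, str, int]]

    @staticmethod
    def from_introns(introns: list[tuple[str, int, int, str]]) -> "ReferenceIntrons":
        exact, donors, acceptors = set(), set(), set()
        for chrom, start, end, strand in introns:
            exact.add((chrom, strand, start, end))
            if strand == "-":
                donors.add((chrom, strand, end))
                acceptors.add((chrom, strand, start))
            else:
                donors.add((chrom, strand, start))
                acceptors.add((chrom, strand, end))
        return ReferenceIntrons(exact=exact, donors=donors, acceptors=acceptors)


def reference_introns_from_gtf(gtf_path) -> ReferenceIntrons:
    """Collect introns between consecutive exons of every transcript.

    GTF is 1-based inclusive; the intron between exon [s1, e1] and exon
    [s2, e2] is [e1, s2 - 1) in 0-based half-open coordinates.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    introns: list[tuple[str, int, int, str]] = []
    for tx in db.features_of_type("transcript"):
        exons = sorted(db.children(tx, featuretype="exon"), key=lambda e: e.start)
        for a, b in zip(exons[:-1], exons[1:]):
            introns.append((tx.seqid, a.end, b.start - 1, tx.strand))
    return ReferenceIntrons.from_introns(introns)


def genome_from_fasta(path):
    """Wrap a FASTA in the fetch(chrom, start, end) protocol (0-based)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))

    class _Fetcher:
        def fetch(self, chrom: str, start: int, end: int) -> str:
            return str(fa[chrom][start:end]).upper()

    return _Fetcher()


# ---------------------------------------------------------------------------
# Usage


def high_genotype_iur(
    raw_usage: pd.Series,
    dosages: pd.Series,
    beta: float,
) -> tuple[float, bool]:
    """Mean raw usage ratio in the genotype group homozygous for the
    usage-increasing allele.

    The usage-increasing allele is the one whose dosage carries a positive
    association slope; a negative ``beta`` flips the dosage coding.  When no
    homozygous-high sample exists the mean over the most extreme available
    genotype group is returned with ``extrapolated=True``.
    """
    usage = raw_usage.dropna()
    if usage.empty:
        raise ValueError("empty usage row")
    dos = dosages.reindex(usage.index).astype(float)
    if beta < 0:
        dos = 2.0 - dos
    dos = dos.round()
    extrapolated = False
    group = usage[dos == 2]
    if group.empty:
        extrapolated = True
        group = usage[dos == dos.max()]
    return float(group.mean()), extrapolated


def classify_low_usage(value: float, cutoff: float = 0.1) -> bool:
    """Strict inequality: low usage iff high-genotype IUR < cutoff."""
    if not (0 <= value <= 1):
        raise ValueError("usage ratio must lie in [0, 1]")
    return value < cutoff


def classify_usage(
    junction_id: str,
    raw_usage: pd.Series,
    dosages: pd.Series,
    beta: float,
    cutoff: float = 0.1,
) -> UsageClassification:
    value, extrapolated = high_genotype_iur(raw_usage, dosages, beta)
    return UsageClassification(
        junction_id=junction_id,
        high_genotype_iur=value,
        low_usage=classify_low_usage(value, cutoff),
        extrapolated=extrapolated,
        n_samples_supporting=int((raw_usage > 0).sum()),
    )


# ---------------------------------------------------------------------------
# Annotation


def _canonical_on_strand(donor2: str, acceptor2: str, strand: str) -> bool:
    if strand == "-":
        # GT..AG read on the minus strand appears as CT..AC on the plus strand
        return donor2 == "CT" and acceptor2 == "AC"
    return donor2 == "GT" and acceptor2 == "AG"


def annotate_junction(
    junction: tuple[str, int, int, str],
    reference: ReferenceIntrons,
    genome=None,
    junction_id: str | None = None,
) -> JunctionAnnotation:
    """Classify one junction against reference splice sites.

    Exact intron match → DA; both sites known but never paired → NDA; known
    acceptor with novel donor → A; known donor with novel acceptor → D;
    neither → N.  Unknown-strand junctions match against both strands.  The
    canonical flag checks the first and last two intronic bases for GT..AG on
    the junction's strand (reverse-complement convention on '-').
    """
    chrom, start, end, strand = junction
    strands = [strand] if strand in ("+", "-") else ["+", "-"]
    category = "N"
    best_rank = 5
    ranks = {c: i for i, c in enumerate(CATEGORIES)}
    for s in strands:
        if (chrom, s, start, end) in reference.exact:
            cat = "DA"
        else:
            donor_pos, acceptor_pos = (end, start) if s == "-" else (start, end)
            dk = (chrom, s, donor_pos) in reference.donors
            ak = (chrom, s, acceptor_pos) in reference.acceptors
            cat = "NDA" if (dk and ak) else "A" if ak else "D" if dk else "N"
        if ranks[cat] < best_rank:
            best_rank, category = ranks[cat], cat
    canonical = False
    if genome is not None:
        left = genome.fetch(chrom, start, start + 2).upper()
        right = genome.fetch(chrom, end - 2, end).upper()
        canonical = any(_canonical_on_strand(left, right, s) for s in strands)
    return JunctionAnnotation(
        junction_id=junction_id or f"{chrom}:{start}:{end}:{strand}",
        category=category,
        canonical=canonical,
    )


# ---------------------------------------------------------------------------
# Enrichment


def usage_enrichment_test(
    coloc_low_usage: pd.Series,
    tested_low_usage: pd.Series,
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test of low-usage status in colocalised vs other
    tested introns.

    Both inputs are boolean series indexed by intron id; the colocalised set
    must be a subset of the tested set.  Returns (conditional-MLE odds ratio,
    two-sided p, 2x2 table); an empty margin yields OR = NaN.
    """
    extra = coloc_low_usage.index.difference(tested_low_usage.index)
    if len(extra):
        raise ValueError("colocalised introns must be a subset of tested introns")
    other = tested_low_usage.drop(index=coloc_low_usage.index)
    a = int(coloc_low_usage.sum())
    b = int((~coloc_low_usage).sum())
    c = int(other.sum())
    d = int((~other).sum())
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return float("nan"), 1.0, table
    orr = _odds_ratio(table, kind="conditional")
    _, p = sstats.fisher_exact(table, alternative="two-sided")
    return float(orr.statistic), float(p), table


def usage_enrichment_grid(
    coloc_iur: pd.Series,
    tested_iur: pd.Series,
    cutoffs=np.arange(0.01, 0.101, 0.01),
) -> pd.DataFrame:
    """Enrichment over a grid of high-genotype IUR cutoffs."""
    rows = []
    for cut in cutoffs:
        orr, p, table = usage_enrichment_test(coloc_iur < cut, tested_iur < cut)
        rows.append({"cutoff": float(cut), "odds_ratio": orr, "p": p,
                     "n_coloc_low": int(table[0, 0]), "n_tested_low": int(table[0, 0] + table[1, 0])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Long-read replication


def replicate_junctions(
    junctions: list[tuple[str, int, int, str]],
    isoform_chains: pd.DataFrame,
    cell_group: str | None = None,
    da_junctions: list[tuple[str, int, int, str]] | None = None,
) -> pd.DataFrame:
    """Exact intron-chain replication of junctions in long-read isoforms.

    ``isoform_chains`` needs columns isoform_id, sample_id, cell_group,
    chrom, start, end, strand (one row per intron per isoform) and may carry
    cell_id for cell-level support counts.  A junction is replicated iff its
    coordinates match an intron of any isoform in the queried cell group.

    When ``da_junctions`` (annotated junctions expected to be present) is
    given and more than half fail to match while a systematic ±1 shift would
    rescue them, a coordinate-convention mismatch is raised.
    """
    chains = isoform_chains
    if cell_group is not None:
        chains = chains[chains["cell_group"] == cell_group]

    def _key(chrom, start, end):
        return (str(chrom), int(start), int(end))

    index: dict[tuple, pd.DataFrame] = {
        k: g for k, g in chains.groupby([chains["chrom"].astype(str), chains["start"], chains["end"]])
    }

    if da_junctions:
        misses = [j for j in da_junctions if _key(j[0], j[1], j[2]) not in index]
        if len(misses) > 0.5 * len(da_junctions):
            shifted_hits = sum(
                1
                for j in misses
                for dx in (-1, 1)
                if _key(j[0], j[1] + dx, j[2] + dx) in index
            )
            if shifted_hits > 0.5 * len(misses):
                raise ValueError(
                    "systematic off-by-one between junction and isoform coordinates"
                )

    rows = []
    for chrom, start, end, strand in junctions:
        hit = index.get(_key(chrom, start, end))
        if hit is None:
            rows.append(
                {"junction_id": f"{chrom}:{start}:{end}:{strand}", "replicated": False,
                 "n_isoforms": 0, "n_samples": 0, "n_cells": 0}
            )
        else:
            n_cells = hit["cell_id"].nunique() if "cell_id" in hit.columns else len(hit)
            rows.append(
                {"junction_id": f"{chrom}:{start}:{end}:{strand}", "replicated": True,
                 "n_isoforms": hit["isoform_id"].nunique(),
                 "n_samples": hit["sample_id"].nunique(), "n_cells": int(n_cells)}
            )
    return pd.DataFrame(rows).set_index("junction_id")
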