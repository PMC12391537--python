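import numpy as np
import pandas as pd
import pytest

from spliceqtl import normalize as nz
from spliceqtl import synthio as si
from spliceqtl.junctions import JunctionTable, cluster_introns, compute_iur, filter_junctions


def make_table(rows, samples=("s1",)):
    """rows: (chrom, start, end, strand, counts-per-sample tuple)."""
    meta, counts = {}, {}
    for chrom, start, end, strand, cnts in rows:
        jid = f"{chrom}:{start}:{end}:{strand}"
        meta[jid] = {"chrom": chrom, "start": start, "end": end, "strand": strand,
                     "anchor_len": 8}
        counts[jid] = dict(zip(samples, cnts))
    meta = pd.DataFrame.from_dict(meta, orient="index")
    counts = pd.DataFrame.from_dict(counts, orient="index")[list(samples)].astype(np.int64)
    return JunctionTable(meta=meta, counts=counts)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small multi-condition synthetic cohort shared across tests."""
    cfg = si.SynthConfig(
        n_samples=60, n_genes=12, n_conditions=2, seed=7,
        prop_sqtl_genes=0.25, prop_response=0.0,
    )
    genotypes = si.simulate_genotypes(cfg)
    truth = si.make_truth_table(cfg, genotypes)
    tables = si.simulate_junction_counts(cfg, genotypes, truth)
    return {"config": cfg, "genotypes": genotypes, "truth": truth, "tables": tables}


@pytest.fixture(scope="session")
def tiny_normalized(tiny_scenario):
    tab = tiny_scenario["tables"]["Ctrl"]
    filt = filter_junctions(tab)
    clusters = cluster_introns(filt)
    raw = compute_iur(clusters, filt)
    norm = nz.inverse_normal_transform(
        nz.quantile_normalize(nz.impute_missing(nz.filter_low_information(raw)))
    )
    return {"raw": raw, "norm": norm, "clusters": clusters}
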