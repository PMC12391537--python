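"""End-to-end orchestration on a synthetic scenario.

Stages: simulate → cluster → normalize → map-sqtl → shrink (multi-condition
response calls) → coloc (GWAS locus definition + per-gene colocalisation)
→ classify (usage / annotation of colocalised junctions) → report.  Every
stage writes its outputs plus a JSON manifest (parameters, seed, row counts)
into the run directory, and reruns from the same config are byte-identical
for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as cl
from . import junclass as jc
from . import multicond as mc
from . import normalize as nz
from . import sqtl as sq
from . import synthio as si
from .junctions import JunctionTable, UsageMatrix, cluster_introns, compute_iur, filter_junctions

__all__ = ["RunConfig", "run_pipeline", "report", "low_usage_scenario"]


def low_usage_scenario(
    seed: int = 0, outdir: str = "run_low_usage", n_genes: int = 50, n_samples: int = 200,
    n_perm: int = 1000,
) -> "RunConfig":
    """Scenario with planted low-usage colocalised sQTLs.

    Every sQTL gene's target intron has a pinned baseline usage of 0.03 and a
    usage-increasing per-allele logit shift of 0.5 (homozygote-high mean
    usage ~0.08, below the low-usage cutoff), at common MAF so the
    homozygote-high genotype group is populated; the GWAS trait shares the
    causal variant (H4).
    """
    synth = si.SynthConfig(
        n_samples=n_samples, n_genes=n_genes, n_conditions=2, seed=seed,
        prop_sqtl_genes=0.15, prop_response=0.0, effect_size=0.5,
        effect_sign="positive", maf_range=(0.25, 0.5),
        target_baseline_usage=0.03, gwas_scenario_mix=(0.0, 0.0, 1.0),
    )
    return RunConfig(synth=synth, outdir=outdir, seed=seed, n_perm=n_perm)


@dataclass
class RunConfig:
    """Run-wide configuration: synthetic scenario plus analysis thresholds."""

    synth: si.SynthConfig = field(default_factory=si.SynthConfig)
    outdir: str = "run"
    n_perm: int = 1000
    n_usage_pcs: int = 0
    max_fdr: float = 0.05
    max_lfsr: float = 0.05
    pp4_thresh: float = 0.75
    gwas_p_thresh: float = 5e-8
    min_shared_variants: int = 20
    low_usage_cutoff: float = 0.1
    n_random_panel: int = 5000
    run_diffsplice: bool = False
    seed: int = 0

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _manifest(outdir: Path, stage: str, seed: int, params: dict, counts: dict) -> None:
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump({"stage": stage, "seed": seed, "params": params, "counts": counts}, fh,
                  indent=1, sort_keys=True, default=str)


def _normalize_condition(raw: UsageMatrix) -> UsageMatrix:
    filt = nz.filter_low_information(raw)
    imp = nz.impute_missing(filt)
    qn = nz.quantile_normalize(imp)
    return nz.inverse_normal_transform(qn)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the in-memory results bundle and writes
    tables plus manifests under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = config.synth

    # ---- simulate -------------------------------------------------------
    genotypes = si.simulate_genotypes(synth)
    truth = si.make_truth_table(synth, genotypes)
    tables = si.simulate_junction_counts(synth, genotypes, truth)
    gwas = si.simulate_gwas_stats(synth, truth, genotypes)
    gene_map = si.gene_of_intron(synth, truth)
    gene_tss = synth.gene_tss()
    genotypes.write_dosage_tsv(outdir / "dosages.tsv")
    si.write_vcf(genotypes, outdir / "genotypes.vcf")
    si.write_truth(truth, outdir / "truth.tsv", outdir / "truth.json")
    si.write_mini_gtf(synth, truth, outdir / "annotation.gtf")
    _manifest(outdir, "simulate", synth.seed, {"n_genes": synth.n_genes},
              {"variants": len(genotypes.variants), "conditions": len(tables)})

    # ---- cluster + normalize -------------------------------------------
    raw_usage: dict[str, UsageMatrix] = {}
    norm_usage: dict[str, UsageMatrix] = {}
    for cond, tab in tables.items():
        filt = filter_junctions(tab)
        clusters = cluster_introns(filt)
        raw = compute_iur(clusters, filt)
        raw_usage[cond] = raw
        norm = _normalize_condition(raw)
        norm_usage[cond] = norm
        norm.to_tsv(outdir / f"usage_normalized_{cond}.tsv")
    _manifest(outdir, "cluster_normalize", synth.seed, {},
              {c: int(norm_usage[c].values.shape[0]) for c in norm_usage})

    # ---- map sQTLs ------------------------------------------------------
    perm_results: dict[str, pd.DataFrame] = {}
    covariates: dict[str, nz.CovariateTable] = {}
    for cond, norm in norm_usage.items():
        cov = (
            nz.compute_usage_pcs(norm, config.n_usage_pcs)
            if config.n_usage_pcs
            else nz.CovariateTable.empty(norm.samples)
        )
        covariates[cond] = cov
        res = sq.map_sqtls(
            norm, genotypes, cov, gene_map, gene_tss,
            n_perm=config.n_perm, seed=config.seed,
        )
        perm_results[cond] = res
        res.to_csv(outdir / f"sqtl_perm_{cond}.tsv", sep="\t")
    _manifest(outdir, "map_sqtl", config.seed, {"n_perm": config.n_perm},
              {c: int((r["qvalue"] <= config.max_fdr).sum()) for c, r in perm_results.items()})

    # ---- multi-condition shrinkage / response calls ---------------------
    conditions = synth.conditions
    lead_pairs: dict[str, tuple[str, str]] = {}
    for cond in conditions:
        res = perm_results[cond]
        for gene, row in res.iterrows():
            if row["qvalue"] <= config.max_fdr and gene not in lead_pairs:
                lead_pairs[gene] = (row["best_intron_id"], row["best_variant_id"])
    nominal: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng([config.seed, 13])
    # random training pairs: any intron x a random cis variant
    random_pairs = []
    introns_all = sorted(set.intersection(*[set(norm_usage[c].values.index) for c in conditions]))
    for iid in introns_all:
        gene = gene_map.get(iid)
        vids = genotypes.variants.index[genotypes.variants["gene_id"] == gene]
        if len(vids):
            random_pairs.append((iid, str(rng.choice(vids))))
    if len(random_pairs) > config.n_random_panel:
        sel = rng.choice(len(random_pairs), size=config.n_random_panel, replace=False)
        random_pairs = [random_pairs[i] for i in sorted(sel)]
    all_pairs = sorted(set(lead_pairs.values()) | set(random_pairs))
    for cond in conditions:
        rows = {}
        norm = norm_usage[cond]
        for iid, vid in all_pairs:
            if iid not in norm.values.index:
                continue
            rec = sq.marginal_association(
                norm.values.loc[iid], genotypes.dosages.loc[vid, norm.samples],
                covariates[cond], intron_id=iid, variant_id=vid,
            )
            if rec is not None:
                rows[f"{iid}|{vid}"] = {"beta": rec.beta, "se": rec.se}
        nominal[cond] = pd.DataFrame.from_dict(rows, orient="index")

    response_flags = pd.DataFrame()
    post = None
    if lead_pairs:
        strong = mc.build_effect_panel(perm_results, nominal, "strong", max_fdr=config.max_fdr)
        random_panel = mc.build_effect_panel(
            perm_results, nominal, "random", n_random=config.n_random_panel, seed=config.seed
        )
        baseline_map = synth.baseline_map
        strong_c = mc.to_contrasts(strong, baseline_map)
        random_c = mc.to_contrasts(random_panel, baseline_map)
        model = mc.fit_shrinkage_model(random_c, strong_c)
        query_ids = pd.Index(sorted(f"{i}|{v}" for i, v in set(lead_pairs.values())))
        query = mc.EffectPanel(
            betas=pd.DataFrame({c: nominal[c].reindex(query_ids)["beta"].fillna(0.0) for c in conditions}),
            ses=pd.DataFrame({c: nominal[c].reindex(query_ids)["se"].fillna(1e6) for c in conditions}),
        )
        post = mc.posterior_effects(mc.to_contrasts(query, baseline_map), model)
        response_flags = mc.call_response_sqtls(post, max_lfsr=config.max_lfsr)
        response_flags.to_csv(outdir / "response_sqtls.tsv", sep="\t")
        with open(outdir / "shrinkage_model.json", "w") as fh:
            json.dump(model.to_json_dict(), fh, indent=1)
    _manifest(outdir, "shrink", config.seed, {"max_lfsr": config.max_lfsr},
              {"n_query": int(len(response_flags))})

    # ---- colocalisation -------------------------------------------------
    gwas_all = pd.concat([g.table for g in gwas.values()], ignore_index=True)
    loci = cl.define_gwas_loci(cl.SummaryStats(gwas_all), p_thresh=config.gwas_p_thresh)
    coloc_rows = []
    coloc_by_gene: dict[str, float] = {}
    for locus in loci:
        pp4s = []
        cand = gene_tss[(gene_tss["chrom"] == locus.chrom)
                        & (gene_tss["tss"] >= locus.window[0])
                        & (gene_tss["tss"] <= locus.window[1])]
        for gene in cand.index:
            if gene not in lead_pairs:
                continue
            iid, _ = lead_pairs[gene]
            for cond in conditions:
                norm = norm_usage[cond]
                if iid not in norm.values.index:
                    continue
                vids = sq.cis_window_variants(
                    (str(gene_tss.loc[gene, "chrom"]), int(gene_tss.loc[gene, "tss"])), genotypes
                )
                panel = genotypes.dosages.loc[vids]
                sstats = si.marginal_stats_for_trait(
                    panel, norm.values.loc[iid, panel.columns].to_numpy(), genotypes.variants
                )
                res = cl.coloc_abf(
                    sstats, gwas[gene], min_shared=config.min_shared_variants,
                    trait1=f"{gene}:{iid}", trait2=locus.lead_variant, condition=cond,
                )
                if res is None:
                    continue
                pp4s.append(res.pp4)
                coloc_rows.append(
                    {"locus": locus.lead_variant, "gene_id": gene, "intron_id": iid,
                     "condition": cond, "n_shared": res.n_shared_variants,
                     **{f"pp{h}": res.pp[h] for h in range(5)}}
                )
                coloc_by_gene[gene] = max(coloc_by_gene.get(gene, 0.0), res.pp4)
        cl.attribute_locus(locus, pp4s, [], pp4_thresh=config.pp4_thresh)
    coloc_df = pd.DataFrame(coloc_rows)
    coloc_df.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
    locus_df = pd.DataFrame(
        [{"lead_variant": l.lead_variant, "chrom": l.chrom, "pos": l.pos, "p": l.p,
          "attribution": l.attribution} for l in loci]
    )
    locus_df.to_csv(outdir / "gwas_loci.tsv", sep="\t", index=False)
    _manifest(outdir, "coloc", config.seed, {"pp4_thresh": config.pp4_thresh},
              {"loci": len(loci), "pairs": len(coloc_df)})

    # ---- classify colocalised junctions ---------------------------------
    reference = jc.reference_introns_from_gtf(outdir / "annotation.gtf")
    intron_coords = []
    for gene in truth.index:
        for jid in gene_map.index[gene_map == gene]:
            chrom, start, end, strand = jid.rsplit(":", 3)
            intron_coords.append((chrom, int(start), int(end)))
    genome = si.SyntheticGenome(intron_coords, noncanonical_frac=synth.noncanonical_frac,
                                seed=synth.seed)
    classify_rows = []
    coloc_genes = {g for g, p in coloc_by_gene.items() if p >= config.pp4_thresh}
    for gene in sorted(lead_pairs):
        iid, vid = lead_pairs[gene]
        chrom, start, end, strand = iid.rsplit(":", 3)
        # raw usage and association sign from the baseline condition
        cond0 = conditions[0]
        raw = raw_usage[cond0]
        if iid not in raw.values.index:
            continue
        beta = float(perm_results[cond0]["beta"].get(gene, 0.0)) if gene in perm_results[cond0].index else 0.0
        if beta == 0.0:
            for c in conditions:
                if gene in perm_results[c].index:
                    beta = float(perm_results[c]["beta"].get(gene, 0.0))
                    break
        usage_cls = jc.classify_usage(
            iid, raw.values.loc[iid], genotypes.dosages.loc[vid, raw.samples], beta,
            cutoff=config.low_usage_cutoff,
        )
        ann = jc.annotate_junction(
            (chrom, int(start), int(end), strand), reference, genome, junction_id=iid
        )
        classify_rows.append(
            {"gene_id": gene, "intron_id": iid, "variant_id": vid,
             "high_genotype_iur": usage_cls.high_genotype_iur,
             "low_usage": usage_cls.low_usage,
             "extrapolated": usage_cls.extrapolated,
             "n_samples_supporting": usage_cls.n_samples_supporting,
             "category": ann.category, "canonical": ann.canonical,
             "colocalised": gene in coloc_genes,
             "max_pp4": coloc_by_gene.get(gene, 0.0)}
        )
    classify_df = pd.DataFrame(classify_rows)
    classify_df.to_csv(outdir / "junction_characterization.tsv", sep="\t", index=False)
    _manifest(outdir, "classify", config.seed, {"cutoff": config.low_usage_cutoff},
              {"junctions": len(classify_df)})

    results = {
        "genotypes": genotypes, "truth": truth, "tables": tables, "gwas": gwas,
        "gene_map": gene_map, "gene_tss": gene_tss, "raw_usage": raw_usage,
        "norm_usage": norm_usage, "perm_results": perm_results,
        "response_flags": response_flags, "posteriors": post, "loci": loci,
        "coloc": coloc_df, "classify": classify_df, "lead_pairs": lead_pairs,
        "outdir": outdir,
    }
    rep = report(results, config)
    with open(outdir / "report.json", "w") as fh:
        json.dump(rep, fh, indent=1, sort_keys=True, default=float)
    return results


def report(results: dict, config: RunConfig) -> dict:
    """Summary counts plus truth-join recovery metrics."""
    truth = results["truth"]
    perm = results["perm_results"]
    sgenes = {
        c: sorted(r.index[r["qvalue"] <= config.max_fdr]) for c, r in perm.items()
    }
    true_sqtl = set(truth.index[truth["sqtl_flag"]])
    all_called = sorted(set().union(*[set(s) for s in sgenes.values()])) if sgenes else []
    tp = len([g for g in all_called if g in true_sqtl])
    fp = len(all_called) - tp
    loci = results["loci"]
    coloc_df = results["coloc"]
    classify = results["classify"]
    h4_genes = set(truth.index[truth["gwas_scenario"] == "H4"])
    coloc_genes = (
        set(coloc_df.loc[coloc_df["pp4"] >= config.pp4_thresh, "gene_id"])
        if len(coloc_df)
        else set()
    )
    # false "both" attributions: synthetic runs carry no eQTL colocs, so any
    # "both" locus is spurious by construction
    false_both = sum(1 for l in loci if l.attribution == "both")
    rep = {
        "sgenes_per_condition": {c: len(s) for c, s in sgenes.items()},
        "sqtl_sensitivity": tp / max(1, len(true_sqtl)),
        "sqtl_fdr": fp / max(1, len(all_called)),
        "n_gwas_loci": len(loci),
        "locus_attribution": {
            a: sum(1 for l in loci if l.attribution == a)
            for a in ("sQTL-only", "eQTL-only", "both", "neither")
        },
        "false_both_loci": false_both,
        "coloc_gene_recall_h4": (
            len(coloc_genes & h4_genes) / max(1, len(h4_genes & set(results["lead_pairs"])))
        ),
        "n_coloc_genes": len(coloc_genes),
        "n_response_genes": int(results["response_flags"]["any_response"].sum())
        if len(results["response_flags"])
        else 0,
        "low_usage_fraction_coloc": (
            float(classify.loc[classify["colocalised"], "low_usage"].mean())
            if len(classify) and classify["colocalised"].any()
            else float("nan")
        ),
        "canonical_fraction": float(classify["canonical"].mean()) if len(classify) else float("nan"),
    }
    return rep
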