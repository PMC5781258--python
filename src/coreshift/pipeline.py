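"""End-to-end run over one dataset: rarefy, diversity, core OTUs, networks.

Mirrors how the individual stages chain together on a real study:
organelle filter -> rarefaction -> Shannon / weighted UniFrac / PCoA /
PERMANOVA + pairwise tests -> per-treatment differential OTUs with the
core-consistency tally -> naive Bayes LOO classification -> per-treatment
SparCC networks, hub subnetworks and the merged membership partition.
Every stage's table is written as TSV under `outdir`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, core_shift, diversity, io, network, sparcc
from .simulate import SimConfig, simulate_dataset


def run_pipeline(table: io.OtuTable, tree, outdir, *,
                 depth: int = 19_000, n_perm: int = 999,
                 control: str = "control",
                 p_thresh: float = 0.05, fdr_alpha: float = 0.10,
                 prevalence: float = 0.80,
                 sparcc_inner: int = 20, sparcc_boot: int = 100,
                 sparcc_p: float = 0.1, top_k: int = 10_000,
                 hub_top_n: int = 20, seed: int = 0) -> dict:
    """Run the full analysis; writes TSV artifacts and returns a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if table.taxonomy:
        table = io.filter_organelle_otus(table)
    rare = diversity.rarefy(table, depth, seed=int(rng.integers(2**31)))
    io.write_otu_table(rare, outdir / "rarefied_table.tsv")
    io.write_metadata(rare, outdir / "metadata.tsv")

    shannon = diversity.shannon_per_sample(rare)
    pd.Series(shannon, name="shannon_h").rename_axis("sample").to_csv(
        outdir / "shannon.tsv", sep="\t")

    dm = diversity.weighted_unifrac(rare, tree)
    io.write_distance_matrix(dm.labels, dm.values, outdir / "weighted_unifrac.tsv")

    ord_res = diversity.pcoa(dm, n_axes=3)
    pd.DataFrame(ord_res.coordinates, index=ord_res.labels,
                 columns=[f"PCoA{i + 1}" for i in range(ord_res.coordinates.shape[1])]
                 ).rename_axis("sample").to_csv(outdir / "pcoa.tsv", sep="\t")

    grouping = {s: rare.metadata[s]["treatment"] for s in rare.sample_ids}
    f_stat, perm_p = diversity.permanova(dm, grouping, n_perm=n_perm,
                                         seed=int(rng.integers(2**31)))
    pairwise = diversity.pairwise_treatment_tests(dm, grouping, n_perm=n_perm,
                                                  seed=int(rng.integers(2**31)))
    pairwise.to_csv(outdir / "pairwise_tests.tsv", sep="\t", index=False)

    treatments = [t for t in rare.treatments() if t != control]
    results = {t: core_shift.differential_otus(rare, t, control,
                                               p_thresh, fdr_alpha)
               for t in treatments}
    core = core_shift.core_consistency(results)
    core.to_csv(outdir / "core_otus.tsv", sep="\t")
    totals = core_shift.consistency_totals(core)
    summary = core_shift.responsive_summary(results, rare)
    summary.to_csv(outdir / "responsive_summary.tsv", sep="\t", index=False)
    profiles = core_shift.log_ratio_profiles(results)
    responsive = core.index[core["n_significant_treatments"] >= 1]
    if len(responsive) >= 4:
        clusters = core_shift.cluster_response_profiles(profiles.loc[responsive])
        clusters.rename_axis("otu").to_csv(outdir / "response_clusters.tsv", sep="\t")

    X, feat_otus = classify.prevalence_filter(rare, prevalence)
    labels = [grouping[s] for s in rare.sample_ids]
    loo = classify.loo_evaluate(X, labels)
    loo.confusion.to_csv(outdir / "loo_confusion.tsv", sep="\t")

    subnets = {}
    for t in rare.treatments():
        sub_table = rare.select_samples(rare.treatments()[t])
        keep_idx = (sub_table.counts > 0).sum(axis=1) / sub_table.n_samples >= prevalence
        filtered = sub_table.select_otus(
            [o for o, k in zip(sub_table.otu_ids, keep_idx) if k])
        res = sparcc.sparcc_correlations(filtered, n_inner=sparcc_inner,
                                         seed=int(rng.integers(2**31)))
        res = sparcc.sparcc_pvalues(filtered, res, n_boot=sparcc_boot,
                                    seed=int(rng.integers(2**31)))
        edges = sparcc.select_edges(res, p_thresh=sparcc_p, top_k=top_k)
        io.write_edge_list(edges, outdir / f"edges_{t}.tsv")
        g = network.edges_to_graph(edges, treatment=t, taxonomy=rare.taxonomy)
        if g.number_of_nodes():
            subnets[t] = network.hub_subnetwork(g, top_n=hub_top_n)
    partition = None
    if len(subnets) >= 2:
        merged, partition = network.merge_subnetworks(subnets)
        partition.to_csv(outdir / "network_membership.tsv", sep="\t")

    report = {
        "n_samples": rare.n_samples,
        "n_otus": rare.n_otus,
        "permanova_F": f_stat,
        "permanova_p": perm_p,
        **totals,
        "loo_accuracy": loo.accuracy,
        "loo_collapsed_accuracy": loo.collapsed_accuracy,
        "network_core_size": (int((partition["class"] == "core").sum())
                              if partition is not None else 0),
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_synthetic_pipeline(outdir, config: SimConfig | None = None, **kwargs) -> dict:
    """Simulate a dataset under `config` (defaults) and run the pipeline on it.

    Returns the pipeline summary augmented with recovery of the planted
    core OTUs into the significant set.
    """
    config = config or SimConfig()
    table, tree, truth = simulate_dataset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_otu_table(table, outdir / "raw_table.tsv")
    io.write_newick(tree, outdir / "tree.nwk")
    truth.to_json(outdir / "truth.json")
    report = run_pipeline(table, tree, outdir, seed=config.seed, **kwargs)
    core = pd.read_csv(outdir / "core_otus.tsv", sep="\t", index_col=0)
    hits = core.index[core["n_significant_treatments"] >= 1]
    planted = truth.core
    recovered = len(planted & set(hits))
    report["planted_core_recovered"] = recovered
    report["planted_core_total"] = len(planted)
    report["planted_core_recovery"] = recovered / len(planted) if planted else 1.0
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    return report
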