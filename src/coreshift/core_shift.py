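"""Stress-responsive OTU calling and the core stress microbiome.

Per treatment, each OTU's relative abundance is compared to the control
group with an equal-variance two-sample t-test; Benjamini-Hochberg FDR is
applied across OTUs within the treatment, and an OTU is called responsive
when both the raw p-value clears 0.05 and the BH-adjusted q-value clears
alpha = 0.10.  OTUs responsive in multiple stress treatments with the
same sign of change in every one form the "core stress" set.  Summaries
tally, per treatment, the community fraction carried by OTUs responsive
in 3/3, 2/3 or 1/3 treatments, and response profiles (log2 ratios vs
control) can be clustered hierarchically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import OtuTable


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_otus(table: OtuTable, treatment: str, control: str = "control",
                      p_thresh: float = 0.05, fdr_alpha: float = 0.10,
                      ) -> pd.DataFrame:
    """Per-OTU treatment-vs-control test on relative abundances.

    Returns a DataFrame indexed by OTU id with columns mean_control,
    mean_treatment, direction, p_raw, q_bh, significant.  Zero-variance
    OTUs with equal group means get p = 1 and direction 0.
    """
    groups = table.treatments()
    for name in (treatment, control):
        if name not in groups or len(groups[name]) < 2:
            raise ValueError(f"group {name!r} missing or has <2 samples")
    rel = table.relative_abundance()
    cols = {s: j for j, s in enumerate(table.sample_ids)}
    xt = rel[:, [cols[s] for s in groups[treatment]]]
    xc = rel[:, [cols[s] for s in groups[control]]]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=True)
    mean_t, mean_c = xt.mean(axis=1), xc.mean(axis=1)
    diff = mean_t - mean_c
    # degenerate rows: no variance anywhere -> no evidence of change
    p = np.where(np.isnan(p), 1.0, p)
    direction = np.sign(diff).astype(int)
    direction[p >= 1.0] = np.where(diff[p >= 1.0] == 0, 0, direction[p >= 1.0])
    q = bh_fdr(p)
    sig = (p < p_thresh) & (q <= fdr_alpha)
    return pd.DataFrame({
        "mean_control": mean_c, "mean_treatment": mean_t,
        "direction": direction, "p_raw": p, "q_bh": q, "significant": sig,
    }, index=pd.Index(table.otu_ids, name="otu"))


def core_consistency(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-treatment tally of responsive OTUs and direction consistency.

    `results` maps stress-treatment name -> differential_otus frame over a
    shared OTU universe.  Returns a per-OTU frame with
    n_significant_treatments, consistent_direction (all significant
    directions share one sign; vacuously true below 2 hits), and the
    per-treatment significance/direction columns.
    """
    names = list(results)
    universe = results[names[0]].index
    for t in names[1:]:
        if not results[t].index.equals(universe):
            raise ValueError("result frames have mismatched OTU sets")
    sig = np.column_stack([results[t]["significant"].to_numpy() for t in names])
    direc = np.column_stack([results[t]["direction"].to_numpy() for t in names])
    n_sig = sig.sum(axis=1)
    consistent = np.ones(len(universe), dtype=bool)
    for i in range(len(universe)):
        d = direc[i][sig[i]]
        consistent[i] = d.size == 0 or (np.all(d > 0) or np.all(d < 0))
    out = pd.DataFrame({"n_significant_treatments": n_sig,
                        "consistent_direction": consistent}, index=universe)
    for k, t in enumerate(names):
        out[f"sig_{t}"] = sig[:, k]
        out[f"dir_{t}"] = direc[:, k]
    return out


def consistency_totals(core: pd.DataFrame) -> dict[str, int]:
    """Headline tallies: responsive in >=1 / >1 treatments, consistent among >1."""
    n_sig = core["n_significant_treatments"]
    multi = core[n_sig > 1]
    return {
        "n_significant_any": int((n_sig >= 1).sum()),
        "n_significant_multi": int((n_sig > 1).sum()),
        "n_consistent_multi": int(multi["consistent_direction"].sum()),
    }


def responsive_summary(results: dict[str, pd.DataFrame],
                       table: OtuTable) -> pd.DataFrame:
    """Per treatment x responsiveness class (3/3, 2/3, 1/3): % abundance and count.

    An OTU responsive in exactly k treatments, that treatment included,
    contributes its mean relative abundance over the treatment's samples.
    Abundance is reported as percent of the community.
    """
    core = core_consistency(results)
    names = list(results)
    rel = table.relative_abundance()
    cols = {s: j for j, s in enumerate(table.sample_ids)}
    groups = table.treatments()
    otu_row = {o: i for i, o in enumerate(table.otu_ids)}
    n_classes = len(names)
    rows = []
    for t in names:
        jdx = [cols[s] for s in groups[t]]
        for k in range(n_classes, 0, -1):
            members = core.index[(core["n_significant_treatments"] == k)
                                 & core[f"sig_{t}"]]
            abund = sum(rel[otu_row[o]][jdx].mean() for o in members)
            rows.append({"treatment": t, "class": f"{k}/{n_classes}",
                         "abundance_pct": 100.0 * abund,
                         "n_otus": len(members)})
    return pd.DataFrame(rows)


def log_ratio_profiles(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """OTUs x treatments matrix of log2((mean_t + eps)/(mean_c + eps)).

    eps is half the smallest nonzero relative-abundance mean seen, so
    zero means stay finite without dominating the profile.
    """
    names = list(results)
    means = np.concatenate([
        results[t][["mean_control", "mean_treatment"]].to_numpy().ravel()
        for t in names])
    nonzero = means[means > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1.0
    out = {}
    for t in names:
        r = results[t]
        out[t] = np.log2((r["mean_treatment"] + eps) / (r["mean_control"] + eps))
    return pd.DataFrame(out, index=results[names[0]].index)


def cluster_response_profiles(profiles: pd.DataFrame, min_cluster: int = 3,
                              ) -> pd.Series:
    """Average-linkage hierarchical clustering of response profiles.

    Euclidean distances between rows; the dendrogram is cut at the
    largest height whose flat clustering leaves every cluster with at
    least `min_cluster` members (scanned over merge heights).  The
    partition is invariant to row order.
    """
    X = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("profiles must be finite")
    n = X.shape[0]
    if n < max(2, min_cluster):
        return pd.Series(np.zeros(n, dtype=int), index=profiles.index, name="cluster")
    # order-stable: cluster on a canonical row ordering, then map back
    order = np.lexsort(X.T[::-1])
    Z = hierarchy.linkage(pdist(X[order]), method="average")
    heights = np.unique(Z[:, 2])
    best = np.ones(n, dtype=int)
    for h in heights:
        labels = hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)[1:]
        if sizes.min() >= min_cluster and len(sizes) > 1:
            best = labels
            break
    out = np.empty(n, dtype=int)
    out[order] = best
    return pd.Series(out, index=profiles.index, name="cluster")
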