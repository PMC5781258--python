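"""Compositional correlation estimation (the SparCC algorithm) and networks.

Sequencing counts are compositional: per-sample fractions sum to one, so
naive correlations between fractions are biased.  SparCC estimates
correlations between latent ("basis") abundances from the log-ratio
variation matrix ``t_ij = Var(log(f_i/f_j))`` under a sparsity
assumption: with most pairs uncorrelated, basis variances ``w`` solve the
linear system ``M w = rowsums(T)`` with ``M = (D-2) I + 11'``, and

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Pairs whose estimated |rho| exceeds a threshold are excluded from the
system one at a time (strongest first) and the solve repeated, since
strong pairs violate sparsity.  Per-sample fractions are drawn from the
Dirichlet posterior with add-one concentration (counts + 1) and the
whole estimate is averaged over ``n_inner`` such draws; a deterministic
mode uses the posterior-mean fractions instead.  Pseudo-p-values come
from re-running the estimator on datasets whose counts are permuted
across samples independently per OTU, which destroys association while
preserving marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SparccResult:
    """Estimated basis correlations and (optional) bootstrap pseudo-p-values."""

    otu_ids: list[str]
    rho: np.ndarray
    pvals: np.ndarray | None = None
    n_inner: int = 1
    exclusion_log: list[list[tuple[str, str]]] = field(default_factory=list)
    n_clipped: int = 0


def _log_fractions(counts: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Log per-sample fractions, Dirichlet-sampled (counts+1) or posterior mean."""
    a = counts.astype(float) + 1.0
    if rng is None:
        frac = a / a.sum(axis=0, keepdims=True)
    else:
        g = rng.standard_gamma(a)
        frac = g / g.sum(axis=0, keepdims=True)
    return np.log(frac)


def _variation_matrix(logf: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of log(f_i/f_j), from the log-fraction covariance."""
    C = np.cov(logf)
    v = np.diag(C)
    return v[:, None] + v[None, :] - 2.0 * C


def _solve_once(T: np.ndarray, exclusion_thresh: float, max_exclusions: int,
                ) -> tuple[np.ndarray, list[tuple[int, int]], int]:
    """One basis solve with iterative strong-pair exclusion.

    Returns (rho, excluded index pairs, clip count).  A nonpositive
    solved basis variance marks that OTU's correlations NaN (warned).
    """
    D = T.shape[0]
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    rowsum = T.sum(axis=1)
    excluded: list[tuple[int, int]] = []
    excl_mask = np.zeros((D, D), dtype=bool)
    rho = np.full((D, D), np.nan)
    n_clip = 0
    for _ in range(max_exclusions + 1):
        omega = np.linalg.solve(M, rowsum)
        bad = omega <= 0
        om = np.where(bad, np.nan, omega)
        denom = 2.0 * np.sqrt(np.outer(om, om))
        raw = (om[:, None] + om[None, :] - T) / denom
        n_clip += int(np.sum(np.abs(raw) > 1.0) // 2)
        rho = np.clip(raw, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} nonpositive basis variances; "
                          "their correlations are undefined", stacklevel=3)
        if len(excluded) >= max_exclusions:
            break
        cand = np.abs(rho.copy())
        np.fill_diagonal(cand, 0.0)
        cand[excl_mask] = 0.0
        cand[np.isnan(cand)] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_thresh:
            break
        # drop pair (i,j) from the sparsity system: its t leaves both row
        # sums and omega_j leaves row i's coefficient (and vice versa)
        excluded.append((min(i, j), max(i, j)))
        excl_mask[i, j] = excl_mask[j, i] = True
        rowsum[i] -= T[i, j]
        rowsum[j] -= T[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
    return rho, excluded, n_clip


def sparcc_correlations(table, n_inner: int = 20, exclusion_thresh: float = 0.1,
                        max_exclusions: int = 10, seed: int = 0,
                        sample_fractions: bool = True) -> SparccResult:
    """Estimate basis correlations, averaged over `n_inner` fraction draws.

    ``sample_fractions=False`` gives the deterministic mode (posterior-mean
    fractions); combined with ``n_inner=1`` it is bit-reproducible.
    """
    counts = np.asarray(table.counts)
    D, n = counts.shape
    if D < 4:
        raise ValueError("SparCC needs at least 4 OTUs")
    if n < 4:
        raise ValueError("SparCC needs at least 4 samples")
    rng = np.random.default_rng(seed) if sample_fractions else None
    acc = np.zeros((D, D))
    nobs = np.zeros((D, D))
    log: list[list[tuple[str, str]]] = []
    n_clip = 0
    for _ in range(n_inner):
        logf = _log_fractions(counts, rng)
        T = _variation_matrix(logf)
        rho, excluded, clips = _solve_once(T, exclusion_thresh, max_exclusions)
        ok = ~np.isnan(rho)
        acc[ok] += rho[ok]
        nobs += ok
        n_clip += clips
        log.append([(table.otu_ids[i], table.otu_ids[j]) for i, j in excluded])
    with np.errstate(invalid="ignore"):
        mean_rho = np.where(nobs > 0, acc / np.maximum(nobs, 1), np.nan)
    np.fill_diagonal(mean_rho, 1.0)
    return SparccResult(otu_ids=list(table.otu_ids), rho=mean_rho,
                        n_inner=n_inner, exclusion_log=log, n_clipped=n_clip)


def sparcc_pvalues(table, result: SparccResult, n_boot: int = 100,
                   seed: int = 0, **estimator_kwargs) -> SparccResult:
    """Two-sided bootstrap pseudo-p-values for an estimated rho matrix.

    Each of the `n_boot` null datasets permutes every OTU's counts across
    samples independently; the full estimator is re-run and
    ``p_ij = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_boot)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    from .io import OtuTable
    counts = np.asarray(table.counts)
    D, n = counts.shape
    rng = np.random.default_rng(seed)
    obs = np.abs(result.rho)
    hits = np.zeros((D, D))
    kwargs = {"n_inner": result.n_inner, **estimator_kwargs}
    for b in range(n_boot):
        perm = np.empty_like(counts)
        for i in range(D):
            perm[i] = counts[i, rng.permutation(n)]
        null_table = OtuTable(perm, list(table.otu_ids),
                              list(table.sample_ids))
        null = sparcc_correlations(null_table, seed=int(rng.integers(2**31)),
                                   **kwargs)
        with np.errstate(invalid="ignore"):
            hits += np.abs(null.rho) >= obs
    pvals = (1.0 + hits) / (1.0 + n_boot)
    np.fill_diagonal(pvals, 1.0)
    return SparccResult(otu_ids=result.otu_ids, rho=result.rho, pvals=pvals,
                        n_inner=result.n_inner,
                        exclusion_log=result.exclusion_log,
                        n_clipped=result.n_clipped)


def select_edges(result: SparccResult, p_thresh: float = 0.1,
                 top_k: int = 10_000, ranking: str = "signed") -> pd.DataFrame:
    """Significant edges, ranked and truncated to the strongest `top_k`.

    Keeps pairs with p < p_thresh, sorts by descending correlation score
    (signed rho by default; ``ranking="absolute"`` uses |rho|), breaks
    boundary ties by lexicographic (otu_a, otu_b) order, and truncates.
    """
    if result.pvals is None:
        raise ValueError("result has no p-values; run sparcc_pvalues first")
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    D = len(result.otu_ids)
    iu = np.triu_indices(D, k=1)
    rows = []
    for i, j in zip(*iu):
        r, p = result.rho[i, j], result.pvals[i, j]
        if np.isnan(r) or p >= p_thresh:
            continue
        rows.append((result.otu_ids[i], result.otu_ids[j], float(r), float(p)))
    df = pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p"])
    if df.empty:
        return df
    score = df["rho"] if ranking == "signed" else df["rho"].abs()
    df = (df.assign(_score=score)
            .sort_values(["_score", "otu_a", "otu_b"],
                         ascending=[False, True, True], kind="mergesort")
            .drop(columns="_score")
            .head(top_k)
            .reset_index(drop=True))
    return df


def threshold_edges(edges: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Edges whose |rho| meets `cutoff`."""
    return edges[edges["rho"].abs() >= cutoff].reset_index(drop=True)


def degree_rank_stability(edge_lists: dict[float, pd.DataFrame],
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Stability diagnostic behind a top-k edge choice.

    For each correlation cutoff's edge list, node degrees are ranked;
    the returned table holds the Spearman rank correlation of degrees
    over shared nodes for every cutoff pair, alongside the edge-count
    curve.  Cutoffs whose graph is empty are excluded (warned).
    """
    if len(edge_lists) < 2:
        raise ValueError("need at least 2 cutoffs")
    degrees: dict[float, pd.Series] = {}
    counts: dict[float, int] = {}
    for cut, df in edge_lists.items():
        if df.empty:
            warnings.warn(f"cutoff {cut} yields an empty graph; excluded",
                          stacklevel=2)
            continue
        deg = pd.concat([df["otu_a"], df["otu_b"]]).value_counts()
        degrees[cut] = deg
        counts[cut] = len(df)
    cuts = sorted(degrees)
    table = pd.DataFrame(np.nan, index=cuts, columns=cuts)
    for a in cuts:
        for b in cuts:
            shared = degrees[a].index.intersection(degrees[b].index)
            if len(shared) < 2:
                continue
            da, db = degrees[a][shared], degrees[b][shared]
            if da.equals(db):
                rho = 1.0  # identical rankings, even when degrees are tied flat
            elif da.nunique() == 1 or db.nunique() == 1:
                rho = np.nan
            else:
                rho = stats.spearmanr(da, db).statistic
            table.loc[a, b] = rho
    return table, pd.Series(counts).sort_index()
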