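"""Community diversity and ordination statistics.

Covers the alpha/beta-diversity arm of the pipeline: rarefaction to a
common depth, Shannon diversity with a low-abundance filter, weighted
UniFrac distances over a rooted tree, principal-coordinates analysis,
PERMANOVA, and the pairwise within-vs-between permutation test used to
compare treatment groups on a distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import skbio
from skbio import TreeNode
from skbio.diversity import beta_diversity

from .io import OtuTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Square symmetric nonnegative matrix over samples, zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix size does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.labels)


@dataclass
class Ordination:
    """PCoA embedding: samples x axes, axes ordered by eigenvalue."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    negative_eigenvalues: np.ndarray

    @property
    def proportion_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to `depth` reads without replacement.

    Samples with fewer than `depth` reads are dropped (logged).  Each
    surviving column is a multivariate-hypergeometric draw, so its total
    is exactly `depth`.  One child seed per sample is derived from the
    root seed so column order does not couple the draws.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_sums()
    keep = [i for i, t in enumerate(totals) if t >= depth]
    if not keep:
        raise ValueError(f"no sample reaches depth {depth}")
    dropped = [table.sample_ids[i] for i in range(table.n_samples) if i not in keep]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    seeds = np.random.SeedSequence(entropy=seed).spawn(table.n_samples)
    new_counts = np.empty((table.n_otus, len(keep)), dtype=np.int64)
    for out_j, j in enumerate(keep):
        col = table.counts[:, j]
        if totals[j] == depth:
            new_counts[:, out_j] = col
        else:
            rng = np.random.default_rng(seeds[j])
            new_counts[:, out_j] = rng.multivariate_hypergeometric(col, depth)
    sample_ids = [table.sample_ids[j] for j in keep]
    meta = {s: table.metadata[s] for s in sample_ids} if table.metadata else {}
    return OtuTable(new_counts, list(table.otu_ids), sample_ids,
                    dict(table.taxonomy), meta)


# ---------------------------------------------------------------------------
# Shannon diversity


def shannon_index(abundances: np.ndarray, min_frac: float = 1e-4) -> float:
    """Shannon H = -sum p_i ln p_i after dropping OTUs at fraction <= min_frac.

    The default floor of 1e-4 (0.01% relative abundance) suppresses noise
    from low-abundance taxa; the surviving fractions are renormalized
    before the entropy is taken (natural log).
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = a / total
    p = p[p > min_frac]
    if p.size == 0:
        raise ValueError("no OTU above min_frac")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: OtuTable, min_frac: float = 1e-4) -> dict[str, float]:
    rel = table.relative_abundance()
    return {s: shannon_index(rel[:, j], min_frac)
            for j, s in enumerate(table.sample_ids)}


# ---------------------------------------------------------------------------
# weighted UniFrac


def weighted_unifrac(table: OtuTable, tree: TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """All-pairs weighted UniFrac over the table's samples.

    Raw variant (default): ``sum_b  l_b * |p_A(b) - p_B(b)|`` over branches,
    where ``p_X(b)`` is the fraction of sample X's reads on tips below
    branch b.  The normalized variant divides by ``sum_b l_b (p_A + p_B)``.
    Every OTU with nonzero counts must be a tip of the tree.
    """
    tips = {t.name for t in tree.tips()}
    nonzero = [o for i, o in enumerate(table.otu_ids) if table.counts[i].any()]
    missing = [o for o in nonzero if o not in tips]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing}")
    dm = beta_diversity("weighted_unifrac", table.counts.T,
                        ids=table.sample_ids, taxa=table.otu_ids,
                        tree=tree, normalized=normalized)
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


# ---------------------------------------------------------------------------
# PCoA


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical (metric) scaling of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix;
    axes with negative eigenvalues are reported separately and excluded
    from the returned coordinates.
    """
    n = len(dm.labels)
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        logger.warning("pcoa: n_axes clipped from %d to %d", n_axes, n - 1)
        n_axes = n - 1
    d2 = dm.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0])) if n else 0.0
    pos = evals > tol
    neg = evals[evals < -tol]
    k = min(n_axes, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k]) if k else np.zeros((n, 0))
    # classical scaling of an all-zero matrix: all coordinates at the origin
    if k == 0:
        coords = np.zeros((n, min(n_axes, 1)))
        return Ordination(list(dm.labels), coords, np.zeros(coords.shape[1]), neg)
    return Ordination(list(dm.labels), coords, evals[:k], neg)


# ---------------------------------------------------------------------------
# PERMANOVA


def _group_indices(labels: list[str], grouping: dict[str, str]) -> list[np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(labels):
        groups.setdefault(grouping[s], []).append(i)
    return [np.array(v) for v in groups.values()]


def _pseudo_f(d2: np.ndarray, member: list[np.ndarray]) -> float:
    n = d2.shape[0]
    a = len(member)
    total = d2[np.triu_indices(n, k=1)].sum() / n
    within = 0.0
    for idx in member:
        sub = d2[np.ix_(idx, idx)]
        within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    between = total - within
    return (between / (a - 1)) / (within / (n - a))


def permanova(dm: DistanceMatrix, grouping: dict[str, str],
              n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Distance-based multivariate ANOVA (Adonis) by label permutation.

    Returns ``(pseudo_F, p)`` with the add-one permutation p-value
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    member = _group_indices(dm.labels, grouping)
    if len(member) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if any(len(m) < 2 for m in member):
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.values ** 2
    f_obs = _pseudo_f(d2, member)
    sizes = [len(m) for m in member]
    splits = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    n = d2.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = np.split(perm, splits)
        if _pseudo_f(d2, pm) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Table-1 style within/between test


def _within_between_t(d: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    # pooled-variance two-sample t, inlined for the permutation loop
    within = d[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)]
    between = d[np.ix_(ia, ib)].ravel()
    n1, n2 = within.size, between.size
    v1 = within.var(ddof=1) if n1 > 1 else 0.0
    v2 = between.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = within.mean() - between.mean()
    if denom == 0:
        # degenerate (both lists constant): infinitely separated unless equal
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


def within_between_test(dm: DistanceMatrix, group_a: list[str], group_b: list[str],
                        n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Compare within-group-a distances to a<->b between-group distances.

    Two-sample t statistic on the two distance lists; significance by
    permuting the sample-to-group assignment within the union (999 Monte
    Carlo permutations by default, add-one convention, two-sided).  The
    asymmetric counterpart (within b vs between) is obtained by swapping
    the arguments.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    union = list(group_a) + list(group_b)
    sub = dm.submatrix(union)
    d = sub.values
    na = len(group_a)
    ia0, ib0 = np.arange(na), np.arange(na, len(union))
    t_obs = _within_between_t(d, ia0, ib0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(union))
        if abs(_within_between_t(d, perm[:na], perm[na:])) >= abs(t_obs):
            hits += 1
    return t_obs, (1 + hits) / (1 + n_perm)


def pairwise_treatment_tests(dm: DistanceMatrix, grouping: dict[str, str],
                             n_perm: int = 999, seed: int = 0):
    """All ordered treatment pairs' within/between tests, as a DataFrame."""
    import pandas as pd
    groups: dict[str, list[str]] = {}
    for s in dm.labels:
        groups.setdefault(grouping[s], []).append(s)
    names = list(groups)
    rows = []
    rng = np.random.default_rng(seed)
    for a in names:
        for b in names:
            if a == b:
                continue
            t, p = within_between_test(dm, groups[a], groups[b], n_perm,
                                       seed=int(rng.integers(2**31)))
            rows.append({"within": a, "versus": b, "t": t, "p": p})
    return pd.DataFrame(rows)
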