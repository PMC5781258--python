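"""Linking stress-responsive OTUs to metabolite and transcript features.

All feature pairs across two matrices (e.g. core-OTU relative abundances
vs metabolite concentrations) are tested with the Pearson product-moment
correlation; records below the raw p threshold (0.05 by default, no FDR)
form the link table, and features can be ranked by how many distinct
partners they correlate with.  Also provides the signed log2 fold-change
convention used for omics summaries: the fold magnitude up or down, log2
scaled, with the sign marking the direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def signed_log2_fc(mean_treatment: float, mean_control: float) -> float:
    """Signed log2 fold change: |log2 fold| with sign of the direction.

    The fold is taken as the larger of r and 1/r for
    r = mean_treatment / mean_control, so the magnitude is symmetric up
    and down; the sign is + for an increase, - for a decrease, 0 when
    the means are equal.
    """
    if mean_treatment <= 0 or mean_control <= 0:
        raise ValueError("means must be positive")
    r = mean_treatment / mean_control
    if r == 1:
        return 0.0
    fold = max(r, 1.0 / r)
    return float(np.sign(r - 1) * np.log2(fold))


def pearson_link_table(X: pd.DataFrame, Y: pd.DataFrame,
                       p_thresh: float = 0.05) -> pd.DataFrame:
    """All X-row x Y-row Pearson correlations; keep records with p < p_thresh.

    Both frames are features x samples; correlations run over the shared
    sample columns (>= 3 required).  Constant features are skipped with a
    warning.  p-values are two-sided via the t transform with n - 2
    degrees of freedom.  Columns: feature_a, feature_b, r, p, n_samples.
    """
    shared = [c for c in X.columns if c in set(Y.columns)]
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    Xs = X[shared].to_numpy(dtype=float)
    Ys = Y[shared].to_numpy(dtype=float)
    x_ok = Xs.std(axis=1) > 0
    y_ok = Ys.std(axis=1) > 0
    n_const = int((~x_ok).sum() + (~y_ok).sum())
    if n_const:
        warnings.warn(f"skipped {n_const} constant features", stacklevel=2)
    Xc = Xs[x_ok] - Xs[x_ok].mean(axis=1, keepdims=True)
    Yc = Ys[y_ok] - Ys[y_ok].mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    Yn = Yc / np.linalg.norm(Yc, axis=1, keepdims=True)
    R = np.clip(Xn @ Yn.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    P[np.isnan(P)] = 0.0  # |r| == 1 exactly
    ai, bi = np.where(P < p_thresh)
    a_ids = list(X.index[x_ok])
    b_ids = list(Y.index[y_ok])
    df = pd.DataFrame({
        "feature_a": [a_ids[i] for i in ai],
        "feature_b": [b_ids[j] for j in bi],
        "r": R[ai, bi],
        "p": P[ai, bi],
        "n_samples": n,
    })
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def rank_by_link_count(links: pd.DataFrame, side: str = "a",
                       ) -> pd.DataFrame:
    """Features ordered by number of distinct correlated partners.

    ``side`` picks which column of the link table is ranked ('a' or 'b');
    ties break by feature id.  Returns columns (feature, n_links).
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    if links.empty:
        return pd.DataFrame(columns=["feature", "n_links"])
    feat, other = f"feature_{side}", f"feature_{'b' if side == 'a' else 'a'}"
    counts = (links.drop_duplicates([feat, other])
                   .groupby(feat)[other].nunique())
    out = (counts.rename("n_links").reset_index()
                 .rename(columns={feat: "feature"})
                 .sort_values(["n_links", "feature"], ascending=[False, True],
                              kind="mergesort")
                 .reset_index(drop=True))
    return out
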