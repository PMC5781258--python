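"""Gaussian naive Bayes treatment classification with leave-one-out folds.

Features are the relative abundances of prevalence-filtered OTUs (kept
when present — nonzero — in at least 80% of samples by default).  The
model assumes each feature is Gaussian within a class; class priors are
empirical unless requested uniform.  Evaluation is leave-one-out: each
sample is predicted by a model fit on the others, and accuracy is
reported both over the full label set and with the three stress labels
collapsed to a single "stress" class versus control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB

STRESS_LABELS = frozenset({"copper", "drought", "shade"})


def prevalence_filter(table, min_prevalence: float = 0.80):
    """Relative-abundance feature matrix over OTUs present in >= min_prevalence of samples.

    "Present" means a nonzero count.  The boundary is inclusive
    (an OTU in exactly 80% of samples is kept at the default).
    Returns ``(X, otu_ids)`` with X shaped samples x features.
    """
    if table.n_otus == 0 or table.n_samples == 0:
        raise ValueError("empty table")
    present = (table.counts > 0).sum(axis=1) / table.n_samples
    keep = np.where(present >= min_prevalence - 1e-12)[0]
    if keep.size == 0:
        raise ValueError(f"no OTU reaches prevalence {min_prevalence}")
    rel = table.relative_abundance()
    return rel[keep].T, [table.otu_ids[i] for i in keep]


@dataclass
class GnbModel:
    """Fitted Gaussian naive Bayes: per-class priors, means, smoothed variances."""

    classes: list[str]
    priors: np.ndarray
    means: np.ndarray      # classes x features
    variances: np.ndarray  # classes x features, > 0 after smoothing
    _sk: GaussianNB = field(repr=False, default=None)


def gnb_fit(X: np.ndarray, labels: list[str], uniform_priors: bool = False) -> GnbModel:
    """Fit the Gaussian NB model (variance floor 1e-9 x largest feature variance)."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("every class needs at least 2 samples")
    sk = GaussianNB(priors=(np.full(len(classes), 1 / len(classes))
                            if uniform_priors else None))
    sk.fit(X, labels)
    order = [list(sk.classes_).index(c) for c in classes]
    return GnbModel(classes=classes,
                    priors=sk.class_prior_[order],
                    means=sk.theta_[order],
                    variances=sk.var_[order],
                    _sk=sk)


def gnb_predict(model: GnbModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Predict one sample; returns (label, posterior vector over model.classes).

    Log-space evaluation; argmax with deterministic tie-break by class
    name order.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.means.shape[1]:
        raise ValueError(f"feature dimension {x.size} != model "
                         f"{model.means.shape[1]}")
    log_lik = -0.5 * (np.log(2 * np.pi * model.variances)
                      + (x - model.means) ** 2 / model.variances).sum(axis=1)
    log_post = np.log(model.priors) + log_lik
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    best = int(np.argmax(post))  # argmax returns the first (name-ordered) maximum
    return model.classes[best], post


@dataclass
class LooReport:
    """Leave-one-out evaluation summary."""

    labels: list[str]
    predicted: list[str]
    posteriors: np.ndarray
    classes: list[str]
    confusion: pd.DataFrame
    accuracy: float
    collapsed_accuracy: float
    collapsed_confusion: pd.DataFrame


def _collapse(label: str) -> str:
    return "stress" if label in STRESS_LABELS else label


def loo_evaluate(X: np.ndarray, labels: list[str],
                 uniform_priors: bool = False) -> LooReport:
    """Leave-one-out evaluation of the Gaussian NB classifier."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    for c in classes:
        if labels.count(c) < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    n = len(labels)
    predicted, posts = [], []
    for i in range(n):
        mask = np.arange(n) != i
        model = gnb_fit(X[mask], [labels[j] for j in range(n) if j != i],
                        uniform_priors=uniform_priors)
        lab, post = gnb_predict(model, X[i])
        # align posterior to the global class list (LOO folds keep all classes)
        aligned = np.zeros(len(classes))
        for k, c in enumerate(model.classes):
            aligned[classes.index(c)] = post[k]
        predicted.append(lab)
        posts.append(aligned)
    confusion = pd.crosstab(pd.Series(labels, name="true"),
                            pd.Series(predicted, name="predicted"),
                            dropna=False).reindex(index=classes, columns=classes,
                                                  fill_value=0)
    acc = float(np.mean([t == p for t, p in zip(labels, predicted)]))
    ct = [_collapse(t) for t in labels]
    cp = [_collapse(p) for p in predicted]
    c_classes = sorted(set(ct))
    collapsed = pd.crosstab(pd.Series(ct, name="true"),
                            pd.Series(cp, name="predicted"),
                            dropna=False).reindex(index=c_classes, columns=c_classes,
                                                  fill_value=0)
    cacc = float(np.mean([t == p for t, p in zip(ct, cp)]))
    return LooReport(labels=labels, predicted=predicted,
                     posteriors=np.array(posts), classes=classes,
                     confusion=confusion, accuracy=acc,
                     collapsed_accuracy=cacc, collapsed_confusion=collapsed)
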