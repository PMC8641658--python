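"""ROC discrimination: AUROC with DeLong variance and the paired DeLong test.

The AUROC is the Mann-Whitney estimator with midranks for ties (half credit),
which also admits the dichotomous early-dysfunction call as a degenerate
score.  Variances and the paired comparison use DeLong's structural
components, computed with the fast midrank formulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RocResult:
    auroc: float
    variance: float          # DeLong structural-component variance
    ci_low: float            # 95% Wald, clipped to [0, 1]
    ci_high: float
    n_events: int
    n_survivors: int
    orientation: str = "higher score = event"


@dataclass(frozen=True)
class PairedComparison:
    auroc_a: float
    auroc_b: float
    difference: float
    variance: float          # covariance-adjusted variance of the difference
    z: float
    p: float                 # two-sided


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong V10 (per event) and V01 (per survivor) components, plus AUROC.

    Uses the midrank identity: for event i,
    V10_i = (rank of x_i among all - rank among events) / n_survivors, and
    symmetrically for survivors.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return float(auc), v10, v01


def auroc(scores, labels) -> RocResult:
    """AUROC (higher score = event) with DeLong variance and 95% Wald CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_labels(labels)
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    half = 1.959963984540054 * np.sqrt(var)
    return RocResult(
        auroc=auc,
        variance=var,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        n_events=m,
        n_survivors=n,
    )


def brute_force_auroc(scores, labels) -> float:
    """Independent O(m*n) pairwise-indicator estimator (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins) / (pos.size * neg.size)


def delong_paired_test(scores_a, scores_b, labels) -> PairedComparison:
    """DeLong test for a difference between two correlated AUROCs measured on
    the same patients with the same labels.  Two-sided normal p-value."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores and labels must have equal length")
    _check_labels(labels)
    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return PairedComparison(auc_a, auc_b, diff, var, float(z), p)


def compare_all_models(
    scores_table: pd.DataFrame,
    labels: pd.Series,
    models: list[str] | None = None,
    holm: bool = False,
) -> tuple[dict[str, RocResult], pd.DataFrame]:
    """Per-model AUROC plus all pairwise DeLong p-values on the common
    complete-case subset (rows with every compared score present).

    ``scores_table`` is indexed by patient with one column per model;
    ``labels`` shares that index.  Models whose column is entirely missing
    are dropped with a warning.  ``holm`` applies a Holm correction to the
    pairwise p-values (off by default, matching the study's presentation).
    """
    if models is None:
        models = list(scores_table.columns)
    usable = []
    for model in models:
        if model not in scores_table or scores_table[model].isna().all():
            warnings.warn(f"model {model!r} has no scores; excluded from comparison")
            continue
        usable.append(model)
    complete = scores_table[usable].dropna()
    lab = labels.loc[complete.index].astype(int)
    if lab.nunique() < 2:
        raise ValueError("complete-case subset contains a single class")

    rocs = {m: auroc(complete[m].to_numpy(), lab.to_numpy()) for m in usable}
    rows = []
    for a, b in itertools.combinations(usable, 2):
        cmp = delong_paired_test(
            complete[a].to_numpy(), complete[b].to_numpy(), lab.to_numpy()
        )
        rows.append(
            {"model_a": a, "model_b": b, "auroc_a": cmp.auroc_a,
             "auroc_b": cmp.auroc_b, "difference": cmp.difference,
             "z": cmp.z, "p": cmp.p}
        )
    pairwise = pd.DataFrame(
        rows, columns=["model_a", "model_b", "auroc_a", "auroc_b", "difference", "z", "p"]
    )
    if holm and len(pairwise):
        order = np.argsort(pairwise["p"].to_numpy())
        k = len(order)
        adj = np.empty(k)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * pairwise["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        pairwise["p_holm"] = adj
    return rocs, pairwise
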