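"""Silhouette-based cluster validation and (k, r) model selection.

For object i with a_i = mean dissimilarity to the other members of its own
cluster and b_i = the smallest mean dissimilarity to any other cluster, the
silhouette width is

    s_i = (b_i - a_i) / max(a_i, b_i)  in [-1, 1]

(objects in singleton clusters take s_i = 0 by convention). The per-object
definition is Rousseeuw's; per-cluster and overall means summarize it. The
sweep fits the fuzzy clusterer over a grid of cluster counts k and
membership exponents r, hardens each solution, and selects the
configuration maximizing either the overall mean silhouette (default) or
the minimum per-cluster mean ("minmax" rule); ties break toward smaller k
then smaller r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .encoding import DissimilarityMatrix
from .fanny import FannyConfig, FannyResult, fanny_fit, harden

logger = logging.getLogger(__name__)

SelectRule = Literal["mean", "minmax"]

#: Membership exponents conventionally screened when selecting fuzziness.
DEFAULT_R_GRID: tuple[float, ...] = (1.5, 2, 2.5, 5, 7.5, 8, 8.1, 8.2, 8.5, 9, 10)


@dataclass
class SilhouetteReport:
    ids: list[str]
    s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    labels: np.ndarray
    cluster_means: dict[int, float] = field(default_factory=dict)
    overall_mean: float = float("nan")


def silhouette_samples(
    D: DissimilarityMatrix, labels: Sequence[int]
) -> SilhouetteReport:
    """Per-object silhouette widths from a dissimilarity matrix and labels."""
    labels = np.asarray(labels)
    if labels.shape[0] != D.n:
        raise ValueError("labels length does not match dissimilarity size")
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("silhouette undefined for a single cluster (k=1)")
    n = D.n
    Dv = D.values
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    sizes = {c: int(np.sum(labels == c)) for c in present}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            # singleton convention: s_i = 0, a_i undefined (kept 0)
            mask_other = labels != own
            b[i] = min(
                Dv[i, labels == c].mean() for c in present if c != own
            )
            s[i] = 0.0
            continue
        same = (labels == own) & (np.arange(n) != i)
        a[i] = Dv[i, same].mean()
        b[i] = min(Dv[i, labels == c].mean() for c in present if c != own)
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    report = SilhouetteReport(list(D.ids), s, a, b, labels.copy())
    report.cluster_means, report.overall_mean = silhouette_summary(report)
    return report


def silhouette_summary(
    report: SilhouetteReport,
) -> tuple[dict[int, float], float]:
    """Per-cluster mean silhouettes and the unweighted overall mean.

    The overall mean averages over objects, not over clusters, so large
    clusters carry proportionally more weight.
    """
    cluster_means = {
        int(c): float(report.s[report.labels == c].mean())
        for c in np.unique(report.labels)
    }
    return cluster_means, float(report.s.mean())


@dataclass
class SweepResult:
    table: pd.DataFrame
    selected_k: int | None
    selected_r: float | None
    results: dict[tuple[int, float], FannyResult] = field(default_factory=dict)


def sweep_parameters(
    D: DissimilarityMatrix,
    k_grid: Sequence[int],
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    select_rule: SelectRule = "mean",
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SweepResult:
    """Fit every (k, r) grid cell, score silhouettes, pick the best cell.

    Cells with k >= n are skipped with a warning. Degenerate geometry (all
    dissimilarities zero, or a hardened partition collapsing to one
    cluster) yields a flagged row with NaN silhouette rather than a
    selection candidate; if no cell is scoreable, no selection is made.
    """
    if not len(k_grid) or not len(r_grid):
        raise ValueError("k and r grids must be non-empty")
    rows = []
    results: dict[tuple[int, float], FannyResult] = {}
    for k in k_grid:
        if k >= D.n:
            logger.warning("skipping k=%d >= n=%d", k, D.n)
            continue
        for r in r_grid:
            config = FannyConfig(
                k=int(k), r=float(r), seed=seed, n_restarts=n_restarts,
                max_iter=max_iter, tol=tol,
            )
            res = fanny_fit(D, config)
            labels, _ = harden(res.membership)
            row = {
                "k": int(k), "r": float(r), "objective": res.objective,
                "converged": res.converged,
            }
            if len(np.unique(labels)) < 2 or not np.any(D.values > 0):
                row.update(mean_silhouette=np.nan, min_cluster_silhouette=np.nan,
                           flagged=True)
            else:
                rep = silhouette_samples(D, labels)
                row.update(
                    mean_silhouette=rep.overall_mean,
                    min_cluster_silhouette=min(rep.cluster_means.values()),
                    flagged=False,
                )
            logger.info(
                "sweep cell k=%d r=%.2f objective=%.6g silhouette=%s converged=%s",
                row["k"], row["r"], row["objective"], row["mean_silhouette"],
                row["converged"],
            )
            rows.append(row)
            results[(int(k), float(r))] = res
    table = pd.DataFrame(rows)
    stat = "mean_silhouette" if select_rule == "mean" else "min_cluster_silhouette"
    scoreable = table.dropna(subset=[stat]) if len(table) else table
    if len(scoreable) == 0:
        return SweepResult(table, None, None, results)
    # maximize the statistic; ties toward smaller k then smaller r
    ordered = scoreable.sort_values([stat, "k", "r"],
                                    ascending=[False, True, True])
    best = ordered.iloc[0]
    return SweepResult(table, int(best["k"]), float(best["r"]), results)
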