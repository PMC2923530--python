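"""Replicate averaging, average-linkage clustering and combined reporting.

The heatmap view of the stable-gene set works on replicate-averaged log2
intensities: each replicate group collapses to the mean of log2(intensity)
over its arrays (a small floor guards against log of sub-1 values). Genes
are then clustered agglomeratively with average linkage (UPGMA) on
Euclidean distance. Average linkage satisfies the reducibility property,
so merge heights are nondecreasing — the dendrogram has no inversions.

The merge tree is built with Lance-Williams updates
(d(u, k) = (|a| d(a,k) + |b| d(b,k)) / (|a|+|b|)) and a deterministic tie
rule: among minimal-distance pairs the one with the smallest (i, j) cluster
indices merges first, where leaves are numbered 0..n-1 in input order and
internal nodes n, n+1, ... in creation order.

Also here: the equal-variance two-sample t-test used to ask whether a
candidate reference gene shifts between two replicate groups (e.g. mock vs
infected), and the combined report joining geNORM M values with
entire-scope CVs — the two stability axes a final gene choice weighs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_expression_matrix

__all__ = [
    "ClusterResult",
    "TTestResult",
    "average_replicates_log2",
    "hierarchical_cluster",
    "two_group_t_test",
    "combined_report",
]


def average_replicates_log2(
    expr: pd.DataFrame, metadata: pd.DataFrame, floor: float = 1.0
) -> pd.DataFrame:
    """Mean of log2(max(intensity, floor)) per replicate group.

    Columns are replicate groups in metadata first-appearance order; every
    sample must map to a group with at least one member present in the
    matrix.
    """
    validate_expression_matrix(expr, metadata)
    if floor <= 0:
        raise ValueError("floor must be positive")
    groups = list(dict.fromkeys(metadata["replicate_group"]))
    logged = np.log2(expr.clip(lower=floor))
    out = {}
    for group in groups:
        samples = [
            s
            for s in metadata.loc[metadata["replicate_group"] == group, "sample_id"]
            if s in expr.columns
        ]
        if not samples:
            raise ValueError(f"replicate group {group!r} has no samples in the matrix")
        out[group] = logged.loc[:, samples].mean(axis=1)
    return pd.DataFrame(out, index=expr.index)


@dataclass
class ClusterResult:
    """Average-linkage merge tree over the rows of a matrix.

    ``merges`` lists (node_a, node_b, height, size) with leaves 0..n-1 and
    internal nodes numbered from n in creation order (scipy linkage layout);
    ``labels`` are the row ids; ``leaf_order`` is the left-to-right
    dendrogram order of the row ids.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    leaf_order: list[str]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def to_newick(self) -> str:
        """Simple nested-parentheses rendering with branch heights."""
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.merges):
            nodes[n + idx] = f"({nodes[a]},{nodes[b]}):{h:g}"
        return nodes[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage (UPGMA) clustering of rows on Euclidean distance.

    Deterministic for a given row order; ties in the minimal inter-cluster
    distance are broken by the smallest (i, j) index pair. Raises on
    non-finite values or fewer than 2 rows.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")
    labels = [str(r) for r in matrix.index]
    n = values.shape[0]

    # dense symmetric distance matrix, grown as clusters are created
    dist = {
        (i, j): float(np.linalg.norm(values[i] - values[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                i, j = (a, b) if a < b else (b, a)
                cand = (d(i, j), i, j)
                if best is None or cand < best:
                    best = cand
        h, i, j = best
        new = next_id
        next_id += 1
        children[new] = (i, j)
        size[new] = size[i] + size[j]
        merges.append((i, j, h, size[new]))
        active = [a for a in active if a not in (i, j)]
        for a in active:
            # Lance-Williams average-linkage update
            dist[(a, new) if a < new else (new, a)] = (
                size[i] * d(a, i) + size[j] * d(a, j)
            ) / (size[i] + size[j])
        active.append(new)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    leaf_order = [labels[i] for i in leaves(next_id - 1)]
    return ClusterResult(merges=merges, labels=labels, leaf_order=leaf_order)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    significant: bool


def two_group_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.01,
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided Student's t-test between two replicate intensity vectors.

    Equal-variance (pooled) by default; ``equal_var=False`` gives Welch.
    Two degenerate groups with zero variance and equal means return t = 0,
    p = 1 rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return TTestResult(statistic=0.0, pvalue=1.0, significant=False)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(statistic=float(t), pvalue=float(p), significant=bool(p < alpha))


def combined_report(
    m_values: Mapping[str, float] | pd.Series,
    stability: pd.DataFrame,
    scope: str = "entire",
) -> pd.DataFrame:
    """Join geNORM M values with per-gene CVs into one ranked report.

    Rows carry ``gene_id``, ``m``, ``cv`` and ``flag``. Genes present in
    both inputs sort by (M ascending, CV ascending); genes missing from one
    input are flagged ``*`` (the convention for genes not measured
    everywhere) and listed last, by gene id. Raises if the two gene sets do
    not overlap at all.
    """
    m = pd.Series(m_values, dtype=float)
    sub = stability[stability["partition"] == scope]
    cv = pd.Series(sub["cv"].to_numpy(), index=sub["gene_id"].to_numpy(), dtype=float)
    genes = sorted(set(m.index) | set(cv.index))
    overlap = set(m.index) & set(cv.index)
    if not overlap:
        raise ValueError("M-value and stability gene sets do not overlap")
    rows = []
    for g in genes:
        mg = float(m[g]) if g in m.index else np.nan
        cg = float(cv[g]) if g in cv.index else np.nan
        flagged = not (np.isfinite(mg) and np.isfinite(cg))
        rows.append((g, mg, cg, "*" if flagged else ""))
    complete = sorted(
        (r for r in rows if not r[3]), key=lambda r: (r[1], r[2], r[0])
    )
    flagged = sorted((r for r in rows if r[3]), key=lambda r: r[0])
    return pd.DataFrame(complete + flagged, columns=["gene_id", "m", "cv", "flag"])
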