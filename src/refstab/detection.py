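"""Probe-level present/absent detection calls and the compendium-wide filter.

Affymetrix-style arrays interrogate each transcript with a set of
perfect-match (PM) / mismatch (MM) probe pairs. Whether a transcript is
reliably detected in a sample is decided from the discrimination scores

    R_i = (PM_i - MM_i) / (PM_i + MM_i)

by a one-sided Wilcoxon signed-rank test of H0: median(R) = tau against
H1: median(R) > tau. Small p-values indicate presence; the p-value is
thresholded into the conventional Present / Marginal / Absent calls.

The compendium filter then retains exactly the genes whose detection
p-value clears a significance cut-off (default 0.05) in *every* array of
*every* replicate group — the first gate a candidate reference gene must
pass, since a transcript absent from any tissue cannot normalise it.

The signed-rank null is computed exactly (by convolution over the rank
values, which handles midranks from tied |R - tau|) for up to 25 informative
pairs; standard 11-pair probesets always take the exact path. Larger sets
fall back to the normal approximation with tie and continuity corrections.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_metadata

__all__ = [
    "DetectionParams",
    "discrimination_scores",
    "detection_pvalue",
    "call_from_p",
    "call_probes",
    "expressed_everywhere",
]

#: Largest number of informative pairs handled by the exact null.
EXACT_LIMIT = 25


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for detection calls and the compendium filter.

    ``tau`` is the small positive offset the median discrimination score must
    exceed; ``alpha_present``/``alpha_marginal`` partition the p-value axis
    into P/M/A calls; ``alpha_filter`` is the separate significance level
    applied by :func:`expressed_everywhere` (kept distinct because the
    compendium criterion is stated as p < 0.05, not as a P call).
    """

    tau: float = 0.015
    alpha_present: float = 0.04
    alpha_marginal: float = 0.06
    alpha_filter: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.alpha_present <= self.alpha_marginal < 0.5):
            raise ValueError(
                "need 0 < alpha_present <= alpha_marginal < 0.5, got "
                f"{self.alpha_present}, {self.alpha_marginal}"
            )
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


def discrimination_scores(pm: Iterable[float], mm: Iterable[float]) -> np.ndarray:
    """Per-pair discrimination scores R = (PM - MM)/(PM + MM).

    Scores lie in (-1, 1) and follow the probe order of the input. A pair
    with PM + MM == 0 carries no signal information; it is returned as NaN
    and excluded by :func:`detection_pvalue`.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape:
        raise ValueError("pm and mm must have the same length")
    total = pm + mm
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(total > 0, (pm - mm) / total, np.nan)
    return scores


@lru_cache(maxsize=4096)
def _exact_tail(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Null distribution of 2*W+ for the given doubled (mid)ranks.

    Returns ``counts`` with ``counts[s]`` = number of the 2^n equiprobable
    sign assignments whose positive-rank sum (doubled) equals ``s``.
    Doubling turns midranks (multiples of 0.5) into integers so the
    convolution is exact.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upper = 0
    for r in doubled_ranks:
        new = counts.copy()
        new[r : upper + r + 1] += counts[: upper + 1]
        counts = new
        upper += r
    return counts


def detection_pvalue(scores: Iterable[float], tau: float = 0.015) -> float:
    """One-sided signed-rank p-value for H1: median score > tau.

    Pairs with score exactly equal to ``tau`` (zero differences) are dropped
    before ranking; tied absolute differences receive midranks. Fewer than 3
    informative pairs make the test indeterminate, returned as NaN (the
    compendium filter treats NaN as Absent).
    """
    d = np.asarray(list(scores), dtype=float) - tau
    d = d[np.isfinite(d) & (d != 0)]
    n = d.size
    if n < 3:
        return float("nan")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= EXACT_LIMIT:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        counts = _exact_tail(doubled)
        w2 = int(round(2 * w_plus))
        return float(counts[w2:].sum() / 2.0**n)
    # normal approximation with tie and continuity corrections
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    z = (w_plus - mu - 0.5) / math.sqrt(sigma2)
    return float(stats.norm.sf(z))


def call_from_p(p: float, params: DetectionParams = DetectionParams()) -> str:
    """Map a detection p-value to a 'P'/'M'/'A' call (NaN counts as Absent)."""
    if not np.isfinite(p):
        return "A"
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < params.alpha_present:
        return "P"
    if p < params.alpha_marginal:
        return "M"
    return "A"


def call_probes(
    probes: pd.DataFrame, params: DetectionParams = DetectionParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection calls and p-values for every (probeset, sample) in a probe table.

    Parameters
    ----------
    probes
        Long-format table with columns ``probeset_id``, ``probe_index``,
        ``pm``, ``mm``, ``sample_id``.

    Returns
    -------
    calls, pvalues
        Two genes x samples frames sharing index and columns; gene order
        follows first appearance in the table, sample order likewise.
    """
    genes = list(dict.fromkeys(probes["probeset_id"]))
    samples = list(dict.fromkeys(probes["sample_id"]))
    pvals = pd.DataFrame(np.nan, index=genes, columns=samples)
    ordered = probes.sort_values("probe_index", kind="stable")
    for (gene, sample), grp in ordered.groupby(
        ["probeset_id", "sample_id"], sort=False
    ):
        scores = discrimination_scores(grp["pm"].to_numpy(), grp["mm"].to_numpy())
        pvals.at[gene, sample] = detection_pvalue(scores[np.isfinite(scores)], params.tau)
    calls = pvals.map(lambda p: call_from_p(p, params))
    pvals.index.name = calls.index.name = "probeset_id"
    return calls, pvals


def expressed_everywhere(
    pvalues: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha_filter: float = 0.05,
) -> list[str]:
    """Genes detected (p < alpha) in every replicate of every sample group.

    This is the compendium-wide expression filter: the returned list contains
    exactly the genes whose detection p-value is below ``alpha_filter`` in
    all samples covered by the metadata, in the row order of ``pvalues``.
    Missing (NaN) p-values fail the criterion.
    """
    validate_metadata(metadata)
    samples = [s for s in metadata["sample_id"] if s in pvalues.columns]
    unknown = set(pvalues.columns) - set(metadata["sample_id"])
    if unknown:
        raise ValueError(f"p-value columns absent from metadata: {sorted(unknown)}")
    if pvalues.empty or not samples:
        return []
    sub = pvalues.loc[:, samples].to_numpy()
    with np.errstate(invalid="ignore"):
        ok = np.all(sub < alpha_filter, axis=1)
    return [g for g, keep in zip(pvalues.index, ok) if keep]
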