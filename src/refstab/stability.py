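"""Partitioned CV statistics and the stable-gene / reference-gene selection.

For every gene the coefficient of variance CV = SD/mean is computed on
linear-scale normalized intensities over three sample scopes:

* ``development`` — arrays from organ/developmental studies,
* ``stress``      — the union of abiotic- and biotic-stress arrays,
* ``entire``      — all arrays, including hormone treatments.

A gene is *stably expressed* when its CV falls at or below the configured
cut-off (default 0.35 for every scope) in the development, stress and/or
entire scope — an OR-combination, so stability in any one scope suffices.
From the stable set, candidate reference genes for qPCR validation are
drawn as the lowest-CV genes per scope plus a seeded random draw from the
low-CV tail of the entire scope, each pick carrying a provenance tag.

The SD uses the n-1 (sample) denominator; because CV is a ratio of SD to
mean, every CV is invariant under a global positive rescaling of the
matrix, which is what makes it comparable across normalization choices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SCOPES, scope_samples, validate_expression_matrix, validate_metadata

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "partition_stats",
    "stability_table",
    "rank_by_cv",
    "select_stable",
]

#: Provenance tags attached to chosen reference genes, in pick order.
PROVENANCE_TAGS = (
    "lowest-CV-stress",
    "lowest-CV-development",
    "lowest-CV-entire",
    "random-below-cutoff",
)


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the reference-gene selection step.

    Defaults mirror the canonical screen: 2 lowest-CV genes from the stress
    scope, 2 from the development scope, 3 from the entire scope, and 4
    random extras drawn (seeded, without replacement) from stable genes with
    entire-scope CV at or below ``cv_cutoff_entire``. The only published
    cut-off value (0.35) is the default for every scope.
    """

    top_k_stress: int = 2
    top_k_development: int = 2
    top_k_entire: int = 3
    cv_cutoff_development: float = 0.35
    cv_cutoff_stress: float = 0.35
    cv_cutoff_entire: float = 0.35
    n_random_extra: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_k_stress", "top_k_development", "top_k_entire", "n_random_extra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cv_cutoff_development", "cv_cutoff_stress", "cv_cutoff_entire"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SelectionResult:
    """Outcome of the stability screen.

    ``stable_set`` preserves the gene order of the input tables;
    ``chosen`` has one row per reference-gene pick with columns ``gene_id``
    and ``provenance`` (tags are mutually exclusive: a gene picked by an
    earlier criterion is skipped by later ones).
    """

    stable_set: list[str]
    chosen: pd.DataFrame

    @property
    def chosen_gene_ids(self) -> list[str]:
        return list(self.chosen["gene_id"])


def partition_stats(
    expr: pd.DataFrame, metadata: pd.DataFrame, scope: str
) -> pd.DataFrame:
    """Per-gene mean, SD (n-1) and CV over the samples of one scope.

    Returns a frame with columns ``gene_id``, ``partition`` (the scope
    label), ``mean``, ``sd``, ``cv`` in the gene order of ``expr``. A gene
    whose scope mean is zero has undefined CV (NaN); such genes are excluded
    from selection downstream.
    """
    validate_expression_matrix(expr, metadata)
    samples = scope_samples(metadata, scope)
    samples = [s for s in samples if s in expr.columns]
    if not samples:
        raise ValueError(f"scope {scope!r} selects no samples present in the matrix")
    sub = expr.loc[:, samples]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean.to_numpy() != 0, sd.to_numpy() / mean.to_numpy(), np.nan)
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "partition": scope,
            "mean": mean.to_numpy(),
            "sd": sd.to_numpy(),
            "cv": cv,
        }
    ).reset_index(drop=True)


def stability_table(expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Stack :func:`partition_stats` for all three scopes into one table."""
    validate_metadata(metadata)
    return pd.concat(
        [partition_stats(expr, metadata, scope) for scope in SCOPES],
        ignore_index=True,
    )


def _scope_cv(stats: pd.DataFrame, scope: str) -> pd.Series:
    sub = stats[stats["partition"] == scope]
    if sub.empty:
        raise ValueError(f"stability table has no rows for scope {scope!r}")
    return pd.Series(sub["cv"].to_numpy(), index=sub["gene_id"].to_numpy())


def rank_by_cv(stats: pd.DataFrame, scope: str | None = None) -> list[str]:
    """Gene ids ordered by ascending CV, ties broken lexicographically.

    Genes with undefined CV (zero mean) are dropped — they cannot be ranked.
    ``scope`` restricts a stacked table to one scope; a single-scope table
    can be passed with ``scope=None``.
    """
    if scope is not None:
        stats = stats[stats["partition"] == scope]
    sub = stats.dropna(subset=["cv"])
    order = sorted(zip(sub["cv"], sub["gene_id"]))
    return [gene for _, gene in order]


def select_stable(
    stats: pd.DataFrame,
    universe: Iterable[str],
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Apply the stability screen and pick candidate reference genes.

    Parameters
    ----------
    stats
        Stacked stability table covering all three scopes for at least the
        genes of ``universe`` (the expressed-everywhere set).
    universe
        Genes that passed the detection filter, in a deterministic order
        (preserved in ``stable_set``).
    config
        Cut-offs, per-scope pick counts and the random-draw seed.

    Notes
    -----
    The stable set is the OR-combination over scopes of ``cv <= cutoff``.
    Per-scope picks take the ``top_k`` lowest-CV stable genes (ties by gene
    id); the random extras are sampled without replacement, seeded, from
    stable genes with entire-scope CV at or below the entire-scope cut-off
    that were not already chosen. If fewer candidates exist than requested,
    all available are returned with a warning.
    """
    universe = list(universe)
    cvs = {scope: _scope_cv(stats, scope) for scope in SCOPES}
    cutoffs = {
        "development": config.cv_cutoff_development,
        "stress": config.cv_cutoff_stress,
        "entire": config.cv_cutoff_entire,
    }
    for scope, series in cvs.items():
        missing = [g for g in universe if g not in series.index]
        if missing:
            raise ValueError(
                f"stability table lacks scope {scope!r} rows for genes {missing[:5]}"
            )

    def _stable(gene: str) -> bool:
        return any(
            np.isfinite(cvs[scope].get(gene, np.nan))
            and cvs[scope][gene] <= cutoffs[scope]
            for scope in SCOPES
        )

    stable_set = [g for g in universe if _stable(g)]
    stable = set(stable_set)

    picks: list[tuple[str, str]] = []
    taken: set[str] = set()

    def _take_lowest(scope: str, k: int, tag: str) -> None:
        ranked = [
            g
            for g in rank_by_cv(stats, scope)
            if g in stable and g not in taken
        ]
        for gene in ranked[:k]:
            picks.append((gene, tag))
            taken.add(gene)
        if len(ranked) < k:
            warnings.warn(
                f"requested {k} {tag} picks but only {len(ranked)} stable "
                "candidates were available",
                stacklevel=2,
            )

    _take_lowest("stress", config.top_k_stress, "lowest-CV-stress")
    _take_lowest("development", config.top_k_development, "lowest-CV-development")
    _take_lowest("entire", config.top_k_entire, "lowest-CV-entire")

    pool = sorted(
        g
        for g in stable
        if g not in taken
        and np.isfinite(cvs["entire"].get(g, np.nan))
        and cvs["entire"][g] <= config.cv_cutoff_entire
    )
    n_draw = min(config.n_random_extra, len(pool))
    if n_draw < config.n_random_extra:
        warnings.warn(
            f"requested {config.n_random_extra} random picks but only "
            f"{len(pool)} candidates remain below the entire-scope cut-off",
            stacklevel=2,
        )
    if n_draw:
        rng = np.random.default_rng(config.rng_seed)
        drawn = rng.choice(len(pool), size=n_draw, replace=False)
        for i in sorted(drawn):
            picks.append((pool[i], "random-below-cutoff"))

    chosen = pd.DataFrame(picks, columns=["gene_id", "provenance"])
    return SelectionResult(stable_set=stable_set, chosen=chosen)
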