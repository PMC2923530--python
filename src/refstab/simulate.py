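"""Seeded generator of a miniature multi-study expression compendium.

Emulates the statistical structure of a heterogeneous microarray
collection — many small studies, 2-4 replicates per biological sample
group, groups spanning development, abiotic stress, biotic stress and
hormone treatment — at desk scale, with known ground truth, so every
pipeline stage (detection calls, CV screening, selection, geNORM) can be
exercised and its recovery measured.

Intensities follow a log-normal model: for gene g on array s

    value_gs = 2 ** (base_g + batch_{g, study(s)} + effect_{g, group(s)} + eps),

with eps ~ N(0, sd_class(g)). The gene-by-study batch term is what makes a
multi-laboratory compendium harder than a single study: it inflates every
gene's CV without carrying biological signal. Four gene classes are
planted:

* ``stable`` — no group effects, small noise; the genes a screen should keep;
* ``responsive`` — each replicate group independently carries a +/-
  ``responsive_effect_log2`` shift with probability
  ``responsive_group_prob``, in every partition, modelling genes regulated
  across tissues and treatments alike; a screen should reject them;
* ``tissue_absent`` — expressed like stable genes except in 1-3 groups
  where they fall to near-background; the detection filter should remove
  them before CV is even considered;
* ``housekeeping_like`` — expressed everywhere with moderate noise,
  straddling the CV cut-off; neither guaranteed in nor out.

Probe-level PM/MM pairs are generated on top of the expression values with
per-probe affinities drawn once per probeset and reused across samples (so
detection calls are correlated within a probeset, as on real arrays):
PM = (signal * affinity + background) * u and MM = background * u' with
log-normal measurement noise u. Expressed genes yield median discrimination
scores far above tau; absent ones hover near zero.

Everything derives from one integer-seeded :func:`numpy.random.default_rng`
(PCG64) in a fixed order, so identical seeds give bitwise-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PARTITIONS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCompendium",
    "simulate_compendium",
    "simulate_ct",
]

GENE_CLASSES = ("stable", "responsive", "tissue_absent", "housekeeping_like")


def _default_groups() -> dict[str, int]:
    return {"development": 6, "abiotic": 5, "biotic": 3, "hormone": 2}


def _default_fractions() -> dict[str, float]:
    return {
        "stable": 0.1,
        "responsive": 0.4,
        "tissue_absent": 0.2,
        "housekeeping_like": 0.3,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters (all effect sizes in log2 units).

    Defaults define the study conditions the test-suite measures recovery
    under: 16 replicate groups across the four partitions, 2-4 replicates
    each, 500 genes split 10/40/20/30% over the four classes, base
    abundances uniform on 2^6..2^14, stable-gene noise SD 0.15, responsive
    shifts of +/-2 (i.e. 4-fold), gene-by-study batch SD 0.3, and 11
    PM/MM probe pairs per probeset.
    """

    n_studies: int = 8
    replicates_min: int = 2
    replicates_max: int = 4
    groups_per_partition: Mapping[str, int] = field(default_factory=_default_groups)
    n_genes: int = 500
    class_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    base_log2_mean_range: tuple[float, float] = (6.0, 14.0)
    stable_noise_sd_log2: float = 0.15
    responsive_noise_sd_log2: float = 0.25
    housekeeping_noise_sd_log2: float = 0.4
    responsive_effect_log2: float = 2.0
    responsive_group_prob: float = 0.5
    batch_sd_log2: float = 0.3
    absent_background_log2: float = 5.0
    absent_noise_sd_log2: float = 0.3
    probe_pairs: int = 11
    probe_affinity_sd_log2: float = 0.5
    probe_noise_sd_log2: float = 0.1
    probe_background: float = 30.0
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in GENE_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        for part in PARTITIONS:
            if self.groups_per_partition.get(part, 0) < 1:
                raise ValueError(f"partition {part!r} needs at least one group")
        if self.probe_pairs < 3:
            raise ValueError("probe_pairs must be >= 3")
        if not (1 <= self.replicates_min <= self.replicates_max):
            raise ValueError("need 1 <= replicates_min <= replicates_max")
        for name in (
            "stable_noise_sd_log2",
            "responsive_noise_sd_log2",
            "housekeeping_noise_sd_log2",
            "batch_sd_log2",
            "absent_noise_sd_log2",
            "probe_affinity_sd_log2",
            "probe_noise_sd_log2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genes < len(GENE_CLASSES):
            raise ValueError("n_genes too small for the four gene classes")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``classes`` maps gene -> class label; ``expected_expression`` is the
    noise-free linear expression per gene x group; ``expressed`` flags
    which (gene, group) cells are genuinely expressed (False only for the
    absent groups of tissue_absent genes).
    """

    classes: pd.Series
    expected_expression: pd.DataFrame
    expressed: pd.DataFrame

    def genes_of_class(self, label: str) -> list[str]:
        return list(self.classes.index[self.classes == label])

    def expressed_everywhere_genes(self) -> list[str]:
        mask = self.expressed.all(axis=1)
        return list(self.expressed.index[mask])


@dataclass
class SimulatedCompendium:
    expression: pd.DataFrame
    probes: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _assign_classes(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    counts = {
        c: int(np.floor(config.class_fractions[c] * config.n_genes))
        for c in GENE_CLASSES
    }
    short = config.n_genes - sum(counts.values())
    for c in GENE_CLASSES[:short]:
        counts[c] += 1
    labels = np.repeat(GENE_CLASSES, [counts[c] for c in GENE_CLASSES])
    rng.shuffle(labels)
    return labels


def simulate_compendium(config: SimulationConfig = SimulationConfig()) -> SimulatedCompendium:
    """Generate metadata, expression matrix, probe-level table and truth.

    All randomness flows from ``config.seed``; rerunning with the same
    config is bitwise-identical.
    """
    rng = np.random.default_rng(config.seed)

    # --- layout: groups, studies, replicates, samples -------------------
    groups: list[str] = []
    group_partition: dict[str, str] = {}
    for part in PARTITIONS:
        for i in range(config.groups_per_partition[part]):
            name = f"{part}_{i + 1:02d}"
            groups.append(name)
            group_partition[name] = part
    study_of_group = {
        g: f"study{int(k) + 1:02d}"
        for g, k in zip(groups, rng.integers(0, config.n_studies, size=len(groups)))
    }
    reps = rng.integers(
        config.replicates_min, config.replicates_max + 1, size=len(groups)
    )
    rows = []
    for g, r in zip(groups, reps):
        for j in range(int(r)):
            rows.append(
                {
                    "sample_id": f"{g}_r{j + 1}",
                    "study_id": study_of_group[g],
                    "replicate_group": g,
                    "partition": group_partition[g],
                }
            )
    metadata = pd.DataFrame(rows)
    samples = list(metadata["sample_id"])
    sample_group = metadata["replicate_group"].to_numpy()
    sample_study = metadata["study_id"].to_numpy()
    studies = sorted({study_of_group[g] for g in groups})
    study_idx = {s: i for i, s in enumerate(studies)}
    group_idx = {g: i for i, g in enumerate(groups)}

    # --- gene-level parameters ------------------------------------------
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    classes = _assign_classes(rng, config)
    lo, hi = config.base_log2_mean_range
    base = rng.uniform(lo, hi, size=config.n_genes)
    batch = rng.normal(0.0, config.batch_sd_log2, size=(config.n_genes, len(studies)))

    noise_sd = np.empty(config.n_genes)
    noise_sd[classes == "stable"] = config.stable_noise_sd_log2
    noise_sd[classes == "responsive"] = config.responsive_noise_sd_log2
    noise_sd[classes == "tissue_absent"] = config.responsive_noise_sd_log2
    noise_sd[classes == "housekeeping_like"] = config.housekeeping_noise_sd_log2

    effect = np.zeros((config.n_genes, len(groups)))
    resp = np.flatnonzero(classes == "responsive")
    hit = rng.random((resp.size, len(groups))) < config.responsive_group_prob
    sign = rng.choice([-1.0, 1.0], size=(resp.size, len(groups)))
    effect[resp] = hit * sign * config.responsive_effect_log2

    absent = np.zeros((config.n_genes, len(groups)), dtype=bool)
    for gi in np.flatnonzero(classes == "tissue_absent"):
        n_absent = int(rng.integers(1, 4))
        absent[gi, rng.choice(len(groups), size=n_absent, replace=False)] = True

    # --- expression matrix ----------------------------------------------
    g_of_s = np.array([group_idx[g] for g in sample_group])
    st_of_s = np.array([study_idx[s] for s in sample_study])
    eps = rng.normal(0.0, 1.0, size=(config.n_genes, len(samples))) * noise_sd[:, None]
    log2val = base[:, None] + batch[:, st_of_s] + effect[:, g_of_s] + eps
    absent_cells = absent[:, g_of_s]
    eps_abs = rng.normal(
        0.0, config.absent_noise_sd_log2, size=(config.n_genes, len(samples))
    )
    log2val = np.where(absent_cells, config.absent_background_log2 + eps_abs, log2val)
    expression = pd.DataFrame(
        np.power(2.0, log2val), index=pd.Index(genes, name="probeset_id"), columns=samples
    )

    # --- ground truth -----------------------------------------------------
    expected = np.power(2.0, base[:, None] + effect)
    expected = np.where(absent, 2.0**config.absent_background_log2, expected)
    truth = GroundTruth(
        classes=pd.Series(classes, index=genes, name="class"),
        expected_expression=pd.DataFrame(expected, index=genes, columns=groups),
        expressed=pd.DataFrame(~absent, index=genes, columns=groups),
    )

    # --- probe-level PM/MM table ----------------------------------------
    affinity = np.power(
        2.0,
        rng.normal(0.0, config.probe_affinity_sd_log2, size=(config.n_genes, config.probe_pairs)),
    )
    signal = np.where(absent_cells, 0.0, expression.to_numpy())
    u_pm = np.power(
        2.0,
        rng.normal(
            0.0,
            config.probe_noise_sd_log2,
            size=(config.n_genes, len(samples), config.probe_pairs),
        ),
    )
    u_mm = np.power(
        2.0,
        rng.normal(
            0.0,
            config.probe_noise_sd_log2,
            size=(config.n_genes, len(samples), config.probe_pairs),
        ),
    )
    bg = config.probe_background
    pm = (signal[:, :, None] * affinity[:, None, :] + bg) * u_pm
    mm = bg * u_mm
    n_g, n_s, n_p = pm.shape
    probes = pd.DataFrame(
        {
            "probeset_id": np.repeat(genes, n_s * n_p),
            "probe_index": np.tile(np.arange(1, n_p + 1), n_g * n_s),
            "pm": pm.reshape(-1),
            "mm": mm.reshape(-1),
            "sample_id": np.tile(np.repeat(samples, n_p), n_g),
        }
    )
    return SimulatedCompendium(
        expression=expression,
        probes=probes,
        metadata=metadata,
        truth=truth,
        config=config,
    )


def simulate_ct(
    truth: GroundTruth,
    genes: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    noise_sd_ct: float | Mapping[str, float] = 0.2,
    seed: int = 0,
    offset: float = 30.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table from the planted expected expression.

    Ct_gs = offset - log2(expected expression of gene g in group s) plus
    N(0, noise_sd) cycles; doubling the expected expression therefore
    lowers Ct by exactly 1 at zero noise. ``noise_sd_ct`` may be a scalar
    or a per-gene mapping (e.g. to plant one deliberately unstable gene
    with inflated noise). One column per replicate group (qPCR measures a
    pooled cDNA per sample), seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else list(truth.expected_expression.index)
    groups = (
        list(groups) if groups is not None else list(truth.expected_expression.columns)
    )
    missing = [g for g in genes if g not in truth.expected_expression.index]
    if missing:
        raise ValueError(f"unknown genes: {missing[:5]}")
    missing = [g for g in groups if g not in truth.expected_expression.columns]
    if missing:
        raise ValueError(f"unknown groups: {missing[:5]}")
    expected = truth.expected_expression.loc[genes, groups].to_numpy(dtype=float)
    if isinstance(noise_sd_ct, Mapping):
        sd = np.array([float(noise_sd_ct[g]) for g in genes])
    else:
        sd = np.full(len(genes), float(noise_sd_ct))
    noise = rng.normal(0.0, 1.0, size=expected.shape) * sd[:, None]
    ct = offset - np.log2(expected) + noise
    return pd.DataFrame(ct, index=pd.Index(genes, name="gene_id"), columns=groups)
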