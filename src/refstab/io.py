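"""Tabular data model and I/O for the reference-gene stability pipeline.

All interchange is TSV (tab-separated, UTF-8, one header row). In memory the
pipeline works on plain :class:`pandas.DataFrame` objects:

* **sample metadata** — one row per array with columns ``sample_id``,
  ``study_id``, ``replicate_group`` and ``partition`` (one of
  :data:`PARTITIONS`);
* **expression matrix** — probesets as the index, one column per
  ``sample_id``, linear-scale normalized intensities (no missing cells);
* **probe-level table** — long format with columns ``probeset_id``,
  ``probe_index``, ``pm``, ``mm``, ``sample_id`` (strictly positive PM/MM);
* **call / p-value matrices** — genes x samples of P/M/A letters and of
  detection p-values (two sibling files);
* **Ct table** — genes x samples of qPCR cycle-threshold values, blank cells
  meaning "not measured";
* **stability table** — long format with one row per (gene, scope) carrying
  mean, SD and CV = SD/mean.

Validation is performed at read time so downstream computation can assume
well-formed inputs. CV values are stored at full float precision; a 2-decimal
half-up display rendering (the field's reporting convention) is attached as a
separate column when the table is serialized.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd

#: The four biological partitions a compendium array can belong to.
PARTITIONS = ("development", "abiotic", "biotic", "hormone")

#: The three scopes over which per-gene stability statistics are computed.
#: ``stress`` is the union of the abiotic and biotic partitions; ``entire``
#: is every sample including hormone treatments.
SCOPES = ("development", "stress", "entire")

METADATA_COLUMNS = ("sample_id", "study_id", "replicate_group", "partition")
STABILITY_COLUMNS = ("gene_id", "partition", "mean", "sd", "cv")


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a metadata frame against the data-model invariants.

    Returns the frame unchanged so the call can be used inline. Raises
    :class:`ValidationError` on missing columns, duplicated ``sample_id`` or
    a ``partition`` outside :data:`PARTITIONS`.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata is missing columns: {missing}")
    dupes = metadata["sample_id"][metadata["sample_id"].duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate sample_id values: {sorted(set(dupes))}")
    bad = sorted(set(metadata["partition"]) - set(PARTITIONS))
    if bad:
        raise ValidationError(
            f"unknown partition labels {bad}; expected one of {list(PARTITIONS)}"
        )
    return metadata


def read_metadata(path: str | PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(metadata: pd.DataFrame, path: str | PathLike) -> None:
    validate_metadata(metadata)
    metadata.to_csv(path, sep="\t", index=False)


def scope_samples(metadata: pd.DataFrame, scope: str) -> list[str]:
    """Sample ids belonging to a stability scope, in metadata row order."""
    if scope == "development":
        mask = metadata["partition"] == "development"
    elif scope == "stress":
        mask = metadata["partition"].isin(["abiotic", "biotic"])
    elif scope == "entire":
        mask = pd.Series(True, index=metadata.index)
    else:
        raise ValueError(f"unknown scope {scope!r}; expected one of {list(SCOPES)}")
    return list(metadata.loc[mask, "sample_id"])


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression_matrix(
    expr: pd.DataFrame, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for gene in expr.index:
            for sample in expr.columns:
                try:
                    v = float(expr.at[gene, sample])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric value at gene {gene!r}, sample {sample!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValidationError(
                        f"non-finite value at gene {gene!r}, sample {sample!r}"
                    )
        raise ValidationError("expression matrix is not numeric")
    if np.isnan(values).any():
        gene, sample = _first_offender(expr, np.isnan(values))
        raise ValidationError(f"missing value at gene {gene!r}, sample {sample!r}")
    if (values < 0).any():
        gene, sample = _first_offender(expr, values < 0)
        raise ValidationError(f"negative intensity at gene {gene!r}, sample {sample!r}")
    if metadata is not None:
        validate_metadata(metadata)
        known = set(metadata["sample_id"])
        unknown = [s for s in expr.columns if s not in known]
        if unknown:
            raise ValidationError(
                f"expression columns absent from metadata: {unknown}"
            )
    return expr


def _first_offender(expr: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return expr.index[i], expr.columns[j]


def read_expression_matrix(
    path: str | PathLike, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a probeset x sample matrix, validating against ``metadata``.

    The file must have ``probeset_id`` as its first column and one column per
    sample. Row and column order are preserved from the file.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = "probeset_id"
    return validate_expression_matrix(expr, metadata)


def write_expression_matrix(expr: pd.DataFrame, path: str | PathLike) -> None:
    out = expr.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# probe-level tables
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ("probeset_id", "probe_index", "pm", "mm", "sample_id")


def validate_probe_table(probes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValidationError(f"probe table is missing columns: {missing}")
    if (probes["pm"] <= 0).any() or (probes["mm"] <= 0).any():
        raise ValidationError("PM/MM intensities must be strictly positive")
    sizes = probes.groupby(["probeset_id", "sample_id"]).size()
    small = sizes[sizes < 3]
    if len(small):
        key = small.index[0]
        raise ValidationError(
            f"probeset {key[0]!r} has only {small.iloc[0]} probe pairs in "
            f"sample {key[1]!r}; at least 3 are required"
        )
    return probes


def read_probe_table(path: str | PathLike) -> pd.DataFrame:
    probes = pd.read_csv(
        path,
        sep="\t",
        dtype={"probeset_id": str, "sample_id": str, "probe_index": int},
    )
    return validate_probe_table(probes)


def write_probe_table(probes: pd.DataFrame, path: str | PathLike) -> None:
    probes.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# call / p-value matrices
# ---------------------------------------------------------------------------

def read_pvalue_matrix(path: str | PathLike) -> pd.DataFrame:
    pvals = pd.read_csv(path, sep="\t", index_col=0)
    pvals.index = pvals.index.astype(str)
    with np.errstate(invalid="ignore"):
        bad = (pvals.to_numpy() < 0) | (pvals.to_numpy() > 1)
    if bad.any():
        gene, sample = _first_offender(pvals, bad)
        raise ValidationError(f"p-value outside [0, 1] at gene {gene!r}, sample {sample!r}")
    return pvals


def write_pvalue_matrix(pvals: pd.DataFrame, path: str | PathLike) -> None:
    out = pvals.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_call_matrix(path: str | PathLike) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls.index = calls.index.astype(str)
    bad = ~calls.isin(["P", "M", "A"]).to_numpy()
    if bad.any():
        gene, sample = _first_offender(calls, bad)
        raise ValidationError(f"call other than P/M/A at gene {gene!r}, sample {sample!r}")
    return calls


def write_call_matrix(calls: pd.DataFrame, path: str | PathLike) -> None:
    out = calls.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(path: str | PathLike) -> pd.DataFrame:
    """Read a gene x sample Ct table; blank cells become NaN (not measured)."""
    ct = pd.read_csv(path, sep="\t", index_col=0)
    ct.index = ct.index.astype(str)
    measured = ct.to_numpy()
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(measured) & (measured <= 0)
    if bad.any():
        gene, sample = _first_offender(ct, bad)
        raise ValidationError(f"non-positive Ct at gene {gene!r}, sample {sample!r}")
    return ct


def write_ct_table(ct: pd.DataFrame, path: str | PathLike) -> None:
    out = ct.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# stability tables
# ---------------------------------------------------------------------------

def format_cv(cv: float) -> str:
    """Render a CV at 2 decimals with half-up rounding (display convention).

    Computation always uses full precision; this rendering exists only for
    reports, where e.g. mean 991.9 and SD 210.2 print as CV ``0.21``.
    """
    if not np.isfinite(cv):
        return "NA"
    return str(Decimal(repr(float(cv))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_stability_table(table: pd.DataFrame, path: str | PathLike) -> None:
    """Serialize a stability table with an added 2-decimal ``cv_display`` column."""
    missing = [c for c in STABILITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"stability table is missing columns: {missing}")
    out = table.loc[:, list(STABILITY_COLUMNS)].copy()
    out["cv_display"] = [format_cv(v) for v in out["cv"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stability_table(path: str | PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "partition": str})
    missing = [c for c in STABILITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"stability table is missing columns: {missing}")
    return table


# ---------------------------------------------------------------------------
# plain gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
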