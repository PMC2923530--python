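"""geNORM-style expression-stability analysis for candidate reference genes.

Given positive relative quantities a_gs (gene g, sample s), the pairwise
variation between genes j and k is the standard deviation over samples of
log2(a_j/a_k). The stability measure of gene j is

    M_j = mean over k != j of V_jk,

the average of its pairwise variations. Because every statistic is built
from ratios, multiplying *all* genes in one sample by a constant (i.e. any
per-sample scaling such as cDNA input amount) cancels exactly — which is
the premise of the method: a pair of ideal reference genes has a constant
ratio in every sample, hence V_jk = 0.

Ranking proceeds by stepwise exclusion: the gene with the highest M among
those remaining is removed (ties broken by gene id) and its M at removal
recorded, until two genes remain; those two share one final M, since each
is the other's only partner. The number of reference genes to use is picked
from the pairwise-variation series V_{n/n+1}: the SD over samples of
log2(NF_n / NF_{n+1}), where NF_n is the per-sample geometric mean of the
n most stable genes. The smallest n >= 2 with V_{n/n+1} below the 0.15
convention is recommended.

qPCR Ct values feed the analysis through the standard efficiency transform
a_gs = E_g^(minCt_g - Ct_gs), so each gene's best (lowest-Ct) sample maps
to relative quantity 1. Missing Ct values propagate as missing quantities;
pairwise statistics then use pairwise-complete samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenormParams",
    "GenormResult",
    "ct_to_relative_quantity",
    "pairwise_variation",
    "stability_m",
    "stepwise_ranking",
    "normalization_factor",
    "pairwise_v_series",
    "run_genorm",
]


@dataclass(frozen=True)
class GenormParams:
    """``v_threshold`` is the V_{n/n+1} cut-off below which adding the
    (n+1)-th reference gene is judged unnecessary (0.15 by convention);
    ``log_base`` is fixed at 2 in this implementation."""

    v_threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.v_threshold <= 0:
            raise ValueError("v_threshold must be > 0")


@dataclass
class GenormResult:
    """Full output of a geNORM run.

    Attributes
    ----------
    m_values
        M of every gene computed on the *full* candidate set.
    exclusion_order
        ``(gene, M at removal)`` from least to most stable; the final two
        genes appear last, both carrying their shared M.
    ranking
        Genes from most to least stable (reverse of exclusion, final pair
        ordered by gene id).
    v_series
        V_{n/n+1} indexed by n = 2 .. G-1.
    recommended_n
        Smallest n >= 2 with V_{n/n+1} < v_threshold; equals G-1 with
        ``threshold_met == False`` when the series never drops below it.
    threshold_met
        Whether any V_{n/n+1} beat the threshold.
    """

    m_values: pd.Series
    exclusion_order: list[tuple[str, float]]
    ranking: list[str]
    v_series: pd.Series
    recommended_n: int
    threshold_met: bool


def ct_to_relative_quantity(
    ct: pd.DataFrame, efficiency: float | Mapping[str, float] = 2.0
) -> pd.DataFrame:
    """Transform Ct values into max-normalized relative quantities.

    a_gs = E_g ** (minCt_g - Ct_gs), so quantities lie in (0, 1] with the
    lowest-Ct sample of each gene at exactly 1. ``efficiency`` is the
    amplification efficiency per cycle (2.0 = perfect doubling), scalar or
    per-gene mapping; values must exceed 1. NaN Ct stays NaN.
    """
    out = pd.DataFrame(np.nan, index=ct.index, columns=ct.columns)
    for gene in ct.index:
        e = efficiency[gene] if isinstance(efficiency, Mapping) else efficiency
        if e <= 1:
            raise ValueError(f"amplification efficiency must be > 1 (gene {gene!r})")
        row = ct.loc[gene].astype(float)
        measured = row.dropna()
        if len(measured) < 2:
            raise ValueError(f"gene {gene!r} has fewer than 2 measured samples")
        out.loc[gene] = np.power(e, measured.min() - row)
    return out


def _log_ratio(a_j: np.ndarray, a_k: np.ndarray) -> np.ndarray:
    """log2 ratios over pairwise-complete samples."""
    a_j = np.asarray(a_j, dtype=float)
    a_k = np.asarray(a_k, dtype=float)
    ok = np.isfinite(a_j) & np.isfinite(a_k)
    a_j, a_k = a_j[ok], a_k[ok]
    if np.any(a_j <= 0) or np.any(a_k <= 0):
        raise ValueError("relative quantities must be strictly positive")
    return np.log2(a_j / a_k)


def pairwise_variation(a_j: Sequence[float], a_k: Sequence[float]) -> float:
    """V_jk = SD (n-1 denominator) over samples of log2(a_j/a_k).

    Symmetric in its arguments and zero iff the two genes are exactly
    proportional across samples. Requires >= 2 pairwise-complete samples.
    """
    ratios = _log_ratio(np.asarray(a_j), np.asarray(a_k))
    if ratios.size < 2:
        raise ValueError("pairwise variation needs >= 2 common measured samples")
    return float(np.std(ratios, ddof=1))


def _pairwise_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Symmetric G x G matrix of V_jk (zero diagonal).

    With complete data each row of V is the SD of the log-ratio differences
    x_j - x_k computed in one vectorized sweep (numerically identical to the
    per-pair definition, including the exact zero for proportional genes);
    with missing values it falls back to pairwise-complete computation.
    """
    values = matrix.to_numpy(dtype=float)
    genes = list(matrix.index)
    g = len(genes)
    if np.any(np.isfinite(values) & (values <= 0)):
        raise ValueError("relative quantities must be strictly positive")
    if np.all(np.isfinite(values)):
        x = np.log2(values)
        if x.shape[1] < 2:
            raise ValueError("pairwise variation needs >= 2 common measured samples")
        v = np.zeros((g, g))
        for i in range(g):
            v[i] = np.std(x[i][None, :] - x, axis=1, ddof=1)
        v = (v + v.T) / 2  # symmetrize away any last-bit asymmetry
        np.fill_diagonal(v, 0.0)
        return v
    v = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            try:
                v[i, j] = v[j, i] = pairwise_variation(values[i], values[j])
            except ValueError as err:
                raise ValueError(
                    f"pairwise variation undefined for genes "
                    f"({genes[i]!r}, {genes[j]!r}): {err}"
                ) from None
    return v


def _m_values(matrix: pd.DataFrame) -> pd.Series:
    genes = list(matrix.index)
    if len(genes) < 3:
        raise ValueError("stability M needs at least 3 genes")
    v = _pairwise_matrix(matrix)
    m = v.sum(axis=1) / (len(genes) - 1)
    return pd.Series(m, index=genes, name="M")


def stability_m(matrix: pd.DataFrame, gene: str | None = None) -> pd.Series | float:
    """M value(s) on a genes x samples quantity matrix.

    With ``gene=None`` returns the full Series; with a gene id returns that
    gene's M as a float.
    """
    m = _m_values(matrix)
    return m if gene is None else float(m[gene])


def stepwise_ranking(matrix: pd.DataFrame) -> GenormResult:
    """Iterative exclusion of the least stable gene.

    At each step M is recomputed on the remaining genes and the gene with
    the highest M is removed; ties on M are broken by gene id, the
    lexicographically greater id being treated as less stable, so runs are
    fully deterministic. Stops when two genes remain; both are recorded
    with their shared M (each is then the other's only partner).
    The returned result has an empty ``v_series`` — use
    :func:`pairwise_v_series` or :func:`run_genorm` for the full analysis.
    """
    if len(matrix.index) < 3:
        raise ValueError("stepwise ranking needs at least 3 genes")
    genes = list(matrix.index)
    v = _pairwise_matrix(matrix)  # V_jk is independent of the remaining set
    full_m = pd.Series(v.sum(axis=1) / (len(genes) - 1), index=genes, name="M")
    idx = {g: i for i, g in enumerate(genes)}
    remaining = list(genes)
    exclusion: list[tuple[str, float]] = []
    while len(remaining) > 2:
        rows = [idx[g] for g in remaining]
        m = v[np.ix_(rows, rows)].sum(axis=1) / (len(remaining) - 1)
        worst_pos = max(range(len(remaining)), key=lambda p: (m[p], remaining[p]))
        exclusion.append((remaining[worst_pos], float(m[worst_pos])))
        remaining.pop(worst_pos)
    final_pair = sorted(remaining)
    final_m = pairwise_variation(
        matrix.loc[final_pair[0]].to_numpy(), matrix.loc[final_pair[1]].to_numpy()
    )
    # least stable of the pair listed first so exclusion_order stays
    # least-to-most stable end to end
    exclusion.append((final_pair[1], final_m))
    exclusion.append((final_pair[0], final_m))
    ranking = [g for g, _ in reversed(exclusion)]
    return GenormResult(
        m_values=full_m,
        exclusion_order=exclusion,
        ranking=ranking,
        v_series=pd.Series(dtype=float),
        recommended_n=0,
        threshold_met=False,
    )


def normalization_factor(matrix: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the chosen genes' quantities.

    Only samples measured for *all* chosen genes get a factor; others are
    NaN. Multiplying one chosen gene by c scales every factor by c^(1/n).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("normalization factor needs at least 2 genes")
    sub = matrix.loc[genes].to_numpy(dtype=float)
    if np.any(np.isfinite(sub) & (sub <= 0)):
        raise ValueError("relative quantities must be strictly positive")
    with np.errstate(invalid="ignore"):
        nf = np.exp(np.mean(np.log(sub), axis=0))
    return pd.Series(nf, index=matrix.columns, name=f"NF{len(genes)}")


def pairwise_v_series(
    matrix: pd.DataFrame,
    ranking: Sequence[str],
    params: GenormParams = GenormParams(),
) -> tuple[pd.Series, int, bool]:
    """V_{n/n+1} series and the recommended number of reference genes.

    V_{n/n+1} is the SD over samples of log2(NF_n / NF_{n+1}) with NF built
    from the n most stable genes of ``ranking`` (best first). The
    recommendation is the smallest n >= 2 with V below ``params.v_threshold``;
    if the series never meets it, G-1 is returned flagged ``met=False``.
    """
    ranking = list(ranking)
    g = len(ranking)
    if g < 3:
        raise ValueError("V series needs at least 3 ranked genes")
    vs = {}
    for n in range(2, g):
        nf_n = normalization_factor(matrix, ranking[:n])
        nf_n1 = normalization_factor(matrix, ranking[: n + 1])
        ratios = _log_ratio(nf_n.to_numpy(), nf_n1.to_numpy())
        if ratios.size < 2:
            raise ValueError(f"V_{n}/{n + 1} has fewer than 2 complete samples")
        vs[n] = float(np.std(ratios, ddof=1))
    series = pd.Series(vs, name="V").sort_index()
    met = bool((series < params.v_threshold).any())
    if met:
        recommended = int(series.index[series < params.v_threshold][0])
    else:
        recommended = g - 1
    return series, recommended, met


def run_genorm(
    matrix: pd.DataFrame, params: GenormParams = GenormParams()
) -> GenormResult:
    """Complete geNORM analysis: ranking plus V series on one matrix."""
    result = stepwise_ranking(matrix)
    v_series, recommended, met = pairwise_v_series(matrix, result.ranking, params)
    result.v_series = v_series
    result.recommended_n = recommended
    result.threshold_met = met
    return result
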