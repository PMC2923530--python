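"""End-to-end orchestration: simulate -> detect -> filter -> select -> geNORM.

Thin glue over the analysis modules, used by the command-line interface and
by reproducibility checks. Every artifact is written as TSV (or a plain
gene list) so a whole run can be compared byte-for-byte against another.
"""
from __future__ import annotations

from os import PathLike
from pathlib import Path

from . import cluster, detection, genorm, io, stability
from .simulate import SimulatedCompendium, SimulationConfig, simulate_compendium, simulate_ct

__all__ = ["run_pipeline"]


def run_pipeline(
    out_dir: str | PathLike,
    sim_config: SimulationConfig = SimulationConfig(),
    detection_params: detection.DetectionParams = detection.DetectionParams(),
    selection_config: stability.SelectionConfig = stability.SelectionConfig(),
    genorm_params: genorm.GenormParams = genorm.GenormParams(),
    ct_seed: int = 0,
    write_probes: bool = False,
) -> dict[str, object]:
    """Run the full screen on a simulated compendium and write artifacts.

    Writes into ``out_dir``: ``meta.tsv``, ``expr.tsv``, ``pvals.tsv``,
    ``calls.tsv``, ``expressed.txt``, ``stability.tsv``, ``stable_set.txt``,
    ``selection.tsv``, ``ct.tsv``, ``genorm_m.tsv``, ``genorm_v.tsv``,
    ``cluster_order.txt``, ``cluster.nwk``, ``report.tsv`` (and optionally
    the large ``probes.tsv``). Returns the in-memory results keyed by stage.

    Determinism: with identical configs and seeds a second run produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim: SimulatedCompendium = simulate_compendium(sim_config)
    io.write_metadata(sim.metadata, out / "meta.tsv")
    io.write_expression_matrix(sim.expression, out / "expr.tsv")
    if write_probes:
        io.write_probe_table(sim.probes, out / "probes.tsv")

    calls, pvals = detection.call_probes(sim.probes, detection_params)
    io.write_call_matrix(calls, out / "calls.tsv")
    io.write_pvalue_matrix(pvals, out / "pvals.tsv")

    expressed = detection.expressed_everywhere(
        pvals, sim.metadata, detection_params.alpha_filter
    )
    io.write_gene_list(expressed, out / "expressed.txt")

    stats = stability.stability_table(sim.expression, sim.metadata)
    io.write_stability_table(stats, out / "stability.tsv")
    selection = stability.select_stable(stats, expressed, selection_config)
    io.write_gene_list(selection.stable_set, out / "stable_set.txt")
    selection.chosen.to_csv(out / "selection.tsv", sep="\t", index=False)

    # qPCR validation of the chosen panel on the simulated ground truth
    panel = selection.chosen_gene_ids
    ct = simulate_ct(sim.truth, genes=panel, seed=ct_seed)
    io.write_ct_table(ct, out / "ct.tsv")
    quantities = genorm.ct_to_relative_quantity(ct)
    gres = genorm.run_genorm(quantities, genorm_params)
    gres.m_values.rename_axis("gene_id").to_frame().to_csv(
        out / "genorm_m.tsv", sep="\t", float_format="%.17g"
    )
    gres.v_series.rename_axis("n").to_frame().to_csv(
        out / "genorm_v.tsv", sep="\t", float_format="%.17g"
    )

    # cluster the stable set on replicate-averaged log2 values
    averaged = cluster.average_replicates_log2(sim.expression, sim.metadata)
    clustered = cluster.hierarchical_cluster(averaged.loc[selection.stable_set])
    io.write_gene_list(clustered.leaf_order, out / "cluster_order.txt")
    (out / "cluster.nwk").write_text(clustered.to_newick() + "\n", encoding="utf-8")

    report = cluster.combined_report(gres.m_values, stats)
    report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.17g")

    return {
        "simulation": sim,
        "pvalues": pvals,
        "expressed": expressed,
        "stability": stats,
        "selection": selection,
        "ct": ct,
        "genorm": gres,
        "cluster": clustered,
        "report": report,
    }
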