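"""Published rice reference-gene panel statistics.

A compact copy of the published candidate-reference-gene panel for rice
(*Oryza sativa*): 26 genes — 12 novel stably-expressed candidates plus 14
previously proposed or commonly used reference genes such as Actin,
polyubiquitin, GAPDH and EF1 — with the mean, standard deviation and CV of
their GC-RMA normalized signal over a 331-array Affymetrix compendium, and
the geNORM M value where one was reported. Four rows are unnumbered sibling
probesets of panel genes that share a transcript.

These printed statistics serve as a fixed-point check: recomputing
CV = SD/mean from the printed mean and SD and rounding half-up to two
decimals must reproduce the printed CV for every row.
"""
from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["rice_reference_panel"]

# columns: gene_no (blank for sibling probesets), probeset_id, tigr_id,
# description, mean, sd, cv (printed, 2 dp), mv (printed geNORM M or blank),
# novel (True = candidate defined by the compendium screen)
_PANEL_TSV = """\
gene_no	probeset_id	tigr_id	description	mean	sd	cv	mv	novel
1	Os.10676.1.S1_a_at	LOC_Os06g11170.1	Nucleic acid binding protein	991.9	210.2	0.21	0.25	True
2	Os.8912.1.S1_at	LOC_Os06g48970.1	Protein kinase	453.3	96.8	0.21	0.50	True
3	Os.6.1.S1_a_at	LOC_Os11g43900.1	Tumor protein homolog	13137.5	3692.7	0.28	0.66	True
	Os.6.1.S1_x_at		Tumor protein homolog	13870.8	3368.4	0.24		True
	Os.12625.2.S1_x_at		NA	18285.5	4473.7	0.24		True
4	Os.12237.2.S1_a_at	LOC_Os06g47230.1	Expressed protein	18251.2	4481.0	0.25	0.30	True
	Os.12237.1.S1_a_at		Expressed protein	22019.9	5294.2	0.24		True
5	Os.46231.2.S1_x_at	LOC_Os03g46770.1	RNA-binding protein	17176.5	4280.7	0.25	0.68	True
	Os.46231.1.S1_a_at		RNA-binding protein	22461.1	5636.0	0.25		True
6	Os.6860.1.S1_at	LOC_Os11g21990.1	Eukaryotic initiation factor 5C	6969.6	1967.0	0.28	0.54	True
7	Os.7945.1.S1_at	LOC_Os07g34589.1	Translation factor SUI1	24678.2	7030.8	0.28	0.61	True
8	Os.12409.1.S1_at	LOC_Os07g02340.1	Expressed protein	11392.3	3488.8	0.31	0.44	True
9	Os.37924.1.S1_x_at	LOC_Os11g26910.1	SKP1-like protein 1A	8488.5	2713.8	0.32	0.85	True
10	Os.12382.1.S1_at	LOC_Os12g32950.1	Membrane protein	6550.4	2258.4	0.34	0.59	True
11	Os.8092.1.S1_at	LOC_Os05g48960.1	Splicing factor U2af	4051.7	1403.7	0.35	0.49	True
12	Os.12151.1.S1_at	LOC_Os06g43650.1	Expressed protein	4504.6	1581.7	0.35	0.39	True
13	AFFX-Os-actin-3_s_at	LOC_Os03g50890.1	Actin	9556.3	5719.5	0.60	0.97	False
14	Os.11355.1.S1_at	LOC_Os05g36290.1	Actin1	1842.8	1471.3	0.80	0.79	False
15	Os.9504.1.S1_at	LOC_Os07g38730.1	Alpha-tubulin	5400.3	3466.6	0.64	0.76	False
16	Os.10139.1.S1_s_at	LOC_Os06g46770.1	Polyubiquitin	15085.3	6524.3	0.43	0.47	False
17	Os.7899.1.S1_at	LOC_Os02g16040.1	Ubiquitin	2598.8	1135.4	0.44	0.63	False
18	Os.22781.1.S1_at	LOC_Os02g38920.1	GAPDH	11640.8	8346.8	0.72	1.09	False
19	Os.10158.1.S1_at	LOC_Os07g43730.1	EF1	5619.9	2549.3	0.45	0.52	False
20	Os.10385.1.S1_at	LOC_Os03g55270.1	TIP41-like	482.7	274.5	0.57	0.42	False
21	Os.5500.1.S1_s_at	LOC_Os08g23180.1	Arabinogalactan protein	4957.5	3114.1	0.63	0.90	False
22	Os.12835.2.S1_a_at	LOC_Os07g42300.1	EF1d	6073.3	3003.7	0.49	0.82	False
23	Os.19618.1.S1_at	LOC_Os01g39260.1	FtsH protease	1487.4	725.5	0.49	0.57	False
24	Os.7952.1.S1_at	LOC_Os03g25980.1	Nucleotide tract-binding protein	607.8	241.8	0.40	0.56	False
25	Os.22806.1.S1_s_at	LOC_Os02g46510.1	AP-2 complex subunit	1550.2	744.5	0.48	0.64	False
26	Os.13910.1.S1_at	LOC_Os03g21210.1	endo-1,4-beta-glucanase	900.7	1063.3	1.18	0.72	False
"""


def rice_reference_panel() -> pd.DataFrame:
    """The published rice reference-gene panel as a DataFrame.

    Columns: ``gene_no`` (nullable), ``probeset_id``, ``tigr_id``,
    ``description``, ``mean``, ``sd``, ``cv`` (printed, 2 dp), ``mv``
    (printed geNORM M, nullable) and ``novel``.
    """
    panel = pd.read_csv(
        StringIO(_PANEL_TSV),
        sep="\t",
        dtype={"probeset_id": str, "tigr_id": str, "description": str},
    )
    panel["novel"] = panel["novel"].astype(bool)
    return panel
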