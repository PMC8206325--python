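"""Published per-plot summary tables from the common-vole road-barrier field
study (30 plots: 15 experimental/control pairs; values printed at 2 dp).

The raw genotypes of that study are not publicly deposited, so these printed
plot-level summaries are the only real-data inputs available to the paired
inference layer: per-plot sample sizes on each barrier side (Na, Nb), mean
alleles per locus (A), observed/expected/unbiased-expected heterozygosity
(Ho, He, uHe), rarefied allelic richness (Ar) and the inbreeding coefficient
(F_IS), plus a per-locus panel (allele counts, Ho, uHe, F_IS and the
duplicate-genotyping dropout/false-allele rates E1, E2).

Plot codes: CB = combined barrier, H = 4-lane highway, R = 2-lane road; a
trailing "c" marks the paired control plot (treatment T, bisected by an
unpaved track).
"""

from __future__ import annotations

import io

import pandas as pd

_PLOT_TSV = """\
plot	Na	Nb	A	Ho	He	uHe	Ar	Fis
CB1	47	61	15.00	0.83	0.83	0.84	11.05	0.00
CB1c	24	20	12.78	0.82	0.82	0.83	10.91	0.00
CB2	35	18	12.89	0.80	0.81	0.82	10.74	0.02
CB2c	20	23	12.33	0.82	0.82	0.83	10.62	0.00
CB3	21	18	10.89	0.78	0.81	0.82	9.87	0.04
CB3c	41	27	12.22	0.78	0.80	0.81	10.13	0.04
H1	23	20	10.67	0.78	0.78	0.79	9.44	0.02
H1c	27	43	11.89	0.79	0.79	0.80	9.93	0.02
H2	32	33	12.89	0.80	0.81	0.82	10.56	0.02
H2c	15	17	10.22	0.81	0.81	0.82	9.47	-0.01
H3	26	27	13.67	0.79	0.82	0.83	11.47	0.05
H3c	33	34	12.78	0.80	0.82	0.83	10.63	0.02
H4	41	43	11.22	0.76	0.78	0.79	9.37	0.04
H4c	19	36	11.11	0.76	0.78	0.79	9.39	0.04
H5	46	27	11.11	0.79	0.80	0.80	9.29	0.01
H5c	33	22	10.56	0.78	0.78	0.79	9.26	0.01
H6	13	26	10.33	0.78	0.79	0.80	9.22	-0.01
H6c	33	15	11.44	0.76	0.80	0.81	9.67	0.06
R1	23	28	11.67	0.81	0.81	0.82	10.00	-0.01
R1c	33	23	11.44	0.78	0.78	0.79	9.61	-0.01
R2	18	14	10.11	0.77	0.77	0.78	9.17	0.00
R2c	18	18	9.89	0.79	0.79	0.80	9.11	-0.02
R3	19	21	9.78	0.73	0.76	0.77	8.83	0.06
R3c	22	29	10.67	0.77	0.78	0.79	9.41	0.01
R4	23	18	11.11	0.80	0.80	0.81	9.96	0.01
R4c	15	11	10.22	0.76	0.78	0.80	9.88	0.05
R5	64	30	12.11	0.79	0.81	0.81	10.07	0.03
R5c	72	72	13.67	0.82	0.82	0.82	10.49	-0.01
R6	16	6	10.11	0.83	0.79	0.81	10.11	-0.07
R6c	32	14	11.67	0.78	0.79	0.80	10.11	0.02
"""

_LOCUS_TSV = """\
locus	size_low	size_high	A	Ho	uHe	Fis	E1	E2
Ma09	72	118	24	0.864	0.860	-0.016	0.009	0.029
Mar102	354	422	22	0.865	0.873	-0.001	0.008	0.016
Mar012	77	139	28	0.851	0.904	0.049	0.000	0.012
Mar003	142	180	20	0.884	0.899	0.005	0.003	0.015
Mar063	270	280	7	0.345	0.359	0.039	0.013	0.012
Mar016	160	186	14	0.799	0.802	-0.007	0.000	0.016
MM6	147	179	18	0.833	0.852	0.012	0.006	0.019
Ma54	189	225	18	0.772	0.814	0.043	0.030	0.003
Ma66	226	284	27	0.878	0.891	0.003	0.023	0.005
"""

# sample accounting of the field study's filtering chain
N_TRAPPED = 1757
N_FAILED_GENOTYPING = 63
N_FULL_SIB_DISCARDED = 16
N_RETAINED = 1678


def load_plot_summaries() -> pd.DataFrame:
    """Per-plot diversity summary with pair/role/treatment metadata attached."""
    df = pd.read_csv(io.StringIO(_PLOT_TSV), sep="\t", dtype={"plot": str})
    df["role"] = df["plot"].map(lambda p: "control" if p.endswith("c") else "experimental")
    df["pair_id"] = df["plot"].str.rstrip("c")
    df["treatment"] = df.apply(
        lambda r: "T" if r["role"] == "control" else r["pair_id"].rstrip("0123456789"),
        axis=1)
    df["n"] = df["Na"] + df["Nb"]
    return df


def load_locus_summary() -> pd.DataFrame:
    """Per-locus allelic panel: allele size range, A, Ho, uHe, F_IS, E1, E2."""
    return pd.read_csv(io.StringIO(_LOCUS_TSV), sep="\t", dtype={"locus": str})


def plot_metric_table(metrics=("Ho", "uHe", "Ar")) -> pd.DataFrame:
    """Published plot summaries as a long metric table for the inference layer."""
    df = load_plot_summaries()
    rows = []
    for _, r in df.iterrows():
        for m in metrics:
            rows.append({"plot": r["plot"], "pair_id": r["pair_id"],
                         "treatment": r["treatment"], "role": r["role"],
                         "metric": m, "value": float(r[m])})
    return pd.DataFrame(rows)
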