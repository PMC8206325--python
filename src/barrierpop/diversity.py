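"""Population- and individual-level genetic diversity metrics.

Per-locus quantities (observed heterozygosity Ho, Nei expected
heterozygosity He = 1 - sum p_i^2, its small-sample-unbiased form
uHe = 2n/(2n-1) * He, allele counts, hypergeometric rarefied allelic
richness Ar, and the within-population inbreeding coefficient F_IS) are
averaged over loci with standard errors across loci, per plot and per barrier
side.  The paired-design summary is the absolute between-side difference of
each metric (one "_DIF" value per plot).

Individual-level heterozygosity follows the classical multilocus panel:
proportion of heterozygous loci (PHt), standardized heterozygosity relative
to the mean observed (Hs_obs) and mean unbiased expected (Hs_exp)
heterozygosity of the typed loci, internal relatedness (IR), and
homozygosity by locus (HL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .genotype_io import MISSING, Dataset, split_by_side

PLOT_METRICS = ("A", "Ho", "He", "uHe", "Ar", "Fis")


class DiversityError(ValueError):
    pass


# -- allele bookkeeping ----------------------------------------------------

def allele_counts(genotypes: np.ndarray) -> dict[int, int]:
    """Allele -> gene-copy count at one locus; genotypes is (n, 2), 0=missing."""
    flat = genotypes.reshape(-1)
    flat = flat[flat != MISSING]
    vals, cnt = np.unique(flat, return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def allele_frequencies(genotypes: np.ndarray) -> tuple[dict[int, float], int]:
    """Allele frequencies and the gene-copy count at one locus.

    The count equals twice the number of non-missing genotypes; all-missing
    input raises :class:`DiversityError`.
    """
    counts = allele_counts(genotypes)
    n = sum(counts.values())
    if n == 0:
        raise DiversityError("all genotypes missing at locus")
    return {a: c / n for a, c in counts.items()}, n


# -- per-locus statistics --------------------------------------------------

def _locus_stats(genotypes: np.ndarray) -> dict:
    """Ho/He/uHe/allele count and W&C F_IS ingredients for one locus."""
    typed = genotypes[genotypes[:, 0] != MISSING]
    n = typed.shape[0]
    if n == 0:
        return dict(n=0, A=np.nan, Ho=np.nan, He=np.nan, uHe=np.nan, Fis=np.nan)
    het = typed[:, 0] != typed[:, 1]
    ho = float(het.mean())
    freqs, ncop = allele_frequencies(typed)
    p = np.array(list(freqs.values()))
    he = float(1.0 - (p ** 2).sum())
    uhe = he * 2 * n / (2 * n - 1) if n > 1 else np.nan
    return dict(n=n, A=len(freqs), Ho=ho, He=he, uHe=uhe,
                Fis=_wc_fis_locus(typed, freqs, ho))


def _wc_fis_locus(typed: np.ndarray, freqs: dict[int, float], ho: float) -> float:
    """Weir & Cockerham (1984) small-sample within-population f for one locus.

    With a single sample the estimator reduces to f = 1 - sum_c / sum_(b+c)
    over alleles, with b the between-individual and c the within-individual
    component.  Undefined (NaN) for monomorphic loci.
    """
    n = typed.shape[0]
    if len(freqs) < 2 or n < 2:
        return np.nan
    num = den = 0.0
    for a, p in freqs.items():
        h_a = float(((typed[:, 0] != typed[:, 1]) &
                     ((typed[:, 0] == a) | (typed[:, 1] == a))).mean())
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h_a)
        c = h_a / 2.0
        num += c
        den += b + c
    if den == 0:
        return np.nan
    return 1.0 - num / den


def nei_fis(ho: float, uhe: float) -> float:
    """Simpler per-sample alternative F_IS = 1 - Ho/uHe."""
    if uhe == 0:
        return np.nan
    return 1.0 - ho / uhe


# -- allelic richness ------------------------------------------------------

def allelic_richness(counts: dict[int, int], g: int) -> float:
    """Expected allele count in a rarefied sample of g gene copies.

    Hypergeometric rarefaction: Ar = sum_i [1 - C(N - N_i, g) / C(N, g)].
    Requires g >= 2 and g <= N.
    """
    if g < 2:
        raise DiversityError("rarefaction size g must be >= 2")
    n_tot = sum(counts.values())
    if g > n_tot:
        raise DiversityError(f"g={g} exceeds gene-copy count N={n_tot}")
    denom = special.comb(n_tot, g, exact=False)
    ar = 0.0
    for c in counts.values():
        ar += 1.0 - special.comb(n_tot - c, g, exact=False) / denom
    return float(ar)


def rarefaction_sizes(dataset: Dataset, scopes: list[np.ndarray]) -> np.ndarray:
    """Per-locus rarefaction size: 2 x smallest non-missing sample across scopes."""
    sizes = np.full(dataset.n_loci, np.inf)
    for mask in scopes:
        geno = dataset.genotypes[mask]
        n_typed = (geno[:, :, 0] != MISSING).sum(axis=0)
        sizes = np.minimum(sizes, 2 * n_typed)
    return sizes.astype(int)


# -- plot-level summaries --------------------------------------------------

@dataclass
class PlotDiversity:
    plot: str
    scope: str                 # 'plot', 'A' or 'B'
    n: int
    per_locus: pd.DataFrame    # locus x (n, A, Ho, He, uHe, Ar, Fis)
    means: pd.Series
    se: pd.Series

    def __getattr__(self, name):
        if name in PLOT_METRICS:
            return float(self.means[name])
        raise AttributeError(name)


def plot_diversity(dataset: Dataset, plot: str, scope: str = "plot",
                   g: np.ndarray | int | None = None) -> PlotDiversity:
    """Locus-wise diversity for one plot (or one side of it), averaged over loci.

    ``g`` sets the rarefaction size for Ar (scalar or per-locus vector);
    when None, g = 2 x the smallest per-locus typed sample within the scope.
    Standard errors are across loci (n = number of loci).
    """
    sub = dataset.for_plot(plot)
    if scope in ("A", "B"):
        sub = sub.subset((sub.samples["side"] == scope).to_numpy())
        if sub.n_individuals == 0:
            raise DiversityError(f"plot {plot!r} side {scope} is empty")
    elif scope != "plot":
        raise ValueError("scope must be 'plot', 'A' or 'B'")

    rows = {}
    for l, locus in enumerate(sub.loci):
        geno = sub.genotypes[:, l, :]
        st = _locus_stats(geno)
        if st["n"] > 0:
            if g is None:
                g_l = 2 * st["n"]
            else:
                g_l = int(g[l]) if np.ndim(g) else int(g)
            st["Ar"] = allelic_richness(allele_counts(geno), g_l) if g_l >= 2 else np.nan
        else:
            st["Ar"] = np.nan
        rows[locus] = st
    per_locus = pd.DataFrame(rows).T[["n", "A", "Ho", "He", "uHe", "Ar", "Fis"]]
    vals = per_locus[list(PLOT_METRICS)]
    means = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(vals.notna().sum())
    return PlotDiversity(plot=plot, scope=scope, n=sub.n_individuals,
                         per_locus=per_locus, means=means, se=se)


def side_differences(div_a: PlotDiversity, div_b: PlotDiversity) -> pd.Series:
    """Absolute between-side difference per metric (the *_DIF statistics)."""
    if div_a.plot != div_b.plot:
        raise DiversityError("sides belong to different plots")
    diffs = {}
    for m in PLOT_METRICS:
        va, vb = div_a.means[m], div_b.means[m]
        if np.isnan(va) or np.isnan(vb):
            raise DiversityError(f"metric {m} missing on one side")
        diffs[f"{m}_DIF"] = abs(va - vb)
    return pd.Series(diffs, name=div_a.plot)


def diversity_table(dataset: Dataset) -> pd.DataFrame:
    """Per-plot diversity summary: plot-level means plus between-side _DIF values.

    Ar is rarefied per locus at g = 2 x the smallest typed side sample over
    all plot-sides, so values are comparable across plots and sides.
    """
    scopes = []
    for plot in dataset.plots():
        a, b = split_by_side(dataset, plot)
        ppl = dataset.samples["plot"].to_numpy()
        sd = dataset.samples["side"].to_numpy()
        scopes.append((ppl == plot) & (sd == "A"))
        scopes.append((ppl == plot) & (sd == "B"))
    g = rarefaction_sizes(dataset, scopes)
    g = np.maximum(g, 2)

    out = []
    for plot in dataset.plots():
        whole = plot_diversity(dataset, plot, "plot", g=g)
        da = plot_diversity(dataset, plot, "A", g=g)
        db = plot_diversity(dataset, plot, "B", g=g)
        row = {"plot": plot, "n": whole.n, "Na": da.n, "Nb": db.n}
        for m in PLOT_METRICS:
            row[m] = whole.means[m]
            row[f"{m}_se"] = whole.se[m]
        row.update(side_differences(da, db))
        out.append(row)
    return pd.DataFrame(out)


def samplesize_correlation(table: pd.DataFrame,
                           metrics: tuple[str, ...] = ("Ho_DIF", "uHe_DIF", "Ar_DIF")) -> pd.Series:
    """Pearson r between each between-side difference metric and plot sample size.

    A sanity check that side differences are not a sample-size artefact;
    constant columns yield NaN (flagged upstream).
    """
    if len(table) < 3:
        raise DiversityError("need >= 3 plots for a correlation")
    n = table["n"].to_numpy(dtype=float)
    out = {}
    for m in metrics:
        v = table[m].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(n) == 0:
            out[m] = np.nan
        else:
            out[m] = float(stats.pearsonr(v, n).statistic)
    return pd.Series(out)


# -- individual-level metrics ----------------------------------------------

@dataclass
class IndividualDiversity:
    id: str
    PHt: float
    Hs_obs: float
    Hs_exp: float
    IR: float
    HL: float
    n_typed_loci: int


def individual_heterozygosity(genotype: np.ndarray, ref_freqs: list[dict[int, float]],
                              ref_ho: np.ndarray, ref_uhe: np.ndarray,
                              ind_id: str = "") -> IndividualDiversity:
    """Multilocus heterozygosity profile of one individual.

    ``genotype`` is (L, 2); ``ref_freqs`` holds the reference allele-frequency
    dict per locus (used by IR and HL), and ``ref_ho`` / ``ref_uhe`` the
    per-locus reference observed and unbiased expected heterozygosities (used
    to standardize PHt).  Alleles absent from the reference contribute
    frequency 0 to IR.
    """
    typed = genotype[:, 0] != MISSING
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise DiversityError("individual typed at zero loci")
    het = typed & (genotype[:, 0] != genotype[:, 1])
    pht = float(het.sum() / n_typed)

    mean_ho = float(np.nanmean(ref_ho[typed]))
    mean_uhe = float(np.nanmean(ref_uhe[typed]))
    hs_obs = pht / mean_ho if mean_ho > 0 else np.nan
    hs_exp = pht / mean_uhe if mean_uhe > 0 else np.nan

    # internal relatedness
    n_hom = int((typed & ~het).sum())
    f_sum = 0.0
    for l in np.flatnonzero(typed):
        for a in genotype[l]:
            f_sum += ref_freqs[l].get(int(a), 0.0)
    denom = 2.0 * n_typed - f_sum
    ir = (2.0 * n_hom - f_sum) / denom if denom != 0 else np.nan

    # homozygosity by locus, weighted by reference expected heterozygosity
    e = np.array([1.0 - sum(f ** 2 for f in ref_freqs[l].values()) for l in range(len(ref_freqs))])
    e_hom = float(e[typed & ~het].sum())
    e_het = float(e[het].sum())
    hl = e_hom / (e_hom + e_het) if (e_hom + e_het) > 0 else np.nan

    return IndividualDiversity(id=ind_id, PHt=pht, Hs_obs=hs_obs, Hs_exp=hs_exp,
                               IR=ir, HL=hl, n_typed_loci=n_typed)


def reference_frequencies(dataset: Dataset) -> list[dict[int, float]]:
    """Unweighted mean of per-plot allele-frequency vectors over all plots.

    The standard reference for individual heterozygosity and relatedness in a
    multi-plot design: every plot contributes equally regardless of sample
    size.
    """
    plots = dataset.plots()
    out = []
    for l in range(dataset.n_loci):
        acc: dict[int, float] = {}
        n_ok = 0
        for plot in plots:
            sub = dataset.for_plot(plot)
            try:
                freqs, _ = allele_frequencies(sub.genotypes[:, l, :])
            except DiversityError:
                continue
            n_ok += 1
            for a, f in freqs.items():
                acc[a] = acc.get(a, 0.0) + f
        if n_ok == 0:
            raise DiversityError(f"locus {dataset.loci[l]!r} untyped everywhere")
        out.append({a: f / n_ok for a, f in acc.items()})
    return out


def individual_table(dataset: Dataset) -> pd.DataFrame:
    """Individual heterozygosity metrics for every individual in the Dataset."""
    ref = reference_frequencies(dataset)
    per_locus = [_locus_stats(dataset.genotypes[:, l, :]) for l in range(dataset.n_loci)]
    ref_ho = np.array([s["Ho"] for s in per_locus])
    ref_uhe = np.array([s["uHe"] for s in per_locus])
    rows = []
    for i, uid in enumerate(dataset.ids):
        d = individual_heterozygosity(dataset.genotypes[i], ref, ref_ho, ref_uhe, uid)
        rows.append(vars(d))
    return pd.DataFrame(rows)
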