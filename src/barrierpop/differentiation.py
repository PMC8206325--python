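"""Between-side differentiation statistics per plot.

For each plot the two barrier sides are treated as k = 2 subpopulations and
compared with:

* an AMOVA-based FST (Phi_ST from the hierarchical partition, permutation
  tested by shuffling individuals across sides), plus a Weir–Cockerham theta
  for comparison;
* the GST family and Jost's D, computed from within-side (HS) and total (HT)
  expected heterozygosities:

      Gst   = (HT - HS) / HT
      G'st  = Gst * (k - 1 + HS) / ((k - 1) * (1 - HS))
      G''st = k * (HT - HS) / ((k * HT - HS) * (1 - HS))
      D     = (k / (k - 1)) * (HT - HS) / (1 - HS)

  With highly polymorphic markers (HS near 1) Gst is bounded far below 1 even
  for fixed allele differences, which is why the standardized forms G'st,
  G''st and D are carried alongside it.  HS and HT use Nei & Chesser's
  small-sample corrections by default; the uncorrected parameter-scale
  variant is available behind a flag.
* a log-likelihood-ratio G-test of allele-count homogeneity across sides,
  summed over loci, with a Monte-Carlo permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amova import amova_permutation, amova_three_level
from .diversity import allele_counts
from .genotype_io import MISSING, Dataset, split_by_side


class DifferentiationError(ValueError):
    pass


@dataclass
class DifferentiationResult:
    plot: str
    fst: float
    fst_p: float | None
    theta_wc: float
    gst: float
    gprime_st: float
    gdoubleprime_st: float
    jost_d: float
    g_statistic: float
    g_p: float | None
    n_permutations: int | None


# -- HS/HT machinery -------------------------------------------------------

def _side_locus_stats(genotypes: np.ndarray):
    """(freqs dict, n typed individuals, observed het) at one locus, one side."""
    typed = genotypes[genotypes[:, 0] != MISSING]
    n = typed.shape[0]
    if n == 0:
        return None
    counts = allele_counts(typed)
    tot = sum(counts.values())
    freqs = {a: c / tot for a, c in counts.items()}
    ho = float((typed[:, 0] != typed[:, 1]).mean())
    return freqs, n, ho


def hs_ht(freqs_per_side, sizes, ho_per_side=None, corrected=True):
    """Within-side and total expected heterozygosity for one locus, k sides.

    With ``corrected=True`` applies the Nei & Chesser small-sample estimators
    using the harmonic mean sample size and the mean observed heterozygosity;
    otherwise returns the parameter-scale quantities (HS = mean 1 - sum p^2,
    HT from the mean frequency vector).
    """
    k = len(freqs_per_side)
    alleles = sorted(set().union(*[f.keys() for f in freqs_per_side]))
    p = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs_per_side])
    hs_raw = float(np.mean(1.0 - (p ** 2).sum(axis=1)))
    p_bar = p.mean(axis=0)
    ht_raw = float(1.0 - (p_bar ** 2).sum())
    if not corrected:
        return hs_raw, ht_raw
    n_harm = k / np.sum(1.0 / np.asarray(sizes, dtype=float))
    ho_bar = float(np.mean(ho_per_side)) if ho_per_side is not None else None
    if ho_bar is None:
        ho_bar = hs_raw  # fall back to HW expectation
    hs = (n_harm / (n_harm - 1.0)) * (hs_raw - ho_bar / (2.0 * n_harm))
    ht = ht_raw + hs / (n_harm * k) - ho_bar / (2.0 * n_harm * k)
    return hs, ht


def gst_family_from_hs_ht(hs: float, ht: float, k: int = 2):
    """(Gst, G'st, G''st, D) from averaged HS and HT."""
    if ht == 0:
        raise DifferentiationError("HT = 0: no allelic variation")
    if hs >= 1.0:
        raise DifferentiationError("HS = 1 is degenerate")
    gst = (ht - hs) / ht
    gprime = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
    gdouble = k * (ht - hs) / ((k * ht - hs) * (1.0 - hs))
    d = (k / (k - 1.0)) * (ht - hs) / (1.0 - hs)
    return gst, gprime, gdouble, d


def gst_family(freqs_a, freqs_b, sizes=None, ho=None, corrected=False):
    """GST family for one locus given two sides' allele frequencies.

    ``freqs_a``/``freqs_b`` are allele -> frequency dicts; ``sizes`` and
    ``ho`` (per-side observed heterozygosities) are required for the
    corrected estimators.
    """
    if corrected and sizes is None:
        raise DifferentiationError("sample sizes required for corrected estimators")
    hs, ht = hs_ht([freqs_a, freqs_b], sizes, ho, corrected=corrected)
    return gst_family_from_hs_ht(hs, ht, k=2)


def gst_family_multilocus(dataset: Dataset, plot: str, corrected=True):
    """GST family for one plot: per-locus HS/HT averaged over loci first."""
    ds_a, ds_b = split_by_side(dataset, plot)
    hs_list, ht_list = [], []
    for l in range(dataset.n_loci):
        sa = _side_locus_stats(ds_a.genotypes[:, l, :])
        sb = _side_locus_stats(ds_b.genotypes[:, l, :])
        if sa is None or sb is None:
            continue
        hs, ht = hs_ht([sa[0], sb[0]], [sa[1], sb[1]], [sa[2], sb[2]], corrected=corrected)
        hs_list.append(hs)
        ht_list.append(ht)
    if not ht_list:
        raise DifferentiationError(f"plot {plot!r}: no locus typed on both sides")
    return gst_family_from_hs_ht(float(np.mean(hs_list)), float(np.mean(ht_list)), k=2)


# -- Weir & Cockerham theta ------------------------------------------------

def weir_cockerham_theta(dataset: Dataset, plot: str) -> float:
    """Multilocus Weir & Cockerham (1984) theta between the two sides."""
    ds_a, ds_b = split_by_side(dataset, plot)
    r = 2.0
    num = den = 0.0
    for l in range(dataset.n_loci):
        stats = [_side_locus_stats(d.genotypes[:, l, :]) for d in (ds_a, ds_b)]
        if any(s is None for s in stats):
            continue
        ns = np.array([s[1] for s in stats], dtype=float)
        n_bar = ns.mean()
        nc = (ns.sum() - (ns ** 2).sum() / ns.sum()) / (r - 1.0)
        alleles = sorted(set(stats[0][0]) | set(stats[1][0]))
        for a in alleles:
            p = np.array([s[0].get(a, 0.0) for s in stats])
            # per-side observed het frequency involving allele a
            h = []
            for d in (ds_a, ds_b):
                g = d.genotypes[:, l, :]
                typed = g[g[:, 0] != MISSING]
                h.append(float(((typed[:, 0] != typed[:, 1]) &
                                ((typed[:, 0] == a) | (typed[:, 1] == a))).mean()))
            h = np.array(h)
            p_bar = (ns * p).sum() / ns.sum()
            s2 = (ns * (p - p_bar) ** 2).sum() / ((r - 1.0) * n_bar)
            h_bar = (ns * h).sum() / ns.sum()
            va = (n_bar / nc) * (s2 - (1.0 / (n_bar - 1.0)) *
                                 (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0))
            vb = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 -
                                            (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
            vc = h_bar / 2.0
            num += va
            den += va + vb + vc
    if den == 0:
        raise DifferentiationError(f"plot {plot!r}: theta undefined (no variation)")
    return num / den


# -- G-test ----------------------------------------------------------------

def _g_stat(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for one side x allele contingency table."""
    table = table.astype(float)
    tot = table.sum()
    if tot == 0:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return 2.0 * float(terms.sum())


def g_test(dataset: Dataset, plot: str, n_mc: int = 999,
           seed: int | None = None):
    """Allele-frequency homogeneity G-test between sides, summed over loci.

    The p-value is Monte-Carlo: gene copies are pooled per locus and side
    labels permuted, preserving per-side copy counts.  Returns (G, p); G is
    additive over loci by construction.
    """
    ds_a, ds_b = split_by_side(dataset, plot)
    rng = np.random.default_rng(seed)

    per_locus = []
    g_obs = 0.0
    any_poly = False
    for l in range(dataset.n_loci):
        copies_a = ds_a.genotypes[:, l, :].reshape(-1)
        copies_b = ds_b.genotypes[:, l, :].reshape(-1)
        copies_a = copies_a[copies_a != MISSING]
        copies_b = copies_b[copies_b != MISSING]
        if len(copies_a) == 0 or len(copies_b) == 0:
            continue
        pooled = np.concatenate([copies_a, copies_b])
        if len(np.unique(pooled)) < 2:
            continue
        any_poly = True
        alleles, inv = np.unique(pooled, return_inverse=True)
        na = len(copies_a)
        tab = np.zeros((2, len(alleles)))
        np.add.at(tab[0], inv[:na], 1)
        np.add.at(tab[1], inv[na:], 1)
        g_obs += _g_stat(tab)
        per_locus.append((inv, na, len(alleles)))
    if not any_poly:
        raise DifferentiationError(f"plot {plot!r}: all loci monomorphic")

    hits = 0
    for _ in range(n_mc):
        g_perm = 0.0
        for inv, na, n_alleles in per_locus:
            shuffled = rng.permutation(inv)
            tab = np.zeros((2, n_alleles))
            np.add.at(tab[0], shuffled[:na], 1)
            np.add.at(tab[1], shuffled[na:], 1)
            g_perm += _g_stat(tab)
        if g_perm >= g_obs:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return g_obs, p


# -- plot-level wrapper ----------------------------------------------------

def fst_between_sides(dataset: Dataset, plot: str, n_perm: int = 999,
                      seed: int | None = None):
    """AMOVA-based FST (Phi_ST) between sides with its permutation p-value."""
    if n_perm:
        res = amova_permutation(dataset, plot, n_perm=n_perm, seed=seed)
        return res.phi_st, res.p_values["Phi_ST"]
    return amova_three_level(dataset, plot).phi_st, None


def differentiation_between_sides(dataset: Dataset, plot: str, n_perm: int = 999,
                                  seed: int | None = None,
                                  corrected: bool = True) -> DifferentiationResult:
    """All between-side differentiation statistics for one plot."""
    rng = np.random.default_rng(seed)
    fst, fst_p = fst_between_sides(dataset, plot, n_perm=n_perm,
                                   seed=int(rng.integers(2 ** 31)))
    gst, gp, gpp, d = gst_family_multilocus(dataset, plot, corrected=corrected)
    g_stat, g_p = g_test(dataset, plot, n_mc=n_perm, seed=int(rng.integers(2 ** 31)))
    theta = weir_cockerham_theta(dataset, plot)
    return DifferentiationResult(plot=plot, fst=fst, fst_p=fst_p, theta_wc=theta,
                                 gst=gst, gprime_st=gp, gdoubleprime_st=gpp,
                                 jost_d=d, g_statistic=g_stat, g_p=g_p,
                                 n_permutations=n_perm)


def differentiation_table(dataset: Dataset, n_perm: int = 999,
                          seed: int | None = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for plot in dataset.plots():
        res = differentiation_between_sides(dataset, plot, n_perm=n_perm,
                                            seed=int(rng.integers(2 ** 31)))
        rows.append(vars(res))
    return pd.DataFrame(rows)
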