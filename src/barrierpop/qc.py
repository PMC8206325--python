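"""Locus- and sample-level quality control for microsatellite datasets.

The filtering chain mirrors standard practice for field-collected rodent
microsatellite data:

1. Hardy–Weinberg equilibrium per locus (Monte-Carlo exact test conditional
   on allele counts — robust with dozens of alleles per locus);
2. genotypic linkage disequilibrium between locus pairs (permutation G-test
   on the joint genotype table);
3. null-allele frequency per locus via the Brookfield estimator
   r = (He - Ho) / (1 + He);
4. allelic dropout (E1) and false-allele (E2) rates from duplicate
   re-genotyping concordance;
5. removal of putative same-litter full sibs: within each sampling point,
   individuals joined by pairwise relatedness at or above a threshold form a
   group of which one random (seeded) member is kept.  The default threshold
   0.35 sits midway between the full-sib (0.5) and half-sib (0.25)
   expectations of the doubled Lynch–Ritland estimator.  Siblings captured at
   different sampling points are retained: only within-point litters bias
   local allele frequencies.

All permutation/Monte-Carlo p-values use the (b + 1) / (B + 1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceError, lynch_ritland
from .diversity import allele_frequencies
from .genotype_io import MISSING, Dataset


class QcError(ValueError):
    pass


@dataclass
class HWEResult:
    locus: str
    scope: str
    p_value: float
    method: str
    n_mc: int
    flag: str = ""


@dataclass
class NullAlleleEstimate:
    locus: str
    scope: str
    r_null: float
    flag: str = ""


@dataclass
class ErrorRateEstimate:
    locus: str
    e1: float    # allelic dropout rate
    e2: float    # false allele rate
    n_duplicates: int
    flag: str = ""


@dataclass
class SibFlag:
    id: str
    sampling_point: str
    kept: bool
    reason: str


# -- Hardy-Weinberg --------------------------------------------------------

def _het_count(pairs: np.ndarray) -> int:
    return int((pairs[:, 0] != pairs[:, 1]).sum())


def _table_log_prob(pairs: np.ndarray) -> float:
    """Log multiplicity weight of a genotype table given its allele counts.

    Conditional on allele counts, the probability of a genotype configuration
    is proportional to 2^h / prod(genotype count factorials); the log of that
    ordering statistic is enough to rank tables for the exact test.
    """
    from collections import Counter
    h = _het_count(pairs)
    counts = Counter(map(tuple, np.sort(pairs, axis=1)))
    from scipy.special import gammaln
    return h * np.log(2.0) - sum(gammaln(c + 1) for c in counts.values())


def hwe_test(genotypes: np.ndarray, n_mc: int = 10_000,
             seed: int | None = None, locus: str = "", scope: str = "global") -> HWEResult:
    """Monte-Carlo exact Hardy–Weinberg test for one locus.

    Gene copies are shuffled and re-paired ``n_mc`` times; the p-value is the
    (smoothed) fraction of resampled tables whose conditional probability is
    at or below the observed table's.  Monomorphic loci return p = 1 with a
    flag.
    """
    typed = genotypes[genotypes[:, 0] != MISSING]
    if typed.shape[0] == 0:
        raise QcError("all genotypes missing")
    if typed.shape[0] < 2:
        raise QcError("need >= 2 non-missing genotypes")
    if len(np.unique(typed)) < 2:
        return HWEResult(locus, scope, 1.0, "mc_exact", n_mc, flag="monomorphic")

    obs = _table_log_prob(typed)
    copies = typed.reshape(-1).copy()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(copies)
        if _table_log_prob(copies.reshape(-1, 2)) <= obs + 1e-12:
            hits += 1
    return HWEResult(locus, scope, (hits + 1) / (n_mc + 1), "mc_exact", n_mc)


# -- linkage disequilibrium ------------------------------------------------

def ld_test(geno_i: np.ndarray, geno_j: np.ndarray, n_perm: int = 999,
            seed: int | None = None) -> float:
    """Permutation p for genotypic association between two loci.

    The statistic is the log-likelihood-ratio G on the joint genotype
    contingency table; locus j's genotypes are permuted across individuals.
    """
    both = (geno_i[:, 0] != MISSING) & (geno_j[:, 0] != MISSING)
    gi = np.sort(geno_i[both], axis=1)
    gj = np.sort(geno_j[both], axis=1)
    if gi.shape[0] < 2:
        raise QcError("fewer than 2 complete genotype pairs")

    # integer genotype categories per locus
    _, ci = np.unique(gi, axis=0, return_inverse=True)
    _, cj = np.unique(gj, axis=0, return_inverse=True)
    ni, nj = ci.max() + 1, cj.max() + 1

    def g_stat(a, b):
        tab = np.bincount(a * nj + b, minlength=ni * nj).reshape(ni, nj).astype(float)
        tot = tab.sum()
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
        return 2.0 * terms.sum()

    obs = g_stat(ci, cj)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if g_stat(ci, rng.permutation(cj)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# -- null alleles ----------------------------------------------------------

def brookfield_null(ho: float, he: float, locus: str = "",
                    scope: str = "global") -> NullAlleleEstimate:
    """Brookfield estimator 1 of null-allele frequency: (He - Ho) / (1 + He).

    Clipped to zero (with a flag) when Ho exceeds He.
    """
    if not (0 <= ho <= 1 and 0 <= he <= 1):
        raise QcError("heterozygosities must lie in [0, 1]")
    r = (he - ho) / (1.0 + he)
    if r < 0:
        return NullAlleleEstimate(locus, scope, 0.0, flag="excess_heterozygosity")
    return NullAlleleEstimate(locus, scope, r)


# -- duplicate genotyping error rates --------------------------------------

def duplicate_error_rates(original: np.ndarray, replicate: np.ndarray,
                          locus: str = "") -> ErrorRateEstimate:
    """E1 (dropout) and E2 (false allele) from matched duplicate genotypes.

    Inputs are (n_dup, 2) allele pairs for one locus.  A comparison counts as
    a dropout event when a heterozygote in one replicate appears as a
    homozygote sharing one allele in the other, and as a false-allele event
    when a replicate shows an allele absent from its partner (other than the
    dropout pattern).  Rates are per comparable duplicate pair.
    """
    ok = (original[:, 0] != MISSING) & (replicate[:, 0] != MISSING)
    o = np.sort(original[ok], axis=1)
    r = np.sort(replicate[ok], axis=1)
    n = o.shape[0]
    if n == 0:
        return ErrorRateEstimate(locus, np.nan, np.nan, 0, flag="no_duplicates")
    e1 = e2 = 0
    for a, b in zip(o, r):
        if tuple(a) == tuple(b):
            continue
        het_a, het_b = a[0] != a[1], b[0] != b[1]
        if het_a != het_b:
            het, hom = (a, b) if het_a else (b, a)
            if hom[0] in het:
                e1 += 1
                continue
        e2 += 1
    return ErrorRateEstimate(locus, e1 / n, e2 / n, n)


# -- full-sib filtering ----------------------------------------------------

def flag_full_sibs(dataset: Dataset, ref_freqs, threshold: float = 0.35,
                   seed: int | None = None) -> list[SibFlag]:
    """Flag putative same-point full sibs for removal, keeping one per group.

    Within each sampling point, pairs with doubled Lynch–Ritland relatedness
    >= ``threshold`` are linked; connected components form putative litters
    and one random (seeded) member of each is kept.
    """
    rng = np.random.default_rng(seed)
    flags: list[SibFlag] = []
    samples = dataset.samples
    for point, grp in samples.groupby("sampling_point", sort=True):
        idx = grp.index.to_numpy()
        if len(idx) == 1:
            continue
        # union-find over the point's individuals
        parent = {i: i for i in idx}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        linked = False
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                a, b = idx[ii], idx[jj]
                try:
                    r = lynch_ritland(dataset.genotypes[a], dataset.genotypes[b],
                                      ref_freqs)
                except DistanceError:
                    continue
                if r >= threshold:
                    parent[find(a)] = find(b)
                    linked = True
        if not linked:
            continue
        groups: dict[int, list[int]] = {}
        for i in idx:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            if len(members) < 2:
                continue
            keep = members[int(rng.integers(len(members)))]
            for i in members:
                flags.append(SibFlag(id=samples["id"].iloc[i], sampling_point=point,
                                     kept=(i == keep),
                                     reason=f"putative_litter_of_{len(members)}"))
    return flags


# -- filter application ----------------------------------------------------

@dataclass
class FilterReport:
    n_initial: int
    n_failed: int
    n_sib_discarded: int
    n_retained: int
    removals: pd.DataFrame  # id, reason


def apply_filters(dataset: Dataset, failed_ids=(), sib_flags=()) -> tuple[Dataset, FilterReport]:
    """Remove failed samples and flagged siblings; return the audit report.

    The retained count is exactly ``initial - failed - sib_discarded``; an id
    appearing in both removal sets is an error.
    """
    failed = set(failed_ids)
    sib_discard = {f.id for f in sib_flags if not f.kept}
    overlap = failed & sib_discard
    if overlap:
        raise QcError(f"ids in both removal sets: {sorted(overlap)[:5]}")
    unknown = (failed | sib_discard) - set(dataset.ids)
    if unknown:
        raise QcError(f"removal ids not in dataset: {sorted(unknown)[:5]}")

    removals = ([(i, "genotyping_failed") for i in sorted(failed)] +
                [(i, "full_sib_same_point") for i in sorted(sib_discard)])
    drop = failed | sib_discard
    mask = ~dataset.samples["id"].isin(drop).to_numpy()
    filtered = dataset.subset(mask)
    report = FilterReport(n_initial=dataset.n_individuals, n_failed=len(failed),
                          n_sib_discarded=len(sib_discard),
                          n_retained=filtered.n_individuals,
                          removals=pd.DataFrame(removals, columns=["id", "reason"]))
    assert report.n_retained == report.n_initial - report.n_failed - report.n_sib_discarded
    return filtered, report


def hwe_report(dataset: Dataset, n_mc: int = 10_000, seed: int | None = None,
               per_plot: bool = False) -> pd.DataFrame:
    """HWE and Brookfield null-allele screen per locus (globally or per plot)."""
    rng = np.random.default_rng(seed)
    scopes = dataset.plots() if per_plot else [None]
    rows = []
    for scope in scopes:
        sub = dataset.for_plot(scope) if scope else dataset
        label = scope or "global"
        for l, locus in enumerate(sub.loci):
            geno = sub.genotypes[:, l, :]
            hwe = hwe_test(geno, n_mc=n_mc, seed=int(rng.integers(2 ** 31)),
                           locus=locus, scope=label)
            typed = geno[geno[:, 0] != MISSING]
            ho = float((typed[:, 0] != typed[:, 1]).mean())
            freqs, n_cop = allele_frequencies(typed)
            he = 1.0 - sum(f ** 2 for f in freqs.values())
            uhe = he * n_cop / (n_cop - 1)
            null = brookfield_null(ho, uhe, locus=locus, scope=label)
            rows.append({"locus": locus, "scope": label, "hwe_p": hwe.p_value,
                         "hwe_flag": hwe.flag, "r_null": null.r_null,
                         "null_flag": null.flag})
    return pd.DataFrame(rows)
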