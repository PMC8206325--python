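"""Three-level codominant AMOVA per plot with Phi-statistics.

Genetic variance within one plot is partitioned across three hierarchical
strata — between barrier sides, among individuals within sides, and within
individuals — from gene-copy-level squared distances (per locus: 0 for
identical alleles, 1 otherwise, summed over loci typed in both copies).
Each diploid individual contributes two gene copies, so the within-individual
stratum captures observed heterozygosity and Phi_IS plays the role of an
inbreeding coefficient.

Variance components follow the classical nested-ANOVA expectations with the
unequal-sample-size coefficient n0 for the among-sides stratum.  Negative
component estimates are retained (not truncated), so Phi_ST may be slightly
negative in panmictic plots; results carry a flag when that happens.

Significance is by permutation, with the exchangeable unit matched to each
statistic: whole individuals across sides for Phi_ST, gene copies among
individuals within sides for Phi_IS, and gene copies across the whole plot
for Phi_IT.  P-values use the (b + 1) / (B + 1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Dataset, split_by_side


class AmovaError(ValueError):
    pass


@dataclass
class AmovaResult:
    plot: str
    df: dict            # stratum -> degrees of freedom
    ss: dict            # stratum -> sum of squares
    sigma2: dict        # 'a' (between sides), 'b' (among ind), 'c' (within ind)
    percent: dict       # stratum -> percentage of total variance
    phi_st: float
    phi_is: float
    phi_it: float
    sigma_bw: float
    negative_component: bool
    p_values: dict | None = None
    n_permutations: int | None = None

    def as_frame(self) -> pd.DataFrame:
        strata = ["between_sides", "among_individuals", "within_individuals"]
        comp = dict(zip(strata, ("a", "b", "c")))
        phis = {"between_sides": ("Phi_ST", self.phi_st),
                "among_individuals": ("Phi_IS", self.phi_is),
                "within_individuals": ("Phi_IT", self.phi_it)}
        rows = []
        for s in strata:
            name, phi = phis[s]
            rows.append({"plot": self.plot, "stratum": s, "df": self.df[s],
                         "SS": self.ss[s], "variance": self.sigma2[comp[s]],
                         "percent": self.percent[s], "Phi": phi,
                         "p": (self.p_values or {}).get(name, np.nan)})
        return pd.DataFrame(rows)


# -- gene-copy distance machinery ------------------------------------------

def gene_copy_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Flatten (n, L, 2) genotypes into a (2n, L) gene-copy allele matrix."""
    n, L, _ = genotypes.shape
    return genotypes.transpose(0, 2, 1).reshape(2 * n, L)


def copy_distance_matrix(copies: np.ndarray) -> np.ndarray:
    """Pairwise squared distances between gene copies.

    Per locus the contribution is 0 for matching alleles and 1 otherwise;
    loci missing in either copy are dropped pairwise (no rescaling), matching
    the usual codominant allele-mismatch convention.
    """
    present = copies != MISSING
    both = present[:, None, :] & present[None, :, :]
    diff = (copies[:, None, :] != copies[None, :, :]) & both
    return diff.sum(axis=2).astype(float)


def _ss_within_groups(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    ss = 0.0
    for g in groups:
        if len(g) == 0:
            continue
        sub = d2[np.ix_(g, g)]
        ss += sub.sum() / (2.0 * len(g))
    return ss


def _components_from_partition(d2: np.ndarray, ind_of_copy: np.ndarray,
                               side_of_copy: np.ndarray):
    """SS, df and variance components for one labelling of the gene copies."""
    n_copies = d2.shape[0]
    individuals = np.unique(ind_of_copy)
    sides = np.unique(side_of_copy)
    k = len(sides)
    n_ind = len(individuals)

    ss_total = d2.sum() / (2.0 * n_copies)
    side_groups = [np.flatnonzero(side_of_copy == s) for s in sides]
    ss_within_sides = _ss_within_groups(d2, side_groups)
    ind_groups = [np.flatnonzero(ind_of_copy == i) for i in individuals]
    ss_wi = _ss_within_groups(d2, ind_groups)

    ss = {"between_sides": ss_total - ss_within_sides,
          "among_individuals": ss_within_sides - ss_wi,
          "within_individuals": ss_wi}
    df = {"between_sides": k - 1,
          "among_individuals": n_ind - k,
          "within_individuals": n_ind}

    ms_a = ss["between_sides"] / df["between_sides"]
    ms_b = ss["among_individuals"] / df["among_individuals"]
    ms_c = ss["within_individuals"] / df["within_individuals"]

    copies_per_side = np.array([len(g) for g in side_groups], dtype=float)
    n0 = (n_copies - (copies_per_side ** 2).sum() / n_copies) / (k - 1)

    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / 2.0
    sigma_a = (ms_a - sigma_c - 2.0 * sigma_b) / n0
    return ss, df, {"a": sigma_a, "b": sigma_b, "c": sigma_c}


def _phis(sigma2: dict) -> tuple[float, float, float]:
    a, b, c = sigma2["a"], sigma2["b"], sigma2["c"]
    total = a + b + c
    phi_st = a / total if total != 0 else np.nan
    phi_is = b / (b + c) if (b + c) != 0 else np.nan
    phi_it = (a + b) / total if total != 0 else np.nan
    return phi_st, phi_is, phi_it


# -- public API ------------------------------------------------------------

def amova_from_arrays(genotypes: np.ndarray, sides: np.ndarray, plot: str = "",
                      d2: np.ndarray | None = None) -> AmovaResult:
    """AMOVA from raw arrays: (n, L, 2) genotypes and a length-n side vector.

    ``d2`` may pass a precomputed gene-copy distance matrix (reused by the
    permutation test).  Requires >= 2 individuals on each side and at least
    one polymorphic locus.
    """
    sides = np.asarray(sides)
    side_codes, side_idx = np.unique(sides, return_inverse=True)
    if len(side_codes) != 2 or min(np.bincount(side_idx)) < 2:
        raise AmovaError(f"plot {plot!r}: both sides need >= 2 individuals")
    copies = gene_copy_matrix(genotypes)
    poly = False
    for l in range(genotypes.shape[1]):
        col = copies[:, l]
        col = col[col != MISSING]
        if len(np.unique(col)) > 1:
            poly = True
            break
    if not poly:
        raise AmovaError(f"plot {plot!r} is monomorphic at every locus")

    if d2 is None:
        d2 = copy_distance_matrix(copies)
    n = genotypes.shape[0]
    ind_of_copy = np.repeat(np.arange(n), 2)
    side_of_copy = np.repeat(side_idx, 2)

    ss, df, sigma2 = _components_from_partition(d2, ind_of_copy, side_of_copy)
    phi_st, phi_is, phi_it = _phis(sigma2)
    total = sum(sigma2.values())
    percent = {"between_sides": 100.0 * sigma2["a"] / total,
               "among_individuals": 100.0 * sigma2["b"] / total,
               "within_individuals": 100.0 * sigma2["c"] / total}
    pct_within = percent["among_individuals"]
    sigma_bw = percent["between_sides"] / pct_within if pct_within != 0 else np.nan

    return AmovaResult(plot=plot, df=df, ss=ss, sigma2=sigma2, percent=percent,
                       phi_st=phi_st, phi_is=phi_is, phi_it=phi_it,
                       sigma_bw=sigma_bw,
                       negative_component=any(v < 0 for v in sigma2.values()))


def amova_three_level(dataset: Dataset, plot: str,
                      d2: np.ndarray | None = None) -> AmovaResult:
    """Hierarchical AMOVA for one plot of a Dataset (sides A vs B)."""
    split_by_side(dataset, plot)  # validates both sides non-empty
    sub = dataset.for_plot(plot)
    return amova_from_arrays(sub.genotypes, sub.samples["side"].to_numpy(),
                             plot=plot, d2=d2)


def amova_permutation(dataset: Dataset, plot: str, n_perm: int = 999,
                      seed: int | None = None,
                      stats: tuple[str, ...] = ("Phi_ST", "Phi_IS", "Phi_IT"),
                      ) -> AmovaResult:
    """AMOVA with permutation p-values for Phi_ST, Phi_IS and Phi_IT.

    Permutation units: whole individuals across sides (Phi_ST); gene copies
    among individuals within sides (Phi_IS); gene copies across the plot
    (Phi_IT).  ``stats`` restricts which p-values are computed (the others
    are omitted).  Reproducible under a fixed seed.

    The permuted statistics are recomputed from invariants of each scheme
    (total SS always; within-individual SS under side shuffling; within-side
    SS under within-side copy shuffling), which keeps the loop at O(copies^2)
    per permutation.
    """
    if n_perm < 1:
        raise AmovaError("n_perm must be >= 1")
    sub = dataset.for_plot(plot)
    copies = gene_copy_matrix(sub.genotypes)
    d2 = copy_distance_matrix(copies)
    result = amova_three_level(dataset, plot, d2=d2)

    rng = np.random.default_rng(seed)
    n = sub.n_individuals
    side_of_ind = (sub.samples["side"] == "B").to_numpy().astype(int)
    side_of_copy = np.repeat(side_of_ind, 2)
    side_pos = [np.flatnonzero(side_of_copy == s) for s in (0, 1)]

    ss_total = d2.sum() / (2.0 * 2 * n)
    ss_ws_obs = result.ss["among_individuals"] + result.ss["within_individuals"]
    ss_wi_obs = result.ss["within_individuals"]
    dfa, dfb, dfc = (result.df["between_sides"], result.df["among_individuals"],
                     result.df["within_individuals"])
    copies_per_side = np.array([len(g) for g in side_pos], dtype=float)
    n0 = (2 * n - (copies_per_side ** 2).sum() / (2 * n)) / dfa

    def phis_from_ss(ss_ws, ss_wi):
        ms_a = (ss_total - ss_ws) / dfa
        ms_b = (ss_ws - ss_wi) / dfb
        ms_c = ss_wi / dfc
        sc = ms_c
        sb = (ms_b - sc) / 2.0
        sa = (ms_a - sc - 2.0 * sb) / n0
        return _phis({"a": sa, "b": sb, "c": sc})

    def ss_within_sides_for(groups):
        return sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)

    def ss_within_ind_for(order):
        return d2[order[0::2], order[1::2]].sum() / 2.0

    hits = dict.fromkeys(stats, 0)
    for _ in range(n_perm):
        if "Phi_ST" in hits:
            perm_side = np.repeat(rng.permutation(side_of_ind), 2)
            groups = [np.flatnonzero(perm_side == s) for s in (0, 1)]
            if phis_from_ss(ss_within_sides_for(groups), ss_wi_obs)[0] >= result.phi_st:
                hits["Phi_ST"] += 1
        if "Phi_IS" in hits:
            order = np.arange(2 * n)
            for g in side_pos:
                order[g] = g[rng.permutation(len(g))]
            if phis_from_ss(ss_ws_obs, ss_within_ind_for(order))[1] >= result.phi_is:
                hits["Phi_IS"] += 1
        if "Phi_IT" in hits:
            order = rng.permutation(2 * n)
            groups = [order[g] for g in side_pos]
            if phis_from_ss(ss_within_sides_for(groups),
                            ss_within_ind_for(order))[2] >= result.phi_it:
                hits["Phi_IT"] += 1

    result.p_values = {k: (v + 1) / (n_perm + 1) for k, v in hits.items()}
    result.n_permutations = n_perm
    return result


def sigma_ratio(result: AmovaResult) -> float:
    """Ratio of the between-sides to among-individuals-within-sides variance
    percentages (sigma_bw); negative between-components pass through <= 0."""
    pct_within = result.percent["among_individuals"]
    if pct_within == 0:
        raise AmovaError("within-side percentage is zero")
    return result.percent["between_sides"] / pct_within


def amova_table(dataset: Dataset, n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Per-plot AMOVA summary across the whole Dataset."""
    rng = np.random.default_rng(seed)
    frames = []
    for plot in dataset.plots():
        res = amova_permutation(dataset, plot, n_perm=n_perm,
                                seed=int(rng.integers(2 ** 31)))
        frames.append(res.as_frame().assign(sigma_bw=res.sigma_bw))
    return pd.concat(frames, ignore_index=True)
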