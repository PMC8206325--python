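"""Shared test utilities: dataset builders and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from barrierpop.genotype_io import Dataset


def make_dataset(genotypes, sides, plot="P1", loci=None, coords=None,
                 points=None, pair_id=None, treatment="R", design=None):
    """Build a one-plot Dataset from raw pieces."""
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    if loci is None:
        loci = [f"L{l+1}" for l in range(genotypes.shape[1])]
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float),
                                  np.zeros(n)])
    if points is None:
        points = [f"pt{i}" for i in range(n)]
    samples = pd.DataFrame({
        "id": [f"{plot}_i{i}" for i in range(n)],
        "plot": plot, "pair_id": pair_id or plot, "treatment": treatment,
        "side": list(sides), "sampling_point": points,
        "x": coords[:, 0], "y": coords[:, 1]})
    ds = Dataset(loci=list(loci), genotypes=genotypes, samples=samples)
    if design is not None:
        ds.design = design
    return ds


# -- independent AMOVA oracle ----------------------------------------------

def _indicator_copies(genotypes):
    """Gene copies as scaled one-hot allele vectors (complete data only).

    Squared Euclidean distance between two copy vectors equals the per-locus
    allele-mismatch count summed over loci (the 1/sqrt(2) scaling folds the
    one-hot distance 2 down to 1 per mismatching locus).
    """
    n, L, _ = genotypes.shape
    blocks = []
    for l in range(L):
        alleles = sorted(set(genotypes[:, l, :].reshape(-1).tolist()))
        lookup = {a: i for i, a in enumerate(alleles)}
        block = np.zeros((2 * n, len(alleles)))
        flat = genotypes[:, l, :].reshape(-1)  # copy order: i0a, i0b, i1a, ...
        for c, a in enumerate(flat):
            block[c, lookup[a]] = 1.0 / np.sqrt(2.0)
        blocks.append(block)
    return np.hstack(blocks)


def amova_oracle(genotypes, sides):
    """Brute-force three-level AMOVA via centroid sums of squares.

    Entirely independent route from the package's pairwise-distance
    implementation: gene copies are embedded as indicator vectors and each
    stratum's SS is a deviation-from-centroid sum.  Returns (ss dict,
    sigma2 dict, phi_st).
    """
    genotypes = np.asarray(genotypes)
    x = _indicator_copies(genotypes)
    n, _, _ = genotypes.shape
    sides = np.asarray(sides)
    copy_side = np.repeat(sides, 2)
    copy_ind = np.repeat(np.arange(n), 2)

    def ss_dev(rows):
        sub = x[rows]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    ss_total = ss_dev(np.arange(2 * n))
    ss_ws = sum(ss_dev(np.flatnonzero(copy_side == s)) for s in np.unique(sides))
    ss_wi = sum(ss_dev(np.flatnonzero(copy_ind == i)) for i in range(n))

    ss = {"between_sides": ss_total - ss_ws,
          "among_individuals": ss_ws - ss_wi,
          "within_individuals": ss_wi}
    k = len(np.unique(sides))
    df_a, df_b, df_c = k - 1, n - k, n
    ms_a = ss["between_sides"] / df_a
    ms_b = ss["among_individuals"] / df_b
    ms_c = ss["within_individuals"] / df_c
    copies_per_side = np.array([np.sum(copy_side == s) for s in np.unique(sides)],
                               dtype=float)
    n0 = (2 * n - (copies_per_side ** 2).sum() / (2 * n)) / df_a
    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / 2.0
    sigma_a = (ms_a - sigma_c - 2 * sigma_b) / n0
    sigma2 = {"a": sigma_a, "b": sigma_b, "c": sigma_c}
    phi_st = sigma_a / (sigma_a + sigma_b + sigma_c)
    return ss, sigma2, phi_st


def gd_dosage_oracle(g1, g2):
    """Codominant genotypic distance as half the squared dosage distance."""
    total = 0.0
    for l in range(len(g1)):
        alleles = sorted(set(list(g1[l]) + list(g2[l])))
        d1 = np.array([list(g1[l]).count(a) for a in alleles], dtype=float)
        d2 = np.array([list(g2[l]).count(a) for a in alleles], dtype=float)
        total += 0.5 * ((d1 - d2) ** 2).sum()
    return total


def random_plot_instance(rng, max_ind=6, max_loci=3, max_alleles=4):
    """A random small complete-data plot for oracle comparisons."""
    n = int(rng.integers(4, max_ind + 1))
    L = int(rng.integers(1, max_loci + 1))
    k = int(rng.integers(2, max_alleles + 1))
    while True:
        genotypes = rng.integers(1, k + 1, size=(n, L, 2))
        # need at least one polymorphic locus
        if any(len(np.unique(genotypes[:, l, :])) > 1 for l in range(L)):
            break
    n_a = int(rng.integers(2, n - 1))
    sides = np.array(["A"] * n_a + ["B"] * (n - n_a))
    return genotypes, sides
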