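"""Individual-pairwise genetic distances, relatedness estimators, and
geographic distances.

Distances
---------
* ``Dps`` — one minus the proportion of shared alleles: per locus the shared
  count is the multiset intersection of the two allele pairs (0, 1 or 2);
  the proportion pools shares over loci typed in both individuals
  (sum shared / (2 * L_typed)).
* ``Gd`` — codominant genotypic distance: per-locus squared distance classes
  d2(ii,ii) = d2(ij,ij) = 0; d2(ii,ij) = d2(ij,ik) = 1; d2(ij,kl) = 2;
  d2(ii,jk) = 3; d2(ii,jj) = 4, summed (not rescaled) over typed loci.
  Equivalent to half the squared Euclidean distance between allele-dosage
  vectors.

Relatedness
-----------
Moment estimators of pairwise relatedness r, all taking reference allele
frequencies as a parameter (here: the unweighted mean of per-plot frequency
vectors): the symmetrized Queller–Goodnight estimator (``Qgm``), the Ritland
kinship-based estimator (``Ri``), and the weighted Lynch–Ritland estimator
(``Lrm``).  ``Lrm`` is conventionally reported on a half scale by the common
spreadsheet tools, so the doubled value (expected 0.5 for parent–offspring
and full-sib dyads) is what this module exposes by default.  Negative values
are informative and never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genotype_io import MISSING, Dataset


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str  # Dps | Gd | Qgm | Ri | Lrm | euclidean | barrier

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise DistanceError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise DistanceError("matrix is not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# -- pairwise genetic distances --------------------------------------------

def dps_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Shared-allele distance between two (L, 2) genotypes: 1 - shared/(2L)."""
    typed = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    if not typed.any():
        raise DistanceError("no locus typed in both individuals")
    shared = 0
    for l in np.flatnonzero(typed):
        a, b = list(g1[l]), list(g2[l])
        for x in a:
            if x in b:
                shared += 1
                b.remove(x)
    return 1.0 - shared / (2.0 * typed.sum())


def smouse_peakall_gd(g1: np.ndarray, g2: np.ndarray) -> float:
    """Codominant genotypic distance, summed over loci typed in both."""
    typed = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    if not typed.any():
        raise DistanceError("no locus typed in both individuals")
    total = 0.0
    for l in np.flatnonzero(typed):
        total += _gd_locus(tuple(g1[l]), tuple(g2[l]))
    return total


def _gd_locus(x: tuple, y: tuple) -> float:
    if set(x) == set(y) and sorted(x) == sorted(y):
        return 0.0
    hom_x, hom_y = x[0] == x[1], y[0] == y[1]
    shared = len(set(x) & set(y))
    if hom_x and hom_y:
        return 4.0            # ii vs jj
    if hom_x != hom_y:
        return 1.0 if shared else 3.0   # ii vs ij / ii vs jk
    return 1.0 if shared else 2.0       # ij vs ik / ij vs kl


# -- relatedness estimators ------------------------------------------------

def _usable_locus(freqs: dict[int, float]) -> bool:
    return len(freqs) >= 2 and max(freqs.values()) < 1.0


def _freq(freqs: dict[int, float], allele: int, pseudo: float) -> float:
    return freqs.get(int(allele), pseudo)


def queller_goodnight(g1, g2, ref_freqs, pseudo=1e-4) -> float:
    """Symmetrized Queller–Goodnight estimator (ratio of locus sums)."""
    nums = [0.0, 0.0]
    dens = [0.0, 0.0]
    used = False
    for l in range(g1.shape[0]):
        if g1[l, 0] == MISSING or g2[l, 0] == MISSING or not _usable_locus(ref_freqs[l]):
            continue
        used = True
        for d, (x, y) in enumerate(((g1[l], g2[l]), (g2[l], g1[l]))):
            a, b = x
            pa = _freq(ref_freqs[l], a, pseudo)
            pb = _freq(ref_freqs[l], b, pseudo)
            share = 0.5 * sum(int(u == v) for u in (a, b) for v in y)
            nums[d] += share - (pa + pb)
            dens[d] += 1.0 + int(a == b) - (pa + pb)
    if not used:
        raise DistanceError("no usable locus for relatedness")
    vals = []
    for d in (0, 1):
        if dens[d] != 0:
            vals.append(nums[d] / dens[d])
    return float(np.mean(vals))


def ritland(g1, g2, ref_freqs, pseudo=1e-4) -> float:
    """Ritland moment estimator, locus-weighted by allele number minus one."""
    num = den = 0.0
    for l in range(g1.shape[0]):
        freqs = ref_freqs[l]
        if g1[l, 0] == MISSING or g2[l, 0] == MISSING or not _usable_locus(freqs):
            continue
        n_all = len(freqs)
        s = 0.0
        for a, p in freqs.items():
            x = int(g1[l, 0] == a) + int(g1[l, 1] == a)
            y = int(g2[l, 0] == a) + int(g2[l, 1] == a)
            s += x * y / (4.0 * max(p, pseudo))
        r_l = (2.0 / (n_all - 1.0)) * (s - 1.0)
        w = n_all - 1.0
        num += w * r_l
        den += w
    if den == 0:
        raise DistanceError("no usable locus for relatedness")
    return num / den


def _lr_directed(gx, gy, ref_freqs, pseudo):
    """Lynch–Ritland estimate with x as the reference individual."""
    num = den = 0.0
    for l in range(gx.shape[0]):
        freqs = ref_freqs[l]
        if gx[l, 0] == MISSING or gy[l, 0] == MISSING or not _usable_locus(freqs):
            continue
        a, b = gx[l]
        c, d = gy[l]
        pa = max(_freq(freqs, a, pseudo), pseudo)
        pb = max(_freq(freqs, b, pseudo), pseudo)
        dab = int(a == b)
        r_num = (pa * (int(b == c) + int(b == d)) + pb * (int(a == c) + int(a == d))
                 - 4.0 * pa * pb)
        r_den = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
        if r_den == 0:
            continue
        w = r_den / (2.0 * pa * pb)
        num += w * (r_num / r_den)
        den += w
    if den == 0:
        raise DistanceError("no usable locus for relatedness")
    return num / den


def lynch_ritland(g1, g2, ref_freqs, pseudo=1e-4, scaled=True) -> float:
    """Weighted Lynch–Ritland relatedness, symmetrized over reference choice.

    ``scaled=True`` (default) returns the doubled half-scale value, i.e. the
    estimator whose expectation is 0.5 for parent–offspring and full-sib
    dyads; ``scaled=False`` returns the raw half-scale value.
    """
    r = 0.5 * (_lr_directed(g1, g2, ref_freqs, pseudo) +
               _lr_directed(g2, g1, ref_freqs, pseudo))
    return r if scaled else 0.5 * r


_ESTIMATORS = {"Qgm": queller_goodnight, "Ri": ritland, "Lrm": lynch_ritland}


def relatedness(g1, g2, ref_freqs, estimator: str = "Qgm") -> float:
    """Pairwise relatedness under a named estimator ('Qgm', 'Ri' or 'Lrm')."""
    try:
        fn = _ESTIMATORS[estimator]
    except KeyError:
        raise DistanceError(f"unknown estimator {estimator!r}") from None
    return fn(g1, g2, ref_freqs)


# -- matrix builders -------------------------------------------------------

def genetic_distance_matrix(dataset: Dataset, kind: str = "Dps",
                            ref_freqs=None) -> DistanceMatrix:
    """Square pairwise matrix over the Dataset's individuals.

    kind 'Dps' or 'Gd' gives a distance (zero diagonal); 'Qgm', 'Ri', 'Lrm'
    give similarity (relatedness) matrices whose diagonal is set to NaN.
    """
    n = dataset.n_individuals
    vals = np.zeros((n, n))
    if kind in ("Dps", "Gd"):
        fn = dps_distance if kind == "Dps" else smouse_peakall_gd
        pair_fn = lambda i, j: fn(dataset.genotypes[i], dataset.genotypes[j])
    elif kind in _ESTIMATORS:
        if ref_freqs is None:
            raise DistanceError("reference frequencies required for relatedness")
        pair_fn = lambda i, j: relatedness(dataset.genotypes[i], dataset.genotypes[j],
                                           ref_freqs, kind)
    else:
        raise DistanceError(f"unknown matrix kind {kind!r}")
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pair_fn(i, j)
    if kind in _ESTIMATORS:
        np.fill_diagonal(vals, np.nan)
    return DistanceMatrix(labels=dataset.ids, values=vals, kind=kind)


def euclidean_geo(dataset: Dataset) -> DistanceMatrix:
    """Planar Euclidean distances (metres) among individuals."""
    xy = dataset.samples[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise DistanceError("missing or non-finite coordinates")
    return DistanceMatrix(labels=dataset.ids, values=squareform(pdist(xy)),
                          kind="euclidean")


def write_matrix(matrix: DistanceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="id")
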