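"""Diversity metrics: per-locus formulas, rarefaction, individual metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrierpop.diversity import (DiversityError, allele_counts,
                                  allele_frequencies, allelic_richness,
                                  diversity_table, individual_heterozygosity,
                                  plot_diversity, reference_frequencies,
                                  samplesize_correlation, side_differences)
from barrierpop.simulate import SimConfig, ancestral_frequencies, founder_genotypes
from helpers import make_dataset


def test_allele_frequencies_hand_count():
    freqs, n = allele_frequencies(np.array([[1, 1], [1, 2]]))
    assert freqs == {1: 0.75, 2: 0.25} and n == 4


def test_allele_frequencies_missing_excluded():
    freqs, n = allele_frequencies(np.array([[1, 2], [0, 0]]))
    assert n == 2 and freqs == {1: 0.5, 2: 0.5}
    with pytest.raises(DiversityError):
        allele_frequencies(np.array([[0, 0]]))


def test_plot_diversity_two_heterozygotes():
    ds = make_dataset(np.array([[[1, 2]], [[1, 2]]]), "AB")
    div = plot_diversity(ds, "P1", g=2)
    assert div.Ho == 1.0
    assert div.He == pytest.approx(0.5)
    assert div.uHe == pytest.approx(2 / 3)


def test_plot_diversity_complete_inbreeding():
    ds = make_dataset(np.array([[[1, 1]], [[2, 2]], [[1, 1]], [[2, 2]]]), "ABAB")
    div = plot_diversity(ds, "P1", g=2)
    assert div.Ho == 0.0 and div.He == pytest.approx(0.5)
    assert div.Fis == pytest.approx(1.0)


def test_allelic_richness_worked_value():
    # two alleles with 2 copies each, rarefied to 2 gene copies
    assert allelic_richness({1: 2, 2: 2}, g=2) == pytest.approx(2 * (1 - 1 / 6))


def test_allelic_richness_identity_and_monotone():
    counts = {1: 5, 2: 3, 3: 2}
    n = sum(counts.values())
    assert allelic_richness(counts, g=n) == pytest.approx(len(counts))
    vals = [allelic_richness(counts, g) for g in range(2, n + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    with pytest.raises(DiversityError):
        allelic_richness(counts, g=1)


@given(st.lists(st.integers(1, 6), min_size=2, max_size=20))
@settings(max_examples=60, deadline=None)
def test_uhe_upper_bounds_he_and_relabel_invariance(alleles):
    geno = np.array([[alleles[i], alleles[(i + 1) % len(alleles)]]
                     for i in range(len(alleles))])
    ds = make_dataset(geno[:, None, :], "AB" * (len(alleles) // 2) + "A" * (len(alleles) % 2))
    div = plot_diversity(ds, "P1", g=2)
    assert div.uHe >= div.He - 1e-12
    # relabel alleles by an order-reversing map: metrics unchanged
    relabeled = 7 - geno
    ds2 = make_dataset(relabeled[:, None, :], ds.samples["side"])
    div2 = plot_diversity(ds2, "P1", g=2)
    for m in ("Ho", "He", "uHe", "A"):
        assert getattr(div, m) == pytest.approx(getattr(div2, m), nan_ok=True)


def test_side_differences_symmetric():
    geno = np.array([[[1, 2]], [[1, 1]], [[2, 2]], [[1, 2]]])
    ds = make_dataset(geno, "AABB")
    da = plot_diversity(ds, "P1", "A", g=2)
    db = plot_diversity(ds, "P1", "B", g=2)
    d1 = side_differences(da, db)
    d2 = side_differences(db, da)
    assert (d1 >= 0).all()
    assert np.allclose(d1.values, d2.values)
    assert d1["Ho_DIF"] == pytest.approx(abs(da.Ho - db.Ho))


def test_samplesize_correlation_cases():
    import pandas as pd
    tab = pd.DataFrame({"n": [10, 20, 30, 40],
                        "Ho_DIF": [0.1, 0.2, 0.3, 0.4],   # exactly linear
                        "uHe_DIF": [0.2, 0.2, 0.2, 0.2],  # constant
                        "Ar_DIF": [0.3, 0.1, 0.4, 0.2]})
    r = samplesize_correlation(tab)
    assert r["Ho_DIF"] == pytest.approx(1.0)
    assert np.isnan(r["uHe_DIF"])
    assert -1 <= r["Ar_DIF"] <= 1


def test_individual_metrics_limits_and_worked_value():
    ref_freqs = [{1: 0.5, 2: 0.5}, {1: 0.6, 2: 0.4}]
    ref_ho = np.array([0.5, 0.5])
    ref_uhe = np.array([0.5, 0.48])
    fully_het = np.array([[1, 2], [1, 2]])
    d = individual_heterozygosity(fully_het, ref_freqs, ref_ho, ref_uhe, "x")
    assert d.PHt == 1.0 and d.HL == 0.0

    hom = np.array([[1, 1]])
    d2 = individual_heterozygosity(hom, [{1: 0.3, 2: 0.7}], np.array([0.5]),
                                   np.array([0.5]), "y")
    assert d2.IR == pytest.approx(1.0) and d2.HL == 1.0

    # HL with E(het locus)=0.8, E(hom locus)=0.6 -> 0.6/(0.6+0.8)
    ref_e = [{i + 1: 0.2 for i in range(5)},           # He = 0.8
             {1: np.sqrt(0.4)} | {2: 1 - np.sqrt(0.4)}]  # He = 0.6 approx
    e2 = 1 - (0.4 + (1 - np.sqrt(0.4)) ** 2)
    ind = np.array([[1, 2], [1, 1]])
    d3 = individual_heterozygosity(ind, ref_e, np.array([0.5, 0.5]),
                                   np.array([0.8, 0.6]), "z")
    assert d3.HL == pytest.approx(e2 / (e2 + 0.8), abs=1e-9)


def test_panmictic_fis_near_zero(rng):
    # Hardy-Weinberg demes: mean F_IS over replicates within +-0.05 of 0
    cfg = SimConfig()
    vals = []
    for _ in range(40):
        freqs = ancestral_frequencies(cfg, rng)
        geno = founder_genotypes(50, freqs, rng)
        ds = make_dataset(geno, "AB" * 25)
        vals.append(plot_diversity(ds, "P1", g=10).Fis)
    assert abs(np.mean(vals)) < 0.05


def test_diversity_table_structure(small_landscape):
    tab = diversity_table(small_landscape.dataset)
    assert len(tab) == len(small_landscape.dataset.plots())
    assert {"Ho", "uHe", "Ar", "Ho_DIF", "uHe_DIF", "Ar_DIF"} <= set(tab.columns)
    assert (tab[["Ho_DIF", "uHe_DIF", "Ar_DIF"]] >= 0).all().all()
    assert tab["n"].equals(tab["Na"] + tab["Nb"])


def test_reference_frequencies_average_over_plots():
    # two plots with different fixed alleles -> reference is the plain mean
    g1 = np.tile([1, 1], (4, 1))[:, None, :]
    g2 = np.tile([2, 2], (4, 1))[:, None, :]
    ds1 = make_dataset(g1, "AABB", plot="X")
    ds2 = make_dataset(g2, "AABB", plot="Y")
    import pandas as pd
    ds = make_dataset(np.concatenate([g1, g2]), "AABBAABB")
    ds.samples.loc[:3, "plot"] = "X"
    ds.samples.loc[4:, "plot"] = "Y"
    ds.samples["id"] = [f"i{k}" for k in range(8)]
    ref = reference_frequencies(ds)
    assert ref[0] == {1: 0.5, 2: 0.5}
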