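"""Quality-control chain: HWE, LD, null alleles, error rates, sib filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrierpop.diversity import reference_frequencies
from barrierpop.qc import (QcError, SibFlag, apply_filters, brookfield_null,
                           duplicate_error_rates, flag_full_sibs, hwe_test,
                           ld_test)
from barrierpop.simulate import (SimConfig, ancestral_frequencies,
                                 mendelian_offspring, simulate_landscape)
from helpers import make_dataset


# -- Hardy-Weinberg --------------------------------------------------------

def _genotypes(pairs):
    return np.array(pairs, dtype=np.int64)


def test_hwe_at_exact_proportions_is_null():
    # AA=25, Aa=50, aa=25 is the modal table given 50/50 allele counts: no
    # table is more probable, so the exact p-value is 1 up to MC noise
    geno = _genotypes([(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25)
    res = hwe_test(geno, n_mc=2000, seed=1)
    assert res.p_value > 0.5


def test_hwe_all_heterozygotes_rejected():
    geno = _genotypes([(1, 2)] * 50)
    res = hwe_test(geno, n_mc=5000, seed=1)
    assert res.p_value < 0.001


def test_hwe_monomorphic_flagged():
    res = hwe_test(_genotypes([(3, 3)] * 10), n_mc=100, seed=0)
    assert res.p_value == 1.0 and res.flag == "monomorphic"


def test_hwe_deterministic_under_seed():
    geno = _genotypes([(1, 1)] * 12 + [(1, 2)] * 6 + [(2, 2)] * 12)
    p1 = hwe_test(geno, n_mc=500, seed=7).p_value
    p2 = hwe_test(geno, n_mc=500, seed=7).p_value
    assert p1 == p2


# -- linkage disequilibrium ------------------------------------------------

def test_ld_duplicated_locus_detected(rng):
    geno = rng.integers(1, 5, size=(50, 2))
    p = ld_test(geno, geno.copy(), n_perm=199, seed=3)
    assert p <= 0.01


def test_ld_p_granularity(rng):
    gi = rng.integers(1, 4, size=(30, 2))
    gj = rng.integers(1, 4, size=(30, 2))
    p = ld_test(gi, gj, n_perm=999, seed=5)
    assert abs(p * 1000 - round(p * 1000)) < 1e-9 and 0 < p <= 1


# -- Brookfield null alleles -----------------------------------------------

def test_brookfield_worked_value():
    est = brookfield_null(ho=0.8, he=0.9)
    assert est.r_null == pytest.approx(0.1 / 1.9, abs=1e-12)


def test_brookfield_equal_and_excess():
    assert brookfield_null(0.7, 0.7).r_null == 0.0
    clipped = brookfield_null(0.9, 0.8)
    assert clipped.r_null == 0.0 and clipped.flag == "excess_heterozygosity"


@given(he=st.floats(0.0, 1.0), delta=st.floats(0.0, 0.5))
@settings(max_examples=50, deadline=None)
def test_brookfield_monotone_in_deficit(he, delta):
    ho = max(he - delta, 0.0)
    lesser = brookfield_null(min(ho + 0.01, he), he).r_null
    assert brookfield_null(ho, he).r_null >= lesser - 1e-12


# -- duplicate error rates -------------------------------------------------

def test_error_rates_identical_duplicates(rng):
    g = rng.integers(1, 6, size=(40, 2))
    est = duplicate_error_rates(g, g.copy())
    assert est.e1 == 0.0 and est.e2 == 0.0 and est.n_duplicates == 40


def test_error_rates_hand_counts(rng):
    orig = np.tile([1, 2], (50, 1))
    rep = orig.copy()
    rep[0] = [1, 1]               # dropout: het -> hom sharing one allele
    est = duplicate_error_rates(orig, rep)
    assert est.e1 == pytest.approx(1 / 50) and est.e2 == 0.0

    orig2 = np.tile([1, 2], (100, 1))
    rep2 = orig2.copy()
    rep2[0] = [1, 9]              # novel allele appears
    est2 = duplicate_error_rates(orig2, rep2)
    assert est2.e2 == pytest.approx(1 / 100) and est2.e1 == 0.0


def test_error_rates_no_duplicates_flagged():
    empty = np.zeros((0, 2), dtype=int)
    est = duplicate_error_rates(empty, empty)
    assert est.flag == "no_duplicates" and np.isnan(est.e1)


# -- full-sib filtering ----------------------------------------------------

def _litter_dataset(rng, split_points=False, n_unrelated=60):
    """Four full sibs plus an unrelated background at distinct points.

    The unrelated background must be large enough for usable reference
    allele frequencies (in the real design the reference pools all plots).
    """
    cfg = SimConfig()
    freqs = ancestral_frequencies(cfg, rng)
    from barrierpop.simulate import founder_genotypes
    unrelated = founder_genotypes(n_unrelated, freqs, rng)
    p1, p2 = founder_genotypes(2, freqs, rng)
    sibs = mendelian_offspring(p1, p2, rng, n=4)
    geno = np.concatenate([unrelated, sibs])
    points = [f"pt{i}" for i in range(n_unrelated)]
    if split_points:
        points += ["ptL1", "ptL1", "ptL2", "ptL2"]
    else:
        points += ["ptL"] * 4
    sides = "AB" * (n_unrelated // 2) + "AAAA"
    sib_ids = [f"P1_i{i}" for i in range(n_unrelated, n_unrelated + 4)]
    return make_dataset(geno, sides, points=points), sib_ids


def test_litter_at_one_point_keeps_one(rng):
    # the relatedness-threshold proxy is stochastic (9 loci): over replicate
    # litters it must resolve the large majority exactly (3 of 4 discarded,
    # 1 kept) and must never discard an entire litter
    resolved = 0
    n_rep = 15
    for _ in range(n_rep):
        ds, sib_ids = _litter_dataset(rng)
        ref = reference_frequencies(ds)
        flags = flag_full_sibs(ds, ref, threshold=0.35, seed=9)
        kept = [f for f in flags if f.id in sib_ids and f.kept]
        discarded = [f for f in flags if f.id in sib_ids and not f.kept]
        assert len(discarded) < 4, "entire litter discarded"
        if len(discarded) == 3 and len(kept) == 1:
            resolved += 1
    assert resolved >= 0.7 * n_rep


def test_litter_split_across_points_mostly_retained(rng):
    ds, sib_ids = _litter_dataset(rng, split_points=True)
    ref = reference_frequencies(ds)
    flags = flag_full_sibs(ds, ref, threshold=0.35, seed=9)
    # one sib survives at each of the two points: >= 2 of the 4 kept
    discarded = {f.id for f in flags if not f.kept}
    assert len(set(sib_ids) - discarded) >= 2


def test_unrelated_dataset_rarely_flagged(rng):
    # same-point unrelated pairs: the 0.35 threshold is calibrated to a
    # small false-positive rate on 9-locus high-diversity genotypes
    cfg = SimConfig()
    freqs = ancestral_frequencies(cfg, rng)
    from barrierpop.simulate import founder_genotypes
    geno = founder_genotypes(60, freqs, rng)
    points = [f"pt{i % 30}" for i in range(60)]  # two unrelated per point
    ds = make_dataset(geno, "AB" * 30, points=points)
    ref = reference_frequencies(ds)
    flags = flag_full_sibs(ds, ref, threshold=0.35, seed=4)
    discarded = [f for f in flags if not f.kept]
    assert len(discarded) <= 3  # <5% of 60


# -- filter application ----------------------------------------------------

def _flags(ids, keep_first=True):
    return [SibFlag(id=i, sampling_point="p", kept=(k == 0 and keep_first),
                    reason="litter") for k, i in enumerate(ids)]


def test_filter_arithmetic_small(small_landscape):
    ds = small_landscape.dataset
    ids = ds.ids
    failed = ids[:5]
    sib = _flags(ids[5:9], keep_first=True)  # 3 discarded
    filtered, rep = apply_filters(ds, failed, sib)
    assert rep.n_retained == ds.n_individuals - 5 - 3
    assert filtered.n_individuals == rep.n_retained
    assert set(rep.removals["reason"]) == {"genotyping_failed", "full_sib_same_point"}


def test_filter_empty_is_identity(small_landscape):
    ds = small_landscape.dataset
    filtered, rep = apply_filters(ds)
    assert filtered.n_individuals == ds.n_individuals and rep.n_failed == 0


def test_filter_overlap_rejected(small_landscape):
    ds = small_landscape.dataset
    dup = ds.ids[0]
    with pytest.raises(QcError, match="both removal sets"):
        apply_filters(ds, [dup], _flags([dup, ds.ids[1]], keep_first=False))
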