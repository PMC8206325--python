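"""Simulator: schedules, sampling geometry, litters, drift/migration limits."""

import numpy as np
import pytest

from barrierpop.amova import amova_from_arrays
from barrierpop.simulate import (SimConfig, ancestral_frequencies,
                                 cyclic_schedule, founder_genotypes,
                                 inject_litters, mendelian_offspring,
                                 sample_individuals, simulate_landscape,
                                 simulate_plot)


def test_schedule_null_barrier_identical():
    cfg = SimConfig(barrier_factor=1.0)
    exp = cyclic_schedule(cfg, experimental=True)
    ctl = cyclic_schedule(cfg, experimental=False)
    assert exp.equals(ctl)


def test_schedule_sealed_barrier_zero_migration():
    cfg = SimConfig(barrier_factor=0.0)
    exp = cyclic_schedule(cfg, experimental=True)
    assert (exp["m_eff"] == 0).all()
    ctl = cyclic_schedule(cfg, experimental=False)
    assert (ctl["m_eff"] > 0).all()


def test_schedule_peak_count():
    cfg = SimConfig(cycle_length=4, generations=20, peak_width=1)
    sched = cyclic_schedule(cfg, experimental=False)
    assert sched["peak"].sum() == 5
    assert set(sched.loc[sched["peak"], "N"]) == {cfg.n_peak}
    # migration capped at 0.5 even with strong pulses
    cfg2 = SimConfig(m=0.4, pulse_factor=2.0)
    assert cyclic_schedule(cfg2, False)["m_eff"].max() == 0.5


def test_sampling_counts_and_geometry(rng):
    cfg = SimConfig(n_sample_min=20, n_sample_max=20, n_low=30, n_peak=60,
                    generations=5)
    freqs = ancestral_frequencies(cfg, rng)
    ga, gb, pa, pb, _ = simulate_plot(cfg, False, freqs, rng)
    genos, rows, ped = sample_individuals((ga, gb), (pa, pb), "P1", cfg, rng)
    sides = [r[2] for r in rows]
    ys = np.array([r[5] for r in rows])
    assert sides.count("A") == 20 and sides.count("B") == 20
    assert (ys[np.array(sides) == "A"] > 0).all()
    assert (ys[np.array(sides) == "B"] < 0).all()


def test_unequal_sampling_supported(rng):
    cfg = SimConfig(n_sample_min=6, n_sample_max=72, n_low=80, n_peak=100,
                    generations=5)
    freqs = ancestral_frequencies(cfg, rng)
    ga, gb, pa, pb, _ = simulate_plot(cfg, False, freqs, rng)
    genos, rows, _ = sample_individuals((ga, gb), (pa, pb), "P1", cfg, rng)
    counts = {s: [r[2] for r in rows].count(s) for s in "AB"}
    assert all(6 <= c <= 72 for c in counts.values())


def test_oversampling_rejected(rng):
    cfg = SimConfig(n_sample_min=50, n_sample_max=50, n_low=30, n_peak=30,
                    generations=3, cycle_length=4, peak_width=0)
    freqs = ancestral_frequencies(cfg, rng)
    ga, gb, pa, pb, _ = simulate_plot(cfg, False, freqs, rng)
    with pytest.raises(ValueError, match="cannot sample"):
        sample_individuals((ga, gb), (pa, pb), "P1", cfg, rng)


def test_litter_injection_truth(rng):
    cfg = SimConfig(n_sample_min=10, n_sample_max=10, n_low=30, n_peak=60,
                    generations=5)
    freqs = ancestral_frequencies(cfg, rng)
    ga, gb, pa, pb, _ = simulate_plot(cfg, False, freqs, rng)
    genos, rows, _ = sample_individuals((ga, gb), (pa, pb), "P1", cfg, rng)
    n_before = genos.shape[0]
    genos2, rows2, truth = inject_litters(genos, list(rows),
                                          [{"plot": "P1", "size": 4}],
                                          "P1", freqs, rng)
    assert genos2.shape[0] == n_before + 4 and len(truth) == 4
    litter_ids = {t[3] for t in truth}
    assert len(litter_ids) == 1
    points = {t[2] for t in truth}
    assert len(points) == 1  # all sibs at one sampling point

    # no-spec identity
    g3, r3, t3 = inject_litters(genos, list(rows), [], "P1", freqs, rng)
    assert g3.shape[0] == n_before and t3 == []


def test_litter_sibs_have_high_relatedness(rng):
    from barrierpop.distances import lynch_ritland
    cfg = SimConfig()
    freqs = ancestral_frequencies(cfg, rng)
    ref = [{a + 1: f for a, f in enumerate(freqs[l]) if f > 0}
           for l in range(cfg.n_loci)]
    vals = []
    for _ in range(150):
        p1, p2 = founder_genotypes(2, freqs, rng)
        kids = mendelian_offspring(p1, p2, rng, n=2)
        vals.append(lynch_ritland(kids[0], kids[1], ref))
    assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


def test_panmixia_limit_low_fst(rng):
    # m_eff = 0.5 -> both sides one deme: Phi_ST scatters around 0
    cfg = SimConfig(n_low=100, n_peak=100, peak_width=0, generations=30,
                    m=0.5, pulse_factor=1.0, mu=0.0)
    vals = []
    for _ in range(10):
        freqs = ancestral_frequencies(cfg, rng)
        ga, gb, *_ = simulate_plot(cfg, False, freqs, rng)
        g = np.concatenate([ga, gb])
        sides = np.array(["A"] * 100 + ["B"] * 100)
        vals.append(amova_from_arrays(g, sides).phi_st)
    assert abs(np.mean(vals)) < 0.01


def test_sealed_barrier_drifts_toward_fixation(rng):
    # b = 0, small demes, many generations: differentiation becomes large
    cfg = SimConfig(n_low=20, n_peak=20, peak_width=0, generations=120,
                    m=0.2, barrier_factor=0.0, mu=0.0, n_alleles=4,
                    dirichlet_alpha=1.0)
    vals = []
    for _ in range(5):
        freqs = ancestral_frequencies(cfg, rng)
        ga, gb, *_ = simulate_plot(cfg, True, freqs, rng)
        g = np.concatenate([ga, gb])
        sides = np.array(["A"] * 20 + ["B"] * 20)
        vals.append(amova_from_arrays(g, sides).phi_st)
    assert np.mean(vals) > 0.5


def test_mutation_respects_allele_bounds(rng):
    cfg = SimConfig(n_low=30, n_peak=60, generations=10, mu=0.2, n_alleles=5)
    freqs = ancestral_frequencies(cfg, rng)
    ga, gb, *_ = simulate_plot(cfg, False, freqs, rng)
    allall = np.concatenate([ga, gb]).reshape(-1)
    assert allall.min() >= 1 and allall.max() <= 5


def test_landscape_structure_and_reproducibility():
    cfg = SimConfig(n_pairs=2, treatments=("R", "CB"), n_low=20, n_peak=60,
                    generations=5, n_sample_min=8, n_sample_max=10)
    res1 = simulate_landscape(cfg, seed=77)
    res2 = simulate_landscape(cfg, seed=77)
    assert np.array_equal(res1.dataset.genotypes, res2.dataset.genotypes)
    ds = res1.dataset
    assert ds.plots() == ["R1", "R1c", "CB1", "CB1c"]
    design = ds.design.set_index("plot")
    assert design.loc["R1", "role"] == "experimental"
    assert design.loc["R1c", "treatment"] == "T"
    # pedigree covers every sampled non-litter individual
    assert set(res1.pedigree["id"]) == set(ds.ids)


def test_config_validation():
    with pytest.raises(ValueError, match="n_low"):
        SimConfig(n_low=1)
    with pytest.raises(ValueError, match="barrier_factor"):
        SimConfig(barrier_factor=1.5)
    with pytest.raises(ValueError, match="one entry per pair"):
        SimConfig(n_pairs=2, treatments=("R",))
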