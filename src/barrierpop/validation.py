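"""Calibration and parameter-recovery experiments on simulated landscapes.

These are the package's statistical self-checks, run by the test suite and
the results-reproduction script:

* type-I-error calibration of the per-plot permutation tests (partial Mantel
  and Phi_ST) and of the full paired pipeline on null landscapes
  (barrier factor b = 1, experimental and control exchangeable);
* barrier recovery: with a sealed barrier (b = 0, no mutation) experimental
  plots must show elevated between-side FST relative to their paired
  controls, and the paired t-test across pairs must detect it;
* relatedness parameter recovery on pedigree dyads of known relationship;
* drift-migration equilibrium of between-deme differentiation against the
  closed-form two-deme island-model expectation.

Simulated problem sizes are chosen so each experiment runs in minutes on one
CPU; the generation counts and deme sizes are stated per experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .amova import amova_from_arrays, amova_permutation
from .differentiation import _side_locus_stats, hs_ht
from .distances import genetic_distance_matrix, euclidean_geo
from .genotype_io import Dataset
from .inference import paired_t_test, pipeline_metric_table, DEFAULT_PRIORITY
from .mantel import barrier_model_matrix, partial_mantel
from .simulate import (SimConfig, ancestral_frequencies, sample_individuals,
                       simulate_plot)

# a cheap null plot: shallow cyclic history, small demes, 12 samples per side
FAST_NULL = dict(n_loci=9, n_alleles=30, n_low=40, n_peak=160, cycle_length=4,
                 peak_width=1, generations=8, m=0.2, mu=5e-4, pulse_factor=2.0,
                 n_sample_min=12, n_sample_max=12)


def _single_plot_dataset(cfg: SimConfig, experimental: bool, freqs, rng,
                         plot: str = "P1") -> Dataset:
    ga, gb, pa, pb, _ = simulate_plot(cfg, experimental, freqs, rng)
    genos, rows, _ = sample_individuals((ga, gb), (pa, pb), plot, cfg, rng)
    samples = pd.DataFrame(
        [(r[0], r[1], plot, "R" if experimental else "T", r[2], r[3], r[4], r[5])
         for r in rows],
        columns=["id", "plot", "pair_id", "treatment", "side",
                 "sampling_point", "x", "y"])
    return Dataset(loci=[f"L{i+1:02d}" for i in range(cfg.n_loci)],
                   genotypes=genos, samples=samples)


def permutation_type_i(n_plots: int = 200, n_perm: int = 199, alpha: float = 0.05,
                       seed: int = 0) -> dict:
    """Rejection rates of the partial-Mantel and Phi_ST permutation tests on
    null (no-barrier) plots.

    Each plot is fully panmictic (m_eff = 0.5: an offspring's parents come
    from either half with equal probability, i.e. the "sides" are arbitrary
    halves of one deme), so the barrier hypothesis is exactly false and any
    rejection is a false positive.  Returns the counts and rates for both
    tests.
    """
    cfg = SimConfig(n_pairs=1, treatments=("R",),
                    **{**FAST_NULL, "m": 0.5, "pulse_factor": 1.0})
    master = np.random.SeedSequence(seed)
    rej_mantel = rej_phist = 0
    for ss in master.spawn(n_plots):
        rng = np.random.default_rng(ss)
        freqs = ancestral_frequencies(cfg, rng)
        ds = _single_plot_dataset(cfg, False, freqs, rng)
        gm = genetic_distance_matrix(ds, kind="Gd")
        res = partial_mantel(gm, barrier_model_matrix(ds), euclidean_geo(ds),
                             n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        if res.p_one_tailed <= alpha:
            rej_mantel += 1
        am = amova_permutation(ds, "P1", n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)), stats=("Phi_ST",))
        if am.p_values["Phi_ST"] <= alpha:
            rej_phist += 1
    return {"n_plots": n_plots, "alpha": alpha,
            "mantel_rejections": rej_mantel, "mantel_rate": rej_mantel / n_plots,
            "phist_rejections": rej_phist, "phist_rate": rej_phist / n_plots}


def pipeline_type_i(n_landscapes: int = 100, n_pairs: int = 15, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Paired-pipeline false-positive rate over null landscapes (b = 1).

    Each landscape runs the full metric pipeline (diversity, AMOVA,
    differentiation, Mantel r) and the paired t-test per metric; with no
    barrier effect the pooled rejection fraction should sit near alpha.
    """
    treatments = tuple(np.resize(["R", "H", "CB"], n_pairs))
    cfg = SimConfig(n_pairs=n_pairs, treatments=treatments, barrier_factor=1.0,
                    **FAST_NULL)
    from .simulate import simulate_landscape
    from .inference import InferenceError
    master = np.random.SeedSequence(seed)
    rejections = {m: 0 for m in DEFAULT_PRIORITY}
    total = n_tests = 0
    for ss in master.spawn(n_landscapes):
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        res = simulate_landscape(cfg, seed=sub_seed)
        table = pipeline_metric_table(res.dataset, n_perm=0)
        total += 1
        for m in DEFAULT_PRIORITY:
            try:
                t = paired_t_test(table, m, n_boot=0, seed=0)
            except InferenceError:
                # rare degenerate plot (e.g. exactly-zero among-individual
                # variance makes sigma_bw undefined for one pair)
                continue
            n_tests += 1
            if t.p <= alpha:
                rejections[m] += 1
    n_rej = sum(rejections.values())
    return {"n_landscapes": total, "alpha": alpha, "per_metric": rejections,
            "pooled_rate": n_rej / n_tests, "n_tests": n_tests}


def barrier_recovery(n_single_pairs: int = 100, n_landscapes: int = 50,
                     n_pairs: int = 15, generations: int = 50, seed: int = 0) -> dict:
    """Power of the design under a sealed barrier.

    Conditions: b = 0 for experimental plots, mu = 0, constant deme size
    N = 100, ``generations`` post-barrier generations, baseline m = 0.05 for
    controls, 20 samples per side.  Reports (a) the fraction of simulated
    pairs in which the experimental plot's Phi_ST exceeds its control's and
    (b) the fraction of replicate landscapes where the paired t-test on FST
    across pairs is significant at 0.05.
    """
    cfg = SimConfig(n_pairs=1, treatments=("R",), n_loci=9, n_alleles=30,
                    n_low=100, n_peak=100, cycle_length=4, peak_width=0,
                    generations=generations, m=0.05, mu=0.0, pulse_factor=1.0,
                    barrier_factor=0.0, n_sample_min=20, n_sample_max=20)
    master = np.random.SeedSequence(seed)

    def pair_fsts(rng):
        freqs = ancestral_frequencies(cfg, rng)
        out = []
        for experimental in (True, False):
            ds = _single_plot_dataset(cfg, experimental, freqs, rng)
            out.append(amova_from_arrays(ds.genotypes,
                                         ds.samples["side"].to_numpy()).phi_st)
        return out  # (experimental, control)

    exceed = 0
    streams = master.spawn(n_single_pairs + n_landscapes)
    for ss in streams[:n_single_pairs]:
        fst_e, fst_c = pair_fsts(np.random.default_rng(ss))
        if fst_e > fst_c:
            exceed += 1

    detected = 0
    from scipy import stats as sps
    for ss in streams[n_single_pairs:]:
        rng = np.random.default_rng(ss)
        diffs = []
        for _ in range(n_pairs):
            fst_e, fst_c = pair_fsts(rng)
            diffs.append(fst_e - fst_c)
        t = sps.ttest_1samp(diffs, 0.0)
        if t.pvalue < 0.05:
            detected += 1
    return {"n_single_pairs": n_single_pairs, "exceed_fraction": exceed / n_single_pairs,
            "n_landscapes": n_landscapes, "detect_fraction": detected / n_landscapes}


def relatedness_recovery(n_dyads: int = 500, seed: int = 0) -> dict:
    """Mean Qgm and doubled Lynch–Ritland relatedness on pedigree dyads.

    Dyads are drawn from the default high-diversity ancestral pool (9 loci,
    up to 30 alleles); expectations are 0.5 for parent–offspring and full
    sibs, 0.25 for half sibs, 0 for unrelated pairs.
    """
    from .distances import lynch_ritland, queller_goodnight
    from .simulate import simulate_dyads
    cfg = SimConfig()
    rng = np.random.default_rng(seed)
    freqs = ancestral_frequencies(cfg, rng)
    ref = [{a + 1: f for a, f in enumerate(freqs[l]) if f > 0}
           for l in range(cfg.n_loci)]
    out = {}
    for rel in ("unrelated", "parent_offspring", "full_sib", "half_sib"):
        a, b = simulate_dyads(freqs, rel, n_dyads, rng)
        out[rel] = {
            "Qgm": float(np.mean([queller_goodnight(a[i], b[i], ref)
                                  for i in range(n_dyads)])),
            "Lrm": float(np.mean([lynch_ritland(a[i], b[i], ref)
                                  for i in range(n_dyads)])),
        }
    return out


def island_model_fst(n_reps: int = 100, n: int = 100, m: float = 0.01,
                     generations: int = 400, seed: int = 0) -> dict:
    """Two-deme drift–migration equilibrium vs the island-model closed form.

    Constant deme size ``n``, no mutation, symmetric migration ``m``; the
    pooled Nei–Chesser GST over replicates is compared with the k-island
    small-m approximation FST = 1 / (4 N m (k/(k-1))^2 + 1), k = 2 — accurate
    to a few percent at m = 0.01.
    """
    cfg = SimConfig(n_pairs=1, treatments=("R",), n_loci=9, n_alleles=30,
                    n_low=n, n_peak=n, cycle_length=4, peak_width=0,
                    generations=generations, m=m, mu=0.0, pulse_factor=1.0)
    master = np.random.SeedSequence(seed)
    num = den = 0.0
    for ss in master.spawn(n_reps):
        rng = np.random.default_rng(ss)
        freqs = ancestral_frequencies(cfg, rng)
        ga, gb, *_ = simulate_plot(cfg, False, freqs, rng)
        for l in range(cfg.n_loci):
            sa = _side_locus_stats(ga[:, l, :])
            sb = _side_locus_stats(gb[:, l, :])
            hs, ht = hs_ht([sa[0], sb[0]], [sa[1], sb[1]], [sa[2], sb[2]],
                           corrected=True)
            num += ht - hs
            den += ht
    expected = 1.0 / (4.0 * n * m * 4.0 + 1.0)
    return {"n_reps": n_reps, "fst": num / den, "expected": expected}
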