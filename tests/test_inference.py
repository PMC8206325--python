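"""Metric pruning, paired tests, effect sizes, LMMs and regressions."""

import numpy as np
import pandas as pd
import pytest

from barrierpop.field_tables import plot_metric_table
from barrierpop.inference import (InferenceError, age_width_correlation,
                                  f2_label, g_label, hedges_g,
                                  highway_regressions, lmm_treatment,
                                  paired_t_test, prune_metrics)


def _metric_table(values_by_pair, metric="m", treatment="R"):
    rows = []
    for pair, (ve, vc) in values_by_pair.items():
        rows.append({"plot": pair, "pair_id": pair, "treatment": treatment,
                     "role": "experimental", "metric": metric, "value": ve})
        rows.append({"plot": pair + "c", "pair_id": pair, "treatment": "T",
                     "role": "control", "metric": metric, "value": vc})
    return pd.DataFrame(rows)


# -- pruning ---------------------------------------------------------------

def test_prune_drops_highly_correlated(rng):
    x = rng.normal(size=30)
    wide = pd.DataFrame({"Ho": x, "uHe": x + rng.normal(0, 0.01, 30),
                         "Ar": rng.normal(size=30)})
    retained, corr = prune_metrics(wide)
    assert retained == ["Ho", "Ar"]
    assert abs(corr.loc["Ho", "uHe"]) >= 0.80


def test_prune_keeps_uncorrelated(rng):
    wide = pd.DataFrame(rng.normal(size=(40, 3)), columns=["Ho", "Fst", "r_Gd"])
    retained, _ = prune_metrics(wide)
    assert retained == ["Ho", "Fst", "r_Gd"]


def test_prune_row_order_invariant(rng):
    wide = pd.DataFrame(rng.normal(size=(25, 4)),
                        columns=["Ho", "uHe", "Fst", "r_Gd"])
    wide["uHe"] = wide["Ho"] * 1.01 + 0.001  # collinear
    r1, _ = prune_metrics(wide)
    r2, _ = prune_metrics(wide.sample(frac=1.0, random_state=4))
    assert r1 == r2 and "uHe" not in r1


def test_prune_constant_column_rejected():
    wide = pd.DataFrame({"Ho": [1.0, 1.0, 1.0], "Ar": [1, 2, 3.0]})
    with pytest.raises(InferenceError, match="constant"):
        prune_metrics(wide)


# -- paired t-test and Hedges' g -------------------------------------------

def test_published_anchor_ho():
    res = paired_t_test(plot_metric_table(), "Ho", n_boot=199, seed=1)
    assert res.t == pytest.approx(0.202, abs=0.02)
    assert res.mean_difference == pytest.approx(0.001, abs=0.01)
    assert res.hedges_g == pytest.approx(0.049, abs=0.01)
    assert res.n_pairs == 15 and res.df == 14


def test_published_anchor_ar():
    res = paired_t_test(plot_metric_table(), "Ar", n_boot=199, seed=1)
    assert res.t == pytest.approx(0.291, abs=0.02)
    assert res.mean_difference == pytest.approx(0.035, abs=0.01)
    assert res.hedges_g == pytest.approx(0.071, abs=0.01)


def test_paired_t_antisymmetric_under_role_swap():
    tab = _metric_table({f"P{k}": (0.5 + 0.02 * k, 0.45) for k in range(6)})
    res = paired_t_test(tab, "m", n_boot=0)
    swapped = tab.copy()
    swapped["role"] = swapped["role"].map({"experimental": "control",
                                           "control": "experimental"})
    res_sw = paired_t_test(swapped, "m", n_boot=0)
    assert res_sw.t == pytest.approx(-res.t)
    assert res_sw.mean_difference == pytest.approx(-res.mean_difference)


def test_paired_t_identical_values():
    tab = _metric_table({f"P{k}": (0.5, 0.5) for k in range(5)})
    res = paired_t_test(tab, "m", n_boot=0)
    assert res.t == 0.0 and res.p == 1.0 and res.hedges_g == 0.0


def test_paired_t_incomplete_pair_raises():
    tab = _metric_table({"P1": (0.5, 0.4), "P2": (0.6, 0.5)})
    tab = tab[~((tab["pair_id"] == "P2") & (tab["role"] == "control"))]
    with pytest.raises(InferenceError, match="incomplete"):
        paired_t_test(tab, "m", n_boot=0)


def test_hedges_g_small_sample_correction(rng):
    d = rng.normal(0.5, 1.0, size=15)
    g, lo, hi, label = hedges_g(d, n_boot=199, seed=2)
    j = 1 - 3 / (4 * 14 - 1)
    assert g == pytest.approx(d.mean() / d.std(ddof=1) * j)
    assert lo <= g <= hi


def test_hedges_g_zero_mean():
    d = np.array([0.1, -0.1, 0.2, -0.2])
    g, *_ , label = hedges_g(d, n_boot=0)
    assert abs(g) < 0.2 and label == "negligible"


def test_bootstrap_ci_coverage(rng):
    # nominal 95% CI for g on normal paired differences, n = 15
    true_mu, true_sd, n = 0.4, 1.0, 15
    true_g = true_mu / true_sd  # population standardized effect
    n_rep, covered = 1000, 0
    for _ in range(n_rep):
        d = rng.normal(true_mu, true_sd, size=n)
        _, lo, hi, _ = hedges_g(d, n_boot=999, seed=int(rng.integers(2 ** 31)))
        if lo <= true_g <= hi:
            covered += 1
    assert covered / n_rep == pytest.approx(0.95, abs=0.03)


def test_effect_size_labels():
    assert [g_label(v) for v in (0.1, 0.3, 0.6, 1.2)] == \
        ["negligible", "small", "medium", "large"]
    assert [f2_label(v) for v in (0.01, 0.05, 0.2, 0.5)] == \
        ["negligible", "small", "medium", "large"]


# -- LMM -------------------------------------------------------------------

def _landscape_table(rng, shift=0.0, n_pairs_per_tr=4, sd_pair=0.1, sd_e=0.05):
    rows = []
    k = 0
    for tr in ("R", "H", "CB"):
        for _ in range(n_pairs_per_tr):
            k += 1
            pair = f"{tr}{k}"
            u = rng.normal(0, sd_pair)
            base = 0.8 + u
            delta = shift if tr == "H" else 0.0
            rows.append({"plot": pair, "pair_id": pair, "treatment": tr,
                         "role": "experimental", "metric": "Ho",
                         "value": base + delta + rng.normal(0, sd_e)})
            rows.append({"plot": pair + "c", "pair_id": pair, "treatment": "T",
                         "role": "control", "metric": "Ho",
                         "value": base + rng.normal(0, sd_e)})
    return pd.DataFrame(rows)


def test_lmm_recovers_shift(rng):
    tab = _landscape_table(rng, shift=0.3)
    res = lmm_treatment(tab, "Ho")
    h_term = [ix for ix in res.fixed_effects.index if "[T.H]" in ix][0]
    assert res.fixed_effects[h_term] == pytest.approx(0.3, abs=0.1)
    assert res.f2 > 0.35  # a 6-sd shift is a large effect


def test_lmm_null_contrasts_small(rng):
    tab = _landscape_table(rng, shift=0.0)
    res = lmm_treatment(tab, "Ho")
    assert np.abs(res.fixed_effects).max() < 0.15
    assert res.random_variance > 0  # pairing variance is picked up


# -- highway regressions ---------------------------------------------------

def _design_with_h(ages, widths):
    rows = []
    for k, (a, w) in enumerate(zip(ages, widths)):
        pid = f"H{k}"
        rows.append({"plot": pid, "pair_id": pid, "treatment": "H",
                     "role": "experimental", "age": a, "width": w})
        rows.append({"plot": pid + "c", "pair_id": pid, "treatment": "T",
                     "role": "control", "age": np.nan, "width": np.nan})
    return pd.DataFrame(rows)


def test_highway_regression_recovers_slope(rng):
    ages = np.array([10.0, 15, 20, 25, 30, 35])
    design = _design_with_h(ages, rng.uniform(30, 60, 6))
    diffs = 0.01 * ages + rng.normal(0, 0.005, 6)
    tab = _metric_table({f"H{k}": (0.8 + diffs[k], 0.8) for k in range(6)},
                        treatment="H")
    res = highway_regressions(tab, design, "m", predictor="age")
    assert res.slope == pytest.approx(0.01, abs=0.005)
    assert res.f2 == pytest.approx(res.r_squared / (1 - res.r_squared))


def test_highway_regression_orthogonal_predictor(rng):
    ages = np.array([10.0, 15, 20, 25, 30, 35])
    design = _design_with_h(ages, rng.uniform(30, 60, 6))
    tab = _metric_table({f"H{k}": (0.8, 0.8) for k in range(6)}, treatment="H")
    tab.loc[tab["role"] == "experimental", "value"] = \
        0.8 + rng.normal(0, 0.01, 6)
    res = highway_regressions(tab, design, "m", predictor="age")
    assert abs(res.slope) < 0.01


def test_age_width_collinearity_check(rng):
    design = _design_with_h(np.arange(6, dtype=float),
                            rng.uniform(30, 60, 6))
    r, p = age_width_correlation(design)
    assert -1 <= r <= 1 and 0 <= p <= 1
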