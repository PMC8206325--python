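"""Statistical inference layer for the paired-plot design.

Inputs are long-format metric tables (one value per plot and metric; see
:func:`pipeline_metric_table` for the assembly from genotypes).  The layer
provides:

* redundancy pruning of candidate metrics at a Pearson |r| >= 0.80 threshold
  (greedy, in a declared priority order);
* paired t-tests of experimental vs control plots on within-pair differences
  (experimental - control), with Hedges' g corrected for small samples
  (J = 1 - 3 / (4 df - 1), df = n_pairs - 1) and a seeded 999-resample
  bootstrap CI (BCa, falling back to percentile when BCa is undefined);
* linear mixed models value ~ barrier Type + (1 | pair id), REML, with the
  control level T as reference and Cohen's f^2 from the marginal-R^2
  difference between full and reduced models;
* simple regressions of within-pair differences on barrier Age or Width for
  the highway subset, with f^2 = R^2 / (1 - R^2).

Effect-magnitude labels follow the conventional thresholds: |g| < 0.2
negligible, 0.2-0.5 small, 0.5-0.8 medium, > 0.8 large; f^2 0.02-0.15 small,
0.15-0.35 medium, >= 0.35 large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .amova import amova_three_level
from .differentiation import gst_family_multilocus
from .diversity import diversity_table, reference_frequencies
from .distances import euclidean_geo, genetic_distance_matrix
from .genotype_io import Dataset
from .mantel import barrier_model_matrix, partial_mantel

# canonical non-redundant metric set, in retention priority order
DEFAULT_PRIORITY = ("Ho", "uHe", "Ar", "Ho_DIF", "uHe_DIF", "Ar_DIF",
                    "sigma_bw", "Fst", "Gdoubleprime_st",
                    "r_Gd", "r_Dps", "r_Lrm")


class InferenceError(ValueError):
    pass


# -- effect-size labels ----------------------------------------------------

def g_label(g: float) -> str:
    a = abs(g)
    if a < 0.2:
        return "negligible"
    if a <= 0.5:
        return "small"
    if a <= 0.8:
        return "medium"
    return "large"


def f2_label(f2: float) -> str:
    a = abs(f2)
    if a < 0.02:
        return "negligible"
    if a < 0.15:
        return "small"
    if a < 0.35:
        return "medium"
    return "large"


# -- metric pruning --------------------------------------------------------

def prune_metrics(wide: pd.DataFrame, priority=None, threshold: float = 0.80):
    """Greedy non-redundancy selection over a plots x metrics table.

    Metrics are visited in ``priority`` order (remaining columns afterwards,
    in table order); a metric is dropped when its Pearson |r| with any
    already-retained metric reaches the threshold.  Returns (retained list,
    full correlation matrix).
    """
    cols = list(wide.columns)
    order = [m for m in (priority or DEFAULT_PRIORITY) if m in cols]
    order += [m for m in cols if m not in order]
    for m in order:
        if np.std(wide[m].to_numpy(dtype=float)) == 0:
            raise InferenceError(f"metric {m!r} is constant across plots")
    corr = wide[order].corr()
    retained: list[str] = []
    for m in order:
        if all(abs(corr.loc[m, r]) < threshold for r in retained):
            retained.append(m)
    return retained, corr


# -- paired t-test and Hedges' g -------------------------------------------

@dataclass
class PairedTestResult:
    metric: str
    mean_difference: float
    t: float
    df: int
    p: float
    hedges_g: float
    g_ci_low: float
    g_ci_high: float
    label: str
    n_pairs: int


def paired_differences(table: pd.DataFrame, metric: str) -> np.ndarray:
    """Within-pair differences (experimental - control) for one metric."""
    sub = table[table["metric"] == metric]
    piv = sub.pivot_table(index="pair_id", columns="role", values="value")
    if not {"experimental", "control"} <= set(piv.columns) or piv.isna().any().any():
        missing = piv.index[piv.isna().any(axis=1)].tolist()
        raise InferenceError(f"incomplete pairs for {metric!r}: {missing}")
    return (piv["experimental"] - piv["control"]).to_numpy(dtype=float)


def hedges_g(differences: np.ndarray, n_boot: int = 999, seed: int | None = None):
    """Small-sample-corrected standardized mean difference with bootstrap CI.

    g = (mean(d) / sd(d)) * J, J = 1 - 3 / (4 df - 1), df = n - 1.  The CI
    resamples pairs with replacement (BCa where defined, else percentile).
    Returns (g, ci_low, ci_high, label); the CI is (nan, nan) for n < 3.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise InferenceError("need >= 2 differences for Hedges' g")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 0.0, 0.0, "negligible"
        raise InferenceError("zero variance with nonzero mean difference")
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)

    def stat(x, axis=-1):
        m = np.mean(x, axis=axis)
        s = np.std(x, axis=axis, ddof=1)
        return np.where(s > 0, m / np.where(s > 0, s, 1.0) * j, 0.0)

    g = float(stat(d))
    if n < 3 or n_boot < 1:
        return g, np.nan, np.nan, g_label(g)
    rng = np.random.default_rng(seed)
    lo = hi = np.nan
    for method in ("BCa", "percentile"):
        try:
            res = stats.bootstrap((d,), stat, n_resamples=n_boot, method=method,
                                  confidence_level=0.95, random_state=rng,
                                  vectorized=True)
            lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
            if np.isfinite(lo) and np.isfinite(hi):
                break
        except Exception:
            continue
    return g, lo, hi, g_label(g)


def paired_t_test(table: pd.DataFrame, metric: str, n_boot: int = 999,
                  seed: int | None = None) -> PairedTestResult:
    """Paired t-test (experimental - control) with Hedges' g for one metric."""
    d = paired_differences(table, metric)
    n = len(d)
    if n < 2:
        raise InferenceError("need >= 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    g, lo, hi, label = hedges_g(d, n_boot=n_boot, seed=seed)
    return PairedTestResult(metric=metric, mean_difference=float(d.mean()),
                            t=float(t), df=n - 1, p=float(p), hedges_g=g,
                            g_ci_low=lo, g_ci_high=hi, label=label, n_pairs=n)


def paired_test_table(table: pd.DataFrame, metrics=None, n_boot: int = 999,
                      seed: int | None = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    metrics = metrics or [m for m in DEFAULT_PRIORITY if m in set(table["metric"])]
    rows = [vars(paired_t_test(table, m, n_boot=n_boot,
                               seed=int(rng.integers(2 ** 31))))
            for m in metrics]
    return pd.DataFrame(rows)


# -- linear mixed model ----------------------------------------------------

@dataclass
class LmmResult:
    metric: str
    fixed_effects: pd.Series     # contrasts vs control level T
    fixed_se: pd.Series
    random_variance: float
    resid_variance: float
    f2: float
    f2_class: str
    singular: bool


def _marginal_r2(fitted, data: pd.DataFrame) -> float:
    """Nakagawa-style marginal R^2: fixed-effect variance over total."""
    fe = fitted.predict(data)
    var_f = float(np.var(fe, ddof=0))
    var_re = float(fitted.cov_re.values.squeeze()) if fitted.cov_re.size else 0.0
    var_e = float(fitted.scale)
    return var_f / (var_f + var_re + var_e)


def lmm_treatment(table: pd.DataFrame, metric: str) -> LmmResult:
    """Random-intercept model value ~ Type + (1 | pair_id), REML.

    Treatment contrasts are against the control level T; f^2 is the
    marginal-R^2 difference between the full model and the intercept-only
    reduced model, (R2_f - R2_r) / (1 - R2_f).
    """
    sub = table[table["metric"] == metric].copy()
    if sub.empty:
        raise InferenceError(f"no rows for metric {metric!r}")
    sub["treatment"] = pd.Categorical(sub["treatment"],
                                      categories=["T", "R", "H", "CB"])
    formula = "value ~ C(treatment, Treatment('T'))"
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(formula, sub, groups=sub["pair_id"]).fit(reml=True)
        reduced = smf.mixedlm("value ~ 1", sub, groups=sub["pair_id"]).fit(reml=True)
    r2f = _marginal_r2(full, sub)
    r2r = _marginal_r2(reduced, sub)
    f2 = (r2f - r2r) / (1.0 - r2f) if r2f < 1 else np.inf
    fe = full.fe_params.drop("Intercept")
    se = full.bse_fe.drop("Intercept")
    var_re = float(full.cov_re.values.squeeze()) if full.cov_re.size else 0.0
    singular = (not full.converged) or var_re <= 1e-10
    return LmmResult(metric=metric, fixed_effects=fe, fixed_se=se,
                     random_variance=var_re, resid_variance=float(full.scale),
                     f2=float(f2), f2_class=f2_label(f2), singular=singular)


# -- highway regressions ---------------------------------------------------

@dataclass
class RegressionResult:
    metric: str
    predictor: str
    slope: float
    slope_se: float
    p: float
    r_squared: float
    f2: float
    f2_class: str
    n: int


def highway_regressions(table: pd.DataFrame, design: pd.DataFrame, metric: str,
                        predictor: str = "age") -> RegressionResult:
    """Regress within-pair differences on barrier age or width (highway subset).

    Uses only pairs whose experimental plot is a 4-lane highway (treatment H)
    — the subset with contrasting ages and widths; f^2 = R^2 / (1 - R^2).
    """
    if predictor not in ("age", "width"):
        raise InferenceError("predictor must be 'age' or 'width'")
    exp_design = design[design["role"] == "experimental"].set_index("pair_id")
    h_pairs = exp_design.index[exp_design["treatment"] == "H"]
    sub = table[(table["metric"] == metric) & table["pair_id"].isin(h_pairs)]
    d = paired_differences(sub, metric)
    pairs = sorted(set(sub["pair_id"]))
    x = exp_design.loc[pairs, predictor].to_numpy(dtype=float)
    if len(d) < 3:
        raise InferenceError("need >= 3 highway pairs")
    X = sm.add_constant(x)
    fit = sm.OLS(d, X).fit()
    r2 = float(fit.rsquared)
    f2 = r2 / (1.0 - r2) if r2 < 1 else np.inf
    return RegressionResult(metric=metric, predictor=predictor,
                            slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
                            p=float(fit.pvalues[1]), r_squared=r2, f2=float(f2),
                            f2_class=f2_label(f2), n=len(d))


def age_width_correlation(design: pd.DataFrame) -> tuple[float, float]:
    """Collinearity check: Pearson r between Age and Width on highway plots."""
    h = design[(design["treatment"] == "H") & (design["role"] == "experimental")]
    if len(h) < 3:
        raise InferenceError("need >= 3 highway plots")
    res = stats.pearsonr(h["age"], h["width"])
    return float(res.statistic), float(res.pvalue)


# -- full pipeline assembly ------------------------------------------------

def pipeline_metric_table(dataset: Dataset, n_perm: int = 0,
                          seed: int | None = None,
                          mantel_kinds: tuple[str, ...] = ("Gd", "Dps", "Lrm"),
                          ) -> pd.DataFrame:
    """Compute the canonical per-plot response metrics from genotypes.

    Runs diversity (Ho, uHe, Ar and their between-side differences), AMOVA
    (sigma_bw and Fst = Phi_ST), the corrected G''st, and the per-plot partial
    Mantel r for each requested genetic matrix kind.  ``n_perm = 0`` skips
    permutation p-values (the point estimates feed the paired inference).
    Returns a long table (plot, pair_id, treatment, role, metric, value).
    """
    div = diversity_table(dataset).set_index("plot")
    ref = reference_frequencies(dataset) if "Lrm" in mantel_kinds else None
    meta = dataset.design.set_index("plot")

    rows = []

    def add(plot, metric, value):
        rows.append({"plot": plot, "pair_id": meta.loc[plot, "pair_id"],
                     "treatment": meta.loc[plot, "treatment"],
                     "role": meta.loc[plot, "role"], "metric": metric,
                     "value": float(value)})

    for plot in dataset.plots():
        for m in ("Ho", "uHe", "Ar", "Ho_DIF", "uHe_DIF", "Ar_DIF"):
            add(plot, m, div.loc[plot, m])
        am = amova_three_level(dataset, plot)
        add(plot, "sigma_bw", am.sigma_bw)
        add(plot, "Fst", am.phi_st)
        _, _, gpp, _ = gst_family_multilocus(dataset, plot, corrected=True)
        add(plot, "Gdoubleprime_st", gpp)

        sub = dataset.for_plot(plot)
        geo = euclidean_geo(sub)
        barrier = barrier_model_matrix(sub)
        for kind in mantel_kinds:
            gm = genetic_distance_matrix(sub, kind=kind, ref_freqs=ref)
            vals = gm.values.copy()
            if np.isnan(vals).any():
                np.fill_diagonal(vals, 0.0)
                gm.values = vals
            res = partial_mantel(gm, barrier, geo, n_perm=n_perm, seed=seed,
                                 plot=plot)
            add(plot, f"r_{kind}", res.r)
    return pd.DataFrame(rows)
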