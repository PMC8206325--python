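"""Binary barrier-model matrices and simple/partial Mantel permutation tests.

The barrier hypothesis is encoded as a binary model matrix (0 between
individuals on the same side of the putative barrier, 1 across it).  The
partial Mantel statistic correlates a genetic matrix G with the barrier
matrix B while controlling for geographic distance E:

    r = (r_GB - r_GE * r_BE) / sqrt((1 - r_GE^2) * (1 - r_BE^2)),

all correlations computed over the off-diagonal upper triangle only.  The
null distribution permutes the *genetic* matrix's rows and columns
simultaneously: under the null the individuals' genotypes are the
exchangeable unit, while barrier and geography matrices are fixed aspects of
the design.  (Permuting the hypothesis matrix instead is anticonservative
here, because the observed barrier matrix maximises its correlation with
geography — sides are geographically separated — which deflates every
permuted statistic through the partialling denominator.)  Both the
one-tailed p for r > 0 — the directional alternative when a barrier is
hypothesized to increase cross-barrier genetic distance — and the two-tailed
p are reported, each with the (b + 1) / (B + 1) convention.

Relatedness-based matrices are similarities, not distances, so their Mantel
r is expected to flip sign relative to distance-based matrices under the
same barrier signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .genotype_io import Dataset


class MantelError(ValueError):
    pass


@dataclass
class MantelResult:
    plot: str
    kind: str             # which genetic matrix was tested
    r: float
    p_one_tailed: float
    p_two_tailed: float
    n_permutations: int
    seed: int | None


def barrier_model_matrix(dataset: Dataset) -> DistanceMatrix:
    """Binary same-side/opposite-side model matrix for one plot's individuals."""
    sides = dataset.samples["side"].to_numpy()
    if len(set(sides)) < 2:
        raise MantelError("all individuals on a single side")
    vals = (sides[:, None] != sides[None, :]).astype(float)
    return DistanceMatrix(labels=dataset.ids, values=vals, kind="barrier")


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def partial_mantel(genetic: DistanceMatrix, barrier: DistanceMatrix,
                   geographic: DistanceMatrix, n_perm: int = 999,
                   seed: int | None = None, plot: str = "") -> MantelResult:
    """Partial Mantel test of genetic ~ barrier | geographic distance."""
    for m in (barrier, geographic):
        if m.labels != genetic.labels:
            raise MantelError("label mismatch across matrices")
    g = _upper(genetic.values)
    b = _upper(barrier.values)
    e = _upper(geographic.values)
    for name, v in (("genetic", g), ("barrier", b), ("geographic", e)):
        if np.std(v) == 0:
            raise MantelError(f"zero variance in {name} matrix off-diagonals")

    r_be = _corr(b, e)

    def partial_r(g_upper):
        r_gb = _corr(g_upper, b)
        r_ge = _corr(g_upper, e)
        return (r_gb - r_ge * r_be) / np.sqrt((1 - r_ge ** 2) * (1 - r_be ** 2))

    r_obs = partial_r(g)

    if n_perm < 1:
        # point estimate only
        return MantelResult(plot=plot, kind=genetic.kind, r=float(r_obs),
                            p_one_tailed=np.nan, p_two_tailed=np.nan,
                            n_permutations=0, seed=seed)
    rng = np.random.default_rng(seed)
    n = genetic.values.shape[0]
    hits_one = hits_two = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = _upper(genetic.values[np.ix_(perm, perm)])
        r_p = partial_r(gp)
        if r_p >= r_obs:
            hits_one += 1
        if abs(r_p) >= abs(r_obs):
            hits_two += 1
    return MantelResult(plot=plot, kind=genetic.kind, r=float(r_obs),
                        p_one_tailed=(hits_one + 1) / (n_perm + 1),
                        p_two_tailed=(hits_two + 1) / (n_perm + 1),
                        n_permutations=n_perm, seed=seed)


def mantel_table(results: list[MantelResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def mantel_summary(results: list[MantelResult], design: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level mean and standard error of Mantel r per genetic matrix kind.

    Plots are grouped by their design treatment (controls under 'T'), so the
    summary mirrors a per-barrier-type comparison of experimental plots
    against their controls.
    """
    tab = mantel_table(results)
    if tab.empty:
        raise MantelError("no Mantel results to summarize")
    tr = design.set_index("plot")["treatment"]
    role = design.set_index("plot")["role"]
    tab = tab.assign(treatment=tab["plot"].map(tr), role=tab["plot"].map(role))
    grp = tab.groupby(["kind", "treatment", "role"])["r"]
    out = grp.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "r_mean", "sem": "r_se", "count": "n_plots"})
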