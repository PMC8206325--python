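"""Forward-time simulator of paired road-barrier study plots.

Each plot holds two demes ("sides" A and B of a putative barrier) evolving
under a monoecious Wright–Fisher model with cyclic boom–bust demography,
barrier-modulated migration with peak-phase pulses, and strict one-step
stepwise mutation on a bounded allele ladder — an idealisation of cyclic
rodent populations (e.g. common voles, with 3–5-year density cycles and
episodes of mass dispersal) genotyped at microsatellite loci.

Migration acts on parental-pool choice: an offspring born on side ``s`` draws
both parents from the opposite side with probability ``m_eff(t)`` and from its
own side otherwise.  The effective rate is

    m_eff(t) = min(0.5, m * b_plot * (rho if peak(t) else 1)),

with ``b_plot = barrier_factor`` for experimental plots and 1 for controls, so
``barrier_factor = 1`` makes experimental and control plots statistically
exchangeable (the null landscape) and ``barrier_factor = 0`` seals the
barrier completely.

All plots are founded from one shared ancestral allele-frequency draw per
locus (symmetric Dirichlet), mimicking the regional homogeneity of a
continuous, recently connected population; per-plot randomness comes from
independent child streams spawned from the master seed, so plots are
statistically independent as a paired field design intends.

The module also provides pedigree dyad generators (parent–offspring, full
sib, half sib, unrelated) used as ground truth for relatedness estimators and
sibling filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import Dataset, validate_design

# default treatment layout: 6 conventional roads, 6 highways, 3 combined
# barriers — one control (T) plot is generated per pair automatically
DEFAULT_TREATMENTS = ("R",) * 6 + ("H",) * 6 + ("CB",) * 3

# plausible infrastructure attributes per treatment: (age range yr, width range m)
_TREATMENT_ATTRS = {"R": ((45.0, 65.0), (8.0, 12.0)),
                    "H": ((15.0, 40.0), (30.0, 60.0)),
                    "CB": ((5.0, 20.0), (60.0, 110.0))}

# side geometry: each side is a 2500 m x 1500 m rectangle; the barrier runs
# along the long (x) axis at y = 0, side A above, side B below
SIDE_LENGTH = 2500.0
SIDE_DEPTH = 1500.0


@dataclass
class SimConfig:
    """Full parameterisation of the paired-landscape simulator.

    Defaults are the field-study-like preset: a 15-pair landscape of highly
    polymorphic microsatellites with boom–bust demography whose sampled
    diversity (uHe ~ 0.8) and between-side differentiation (Phi_ST near 0)
    match a cyclic, well-connected rodent population.
    """

    n_pairs: int = 15
    treatments: Sequence[str] = DEFAULT_TREATMENTS
    n_loci: int = 9
    n_alleles: int = 30          # allele-ladder size K (repeat indices 1..K)
    dirichlet_alpha: float = 0.3  # ancestral-frequency concentration
    n_low: int = 50              # deme size in trough generations
    n_peak: int = 1000           # deme size in peak generations
    cycle_length: int = 4        # generations per boom-bust cycle
    peak_width: int = 1          # peak generations per cycle
    generations: int = 21        # forward generations simulated
    m: float = 0.2               # baseline per-generation migration probability
    barrier_factor: float = 1.0  # b in [0,1]; applied to experimental plots
    pulse_factor: float = 2.0    # rho >= 1; migration multiplier during peaks
    mu: float = 5e-4             # stepwise mutation rate per allele copy
    n_sample_min: int = 15       # sampled individuals per side (inclusive range)
    n_sample_max: int = 40
    point_spacing: float = 350.0  # capture-point grid spacing, metres
    litters: Sequence[dict] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 2:
            raise ValueError("n_low must be >= 2 (two distinct parents needed)")
        if self.n_alleles < 2:
            raise ValueError("n_alleles must be >= 2")
        if not 0.0 <= self.barrier_factor <= 1.0:
            raise ValueError("barrier_factor must be in [0, 1]")
        if self.pulse_factor < 1.0:
            raise ValueError("pulse_factor must be >= 1")
        if len(self.treatments) != self.n_pairs:
            raise ValueError("treatments must list one entry per pair")
        if not set(self.treatments) <= {"R", "H", "CB"}:
            raise ValueError("treatments must be drawn from {R, H, CB}")


@dataclass
class SimResult:
    """A simulated landscape with its ground truth."""

    dataset: Dataset
    pedigree: pd.DataFrame      # id, plot, side, mother, father
    litters: pd.DataFrame       # id, plot, sampling_point, litter_id, mother, father
    schedules: dict             # plot -> DataFrame(t, N, m_eff)
    config: SimConfig
    seed: int


# -- demography schedule ---------------------------------------------------

def is_peak(t: int, cycle_length: int, peak_width: int) -> bool:
    return (t - 1) % cycle_length < peak_width


def cyclic_schedule(config: SimConfig, experimental: bool) -> pd.DataFrame:
    """Per-generation deme size and effective migration for one plot.

    Generations are numbered 1..G; generation t is a peak when
    ``(t-1) % cycle_length < peak_width``.
    """
    b = config.barrier_factor if experimental else 1.0
    rows = []
    for t in range(1, config.generations + 1):
        peak = is_peak(t, config.cycle_length, config.peak_width)
        n = config.n_peak if peak else config.n_low
        m_eff = min(0.5, config.m * b * (config.pulse_factor if peak else 1.0))
        rows.append((t, n, m_eff, peak))
    return pd.DataFrame(rows, columns=["t", "N", "m_eff", "peak"])


# -- core Wright-Fisher engine --------------------------------------------

def _mutate(alleles: np.ndarray, mu: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """Strict one-step stepwise mutation with reflecting bounds at [1, k]."""
    if mu <= 0:
        return alleles
    hit = rng.random(alleles.shape) < mu
    if not hit.any():
        return alleles
    step = np.where(rng.random(alleles.shape) < 0.5, -1, 1)
    step = np.where(alleles == 1, 1, step)
    step = np.where(alleles == k, -1, step)
    return np.where(hit, alleles + step, alleles)


def _draw_distinct_pairs(n_offspring: int, pool_size: int, rng: np.random.Generator):
    p1 = rng.integers(0, pool_size, size=n_offspring)
    p2 = rng.integers(0, pool_size - 1, size=n_offspring)
    p2 = np.where(p2 >= p1, p2 + 1, p2)
    return p1, p2


def founder_genotypes(n: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, L, 2) genotypes at Hardy–Weinberg from ancestral frequencies."""
    n_loci, k = freqs.shape
    out = np.empty((n, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        out[:, l, :] = rng.choice(np.arange(1, k + 1), size=(n, 2), p=freqs[l])
    return out


def simulate_plot(config: SimConfig, experimental: bool, ancestral_freqs: np.ndarray,
                  rng: np.random.Generator):
    """Run one plot's two demes forward for ``config.generations`` generations.

    Returns ``(genotypes_a, genotypes_b, parents_a, parents_b, schedule)``
    where the parent arrays give, for each final-generation individual, the
    two (side, index) parent references into the penultimate generation —
    final-generation individuals sharing both parents are full sibs.
    """
    sched = cyclic_schedule(config, experimental)
    demes = [founder_genotypes(config.n_low, ancestral_freqs, rng) for _ in range(2)]
    parents = [None, None]
    k = config.n_alleles

    for _, row in sched.iterrows():
        n_next, m_eff = int(row["N"]), float(row["m_eff"])
        new_demes, new_parents = [], []
        for s in (0, 1):
            migrant = rng.random(n_next) < m_eff
            src = np.where(migrant, 1 - s, s)
            geno = np.empty((n_next, config.n_loci, 2), dtype=np.int64)
            par = np.empty((n_next, 2, 2), dtype=np.int64)  # (offspring, parent, [side, index])
            for side_src in (0, 1):
                sel = np.flatnonzero(src == side_src)
                if sel.size == 0:
                    continue
                pool = demes[side_src]
                p1, p2 = _draw_distinct_pairs(sel.size, pool.shape[0], rng)
                # one gamete per parent: pick one of the parent's two alleles per locus
                pick1 = rng.integers(0, 2, size=(sel.size, config.n_loci))
                pick2 = rng.integers(0, 2, size=(sel.size, config.n_loci))
                g1 = np.take_along_axis(pool[p1], pick1[:, :, None], axis=2)[:, :, 0]
                g2 = np.take_along_axis(pool[p2], pick2[:, :, None], axis=2)[:, :, 0]
                geno[sel, :, 0] = _mutate(g1, config.mu, k, rng)
                geno[sel, :, 1] = _mutate(g2, config.mu, k, rng)
                par[sel, 0, 0] = side_src
                par[sel, 0, 1] = p1
                par[sel, 1, 0] = side_src
                par[sel, 1, 1] = p2
            new_demes.append(geno)
            new_parents.append(par)
        demes, parents = new_demes, new_parents

    return demes[0], demes[1], parents[0], parents[1], sched


# -- sampling --------------------------------------------------------------

def _capture_points(spacing: float):
    xs = np.arange(spacing / 2, SIDE_LENGTH, spacing)
    ys = np.arange(spacing / 2, SIDE_DEPTH, spacing)
    return xs, ys


def sample_individuals(deme_genotypes, deme_parents, plot: str, config: SimConfig,
                       rng: np.random.Generator):
    """Sample individuals without replacement from each side and place them.

    Coordinates are uniform within each side's 2500 x 1500 m rectangle (side A
    at y > 0, side B at y < 0); sampling-point labels snap each capture to a
    regular grid of trap stations.  Returns (genotypes, samples-frame rows,
    pedigree rows).
    """
    xs, ys = _capture_points(config.point_spacing)
    genos, rows, ped = [], [], []
    for s, side in enumerate("AB"):
        pool = deme_genotypes[s]
        n_avail = pool.shape[0]
        n_want = int(rng.integers(config.n_sample_min, config.n_sample_max + 1))
        if n_want > n_avail:
            raise ValueError(f"cannot sample {n_want} from a deme of {n_avail}")
        take = rng.choice(n_avail, size=n_want, replace=False)
        x = rng.uniform(0, SIDE_LENGTH, size=n_want)
        y = rng.uniform(0, SIDE_DEPTH, size=n_want)
        y = y if side == "A" else -y
        gx = xs[np.argmin(np.abs(x[:, None] - xs[None, :]), axis=1)]
        gy = np.abs(ys)[np.argmin(np.abs(np.abs(y)[:, None] - ys[None, :]), axis=1)]
        for j, i in enumerate(take):
            uid = f"{plot}_{side}{j:03d}"
            point = f"{plot}_P{int(gx[j])}_{int(gy[j])}{side}"
            rows.append((uid, plot, side, point, float(x[j]), float(y[j])))
            genos.append(deme_genotypes[s][i])
            pa = deme_parents[s][i]
            # parent labels sorted so full sibs share an identical (mother, father)
            mother, father = sorted(f"{plot}_g{pa[q, 0]}i{pa[q, 1]}" for q in (0, 1))
            ped.append((uid, plot, side, mother, father))
    return np.array(genos), rows, ped


# -- litters ---------------------------------------------------------------

def mendelian_offspring(parent1: np.ndarray, parent2: np.ndarray,
                        rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Draw n offspring genotypes from two parent genotypes (no mutation)."""
    L = parent1.shape[0]
    pick1 = rng.integers(0, 2, size=(n, L))
    pick2 = rng.integers(0, 2, size=(n, L))
    g1 = np.take_along_axis(np.broadcast_to(parent1, (n, L, 2)), pick1[:, :, None], axis=2)[:, :, 0]
    g2 = np.take_along_axis(np.broadcast_to(parent2, (n, L, 2)), pick2[:, :, None], axis=2)[:, :, 0]
    return np.stack([g1, g2], axis=2)


def simulate_dyads(freqs: np.ndarray, relationship: str, n_dyads: int,
                   rng: np.random.Generator):
    """Generate genotype dyads of known pedigree relationship.

    relationship: 'unrelated', 'parent_offspring', 'full_sib' or 'half_sib'.
    Returns two (n_dyads, L, 2) arrays.
    """
    draw = lambda n: founder_genotypes(n, freqs, rng)
    if relationship == "unrelated":
        return draw(n_dyads), draw(n_dyads)
    a, b = [], []
    for _ in range(n_dyads):
        p1, p2 = draw(1)[0], draw(1)[0]
        if relationship == "parent_offspring":
            a.append(p1)
            b.append(mendelian_offspring(p1, p2, rng)[0])
        elif relationship == "full_sib":
            kids = mendelian_offspring(p1, p2, rng, n=2)
            a.append(kids[0])
            b.append(kids[1])
        elif relationship == "half_sib":
            p3 = draw(1)[0]
            a.append(mendelian_offspring(p1, p2, rng)[0])
            b.append(mendelian_offspring(p1, p3, rng)[0])
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
    return np.array(a), np.array(b)


def inject_litters(genotypes: np.ndarray, rows: list, litter_spec: Sequence[dict],
                   plot: str, freqs: np.ndarray, rng: np.random.Generator):
    """Append full-sib litters at existing sampling points of one plot.

    Each spec entry: ``{"plot": ..., "size": k}`` with optional
    ``"sampling_point"``; parents are drawn at Hardy–Weinberg from the
    ancestral frequencies.  Returns updated (genotypes, rows, litter-truth
    rows).
    """
    truth = []
    extra_genos = []
    for li, spec in enumerate(litter_spec):
        if spec.get("plot") != plot:
            continue
        points = [r[3] for r in rows]
        if not points:
            raise ValueError("no sampling points available for litter injection")
        point = spec.get("sampling_point")
        if point is None:
            point = points[int(rng.integers(0, len(points)))]
        elif point not in points:
            raise ValueError(f"unknown sampling point {point!r} in litter spec")
        ref = rows[points.index(point)]
        side, x, y = ref[2], ref[4], ref[5]
        size = int(spec["size"])
        p1, p2 = founder_genotypes(2, freqs, rng)
        kids = mendelian_offspring(p1, p2, rng, n=size)
        litter_id = f"{plot}_L{li}"
        for j in range(size):
            uid = f"{plot}_{litter_id}_{j}"
            rows.append((uid, plot, side, point, x, y))
            extra_genos.append(kids[j])
            truth.append((uid, plot, point, litter_id, f"{litter_id}_m", f"{litter_id}_f"))
    if extra_genos:
        genotypes = np.concatenate([genotypes, np.array(extra_genos)], axis=0)
    return genotypes, rows, truth


# -- landscape assembly ----------------------------------------------------

def ancestral_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One shared Dirichlet frequency vector per locus (all plots)."""
    return rng.dirichlet([config.dirichlet_alpha] * config.n_alleles,
                         size=config.n_loci)


def _design_row(plot, pair_id, treatment, role, rng):
    if role == "control":
        return (plot, pair_id, "T", role, np.nan, np.nan)
    (a_lo, a_hi), (w_lo, w_hi) = _TREATMENT_ATTRS[treatment]
    return (plot, pair_id, treatment, role,
            float(np.round(rng.uniform(a_lo, a_hi))), float(np.round(rng.uniform(w_lo, w_hi), 1)))


def simulate_landscape(config: SimConfig, seed: int | None = None) -> SimResult:
    """Simulate a full paired landscape and package it as a Dataset.

    One master seed spawns an independent stream per plot, so plots are
    statistically independent; experimental and control plots of a pair share
    nothing but the ancestral frequency vector (common to all plots).
    """
    if seed is None:
        seed = config.seed
    master = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(master.spawn(1)[0])
    freqs = ancestral_frequencies(config, design_rng)

    counts = {}
    plots = []
    for i, tr in enumerate(config.treatments):
        counts[tr] = counts.get(tr, 0) + 1
        pair = f"{tr}{counts[tr]}"
        plots.append((pair, pair, tr, "experimental", True))
        plots.append((pair + "c", pair, tr, "control", False))

    design_rows = [_design_row(p, pid, tr, role, design_rng)
                   for p, pid, tr, role, _ in plots]
    design = pd.DataFrame(design_rows, columns=["plot", "pair_id", "treatment", "role", "age", "width"])
    validate_design(design)

    streams = master.spawn(len(plots) + 1)[1:]
    all_genos, all_rows, all_ped, all_litters = [], [], [], []
    schedules = {}
    for (plot, pair_id, tr, role, is_exp), ss in zip(plots, streams):
        rng = np.random.default_rng(ss)
        ga, gb, pa, pb, sched = simulate_plot(config, is_exp, freqs, rng)
        schedules[plot] = sched
        genos, rows, ped = sample_individuals((ga, gb), (pa, pb), plot, config, rng)
        genos, rows, lit = inject_litters(genos, rows, config.litters, plot, freqs, rng)
        treatment = tr if role == "experimental" else "T"
        for r in rows:
            all_rows.append((r[0], r[1], pair_id, treatment, r[2], r[3], r[4], r[5]))
        all_genos.append(genos)
        all_ped.extend(ped)
        all_litters.extend(lit)

    samples = pd.DataFrame(all_rows, columns=["id", "plot", "pair_id", "treatment",
                                              "side", "sampling_point", "x", "y"])
    dataset = Dataset(loci=[f"L{i+1:02d}" for i in range(config.n_loci)],
                      genotypes=np.concatenate(all_genos, axis=0),
                      samples=samples, design=design).validate()
    pedigree = pd.DataFrame(all_ped, columns=["id", "plot", "side", "mother", "father"])
    litters = pd.DataFrame(all_litters, columns=["id", "plot", "sampling_point",
                                                 "litter_id", "mother", "father"])
    return SimResult(dataset=dataset, pedigree=pedigree, litters=litters,
                     schedules=schedules, config=config, seed=seed)
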