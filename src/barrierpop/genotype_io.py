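"""Data model and I/O for codominant microsatellite genotypes in a paired-plot design.

The central container is :class:`Dataset`: diploid genotypes (unordered allele
pairs per locus, integer-coded) together with per-individual metadata (plot,
pair id, treatment, barrier side, sampling point, planar coordinates in
metres) and a plot-design table (treatment, experimental/control role, barrier
age and width).  Genotypes are read from GenePop files via biopython; sample
and design metadata come from plain TSV tables.

Allele values are positive integers — fragment lengths in base pairs for real
data, repeat indices for simulated data.  ``0`` is the missing sentinel and a
genotype is either fully typed or fully missing at a locus (no half-calls).
Within a genotype the two alleles are stored sorted ascending, which makes
unordered pairs canonical for hashing and comparison.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.PopGen import GenePop

MISSING = 0

TREATMENTS = ("R", "H", "CB", "T")
SIDES = ("A", "B")

SAMPLE_COLUMNS = ["id", "plot", "pair_id", "treatment", "side",
                  "sampling_point", "x", "y"]
DESIGN_COLUMNS = ["plot", "pair_id", "treatment", "role", "age", "width"]


class DataError(ValueError):
    """Raised when an input file or Dataset violates a structural invariant."""


@dataclass
class Dataset:
    """Genotypes plus design metadata for a set of paired study plots.

    Attributes
    ----------
    loci : list of str
        Ordered, unique locus names.
    genotypes : ndarray of shape (n_individuals, n_loci, 2), int
        Allele values sorted ascending within each pair; 0 = missing
        (both entries 0 when a genotype is missing).
    samples : DataFrame
        One row per individual, columns ``id, plot, pair_id, treatment,
        side, sampling_point, x, y``; row order matches ``genotypes``.
    design : DataFrame
        One row per plot, columns ``plot, pair_id, treatment, role, age,
        width``.
    """

    loci: list[str]
    genotypes: np.ndarray
    samples: pd.DataFrame
    design: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DESIGN_COLUMNS))

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise DataError("genotypes must have shape (n, n_loci, 2)")
        self.genotypes = np.sort(self.genotypes, axis=2)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> list[str]:
        return self.samples["id"].tolist()

    def plots(self) -> list[str]:
        return list(dict.fromkeys(self.samples["plot"]))

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def subset(self, mask_or_index) -> "Dataset":
        """Row-subset individuals; design is carried over unchanged."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self,
                       genotypes=self.genotypes[idx],
                       samples=self.samples.iloc[idx].reset_index(drop=True))

    def for_plot(self, plot: str) -> "Dataset":
        mask = (self.samples["plot"] == plot).to_numpy()
        if not mask.any():
            raise DataError(f"unknown plot {plot!r}")
        return self.subset(mask)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci): True where the genotype is missing."""
        return self.genotypes[:, :, 0] == MISSING

    # -- validation --------------------------------------------------------

    def validate(self) -> "Dataset":
        if len(set(self.loci)) != len(self.loci):
            raise DataError("duplicate locus names")
        if self.genotypes.shape[1] != self.n_loci:
            raise DataError("genotype array does not cover the declared loci")
        ids = self.samples["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DataError(f"duplicated individual id {dup!r}")
        bad = ~self.samples["side"].isin(SIDES)
        if bad.any():
            raise DataError(f"invalid side labels: {sorted(self.samples.loc[bad, 'side'].unique())}")
        bad = ~self.samples["treatment"].isin(TREATMENTS)
        if bad.any():
            raise DataError(f"unknown treatment codes: {sorted(self.samples.loc[bad, 'treatment'].unique())}")
        xy = self.samples[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise DataError("non-finite coordinates")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise DataError(f"half-missing genotype for {ids.iloc[i]!r} at locus {self.loci[l]!r}")
        if (self.genotypes < 0).any():
            raise DataError("negative allele values")
        if len(self.design):
            known = set(self.design["plot"])
            missing_plots = set(self.samples["plot"]) - known
            if missing_plots:
                raise DataError(f"plots absent from design table: {sorted(missing_plots)}")
        return self


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the experimental/control pairing structure of a design table."""
    for pair, grp in design.groupby("pair_id"):
        roles = sorted(grp["role"])
        if roles != ["control", "experimental"]:
            raise DataError(f"pair {pair!r} must have exactly one experimental and one control plot")
        ctrl = grp.loc[grp["role"] == "control", "treatment"]
        if not (ctrl == "T").all():
            raise DataError(f"control plot in pair {pair!r} must have treatment 'T'")
    return design


# -- GenePop reading -------------------------------------------------------

def _decode_genepop_pair(pair) -> tuple[int, int]:
    a, b = pair
    if a is None or b is None or (a == 0 and b == 0):
        return (MISSING, MISSING)
    if a == 0 or b == 0:
        # a single 0 allele in GenePop also means "untyped"
        return (MISSING, MISSING)
    return (int(a), int(b))


def read_genepop(path, sample_table_path, design_path=None) -> Dataset:
    """Read a GenePop genotype file with its TSV sample (and design) tables.

    The GenePop file may group individuals per plot or per plot-side; the
    sample table is authoritative for plot and side assignment and its ids
    must match the GenePop individual names exactly (one-to-one).
    """
    with open(path) as fh:
        record = GenePop.read(fh)
    loci = list(record.loci_list)

    names: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for pop in record.populations:
        for name, genos in pop:
            names.append(str(name).strip().rstrip(","))
            if len(genos) != len(loci):
                raise DataError(f"individual {name!r}: {len(genos)} genotypes for {len(loci)} loci")
            rows.append([_decode_genepop_pair(g) for g in genos])

    samples = pd.read_csv(sample_table_path, sep="\t", dtype={"id": str, "plot": str,
                                                              "pair_id": str, "sampling_point": str})
    missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise DataError(f"sample table lacks columns: {sorted(missing_cols)}")

    seen = set(names)
    if len(seen) != len(names):
        raise DataError("duplicated individual id in GenePop file")
    table_ids = set(samples["id"])
    if table_ids - seen:
        raise DataError(f"sample-table ids absent from GenePop file: {sorted(table_ids - seen)[:5]}")
    if seen - table_ids:
        raise DataError(f"GenePop ids absent from sample table: {sorted(seen - table_ids)[:5]}")

    order = {n: i for i, n in enumerate(names)}
    samples = samples.sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)
    genotypes = np.array(rows, dtype=np.int64)

    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t", dtype={"plot": str, "pair_id": str})
        missing_cols = set(DESIGN_COLUMNS) - set(design.columns)
        if missing_cols:
            raise DataError(f"design table lacks columns: {sorted(missing_cols)}")
        validate_design(design)
    else:
        design = pd.DataFrame(columns=DESIGN_COLUMNS)

    return Dataset(loci=loci, genotypes=genotypes, samples=samples, design=design).validate()


# -- GenePop writing -------------------------------------------------------

def write_genepop(dataset: Dataset, path, title: str = "barrierpop export",
                  group_by: str = "plot") -> None:
    """Write a Dataset as a GenePop file, one POP block per plot (or plot-side).

    The allele digit width is auto-selected: 3 digits when any allele exceeds
    99, else 2.  Alleles above 999 cannot be encoded and raise
    :class:`DataError`.
    """
    if dataset.n_individuals == 0:
        raise DataError("cannot write an empty Dataset")
    amax = int(dataset.genotypes.max(initial=0))
    digits = 3 if amax > 99 else 2
    if amax > 999:
        raise DataError(f"allele value {amax} exceeds GenePop 3-digit encoding")

    if group_by == "plot":
        keys = dataset.samples["plot"]
    elif group_by == "plot_side":
        keys = dataset.samples["plot"] + "_" + dataset.samples["side"]
    else:
        raise ValueError("group_by must be 'plot' or 'plot_side'")

    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in dataset.loci:
        buf.write(locus + "\n")
    for key in dict.fromkeys(keys):
        buf.write("POP\n")
        for i in np.flatnonzero((keys == key).to_numpy()):
            toks = ["".join(f"{a:0{digits}d}" for a in pair)
                    for pair in dataset.genotypes[i]]
            buf.write(f"{dataset.samples['id'].iloc[i]} ,  " + " ".join(toks) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_tables(dataset: Dataset, sample_path, design_path=None) -> None:
    """Write the sample (and design) metadata as TSV tables."""
    dataset.samples[SAMPLE_COLUMNS].to_csv(sample_path, sep="\t", index=False)
    if design_path is not None:
        dataset.design[DESIGN_COLUMNS].to_csv(design_path, sep="\t", index=False)


# -- design helpers --------------------------------------------------------

def split_by_side(dataset: Dataset, plot: str) -> tuple[Dataset, Dataset]:
    """Partition a plot's individuals into its two barrier sides (A, B)."""
    sub = dataset.for_plot(plot)
    a = sub.subset((sub.samples["side"] == "A").to_numpy())
    b = sub.subset((sub.samples["side"] == "B").to_numpy())
    if a.n_individuals == 0 or b.n_individuals == 0:
        raise DataError(f"plot {plot!r} has an empty side "
                        f"(Na={a.n_individuals}, Nb={b.n_individuals})")
    return a, b
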