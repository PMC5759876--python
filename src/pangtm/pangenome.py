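"""Pan-genome partitioning, accumulation curves and genome summaries.

The central object is the presence/absence matrix: gene families (rows) by
genomes (columns), holding occurrence counts.  Families are partitioned
into the *core* genome (present in every genome), *shared dispensable*
families (present in more than one but not all genomes) and *unique*
families (present in exactly one genome; truly unique genes, TUGs).  In
report terms the "dispensable" or "variable" genome aggregates shared
dispensable plus unique families.

Pan- and core-genome accumulation curves are computed over random genome
orderings: pan(N) is the number of families seen in the first N genomes,
core(N) the number present in all of the first N.  The pan curve is fitted
with a Heaps-type power law P(N) = kappa * N**gamma and the core curve
with an exponential decay C(N) = Omega + A * exp(-N / tau); Omega
estimates the asymptotic core size.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.spatial.distance import pdist

from .clustering import FamilySet

__all__ = [
    "PanGenomePartition",
    "AccumulationCurve",
    "presence_absence",
    "presence_absence_from_membership",
    "partition_families",
    "accumulation_curves",
    "new_gene_rate",
    "compare_pangenomes",
    "shared_fraction_pct",
    "core_fraction_pct",
    "genome_summary",
    "hierarchical_heatmap_export",
]

#: exhaustive permutation enumeration is used whenever G! does not exceed this
EXHAUSTIVE_PERMUTATION_LIMIT = 5040  # 7!


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def presence_absence(families: FamilySet, genome_ids: Sequence[str]) -> pd.DataFrame:
    """Family x genome occurrence-count matrix (sorted rows and columns).

    Families with no member in any of ``genome_ids`` are dropped (the
    matrix never contains all-zero rows).
    """
    cols = sorted(genome_ids)
    colset = set(cols)
    rows = {}
    for fid, by_genome in families.families.items():
        counts = {g: len(gs) for g, gs in by_genome.items() if g in colset}
        if counts:
            rows[fid] = counts
    mat = pd.DataFrame(0, index=sorted(rows), columns=cols, dtype=int)
    for fid, counts in rows.items():
        for g, c in counts.items():
            mat.at[fid, g] = c
    return mat


def presence_absence_from_membership(
    membership: dict[str, set[str]], genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Binary presence/absence matrix from a family -> genomes mapping."""
    cols = sorted(genome_ids)
    colset = set(cols)
    rows = {f: carried & colset for f, carried in membership.items()}
    rows = {f: c for f, c in rows.items() if c}
    mat = pd.DataFrame(0, index=sorted(rows), columns=cols, dtype=int)
    for fid, carried in rows.items():
        mat.loc[fid, sorted(carried)] = 1
    return mat


@dataclass
class PanGenomePartition:
    """Three-way split of the families of a presence/absence matrix."""

    core: set[str]
    dispensable: set[str]            # present in >1 but not all genomes
    unique: dict[str, str]           # family -> its single carrying genome

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_dispensable(self) -> int:
        return len(self.dispensable)

    @property
    def n_unique(self) -> int:
        return len(self.unique)

    @property
    def variable(self) -> set[str]:
        """The variable ("dispensable genome") total: all non-core families."""
        return self.dispensable | set(self.unique)

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_dispensable + self.n_unique

    def unique_per_genome(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for genome in self.unique.values():
            out[genome] = out.get(genome, 0) + 1
        return out

    def core_fraction_pct(self) -> int:
        return core_fraction_pct(self.n_core, len(self.variable))


def partition_families(matrix: pd.DataFrame) -> PanGenomePartition:
    """Partition families into core / shared dispensable / unique.

    Core families are present (count > 0) in every genome of the matrix;
    unique families in exactly one (and are attributed to it); the shared
    dispensable remainder in more than one but not all.
    """
    present = matrix.to_numpy() > 0
    n_genomes = matrix.shape[1]
    n_present = present.sum(axis=1)
    core = set(matrix.index[n_present == n_genomes])
    unique_rows = np.nonzero(n_present == 1)[0]
    unique = {
        matrix.index[i]: matrix.columns[int(np.nonzero(present[i])[0][0])]
        for i in unique_rows
    }
    dispensable = set(matrix.index) - core - set(unique)
    return PanGenomePartition(core=core, dispensable=dispensable, unique=unique)


@dataclass
class AccumulationCurve:
    """Pan/core accumulation means over genome orderings, plus fits."""

    N: np.ndarray                   # 1..G
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_permutations: int
    exhaustive: bool
    seed: int | None
    fitted_pan: tuple[float, float] | None    # (kappa, gamma)
    fitted_core: tuple[float, float, float] | None  # (Omega, A, tau)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.N,
                "pan_mean": self.pan_mean,
                "pan_sd": self.pan_sd,
                "core_mean": self.core_mean,
                "core_sd": self.core_sd,
            }
        )


def _heaps(n: np.ndarray, kappa: float, gamma: float) -> np.ndarray:
    return kappa * np.power(n, gamma)


def _core_decay(n: np.ndarray, omega: float, amp: float, tau: float) -> np.ndarray:
    return omega + amp * np.exp(-n / tau)


def accumulation_curves(
    matrix: pd.DataFrame,
    n_permutations: int = 100,
    seed: int | None = None,
) -> AccumulationCurve:
    """Pan/core sizes as genomes are added in random order.

    When G! <= 5040 every ordering is enumerated exactly; otherwise
    ``n_permutations`` seeded random orderings are drawn.  Curve fits are
    least squares on the permutation means; with fewer than 3 genomes the
    fits are skipped with a warning.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    present = matrix.to_numpy() > 0
    n_fam, g = present.shape
    exhaustive = math.factorial(g) <= EXHAUSTIVE_PERMUTATION_LIMIT
    if exhaustive:
        orders = list(itertools.permutations(range(g)))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(g) for _ in range(n_permutations)]

    pan = np.empty((len(orders), g), dtype=np.int64)
    core = np.empty((len(orders), g), dtype=np.int64)
    for k, order in enumerate(orders):
        cols = present[:, list(order)]
        seen = np.cumsum(cols, axis=1) > 0      # family seen in first N
        inall = np.cumprod(cols, axis=1) > 0    # family in all of first N
        pan[k] = seen.sum(axis=0)
        core[k] = inall.sum(axis=0)

    pan_mean = pan.mean(axis=0)
    core_mean = core.mean(axis=0)
    pan_sd = pan.std(axis=0)
    core_sd = core.std(axis=0)
    n_axis = np.arange(1, g + 1, dtype=float)

    fitted_pan = fitted_core = None
    if g < 3:
        warnings.warn("fewer than 3 genomes: accumulation-curve fits skipped")
    else:
        with warnings.catch_warnings():
            # degenerate (flat) curves fit exactly but with singular covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            try:
                p_pan, _ = curve_fit(
                    _heaps, n_axis, pan_mean, p0=(float(pan_mean[0]), 0.5),
                    maxfev=10000,
                )
                fitted_pan = (float(p_pan[0]), float(p_pan[1]))
            except RuntimeError:
                warnings.warn("pan-curve power-law fit did not converge")
            try:
                amp0 = max(float(core_mean[0] - core_mean[-1]), 1e-6)
                p_core, _ = curve_fit(
                    _core_decay,
                    n_axis,
                    core_mean,
                    p0=(float(core_mean[-1]), amp0, 2.0),
                    bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, np.inf]),
                    maxfev=10000,
                )
                fitted_core = (float(p_core[0]), float(p_core[1]), float(p_core[2]))
            except RuntimeError:
                warnings.warn("core-curve exponential fit did not converge")

    return AccumulationCurve(
        N=np.arange(1, g + 1),
        pan_mean=pan_mean,
        pan_sd=pan_sd,
        core_mean=core_mean,
        core_sd=core_sd,
        n_permutations=len(orders),
        exhaustive=exhaustive,
        seed=seed,
        fitted_pan=fitted_pan,
        fitted_core=fitted_core,
    )


def new_gene_rate(curve: AccumulationCurve, from_N: int, to_N: int) -> float:
    """Mean new families per added genome over additions ``from_N..to_N``.

    The increment at N is pan(N) - pan(N-1) on the permutation-mean curve,
    so ``from_N`` must be at least 2.
    """
    g = len(curve.N)
    if not (1 < from_N <= to_N <= g):
        raise ValueError(
            f"invalid range [{from_N}, {to_N}] for a {g}-genome curve "
            "(need 1 < from_N <= to_N <= G)"
        )
    diffs = [
        curve.pan_mean[n - 1] - curve.pan_mean[n - 2] for n in range(from_N, to_N + 1)
    ]
    return float(np.mean(diffs))


def shared_fraction_pct(total_families: int, n_absent: int) -> int:
    """Percent of a pan-genome's families present in a sub-collection.

    Reported rounded to the nearest integer (half-up), matching how such
    overlaps are printed in comparative surveys.
    """
    if total_families <= 0:
        raise ValueError("total_families must be positive")
    if not 0 <= n_absent <= total_families:
        raise ValueError("n_absent out of range")
    return int(_round_half_up(100.0 * (total_families - n_absent) / total_families))


def core_fraction_pct(n_core: int, n_variable: int) -> int:
    """Core families as an integer percentage of all families."""
    total = n_core + n_variable
    if total <= 0:
        raise ValueError("empty family set")
    return int(_round_half_up(100.0 * n_core / total))


def compare_pangenomes(
    full: pd.DataFrame, subset_genomes: Sequence[str]
) -> tuple[int, int]:
    """How much of a pan-genome is covered by a subset of its genomes.

    Returns ``(pct_present, n_absent)``: the families of ``full`` with no
    occurrence across ``subset_genomes`` are absent; the present percentage
    is reported rounded to the nearest integer.
    """
    if len(subset_genomes) == 0:
        raise ValueError("subset_genomes must not be empty")
    missing = set(subset_genomes) - set(full.columns)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    sub = full.loc[:, list(subset_genomes)]
    n_absent = int((sub.sum(axis=1) == 0).sum())
    return shared_fraction_pct(len(full), n_absent), n_absent


def genome_summary(stats: pd.DataFrame) -> dict[str, dict]:
    """Per-column summary of a genome statistics table.

    ``stats`` is indexed by genome with columns ``orfs``,
    ``genome_size_bp``, ``gc_percent`` and (optionally) ``unique_genes``.
    Means and *population* standard deviations (divisor n) are reported,
    rounded half-up: ORF counts to integers, GC to 2 decimals, sizes to
    2 decimals in Mbp.  Extremes come with the genome that attains them.
    """
    if len(stats) < 1:
        raise ValueError("need at least one genome")

    def col_summary(values: pd.Series, ndigits: int, as_int: bool) -> dict:
        mean = _round_half_up(float(values.mean()), 0 if as_int else ndigits)
        sd = _round_half_up(float(values.std(ddof=0)), 0 if as_int else ndigits)
        if as_int:
            mean, sd = int(mean), int(sd)
        return {
            "mean": mean,
            "sd": sd,
            "min": float(values.min()),
            "max": float(values.max()),
            "argmin": str(values.idxmin()),
            "argmax": str(values.idxmax()),
        }

    out = {
        "orfs": col_summary(stats["orfs"], 0, as_int=True),
        "gc_percent": col_summary(stats["gc_percent"], 2, as_int=False),
        "genome_size_mbp": col_summary(stats["genome_size_bp"] / 1e6, 2, as_int=False),
    }
    if "unique_genes" in stats.columns:
        out["unique_genes"] = {
            "total": int(stats["unique_genes"].sum()),
            "min": int(stats["unique_genes"].min()),
            "max": int(stats["unique_genes"].max()),
            "argmin": str(stats["unique_genes"].idxmin()),
            "argmax": str(stats["unique_genes"].idxmax()),
        }
    return out


def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: str(labels[i]) for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0) / 2
        lb = max(h - heights[b], 0.0) / 2
        nodes[n + k] = f"({nodes[a]}:{la:.6f},{nodes[b]}:{lb:.6f})"
        heights[n + k] = h
    return nodes[n + len(linkage) - 1] + ";"


def hierarchical_heatmap_export(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Average-linkage clustering of genomes on Jaccard distance.

    Returns the matrix with genome columns reordered to the dendrogram
    leaf order, the scipy linkage array, and a Newick rendering of the
    dendrogram.  Input columns are processed in sorted genome order so the
    leaf order is deterministic.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 genomes")
    cols = sorted(matrix.columns)
    binary = (matrix.loc[:, cols].to_numpy() > 0).T  # genomes x families
    dists = pdist(binary, metric="jaccard")
    linkage = average(dists)
    order = [cols[i] for i in leaves_list(linkage)]
    newick = _linkage_to_newick(linkage, cols)
    return matrix.loc[:, order], linkage, newick
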