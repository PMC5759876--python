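"""Gene-trait matching (GTM).

Associates gene-family presence/absence with binary growth phenotypes by
exact pattern matching.  The genotype matrix is the presence/absence
matrix after removing core families (no signal: present everywhere) and
families whose annotation marks them as mobile or defence elements
(transposases, prophages, restriction/modification, CRISPR), then
collapsing families with identical occurrence patterns into single rows.
Each genotype pattern row is scored against each phenotype row as the
percentage of strains where the two binary vectors agree; cells strictly
above the hit threshold (default 95%) are reported as candidate
carbohydrate-utilization gene clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotype import PhenotypeMatrix, select_differential

__all__ = [
    "DEFAULT_EXCLUSION_KEYWORDS",
    "GenotypePatternMatrix",
    "MatchResult",
    "Hit",
    "family_annotations",
    "build_genotype_matrix",
    "collapse_patterns",
    "match_percentage",
    "match_all",
    "report_hits",
]

#: annotation substrings (case-insensitive) excluded from trait matching;
#: mobile elements and defence systems are unrelated to carbon utilization
DEFAULT_EXCLUSION_KEYWORDS = (
    "transposase",
    "integrase",
    "phage",
    "prophage",
    "restriction",
    "methyltransferase",
    "crispr",
    "mobile element",
)

#: how indeterminate phenotype calls enter the match percentage
POLICY_AS_ZERO = "as_zero"    # count the position, treating the call as 0
POLICY_STRICT = "strict"      # drop the position from numerator and denominator


def family_annotations(
    families: Mapping[str, Mapping[str, Sequence[str]]],
    annotations: Mapping[str, str],
) -> dict[str, str | None]:
    """Representative annotation per family.

    The most frequent member-gene annotation wins; ties break towards the
    lexicographically smallest text.  Families whose members all lack an
    annotation map to None (they are retained downstream and flagged).
    """
    out: dict[str, str | None] = {}
    for fid, by_genome in families.items():
        texts = [
            annotations[g]
            for members in by_genome.values()
            for g in members
            if g in annotations
        ]
        if not texts:
            out[fid] = None
            continue
        counts = Counter(texts)
        top = max(counts.values())
        out[fid] = min(t for t, c in counts.items() if c == top)
    return out


def build_genotype_matrix(
    matrix: pd.DataFrame,
    annotations: Mapping[str, str | None],
    exclusion_keywords: Iterable[str] = DEFAULT_EXCLUSION_KEYWORDS,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Filter the presence/absence matrix for trait matching.

    Drops families present in every strain (the core carries no contrast)
    and families whose annotation contains any exclusion keyword
    (case-insensitive substring).  ``annotations`` maps family id to its
    representative annotation (see :func:`family_annotations`); families
    missing from it, or mapped to None, are retained and flagged.

    Returns the filtered binary matrix and a dict of the dropped family
    ids under ``"core"`` and ``"excluded"``, plus ``"unannotated"``
    listing retained families without any annotation.
    """
    keywords = [k.lower() for k in exclusion_keywords]
    binary = (matrix > 0).astype(int)
    is_core = binary.sum(axis=1) == binary.shape[1]

    dropped = {"core": sorted(binary.index[is_core]), "excluded": [], "unannotated": []}
    keep: list[str] = []
    for fid in binary.index[~is_core]:
        text = annotations.get(fid)
        if text is None:
            dropped["unannotated"].append(fid)
            keep.append(fid)
            continue
        low = text.lower()
        if any(k in low for k in keywords):
            dropped["excluded"].append(fid)
        else:
            keep.append(fid)
    return binary.loc[keep], dropped


@dataclass
class GenotypePatternMatrix:
    """Distinct occurrence patterns with their member families.

    ``patterns`` is pattern id x strains (0/1, all rows distinct);
    ``members`` maps pattern id -> member family ids; ``annotations``
    maps pattern id -> the members' representative annotations (aligned
    with ``members``).
    """

    patterns: pd.DataFrame
    members: dict[str, list[str]]
    annotations: dict[str, list[str | None]] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.patterns.columns)

    def expand(self) -> pd.DataFrame:
        """Reconstruct the per-family binary matrix (members x strains)."""
        rows = {
            fid: self.patterns.loc[pid]
            for pid, fams in self.members.items()
            for fid in fams
        }
        return pd.DataFrame(rows).T.sort_index()


def collapse_patterns(
    filtered: pd.DataFrame,
    annotations: Mapping[str, str | None] | None = None,
) -> GenotypePatternMatrix:
    """Group families with identical presence/absence vectors.

    Pattern rows are ordered by decreasing carriage (then by vector), and
    labelled G0001, G0002, ...; member family lists stay sorted.
    """
    groups: dict[tuple[int, ...], list[str]] = {}
    for fid in filtered.index:
        vec = tuple(int(v) for v in filtered.loc[fid])
        groups.setdefault(vec, []).append(fid)

    ordered = sorted(groups, key=lambda v: (-sum(v), tuple(-x for x in v)))
    width = max(4, len(str(len(ordered))))
    pattern_rows = {}
    members: dict[str, list[str]] = {}
    annot: dict[str, list[str | None]] = {}
    for k, vec in enumerate(ordered, start=1):
        pid = f"G{k:0{width}d}"
        pattern_rows[pid] = list(vec)
        members[pid] = sorted(groups[vec])
        if annotations is not None:
            annot[pid] = [annotations.get(f) for f in members[pid]]
    patterns = pd.DataFrame.from_dict(
        pattern_rows, orient="index", columns=list(filtered.columns)
    ).astype(int)
    return GenotypePatternMatrix(patterns=patterns, members=members, annotations=annot)


def match_percentage(
    genotype_row: Sequence[int],
    phenotype_row: Sequence,
    policy: str = POLICY_AS_ZERO,
) -> tuple[float, int]:
    """Position-wise agreement between a genotype and a phenotype vector.

    Agreement counts both 1-1 and 0-0 positions.  Indeterminate phenotype
    calls (None/NA) are treated as 0 under the default policy, or removed
    from both numerator and denominator under ``"strict"``.  Returns
    ``(percent, n_compared)``; an empty comparison scores 0 over 0.
    """
    g = list(genotype_row)
    p = list(phenotype_row)
    if len(g) != len(p):
        raise ValueError(f"length mismatch: genotype {len(g)} vs phenotype {len(p)}")
    agree = 0
    n = 0
    for gv, pv in zip(g, p):
        indet = pv is None or pv is pd.NA or (isinstance(pv, float) and np.isnan(pv))
        if indet:
            if policy == POLICY_STRICT:
                continue
            pv = 0
        n += 1
        if int(gv) == int(pv):
            agree += 1
    return (100.0 * agree / n if n else 0.0, n)


@dataclass
class MatchResult:
    """Pattern x carbohydrate matching percentages."""

    matches: pd.DataFrame      # percent, patterns x carbohydrates
    n_compared: pd.DataFrame   # strains compared per cell
    policy: str
    n_indeterminate: int


def match_all(
    genotype: GenotypePatternMatrix,
    phenotype: PhenotypeMatrix,
    carbohydrates: Sequence[str] | None = None,
    policy: str = POLICY_AS_ZERO,
) -> MatchResult:
    """Score every genotype pattern against every (differential) phenotype row.

    Strains must agree between the two matrices (they are aligned by id).
    By default the phenotype is restricted to differentially utilized,
    non-control carbohydrates.
    """
    gs, ps = set(genotype.strains), set(phenotype.strains)
    if gs != ps:
        raise ValueError(
            "strain sets differ between genotype and phenotype; "
            f"only in genotype: {sorted(gs - ps)}, only in phenotype: {sorted(ps - gs)}"
        )
    if carbohydrates is None:
        carbohydrates = select_differential(phenotype)
    strains = sorted(gs)
    gmat = genotype.patterns.loc[:, strains]
    pmat = phenotype.calls.loc[list(carbohydrates), strains]

    matches = pd.DataFrame(
        0.0, index=gmat.index, columns=list(carbohydrates)
    )
    ncmp = pd.DataFrame(0, index=gmat.index, columns=list(carbohydrates), dtype=int)
    for carb in carbohydrates:
        prow = list(pmat.loc[carb])
        for pid in gmat.index:
            pct, n = match_percentage(list(gmat.loc[pid]), prow, policy=policy)
            matches.at[pid, carb] = pct
            ncmp.at[pid, carb] = n
    return MatchResult(
        matches=matches,
        n_compared=ncmp,
        policy=policy,
        n_indeterminate=int(pmat.isna().to_numpy().sum()),
    )


@dataclass(frozen=True)
class Hit:
    carbohydrate: str
    pattern_id: str
    match_pct: float
    n_compared: int
    families: tuple[str, ...]
    annotations: tuple[str | None, ...]


def report_hits(
    result: MatchResult,
    genotype: GenotypePatternMatrix,
    threshold: float = 95.0,
) -> tuple[list[Hit], list[Hit]]:
    """Candidate gene clusters from the match matrix.

    Hits are cells with match strictly greater than ``threshold`` (at 20
    strains, 19/20 = 95% does not qualify under the default rule).
    Returns ``(hits, partial)``: partial matches are the remaining cells
    ranked by decreasing percentage (candidates for manual inspection,
    e.g. clusters with a single discordant strain), truncated to those
    above 50%.
    """
    hits: list[Hit] = []
    partial: list[Hit] = []
    for carb in result.matches.columns:
        for pid in result.matches.index:
            pct = float(result.matches.at[pid, carb])
            item = Hit(
                carbohydrate=carb,
                pattern_id=pid,
                match_pct=pct,
                n_compared=int(result.n_compared.at[pid, carb]),
                families=tuple(genotype.members.get(pid, ())),
                annotations=tuple(genotype.annotations.get(pid, ())),
            )
            if pct > threshold:
                hits.append(item)
            elif pct > 50.0:
                partial.append(item)
    hits.sort(key=lambda h: (-h.match_pct, h.carbohydrate, h.pattern_id))
    partial.sort(key=lambda h: (-h.match_pct, h.carbohydrate, h.pattern_id))
    return hits, partial
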