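"""Protein-family clustering: similarity filtering, graph construction and MCL.

Genes are clustered into families by filtering an all-vs-all protein
similarity search (minimum percent identity, maximum e-value), building an
undirected weighted similarity graph, and running the Markov Cluster
Algorithm (MCL).  MCL alternates random-walk *expansion* (matrix squaring)
with *inflation* (elementwise powering and column renormalisation); the
limit matrix decomposes the graph into attractor systems which are read out
as clusters.  The inflation exponent controls granularity (default 2.5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align

__all__ = [
    "SimilarityRecord",
    "FamilySet",
    "MCLConvergenceError",
    "pairwise_identity",
    "all_vs_all_identity",
    "filter_similarities",
    "build_graph",
    "mcl_cluster",
    "extract_single_copy",
    "genome_from_gene_id",
]

# 20 canonical amino acids plus X (unknown), B/Z/U/O occur in real data.
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO*")


@dataclass(frozen=True)
class SimilarityRecord:
    """One row of an all-vs-all protein comparison (BLAST-tabular-like)."""

    query: str
    subject: str
    pct_identity: float
    evalue: float = 0.0
    bitscore: float | None = None
    aln_len: int = 0

    def __post_init__(self) -> None:
        if not self.query or not self.subject:
            raise ValueError("query and subject ids must be non-empty")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative: {self.evalue}")


@dataclass
class FamilySet:
    """Partition of genes into families.

    ``families`` maps family id -> (genome id -> list of member gene ids).
    Every input gene belongs to exactly one family; singletons form their
    own family.  ``provenance`` records the parameters that produced the
    clustering (identity/e-value cut-offs, inflation).
    """

    families: dict[str, dict[str, list[str]]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.families)

    def genes(self, family_id: str) -> list[str]:
        return sorted(
            g for members in self.families[family_id].values() for g in members
        )

    def all_genes(self) -> list[str]:
        return sorted(
            g
            for members_by_genome in self.families.values()
            for members in members_by_genome.values()
            for g in members
        )

    def membership(self) -> dict[str, set[str]]:
        """Family id -> set of genomes carrying at least one member."""
        return {fid: set(by_gen) for fid, by_gen in self.families.items()}


class MCLConvergenceError(RuntimeError):
    pass


def genome_from_gene_id(gene_id: str) -> str:
    """Default genome lookup for ids shaped ``<strain>|<family>|<serial>``."""
    return gene_id.split("|", 1)[0]


# ---------------------------------------------------------------------------
# similarity computation and filtering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq.upper()) - _AA_ALPHABET
    if bad:
        raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")


def pairwise_identity(seq_a: str, seq_b: str) -> SimilarityRecord:
    """Global-alignment percent identity between two protein sequences.

    Identity scoring (match 1, mismatch 0) with a linear gap penalty;
    percent identity is 100 * matches / alignment length.  The e-value is
    reported as 0 for this internal path — downstream filtering on such
    records relies on identity alone.  Symmetric in its arguments.
    """
    _check_protein(seq_a, "seq_a")
    _check_protein(seq_b, "seq_b")
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) == len(b):
        # Sequences of equal length: the optimal identity-scored global
        # alignment is ungapped (every gap pair costs 2 and gains <= 1).
        matches = sum(x == y for x, y in zip(a, b))
        aln_len = len(a)
    else:
        aln = _make_aligner().align(a, b)[0]
        counts = aln.counts()
        matches = counts.identities
        aln_len = aln.length
    pct = 100.0 * matches / aln_len
    return SimilarityRecord(
        query="seq_a", subject="seq_b", pct_identity=pct, evalue=0.0,
        bitscore=None, aln_len=aln_len,
    )


def all_vs_all_identity(
    sequences: Mapping[str, str],
    min_report: float = 30.0,
) -> list[SimilarityRecord]:
    """All-vs-all percent identity for a set of protein sequences.

    Vectorised over equal-length sequence blocks (the common case for
    simulator output, where families are emitted pre-aligned); unequal
    lengths fall back to the pairwise global aligner.  Records below
    ``min_report`` identity are not emitted, which keeps the edge list
    sparse; the downstream family filter is stricter anyway.
    """
    ids = sorted(sequences)
    by_len: dict[int, list[str]] = {}
    for gid in ids:
        by_len.setdefault(len(sequences[gid]), []).append(gid)

    records: list[SimilarityRecord] = []
    for length, group in sorted(by_len.items()):
        arr = np.frombuffer(
            "".join(sequences[g] for g in group).encode("ascii"), dtype=np.uint8
        ).reshape(len(group), length)
        n = len(group)
        block = 256
        for i0 in range(0, n, block):
            sub = arr[i0 : i0 + block]
            # identity of every row in `sub` against every later row
            eq = (sub[:, None, :] == arr[None, :, :]).mean(axis=2) * 100.0
            for ii in range(sub.shape[0]):
                gi = i0 + ii
                js = np.nonzero(eq[ii] >= min_report)[0]
                for j in js:
                    if j <= gi:
                        continue
                    records.append(
                        SimilarityRecord(
                            query=group[gi],
                            subject=group[j],
                            pct_identity=float(eq[ii, j]),
                            evalue=0.0,
                            bitscore=None,
                            aln_len=length,
                        )
                    )
    # cross-length comparisons via the aligner
    lengths = sorted(by_len)
    for la, lb in itertools.combinations(lengths, 2):
        aligner = _make_aligner()
        for ga in by_len[la]:
            for gb in by_len[lb]:
                aln = aligner.align(sequences[ga], sequences[gb])[0]
                matches = aln.counts().identities
                pct = 100.0 * matches / aln.length
                if pct >= min_report:
                    records.append(
                        SimilarityRecord(
                            query=ga, subject=gb, pct_identity=pct,
                            evalue=0.0, bitscore=None, aln_len=aln.length,
                        )
                    )
    return records


def filter_similarities(
    records: Iterable[SimilarityRecord],
    min_identity: float = 50.0,
    max_evalue: float = 1e-4,
) -> list[SimilarityRecord]:
    """Apply the family-definition cut-offs (>=50% identity, e-value <=1e-4).

    Self-hits (query == subject) are removed here; MCL reintroduces
    self-loops internally.  Order-stable.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError("min_identity must be in [0, 100]")
    if max_evalue < 0:
        raise ValueError("max_evalue must be non-negative")
    return [
        r
        for r in records
        if r.query != r.subject
        and r.pct_identity >= min_identity
        and r.evalue <= max_evalue
    ]


def build_graph(
    records: Iterable[SimilarityRecord],
    all_genes: Sequence[str],
) -> nx.Graph:
    """Undirected similarity graph over ``all_genes``.

    Reciprocal hits collapse to a single edge whose weight is the maximum
    bitscore of the two directions (falling back to percent identity when
    bitscores are absent, as on the internal identity path).  Genes with no
    passing hits remain as isolated nodes so that they become singleton
    families.
    """
    known = set(all_genes)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(known))
    for r in records:
        if r.query not in known or r.subject not in known:
            missing = {r.query, r.subject} - known
            raise ValueError(f"record references unknown gene(s): {sorted(missing)}")
        w = r.bitscore if r.bitscore is not None else r.pct_identity
        if w <= 0:
            continue
        u, v = r.query, r.subject
        if graph.has_edge(u, v):
            graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
        else:
            graph.add_edge(u, v, weight=w)
    return graph


# ---------------------------------------------------------------------------
# Markov Cluster Algorithm
# ---------------------------------------------------------------------------

def _mcl_limit(
    weights: np.ndarray,
    inflation: float,
    max_iter: int,
    tol: float,
    prune: float,
) -> np.ndarray:
    """Iterate expansion/inflation/pruning on one dense adjacency block."""
    n = weights.shape[0]
    m = weights.astype(float).copy()
    # self-loop per node = maximum incident edge weight (canonical stabiliser)
    incident_max = m.max(axis=0)
    incident_max[incident_max <= 0] = 1.0
    np.fill_diagonal(m, incident_max)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        nxt = m @ m                      # expansion
        np.power(nxt, inflation, out=nxt)  # inflation
        nxt[nxt < prune] = 0.0           # pruning
        colsum = nxt.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        nxt /= colsum
        change = np.abs(nxt - m).max()
        m = nxt
        if change < tol:
            return m
    raise MCLConvergenceError(
        f"MCL did not converge within {max_iter} iterations "
        f"(last max-change {change:.2e} >= tol {tol:.2e}) on a {n}-node component"
    )


def _clusters_from_limit(limit: np.ndarray, eps: float = 1e-6) -> list[list[int]]:
    """Read attractor systems out of the MCL limit matrix.

    Attractors are nodes with positive diagonal mass; an attractor's cluster
    is the support of its row.  Attractors whose rows overlap belong to one
    attractor system.  A non-attractor node reachable from several systems
    is assigned to the system with the larger total steady-state (diagonal)
    mass; ties break towards the system containing the smallest node index.
    """
    n = limit.shape[0]
    attractors = [i for i in range(n) if limit[i, i] > eps]
    if not attractors:           # numerically degenerate; treat all as singletons
        return [[i] for i in range(n)]

    # union attractors that attract each other / share support
    parent = {a: a for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a in attractors:
        for b in attractors:
            if a < b and (limit[a, b] > eps or limit[b, a] > eps):
                union(a, b)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)

    mass = {root: sum(limit[a, a] for a in members) for root, members in systems.items()}
    members_of: dict[int, set[int]] = {root: set(members) for root, members in systems.items()}
    for root, atts in systems.items():
        for a in atts:
            members_of[root].update(np.nonzero(limit[a] > eps)[0].tolist())

    assigned: dict[int, int] = {}
    for node in range(n):
        owners = [root for root in systems if node in members_of[root]]
        if not owners:
            continue
        # larger steady-state mass wins; ties -> smallest root index
        owners.sort(key=lambda r: (-mass[r], r))
        assigned[node] = owners[0]

    clusters: dict[int, list[int]] = {}
    for node in range(n):
        root = assigned.get(node)
        if root is None:
            clusters.setdefault(-node - 1, []).append(node)  # orphan -> singleton
        else:
            clusters.setdefault(root, []).append(node)
    return [sorted(c) for c in clusters.values()]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.5,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-5,
    genome_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> FamilySet:
    """Cluster a similarity graph into gene families with MCL.

    Connected components are processed independently (MCL never merges
    disconnected components, and a random walk cannot cross between them),
    which keeps the dense iteration desk-scale.  Isolated nodes become
    singleton families.  Family labels are assigned deterministically,
    ordered by each family's smallest member gene id.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    if genome_of is None:
        lookup: Callable[[str], str] = genome_from_gene_id
    elif callable(genome_of):
        lookup = genome_of
    else:
        mapping = dict(genome_of)
        lookup = mapping.__getitem__

    clusters: list[list[str]] = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            clusters.append(nodes)
            continue
        index = {g: i for i, g in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for u, v, data in graph.subgraph(component).edges(data=True):
            w[index[u], index[v]] = w[index[v], index[u]] = data["weight"]
        limit = _mcl_limit(w, inflation, max_iter, tol, prune)
        for idx_cluster in _clusters_from_limit(limit):
            clusters.append([nodes[i] for i in idx_cluster])

    clusters.sort(key=lambda c: c[0])
    width = max(4, len(str(len(clusters))))
    families: dict[str, dict[str, list[str]]] = {}
    for k, members in enumerate(clusters, start=1):
        fid = f"F{k:0{width}d}"
        by_genome: dict[str, list[str]] = {}
        for gene in members:
            by_genome.setdefault(lookup(gene), []).append(gene)
        families[fid] = {g: sorted(gs) for g, gs in sorted(by_genome.items())}
    return FamilySet(
        families=families,
        provenance={"inflation": inflation, "max_iter": max_iter,
                    "tol": tol, "prune": prune},
    )


def extract_single_copy(families: FamilySet, genome_ids: Sequence[str]) -> FamilySet:
    """Families with exactly one member in every listed genome.

    This is the paralogue filter used ahead of the core-gene supertree:
    a family qualifies only if it is present in all genomes and is
    single-copy everywhere.
    """
    wanted = set(genome_ids)
    kept = {
        fid: by_gen
        for fid, by_gen in families.families.items()
        if wanted <= set(by_gen) and all(len(by_gen[g]) == 1 for g in wanted)
    }
    return FamilySet(
        families=kept,
        provenance={**families.provenance, "single_copy_in": sorted(wanted)},
    )
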