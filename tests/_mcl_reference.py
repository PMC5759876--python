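"""Independent dense reference implementation of Markov clustering.

Written separately from the package implementation (whole-matrix dense
iteration, no per-component decomposition, its own readout code) so it can
serve as the oracle in clustering equivalence tests.  Parameters follow the
same published algorithm: self-loops equal to the maximum incident weight,
column-stochastic normalisation, expansion by squaring, inflation by
elementwise powering, pruning below 1e-5, convergence when the matrix stops
changing.
"""

from __future__ import annotations

import numpy as np


def reference_mcl(
    adjacency: np.ndarray,
    inflation: float = 2.5,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> list[list[int]]:
    """Cluster a symmetric weighted adjacency matrix; returns index lists."""
    a = np.asarray(adjacency, dtype=float).copy()
    n = a.shape[0]
    for i in range(n):
        row_max = a[i].max()
        a[i, i] = row_max if row_max > 0 else 1.0
    m = a / a.sum(axis=0)

    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, 2)
        new = new ** inflation
        new[new < prune] = 0.0
        sums = new.sum(axis=0)
        sums[sums == 0] = 1.0
        new = new / sums
        if np.max(np.abs(new - m)) < tol:
            m = new
            break
        m = new
    else:
        raise RuntimeError("reference MCL failed to converge")

    eps = 1e-6
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:
        return [[i] for i in range(n)]

    # group attractors into systems (mutual/shared support)
    systems: list[set[int]] = []
    for att in attractors:
        merged = None
        for sys_ in systems:
            if any(m[att, other] > eps or m[other, att] > eps for other in sys_):
                sys_.add(att)
                merged = sys_
                break
        if merged is None:
            systems.append({att})
    # transitive closure of the merge
    changed = True
    while changed:
        changed = False
        for i in range(len(systems)):
            for j in range(i + 1, len(systems)):
                if any(
                    m[a1, a2] > eps or m[a2, a1] > eps
                    for a1 in systems[i]
                    for a2 in systems[j]
                ):
                    systems[i] |= systems[j]
                    del systems[j]
                    changed = True
                    break
            if changed:
                break

    support = []
    for sys_ in systems:
        nodes = set()
        for att in sys_:
            nodes.update(int(j) for j in np.nonzero(m[att] > eps)[0])
        support.append(nodes)
    masses = [sum(m[a, a] for a in sys_) for sys_ in systems]

    assignment: dict[int, int] = {}
    for node in range(n):
        owners = [k for k, nodes in enumerate(support) if node in nodes]
        if not owners:
            continue
        owners.sort(key=lambda k: (-masses[k], min(systems[k])))
        assignment[node] = owners[0]

    clusters: dict[int, list[int]] = {}
    orphan = len(systems)
    for node in range(n):
        if node in assignment:
            clusters.setdefault(assignment[node], []).append(node)
        else:
            clusters.setdefault(orphan, []).append(node)
            orphan += 1
    return sorted([sorted(c) for c in clusters.values()])
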