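"""Independent reference implementations used only as test oracles.

Each oracle is written from the mathematical definition, sharing no code
path with the package: a hand-rolled Gotoh dynamic program and an
exhaustive alignment-path enumerator for local alignment scores, a
vectorized pH-grid scan for isoelectric points, and a union-find for
graph components.
"""
from __future__ import annotations

import numpy as np

# --- local alignment -------------------------------------------------------


def gotoh_local_score(a: str, b: str, S: dict, gap_open: float, gap_ext: float) -> float:
    """Smith-Waterman score with affine gaps; a length-L gap costs
    gap_open + (L-1)*gap_ext. Independent reimplementation (plain dicts,
    no traceback)."""
    n, m = len(a), len(b)
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            H[i, j] = max(0.0, H[i - 1, j - 1] + S[a[i - 1]][b[j - 1]], E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def enumerate_local_score(a: str, b: str, S: dict, gap_open: float, gap_ext: float) -> float:
    """True brute force: enumerate every local alignment path explicitly.

    Feasible only for very short sequences; validates the Gotoh oracle.
    Every alignment starts with an aligned residue pair (leading or
    trailing gaps only lower a local score, so none is optimal without
    this property).
    """
    n, m = len(a), len(b)
    best = 0.0

    def rec(i: int, j: int, score: float, state: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + S[a[i]][b[j]], "M")
        if i < n:
            rec(i + 1, j, score - (gap_ext if state == "A" else gap_open), "A")
        if j < m:
            rec(i, j + 1, score - (gap_ext if state == "B" else gap_open), "B")

    for i in range(n):
        for j in range(m):
            rec(i + 1, j + 1, S[a[i]][b[j]], "M")
    return best


def blosum_dict(matrix) -> dict:
    """Plain nested-dict copy of a biopython substitution matrix."""
    letters = matrix.alphabet
    return {x: {y: float(matrix[x, y]) for y in letters} for x in letters}


# --- isoelectric point -----------------------------------------------------

_EMBOSS = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5}
_BASIC = {"K", "R", "H"}


def grid_charge(sequence: str, ph: np.ndarray, cyclic: bool) -> np.ndarray:
    """Vectorized Henderson-Hasselbalch net charge over a pH grid."""
    q = np.zeros_like(ph)
    for res in sequence:
        pk = _EMBOSS.get(res)
        if pk is None:
            continue
        if res in _BASIC:
            q += 1.0 / (1.0 + 10.0 ** (ph - pk))
        else:
            q -= 1.0 / (1.0 + 10.0 ** (pk - ph))
    if not cyclic:
        q += 1.0 / (1.0 + 10.0 ** (ph - 8.6))
        q -= 1.0 / (1.0 + 10.0 ** (3.6 - ph))
    return q


def grid_pi(sequence: str, cyclic: bool):
    """pI by pH-grid scan at 1e-5 resolution (hierarchical: net charge is
    strictly decreasing in pH, so refining the coarse bracketing interval
    visits exactly the grid points a full scan would select from)."""
    coarse = np.arange(0.001, 13.999, 0.01)
    q = grid_charge(sequence, coarse, cyclic)
    if not (q[0] > 0.0 > q[-1]):
        return None
    k = int(np.argmax(q < 0.0))
    fine = np.arange(coarse[k - 1], coarse[k] + 1e-5, 1e-5)
    qf = grid_charge(sequence, fine, cyclic)
    return float(fine[np.argmin(np.abs(qf))])


# --- graph components ------------------------------------------------------


def union_find_components(node_ids: list, edges: list) -> list[tuple]:
    """Connected components via union-find; returns sorted tuples."""
    parent = {n: n for n in node_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict = {}
    for n in node_ids:
        comps.setdefault(find(n), []).append(n)
    return sorted(tuple(sorted(c)) for c in comps.values())


# --- random additive trees -------------------------------------------------


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with branch lengths; returns (leaf names,
    distance matrix, bipartition set) computed by path summation."""
    import itertools

    nodes = [{"name": f"t{i}", "children": []} for i in range(n_leaves)]
    lengths: dict = {}
    avail = list(range(n_leaves))
    all_nodes = list(nodes)
    while len(avail) > 1:
        i = int(rng.integers(len(avail)))
        a = avail.pop(i)
        j = int(rng.integers(len(avail)))
        b = avail.pop(j)
        parent = {"name": None, "children": [a, b]}
        all_nodes.append(parent)
        pid = len(all_nodes) - 1
        lengths[(pid, a)] = float(rng.uniform(0.1, 1.0))
        lengths[(pid, b)] = float(rng.uniform(0.1, 1.0))
        avail.append(pid)

    # leaf-to-leaf distances by tracing paths to the root
    def path_to_root(x):
        path = []
        cur = x
        while True:
            parents = [p for (p, c) in lengths if c == cur]
            if not parents:
                return path
            p = parents[0]
            path.append((p, cur))
            cur = p

    names = [f"t{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for x, y in itertools.combinations(range(n_leaves), 2):
        px = path_to_root(x)
        py = path_to_root(y)
        shared = set(px) & set(py)
        d = sum(lengths[e] for e in px if e not in shared)
        d += sum(lengths[e] for e in py if e not in shared)
        D[x, y] = D[y, x] = d

    # bipartitions: leaves below each internal edge
    def leaves_below(idx):
        node = all_nodes[idx]
        if not node["children"]:
            return {node["name"]}
        out = set()
        for c in node["children"]:
            out |= leaves_below(c)
        return out

    allset = frozenset(names)
    splits = set()
    for (p, c) in lengths:
        below = frozenset(leaves_below(c))
        if 1 < len(below) < n_leaves - 1:
            other = allset - below
            splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return names, D, splits
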