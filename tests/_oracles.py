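"""Independent brute-force oracles used by the test suite.

These deliberately share no logic with the package: alignment scores come
from exhaustive enumeration of every global alignment, divergent sites from
a direct column scan, and NJ correctness from distances generated off a
known random tree.
"""

from __future__ import annotations

import math
import random


def enumerate_alignment_optimum(s1: str, s2: str, score_fn, gap_open: float,
                                gap_extend: float) -> float:
    """Best global-alignment score by exhaustive enumeration (strings <= ~7).

    Affine cost: a maximal run of L gap columns in one sequence costs
    gap_open + (L - 1) * gap_extend.
    """
    best = -math.inf

    def rec(i: int, j: int, prev: str, acc: float) -> None:
        nonlocal best
        if i == len(s1) and j == len(s2):
            best = max(best, acc)
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1, "M", acc + score_fn(s1[i], s2[j]))
        if i < len(s1):
            cost = gap_extend if prev == "E" else gap_open
            rec(i + 1, j, "E", acc - cost)
        if j < len(s2):
            cost = gap_extend if prev == "F" else gap_open
            rec(i, j + 1, "F", acc - cost)

    rec(0, 0, "", 0.0)
    return best


def brute_force_divergent_columns(rows: dict[str, str], ids_a, ids_b,
                                  score_fn, charge_fn) -> list[tuple[int, str, str]]:
    """Direct re-implementation of the divergence rule, column by column."""
    length = len(next(iter(rows.values())))
    out = []
    for c in range(length):
        va = {rows[i][c] for i in ids_a}
        vb = {rows[i][c] for i in ids_b}
        if len(va) != 1 or len(vb) != 1:
            continue
        (a,), (b,) = va, vb
        if a in "-X" or b in "-X" or a == b:
            continue
        if score_fn(a, b) < 0 or charge_fn(a) * charge_fn(b) == -1:
            out.append((c + 1, a, b))
    return out


class _Node:
    def __init__(self, name=None):
        self.name = name
        self.children = []  # (child, edge length)


def random_additive_tree(n_leaves: int, rng: random.Random
                         ) -> tuple[str, list[str], list[list[float]]]:
    """A random binary tree; returns (newick, taxa, leaf-leaf distances)."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    nodes = [_Node(t) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        parent = _Node()
        parent.children = [(nodes[i], rng.uniform(0.5, 1.5)),
                           (nodes[j], rng.uniform(0.5, 1.5))]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = _Node()
    root.children = [(nodes[0], rng.uniform(0.5, 1.5)),
                     (nodes[1], rng.uniform(0.5, 1.5))]

    # leaf depths along the tree, then distances through lowest common ancestors
    paths: dict[str, list[tuple[_Node, float]]] = {}

    def walk(node: _Node, path):
        if node.name is not None:
            paths[node.name] = path
        for child, length in node.children:
            walk(child, path + [(child, length)])

    walk(root, [])
    dist = [[0.0] * n_leaves for _ in range(n_leaves)]
    for a in range(n_leaves):
        for b in range(a + 1, n_leaves):
            pa, pb = paths[taxa[a]], paths[taxa[b]]
            shared = 0
            while (shared < len(pa) and shared < len(pb)
                   and pa[shared][0] is pb[shared][0]):
                shared += 1
            d = sum(l for _, l in pa[shared:]) + sum(l for _, l in pb[shared:])
            dist[a][b] = dist[b][a] = d

    def newick(node: _Node) -> str:
        if node.name is not None:
            return node.name
        inner = ",".join(f"{newick(c)}:{l:g}" for c, l in node.children)
        return f"({inner})"

    return newick(root) + ";", taxa, dist
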