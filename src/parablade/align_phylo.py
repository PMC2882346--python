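"""Pairwise/progressive alignment, percent identity, domain cross-comparison
and neighbor-joining trees.

The aligner is a global Needleman-Wunsch/Gotoh with affine gap costs: a gap
of length L costs ``gap_open + (L - 1) * gap_extend``.  The same dynamic
program aligns single sequences and profiles (for the progressive MSA), with
the profile-profile column score defined as the mean of all cross-pair
substitution scores; a gap paired with a residue contributes
``-gap_extend`` and a gap paired with a gap contributes 0.  Existing gaps
inside a profile are never removed ("once a gap, always a gap").

Trees are built with the Saitou-Nei neighbor-joining algorithm from a
percent-identity distance matrix; negative branch-length estimates are
clamped to zero and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import (ALPHABET, GAP, MultipleAlignment, ProteinSequence,
                    SubstitutionMatrix, load_blosum62)

_NEG = -1e30


@dataclass
class AlignmentParams:
    """Scoring parameters: substitution matrix plus affine gap costs."""

    matrix: SubstitutionMatrix = field(default_factory=load_blosum62)
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class DomainPartition:
    """Ordered (label, first, last) residue ranges partitioning one sequence.

    Ranges are 1-based inclusive, contiguous from 1.  Whether the last range
    ends at the sequence length can only be checked against a sequence; use
    :meth:`validate_for`.
    """

    ranges: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("empty partition")
        expect = 1
        for label, first, last in self.ranges:
            if first != expect or last < first:
                raise ValueError(
                    f"partition ranges must be contiguous from 1; got {label} {first}-{last}"
                )
            expect = last + 1

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _, _ in self.ranges]

    def validate_for(self, seq: ProteinSequence) -> None:
        if self.ranges[-1][2] != len(seq):
            raise ValueError(
                f"partition for {seq.id!r} ends at {self.ranges[-1][2]} "
                f"but sequence has {len(seq)} residues"
            )

    def extract(self, seq: ProteinSequence, label: str) -> str:
        for lab, first, last in self.ranges:
            if lab == label:
                return seq.residues[first - 1:last]
        raise KeyError(f"no domain {label!r} in partition")


def load_domain_partitions() -> dict[str, DomainPartition]:
    """Packaged N/M/C domain boundaries for the seven Tup proteins."""
    text = resources.files("parablade.data").joinpath("domain_partitions.tsv").read_text()
    table: dict[str, list[tuple[str, int, int]]] = {}
    for line in text.splitlines()[1:]:
        protein, domain, start, end = line.split("\t")
        table.setdefault(protein, []).append((domain, int(start), int(end)))
    return {p: DomainPartition(r) for p, r in table.items()}


def load_wd40_segments() -> dict[str, tuple[int, int]]:
    """Packaged WD40 (C-terminal) alignment segments in native numbering.

    The reference (S. cerevisiae Tup1) segment is 282-713.
    """
    text = resources.files("parablade.data").joinpath("wd40_segments.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        protein, start, end = line.split("\t")
        out[protein] = (int(start), int(end))
    return out


# ---------------------------------------------------------------------------
# Profile representation and the Gotoh dynamic program

_SYMBOLS = ALPHABET + GAP
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP_IDX = _SYM_INDEX[GAP]


def _score_array(matrix: SubstitutionMatrix, gap_extend: float) -> np.ndarray:
    """Symbol-by-symbol score table including the gap symbol."""
    k = len(_SYMBOLS)
    S = np.zeros((k, k))
    for a in ALPHABET:
        for b in ALPHABET:
            S[_SYM_INDEX[a], _SYM_INDEX[b]] = matrix.score(a, b)
    S[_GAP_IDX, :] = -gap_extend
    S[:, _GAP_IDX] = -gap_extend
    S[_GAP_IDX, _GAP_IDX] = 0.0
    return S


class _Profile:
    """A block of gapped rows treated as one alignable unit."""

    def __init__(self, ids: list[str], rows: list[str]):
        self.ids = ids
        self.rows = rows
        self.length = len(rows[0]) if rows else 0

    def counts(self) -> np.ndarray:
        """(length, n_symbols) symbol counts per column."""
        C = np.zeros((self.length, len(_SYMBOLS)))
        for row in self.rows:
            idx = np.fromiter((_SYM_INDEX[c] for c in row), dtype=np.intp,
                              count=self.length)
            np.add.at(C, (np.arange(self.length), idx), 1.0)
        return C

    def with_gaps(self, ops: list[str], here: str) -> "_Profile":
        """Expand rows along an op string; *here* is this profile's consume op."""
        new_rows = []
        for row in self.rows:
            it = iter(row)
            new_rows.append("".join(next(it) if op in ("M", here) else GAP
                                    for op in ops))
        return _Profile(self.ids, new_rows)


def _gotoh(sub: np.ndarray, gap_open: float, gap_extend: float
           ) -> tuple[float, list[str]]:
    """Affine-gap global alignment over a precomputed column-score table.

    Returns the optimal score and the op string (``M`` consume both,
    ``E`` consume first/gap in second, ``F`` gap in first/consume second).
    Traceback ties prefer M over E over F.
    """
    n, m = sub.shape
    go, ge = float(gap_open), float(gap_extend)
    M = np.full((n + 1, m + 1), _NEG)
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if m:
        F[0, 1:] = -(go + np.arange(m) * ge)
    cols = np.arange(m + 1)
    for i in range(1, n + 1):
        H_prev = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        M[i, 1:] = H_prev[:-1] + sub[i - 1]
        E[i] = np.maximum(H_prev - go, E[i - 1] - ge)
        ME = np.maximum(M[i], E[i])
        run = np.maximum.accumulate(ME + cols * ge)
        F[i, 1:] = run[:-1] - go - (cols[1:] - 1) * ge
    i, j = n, m
    best = max(M[i, j], E[i, j], F[i, j])
    eps = 1e-6
    if M[i, j] >= best - eps:
        state = "M"
    elif E[i, j] >= best - eps:
        state = "E"
    else:
        state = "F"
    ops: list[str] = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, val in (("M", M[i, j]), ("E", E[i, j]), ("F", F[i, j])):
                if abs(val - target) <= eps:
                    state = cand
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failure in M state")
        elif state == "E":
            val = E[i, j]
            i -= 1
            if abs(M[i, j] - go - val) <= eps:
                state = "M"
            elif abs(E[i, j] - ge - val) <= eps:
                state = "E"
            elif abs(F[i, j] - go - val) <= eps:
                state = "F"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failure in E state")
        else:
            val = F[i, j]
            j -= 1
            if abs(M[i, j] - go - val) <= eps:
                state = "M"
            elif abs(E[i, j] - go - val) <= eps:
                state = "E"
            elif abs(F[i, j] - ge - val) <= eps:
                state = "F"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failure in F state")
    ops.reverse()
    return float(best), ops


def _align_profiles(a: _Profile, b: _Profile, params: AlignmentParams
                    ) -> tuple[_Profile, float]:
    S = _score_array(params.matrix, params.gap_extend)
    ca, cb = a.counts(), b.counts()
    denom = len(a.rows) * len(b.rows)
    sub = (ca @ S @ cb.T) / denom
    score, ops = _gotoh(sub, params.gap_open, params.gap_extend)
    merged = _Profile(a.ids + b.ids,
                      a.with_gaps(ops, "E").rows + b.with_gaps(ops, "F").rows)
    return merged, score


# ---------------------------------------------------------------------------
# Pairwise alignment and identity


def _as_id_and_residues(seq, default_id: str) -> tuple[str, str]:
    if isinstance(seq, ProteinSequence):
        return seq.id, seq.residues
    return default_id, str(seq)


def pairwise_align(s1, s2, params: Optional[AlignmentParams] = None
                   ) -> tuple[MultipleAlignment, float]:
    """Optimal global alignment of two sequences (affine gap costs).

    Accepts :class:`ProteinSequence` objects or plain strings; one of the
    two may be empty.  Returns a two-row alignment and its score.
    Traceback ties are broken deterministically, preferring a substitution
    column over a gap in the second sequence over a gap in the first.
    """
    params = params or AlignmentParams()
    id1, r1 = _as_id_and_residues(s1, "seq1")
    id2, r2 = _as_id_and_residues(s2, "seq2")
    if id1 == id2:
        id2 = id2 + "_2"
    if not r1 and not r2:
        raise ValueError("both sequences empty")
    a = _Profile([id1], [r1]) if r1 else None
    b = _Profile([id2], [r2]) if r2 else None
    if a is None:
        L = len(r2)
        cost = params.gap_open + (L - 1) * params.gap_extend
        return MultipleAlignment([(id1, GAP * L), (id2, r2)]), -cost
    if b is None:
        L = len(r1)
        cost = params.gap_open + (L - 1) * params.gap_extend
        return MultipleAlignment([(id1, r1), (id2, GAP * L)]), -cost
    merged, score = _align_profiles(a, b, params)
    return MultipleAlignment(list(zip(merged.ids, merged.rows))), score


def percent_identity(row1: str, row2: str) -> float:
    """Percent identity over columns where both rows carry a residue.

    Columns with a gap in either row are excluded from the denominator, so
    the value is insensitive to terminal gap placement.  If no column is
    comparable the function warns and returns 0.
    """
    if len(row1) != len(row2):
        raise ValueError(f"length mismatch: {len(row1)} vs {len(row2)}")
    comparable = identical = 0
    for c1, c2 in zip(row1, row2):
        if c1 != GAP and c2 != GAP:
            comparable += 1
            if c1 == c2:
                identical += 1
    if comparable == 0:
        warnings.warn("no comparable (gap-free) columns; returning 0 identity")
        return 0.0
    return 100.0 * identical / comparable


class DomainIdentityMatrix:
    """Per-domain percent identities for every protein pair."""

    def __init__(self, proteins: list[str], domains: list[str]):
        self.proteins = list(proteins)
        self.domains = list(domains)
        self.values: dict[tuple[str, str, str], float] = {}
        for p in proteins:
            for dom in domains:
                self.values[(p, p, dom)] = 100.0

    def set(self, p1: str, p2: str, domain: str, pid: float) -> None:
        self.values[(p1, p2, domain)] = pid
        self.values[(p2, p1, domain)] = pid

    def get(self, p1: str, p2: str, domain: str) -> float:
        return self.values[(p1, p2, domain)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per unordered protein pair and domain."""
        rows = []
        for i, p1 in enumerate(self.proteins):
            for p2 in self.proteins[i + 1:]:
                for dom in self.domains:
                    rows.append((p1, p2, dom, self.values[(p1, p2, dom)]))
        return pd.DataFrame(rows, columns=["protein_1", "protein_2", "domain",
                                           "percent_identity"])


def domain_identity_matrix(seqs: Sequence[ProteinSequence],
                           partitions: dict[str, DomainPartition],
                           params: Optional[AlignmentParams] = None
                           ) -> DomainIdentityMatrix:
    """Domain-wise cross comparison: align each domain pair, report identity."""
    params = params or AlignmentParams()
    for s in seqs:
        if s.id not in partitions:
            raise KeyError(f"no domain partition for sequence {s.id!r}")
        partitions[s.id].validate_for(s)
    domains = partitions[seqs[0].id].labels
    out = DomainIdentityMatrix([s.id for s in seqs], domains)
    for i, s1 in enumerate(seqs):
        for s2 in seqs[i + 1:]:
            for dom in domains:
                sub1 = partitions[s1.id].extract(s1, dom)
                sub2 = partitions[s2.id].extract(s2, dom)
                aln, _ = pairwise_align(sub1, sub2, params)
                out.set(s1.id, s2.id, dom,
                        percent_identity(aln.rows[0][1], aln.rows[1][1]))
    return out


# ---------------------------------------------------------------------------
# Distance matrices


class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    def __init__(self, taxa: Sequence[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        n = len(taxa)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.taxa = list(taxa)
        self.d = d

    def __len__(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def build_distance_matrix(seqs: Sequence[ProteinSequence],
                          params: Optional[AlignmentParams] = None,
                          model: str = "identity") -> DistanceMatrix:
    """Pairwise distances from full-length global alignments.

    ``identity``: d = 1 - fractional identity.  ``poisson``: the Poisson
    multiple-hit correction d = -ln(fractional identity).
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    if model not in ("identity", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    params = params or AlignmentParams()
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_align(seqs[i], seqs[j], params)
            frac = percent_identity(aln.rows[0][1], aln.rows[1][1]) / 100.0
            if model == "identity":
                dist = 1.0 - frac
            else:
                dist = -math.log(frac) if frac > 0 else 10.0
            d[i, j] = d[j, i] = dist
    return DistanceMatrix([s.id for s in seqs], d)


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    """Minimal rooted tree node; ``length`` is the edge to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode", length: float) -> None:
        child.length = length
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def find(self, name: str) -> "TreeNode":
        for node in self._walk():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def _walk(self):
        yield self
        for c in self.children:
            yield from c._walk()

    def newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"


def _invert_to(node: TreeNode) -> TreeNode:
    """Make *node* the root by reversing parent pointers along its path."""
    chain = []
    cur: Optional[TreeNode] = node
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    for child, parent in zip(chain, chain[1:]):
        parent.children.remove(child)
        child.add(parent, child.length)
    node.parent = None
    node.length = 0.0
    # splice out any node left with a single child (old root of degree 2)
    for n in list(node._walk()):
        if n is not node and len(n.children) == 1 and n.name is None:
            (only,) = n.children
            only.length += n.length
            parent = n.parent
            idx = parent.children.index(n)
            parent.children[idx] = only
            only.parent = parent
    return node


@dataclass
class PhyloTree:
    """Unrooted tree (stored with an arbitrary or outgroup root)."""

    root: TreeNode
    negative_branches_clamped: bool = False
    outgroup: Optional[str] = None

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self) -> str:
        return self.root.newick()

    def rooted_at_outgroup(self, outgroup: str) -> "PhyloTree":
        """Root on the outgroup's pendant branch (split at its midpoint)."""
        tree = _parse_newick(self.newick())  # private copy
        leaf = tree.find(outgroup)
        half = leaf.length / 2.0
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot root a single-leaf tree")
        parent.children.remove(leaf)
        new_root = TreeNode()
        rest = _invert_to(parent)
        new_root.add(leaf, half)
        new_root.add(rest, half)
        return PhyloTree(new_root, self.negative_branches_clamped, outgroup)

    def rooted_at_midpoint(self) -> "PhyloTree":
        """Root at the midpoint of the longest leaf-to-leaf path."""
        tree = _parse_newick(self.newick())  # private copy
        leaves = tree.leaves()

        def depth(n: TreeNode) -> float:
            d = 0.0
            while n.parent is not None:
                d += n.length
                n = n.parent
            return d

        def path(u: TreeNode, v: TreeNode) -> list[TreeNode]:
            """Node sequence from u to v through their common ancestor."""
            lca = _lca(u, v)
            up = []
            n = u
            while n is not lca:
                up.append(n)
                n = n.parent
            up.append(lca)
            down = []
            n = v
            while n is not lca:
                down.append(n)
                n = n.parent
            return up + list(reversed(down))

        best = (0.0, None, None)
        for i, u in enumerate(leaves):
            for v in leaves[i + 1:]:
                dist = depth(u) + depth(v) - 2 * depth(_lca(u, v))
                if dist > best[0]:
                    best = (dist, u, v)
        D, u, v = best
        if u is None or D <= 0:
            return PhyloTree(tree, self.negative_branches_clamped)
        # walk u -> v, splitting the edge on which the midpoint falls
        p = path(u, v)
        acc = 0.0
        for a, b in zip(p, p[1:]):
            rootward = b is a.parent  # walking up toward the ancestor
            child = a if rootward else b
            edge_len = child.length
            if acc + edge_len >= D / 2 - 1e-12:
                remain = D / 2 - acc  # distance from node a into this edge
                # distance from the child end of the edge to the split point
                from_child = remain if rootward else edge_len - remain
                split = TreeNode()
                par = child.parent
                par.children.remove(child)
                split.parent = par
                split.length = edge_len - from_child
                par.children.append(split)
                split.add(child, from_child)
                return PhyloTree(_invert_to(split), self.negative_branches_clamped)
            acc += edge_len
        return PhyloTree(tree, self.negative_branches_clamped)


def _lca(u: TreeNode, v: TreeNode) -> TreeNode:
    anc = set()
    n = u
    while n is not None:
        anc.add(id(n))
        n = n.parent
    n = v
    while id(n) not in anc:
        n = n.parent
    return n


def _parse_newick(text: str) -> TreeNode:
    """Parse the subset of newick this package writes."""
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                child = parse_node()
                node.children.append(child)
                child.parent = node
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # name and length
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        token = text[start:pos]
        if ":" in token:
            name, length = token.split(":")
        elif pos < len(text) and text[pos] == ":":
            name, length = token, ""
        else:
            name, length = token, "0"
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            length = text[start:pos]
        node.name = name or None
        node.length = float(length) if length else 0.0
        return node

    return parse_node()


def nj_tree(dm: DistanceMatrix, outgroup: Optional[str] = None) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``
    is joined; ties go to the lexicographically smallest index pair.
    Negative branch-length estimates are clamped to zero and flagged on the
    returned tree.  With an outgroup, the tree is rooted on the outgroup's
    pendant branch.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in dm.taxa:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.d.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best_q = math.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, bi, bj = q, i, j
        li = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = d[bi, bj] - li
        new = TreeNode()
        new.add(nodes[bi], clamp(li))
        new.add(nodes[bj], clamp(lj))
        dnew = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d2
    # resolve the final three lineages around an unrooted "root"
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    root.add(nodes[0], clamp(la))
    root.add(nodes[1], clamp(lb))
    root.add(nodes[2], clamp(lc))
    tree = PhyloTree(root, negative_branches_clamped=clamped)
    if outgroup is not None:
        rooted = tree.rooted_at_outgroup(outgroup)
        rooted.negative_branches_clamped = clamped
        return rooted
    return tree


# ---------------------------------------------------------------------------
# Progressive MSA


def progressive_msa(seqs: Sequence[ProteinSequence],
                    params: Optional[AlignmentParams] = None
                    ) -> MultipleAlignment:
    """Progressive multiple alignment along a neighbor-joining guide tree.

    The guide tree is built from full-length pairwise identity distances and
    midpoint-rooted; profiles are merged bottom-up.  Rows are returned in
    the input order.
    """
    params = params or AlignmentParams()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 2:
        aln, _ = pairwise_align(seqs[0], seqs[1], params)
        return aln
    dm = build_distance_matrix(seqs, params)
    guide = nj_tree(dm).rooted_at_midpoint()
    by_id = {s.id: s for s in seqs}

    def build(node: TreeNode) -> _Profile:
        if node.is_leaf():
            return _Profile([node.name], [by_id[node.name].residues])
        prof = build(node.children[0])
        for child in node.children[1:]:
            prof, _ = _align_profiles(prof, build(child), params)
        return prof

    prof = build(guide.root)
    by_row = dict(zip(prof.ids, prof.rows))
    return MultipleAlignment([(i, by_row[i]) for i in ids])
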