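"""Tree building and species-discrimination assessment.

Distance trees use Saitou–Nei neighbor joining (exact on additive
matrices); likelihood trees use the K80 substitution model — the
likelihood counterpart of the K2P distance — with Felsenstein pruning,
per-branch bounded optimization, kappa estimation and NNI hill climbing.
Column-resampling bootstrap maps percentage supports onto the internal
edges of the point-estimate tree.  Rooting is on the designated outgroup,
and a species is monophyletic when its samples form a complete clade of
the rooted tree.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .distances import DistanceMatrix, encode_alignment, k2p_distance
from .seqio import Alignment, IUPAC_AMBIGUITY, SequenceError

__all__ = [
    "Node",
    "Tree",
    "neighbor_joining",
    "k80_loglik",
    "k80_transition_matrix",
    "ml_search",
    "bootstrap_support",
    "root_on_outgroup",
    "root_and_monophyly",
    "monophyly",
    "write_newick",
    "read_newick",
]

BRANCH_MIN = 0.0
BRANCH_MAX = 10.0
BRANCH_TOL = 1e-6
KAPPA_INIT = 2.0
KAPPA_BOUNDS = (0.02, 100.0)


class Node:
    """A tree node; the tree is a rooted data structure even when the
    topology it represents is unrooted (trifurcating root)."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())


@dataclass
class Tree:
    root: Node

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def copy(self) -> "Tree":
        return read_newick(write_newick(self))

    def edges(self) -> list[Node]:
        """Every non-root node stands for the edge to its parent."""
        return [n for n in self.root.walk() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        return [n for n in self.edges() if not n.is_leaf]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each normalized to the side not containing
        a fixed reference leaf, so rootings compare equal."""
        all_leaves = self.leaf_names
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.internal_edges():
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(side))
        return out

    def clades(self) -> set[frozenset[str]]:
        return {n.leaf_names() for n in self.root.walk() if not n.is_leaf}


# ---------------------------------------------------------------------------
# Newick I/O


_UNQUOTED_FORBIDDEN = re.compile(r"[\s(),:;'\[\]]")


def _format_label(name: str) -> str:
    if name == "" or _UNQUOTED_FORBIDDEN.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _node_newick(node: Node) -> str:
    if node.is_leaf:
        text = _format_label(node.name or "")
    else:
        inner = ",".join(_node_newick(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = f"{node.support:g}"
        elif node.name:
            label = _format_label(node.name)
        text = f"({inner}){label}"
    if node.length is not None:
        text += f":{node.length:.10g}"
    return text


def write_newick(tree: Tree) -> str:
    """Newick string with branch lengths; bootstrap supports appear as
    internal-node labels."""
    return _node_newick(tree.root) + ";"


def read_newick(text: str) -> Tree:
    """Parse Newick (quoted labels supported; numeric internal labels are
    interpreted as bootstrap supports)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while True:
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(text[pos])
                pos += 1
            return "".join(out)
        m = re.match(r"[^\s(),:;\[\]]*", text[pos:])
        pos += m.end()
        return m.group()

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            node.name = parse_label()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", text[pos:])
            node.length = float(m.group())
            pos += m.end()
        return node

    root = parse_node()
    if text[pos] != ";":
        raise ValueError(f"trailing characters at {pos}: {text[pos:]!r}")
    return Tree(root)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei NJ; deterministic (Q ties break to the lexicographically
    smallest pair of subtree keys); negative branch lengths clamp to 0."""
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if not matrix.defined.all():
        raise ValueError(
            "distance matrix has undefined pairs; impute or drop those rows"
        )
    D = matrix.values.copy()
    nodes = [Node(name=label) for label in matrix.labels]
    # tie-break key: smallest leaf label within the subtree
    keys = list(matrix.labels)
    active = list(range(n))
    store_cols = D.shape[0]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        u, v = active[i], active[j]
        duv = sub[i, j]
        lu = 0.5 * duv + (r[i] - r[j]) / (2.0 * (m - 2))
        lv = duv - lu
        new = Node()
        nu, nv = nodes[u], nodes[v]
        nu.length = max(lu, BRANCH_MIN)
        nv.length = max(lv, BRANCH_MIN)
        new.add(nu)
        new.add(nv)
        # distances from the new node to the remaining taxa
        new_d = np.zeros(store_cols + 1)
        rest = [a for a in active if a not in (u, v)]
        for a in rest:
            new_d[a] = 0.5 * (D[u, a] + D[v, a] - duv)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[store_cols, : store_cols + 1] = new_d
        D[: store_cols + 1, store_cols] = new_d
        nodes.append(new)
        keys.append(min(keys[u], keys[v]))
        active = rest + [store_cols]
        store_cols += 1

    a, b, c = active
    root = Node()
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, BRANCH_MIN)
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# K80 likelihood


def k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """Exact K80 transition probabilities, branch length in expected
    substitutions/site, base order A, C, G, T."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    e1 = math.exp(-4.0 * t / (kappa + 2.0))
    e2 = math.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    # transitions: A<->G (0,2) and C<->T (1,3)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


_LEAF_PARTIALS = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "-": (1.0, 1.0, 1.0, 1.0),
}
for _code, _bases in IUPAC_AMBIGUITY.items():
    _LEAF_PARTIALS[_code] = tuple(
        1.0 if b in _bases else 0.0 for b in "ACGT"
    )


def leaf_partials(alignment: Alignment) -> dict[str, np.ndarray]:
    """Per-row (4, L) conditional likelihood arrays; gaps and ambiguity are
    missing data (uniform over their base sets)."""
    out = {}
    for rec in alignment.records:
        arr = np.array([_LEAF_PARTIALS[c] for c in rec.seq]).T
        out[rec.id] = np.ascontiguousarray(arr)
    return out


def k80_loglik(
    tree: Tree,
    alignment: Alignment,
    kappa: float,
    partials: Mapping[str, np.ndarray] | None = None,
    column_weights: np.ndarray | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood under K80 (equal base frequencies).

    ``column_weights`` supports bootstrap resampling without copying the
    alignment.  Per-node rescaling keeps the computation finite on deep
    trees.
    """
    names = {n.name for n in tree.root.leaves()}
    if names != set(alignment.ids):
        raise SequenceError("tree leaves do not match alignment rows")
    if partials is None:
        partials = leaf_partials(alignment)
    L = alignment.length

    def post(node: Node) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            return partials[node.name], np.zeros(L)
        cl = np.ones((4, L))
        log_scale = np.zeros(L)
        for child in node.children:
            child_cl, child_scale = post(child)
            t = child.length if child.length is not None else 0.0
            P = k80_transition_matrix(max(t, 0.0), kappa)
            cl = cl * (P @ child_cl)
            log_scale += child_scale
        peak = cl.max(axis=0)
        peak[peak == 0.0] = 1.0
        cl = cl / peak
        log_scale += np.log(peak)
        return cl, log_scale

    root_cl, log_scale = post(tree.root)
    site_lik = 0.25 * root_cl.sum(axis=0)
    if np.any(site_lik <= 0.0):
        bad = int(np.argmax(site_lik <= 0.0)) + 1
        raise FloatingPointError(f"non-finite site likelihood at column {bad}")
    site_logs = np.log(site_lik) + log_scale
    if column_weights is not None:
        return float(np.dot(column_weights, site_logs))
    return float(site_logs.sum())


# ---------------------------------------------------------------------------
# ML search (branch lengths + kappa + NNI)


@dataclass
class MLResult:
    tree: Tree
    kappa: float
    loglik: float
    n_nni_accepted: int = 0


def _optimize_branches(
    tree: Tree, alignment: Alignment, kappa: float, partials
) -> float:
    ll = k80_loglik(tree, alignment, kappa, partials)
    for edge in tree.edges():
        t0 = edge.length

        def negll(t: float) -> float:
            edge.length = t
            return -k80_loglik(tree, alignment, kappa, partials)

        res = minimize_scalar(
            negll,
            bounds=(BRANCH_MIN, BRANCH_MAX),
            method="bounded",
            options={"xatol": BRANCH_TOL},
        )
        if -res.fun >= ll:
            edge.length = float(res.x)
            ll = -res.fun
        else:  # optimizer failed to improve: restore the previous value
            edge.length = t0
            ll = k80_loglik(tree, alignment, kappa, partials)
    return ll


def _optimize_kappa(tree: Tree, alignment: Alignment, kappa: float, partials):
    def negll(k: float) -> float:
        return -k80_loglik(tree, alignment, k, partials)

    res = minimize_scalar(
        negll, bounds=KAPPA_BOUNDS, method="bounded", options={"xatol": 1e-5}
    )
    if -res.fun > -negll(kappa):
        return float(res.x), -res.fun
    return kappa, -negll(kappa)


def _nni_neighbors(tree: Tree) -> list[Tree]:
    """All trees one NNI move away (around each internal edge)."""
    out = []
    # operate on fresh copies so the input tree is never mutated
    n_internal = len(tree.internal_edges())
    for idx in range(n_internal):
        for variant in (0, 1):
            t = tree.copy()
            edge = t.internal_edges()[idx]
            parent = edge.parent
            # a: a sibling subtree of `edge` on the parent side
            siblings = [c for c in parent.children if c is not edge]
            if not siblings:
                continue
            a = siblings[0]
            b = edge.children[variant]
            # swap a and b
            parent.children[parent.children.index(a)] = b
            edge.children[edge.children.index(b)] = a
            a.parent, b.parent = edge, parent
            out.append(t)
    return out


def ml_search(
    alignment: Alignment,
    start: Tree | None = None,
    kappa: float = KAPPA_INIT,
    optimize_kappa: bool = True,
    max_rounds: int = 20,
) -> MLResult:
    """Hill-climbing ML tree search under K80.

    Alternates per-branch bounded length optimization, kappa optimization
    and an NNI sweep accepting strict improvements; terminates at an
    NNI-local optimum.  Deterministic given the start tree (default: NJ on
    the K2P matrix).
    """
    if start is None:
        from .distances import pairwise_matrix

        start = neighbor_joining(pairwise_matrix(alignment))
    partials = leaf_partials(alignment)
    tree = start.copy()
    for edge in tree.edges():
        if edge.length is None or edge.length < BRANCH_MIN:
            edge.length = max(edge.length or 0.01, BRANCH_MIN)
        edge.length = min(edge.length, BRANCH_MAX)
    ll = _optimize_branches(tree, alignment, kappa, partials)
    if optimize_kappa:
        kappa, ll = _optimize_kappa(tree, alignment, kappa, partials)
        ll = _optimize_branches(tree, alignment, kappa, partials)
    n_accepted = 0
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbors(tree):
            cand_ll = _optimize_branches(cand, alignment, kappa, partials)
            if cand_ll > ll + 1e-8:
                tree, ll = cand, cand_ll
                improved = True
                n_accepted += 1
                break  # restart the sweep from the improved tree
        if not improved:
            break
        if optimize_kappa:
            kappa, ll = _optimize_kappa(tree, alignment, kappa, partials)
    return MLResult(tree=tree, kappa=kappa, loglik=ll, n_nni_accepted=n_accepted)


# ---------------------------------------------------------------------------
# Bootstrap


def _fast_k2p_builder(alignment: Alignment):
    """Precompute per-pair per-column transition/transversion indicators so
    replicate distance matrices are column-count dot products."""
    codes = encode_alignment(alignment)
    n, L = codes.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = codes[[p[0] for p in pairs]]
    B = codes[[p[1] for p in pairs]]
    valid = (A >= 0) & (B >= 0)
    purine_a = (A == 0) | (A == 2)
    purine_b = (B == 0) | (B == 2)
    diff = (A != B) & valid
    ts = diff & (purine_a == purine_b)
    tv = diff & (purine_a != purine_b)
    labels = list(alignment.ids)

    def build(counts_cols: np.ndarray | None) -> DistanceMatrix | None:
        if counts_cols is None:
            w = np.ones(L)
        else:
            w = counts_cols
        Lv = valid @ w
        nts = ts @ w
        ntv = tv @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(Lv > 0, nts / Lv, 0.0)
            Q = np.where(Lv > 0, ntv / Lv, 0.0)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            ok = (Lv > 0) & (w1 > 0) & (w2 > 0)
            d = np.where(ok, -0.5 * np.log(np.where(ok, w1 * np.sqrt(np.abs(w2)), 1.0)), np.nan)
        values = np.zeros((n, n))
        defined = np.ones((n, n), dtype=bool)
        for k, (i, j) in enumerate(pairs):
            values[i, j] = values[j, i] = d[k]
            defined[i, j] = defined[j, i] = bool(ok[k])
        if not defined.all():
            return None
        return DistanceMatrix(labels, values, defined)

    return build


@dataclass
class BootstrapResult:
    tree: Tree  # point-estimate tree with supports on internal edges
    n_replicates: int
    n_dropped: int


def bootstrap_support(
    alignment: Alignment,
    builder: Literal["nj", "ml"] = "nj",
    reps: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Column-resampling bootstrap.

    Support on each internal edge of the point-estimate tree is the
    percentage of replicates whose tree contains the same bipartition.
    Replicate r draws from the stream ``default_rng([seed, r])`` so the
    replicate set is reproducible regardless of execution order.
    Replicates with undefined distances are dropped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    L = alignment.length
    build_dm = _fast_k2p_builder(alignment)

    def make_tree(weights: np.ndarray | None) -> Tree | None:
        dm = build_dm(weights)
        if dm is None:
            return None
        tree = neighbor_joining(dm)
        if builder == "ml":
            aln = alignment  # ML refines the NJ replicate topology
            res = ml_search(aln, start=tree) if weights is None else ml_search(
                aln, start=tree, max_rounds=5
            )
            return res.tree
        return tree

    if builder == "ml":
        # the point estimate uses the full search; replicates resample
        # columns explicitly because the likelihood needs column weights
        point = ml_search(alignment).tree
    else:
        point = make_tree(None)
        if point is None:
            raise ValueError("point-estimate distances undefined")

    target = {bp: 0 for bp in point.bipartitions()}
    n_dropped = 0
    n_done = 0
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, L, size=L)
        weights = np.bincount(idx, minlength=L).astype(float)
        if builder == "nj":
            rep_tree = make_tree(weights)
            if rep_tree is None:
                n_dropped += 1
                continue
        else:
            rep_tree = _ml_replicate(alignment, weights, point)
        n_done += 1
        for bp in rep_tree.bipartitions():
            if bp in target:
                target[bp] += 1

    denom = max(n_done, 1)
    supported = point.copy()
    all_leaves = supported.leaf_names
    ref = min(all_leaves)
    for node in supported.internal_edges():
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            node.support = 100.0 * target[frozenset(side)] / denom
    return BootstrapResult(tree=supported, n_replicates=n_done, n_dropped=n_dropped)


def _ml_replicate(alignment: Alignment, weights: np.ndarray, start: Tree) -> Tree:
    """One ML bootstrap replicate: NJ start on resampled distances when
    defined, else the point tree; branch lengths refit with weights."""
    build_dm = _fast_k2p_builder(alignment)
    dm = build_dm(weights)
    tree = neighbor_joining(dm) if dm is not None else start.copy()
    partials = leaf_partials(alignment)
    kappa = KAPPA_INIT
    tree = tree.copy()
    for edge in tree.edges():
        if edge.length is None:
            edge.length = 0.01
        edge.length = min(max(edge.length, BRANCH_MIN), BRANCH_MAX)

    def ll_of(t: Tree) -> float:
        return k80_loglik(t, alignment, kappa, partials, column_weights=weights)

    ll = ll_of(tree)
    for edge in tree.edges():
        def negll(x: float) -> float:
            edge.length = x
            return -ll_of(tree)

        res = minimize_scalar(
            negll, bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
            options={"xatol": 1e-4},
        )
        edge.length = float(res.x)
    return tree


# ---------------------------------------------------------------------------
# Rooting and monophyly


def root_on_outgroup(tree: Tree, outgroup_leaves: Sequence[str]) -> Tree:
    """Root on the edge separating the outgroup from the ingroup.

    With a single outgroup leaf the root bisects its terminal edge; with
    several, the outgroup must already form one side of a bipartition.
    """
    og = set(outgroup_leaves)
    if not og:
        raise ValueError("no outgroup leaves given")
    missing = og - set(tree.leaf_names)
    if missing:
        raise ValueError(f"outgroup leaves absent from tree: {sorted(missing)}")
    work = tree.copy()
    target = None
    for node in work.edges():
        if node.leaf_names() == og:
            target = node
            break
        if work.root.leaf_names() - node.leaf_names() == og:
            target = node  # outgroup is the complement side
            break
    if target is None:
        raise ValueError("outgroup does not form one side of any edge")
    return _reroot_on_edge(work, target)


def _reroot_on_edge(tree: Tree, node: Node) -> Tree:
    """Place a degree-2 root in the middle of the edge above ``node``."""
    half = (node.length or 0.0) / 2.0
    new_root = Node()
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    node.length = half
    new_root.add(node)
    # reverse all edges from old parent chain up to the old root
    prev = new_root
    prev_len = half
    cur = parent
    while cur is not None:
        nxt = cur.parent
        if nxt is not None:
            nxt.children.remove(cur)
        cur.parent = None
        carried = cur.length
        cur.length = prev_len
        prev.add(cur)
        prev = cur
        prev_len = carried
        cur = nxt
    # the old root may now have a single child; splice it out
    _suppress_unifurcations(new_root)
    return Tree(new_root)


def _suppress_unifurcations(root: Node) -> None:
    for node in list(root.walk()):
        while len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
            node.children = []
            node = child
    # root itself
    while len(root.children) == 1 and root.children[0].children:
        only = root.children[0]
        root.children = only.children
        for c in root.children:
            c.parent = root


def monophyly(
    rooted: Tree, species_of: Mapping[str, str], ingroup: Sequence[str] | None = None
) -> dict[str, bool]:
    """Species -> is its leaf set exactly some clade of the rooted tree?
    Single-leaf species are monophyletic by definition."""
    leaves_by_species: dict[str, set[str]] = {}
    for leaf in rooted.leaf_names:
        if leaf not in species_of:
            raise KeyError(f"no species for leaf {leaf!r}")
        leaves_by_species.setdefault(species_of[leaf], set()).add(leaf)
    clades = rooted.clades()
    species = list(ingroup) if ingroup is not None else sorted(leaves_by_species)
    out = {}
    for sp in species:
        members = frozenset(leaves_by_species.get(sp, ()))
        if not members:
            raise KeyError(f"species {sp!r} has no leaves in the tree")
        out[sp] = len(members) == 1 or members in clades
    return out


def root_and_monophyly(
    tree: Tree, species_of: Mapping[str, str], outgroup_species: str
) -> tuple[Tree, dict[str, bool]]:
    """Root on the outgroup species and assess ingroup species monophyly."""
    og_leaves = [l for l in tree.leaf_names if species_of.get(l) == outgroup_species]
    if not og_leaves:
        raise ValueError(f"outgroup species {outgroup_species!r} not in tree")
    rooted = root_on_outgroup(tree, og_leaves)
    ingroup = sorted(
        {sp for l, sp in species_of.items() if sp != outgroup_species
         and l in tree.leaf_names}
    )
    return rooted, monophyly(rooted, species_of, ingroup)
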