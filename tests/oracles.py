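"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or
a literal transcription of a decision rule, sharing no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# unrooted tree topologies (adjacency-dict representation)


def enumerate_unrooted_topologies(leaves: Sequence[str]):
    """Yield every unrooted binary topology over the leaves (n <= 7 sane)."""
    leaves = list(leaves)
    assert len(leaves) >= 3
    base: dict = {-1: {leaves[0], leaves[1], leaves[2]}}
    for lf in leaves[:3]:
        base[lf] = {-1}
    trees = [base]
    next_internal = -2
    for lf in leaves[3:]:
        grown = []
        for tree in trees:
            for u, v in _edges(tree):
                t = {k: set(vs) for k, vs in tree.items()}
                w = next_internal
                t[u].discard(v)
                t[v].discard(u)
                t[w] = {u, v, lf}
                t[u].add(w)
                t[v].add(w)
                t[lf] = {w}
                grown.append(t)
        trees = grown
        next_internal -= 1
    return trees


def _edges(tree: dict) -> list[tuple]:
    seen = set()
    out = []
    for u, vs in tree.items():
        for v in vs:
            key = frozenset({u, v})
            if key not in seen:
                seen.add(key)
                out.append((u, v))
    return out


def topology_bipartitions(tree: dict, leaves: Sequence[str]) -> set[frozenset]:
    """Canonical nontrivial bipartition sides (side without min leaf)."""
    ref = min(leaves)
    n = len(leaves)
    out = set()
    for u, v in _edges(tree):
        side = _side_leaves(tree, u, v)
        if len(side) < 2 or len(side) > n - 2:
            continue
        if ref in side:
            side = frozenset(leaves) - side
        out.add(frozenset(side))
    return out


def _side_leaves(tree: dict, u, v) -> frozenset:
    """Leaves reachable from v when the u-v edge is cut."""
    stack, seen = [v], {u, v}
    found = set()
    while stack:
        node = stack.pop()
        if isinstance(node, str):
            found.add(node)
        for nb in tree[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return frozenset(found)


def tree_path_distances(tree: dict, lengths: dict, leaves: Sequence[str]) -> np.ndarray:
    """Exact leaf-to-leaf path-length matrix for given edge lengths."""
    n = len(leaves)
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            for nb in tree[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + lengths[frozenset({node, nb})]
                    stack.append(nb)
        for j, b in enumerate(leaves):
            D[i, j] = dist[b]
    return D


def best_topology_by_least_squares(
    D: np.ndarray, leaves: Sequence[str]
) -> set[frozenset]:
    """Exhaustive search: topology with the least-squares best fit to D."""
    best_rss, best_bips = None, None
    for tree in enumerate_unrooted_topologies(leaves):
        edges = _edges(tree)
        pos = {frozenset(e): k for k, e in enumerate(edges)}
        rows, targets = [], []
        for i, j in itertools.combinations(range(len(leaves)), 2):
            path = _path_edges(tree, leaves[i], leaves[j])
            row = np.zeros(len(edges))
            for e in path:
                row[pos[e]] = 1.0
            rows.append(row)
            targets.append(D[i, j])
        A = np.array(rows)
        b = np.array(targets)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        rss = float(((A @ x - b) ** 2).sum())
        if best_rss is None or rss < best_rss - 1e-12:
            best_rss, best_bips = rss, topology_bipartitions(tree, leaves)
    return best_bips


def _path_edges(tree: dict, a, b) -> list[frozenset]:
    prev = {a: None}
    stack = [a]
    while stack:
        node = stack.pop()
        if node == b:
            break
        for nb in tree[node]:
            if nb not in prev:
                prev[nb] = node
                stack.append(nb)
    path = []
    node = b
    while prev[node] is not None:
        path.append(frozenset({node, prev[node]}))
        node = prev[node]
    return path


# ---------------------------------------------------------------------------
# literal transcription of the >=95% / dominance assignment rule


def oracle_assign(
    identities: Sequence[float | None],
    species: Sequence[str],
    recorded: str,
    threshold: float,
) -> str:
    """Apply the identification rule exactly as stated, at one rank."""
    pairs = [(v, s) for v, s in zip(identities, species) if v is not None]
    if not pairs:
        return "unscorable"
    own = [v for v, s in pairs if s == recorded]
    if not own:
        return "none"
    if max(own) < threshold:
        return "no_assignment"
    top = max(v for v, _ in pairs)
    top_species = {s for v, s in pairs if v == top}
    if len(top_species) > 1:
        return "incorrect"
    best = top_species.pop()
    best_vals = [v for v, s in pairs if s == best]
    other_vals = [v for v, s in pairs if s != best]
    dominated = not other_vals or min(best_vals) > max(other_vals)
    if dominated and best == recorded:
        return "correct"
    return "incorrect"


def oracle_identity_aligned(q: str, s: str) -> float | None:
    scored = matches = 0
    for a, b in zip(q, s):
        if a in "ACGT" and b in "ACGT":
            scored += 1
            matches += a == b
    return matches / scored if scored else None


# ---------------------------------------------------------------------------
# clade-enumeration oracle for conflict flagging


def newick_adjacency(newick: str) -> dict:
    """Parse a (possibly nested) newick string into an adjacency dict."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    adj: dict = {}
    ids = {}

    def key(node):
        if node.is_leaf():
            return node.taxon.label
        if node not in ids:
            ids[node] = -(len(ids) + 1)
        return ids[node]

    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            a, b = key(node), key(child)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return adj


def oracle_clades(adj: dict, leaves: Sequence[str]) -> list[frozenset]:
    """All leaf subsets that are one side of some edge (cut crosses one edge)."""
    edges = _edges(adj)
    clades = set()
    for u, v in edges:
        for side in (_side_leaves(adj, u, v), _side_leaves(adj, v, u)):
            clades.add(frozenset(side))
    return sorted(clades, key=lambda s: (len(s), tuple(sorted(s))))


def oracle_flags(
    newick: str,
    records: dict,
    min_support: float = 50.0,
    supports: dict | None = None,
) -> dict[str, tuple[str, str, str]]:
    """Leaf -> neighborhood (species, genus, family) for flagged leaves.

    Literal rule: smallest clade with >=2 leaves containing the leaf has
    no conspecific; the support gate takes the best-supported internal
    edge separating the leaf from all conspecifics (enclosing-clade edge
    for singletons); singleton species are not flagged for species-level
    disagreement.
    """
    from collections import Counter

    adj = newick_adjacency(newick)
    leaves = sorted(k for k in adj if isinstance(k, str))
    n = len(leaves)
    clades = [c for c in oracle_clades(adj, leaves) if 2 <= len(c) <= n - 1]
    supports = supports or {}
    flagged = {}
    for leaf in leaves:
        rec = records[leaf]
        smallest = next(c for c in clades if leaf in c)
        others = sorted(smallest - {leaf})
        if any(records[o].species == rec.species for o in others):
            continue
        conspecifics = [l for l in leaves if l != leaf and records[l].species == rec.species]
        if conspecifics:
            seps = [
                supports.get(frozenset(c))
                for c in clades
                if len(c) <= n - 2 and leaf in c
                and not any(x in c for x in conspecifics)
            ]
            defined = [s for s in seps if s is not None]
            sup = max(defined) if defined else None
            if sup is not None and sup < min_support:
                continue
        else:
            sup = supports.get(frozenset(smallest))
            if sup is not None and sup < min_support:
                continue

        def majority(vals):
            c = Counter(vals)
            top = max(c.values())
            return sorted(v for v, k in c.items() if k == top)[0]

        hood = (
            majority([records[o].species for o in others]),
            majority([records[o].genus for o in others]),
            majority([records[o].family for o in others]),
        )
        if not conspecifics and hood[1] == rec.genus and hood[2] == rec.family:
            continue
        flagged[leaf] = hood
    return flagged


# ---------------------------------------------------------------------------
# exhaustive free-end-gap alignment oracle


def oracle_free_end(q: str, s: str) -> tuple[float, set[float]]:
    """(best score, identities of all score-optimal alignments).

    Enumerates every global alignment of q and s; terminal-gap columns
    (before the first / after the last both-residue column) score 0,
    interior columns score match +1 / mismatch -1 / gap -2; identity is
    identical pairs over interior columns.  Exponential — short strings only.
    """
    best: dict[str, object] = {"score": None, "idents": set()}

    def score_alignment(cols: list[tuple[str, str]]):
        both = [k for k, (a, b) in enumerate(cols) if a != "-" and b != "-"]
        if not both:
            return 0, None  # zero-overlap alignment: all gaps terminal
        # a gap is free only inside a row's leading or trailing gap run
        spans = []
        for row in (0, 1):
            residues = [k for k, c in enumerate(cols) if c[row] != "-"]
            spans.append((residues[0], residues[-1]))
        sc = 0
        for k, (a, b) in enumerate(cols):
            if a != "-" and b != "-":
                sc += 1 if a == b else -1
            else:
                gap_row = 0 if a == "-" else 1
                lo, hi = spans[gap_row]
                if lo <= k <= hi:
                    sc -= 2
        lo, hi = both[0], both[-1] + 1
        matches = sum(1 for a, b in cols[lo:hi] if a == b and a != "-")
        return sc, matches / (hi - lo)

    def rec(i: int, j: int, cols: list):
        if i == len(q) and j == len(s):
            sc, ident = score_alignment(cols)
            if best["score"] is None or sc > best["score"]:
                best["score"], best["idents"] = sc, {ident}
            elif sc == best["score"]:
                best["idents"].add(ident)
            return
        if i < len(q) and j < len(s):
            rec(i + 1, j + 1, cols + [(q[i], s[j])])
        if i < len(q):
            rec(i + 1, j, cols + [(q[i], "-")])
        if j < len(s):
            rec(i, j + 1, cols + [("-", s[j])])

    rec(0, 0, [])
    return best["score"], best["idents"]
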