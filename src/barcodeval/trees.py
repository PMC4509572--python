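"""Distances, Neighbor-Joining, nonparametric bootstrap and support mapping.

Distances use pairwise deletion: a column counts for a pair only when
both sequences carry a plain base (A/C/G/T) there.  A pair with zero
comparable columns is *undefined* (NaN plus a zero comparable-site
count), never silently 0 — such pairs arise e.g. between families at a
block-diagonal locus and must be resolved by the caller before tree
building.

The NJ agglomeration is the classic Saitou-Nei Q-criterion with
deterministic lexicographic tie-breaking and negative branch lengths
clamped to zero (remainder moved to the sister edge).  Bootstrap
resamples alignment columns with replacement — within each partition
independently when a partition map is given — rebuilds the NJ tree, and
reports for every internal edge of the original tree the percentage of
replicate trees containing the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

from .datamodel import Dataset, LocusAlignment, ValidationError


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with comparable-site bookkeeping."""

    members: list[str]
    values: np.ndarray  # float, NaN where undefined
    comparable_sites: np.ndarray  # int, jointly non-missing columns per pair

    def __post_init__(self) -> None:
        n = len(self.members)
        if self.values.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.members)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.comparable_sites[i, j] == 0 or np.isnan(self.values[i, j]):
                    out.append((self.members[i], self.members[j]))
        return out

    def write_tsv(self, path) -> None:
        from .io import write_tsv

        rows = [
            [self.members[i]] + [f"{v:.6g}" if not np.isnan(v) else "NA" for v in self.values[i]]
            for i in range(self.n)
        ]
        write_tsv(path, [""] + self.members, rows)


def _pair_counts(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(comparable, transitions, transversions) count matrices."""
    return _pair_counts_encoded(aln.encoded())


def _pair_counts_encoded(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    valid = X < 4
    group = X >> 1  # purine 0 / pyrimidine 1 (garbage where invalid)
    n = X.shape[0]
    comparable = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid
        diff = (X[i] != X) & both
        same_group = (group[i] == group) & diff
        comparable[i] = both.sum(axis=1)
        ts[i] = same_group.sum(axis=1)
        tv[i] = (diff & ~same_group).sum(axis=1)
    return comparable, ts, tv


def _p_from_counts(members, comparable, ts, tv) -> DistanceMatrix:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, (ts + tv) / np.maximum(comparable, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(members), d, comparable)


def _k2p_from_counts(members, comparable, ts, tv) -> DistanceMatrix:
    with np.errstate(invalid="ignore", divide="ignore"):
        P = ts / np.maximum(comparable, 1)
        Q = tv / np.maximum(comparable, 1)
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        d = np.where(
            (a > 0) & (b > 0) & (comparable > 0),
            -0.5 * np.log(np.where(a > 0, a, 1.0))
            - 0.25 * np.log(np.where(b > 0, b, 1.0)),
            np.nan,
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(members), d, comparable)


def p_distance(aln: LocusAlignment) -> DistanceMatrix:
    """Proportion of mismatching comparable sites, pairwise deletion."""
    if len(aln.members) < 2:
        raise ValidationError("need at least 2 members")
    comparable, ts, tv = _pair_counts(aln)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, (ts + tv) / np.maximum(comparable, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.members), d, comparable)


def k2p_distance(aln: LocusAlignment) -> DistanceMatrix:
    """Kimura two-parameter distance; saturated pairs are NaN-marked.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the transition
    and transversion proportions over comparable sites.
    """
    if len(aln.members) < 2:
        raise ValidationError("need at least 2 members")
    comparable, ts, tv = _pair_counts(aln)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = ts / np.maximum(comparable, 1)
        Q = tv / np.maximum(comparable, 1)
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        d = np.where(
            (a > 0) & (b > 0) & (comparable > 0),
            -0.5 * np.log(np.where(a > 0, a, 1.0))
            - 0.25 * np.log(np.where(b > 0, b, 1.0)),
            np.nan,
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.members), d, comparable)


DISTANCE_MODELS: dict[str, Callable[[LocusAlignment], DistanceMatrix]] = {
    "p": p_distance,
    "k2p": k2p_distance,
}


# ---------------------------------------------------------------------------
# support trees


class SupportTree:
    """Unrooted tree over sample ids with bootstrap support per bipartition.

    Bipartitions are canonicalised as the frozenset side *not* containing
    the lexicographically smallest leaf, so membership tests are
    independent of rooting and orientation.
    """

    def __init__(self, tree: dendropy.Tree, support: dict[frozenset, float] | None = None):
        self.tree = tree
        self.support: dict[frozenset, float] = support or {}

    @classmethod
    def from_newick(cls, newick: str) -> "SupportTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        st = cls(tree)
        # internal node labels, when numeric, are read as supports
        for node in tree.preorder_internal_node_iter():
            if node.label is not None and node.parent_node is not None:
                try:
                    sup = float(node.label)
                except ValueError:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
                )
                st.support[st.canonical(side)] = sup
        return st

    @property
    def leaves(self) -> list[str]:
        return sorted(
            lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon is not None
        )

    def canonical(self, side: Iterable[str]) -> frozenset:
        side = frozenset(side)
        leaves = self.leaves
        ref = min(leaves)
        if ref in side:
            side = frozenset(leaves) - side
        return side

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical sides of all (by default internal) edges."""
        n = len(self.leaves)
        out: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
            )
            if not include_trivial and (len(side) < 2 or len(side) > n - 2):
                continue
            out.add(self.canonical(side))
        return out

    def has_bipartition(self, side: Iterable[str]) -> bool:
        side = frozenset(side)
        n = len(self.leaves)
        if len(side) in (1, n - 1):  # pendant edges always exist
            return True
        return self.canonical(side) in self.bipartitions()

    def support_for(self, side: Iterable[str]) -> float | None:
        side = frozenset(side)
        n = len(self.leaves)
        if len(side) in (1, n - 1):
            # a trivial bipartition is in every replicate by construction
            return 100.0
        return self.support.get(self.canonical(side))

    def newick(self) -> str:
        """Newick with supports as internal node labels."""
        for node in self.tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
            )
            sup = self.support.get(self.canonical(side))
            node.label = None if sup is None else f"{sup:g}"
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> SupportTree:
    """Saitou-Nei agglomeration; deterministic; supports left unset.

    Ties on the Q criterion are broken toward the pair whose clusters
    carry the lexicographically smallest leaf names.  Negative branch
    lengths are clamped to zero with the remainder moved to the sister
    edge, since downstream use is topology and support only.
    """
    n = D.n
    if n < 3:
        raise ValidationError("need at least 3 members for NJ")
    undef = D.undefined_pairs()
    if undef:
        raise ValidationError(
            f"undefined distances for {len(undef)} pair(s), e.g. {undef[0]}; "
            "resolve via supermatrix or member filtering"
        )
    d = D.values.copy().astype(float)
    # cluster bookkeeping: newick fragment and smallest leaf per cluster
    newicks = [_quote(m) for m in D.members]
    minleaf = list(D.members)
    active = list(range(n))
    next_col = n
    d = np.pad(d, ((0, 2 * n), (0, 2 * n)))

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((minleaf[idx[a]], minleaf[idx[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = idx[a], idx[b]
        dij = d[i, j]
        li = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        ordered = sorted([(minleaf[i], i, li), (minleaf[j], j, lj)])
        parts = ", ".join(f"{newicks[k]}:{lk:.10g}" for _, k, lk in ordered)
        newicks.append(f"({parts})")
        minleaf.append(ordered[0][0])
        u = next_col
        next_col += 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    ordered = sorted([(minleaf[i], i, li), (minleaf[j], j, lj), (minleaf[k], k, lk)])
    parts = ", ".join(f"{newicks[m]}:{lm:.10g}" for _, m, lm in ordered)
    return SupportTree.from_newick(f"({parts});")


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# bootstrap


def _resample_columns(
    length: int,
    partitions: Sequence[tuple[int, int]] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if not partitions:
        return rng.integers(0, length, length)
    cols = []
    for start, end in partitions:
        cols.append(rng.integers(start, end, end - start))
    return np.concatenate(cols)


_FROM_COUNTS = {"p": _p_from_counts, "k2p": _k2p_from_counts}


@dataclass
class BootstrapResult:
    tree: SupportTree
    replicates: int
    redrawn: int  # replicates discarded because a pair became undefined


def bootstrap_support(
    aln: LocusAlignment,
    base_tree: SupportTree,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    partitions: Sequence[tuple[int, int]] | None = None,
    model: str = "k2p",
) -> BootstrapResult:
    """Attach column-resampling bootstrap supports to the base tree's edges."""
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from_counts = _FROM_COUNTS[model]
    X = aln.encoded()
    base_bips = base_tree.bipartitions()
    counts = {bp: 0 for bp in base_bips}
    redrawn = 0
    done = 0
    max_attempts = 100 * replicates
    attempts = 0
    while done < replicates:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                "bootstrap: too many replicates with undefined pairwise distances"
            )
        cols = _resample_columns(aln.length, partitions, rng)
        comparable, ts, tv = _pair_counts_encoded(X[:, cols])
        D = from_counts(aln.members, comparable, ts, tv)
        if D.undefined_pairs():
            redrawn += 1
            continue
        rep_tree = neighbor_joining(D)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
        done += 1
    support = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    return BootstrapResult(
        tree=SupportTree(base_tree.tree, support), replicates=replicates, redrawn=redrawn
    )


def nj_with_support(
    aln: LocusAlignment,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    partitions: Sequence[tuple[int, int]] | None = None,
    model: str = "k2p",
) -> SupportTree:
    """Convenience: NJ tree plus bootstrap supports in one call."""
    base = neighbor_joining(DISTANCE_MODELS[model](aln))
    return bootstrap_support(aln, base, replicates, seed, partitions, model).tree


# ---------------------------------------------------------------------------
# intraspecific variation (single-base differences within species)


@dataclass
class SpeciesVariation:
    species: str
    n_members: int
    n_variable_sites: int
    n_within_plot: int  # variable already inside at least one plot
    n_between_plot_only: int  # variation appears only across plots
    plots: list[str] = field(default_factory=list)


def intraspecific_variation(dataset: Dataset, locus: str) -> list[SpeciesVariation]:
    """Tally per-species variable alignment columns and their plot structure.

    A column is variable for a species when its conspecific sequences
    show >= 2 plain bases there; it is 'within-plot' when some single
    plot already shows >= 2 bases, otherwise 'between-plot only'.
    """
    by_id = dataset.by_id
    out: list[SpeciesVariation] = []
    for block in dataset.iter_blocks(locus):
        X = block.encoded()
        valid = X < 4
        species_members: dict[str, list[int]] = {}
        for i, m in enumerate(block.members):
            species_members.setdefault(by_id[m].species, []).append(i)
        for species in sorted(species_members):
            rows = species_members[species]
            if len(rows) < 2:
                continue
            plots = [by_id[block.members[i]].plot for i in rows]
            sub = X[rows]
            sval = valid[rows]
            n_var = n_within = 0
            for col in range(sub.shape[1]):
                bases = set(sub[sval[:, col], col].tolist())
                if len(bases) < 2:
                    continue
                n_var += 1
                within = False
                for plot in set(plots):
                    sel = [k for k, p in enumerate(plots) if p == plot]
                    pb = set(sub[sel, col][sval[sel, col]].tolist())
                    if len(pb) >= 2:
                        within = True
                        break
                n_within += within
            out.append(
                SpeciesVariation(
                    species=species,
                    n_members=len(rows),
                    n_variable_sites=n_var,
                    n_within_plot=n_within,
                    n_between_plot_only=n_var - n_within,
                    plots=sorted(set(plots)),
                )
            )
    out.sort(key=lambda v: v.species)
    return out
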