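"""Flagging specimens whose tree placement conflicts with their field taxonomy.

This is the algorithmic half of reciprocal illumination: a leaf is
flagged when the smallest clade (bipartition side of the unrooted tree)
containing it and at least one other leaf holds no conspecific, and —
when the species has other sampled members — the edge defining that
clade has bootstrap support at or above ``min_support``.  The flagged
specimen inherits a *neighborhood* taxon, the majority species / genus
/ family among the other leaves of that smallest clade, and the
conflict level is the shallowest rank at which recorded and
neighborhood labels disagree.  Reviewing vouchers and re-extracting DNA
(the second, human, half of the procedure) is out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._util import percent
from .datamodel import SpecimenRecord, UNKNOWN_SPECIES, ValidationError
from .trees import SupportTree

LEVELS = ("family", "genus", "species")


@dataclass(frozen=True)
class ConflictFlag:
    sample_id: str
    recorded_species: str
    recorded_genus: str
    recorded_family: str
    neighborhood_species: str
    neighborhood_genus: str
    neighborhood_family: str
    level: str  # family | genus | species | unknown
    support: float | None  # of the separating edge


def classify_level(
    recorded: tuple[str, str, str], neighborhood: tuple[str, str, str]
) -> str:
    """Shallowest rank of disagreement between two (species, genus, family) triples."""
    r_sp, r_gn, r_fa = recorded
    n_sp, n_gn, n_fa = neighborhood
    if r_sp == UNKNOWN_SPECIES:
        return "unknown"
    if r_fa != n_fa:
        return "family"
    if r_gn != n_gn:
        return "genus"
    return "species"


def _majority(values: list[str]) -> str:
    counts = Counter(values)
    top = max(counts.values())
    return sorted(v for v, c in counts.items() if c == top)[0]


def flag_conflicts(
    tree: SupportTree,
    records: dict[str, SpecimenRecord],
    min_support: float = 50.0,
) -> list[ConflictFlag]:
    """Flag leaves isolated from all conspecifics by a supported edge.

    The support gate uses the best-supported edge separating the leaf
    from every other member of its recorded species: nearly identical
    conspecific sequences resolve arbitrarily, so the edge defining the
    smallest enclosing clade is often weak even when a deeper
    (genus- or family-level) split isolates the leaf decisively.
    Singleton species have no conspecific to be separated from; for
    them the gate falls on the enclosing-clade edge itself, and a
    species-level disagreement is not a conflict (no conspecific
    exists to contradict).  Edges without a recorded support
    (un-bootstrapped trees) satisfy the gate.  In a two-leaf pocket of
    mutually foreign taxa both leaves are flagged — the tree alone
    cannot tell which label is wrong; that is the reviewer's call.
    """
    leaves = tree.leaves
    missing = [lf for lf in leaves if lf not in records]
    if missing:
        raise ValidationError(f"unlabeled leaves: {missing[:5]}")
    species_members: dict[str, list[str]] = {}
    for lf in leaves:
        species_members.setdefault(records[lf].species, []).append(lf)

    # all clades (bipartition sides), smallest first
    sides: list[frozenset] = []
    n = len(leaves)
    all_leaves = frozenset(leaves)
    for bp in tree.bipartitions(include_trivial=True):
        for side in (bp, all_leaves - bp):
            if 2 <= len(side) <= n - 1:
                sides.append(side)
    sides = sorted(set(sides), key=lambda s: (len(s), tuple(sorted(s))))

    flags: list[ConflictFlag] = []
    for leaf in leaves:
        rec = records[leaf]
        enclosing = next((s for s in sides if leaf in s), None)
        if enclosing is None:
            continue
        others = sorted(enclosing - {leaf})
        if any(records[o].species == rec.species for o in others):
            continue
        conspecifics = [m for m in species_members[rec.species] if m != leaf]
        singleton = not conspecifics
        if singleton:
            support = tree.support_for(enclosing)
        else:
            separating = [
                tree.support_for(s)
                for s in sides
                # internal edges only: a pendant edge exists in every
                # replicate and would satisfy the gate vacuously
                if len(s) <= n - 2
                and leaf in s
                and not any(c in s for c in conspecifics)
            ]
            defined = [s for s in separating if s is not None]
            support = max(defined) if defined else None
        if support is not None and support < min_support:
            continue
        neighborhood = (
            _majority([records[o].species for o in others]),
            _majority([records[o].genus for o in others]),
            _majority([records[o].family for o in others]),
        )
        level = classify_level(rec.taxon_triple, neighborhood)
        if singleton and level == "species":
            continue
        flags.append(
            ConflictFlag(
                sample_id=leaf,
                recorded_species=rec.species,
                recorded_genus=rec.genus,
                recorded_family=rec.family,
                neighborhood_species=neighborhood[0],
                neighborhood_genus=neighborhood[1],
                neighborhood_family=neighborhood[2],
                level=level,
                support=support,
            )
        )
    flags.sort(key=lambda f: f.sample_id)
    return flags


@dataclass
class AuditSummary:
    n_audited: int
    n_flagged: int
    level_counts: dict[str, int]
    exclude_unknowns: bool

    @property
    def flag_rate(self) -> float:
        return percent(self.n_flagged, self.n_audited)

    @property
    def level_denominator(self) -> int:
        if self.exclude_unknowns:
            return self.n_flagged - self.level_counts.get("unknown", 0)
        return self.n_flagged

    @property
    def level_shares(self) -> dict[str, float]:
        denom = self.level_denominator
        if denom == 0:
            return {}
        return {
            lvl: percent(c, denom)
            for lvl, c in self.level_counts.items()
            if lvl != "unknown" or not self.exclude_unknowns
        }


def audit_summary(
    flags: list[ConflictFlag], n_audited: int, exclude_unknowns: bool = True
) -> AuditSummary:
    """Overall flag rate and per-level shares.

    ``exclude_unknowns`` drops placeholder-taxonomy flags from the
    level-share denominator (the flag rate itself always counts them).
    """
    if n_audited < 1:
        raise ValidationError("n_audited must be >= 1")
    counts: dict[str, int] = {}
    for f in flags:
        counts[f.level] = counts.get(f.level, 0) + 1
    return AuditSummary(
        n_audited=n_audited,
        n_flagged=len(flags),
        level_counts=counts,
        exclude_unknowns=exclude_unknowns,
    )
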