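"""Supported-monophyly scoring of species/genus/family discrimination.

A taxon sampled with >= 2 sequences is *resolved* when its leaves form
an exclusive clade of the unrooted tree (the bipartition taxon-vs-rest
exists) whose defining edge has bootstrap support at or above the
cutoff (default 50%).  Taxa with a single sampled leaf are excluded
from the denominator.  Genus and family discrimination are scored with
exactly the same criterion, just with leaves labeled at the coarser
rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._util import percent
from .datamodel import ValidationError
from .trees import SupportTree

SUPPORTED = "supported_monophyletic"
UNSUPPORTED = "unsupported_monophyletic"
NON_MONOPHYLETIC = "non_monophyletic"
EXCLUDED = "excluded_singleton"


@dataclass(frozen=True)
class MonophylyStatus:
    taxon: str
    rank: str
    n_leaves: int
    status: str
    support: float | None = None


def monophyly_status(
    tree: SupportTree,
    labels: Mapping[str, str],
    rank: str = "species",
    cutoff: float = 50.0,
) -> list[MonophylyStatus]:
    """Classify every taxon at a rank by supported monophyly on the tree.

    ``labels`` maps each leaf (sample id) to its taxon at the rank.  A
    taxon whose leaves are ALL leaves of the tree has no separating edge;
    it is monophyletic with the support requirement treated as satisfied.
    Edges without a recorded support (un-bootstrapped trees) also count
    as satisfied, so plain topology tests work on hand-built trees.
    """
    leaves = tree.leaves
    unlabeled = [lf for lf in leaves if lf not in labels]
    if unlabeled:
        raise ValidationError(f"unlabeled leaves: {unlabeled[:5]}")
    groups: dict[str, set[str]] = {}
    for leaf in leaves:
        groups.setdefault(labels[leaf], set()).add(leaf)
    n = len(leaves)
    out: list[MonophylyStatus] = []
    for taxon in sorted(groups):
        S = groups[taxon]
        if len(S) < 2:
            out.append(MonophylyStatus(taxon, rank, len(S), EXCLUDED))
            continue
        if len(S) == n:
            out.append(MonophylyStatus(taxon, rank, n, SUPPORTED, None))
            continue
        if not tree.has_bipartition(S):
            out.append(MonophylyStatus(taxon, rank, len(S), NON_MONOPHYLETIC))
            continue
        sup = tree.support_for(S)
        if sup is None or sup >= cutoff:
            out.append(MonophylyStatus(taxon, rank, len(S), SUPPORTED, sup))
        else:
            out.append(MonophylyStatus(taxon, rank, len(S), UNSUPPORTED, sup))
    return out


@dataclass(frozen=True)
class ResolutionReport:
    label: str
    rank: str
    eligible: int  # taxa with >= 2 sampled leaves
    supported: int

    @property
    def rate(self) -> float:
        return percent(self.supported, self.eligible)


def resolution_rates(
    statuses: list[MonophylyStatus], rank: str, label: str = ""
) -> ResolutionReport:
    """Share of eligible (>= 2 leaves) taxa that are supported monophyletic."""
    at_rank = [s for s in statuses if s.rank == rank]
    eligible = [s for s in at_rank if s.status != EXCLUDED]
    if not eligible:
        raise ValidationError(f"no eligible taxa at rank {rank!r} (all singletons)")
    supported = sum(s.status == SUPPORTED for s in eligible)
    return ResolutionReport(label=label, rank=rank, eligible=len(eligible), supported=supported)
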