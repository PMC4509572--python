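"""Similarity-based identification under the >=95%-identity/dominance rule.

A query is assigned correctly at species level when (i) it is at least
``threshold`` identical to some sequence of its own (recorded) species
in the database and (ii) *every* database sequence of the best-matching
species is strictly more identical to the query than every sequence of
any other species.  Failing (i) yields no assignment; failing (ii), or
a best-matching species other than the recorded one, is an incorrect
assignment.  Genus-level outcomes apply the same rule at genus
granularity.  Ties between the best conspecific and a heterospecific
break the strict-dominance requirement and score as incorrect.

Identity is the fraction of identical sites over scored columns; for
pre-aligned data the scored columns are those where both sequences
carry a plain base, and multi-locus identities pool matched and scored
sites across the loci shared by query and subject (a scored-site-
weighted average, equal to the identity of the concatenation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from ._util import percent
from .datamodel import Dataset, LocusAlignment, ValidationError

UNSCORABLE = "unscorable"
NO_ASSIGNMENT = "no_assignment"
CORRECT = "correct"
INCORRECT = "incorrect"
VACUOUS = "none"  # query's taxon absent from the database at that rank


# ---------------------------------------------------------------------------
# pairwise identity


@dataclass(frozen=True)
class IdentityScore:
    query_id: str
    subject_id: str
    identity: float | None  # None when unscorable
    scored_sites: int


def _aligned_identity(q: str, s: str) -> tuple[float | None, int]:
    if len(q) != len(s):
        raise ValidationError("aligned mode requires equal-length sequences")
    matches = scored = 0
    for a, b in zip(q, s):
        if a in "ACGT" and b in "ACGT":
            scored += 1
            matches += a == b
    if scored == 0:
        return None, 0
    return matches / scored, scored


def _free_end_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_gap_score = 0
    return aligner


def free_end_alignment_score(q: str, s: str) -> float:
    """Optimal free-end-gap global alignment score (match +1/mm -1/gap -2)."""
    return _free_end_aligner().score(q, s)


def _free_end_identity(q: str, s: str) -> tuple[float | None, int]:
    """Identity of the best free-end-gap global alignment.

    Scored columns run from the first to the last column where both
    sequences carry a residue (terminal gaps excluded); internal gap
    columns count against identity.
    """
    aln = _free_end_aligner().align(q, s)[0]
    a, b = aln[0], aln[1]  # gapped rows of the first optimal alignment
    both = [i for i in range(len(a)) if a[i] != "-" and b[i] != "-"]
    if not both:
        return None, 0
    start, end = both[0], both[-1] + 1
    scored = end - start
    matches = sum(
        1 for i in range(start, end) if a[i] == b[i] and a[i] != "-"
    )
    return matches / scored, scored


def pairwise_identity(
    query: str,
    subject: str,
    mode: str = "aligned",
    query_id: str = "query",
    subject_id: str = "subject",
) -> IdentityScore:
    """Identity between two sequences, pre-aligned or freely aligned."""
    if not query or not subject:
        raise ValidationError("empty sequence")
    if mode == "aligned":
        ident, scored = _aligned_identity(query.upper(), subject.upper())
    elif mode == "free_end_global":
        ident, scored = _free_end_identity(
            query.upper().replace("-", ""), subject.upper().replace("-", "")
        )
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return IdentityScore(query_id, subject_id, ident, scored)


# ---------------------------------------------------------------------------
# the assignment decision rule


@dataclass(frozen=True)
class AssignmentResult:
    query_id: str
    assigned_species: str | None
    assigned_genus: str | None
    outcome: str  # species-level: correct|incorrect|no_assignment|none|unscorable
    genus_outcome: str
    best_identity: float | None

    @property
    def species_outcome(self) -> str:
        return self.outcome


def _species_outcome(
    idents: np.ndarray,
    species: Sequence[str],
    recorded: str,
    threshold: float,
) -> tuple[str, str | None]:
    """Threshold + strict-dominance rule; (outcome, dominant best species)."""
    own = idents[[s == recorded for s in species]]
    top = float(np.max(idents))
    top_species = sorted({s for s, v in zip(species, idents) if v == top})
    best = top_species[0]
    others = idents[[s != best for s in species]]
    dominated = others.size == 0 or float(
        np.min(idents[[s == best for s in species]])
    ) > float(np.max(others))
    assigned = best if dominated and len(top_species) == 1 else None
    if own.size == 0:
        return VACUOUS, assigned
    if float(np.max(own)) < threshold:
        return NO_ASSIGNMENT, assigned
    if assigned is not None and assigned == recorded:
        return CORRECT, assigned
    return INCORRECT, assigned


def assign_from_identities(
    query_id: str,
    identities: Sequence[float | None],
    species: Sequence[str],
    genera: Sequence[str],
    recorded_species: str,
    recorded_genus: str,
    threshold: float = 0.95,
) -> AssignmentResult:
    """Decision rule on precomputed query-vs-database identities.

    The genus outcome is derived from the assigned species: it is
    correct when some congeneric subject reaches the threshold and the
    strictly dominant best species belongs to the recorded genus, so a
    correct species assignment always implies a correct genus one.
    """
    keep = [i for i, v in enumerate(identities) if v is not None]
    if not keep:
        return AssignmentResult(query_id, None, None, UNSCORABLE, UNSCORABLE, None)
    idents = np.array([identities[i] for i in keep], dtype=float)
    sp = [species[i] for i in keep]
    gn = [genera[i] for i in keep]
    sp_outcome, sp_assigned = _species_outcome(idents, sp, recorded_species, threshold)
    genus_of = {s: g for s, g in zip(sp, gn)}
    gn_assigned = genus_of[sp_assigned] if sp_assigned is not None else None
    congeneric = idents[[g == recorded_genus for g in gn]]
    if congeneric.size == 0:
        gn_outcome = VACUOUS
    elif float(np.max(congeneric)) < threshold:
        gn_outcome = NO_ASSIGNMENT
    elif gn_assigned is not None and gn_assigned == recorded_genus:
        gn_outcome = CORRECT
    else:
        gn_outcome = INCORRECT
    return AssignmentResult(
        query_id=query_id,
        assigned_species=sp_assigned,
        assigned_genus=gn_assigned,
        outcome=sp_outcome,
        genus_outcome=gn_outcome,
        best_identity=float(np.max(idents)),
    )


def assign_query(
    query_id: str,
    query_seq: str,
    database: Sequence[tuple[str, str, str, str]],  # (subject_id, seq, species, genus)
    recorded_species: str,
    recorded_genus: str,
    threshold: float = 0.95,
    mode: str = "aligned",
) -> AssignmentResult:
    """Score one query against an explicit database and apply the rule."""
    if not database:
        raise ValidationError("empty database")
    identities = [
        pairwise_identity(query_seq, seq, mode, query_id, sid).identity
        for sid, seq, _, _ in database
    ]
    return assign_from_identities(
        query_id,
        identities,
        [sp for _, _, sp, _ in database],
        [g for _, _, _, g in database],
        recorded_species,
        recorded_genus,
        threshold,
    )


# ---------------------------------------------------------------------------
# dataset-level evaluation


def combined_identity_counts(
    dataset: Dataset, loci: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pooled (matches, scored_sites) matrices over the loci of a combination.

    Members are the union of specimens with at least one constituent
    locus.  Family-block loci contribute within-block pairs only.
    """
    if not loci:
        raise ValidationError("empty combination")
    members: set[str] = set()
    for locus in loci:
        members |= dataset.members(locus)
    order = sorted(members)
    pos = {m: i for i, m in enumerate(order)}
    n = len(order)
    matches = np.zeros((n, n), dtype=np.int64)
    scored = np.zeros((n, n), dtype=np.int64)
    from .trees import _pair_counts

    for locus in loci:
        for block in dataset.iter_blocks(locus):
            comparable, ts, tv = _pair_counts(block)
            idx = np.array([pos[m] for m in block.members])
            matches[np.ix_(idx, idx)] += comparable - ts - tv
            scored[np.ix_(idx, idx)] += comparable
    return order, matches, scored


@dataclass
class EvalReport:
    """Identification success for one locus combination and query design."""

    mode: str  # leave_one_out | cross_plot
    label: str
    species_outcomes: Counter = field(default_factory=Counter)
    genus_outcomes: Counter = field(default_factory=Counter)
    results: list[AssignmentResult] = field(default_factory=list)
    db_plot: str | None = None
    query_plot: str | None = None
    n_shared_species: int | None = None
    n_shared_genera: int | None = None

    @staticmethod
    def _rate(outcomes: Counter) -> float | None:
        denom = outcomes[CORRECT] + outcomes[INCORRECT] + outcomes[NO_ASSIGNMENT]
        if denom == 0:
            return None
        return percent(outcomes[CORRECT], denom)

    @property
    def species_denominator(self) -> int:
        c = self.species_outcomes
        return c[CORRECT] + c[INCORRECT] + c[NO_ASSIGNMENT]

    @property
    def genus_denominator(self) -> int:
        c = self.genus_outcomes
        return c[CORRECT] + c[INCORRECT] + c[NO_ASSIGNMENT]

    @property
    def species_rate(self) -> float | None:
        return self._rate(self.species_outcomes)

    @property
    def genus_rate(self) -> float | None:
        return self._rate(self.genus_outcomes)


def _evaluate(
    dataset: Dataset,
    loci: Sequence[str],
    db_ids: Iterable[str],
    query_ids: Iterable[str],
    threshold: float,
    mode: str,
    label: str,
    species_queries: set[str] | None = None,
    genus_queries: set[str] | None = None,
) -> EvalReport:
    order, matches, scored = combined_identity_counts(dataset, loci)
    pos = {m: i for i, m in enumerate(order)}
    by_id = dataset.by_id
    db = [m for m in order if m in set(db_ids)]
    queries = [m for m in order if m in set(query_ids)]
    if not db:
        raise ValidationError("empty database")
    report = EvalReport(mode=mode, label=label)
    species_of = {m: by_id[m].species for m in db}
    genus_of = {m: by_id[m].genus for m in db}
    for q in queries:
        subjects = [m for m in db if m != q]
        if not subjects:
            continue
        qi = pos[q]
        identities: list[float | None] = []
        for s in subjects:
            si = pos[s]
            identities.append(
                matches[qi, si] / scored[qi, si] if scored[qi, si] > 0 else None
            )
        sp = [species_of[s] for s in subjects]
        gn = [genus_of[s] for s in subjects]
        res = assign_from_identities(
            q, identities, sp, gn, by_id[q].species, by_id[q].genus, threshold
        )
        report.results.append(res)
        if species_queries is None or q in species_queries:
            report.species_outcomes[res.outcome] += 1
        if genus_queries is None or q in genus_queries:
            report.genus_outcomes[res.genus_outcome] += 1
    return report


def evaluate_leave_one_out(
    dataset: Dataset,
    loci: Sequence[str],
    threshold: float = 0.95,
    label: str | None = None,
) -> EvalReport:
    """Every sequenced specimen queried against all the others."""
    order, _, _ = combined_identity_counts(dataset, loci)
    return _evaluate(
        dataset,
        loci,
        db_ids=order,
        query_ids=order,
        threshold=threshold,
        mode="leave_one_out",
        label=label or "+".join(loci),
    )


def evaluate_cross_plot(
    dataset: Dataset,
    db_plot: str,
    query_plots: Sequence[str],
    loci: Sequence[str],
    threshold: float = 0.95,
) -> list[EvalReport]:
    """One plot as the reference database, other plots as queries.

    Queries are filtered to specimens whose recorded species (species-
    level tally) or genus (genus-level tally) is represented in the
    database plot.  Querying the database plot against itself reduces to
    leave-one-out within that plot.
    """
    by_id = dataset.by_id
    plots = {s.plot for s in dataset.specimens}
    for p in [db_plot, *query_plots]:
        if p not in plots:
            raise ValidationError(f"unknown plot label {p!r}")
    order, _, _ = combined_identity_counts(dataset, loci)
    db_ids = [m for m in order if by_id[m].plot == db_plot]
    if not db_ids:
        raise ValidationError(f"no sequenced specimens in database plot {db_plot!r}")
    db_species = {by_id[m].species for m in db_ids}
    db_genera = {by_id[m].genus for m in db_ids}
    reports = []
    for plot in query_plots:
        plot_ids = [m for m in order if by_id[m].plot == plot]
        sp_q = {m for m in plot_ids if by_id[m].species in db_species}
        gn_q = {m for m in plot_ids if by_id[m].genus in db_genera}
        rep = _evaluate(
            dataset,
            loci,
            db_ids=db_ids,
            query_ids=sp_q | gn_q,
            threshold=threshold,
            mode="cross_plot",
            label="+".join(loci),
            species_queries=sp_q,
            genus_queries=gn_q,
        )
        rep.db_plot = db_plot
        rep.query_plot = plot
        rep.n_shared_species = len({by_id[m].species for m in sp_q})
        rep.n_shared_genera = len({by_id[m].genus for m in gn_q})
        reports.append(rep)
    return reports
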