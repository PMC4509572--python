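"""Core containers for specimens, per-locus alignments and recovery statistics.

A dataset couples a specimen metadata table (sample id, species, genus,
family, plot) with one aligned sequence matrix per barcode locus.  A
specimen may be absent from any locus — that models PCR or sequencing
failure — but every sequence must belong to a known specimen, and the
taxonomy must be internally consistent (one genus per species, one family
per genus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ._util import percent

VALID_CHARS = frozenset("ACGTN-")

#: placeholder species label for specimens without a field identification
UNKNOWN_SPECIES = "unknown"

# nucleotide encoding shared by distance and identity code:
# A,G are purines (codes 0,1), C,T pyrimidines (codes 2,3); anything
# else (N, gap) is 255 and never counts as a comparable site.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("AGCT"):
    _CODE[ord(_c)] = _i


class ValidationError(ValueError):
    """Raised when inputs violate a dataset invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed at all."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected individual with its field taxonomy and plot."""

    sample_id: str
    species: str
    genus: str
    family: str
    plot: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample_id")
        if self.species != UNKNOWN_SPECIES:
            first = self.species.split()[0] if self.species.split() else ""
            if first != self.genus:
                raise ValidationError(
                    f"species {self.species!r} does not start with its genus "
                    f"{self.genus!r} (sample {self.sample_id})"
                )

    @property
    def taxon_triple(self) -> tuple[str, str, str]:
        return (self.species, self.genus, self.family)


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus over a subset of specimens.

    Rows are uppercase strings over ``{A,C,G,T,N,-}``, all the same length.
    """

    locus: str
    members: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.rows):
            raise ValidationError(f"{self.locus}: members/rows length mismatch")
        if not self.rows:
            raise ValidationError(f"{self.locus}: empty alignment")
        if len(set(self.members)) != len(self.members):
            dupes = sorted({m for m in self.members if self.members.count(m) > 1})
            raise ValidationError(f"{self.locus}: duplicate members {dupes}")
        length = len(self.rows[0])
        if length < 1:
            raise ValidationError(f"{self.locus}: zero-length alignment")
        for sid, row in zip(self.members, self.rows):
            if len(row) != length:
                raise ValidationError(
                    f"{self.locus}: ragged alignment — row {sid!r} has length "
                    f"{len(row)}, expected {length}"
                )
            bad = set(row) - VALID_CHARS
            if bad:
                raise ValidationError(
                    f"{self.locus}: invalid characters {sorted(bad)} in {sid!r}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, sample_id: str) -> str:
        return self.rows[self.members.index(sample_id)]

    def subset(self, members: Iterable[str]) -> "LocusAlignment":
        keep = [m for m in self.members if m in set(members)]
        idx = {m: i for i, m in enumerate(self.members)}
        return LocusAlignment(self.locus, keep, [self.rows[idx[m]] for m in keep])

    def encoded(self) -> np.ndarray:
        """uint8 matrix: A=0,G=1,C=2,T=3, everything else 255."""
        flat = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return _CODE[flat].reshape(len(self.rows), self.length)


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every non-{A,C,G,T,-} character to N."""
    up = seq.upper()
    return "".join(c if c in "ACGT-" else "N" for c in up)


def check_taxonomy(specimens: Iterable[SpecimenRecord]) -> None:
    """Enforce one genus per species and one family per genus."""
    seen_ids: set[str] = set()
    species_genus: dict[str, str] = {}
    genus_family: dict[str, str] = {}
    for rec in specimens:
        if rec.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen_ids.add(rec.sample_id)
        if rec.species != UNKNOWN_SPECIES:
            prev = species_genus.setdefault(rec.species, rec.genus)
            if prev != rec.genus:
                raise ValidationError(
                    f"species {rec.species!r} mapped to two genera: "
                    f"{prev!r} and {rec.genus!r}"
                )
        prev_f = genus_family.setdefault(rec.genus, rec.family)
        if prev_f != rec.family:
            raise ValidationError(
                f"genus {rec.genus!r} mapped to two families: "
                f"{prev_f!r} and {rec.family!r}"
            )


# a per-locus alignment is either global (one alignment) or split into
# per-family blocks (loci that cannot be globally aligned)
AlignmentOrBlocks = LocusAlignment | Mapping[str, LocusAlignment]


@dataclass
class Dataset:
    """Specimen table plus per-locus alignments."""

    specimens: list[SpecimenRecord]
    alignments: dict[str, AlignmentOrBlocks] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_taxonomy(self.specimens)
        ids = {s.sample_id for s in self.specimens}
        for locus, aln in self.alignments.items():
            for sub in self.iter_blocks(locus):
                extra = set(sub.members) - ids
                if extra:
                    raise ValidationError(
                        f"{locus}: members without a specimen record: {sorted(extra)}"
                    )

    @property
    def loci(self) -> list[str]:
        return list(self.alignments)

    @property
    def by_id(self) -> dict[str, SpecimenRecord]:
        return {s.sample_id: s for s in self.specimens}

    def iter_blocks(self, locus: str) -> list[LocusAlignment]:
        aln = self.alignments[locus]
        if isinstance(aln, LocusAlignment):
            return [aln]
        return list(aln.values())

    def members(self, locus: str) -> set[str]:
        out: set[str] = set()
        for sub in self.iter_blocks(locus):
            out.update(sub.members)
        return out

    def subset(self, sample_ids: Iterable[str]) -> "Dataset":
        keep = set(sample_ids)
        specs = [s for s in self.specimens if s.sample_id in keep]
        alns: dict[str, AlignmentOrBlocks] = {}
        for locus, aln in self.alignments.items():
            if isinstance(aln, LocusAlignment):
                kept = [m for m in aln.members if m in keep]
                if kept:
                    alns[locus] = aln.subset(kept)
            else:
                blocks = {
                    fam: sub.subset([m for m in sub.members if m in keep])
                    for fam, sub in aln.items()
                    if any(m in keep for m in sub.members)
                }
                if blocks:
                    alns[locus] = blocks
        return Dataset(specs, alns)


@dataclass
class RecoveryStats:
    """Per-locus and any-marker sequence recovery."""

    n_specimens: int
    per_locus_count: dict[str, int]
    any_marker_count: int
    denominator: int  # defaults to n_specimens; caller may supply another

    @property
    def per_locus_fraction(self) -> dict[str, float]:
        return {k: v / self.denominator for k, v in self.per_locus_count.items()}

    @property
    def any_marker_fraction(self) -> float:
        return self.any_marker_count / self.denominator

    @property
    def per_locus_percent(self) -> dict[str, float]:
        return {
            k: percent(v, self.denominator) for k, v in self.per_locus_count.items()
        }

    @property
    def any_marker_percent(self) -> float:
        return percent(self.any_marker_count, self.denominator)


def recovery_stats(dataset: Dataset, denominator: int | None = None) -> RecoveryStats:
    """Count specimens recovered per locus and for at least one locus.

    ``denominator`` defaults to the total specimen count; a caller-supplied
    value supports success rates over e.g. PCR-positive samples only, whose
    count is not derivable from sequence data.
    """
    n = len(dataset.specimens)
    if n == 0:
        raise ValidationError("empty dataset")
    per_locus = {locus: len(dataset.members(locus)) for locus in dataset.loci}
    union: set[str] = set()
    for locus in dataset.loci:
        union |= dataset.members(locus)
    return RecoveryStats(
        n_specimens=n,
        per_locus_count=per_locus,
        any_marker_count=len(union),
        denominator=denominator if denominator is not None else n,
    )
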