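"""Concatenation of per-locus alignments into a partitioned supermatrix.

Missing data policy: a specimen absent from a locus is padded with '-'
across that locus's columns, and downstream distance/identity code
treats '-' as missing (pairwise deletion), never as an indel.  Loci that
cannot be aligned across families enter as a block-diagonal alignment:
each family occupies its own disjoint column range, so that locus
carries no cross-family signal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .datamodel import LocusAlignment, SpecimenRecord, ValidationError
from .io import write_json, write_tsv


@dataclass
class BlockAlignment(LocusAlignment):
    """A block-diagonal locus alignment with per-family column ranges."""

    blocks: list[tuple[str, int, int]] = None  # (family, start, end), half-open

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.blocks is None:
            raise ValidationError("BlockAlignment requires a block map")


@dataclass
class Supermatrix:
    """Concatenated multi-locus alignment with a partition map."""

    members: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (label, start, end), half-open

    def __post_init__(self) -> None:
        if len(self.members) != len(self.rows):
            raise ValidationError("members/rows length mismatch")
        length = len(self.rows[0]) if self.rows else 0
        if any(len(r) != length for r in self.rows):
            raise ValidationError("ragged supermatrix")
        pos = 0
        for label, start, end in self.partitions:
            if start != pos or end <= start:
                raise ValidationError(
                    f"partitions do not tile the matrix: {label} at ({start},{end}), "
                    f"expected start {pos}"
                )
            pos = end
        if pos != length:
            raise ValidationError(f"partitions cover {pos} of {length} columns")
        for sid, row in zip(self.members, self.rows):
            if set(row) == {"-"}:
                raise ValidationError(f"{sid}: no data in any partition")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def as_alignment(self, label: str = "supermatrix") -> LocusAlignment:
        return LocusAlignment(label, list(self.members), list(self.rows))

    def partition_ranges(self) -> list[tuple[int, int]]:
        return [(s, e) for _, s, e in self.partitions]

    def write_fasta(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for sid, row in zip(self.members, self.rows):
                fh.write(f">{sid}\n{row}\n")

    def write_partitions(self, path: str | Path) -> None:
        """RAxML-style partition lines, 1-based inclusive coordinates."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for label, start, end in self.partitions:
                fh.write(f"DNA, {label} = {start + 1}-{end}\n")

    def write_partition_json(self, path: str | Path) -> None:
        write_json(
            path,
            [
                {"label": label, "start": start, "end": end}
                for label, start, end in self.partitions
            ],
        )


def concatenate(
    alignments: Mapping[str, LocusAlignment],
    member_policy: str = "union",
) -> Supermatrix:
    """Concatenate loci in the caller's order.

    Under the (default) union policy a member missing a locus is padded
    with '-' across that locus's columns; under intersection only members
    present at every locus are kept.
    """
    if not alignments:
        raise ValidationError("no loci to concatenate")
    if member_policy not in ("union", "intersection"):
        raise ValidationError(f"unknown member_policy {member_policy!r}")

    member_sets = [set(a.members) for a in alignments.values()]
    if member_policy == "union":
        members = sorted(set().union(*member_sets))
    else:
        members = sorted(set.intersection(*member_sets))
        if not members:
            raise ValidationError("empty member set under intersection policy")

    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {m: [] for m in members}
    pos = 0
    for locus, aln in alignments.items():
        if isinstance(aln, BlockAlignment):
            for fam, bstart, bend in aln.blocks:
                parts.append((f"{locus}/{fam}", pos + bstart, pos + bend))
        else:
            parts.append((locus, pos, pos + aln.length))
        idx = {m: i for i, m in enumerate(aln.members)}
        pad = "-" * aln.length
        for m in members:
            chunks[m].append(aln.rows[idx[m]] if m in idx else pad)
        pos += aln.length
    return Supermatrix(members, ["".join(chunks[m]) for m in members], parts)


def concatenate_family_blocks(
    per_family: Mapping[str, LocusAlignment],
    taxonomy: Sequence[SpecimenRecord],
) -> BlockAlignment:
    """Lay per-family alignments out block-diagonally as one locus.

    Each family's columns form a disjoint range; a member's row carries
    its family-block sequence there and '-' everywhere else.  Members of
    two different sampled families share no scored sites at this locus,
    so any pairwise comparison restricted to it is undefined — downstream
    code must flag that, not return 0.
    """
    if not per_family:
        raise ValidationError("no family blocks")
    family_of = {r.sample_id: r.family for r in taxonomy}
    seen: dict[str, str] = {}
    for fam, aln in per_family.items():
        for m in aln.members:
            if m in seen:
                raise ValidationError(f"{m}: assigned to family blocks {seen[m]} and {fam}")
            seen[m] = fam
            if m not in family_of:
                raise ValidationError(f"{m}: no specimen record")
            if family_of[m] != fam:
                raise ValidationError(
                    f"{m}: in block {fam!r} but recorded family is {family_of[m]!r}"
                )

    fams = list(per_family)
    locus = per_family[fams[0]].locus
    total = sum(per_family[f].length for f in fams)
    blocks: list[tuple[str, int, int]] = []
    members: list[str] = []
    rows: list[str] = []
    pos = 0
    for fam in fams:
        aln = per_family[fam]
        blocks.append((fam, pos, pos + aln.length))
        for m, r in zip(aln.members, aln.rows):
            members.append(m)
            rows.append("-" * pos + r + "-" * (total - pos - aln.length))
        pos += aln.length
    return BlockAlignment(locus, members, rows, blocks=blocks)


def write_supermatrix_report(sm: Supermatrix, outdir: str | Path, stem: str) -> None:
    outdir = Path(outdir)
    sm.write_fasta(outdir / f"{stem}.fasta")
    sm.write_partitions(outdir / f"{stem}.partitions.txt")
    sm.write_partition_json(outdir / f"{stem}.partitions.json")
    write_tsv(
        outdir / f"{stem}.partitions.tsv",
        ["label", "start", "end"],
        sm.partitions,
    )
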