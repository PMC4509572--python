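"""Reading and writing the on-disk formats: metadata TSV, aligned FASTA, reports."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

from Bio import SeqIO

from .datamodel import (
    Dataset,
    FormatError,
    LocusAlignment,
    SpecimenRecord,
    ValidationError,
    check_taxonomy,
    normalize_sequence,
)

REQUIRED_COLUMNS = ("sample_id", "species", "genus", "family", "plot")


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a tab-separated specimen metadata table.

    The header must contain sample_id, species, genus, family and plot;
    extra columns are ignored.  Taxonomy consistency (unique sample ids,
    one genus per species, one family per genus) is validated.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        records = [
            SpecimenRecord(
                sample_id=row["sample_id"].strip(),
                species=row["species"].strip(),
                genus=row["genus"].strip(),
                family=row["family"].strip(),
                plot=row["plot"].strip(),
            )
            for row in reader
        ]
    check_taxonomy(records)
    return records


def write_specimen_table(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow([rec.sample_id, rec.species, rec.genus, rec.family, rec.plot])


def read_locus_fasta(path: str | Path, locus: str) -> LocusAlignment:
    """Read one pre-aligned FASTA; record ids are sample ids.

    Sequences are upper-cased and any character outside {A,C,G,T,-}
    (IUPAC ambiguity codes included) collapses to N.  Rows must all have
    the same length — unequal lengths mean the input was not aligned.
    """
    path = Path(path)
    members: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in members:
            raise ValidationError(f"{path}: duplicate id {rec.id!r}")
        members.append(rec.id)
        rows.append(normalize_sequence(str(rec.seq)))
    if not members:
        raise FormatError(f"{path}: no FASTA records")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValidationError(
            f"{path}: ragged alignment (row lengths {sorted(lengths)}); "
            "inputs must be pre-aligned"
        )
    return LocusAlignment(locus, members, rows)


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sid, row in zip(aln.members, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def read_dataset(
    meta_path: str | Path,
    locus_paths: Mapping[str, str | Path | Mapping[str, str | Path]],
) -> Dataset:
    """Assemble a Dataset from a metadata table and per-locus FASTA paths.

    For family-block loci, pass a mapping family -> FASTA path instead of a
    single path.
    """
    specimens = read_specimen_table(meta_path)
    alignments: dict[str, Any] = {}
    for locus, entry in locus_paths.items():
        if isinstance(entry, Mapping):
            alignments[locus] = {
                fam: read_locus_fasta(p, locus) for fam, p in entry.items()
            }
        else:
            alignments[locus] = read_locus_fasta(entry, locus)
    return Dataset(specimens, alignments)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Any]:
    """Write metadata TSV + per-locus FASTA files; return the path layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = outdir / "specimens.tsv"
    write_specimen_table(dataset.specimens, meta)
    layout: dict[str, Any] = {"meta": str(meta), "loci": {}}
    for locus, aln in dataset.alignments.items():
        if isinstance(aln, LocusAlignment):
            p = outdir / f"{locus}.fasta"
            write_locus_fasta(aln, p)
            layout["loci"][locus] = str(p)
        else:
            sub: dict[str, str] = {}
            for fam, block in aln.items():
                p = outdir / f"{locus}.{fam}.fasta"
                write_locus_fasta(block, p)
                sub[fam] = str(p)
            layout["loci"][locus] = sub
    return layout


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable[Any]]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_json(path: str | Path, payload: Any) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
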