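"""Sequence and metadata I/O.

Reads aligned (equal-length) FASTA files together with a specimen metadata
table (specimen_id, species, marker) into an :class:`Alignment`, and writes
Newick trees and CSV reports. Sequences are case-normalized to upper and
validated against the IUPAC nucleotide alphabet (plus ``-`` for gaps);
ambiguity codes are kept in storage and interpreted per analysis stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "SequenceRecord",
    "Alignment",
    "AlignmentLengthError",
    "MetadataError",
    "read_fasta_with_metadata",
    "write_fasta_with_metadata",
    "write_newick",
]

#: Allowed sequence characters: the four bases, IUPAC ambiguity codes, gap.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Species label used for specimens without a binomial assignment.
UNKNOWN_SPECIES = "unknown"


class AlignmentLengthError(ValueError):
    """Raised when records in one alignment have unequal lengths."""


class MetadataError(ValueError):
    """Raised when FASTA identifiers and the metadata table disagree."""


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen's sequence for one marker.

    ``species`` is a binomial or :data:`UNKNOWN_SPECIES`; unknown specimens
    are kept in trees and clustering but excluded from species-wise
    statistics downstream.
    """

    specimen_id: str
    species: str
    marker: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.specimen_id}: sequence must be non-empty")
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.specimen_id}: illegal sequence characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class Alignment:
    """An ordered set of equal-length sequence records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            offending = sorted(
                {r.specimen_id: len(r.sequence) for r in self.records}.items(),
                key=lambda kv: kv[1],
            )
            raise AlignmentLengthError(
                f"records have unequal lengths: {offending}"
            )
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate specimen_id(s): {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def species_map(self) -> dict[str, str]:
        """specimen_id -> species label (including "unknown")."""
        return {r.specimen_id: r.species for r in self.records}

    def species_groups(self) -> dict[str, list[SequenceRecord]]:
        """Named species -> records; specimens labelled "unknown" excluded."""
        groups: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            if r.species == UNKNOWN_SPECIES:
                continue
            groups.setdefault(r.species, []).append(r)
        return groups


def _read_metadata(metadata_path: str | Path) -> dict[str, dict[str, str]]:
    path = Path(metadata_path)
    with path.open(newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"specimen_id", "species", "marker"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MetadataError(
                f"metadata must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        rows: dict[str, dict[str, str]] = {}
        for row in reader:
            sid = row["specimen_id"].strip()
            if sid in rows:
                raise MetadataError(f"duplicate specimen_id in metadata: {sid}")
            rows[sid] = row
    return rows


def read_fasta_with_metadata(
    fasta_path: str | Path, metadata_path: str | Path
) -> Alignment:
    """Read an aligned FASTA plus a TSV/CSV metadata table.

    The join key is the full FASTA identifier up to the first whitespace.
    Every FASTA record must appear exactly once in the metadata; a missing
    or empty species field is stored as ``"unknown"``.
    """
    meta = _read_metadata(metadata_path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = rec.id
        if sid not in meta:
            raise MetadataError(f"FASTA id {sid!r} missing from metadata")
        row = meta[sid]
        species = (row.get("species") or "").strip() or UNKNOWN_SPECIES
        records.append(
            SequenceRecord(
                specimen_id=sid,
                species=species,
                marker=(row.get("marker") or "").strip(),
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise MetadataError(f"no FASTA records parsed from {fasta_path}")
    return Alignment(records)


def write_fasta_with_metadata(
    aln: Alignment, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write an alignment back to FASTA + TSV (inverse of the reader)."""
    with Path(fasta_path).open("w", encoding="utf-8") as fh:
        for r in aln.records:
            fh.write(f">{r.specimen_id}\n{r.sequence}\n")
    with Path(metadata_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["specimen_id", "species", "marker"])
        for r in aln.records:
            writer.writerow([r.specimen_id, r.species, r.marker])


def write_newick(tree, path: str | Path, min_support: float = 50.0) -> None:
    """Write a tree as Newick, showing supports only when >= ``min_support``.

    ``min_support=0`` writes every support value.
    """
    Path(path).write_text(tree.newick(min_support=min_support) + "\n",
                          encoding="utf-8")


def write_csv(rows: Iterable[Mapping[str, object]], path: str | Path,
              columns: list[str]) -> None:
    """Write dict rows as UTF-8 CSV with a header row."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
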