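"""Aligned barcode records: parsing, validation, quality flags, round-trip I/O.

A dataset is a set of equal-length, pre-aligned COI barcode sequences joined
to a specimen metadata table (specimen ID, genus, species epithet, region
tag).  Sequences use IUPAC codes; only unambiguous A/C/G/T positions count
toward the "barcode-compliant length" quality flag.  Gaps ('-') and
ambiguity codes are retained — downstream distance computations apply
pairwise deletion, so no record is ever silently dropped here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, JoinError, ValidationError

METADATA_COLUMNS = ("specimen_id", "genus", "species", "region")
_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced voucher specimen.

    ``species`` holds the specific epithet only; :attr:`binomial` joins it
    with the genus.  ``sequence`` is the aligned IUPAC string, uppercase,
    with 'U' already mapped to 'T'.
    """

    specimen_id: str
    genus: str
    species: str
    region: str
    sequence: str

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}"

    @property
    def seq_length_unambiguous(self) -> int:
        """Number of unambiguous A/C/G/T positions (gaps and IUPAC
        ambiguity codes excluded)."""
        return sum(c in _UNAMBIGUOUS for c in self.sequence)


@dataclass(frozen=True)
class Dataset:
    """An aligned barcode library: records sharing one alignment length."""

    records: tuple[SpecimenRecord, ...]
    alignment_length: int

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("dataset contains no records")
        lengths = {len(r.sequence) for r in self.records}
        if lengths != {self.alignment_length}:
            raise AlignmentError(
                f"sequence lengths {sorted(lengths)} do not all equal the "
                f"alignment length {self.alignment_length}"
            )
        dup = [i for i, c in Counter(r.specimen_id for r in self.records).items() if c > 1]
        if dup:
            raise ValidationError(f"duplicate specimen IDs: {sorted(dup)}")
        bad = [r.specimen_id for r in self.records if not r.genus or not r.species]
        if bad:
            raise ValidationError(f"records with empty genus/species: {bad}")

    @classmethod
    def from_records(cls, records: Iterable[SpecimenRecord]) -> "Dataset":
        records = tuple(records)
        if not records:
            raise ValidationError("dataset contains no records")
        return cls(records=records, alignment_length=len(records[0].sequence))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def record(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def species_members(self) -> dict[str, list[str]]:
        """Map binomial -> specimen IDs, in record order."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.binomial, []).append(r.specimen_id)
        return out


def _normalize(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def read_dataset(fasta_path: str | Path, metadata_path: str | Path) -> Dataset:
    """Join an aligned FASTA with its specimen metadata TSV.

    The metadata file is strict TSV with a header row containing at least
    the columns ``specimen_id``, ``genus``, ``species``, ``region``
    (case-sensitive).  FASTA IDs and metadata specimen IDs must match as
    sets; either direction of mismatch raises :class:`JoinError` naming the
    offenders.
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA ID: {rec.id}")
        seqs[rec.id] = _normalize(rec.seq)
    if not seqs:
        raise ValidationError(f"no FASTA records in {fasta_path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing required columns: {missing_cols}")
    dup_meta = meta["specimen_id"][meta["specimen_id"].duplicated()].tolist()
    if dup_meta:
        raise ValidationError(f"duplicate metadata specimen IDs: {sorted(set(dup_meta))}")

    fasta_ids, meta_ids = set(seqs), set(meta["specimen_id"])
    only_fasta = sorted(fasta_ids - meta_ids)
    only_meta = sorted(meta_ids - fasta_ids)
    if only_fasta or only_meta:
        raise JoinError(
            f"FASTA/metadata mismatch: IDs only in FASTA {only_fasta}; "
            f"only in metadata {only_meta}"
        )

    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths in {fasta_path}: {sorted(lengths)}")

    records = tuple(
        SpecimenRecord(
            specimen_id=row.specimen_id,
            genus=row.genus,
            species=row.species,
            region=row.region,
            sequence=seqs[row.specimen_id],
        )
        for row in meta.itertuples()
    )
    return Dataset(records=records, alignment_length=lengths.pop())


def write_dataset(d: Dataset, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a dataset back to FASTA + metadata TSV (inverse of read_dataset)."""
    recs = [SeqRecord(Seq(r.sequence), id=r.specimen_id, description="") for r in d.records]
    SeqIO.write(recs, str(fasta_path), "fasta")
    meta = pd.DataFrame(
        [(r.specimen_id, r.genus, r.species, r.region) for r in d.records],
        columns=list(METADATA_COLUMNS),
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def qc_flags(d: Dataset, min_len: int = 500) -> pd.DataFrame:
    """Advisory barcode-compliance flags, one row per record.

    ``meets_standard`` is true when the count of unambiguous A/C/G/T
    positions is >= ``min_len`` (the community minimum-length criterion for
    a full-quality barcode).  Flags never filter: short records stay in
    every analysis, they are merely marked.
    """
    rows = [
        (r.specimen_id, r.seq_length_unambiguous, r.seq_length_unambiguous >= min_len)
        for r in d.records
    ]
    return pd.DataFrame(rows, columns=["specimen_id", "seq_length_unambiguous", "meets_standard"])
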