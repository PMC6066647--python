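"""Reading and writing barcode libraries: FASTA sequences, specimen metadata,
open-nomenclature parsing and NUMT screening.

A *barcode library* couples an aligned set of COI sequences with a specimen
metadata table.  Sequences are kept exactly as read (IUPAC codes and gap
characters included); ambiguity handling is deferred to distance computation,
which uses pairwise deletion.

The NUMT screen implements the standard coding-sequence sanity check for
mitochondrial barcodes: a genuine COI fragment translates without stop codons
in some reading frame and carries no internal alignment gaps (which would
imply indels in a protein-coding gene).  Sequences failing either test are
candidate nuclear pseudogene (NUMT) artefacts.
"""

from __future__ import annotations

import csv
import enum
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: Stop codons per NCBI translation table id.  Table 2 is the vertebrate
#: mitochondrial code, the default for fish COI barcodes.
STOP_CODONS = {
    1: {"TAA", "TAG", "TGA"},
    2: {"TAA", "TAG", "AGA", "AGG"},
    5: {"TAA", "TAG"},
}

#: Suffixes marking a suprageneric (subfamily/family level) identification.
SUPRAGENERIC_SUFFIXES = ("inae", "idae", "iformes", "oidea")


class NomenclatureStatus(str, enum.Enum):
    DESCRIBED = "described"
    OPEN = "open"


class Qualifier(str, enum.Enum):
    NONE = "none"
    SP = "sp"
    AFF = "aff"
    CF = "cf"
    GR = "gr"
    FAMILY_LEVEL = "family_level"


class NativeStatus(str, enum.Enum):
    NATIVE = "native"
    INTRODUCED = "introduced"
    UNKNOWN = "unknown"


class LibraryError(ValueError):
    """Malformed or inconsistent library input."""


@dataclass
class SpecimenRecord:
    """One barcode sequence plus its taxonomy and provenance."""

    specimen_id: str
    sequence: str
    morphospecies: str
    genus: str = ""
    family: str = ""
    site_id: str = ""
    basin: str = ""
    native_status: NativeStatus = NativeStatus.UNKNOWN
    voucher: str = ""
    nomenclature_status: NomenclatureStatus = NomenclatureStatus.DESCRIBED
    qualifier: Qualifier = Qualifier.NONE

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LibraryError(f"{self.specimen_id}: empty sequence")
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise LibraryError(
                f"{self.specimen_id}: non-IUPAC characters {sorted(bad)!r}"
            )
        self.sequence = self.sequence.upper()


@dataclass
class BarcodeLibrary:
    """An aligned set of specimen records (all sequences equal length)."""

    records: list[SpecimenRecord]
    alignment_length: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise LibraryError("library holds no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise LibraryError(
                "sequences have unequal lengths "
                f"{sorted(lengths)}; align the input first"
            )
        self.alignment_length = lengths.pop()
        ids = [r.specimen_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise LibraryError(f"duplicate specimen ids: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def by_id(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def species_of(self) -> dict[str, list[str]]:
        """Map morphospecies label -> specimen ids, in record order."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.morphospecies, []).append(r.specimen_id)
        return out


@dataclass
class NumtReport:
    specimen_id: str
    frame: int
    stop_codon_count: int
    internal_gap: bool

    @property
    def passed(self) -> bool:
        return self.stop_codon_count == 0 and not self.internal_gap


def parse_nomenclature(label: str) -> tuple[NomenclatureStatus, Qualifier]:
    """Classify a morphospecies label as described or open nomenclature.

    Open-nomenclature markers recognised: ``sp.`` (undescribed), ``aff.``,
    ``cf.``, ``gr.`` (uncertain identification against a nominal species),
    and single-word suprageneric names such as subfamilies ending in
    ``-inae``.  Anything else (a plain binomial) is treated as described.
    """
    if not label or not label.strip():
        raise LibraryError("empty morphospecies label")
    text = f" {label.strip()} "
    for marker, qual in (
        (" aff. ", Qualifier.AFF),
        (" cf. ", Qualifier.CF),
        (" gr. ", Qualifier.GR),
    ):
        if marker in text:
            return NomenclatureStatus.OPEN, qual
    if " sp. " in text or text.rstrip().endswith(" sp"):
        return NomenclatureStatus.OPEN, Qualifier.SP
    tokens = label.split()
    if len(tokens) == 1 and tokens[0].lower().endswith(SUPRAGENERIC_SUFFIXES):
        return NomenclatureStatus.OPEN, Qualifier.FAMILY_LEVEL
    return NomenclatureStatus.DESCRIBED, Qualifier.NONE


METADATA_COLUMNS = [
    "specimen_id",
    "morphospecies",
    "genus",
    "family",
    "site_id",
    "basin",
    "native_status",
    "voucher",
]


def _read_metadata(metadata_path: str | Path) -> dict[str, dict[str, str]]:
    rows: dict[str, dict[str, str]] = {}
    with open(metadata_path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise LibraryError(f"{metadata_path}: empty metadata file")
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None or "specimen_id" not in reader.fieldnames:
        raise LibraryError(f"{metadata_path}: missing 'specimen_id' column")
    for row in reader:
        sid = row["specimen_id"].strip()
        if sid in rows:
            raise LibraryError(f"duplicate metadata row for {sid!r}")
        rows[sid] = {k: (v or "").strip() for k, v in row.items()}
    return rows


def read_library(
    fasta_path: str | Path, metadata_path: str | Path
) -> BarcodeLibrary:
    """Read an aligned FASTA plus a tab-separated metadata table.

    Every FASTA id must have a metadata row; unmatched ids on either side
    are an error.  Ragged (unequal length) sequences raise, directing the
    user to align first.
    """
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise LibraryError(f"{fasta_path}: no FASTA records")
    meta = _read_metadata(metadata_path)
    records = []
    for rec in seqs:
        if rec.id not in meta:
            raise LibraryError(f"FASTA id {rec.id!r} has no metadata row")
        row = meta[rec.id]
        label = row.get("morphospecies", "")
        status, qual = parse_nomenclature(label)
        records.append(
            SpecimenRecord(
                specimen_id=rec.id,
                sequence=str(rec.seq),
                morphospecies=label,
                genus=row.get("genus", ""),
                family=row.get("family", ""),
                site_id=row.get("site_id", ""),
                basin=row.get("basin", ""),
                native_status=NativeStatus(
                    row.get("native_status") or "unknown"
                ),
                voucher=row.get("voucher", ""),
                nomenclature_status=status,
                qualifier=qual,
            )
        )
    extra = set(meta) - {r.specimen_id for r in records}
    if extra:
        raise LibraryError(
            f"metadata rows without FASTA entries: {sorted(extra)}"
        )
    return BarcodeLibrary(records=records)


def write_library(
    library: BarcodeLibrary, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the FASTA + metadata TSV pair that :func:`read_library` reads."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in library.records
    ]
    with open(fasta_path, "w", encoding="utf-8") as fh:
        SeqIO.write(seqrecs, fh, "fasta")
    with open(metadata_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for r in library.records:
            writer.writerow(
                [
                    r.specimen_id,
                    r.morphospecies,
                    r.genus,
                    r.family,
                    r.site_id,
                    r.basin,
                    r.native_status.value,
                    r.voucher,
                ]
            )


def numt_screen(
    record: SpecimenRecord, genetic_code: int = 2
) -> NumtReport:
    """Screen one barcode for NUMT artefacts.

    Strips terminal gaps, flags internal gaps, then counts in-frame stop
    codons (unambiguous codons only) in each of the three forward frames and
    keeps the frame with the fewest.  A clean COI fragment has zero stops in
    its best frame and no internal gaps.
    """
    seq = record.sequence
    core = seq.strip("-")
    if not core or set(core) <= {"N"}:
        raise LibraryError(f"{record.specimen_id}: sequence is all gaps/Ns")
    if len(core) < 60:
        raise LibraryError(
            f"{record.specimen_id}: too short to frame-screen ({len(core)} nt)"
        )
    internal_gap = "-" in core
    ungapped = core.replace("-", "")
    stops = STOP_CODONS[genetic_code]
    best_frame, best_count = 0, None
    for frame in range(3):
        count = 0
        for i in range(frame, len(ungapped) - 2, 3):
            codon = ungapped[i : i + 3]
            if set(codon) <= set("ACGT") and codon in stops:
                count += 1
        if best_count is None or count < best_count:
            best_frame, best_count = frame, count
    return NumtReport(
        specimen_id=record.specimen_id,
        frame=best_frame,
        stop_codon_count=int(best_count or 0),
        internal_gap=internal_gap,
    )


def screen_library(
    library: BarcodeLibrary, genetic_code: int = 2
) -> list[NumtReport]:
    return [numt_screen(r, genetic_code) for r in library.records]
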