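"""Readers and writers for the formats the pipeline touches.

Sequence data moves as FASTA (via Biopython), tables as TSV. Two tables of
study metadata ship with the package: per-genome assembly metadata
(:func:`load_genome_metadata`) and the functional annotation of the
group-specific genes (:func:`load_gene_table`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "MolType",
    "MappingTool",
    "SequenceRecord",
    "GenomeMetadata",
    "SpecificGeneRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "load_gene_table",
    "load_genome_metadata",
    "packaged_fixture_path",
    "GENE_TABLE_GROUPS",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class MolType(enum.Enum):
    PROTEIN = "protein"
    DNA = "dna"


class MappingTool(enum.Enum):
    """Annotation source of a specific gene.

    ``UNSPECIFIED`` marks a database hit whose tool column was left blank in
    the source table; it still counts as a hit (only ``NONE`` rows are
    "unseen in databases").
    """

    COG = "COG"
    MANTIS = "Mantis"
    UNSPECIFIED = "unspecified"
    NONE = "none"


_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "BZJUOX*-?")
_DNA_ALPHABET = set("ACGT" + "RYSWKMBDHVN-?X")


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with its identifier and molecule type."""

    id: str
    seq: str
    moltype: MolType

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        alphabet = _PROTEIN_ALPHABET if self.moltype is MolType.PROTEIN else _DNA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside the "
                f"{self.moltype.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class GenomeMetadata:
    """One assembly's quality and provenance metrics."""

    accession: str
    strain: str
    group: str
    host: str
    completeness: float
    contamination: float
    length: int
    n_contigs: int
    n50: int
    species: str = ""
    origin: str = ""
    derep_representative: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise FormatError(
                f"{self.accession}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise FormatError(f"{self.accession}: negative contamination")
        if self.length <= 0:
            raise FormatError(f"{self.accession}: non-positive length")
        if self.n50 > self.length:
            raise FormatError(f"{self.accession}: N50 {self.n50} exceeds length {self.length}")


GENE_TABLE_GROUPS = (
    "Apis group1",
    "Apis group2",
    "Apis group1&2",
    "Bombus group1",
    "Bombus group3",
    "Bombus group4",
    "Bombus group5",
    "Apis-Bombus groups",
)


@dataclass(frozen=True)
class SpecificGeneRecord:
    """One row of the specific-gene annotation table."""

    gene_id: str
    group: str
    length_aa: int
    product: str
    mapping_tool: MappingTool
    category: str
    gene_name: str = ""
    putative_hgt: bool = False

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise FormatError(f"{self.gene_id}: non-positive length {self.length_aa}")
        if self.group not in GENE_TABLE_GROUPS:
            raise FormatError(f"{self.gene_id}: unknown group label {self.group!r}")
        if self.mapping_tool is MappingTool.NONE and self.category not in (
            "Unknown",
            "Function unknown",
        ):
            raise FormatError(
                f"{self.gene_id}: no mapping tool but category {self.category!r}"
            )


def read_fasta(path: str | Path, moltype: MolType) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, whitespace inside sequences is stripped and case is
    normalised to upper. Duplicate identifiers, empty sequences or malformed
    headers raise :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA header without an identifier")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq, moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def packaged_fixture_path(which: str) -> Path:
    """Path of a packaged study table: ``table1`` (genomes) or ``table2`` (genes)."""
    names = {
        "table1": "table1_genomes.tsv",
        "table2": "table2_specific_genes.tsv",
    }
    try:
        name = names[which]
    except KeyError:
        raise ValueError(f"unknown fixture {which!r}; expected 'table1' or 'table2'")
    return Path(str(resources.files("snodkit.data").joinpath(name)))


def _parse_tool(tool: str, category: str) -> MappingTool:
    tool = tool.strip()
    if tool == "COG":
        return MappingTool.COG
    if tool == "Mantis":
        return MappingTool.MANTIS
    if tool == "":
        # A blank tool with a real category is a hit whose tool column was
        # left blank in the source table; only blank-tool/"Unknown" rows are
        # genuinely unseen in databases.
        if category.strip() in ("", "Unknown"):
            return MappingTool.NONE
        return MappingTool.UNSPECIFIED
    raise FormatError(f"unknown mapping tool {tool!r}")


def load_gene_table(path: str | Path | None = None) -> list[SpecificGeneRecord]:
    """Load a specific-gene annotation table (packaged fixture by default)."""
    if path is None:
        path = packaged_fixture_path("table2")
    rows = _read_tsv(path)
    required = {"group", "gene_id", "length_aa", "mapping_tool", "category"}
    missing = required - set(rows[0]) if rows else required
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in rows:
        category = row["category"].strip() or "Unknown"
        records.append(
            SpecificGeneRecord(
                gene_id=row["gene_id"],
                group=row["group"],
                length_aa=int(row["length_aa"]),
                product=row.get("product", "").strip(),
                mapping_tool=_parse_tool(row["mapping_tool"], row["category"]),
                category=category,
                gene_name=row.get("gene_name", "").strip(),
                putative_hgt=row.get("putative_hgt", "no").strip() == "yes",
            )
        )
    return records


def load_genome_metadata(path: str | Path | None = None) -> list[GenomeMetadata]:
    """Load a genome-metadata table (packaged fixture by default)."""
    if path is None:
        path = packaged_fixture_path("table1")
    rows = _read_tsv(path)
    records = []
    for row in rows:
        records.append(
            GenomeMetadata(
                accession=row["accession"],
                strain=row["strain"],
                group=row["group"],
                host=row.get("host", ""),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                length=int(row["length"]),
                n_contigs=int(row["n_contigs"]),
                n50=int(row["n50"]),
                species=row.get("species", ""),
                origin=row.get("origin", ""),
                derep_representative=row.get("derep_representative", "no") == "yes",
            )
        )
    return records


def _read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        cells += [""] * (len(header) - len(cells))
        rows.append(dict(zip(header, cells)))
    return rows
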