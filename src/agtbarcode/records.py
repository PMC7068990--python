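"""Sequence records, taxonomy tables and alignment blocks.

The data model centres on :class:`MarkerRecord`, one barcode sequence with
its taxonomy and provenance plus optional region annotation: the 0-based
half-open index of the exon IV / intron IV boundary (``exon_end``) and of
the intron IV / exon V boundary (``intron_end``).  A record spanning the
full amplicon is therefore ``exon_IV + intron_IV + exon_V_remnant`` where
the trailing exon V remnant is ``len(sequence) - intron_end`` bases (14 bp
in the marker this package was designed around).

Metadata travels in the FASTA header using a configurable delimited schema;
the default is six pipe-separated fields::

    >record_id|species|genus|subfamily|species_group|provenance

All coordinates are 0-based half-open.  Only the forward strand is ever
considered: barcodes are amplified with a fixed primer orientation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Bases treated as fully determined; everything else in IUPAC_AMBIGUOUS is
#: retained on input but treated as missing data downstream.
UNAMBIGUOUS = frozenset("ACGT")
IUPAC_AMBIGUOUS = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"

#: Length of the conserved exon fragment a full barcode read starts with.
DEFAULT_EXON_LENGTH = 264
#: Length of the short downstream-exon remnant at the 3' end of the amplicon.
EXON_V_REMNANT = 14

DEFAULT_HEADER_FIELDS = (
    "record_id",
    "species",
    "genus",
    "subfamily",
    "species_group",
    "provenance",
)

TAXONOMY_COLUMNS = ("species", "genus", "subfamily", "species_group", "literature_support")


class RecordError(ValueError):
    """Malformed record, header or taxonomy input."""


@dataclass(frozen=True)
class MarkerRecord:
    """One marker sequence with taxonomy, provenance and region annotation."""

    record_id: str
    species: str
    genus: str = ""
    subfamily: str = ""
    species_group: str | None = None
    provenance: str = ""
    allele_id: str | None = None
    sequence: str = ""
    exon_end: int | None = None
    intron_end: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RecordError(f"record {self.record_id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - IUPAC_AMBIGUOUS
        if bad:
            raise RecordError(
                f"record {self.record_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.exon_end is not None or self.intron_end is not None:
            e = 0 if self.exon_end is None else self.exon_end
            i = len(seq) if self.intron_end is None else self.intron_end
            if not (0 <= e <= i <= len(seq)):
                raise RecordError(
                    f"record {self.record_id!r}: invalid region boundaries "
                    f"exon_end={self.exon_end} intron_end={self.intron_end} "
                    f"length={len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def individual_id(self) -> str:
        """Identifier of the individual; alleles of one accession share it."""
        if self.allele_id and self.record_id.endswith("." + self.allele_id):
            return self.record_id[: -(len(self.allele_id) + 1)]
        return self.record_id

    def with_sequence(self, sequence: str, exon_end: int | None = None,
                      intron_end: int | None = None) -> "MarkerRecord":
        return replace(self, sequence=sequence, exon_end=exon_end, intron_end=intron_end)


@dataclass
class TaxonomyTable:
    """Species-level taxonomy: genus, subfamily, clade/complex membership.

    ``species_group`` may be empty (species not yet placed in any published
    clade); ``literature_support`` flags whether the group assignment has
    published phylogenetic support.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TAXONOMY_COLUMNS if c not in self.table.columns]
        if missing:
            raise RecordError(f"taxonomy table missing columns: {missing}")
        if self.table["species"].duplicated().any():
            dupes = self.table.loc[self.table["species"].duplicated(), "species"]
            raise RecordError(f"duplicate species in taxonomy: {sorted(set(dupes))}")
        self.table = self.table.set_index("species", drop=False)

    def __contains__(self, species: str) -> bool:
        return species in self.table.index

    def group_of(self, species: str) -> str:
        g = self.table.at[species, "species_group"]
        return "" if pd.isna(g) else str(g)

    def genus_of(self, species: str) -> str:
        return str(self.table.at[species, "genus"])

    def subfamily_of(self, species: str) -> str:
        return str(self.table.at[species, "subfamily"])

    @property
    def species(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MsaBlock:
    """A multiple alignment: equal-length gapped rows keyed by record id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise RecordError("empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise RecordError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise RecordError("ids/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    def gap_only_columns(self) -> list[int]:
        return [j for j in range(self.n_columns)
                if all(c == GAP for c in self.column(j))]


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str, fields: Sequence[str], delimiter: str) -> dict[str, str]:
    parts = header.split(delimiter)
    if len(parts) != len(fields):
        raise RecordError(
            f"header {header!r}: expected {len(fields)} "
            f"{delimiter!r}-separated fields, got {len(parts)}"
        )
    return dict(zip(fields, parts))


def read_fasta(path: str | Path | io.TextIOBase,
               header_fields: Sequence[str] = DEFAULT_HEADER_FIELDS,
               delimiter: str = "|") -> list[MarkerRecord]:
    """Read marker records from FASTA with a delimited header schema.

    Sequences are uppercased; wrapped lines and CRLF endings are handled by
    the underlying parser.  Raises :class:`RecordError` on a malformed
    header (with the offending entry named) or a duplicate ``record_id``.
    """
    records: list[MarkerRecord] = []
    seen: set[str] = set()
    for i, sr in enumerate(SeqIO.parse(path, "fasta"), start=1):
        header = sr.description
        try:
            meta = _parse_header(header, header_fields, delimiter)
        except RecordError as e:
            raise RecordError(f"entry {i}: {e}") from None
        rid = meta.get("record_id", sr.id)
        if rid in seen:
            raise RecordError(f"entry {i}: duplicate record_id {rid!r}")
        seen.add(rid)
        group = meta.get("species_group") or None
        records.append(MarkerRecord(
            record_id=rid,
            species=meta.get("species", ""),
            genus=meta.get("genus", ""),
            subfamily=meta.get("subfamily", ""),
            species_group=group,
            provenance=meta.get("provenance", ""),
            allele_id=meta.get("allele_id") or None,
            sequence=str(sr.seq),
        ))
    return records


def write_fasta(records: Iterable[MarkerRecord], path: str | Path,
                header_fields: Sequence[str] = DEFAULT_HEADER_FIELDS,
                delimiter: str = "|", wrap: int = 70) -> None:
    """Write records with the same delimited header schema ``read_fasta`` uses."""
    seqrecords = []
    for r in records:
        values = []
        for f in header_fields:
            v = getattr(r, f, "") or ""
            values.append(str(v))
        header = delimiter.join(values)
        seqrecords.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecords)


def read_aligned_fasta(path: str | Path) -> MsaBlock:
    """Read an aligned FASTA into an :class:`MsaBlock` (first header token as id)."""
    ids, rows = [], []
    for sr in SeqIO.parse(path, "fasta"):
        ids.append(sr.description.split("|")[0])
        rows.append(str(sr.seq).upper())
    return MsaBlock(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# Region handling

def split_regions(record: MarkerRecord,
                  exon_length: int = DEFAULT_EXON_LENGTH) -> tuple[str, str]:
    """Split a barcode into (exon part, intron part).

    The exon part is trimmed to at most ``exon_length`` bases by dropping
    excess from the 5' end; the intron part runs from ``exon_end`` to
    ``intron_end`` and so excludes any downstream-exon remnant.  Boundaries
    must be annotated on the record (see :func:`locate_boundaries` for the
    alignment fallback).
    """
    if record.exon_end is None:
        raise RecordError(
            f"record {record.record_id!r}: exon_end unset; annotate boundaries "
            "or use locate_boundaries() with a reference exon"
        )
    exon = record.sequence[: record.exon_end]
    if len(exon) > exon_length:
        exon = exon[-exon_length:]
    intron_end = record.intron_end if record.intron_end is not None else len(record.sequence)
    intron = record.sequence[record.exon_end: intron_end]
    return exon, intron


def locate_boundaries(record: MarkerRecord, reference_exon: str,
                      exon_v_remnant: int = EXON_V_REMNANT) -> MarkerRecord:
    """Annotate boundaries by locating a reference exon at the 5' end.

    Fallback for records lacking annotation: the exon/intron boundary is
    placed where the best un-gapped local match of ``reference_exon``
    against the record's 5' region ends, and the intron/exon-V boundary
    ``exon_v_remnant`` bases before the 3' end.  Adequate when the exon is
    conserved, which is the premise of a two-part barcode.
    """
    from .align import ScoringScheme, local_align
    aln = local_align(record.sequence, reference_exon.upper(), ScoringScheme())
    exon_end = aln.query_end
    intron_end = max(exon_end, len(record.sequence) - exon_v_remnant)
    return replace(record, exon_end=exon_end, intron_end=intron_end)


# ---------------------------------------------------------------------------
# Taxonomy and trees

def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read the species taxonomy TSV (columns: species, genus, subfamily,
    species_group, literature_support)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.table.to_csv(path, sep="\t", index=False)


def taxonomy_from_records(records: Iterable[MarkerRecord],
                          literature_support: bool = True) -> TaxonomyTable:
    """Build a taxonomy table from record metadata (one row per species)."""
    rows = {}
    for r in records:
        rows.setdefault(r.species, {
            "species": r.species,
            "genus": r.genus,
            "subfamily": r.subfamily,
            "species_group": r.species_group or "",
            "literature_support": str(literature_support),
        })
    return TaxonomyTable(pd.DataFrame(list(rows.values())))


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree (from a path or a newick string)."""
    s = str(source)
    if s.strip().startswith("(") or s.strip().endswith(";"):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to a newick string parseable by standard tools."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
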