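"""Barcode species identification with a unique-top-score rule.

A query is searched against a reference database by seeded local
alignment; identification is *correct* only when every hit sharing the
maximum bit score is conspecific with the query and all other species
score strictly lower.  When the top-score tie set also contains other
species alongside the query's, the call is *ambiguous*; when the query's
species is absent from the tie set it is *incorrect*; an empty hit list
is *no_hit*.  With integer raw scores and fixed Karlin–Altschul
parameters, bit-score ties are exactly raw-score ties, so "strictly
lower" needs no epsilon.

The database can hold exon-only sequences (trimmed to 264 bp) or
exon+intron, the two-part mode that carries the intron's extra signal.
Queries are records of species sampled from more than one provenance
(so a conspecific from another origin exists to be found), and every
query's own record is removed from its hit list — leaving it in would
make every search trivially correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import (BitScoreParams, PairwiseHit, ScoringScheme,
                    seeded_local_search)
from .records import DEFAULT_EXON_LENGTH, MarkerRecord, TaxonomyTable, split_regions

MODES = ("exon", "exon_intron")


class IdentificationError(ValueError):
    pass


@dataclass
class ReferenceDatabase:
    """Processed reference sequences plus their taxonomy metadata."""

    mode: str
    entries: list[tuple[str, str]]              # (record_id, processed seq)
    meta: dict[str, MarkerRecord]

    @classmethod
    def build(cls, records: Sequence[MarkerRecord], mode: str = "exon_intron",
              exon_length: int = DEFAULT_EXON_LENGTH) -> "ReferenceDatabase":
        if mode not in MODES:
            raise IdentificationError(f"mode must be one of {MODES}")
        entries = []
        meta = {}
        for r in records:
            seq = process_sequence(r, mode, exon_length)
            if not seq:
                raise IdentificationError(f"record {r.record_id!r}: empty {mode} sequence")
            entries.append((r.record_id, seq))
            meta[r.record_id] = r
        return cls(mode=mode, entries=entries, meta=meta)

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.meta.values()}


def process_sequence(record: MarkerRecord, mode: str,
                     exon_length: int = DEFAULT_EXON_LENGTH) -> str:
    """Exon-only (trimmed) or exon+intron sequence of a record."""
    exon, intron = split_regions(record, exon_length)
    return exon if mode == "exon" else exon + intron


@dataclass
class IdentificationResult:
    query_id: str
    query_species: str
    outcome: str                                # correct|ambiguous|incorrect|no_hit
    hits: list[PairwiseHit]
    top_species: set[str]
    group_correct: bool
    no_conspecific: bool = False

    @property
    def top_bit_score(self) -> float | None:
        return self.hits[0].bit_score if self.hits else None


def select_queries(records: Sequence[MarkerRecord]) -> list[MarkerRecord]:
    """One designated query per species sampled from ≥2 provenances.

    The query is the record with the lexicographically smallest id among
    that species' records, so the choice is deterministic.
    """
    by_species: dict[str, list[MarkerRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    queries = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        if len({r.provenance for r in recs}) >= 2:
            queries.append(min(recs, key=lambda r: r.record_id))
    return queries


def identify(query: MarkerRecord, database: ReferenceDatabase,
             scoring: ScoringScheme = ScoringScheme(),
             bitparams: BitScoreParams | None = None,
             taxonomy: TaxonomyTable | None = None) -> IdentificationResult:
    """Identify one query against the database (self-hit removed)."""
    qseq = process_sequence(query, database.mode)
    subjects = [(rid, seq) for rid, seq in database.entries
                if rid != query.record_id]
    no_conspecific = query.species not in {
        database.meta[rid].species for rid, _ in subjects}
    hits = seeded_local_search((query.record_id, qseq), subjects,
                               scoring, bitparams)
    if not hits:
        return IdentificationResult(
            query_id=query.record_id, query_species=query.species,
            outcome="no_hit", hits=[], top_species=set(),
            group_correct=False, no_conspecific=no_conspecific)

    top_raw = hits[0].raw_score
    top_species = {database.meta[h.subject_id].species
                   for h in hits if h.raw_score == top_raw}
    if top_species == {query.species}:
        outcome = "correct"
    elif query.species in top_species:
        outcome = "ambiguous"
    else:
        outcome = "incorrect"

    top_rec = database.meta[hits[0].subject_id]
    if taxonomy is not None and query.species in taxonomy and top_rec.species in taxonomy:
        q_group = taxonomy.group_of(query.species)
        t_group = taxonomy.group_of(top_rec.species)
    else:
        q_group = query.species_group or ""
        t_group = top_rec.species_group or ""
    group_correct = bool(q_group) and q_group == t_group

    return IdentificationResult(
        query_id=query.record_id, query_species=query.species,
        outcome=outcome, hits=hits, top_species=top_species,
        group_correct=group_correct, no_conspecific=no_conspecific)


def identify_all(queries: Sequence[MarkerRecord], database: ReferenceDatabase,
                 scoring: ScoringScheme = ScoringScheme(),
                 bitparams: BitScoreParams | None = None,
                 taxonomy: TaxonomyTable | None = None) -> list[IdentificationResult]:
    if bitparams is None:
        bitparams = BitScoreParams.from_scoring(scoring)
    return [identify(q, database, scoring, bitparams, taxonomy) for q in queries]


def success_table(results: Sequence[IdentificationResult],
                  marker_label: str = "marker") -> pd.DataFrame:
    """Identification-success summary at species and genus/clade level.

    One row per taxonomic level: species tested, ambiguous calls, correct
    identifications.  At genus/clade level "correct" means the single
    top-scoring hit belongs to the query's species group; no ambiguity
    column applies there.
    """
    if not results:
        raise IdentificationError("no identification results to summarise")
    n = len(results)
    rows = [
        {"marker": marker_label, "level": "species", "n_tested": n,
         "ambiguous": sum(r.outcome == "ambiguous" for r in results),
         "correct": sum(r.outcome == "correct" for r in results)},
        {"marker": marker_label, "level": "genus_clade", "n_tested": n,
         "ambiguous": pd.NA,
         "correct": sum(r.group_correct for r in results)},
    ]
    return pd.DataFrame(rows)


def results_to_rows(results: Iterable[IdentificationResult]) -> list[dict]:
    """Result rows in the fixed TSV column order."""
    out = []
    for r in results:
        out.append({
            "query_id": r.query_id, "species": r.query_species,
            "outcome": r.outcome,
            "top_bit_score": round(r.top_bit_score, 3) if r.hits else "",
            "top_species": ";".join(sorted(r.top_species)),
            "group_correct": r.group_correct})
    return out
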