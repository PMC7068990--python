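"""Greedy incremental identity clustering (CD-HIT-EST style).

Sequences are sorted longest first (ties by id) and assigned to the first
existing cluster whose representative they match at or above the identity
threshold (first-fit); otherwise they seed a new cluster.  Identity is
matches over the shorter sequence's length, from banded global alignment
(see :mod:`agtbarcode.align`).  Because the processing order is fully
determined by (length, id), the clustering does not depend on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import ScoringScheme, global_identity
from .records import MarkerRecord, TaxonomyTable


class ClusterError(ValueError):
    pass


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]
    identities: dict[str, float]        # member id -> identity to representative


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c.member_ids}


def greedy_cluster(records: Sequence[MarkerRecord], threshold: float = 0.98,
                   scoring: ScoringScheme = ScoringScheme()) -> ClusterSet:
    """Cluster records at an identity threshold, longest-first greedy."""
    if not records:
        raise ClusterError("no records to cluster")
    if not (0.0 < threshold <= 1.0):
        raise ClusterError("threshold must be in (0, 1]")
    by_id = {r.record_id: r for r in records}
    if len(by_id) != len(records):
        raise ClusterError("duplicate record ids")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.record_id))

    clusters: list[Cluster] = []
    for rec in order:
        placed = False
        for c in clusters:
            rep = by_id[c.representative_id]
            ident, _, _ = global_identity(rec.sequence, rep.sequence, scoring)
            if ident >= threshold:
                c.member_ids.append(rec.record_id)
                c.identities[rec.record_id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=rec.record_id,
                                    member_ids=[rec.record_id],
                                    identities={rec.record_id: 1.0}))
    return ClusterSet(clusters=clusters, threshold=threshold)


def cluster_purity(cluster_set: ClusterSet, records: Sequence[MarkerRecord],
                   taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Label each cluster by its taxonomic concordance.

    ``species_cluster``: all members one species.  ``supported``: members
    span species but share a species group (or, for ungrouped species, a
    genus).  ``unsupported``: members mix groups.  ``unknown``: a member
    species is absent from the taxonomy (those species are listed in the
    ``missing_species`` column).
    """
    by_id = {r.record_id: r for r in records}
    rows = []
    for idx, c in enumerate(cluster_set.clusters):
        species = sorted({by_id[m].species for m in c.member_ids})
        missing = sorted(s for s in species if s not in taxonomy)
        if missing:
            label = "unknown"
        elif len(species) == 1:
            label = "species_cluster"
        else:
            groups = {taxonomy.group_of(s) or None for s in species}
            genera = {taxonomy.genus_of(s) for s in species}
            if len(groups) == 1 and None not in groups:
                label = "supported"
            elif len(genera) == 1:
                label = "supported"
            else:
                label = "unsupported"
        subfams = sorted({by_id[m].subfamily for m in c.member_ids})
        rows.append({
            "cluster_id": idx,
            "representative_id": c.representative_id,
            "n_members": len(c.member_ids),
            "n_species": len(species),
            "subfamily": subfams[0] if len(subfams) == 1 else ";".join(subfams),
            "label": label,
            "missing_species": ";".join(missing),
        })
    return pd.DataFrame(rows)


def subfamily_summary(purity: pd.DataFrame,
                      records: Sequence[MarkerRecord]) -> pd.DataFrame:
    """Aggregate cluster labels per subfamily (sequence/species/cluster
    counts, supported vs unsupported, pure species clusters)."""
    recs = pd.DataFrame({
        "subfamily": [r.subfamily for r in records],
        "species": [r.species for r in records],
    })
    rows = []
    for subfam, grp in recs.groupby("subfamily", sort=True):
        sub = purity[purity["subfamily"] == subfam]
        rows.append({
            "subfamily": subfam,
            "n_sequences": len(grp),
            "n_species": grp["species"].nunique(),
            "n_clusters": len(sub),
            "supported": int((sub["label"].isin(["supported", "species_cluster"])).sum()),
            "unsupported": int((sub["label"] == "unsupported").sum()),
            "species_clusters": int((sub["label"] == "species_cluster").sum()),
        })
    return pd.DataFrame(rows)


def write_clstr(cluster_set: ClusterSet, records: Sequence[MarkerRecord],
                path: str | Path) -> None:
    """CD-HIT-style ``.clstr`` text output."""
    by_id = {r.record_id: r for r in records}
    with open(path, "w") as fh:
        for idx, c in enumerate(cluster_set.clusters):
            fh.write(f">Cluster {idx}\n")
            for k, m in enumerate(c.member_ids):
                length = len(by_id[m].sequence)
                if m == c.representative_id:
                    fh.write(f"{k}\t{length}nt, >{m}... *\n")
                else:
                    pct = 100.0 * c.identities[m]
                    fh.write(f"{k}\t{length}nt, >{m}... at +/{pct:.2f}%\n")


def clusters_to_tsv(cluster_set: ClusterSet, path: str | Path) -> None:
    rows = []
    for idx, c in enumerate(cluster_set.clusters):
        for m in c.member_ids:
            rows.append({"cluster_id": idx, "record_id": m,
                         "is_representative": m == c.representative_id,
                         "identity_to_rep": round(c.identities[m], 5)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
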