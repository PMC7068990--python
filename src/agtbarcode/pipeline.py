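"""End-to-end orchestration: simulate → cluster → distances → identify →
gap → trees/assignment, with report tables.

``run_pipeline`` produces the study-style report bundle in one output
directory:

* ``table1.tsv`` — clusters per subfamily with concordance labels
* ``table2.tsv`` — alignment length, variable and parsimony-informative sites
* ``table3.tsv`` — identification success per marker mode and level
* ``gap_report.json`` — intra/inter K2P distributions, overlap, rank-sum test
* ``tree.nwk`` — bootstrapped NJ tree of the hybrid case-study subset
* ``assignments.tsv`` — allele-to-genepool assignments with hybrid flags

Every file carries a provenance header (package version, seed, config
hash); outputs are a pure function of (inputs, config, seed).  All
randomness flows through the single seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import BitScoreParams, ScoringScheme, seeded_local_search
from .cluster import cluster_purity, greedy_cluster, subfamily_summary
from .distances import distance_matrix, site_stats
from .gapstats import gap_report
from .identify import (ReferenceDatabase, identify_all, select_queries,
                       success_table, results_to_rows)
from .records import MarkerRecord, MsaBlock, TaxonomyTable, write_newick
from .simulate import SimParams, TruthTable, simulate
from .trees import assign_alleles, assignments_to_rows, bootstrap_support

log = logging.getLogger("agtbarcode")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    sim: SimParams = field(default_factory=SimParams)
    threshold: float = 0.98
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    modes: tuple[str, ...] = ("exon", "exon_intron")
    bootstrap_replicates: int = 100
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)      # analysis-irrelevant; keeps reruns comparable
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (f"# agtbarcode {__version__} seed={config.seed} "
            f"config={config.config_hash()}")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage on a simulated dataset; returns the output paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("table1", "table1.tsv"), ("table2", "table2.tsv"),
        ("table3", "table3.tsv"), ("gap_report", "gap_report.json"),
        ("tree", "tree.nwk"), ("assignments", "assignments.tsv")]}
    written: list[Path] = []
    try:
        _run_stages(config, paths, written)
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage failed: {e}") from e
    return paths


def _run_stages(config: RunConfig, paths: dict[str, Path],
                written: list[Path]) -> None:
    sim_params = dataclasses.replace(config.sim, seed=config.seed)
    log.info("simulating dataset (seed=%d)", config.seed)
    records, exon_msa, truth = simulate(sim_params)
    from .records import taxonomy_from_records
    taxonomy = taxonomy_from_records(records)

    log.info("clustering %d records at %.2f", len(records), config.threshold)
    cluster_set = greedy_cluster(records, config.threshold, config.scoring)
    purity = cluster_purity(cluster_set, records, taxonomy)
    _write_tsv(subfamily_summary(purity, records), paths["table1"], config)
    written.append(paths["table1"])

    stats = site_stats(exon_msa)
    _write_tsv(pd.DataFrame([{
        "marker": "exon", "aln_length": stats.aln_length,
        "variable": stats.variable, "informative": stats.informative,
        "variable_pct": round(100.0 * stats.variable / stats.aln_length, 1),
        "informative_pct": round(100.0 * stats.informative / stats.aln_length, 1),
    }]), paths["table2"], config)
    written.append(paths["table2"])

    log.info("identification in modes %s", config.modes)
    bitparams = BitScoreParams.from_scoring(config.scoring)
    queries = select_queries(records)
    tables = []
    results_by_mode = {}
    for mode in config.modes:
        db = ReferenceDatabase.build(records, mode=mode)
        results = identify_all(queries, db, config.scoring, bitparams, taxonomy)
        results_by_mode[mode] = results
        tables.append(success_table(results, marker_label=mode))
    _write_tsv(pd.concat(tables, ignore_index=True), paths["table3"], config)
    written.append(paths["table3"])

    log.info("barcoding-gap assessment")
    matrix = distance_matrix(exon_msa)
    species_of = dict(zip(truth.table["record_id"], truth.table["species"]))
    report = gap_report(matrix, taxonomy, species_of)
    payload = {"provenance": {"version": __version__, "seed": config.seed,
                              "config": config.config_hash()},
               "report": report.to_dict()}
    if report.level_summaries is not None:
        payload["levels"] = report.level_summaries.to_dict(orient="records")
    paths["gap_report"].write_text(json.dumps(payload, indent=2) + "\n")
    written.append(paths["gap_report"])

    _tree_and_assignments(config, records, truth, paths, written)


def _tree_and_assignments(config: RunConfig, records: list[MarkerRecord],
                          truth: TruthTable, paths: dict[str, Path],
                          written: list[Path]) -> None:
    """Fig.-3-style case study: tree + allele assignment on the hybrid
    subset (or the first species group when no hybrids were planted)."""
    t = truth.table
    hybrids = t[t["is_hybrid"]]
    if len(hybrids):
        parents = sorted(set(hybrids["parent_a"]) | set(hybrids["parent_b"]))
        subset_species = set(parents) | set(hybrids["species"])
    else:
        first_group = sorted(g for g in t["species_group"] if g)[0] if len(t) else ""
        subset_species = set(t.loc[t["species_group"] == first_group, "species"])
    subset = [r for r in records if r.species in subset_species]

    by_id = {r.record_id: r for r in records}
    from .identify import process_sequence
    sub_msa_ids, sub_rows = [], []
    for r in subset:
        sub_msa_ids.append(r.record_id)
        sub_rows.append(r.sequence[: r.exon_end])   # exon part aligns gap-free
    tree_txt = ""
    if len(subset) >= 4:
        msa = MsaBlock(ids=sub_msa_ids, rows=sub_rows)
        tree, skipped = bootstrap_support(msa, config.bootstrap_replicates,
                                          seed=config.seed)
        if skipped:
            log.warning("%d bootstrap replicates skipped (saturation)", skipped)
        tree_txt = write_newick(tree)
    with open(paths["tree"], "w") as fh:
        fh.write(f"[agtbarcode {__version__} seed={config.seed} "
                 f"config={config.config_hash()}]\n{tree_txt}\n")
    written.append(paths["tree"])

    if len(hybrids):
        pools = {sp: [r for r in records
                      if r.species == sp and not _is_hybrid(r, t)]
                 for sp in sorted(set(hybrids["parent_a"]) | set(hybrids["parent_b"]))}
        alleles = [by_id[rid] for rid in hybrids["record_id"]]
        assignments = assign_alleles(
            alleles, pools,
            distance_fn=_barcode_distance)
        rows = assignments_to_rows(assignments)
    else:
        rows = []
    _write_tsv(pd.DataFrame(rows, columns=["allele_id", "individual", "genepool",
                                           "margin", "identical", "hybrid_flag"]),
               paths["assignments"], config)
    written.append(paths["assignments"])


def _is_hybrid(record: MarkerRecord, truth_table: pd.DataFrame) -> bool:
    row = truth_table[truth_table["record_id"] == record.record_id]
    return bool(len(row) and row["is_hybrid"].iloc[0])


def _barcode_distance(a: str, b: str) -> float:
    from .distances import pairwise_k2p
    return pairwise_k2p(a, b).d


# ---------------------------------------------------------------------------
# Marker comparison

@dataclass
class MarkerDataset:
    """One marker's records plus its trimmed multiple alignment."""

    label: str
    records: list[MarkerRecord]
    msa: MsaBlock


def compare_markers(dataset_a: MarkerDataset, dataset_b: MarkerDataset,
                    scoring: ScoringScheme = ScoringScheme()
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Side-by-side marker metrics (site statistics, identification
    success, per-level K2P summaries).  Returns (table, warnings)."""
    warnings: list[str] = []
    sp_a = {r.species for r in dataset_a.records}
    sp_b = {r.species for r in dataset_b.records}
    denom = min(len(sp_a), len(sp_b))
    if denom and len(sp_a & sp_b) / denom < 0.5:
        warnings.append(
            f"species overlap below 50% between {dataset_a.label!r} and "
            f"{dataset_b.label!r}: comparison may not be like-for-like")

    rows = []
    for ds in (dataset_a, dataset_b):
        stats = site_stats(ds.msa)
        results = _identify_raw(ds.records, scoring)
        n = len(results)
        matrix = distance_matrix(ds.msa)
        from .records import taxonomy_from_records
        taxonomy = taxonomy_from_records(ds.records)
        species_of = {r.record_id: r.species for r in ds.records}
        report = gap_report(matrix, taxonomy, species_of)
        rows.append({
            "marker": ds.label,
            "aln_length": stats.aln_length,
            "variable": stats.variable,
            "informative": stats.informative,
            "n_queries": n,
            "correct": sum(r.outcome == "correct" for r in results),
            "ambiguous": sum(r.outcome == "ambiguous" for r in results),
            "median_intra": report.to_dict()["median_intra"],
            "median_inter": report.to_dict()["median_inter"],
        })
    return pd.DataFrame(rows), warnings


def _identify_raw(records: list[MarkerRecord],
                  scoring: ScoringScheme) -> list:
    """Identification over whole sequences (no region split), for markers
    without exon/intron annotation."""
    from .identify import IdentificationResult
    bitparams = BitScoreParams.from_scoring(scoring)
    queries = select_queries(records)
    meta = {r.record_id: r for r in records}
    results = []
    for q in queries:
        subjects = [(r.record_id, r.sequence) for r in records
                    if r.record_id != q.record_id]
        hits = seeded_local_search((q.record_id, q.sequence), subjects,
                                   scoring, bitparams)
        if not hits:
            results.append(IdentificationResult(
                query_id=q.record_id, query_species=q.species,
                outcome="no_hit", hits=[], top_species=set(),
                group_correct=False))
            continue
        top_raw = hits[0].raw_score
        tops = {meta[h.subject_id].species for h in hits
                if h.raw_score == top_raw}
        outcome = ("correct" if tops == {q.species}
                   else "ambiguous" if q.species in tops else "incorrect")
        top_rec = meta[hits[0].subject_id]
        results.append(IdentificationResult(
            query_id=q.record_id, query_species=q.species, outcome=outcome,
            hits=hits, top_species=tops,
            group_correct=bool(q.species_group)
            and q.species_group == top_rec.species_group))
    return results
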