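"""Synthetic two-part barcode datasets with known truth.

The generator emulates a low-copy nuclear marker in a slowly radiating
plant family: a conserved 264-bp exon evolving under a K80 (Kimura
two-parameter) substitution process, an adjacent 100–400 bp intron
evolving several-fold faster and accumulating indels, multiple accessions
per species whose intraspecific divergence overlaps the interspecific
range, heterozygous accessions carrying two intron alleles that differ by
at least one indel, and optional F1 hybrids carrying one allele from each
of two parental species.

Hierarchy: a family root sequence diverges into subfamilies, each
subfamily into species groups (clades), and each group radiates through a
pure-birth (Yule) species tree whose branch lengths are rescaled so the
expected (or, with ``calibrate_to='min'``, the minimum expected)
between-species exon K2P equals ``exon_divergence_target``.  Accessions
hang off each species tip as a star.  Substitutions are placed per branch
by a Poisson draw of events with transition:transversion odds kappa:1;
indels never touch the exon.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .records import (EXON_V_REMNANT, MarkerRecord, MsaBlock, TaxonomyTable,
                      split_regions, taxonomy_from_records, write_fasta,
                      write_taxonomy)

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: Stem lengths of subfamily and species-group ancestors, as multiples of
#: ``exon_divergence_target``: deep splits are a few-fold older than the
#: within-group radiation, giving ordered interfamilial > intergeneric >
#: congeneric > intraspecific divergence as real markers show.
SUBFAMILY_STEM = 3.0
GROUP_STEM = 1.5

PROVENANCES = ("HD", "GOE", "BER", "WU", "RIO")


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Generator settings; defaults emulate the marker's published regime
    (interspecific exon K2P around 0.01 with overlapping intraspecific
    values, intron a few-fold faster with frequent indels, ~15% of
    accessions heterozygous for intron indels)."""

    n_subfamilies: int = 2
    n_groups_per_subfamily: int = 2
    n_species_per_group: int = 5
    accessions_per_species: int | tuple[int, int] = 3
    exon_length: int = 264
    intron_length_range: tuple[int, int] = (100, 400)
    kappa: float = 2.0
    exon_divergence_target: float = 0.01
    intron_rate_multiplier: float = 5.0
    intraspecific_divergence: float = 0.004
    indel_rate: float = 0.3
    indel_length: float = 0.25          # geometric success prob; mean 1/p = 4 nt
    het_fraction: float = 0.15
    n_hybrids: int = 0
    calibrate_to: str = "mean"          # 'mean' or 'min' expected tip-pair K2P
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subfamilies", "n_groups_per_subfamily",
                     "n_species_per_group"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in ("indel_rate", "het_fraction", "indel_length"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.calibrate_to not in ("mean", "min"):
            raise SimulationError("calibrate_to must be 'mean' or 'min'")
        # deepest expected intron path must stay far from K2P saturation
        deepest = self.exon_divergence_target * (
            2 * SUBFAMILY_STEM + 2 * GROUP_STEM + 1.0) * self.intron_rate_multiplier
        if deepest >= 2.0:
            raise SimulationError(
                f"target divergence saturates the substitution model "
                f"(deepest expected intron path {deepest:.2f} subs/site)")


@dataclass
class TruthTable:
    """Per-record truth emitted alongside the sequences."""

    table: pd.DataFrame

    def expected_class(self, rid_a: str, rid_b: str) -> str:
        """Expected divergence class of a record pair from planted taxonomy."""
        t = self.table.set_index("record_id")
        a, b = t.loc[rid_a], t.loc[rid_b]
        if a["species"] == b["species"]:
            return "intraspecific"
        if a["subfamily"] != b["subfamily"]:
            return "interfamilial"
        if a["species_group"] == b["species_group"]:
            return "congeneric"
        return "intergeneric"

    @property
    def hybrids(self) -> pd.DataFrame:
        return self.table[self.table["is_hybrid"]]


# ---------------------------------------------------------------------------
# Evolutionary operators

def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _evolve(seq: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Apply a Poisson(d·L) number of K80-style substitutions."""
    if d <= 0 or not seq:
        return seq
    n_events = rng.poisson(d * len(seq))
    if n_events == 0:
        return seq
    out = list(seq)
    p_ts = kappa / (kappa + 1.0)
    for _ in range(n_events):
        pos = int(rng.integers(len(out)))
        base = out[pos]
        if base not in TRANSITION:
            continue
        if rng.random() < p_ts:
            out[pos] = TRANSITION[base]
        else:
            out[pos] = TRANSVERSIONS[base][int(rng.integers(2))]
    return "".join(out)


def _apply_indels(seq: str, rate: float, p_len: float,
                  rng: np.random.Generator, min_length: int = 50,
                  force: bool = False) -> str:
    """Maybe apply one insertion or deletion of geometric length."""
    if not force and rng.random() >= rate:
        return seq
    length = int(rng.geometric(p_len))
    if rng.random() < 0.5 and len(seq) - length >= min_length:
        pos = int(rng.integers(0, len(seq) - length + 1))
        return seq[:pos] + seq[pos + length:]
    pos = int(rng.integers(0, len(seq) + 1))
    return seq[:pos] + _random_seq(length, rng) + seq[pos:]


# ---------------------------------------------------------------------------
# Pure-birth species tree

@dataclass
class _TreeNode:
    time: float
    children: list = field(default_factory=list)
    name: str | None = None


def _yule(n_tips: int, rng: np.random.Generator) -> tuple[_TreeNode, float]:
    """Ultrametric pure-birth tree; returns (root, tip time)."""
    root = _TreeNode(time=0.0)
    if n_tips == 1:
        root.name = "t0"
        return root, float(rng.exponential(1.0))
    active = [_TreeNode(time=0.0), _TreeNode(time=0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_tips:
        t += float(rng.exponential(1.0 / len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.time = t
        kids = [_TreeNode(time=t), _TreeNode(time=t)]
        parent.children = kids
        active.extend(kids)
    t_end = t + float(rng.exponential(1.0 / len(active)))
    for i, leaf in enumerate(active):
        leaf.name = f"t{i}"
        leaf.time_leaf = t_end  # type: ignore[attr-defined]
    return root, t_end


def _pairwise_depths(node: _TreeNode, t_end: float) -> tuple[int, list[tuple[int, float]]]:
    """(n_tips, [(pair_count, 2*(t_end - split_time)), ...]) per internal node."""
    if not node.children:
        return 1, []
    sizes, entries = [], []
    for ch in node.children:
        s, e = _pairwise_depths(ch, t_end)
        sizes.append(s)
        entries.extend(e)
    pairs = 0
    for i in range(len(sizes)):
        for j in range(i + 1, len(sizes)):
            pairs += sizes[i] * sizes[j]
    entries.append((pairs, 2.0 * (t_end - node.time)))
    return sum(sizes), entries


# ---------------------------------------------------------------------------
# Main generator

def simulate(params: SimParams) -> tuple[list[MarkerRecord], MsaBlock, TruthTable]:
    """Generate records, the true exon alignment, and the truth table.

    The exon carries no indels, so its true alignment is simply the stack
    of 264-bp exon sequences.  Returned records span the full amplicon
    (exon + intron + 14-bp downstream-exon remnant) with annotated
    boundaries.
    """
    rng = np.random.default_rng(params.seed)
    t = params.exon_divergence_target
    mult = params.intron_rate_multiplier
    kappa = params.kappa

    root_exon = _random_seq(params.exon_length, rng)
    lo, hi = params.intron_length_range
    root_intron = _random_seq(int(rng.integers(lo, hi + 1)), rng)
    remnant = _random_seq(EXON_V_REMNANT, rng)

    records: list[MarkerRecord] = []
    truth_rows: list[dict] = []
    species_tip: dict[str, tuple[str, str]] = {}   # species -> (exon, intron)
    species_meta: dict[str, dict] = {}

    for sf in range(params.n_subfamilies):
        subfam = f"Subfamily{sf + 1}"
        sf_exon = _evolve(root_exon, SUBFAMILY_STEM * t, kappa, rng)
        sf_intron = _apply_indels(
            _evolve(root_intron, SUBFAMILY_STEM * t * mult, kappa, rng),
            params.indel_rate, params.indel_length, rng)
        for gr in range(params.n_groups_per_subfamily):
            group = f"Clade{sf + 1}.{gr + 1}"
            g_exon = _evolve(sf_exon, GROUP_STEM * t, kappa, rng)
            g_intron = _apply_indels(
                _evolve(sf_intron, GROUP_STEM * t * mult, kappa, rng),
                params.indel_rate, params.indel_length, rng)

            tree, t_end = _yule(params.n_species_per_group, rng)
            _, entries = _pairwise_depths(tree, t_end)
            tip_extra = 0.0
            if entries:
                total_pairs = sum(p for p, _ in entries)
                ref = (sum(p * d for p, d in entries) / total_pairs
                       if total_pairs else t_end)
                scale = t / ref if ref > 0 else 0.0
                if params.calibrate_to == "min":
                    # lengthen every terminal branch just enough that the
                    # shallowest species pair still meets the target
                    min_d = min(d for p, d in entries if p) * scale
                    tip_extra = max(0.0, (t - min_d) / 2.0)
            else:
                scale = t / (2.0 * t_end) if t_end > 0 else 0.0

            def descend(node: _TreeNode, exon: str, intron: str,
                        parent_time: float) -> None:
                blen = (getattr(node, "time_leaf", node.time) - parent_time) * scale
                if not node.children:
                    blen += tip_extra
                exon = _evolve(exon, blen, kappa, rng)
                intron = _apply_indels(_evolve(intron, blen * mult, kappa, rng),
                                       params.indel_rate, params.indel_length, rng)
                if not node.children:
                    sp = f"Sp{sf + 1}.{gr + 1}.{node.name[1:]}"
                    species_tip[sp] = (exon, intron)
                    species_meta[sp] = {"genus": f"Genus{sf + 1}.{gr + 1}",
                                        "subfamily": subfam, "species_group": group}
                else:
                    for ch in node.children:
                        descend(ch, exon, intron, node.time)

            for ch in (tree.children or [tree]):
                descend(ch, g_exon, g_intron, tree.time)

    intra = params.intraspecific_divergence / 2.0
    if isinstance(params.accessions_per_species, tuple):
        acc_lo, acc_hi = params.accessions_per_species
    else:
        acc_lo = acc_hi = params.accessions_per_species

    def emit_individual(base_id: str, species: str, provenance: str,
                        exon: str, intron: str, is_het: bool,
                        is_hybrid: bool = False, parent_a: str = "",
                        parent_b: str = "",
                        second: tuple[str, str] | None = None) -> None:
        meta = species_meta.get(species) or {"genus": "HybGenus",
                                             "subfamily": species_meta[parent_a]["subfamily"],
                                             "species_group": ""}
        alleles: list[tuple[str, str, str]] = []
        if is_het or second is not None:
            if second is None:
                # heterozygous intron alleles differ by at least one indel
                intron2 = _apply_indels(intron, 1.0, params.indel_length, rng,
                                        force=True)
                second = (exon, intron2)
            alleles = [("a1", exon, intron), ("a2", *second)]
        else:
            alleles = [("", exon, intron)]
        for allele, ex, intr in alleles:
            rid = f"{base_id}.{allele}" if allele else base_id
            seq = ex + intr + remnant
            records.append(MarkerRecord(
                record_id=rid, species=species, genus=meta["genus"],
                subfamily=meta["subfamily"],
                species_group=meta["species_group"] or None,
                provenance=provenance, allele_id=allele or None,
                sequence=seq, exon_end=len(ex), intron_end=len(ex) + len(intr)))
            truth_rows.append({
                "record_id": rid, "individual_id": base_id, "species": species,
                "species_group": meta["species_group"], "subfamily": meta["subfamily"],
                "provenance": provenance, "allele_id": allele,
                "is_het": bool(allele), "is_hybrid": is_hybrid,
                "parent_a": parent_a, "parent_b": parent_b,
                "exon_end": len(ex), "intron_end": len(ex) + len(intr),
                "exon_seq": ex, "intron_seq": intr})

    for sp in sorted(species_tip):
        exon0, intron0 = species_tip[sp]
        n_acc = int(rng.integers(acc_lo, acc_hi + 1)) if acc_hi > acc_lo else acc_lo
        for k in range(n_acc):
            exon = _evolve(exon0, intra, kappa, rng)
            intron = _apply_indels(_evolve(intron0, intra * mult, kappa, rng),
                                   params.indel_rate * 0.5, params.indel_length, rng)
            is_het = rng.random() < params.het_fraction
            base_id = f"{sp}-{k + 1:02d}"
            emit_individual(base_id, sp, PROVENANCES[k % len(PROVENANCES)],
                            exon, intron, is_het)

    all_species = sorted(species_tip)
    for h in range(params.n_hybrids):
        if len(all_species) < 2:
            raise SimulationError("hybrids need at least 2 parental species")
        # prefer parents from different species groups for a clean signal
        pa = all_species[int(rng.integers(len(all_species)))]
        others = [s for s in all_species
                  if species_meta[s]["species_group"]
                  != species_meta[pa]["species_group"]] or \
                 [s for s in all_species if s != pa]
        pb = others[int(rng.integers(len(others)))]
        exon_a = _evolve(species_tip[pa][0], intra, kappa, rng)
        intron_a = _evolve(species_tip[pa][1], intra * mult, kappa, rng)
        exon_b = _evolve(species_tip[pb][0], intra, kappa, rng)
        intron_b = _evolve(species_tip[pb][1], intra * mult, kappa, rng)
        emit_individual(f"Hyb{h + 1}", f"Hybrid{h + 1}", PROVENANCES[h % len(PROVENANCES)],
                        exon_a, intron_a, is_het=True, is_hybrid=True,
                        parent_a=pa, parent_b=pb, second=(exon_b, intron_b))

    truth = TruthTable(pd.DataFrame(truth_rows))
    exon_msa = MsaBlock(
        ids=[r["record_id"] for r in truth_rows],
        rows=[r["exon_seq"] for r in truth_rows])
    return records, exon_msa, truth


def emit_dataset(records: list[MarkerRecord], truth: TruthTable,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset files every downstream module consumes.

    ``barcodes.fasta`` holds exon+intron (downstream-exon remnant cut),
    ``exon.fasta`` the exon trimmed to 264 bp, plus ``truth.tsv`` and
    ``taxonomy.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in [
        ("barcodes", "barcodes.fasta"), ("exon", "exon.fasta"),
        ("truth", "truth.tsv"), ("taxonomy", "taxonomy.tsv")]}

    barcode_recs, exon_recs = [], []
    for r in records:
        exon, intron = split_regions(r)
        barcode_recs.append(r.with_sequence(exon + intron, exon_end=len(exon),
                                            intron_end=len(exon) + len(intron)))
        exon_recs.append(r.with_sequence(exon, exon_end=len(exon),
                                         intron_end=len(exon)))
    write_fasta(barcode_recs, paths["barcodes"])
    write_fasta(exon_recs, paths["exon"])
    truth.table.drop(columns=["exon_seq", "intron_seq"]).to_csv(
        paths["truth"], sep="\t", index=False)
    write_taxonomy(taxonomy_from_records(records), paths["taxonomy"])
    return paths
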