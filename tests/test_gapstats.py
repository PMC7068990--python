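"""Distance partitions and the rank-sum test against enumeration/scipy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from agtbarcode.distances import DistanceMatrix, distance_matrix
from agtbarcode.gapstats import (GapStatsError, classify_pairs, gap_report,
                                 partition_distances, wilcoxon_rank_sum)
from agtbarcode.records import MarkerRecord, MsaBlock, taxonomy_from_records


def enumeration_p(a, b):
    """Independent exact two-sided p: enumerate all rank assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(pooled)
    mean = len(a) * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), len(a)):
        total += 1
        if abs(sum(combo) - mean) >= abs(w_obs - mean) - 1e-9:
            count += 1
    return count / total


def tax_and_matrix(accessions):
    """Build a tiny DistanceMatrix + taxonomy. ``accessions`` maps
    record id -> (species, group, subfamily, distance seedling)."""
    ids = sorted(accessions)
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                vals[i, j] = abs(accessions[ids[i]][3] - accessions[ids[j]][3]) + 0.001
    records = [MarkerRecord(record_id=r, species=accessions[r][0], genus="G",
                            subfamily=accessions[r][2], species_group=accessions[r][1],
                            provenance="HD", sequence="ACGT")
               for r in ids]
    tax = taxonomy_from_records(records)
    species_of = {r: accessions[r][0] for r in ids}
    return DistanceMatrix(ids=ids, values=vals, mask=np.zeros((n, n), bool)), tax, species_of


class TestPartitionDistances:
    def test_three_conspecific_accessions(self):
        m, tax, sof = tax_and_matrix({
            "a1": ("sp1", "g", "SF", 0.0), "a2": ("sp1", "g", "SF", 0.1),
            "a3": ("sp1", "g", "SF", 0.2)})
        intra, other = partition_distances(m, tax, sof, "intraspecific")
        assert len(intra) == 3 and len(other) == 0

    def test_two_singleton_species(self):
        m, tax, sof = tax_and_matrix({
            "a1": ("sp1", "g", "SF", 0.0), "b1": ("sp2", "g", "SF", 0.5)})
        intra, other = partition_distances(m, tax, sof, "intraspecific")
        assert len(intra) == 0 and len(other) == 1

    def test_planted_11x5_pair_count(self):
        acc = {}
        for s in range(11):
            for k in range(5):
                acc[f"s{s:02d}a{k}"] = (f"sp{s}", "g", "SF", s + 0.01 * k)
        m, tax, sof = tax_and_matrix(acc)
        intra, other = partition_distances(m, tax, sof, "intraspecific")
        assert len(intra) == 11 * 10   # 11 * C(5,2)
        assert len(intra) + len(other) == 55 * 54 // 2

    def test_levels_disjoint_and_cover(self):
        acc = {"a1": ("sp1", "g1", "SF1", 0.0), "a2": ("sp1", "g1", "SF1", 0.1),
               "b1": ("sp2", "g1", "SF1", 0.4), "c1": ("sp3", "g2", "SF1", 0.9),
               "d1": ("sp4", "g3", "SF2", 1.9)}
        m, tax, sof = tax_and_matrix(acc)
        table = classify_pairs(m, tax, sof)
        total = 0
        for level in ("intraspecific", "congeneric", "intergeneric", "interfamilial"):
            at, other = partition_distances(m, tax, sof, level)
            total += len(at)
            assert len(at) + len(other) == len(table)
        assert total == len(table) == 10

    def test_unknown_level(self):
        m, tax, sof = tax_and_matrix({"a1": ("sp1", "g", "SF", 0.0),
                                      "a2": ("sp1", "g", "SF", 0.1)})
        with pytest.raises(GapStatsError):
            partition_distances(m, tax, sof, "galactic")


class TestWilcoxonRankSum:
    def test_exact_extreme_arrangement(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.5, 1.5, 1.5], [1.5, 1.5])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = list(np.round(rng.normal(size=5), 6))
            b = list(np.round(rng.normal(0.5, size=6), 6))
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(enumeration_p(a, b), abs=1e-9)

    def test_normal_approx_matches_scipy(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(0.3, size=45)
        w, p = wilcoxon_rank_sum(list(a), list(b))
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_and_normal_agree_at_boundary(self, rng):
        # 8 vs 8 tie-free sits on the exact/normal boundary: the two p-values
        # should track each other closely (continuity correction leaves a
        # wobble of about 0.01 near p ~ 0.5)
        diffs = []
        for shift in (0.0, 0.4, 0.8, 1.2):
            for _ in range(10):
                a = list(np.round(rng.normal(size=8), 6))
                b = list(np.round(rng.normal(shift, size=8), 6))
                _, p_exact = wilcoxon_rank_sum(a, b)
                ref = mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
                diffs.append(abs(p_exact - ref))
        assert np.mean(diffs) < 0.01
        assert max(diffs) < 0.02

    def test_monotone_transform_invariance(self, rng):
        a = list(rng.normal(size=12))
        b = list(rng.normal(0.4, size=15))
        _, p1 = wilcoxon_rank_sum(a, b)
        _, p2 = wilcoxon_rank_sum([np.exp(x) for x in a], [np.exp(x) for x in b])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_sample_error(self):
        with pytest.raises(GapStatsError):
            wilcoxon_rank_sum([], [1.0])

    def test_type_one_error_calibration(self):
        # 2000 null replicates at n=50/50: rejection rate close to alpha
        rng = np.random.default_rng(20240917)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            _, p = wilcoxon_rank_sum(list(x), list(y))
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestGapReport:
    def test_planted_disjoint_no_overlap(self):
        acc = {}
        for s in range(3):
            for k in range(3):
                acc[f"s{s}a{k}"] = (f"sp{s}", "g", "SF", 10.0 * s + 0.0005 * k)
        m, tax, sof = tax_and_matrix(acc)
        report = gap_report(m, tax, sof)
        assert report.overlap is False
        assert report.p_value is not None and report.p_value < 0.001

    def test_planted_overlap_detected(self, small_dataset):
        _, _, exon_msa, truth = small_dataset
        from agtbarcode.records import taxonomy_from_records as tfr
        m = distance_matrix(exon_msa)
        records_tax = truth.table
        recs = [MarkerRecord(record_id=r["record_id"], species=r["species"],
                             genus="G", subfamily=r["subfamily"],
                             species_group=r["species_group"], provenance="HD",
                             sequence="ACGT")
                for _, r in records_tax.iterrows()]
        tax = tfr(recs)
        sof = dict(zip(records_tax["record_id"], records_tax["species"]))
        report = gap_report(m, tax, sof)
        # slow exon + low intraspecific divergence: distributions overlap
        # (identical sequences occur both within and between species)
        assert report.n_intra > 0 and report.n_inter > 0
        assert report.p_value is not None
        if report.overlap:
            lo, hi = report.overlap_interval
            assert lo <= hi

    def test_single_species_warning_path(self):
        m, tax, sof = tax_and_matrix({
            "a1": ("sp1", "g", "SF", 0.0), "a2": ("sp1", "g", "SF", 0.1),
            "a3": ("sp1", "g", "SF", 0.2)})
        report = gap_report(m, tax, sof)
        assert report.p_value is None
        assert report.warning is not None
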