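"""Kimura two-parameter distances and alignment column statistics.

The K2P model distinguishes transitions (purine↔purine, pyrimidine↔
pyrimidine) from transversions.  With observed transition proportion P and
transversion proportion Q over the compared sites, the distance is

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

Sites where either sequence carries a gap or an ambiguity code are
excluded pairwise (pairwise deletion, the common distance-analysis
default); set ``deletion='complete'`` on :func:`distance_matrix` to drop
any column with a gap/ambiguity in any row instead.  When the observed
proportions saturate the model (the log arguments become non-positive) the
distance is undefined; :func:`k2p` raises and :func:`distance_matrix`
masks the pair rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import GAP, UNAMBIGUOUS, MsaBlock

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Observed divergence outside the K2P model's valid range."""


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class K2PResult:
    d: float
    P: float
    Q: float
    n_sites: int


@dataclass(frozen=True)
class SiteStats:
    aln_length: int
    variable: int
    informative: int


@dataclass
class DistanceMatrix:
    """Symmetric K2P matrix with a mask for saturated/uncomputable pairs."""

    ids: list[str]
    values: np.ndarray          # (n, n) float, nan where masked
    mask: np.ndarray            # (n, n) bool, True = unavailable

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise DistanceError("matrix shape does not match id count")

    def get(self, id_a: str, id_b: str) -> float | None:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return None if self.mask[i, j] else float(self.values[i, j])

    @property
    def is_complete(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return not self.mask[off].any()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two rows of an alignment (pairwise deletion).

    Both inputs must have equal (aligned) length; gap and ambiguity
    positions in either row are skipped.  Raises :class:`SaturationError`
    when 1−2P−Q ≤ 0 or 1−2Q ≤ 0, and :class:`DistanceError` when no site
    is comparable.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise DistanceError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        n += 1
        if x != y:
            if _is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise DistanceError("no comparable sites (all gaps/ambiguities)")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} (saturated)")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(d=float(d), P=P, Q=Q, n_sites=n)


def site_stats(msa: MsaBlock, gap_policy: str = "exclude") -> SiteStats:
    """Count variable and parsimony-informative columns of an alignment.

    A column is *variable* when at least two distinct states occur, and
    *parsimony-informative* when at least two states each occur in at
    least two rows.  Under the default ``gap_policy='exclude'`` gaps and
    ambiguity codes never count as states (the usual convention of
    alignment-statistics software); ``gap_policy='fifth_state'`` treats
    the gap character as an additional state.
    """
    if gap_policy not in ("exclude", "fifth_state"):
        raise DistanceError(f"unknown gap_policy {gap_policy!r}")
    variable = informative = 0
    for j in range(msa.n_columns):
        counts: dict[str, int] = {}
        for c in msa.column(j):
            if c in UNAMBIGUOUS or (gap_policy == "fifth_state" and c == GAP):
                counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
    return SiteStats(aln_length=msa.n_columns, variable=variable,
                     informative=informative)


def distance_matrix(msa: MsaBlock, deletion: str = "pairwise") -> DistanceMatrix:
    """All pairwise K2P distances of an alignment; saturated pairs masked."""
    if msa.n_rows < 2:
        raise DistanceError("need at least two rows")
    rows = msa.rows
    if deletion == "complete":
        keep = [j for j in range(msa.n_columns)
                if all(r[j] in UNAMBIGUOUS for r in rows)]
        rows = ["".join(r[j] for j in keep) for r in rows]
    elif deletion != "pairwise":
        raise DistanceError(f"unknown deletion mode {deletion!r}")
    n = msa.n_rows
    vals = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                vals[i, j] = vals[j, i] = k2p(rows[i], rows[j]).d
            except (SaturationError, DistanceError):
                vals[i, j] = vals[j, i] = np.nan
                mask[i, j] = mask[j, i] = True
    return DistanceMatrix(ids=list(msa.ids), values=vals, mask=mask)


def pairwise_k2p(seq_a: str, seq_b: str, scoring=None) -> K2PResult:
    """K2P between two *unaligned* sequences via banded global alignment."""
    from .align import ScoringScheme, global_align
    aln = global_align(seq_a, seq_b, scoring or ScoringScheme())
    return k2p(aln.a_aligned, aln.b_aligned)


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix (masked entries written as -1.0)."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, rid in enumerate(matrix.ids):
            row = ["-1.000000" if matrix.mask[i, j] else f"{matrix.values[i, j]:.6f}"
                   for j in range(len(matrix.ids))]
            fh.write(f"{rid:<10s} " + " ".join(row) + "\n")


def write_matrix_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t")
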