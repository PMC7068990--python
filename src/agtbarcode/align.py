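"""Pairwise alignment engines and megablast-style hit statistics.

Two engines share one linear-gap scoring scheme:

* a banded global aligner used for identity computation (the clustering
  module's workhorse), with the CD-HIT-EST convention that identity is the
  number of identical aligned positions divided by the length of the
  *shorter* sequence, so that terminal indels do not dilute identity;
* a word-seeded local aligner in the megablast mould: only subjects that
  share at least one exact word of ``word_size`` with the query are
  aligned (full Smith–Waterman with linear gaps on the survivors), and
  hits are ranked by Karlin–Altschul bit score with E-value filtering.

Raw scores are integers.  The ungapped Karlin–Altschul λ is always solved
from the scoring scheme (the unique positive root of
``Σ pᵢpⱼ·exp(λ·s(i,j)) = 1``); K defaults to 0.62 and only shifts bit
scores by a constant, so every ranking decision downstream is K-free.

The dynamic programming inner loops are JIT-compiled (numba), so whole
reference databases of a few hundred sequences align in seconds while the
recurrences stay written out explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numba
import numpy as np
from scipy.optimize import brentq

from .records import MarkerRecord

NEG = np.int32(-(2 ** 30))
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Megablast-style scoring: +1 match, −2 mismatch, linear gap cost."""

    match: int = 1
    mismatch: int = -2
    gap_per_position: int = 2
    word_size: int = 28
    max_evalue: float = 10.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise AlignmentError("require match > 0 > mismatch")
        if self.gap_per_position <= 0:
            raise AlignmentError("gap_per_position must be positive")
        if self.word_size < 4:
            raise AlignmentError("word_size must be >= 4")


@dataclass(frozen=True)
class BitScoreParams:
    """Karlin–Altschul parameters for bit-score / E-value conversion."""

    lambda_: float
    k_const: float = 0.62
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise AlignmentError("lambda_ and k_const must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise AlignmentError("background must sum to 1")

    @classmethod
    def from_scoring(cls, scoring: ScoringScheme,
                     background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                     k_const: float = 0.62) -> "BitScoreParams":
        lam = solve_lambda(scoring, background)
        return cls(lambda_=lam, k_const=k_const, background=tuple(background))


@dataclass
class Alignment:
    """One pairwise alignment with its traceback."""

    score: int
    matches: int
    aligned_length: int
    a_aligned: str
    b_aligned: str
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    @property
    def query_end(self) -> int:
        return self.a_end


@dataclass
class PairwiseHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    aligned_length: int
    alignment: tuple[str, str]


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics

def solve_lambda(scoring: ScoringScheme,
                 background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> float:
    """Solve the ungapped Karlin–Altschul λ for a match/mismatch scheme.

    λ is the unique positive root of ``Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1``; with a
    uniform background and +1/−2 scoring this is
    ``0.25·e^λ + 0.75·e^{−2λ} = 1``.  Requires a negative expected score,
    otherwise no positive root exists.
    """
    p = np.asarray(background, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise AlignmentError("background must sum to 1")
    p_match = float(np.sum(p * p))
    p_mismatch = 1.0 - p_match
    expected = p_match * scoring.match + p_mismatch * scoring.mismatch
    if expected >= 0:
        raise AlignmentError(
            f"expected score per pair is {expected:.4f} >= 0; no positive lambda"
        )

    def f(lam: float) -> float:
        return (p_match * math.exp(lam * scoring.match)
                + p_mismatch * math.exp(lam * scoring.mismatch) - 1.0)

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-9))


def bit_score(raw_score: int, params: BitScoreParams) -> float:
    """Normalised score S' = (λS − ln K) / ln 2."""
    return (params.lambda_ * raw_score - math.log(params.k_const)) / math.log(2.0)


def evalue(raw_score: int, query_len: int, subject_total_len: int,
           params: BitScoreParams) -> float:
    """Expected chance hits: E = K·m·n·e^{−λS} (no edge correction)."""
    if query_len <= 0 or subject_total_len <= 0:
        raise AlignmentError("lengths must be positive")
    return (params.k_const * query_len * subject_total_len
            * math.exp(-params.lambda_ * raw_score))


# ---------------------------------------------------------------------------
# Dynamic programming cores

def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; ambiguity codes to 4 (never match anything)."""
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8,
                       count=len(seq))


@numba.njit(cache=False)
def _global_banded_kernel(a, b, match, mismatch, gap, w):  # pragma: no cover
    la, lb = a.shape[0], b.shape[0]
    neg = np.int32(-(2 ** 30))
    H = np.full((la + 1, lb + 1), neg, dtype=np.int32)
    H[0, 0] = 0
    for j in range(1, min(lb, w) + 1):
        H[0, j] = -gap * j
    for i in range(1, la + 1):
        if i <= w:
            H[i, 0] = -gap * i
        lo = 1 if i - w < 1 else i - w
        hi = lb if i + w > lb else i + w
        for j in range(lo, hi + 1):
            ai = a[i - 1]
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            h2 = H[i - 1, j] - gap
            if h2 > h:
                h = h2
            h3 = H[i, j - 1] - gap
            if h3 > h:
                h = h3
            H[i, j] = h
    return H


@numba.njit(cache=False)
def _local_kernel(a, b, match, mismatch, gap):  # pragma: no cover
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1), dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            h2 = H[i - 1, j] - gap
            if h2 > h:
                h = h2
            h3 = H[i, j - 1] - gap
            if h3 > h:
                h = h3
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, bi, bj


def global_align(seq_a: str, seq_b: str, scoring: ScoringScheme = ScoringScheme(),
                 band_extra: int = 32, band: int | None = None) -> Alignment:
    """Banded global (Needleman–Wunsch, linear gaps) alignment.

    The band allows ``|i − j| ≤ |len_a − len_b| + band_extra``, wide enough
    for the intron-indel-driven length differences this marker shows; pass
    ``band`` explicitly to override.  Traceback prefers diagonal, then
    up (gap in b), then left, making the reported alignment deterministic.
    """
    if not seq_a or not seq_b:
        raise AlignmentError("sequences must be non-empty")
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    la, lb = len(a), len(b)
    w = band if band is not None else abs(la - lb) + band_extra
    H = _global_banded_kernel(a, b, scoring.match, scoring.mismatch,
                              scoring.gap_per_position, w)
    if H[la, lb] <= NEG // 2:
        raise AlignmentError("band too narrow for a complete global path")
    return _traceback(H, a, b, seq_a.upper(), seq_b.upper(), scoring,
                      la, lb, local=False)


def local_align(seq_a: str, seq_b: str,
                scoring: ScoringScheme = ScoringScheme()) -> Alignment:
    """Smith–Waterman local alignment with linear gap costs (full matrix)."""
    if not seq_a or not seq_b:
        raise AlignmentError("sequences must be non-empty")
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    H, bi, bj = _local_kernel(a, b, scoring.match, scoring.mismatch,
                              scoring.gap_per_position)
    return _traceback(H, a, b, seq_a.upper(), seq_b.upper(), scoring,
                      bi, bj, local=True)


def _traceback(H: np.ndarray, a: np.ndarray, b: np.ndarray,
               sa: str, sb: str, scoring: ScoringScheme,
               i: int, j: int, local: bool) -> Alignment:
    g = scoring.gap_per_position
    end_i, end_j = i, j
    out_a: list[str] = []
    out_b: list[str] = []
    matches = 0
    score = int(H[i, j])
    while i > 0 or j > 0:
        h = int(H[i, j])
        if local and h == 0:
            break
        if i > 0 and j > 0:
            s = scoring.match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else scoring.mismatch
            if h == int(H[i - 1, j - 1]) + s:
                out_a.append(sa[i - 1]); out_b.append(sb[j - 1])
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1; j -= 1
                continue
        if i > 0 and h == int(H[i - 1, j]) - g:
            out_a.append(sa[i - 1]); out_b.append("-")
            i -= 1
            continue
        if j > 0 and h == int(H[i, j - 1]) - g:
            out_a.append("-"); out_b.append(sb[j - 1])
            j -= 1
            continue
        raise AlignmentError("traceback failed (inconsistent DP matrix)")
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return Alignment(score=score, matches=matches, aligned_length=len(aligned_a),
                     a_aligned=aligned_a, b_aligned=aligned_b,
                     a_start=i, a_end=end_i, b_start=j, b_end=end_j)


# ---------------------------------------------------------------------------
# Identity and seeded search

def global_identity(seq_a: str, seq_b: str,
                    scoring: ScoringScheme = ScoringScheme(),
                    band_extra: int = 32,
                    denominator: str = "shorter") -> tuple[float, int, int]:
    """Identity between two sequences from banded global alignment.

    Returns ``(identity, matches, aligned_length)`` with identity counted
    over the shorter sequence's length (CD-HIT-EST convention) by default;
    ``denominator='alignment'`` divides by alignment columns instead.
    """
    aln = global_align(seq_a, seq_b, scoring, band_extra=band_extra)
    if denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "alignment":
        denom = aln.aligned_length
    else:
        raise AlignmentError(f"unknown identity denominator {denominator!r}")
    return aln.matches / denom, aln.matches, aln.aligned_length


def _words(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def seeded_local_search(query: MarkerRecord | tuple[str, str],
                        database: Iterable[MarkerRecord | tuple[str, str]],
                        scoring: ScoringScheme = ScoringScheme(),
                        bitparams: BitScoreParams | None = None) -> list[PairwiseHit]:
    """Word-seeded local search of a query against a sequence database.

    Only subjects sharing at least one exact ``word_size``-mer with the
    query are aligned (queries shorter than the word size fall back to
    aligning everything).  Hits with E-value above ``scoring.max_evalue``
    are discarded; survivors are sorted by descending bit score with ties
    broken by subject id, so results are reproducible.
    """
    qid, qseq = _as_pair(query)
    db = [_as_pair(s) for s in database]
    if not db:
        return []
    if bitparams is None:
        bitparams = BitScoreParams.from_scoring(scoring)
    total_len = sum(len(s) for _, s in db)
    k = scoring.word_size
    qwords = _words(qseq, k) if len(qseq) >= k else None

    hits: list[PairwiseHit] = []
    for sid, sseq in db:
        if qwords is not None:
            if len(sseq) < k or not (qwords & _words(sseq, k)):
                continue
        aln = local_align(qseq, sseq, scoring)
        if aln.aligned_length == 0:
            continue
        e = evalue(aln.score, len(qseq), total_len, bitparams)
        if e > scoring.max_evalue:
            continue
        hits.append(PairwiseHit(
            query_id=qid, subject_id=sid, raw_score=aln.score,
            bit_score=bit_score(aln.score, bitparams), evalue=e,
            identity=aln.matches / aln.aligned_length,
            aligned_length=aln.aligned_length,
            alignment=(aln.a_aligned, aln.b_aligned)))
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


def _as_pair(item: MarkerRecord | tuple[str, str]) -> tuple[str, str]:
    if isinstance(item, MarkerRecord):
        return item.record_id, item.sequence
    rid, seq = item
    return rid, seq.upper()


def hits_to_rows(hits: Iterable[PairwiseHit]) -> list[dict]:
    """Hit table rows in the fixed TSV column order."""
    return [{"query_id": h.query_id, "subject_id": h.subject_id,
             "raw_score": h.raw_score, "bit_score": round(h.bit_score, 3),
             "evalue": h.evalue, "identity": round(h.identity, 5),
             "aligned_length": h.aligned_length} for h in hits]
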