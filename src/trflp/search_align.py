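"""Closest-reference retrieval and exact local alignment.

A sample is first matched against the reference subset by counting
distinct shared k-mers (a seeded nearest-neighbour search standing in
for a heuristic homology search), and the top candidates are then
re-ranked by exact Smith-Waterman alignment under affine gap scoring.

Scoring defaults follow the two classic tools for these steps: match
+5 / mismatch -4 (megablast-style nucleotide scoring) and gap open 10 /
gap extend 0.5 (EMBOSS ``water`` defaults).  A gap of length L costs
``gap_open + L * gap_extend``.  Percent identity counts identical
columns over ALL alignment columns, gap columns included (EMBOSS
convention).

Traceback is deterministic: ties prefer diagonal over up (gap in the
second sequence) over left, and the alignment ends at the first maximal
cell in row-major order, so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (non-ACGT -> 4, matches nothing)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class SearchHit:
    """One ranked reference candidate for a sample."""

    ref_id: str
    seed_score: int
    sw_score: float
    rank: int


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment with 1-based inclusive coordinates on both sequences."""

    sample_start: int
    sample_end: int
    ref_start: int
    ref_end: int
    score: float
    percent_identity: float
    aligned_sample: str
    aligned_ref: str

    def __post_init__(self) -> None:
        if len(self.aligned_sample) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")


# Traceback pointer codes for the H (match) state.
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):
    """DP fill for local alignment with affine gaps.

    Returns (best score, end row, end col, H-state pointers, E pointers,
    F pointers).  E is the "gap in a / move left" state, F the "gap in
    b / move up" state; their pointers record whether the gap was opened
    (1) or extended (0).  Opening is preferred on ties so gaps are
    reported as late-opened and traceback stays deterministic.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), -1e30, dtype=np.float64)
    F = np.full((m + 1, n + 1), -1e30, dtype=np.float64)
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
                ptr_e[i, j] = 0
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
                ptr_f[i, j] = 0
            if ai == b[j - 1] and ai < 4:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] + mismatch
            p = _DIAG
            if F[i, j] > h:
                h = F[i, j]
                p = _UP
            if E[i, j] > h:
                h = E[i, j]
                p = _LEFT
            if h <= 0.0:
                h = 0.0
                p = _STOP
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr_h, ptr_e, ptr_f


try:  # the jitted kernel is a drop-in for the pure-Python fill
    from numba import njit

    _sw_fill = njit(cache=True)(_sw_fill)  # type: ignore[assignment]
except Exception:  # pragma: no cover - numba present in supported envs
    logger.warning("numba unavailable; Smith-Waterman runs in pure Python")


def smith_waterman(a: str, b: str, params: ScoringParams = ScoringParams()) -> AlignmentResult:
    """Optimal local alignment of ``a`` against ``b`` (affine gaps).

    Tie preference in traceback: diagonal > up > left; the alignment
    ends at the earliest maximal cell in row-major order.  A zero score
    yields an empty alignment anchored at (0, 0).
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    ea, eb = _encode(a), _encode(b)
    best, bi, bj, ptr_h, ptr_e, ptr_f = _sw_fill(
        ea, eb, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    if best <= 0.0:
        return AlignmentResult(
            sample_start=0, sample_end=0, ref_start=0, ref_end=0,
            score=0.0, percent_identity=0.0, aligned_sample="", aligned_ref="",
        )
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                cols_a.append(a[i - 1])
                cols_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif p == _UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            opened = ptr_f[i, j]
            i -= 1
            if opened:
                state = "H"
        else:  # E
            cols_a.append("-")
            cols_b.append(b[j - 1])
            opened = ptr_e[i, j]
            j -= 1
            if opened:
                state = "H"
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    total = len(aligned_a)
    ident = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return AlignmentResult(
        sample_start=i + 1, sample_end=bi,
        ref_start=j + 1, ref_end=bj,
        score=float(best),
        percent_identity=100.0 * ident / total if total else 0.0,
        aligned_sample=aligned_a, aligned_ref=aligned_b,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _subset_kmer_index(subset, k: int) -> dict[str, set[str]]:
    """Per-reference distinct k-mer sets, cached on the subset object."""
    cache = getattr(subset, "_kmer_index", None)
    if cache is None or cache[0] != k:
        index = {r.id: _kmer_set(r.ungapped_seq, k) for r in subset.records}
        subset._kmer_index = (k, index)
        return index
    return cache[1]


def seed_rank(sample: str, subset, k: int = 11, top_m: int = 25) -> list[str]:
    """Rank references by distinct shared k-mers with the sample.

    Returns at most ``top_m`` reference ids ordered by descending shared
    k-mer count, ties broken by ascending ref_id.  References sharing no
    k-mer at all are not candidates (no seed, no hit).  A sample shorter
    than ``k`` yields an empty list (with a warning).
    """
    if k < 4:
        raise ValueError(f"k must be >= 4, got {k}")
    if len(sample) < k:
        logger.warning("sample (len %d) shorter than k=%d; no candidates", len(sample), k)
        return []
    sample_kmers = _kmer_set(sample, k)
    index = _subset_kmer_index(subset, k)
    scored = sorted(
        ((len(sample_kmers & kmers), rid) for rid, kmers in index.items()
         if sample_kmers & kmers),
        key=lambda t: (-t[0], t[1]),
    )
    return [rid for _, rid in scored[:top_m]]


def seed_counts(sample: str, subset, k: int = 11) -> dict[str, int]:
    """Distinct shared k-mer count for every reference in the subset."""
    if len(sample) < k:
        return {r.id: 0 for r in subset.records}
    sample_kmers = _kmer_set(sample, k)
    index = _subset_kmer_index(subset, k)
    return {rid: len(sample_kmers & kmers) for rid, kmers in index.items()}


def best_hits(
    sample: str,
    subset,
    n: int = 1,
    k: int = 11,
    top_m: int = 25,
    params: ScoringParams = ScoringParams(),
) -> list[tuple[SearchHit, AlignmentResult]]:
    """The ``n`` closest references by exact local alignment.

    The ``top_m`` seed candidates are aligned with Smith-Waterman and
    ordered by sw_score (desc), then seed_score (desc), then ref_id
    (asc).  Candidates with a zero alignment score are dropped; an empty
    result marks the sample unassignable.
    """
    if not subset.records:
        raise ValueError("reference subset is empty")
    counts = seed_counts(sample, subset, k)
    candidates = seed_rank(sample, subset, k=k, top_m=top_m)
    scored = []
    for rid in candidates:
        aln = smith_waterman(sample, subset.by_id[rid].ungapped_seq, params)
        if aln.score > 0:
            scored.append((rid, counts[rid], aln))
    scored.sort(key=lambda t: (-t[2].score, -t[1], t[0]))
    out = []
    for rank, (rid, seeds, aln) in enumerate(scored[:n], start=1):
        out.append((SearchHit(ref_id=rid, seed_score=seeds, sw_score=aln.score, rank=rank), aln))
    if not out:
        logger.warning("no reference aligned with positive score; sample unassignable")
    return out


def format_alignment_text(sample_id: str, ref_id: str, aln: AlignmentResult,
                          width: int = 60) -> str:
    """Plain-text pairwise alignment dump for manual inspection."""
    lines = [
        f"# {sample_id} vs {ref_id}",
        f"# score: {aln.score:.1f}  identity: {aln.percent_identity:.2f}%",
        f"# sample {aln.sample_start}-{aln.sample_end}  reference {aln.ref_start}-{aln.ref_end}",
    ]
    for off in range(0, len(aln.aligned_sample), width):
        sa = aln.aligned_sample[off:off + width]
        sr = aln.aligned_ref[off:off + width]
        midline = "".join("|" if x == y and x != "-" else " " for x, y in zip(sa, sr))
        lines += [f"  smp {sa}", f"      {midline}", f"  ref {sr}", ""]
    return "\n".join(lines)
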