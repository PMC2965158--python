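"""Independent brute-force oracles used to check the fast implementations.

These are deliberately naive textbook routines, written separately from
the package code paths they validate: a quadratic three-matrix local
alignment DP (score only), exhaustive window enumeration for degenerate
motif search, and a both-orientations site scan for restriction cuts.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
        "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
        "D": "H", "H": "D", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def sw_score(a: str, b: str, match=5.0, mismatch=-4.0,
             gap_open=10.0, gap_extend=0.5) -> float:
    """Textbook affine-gap local alignment score (Gotoh three matrices).

    A gap of length L costs gap_open + L * gap_extend.
    """
    m, n = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def primer_windows(seq: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (1-based start, mismatches) windows matching a degenerate motif."""
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        mm = sum(1 for j, c in enumerate(pattern) if seq[i + j] not in IUPAC[c])
        if mm <= max_mismatch:
            hits.append((i + 1, mm))
    return hits


def cut_positions(seq: str, site: str, top: int, bottom: int) -> list[int]:
    """Both-orientation site scan; cuts in [0, len(seq)], deduplicated."""
    cuts = set()
    L = len(site)
    for i in range(len(seq) - L + 1):
        win = seq[i:i + L]
        if all(win[j] in IUPAC[site[j]] for j in range(L)):
            cuts.add(i + top)
        if all(win[j] in IUPAC[rc(site)[j]] for j in range(L)):
            cuts.add(i + L - bottom)
    return sorted(c for c in cuts if 0 <= c <= len(seq))
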