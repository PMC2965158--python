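"""IUPAC nucleotide alphabet and fuzzy (fuzznuc-style) primer matching.

Primer sites are fixed-length degenerate motifs, so matching counts
substitution mismatches only -- no indels.  Degeneracy is asymmetric:
codes in the primer denote base *sets*, while the searched sequence is
expected to be concrete A/C/G/T after ingest normalization; any other
character in the subject counts as a mismatch (an ``N`` in a read means
"unknown", not "anything").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

logger = logging.getLogger(__name__)

#: The 15-letter IUPAC nucleotide alphabet mapped to its base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC complement table (R<->Y, K<->M, B<->V, D<->H; S, W, N are
#: self-complementary because their base sets are).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CONCRETE_BASES = frozenset("ACGT")


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA ``U`` to ``T``.

    This is the single ingest normalization applied to all sequences
    (samples, references, primers) before any matching.
    """
    return seq.upper().replace("U", "T")


def iupac_compatible(code: str, base: str) -> bool:
    """True iff concrete ``base`` belongs to the set denoted by ``code``."""
    try:
        allowed = IUPAC_SETS[code]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {code!r}") from None
    if base not in CONCRETE_BASES:
        raise ValueError(f"subject base must be concrete A/C/G/T, got {base!r}")
    return base in allowed


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (degenerate codes included)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError:
        bad = next(c for c in seq if c not in IUPAC_COMPLEMENT)
        raise ValueError(f"invalid IUPAC character {bad!r} in sequence") from None


def validate_iupac(seq: str, *, what: str = "sequence") -> None:
    """Raise ``ValueError`` if ``seq`` is empty or not pure IUPAC."""
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"{what} contains non-IUPAC characters: {sorted(bad)}")


@dataclass(frozen=True)
class PrimerSpec:
    """A (possibly degenerate) PCR primer, written 5'->3'.

    ``orientation`` says which amplicon strand the primer anneals to:
    a ``reverse`` primer is searched on the sense strand as its reverse
    complement, and reverse-mode analyses operate on reverse-complemented
    sequences so that a single forward code path serves both cases.
    """

    name: str
    sequence: str
    orientation: Literal["forward", "reverse"] = "forward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        validate_iupac(self.sequence, what=f"primer {self.name!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    def sense_pattern(self) -> str:
        """The motif actually searched on the sense (labeled) strand."""
        if self.orientation == "reverse":
            return reverse_complement(self.sequence)
        return self.sequence

    def as_forward(self) -> "PrimerSpec":
        """Equivalent forward primer for analyses run on the reverse
        complement of all sequences (reverse-primer mode)."""
        if self.orientation == "forward":
            return self
        return PrimerSpec(self.name, self.sequence, "forward")


@dataclass(frozen=True)
class PrimerHit:
    """A primer match on the sense strand (1-based start, leftmost base)."""

    start: int
    mismatches: int
    strand: str = "sense"


def find_primer(seq: str, primer: PrimerSpec, max_mismatch: int = 1) -> list[PrimerHit]:
    """Scan every window of ``seq`` for the primer motif.

    A window position mismatches when the subject base is not in the
    primer code's set (ambiguous subject bases always mismatch).  Hits
    are returned sorted by position.  Reverse-orientation primers are
    searched as their reverse complement on the sense strand.

    Parameters
    ----------
    seq
        Concrete nucleotide string (normalize first; non-ACGT characters
        are tolerated but count as mismatches at every window).
    primer
        The degenerate motif to locate.
    max_mismatch
        Maximum substitution mismatches tolerated per window.
    """
    pattern = primer.sense_pattern()
    plen = len(pattern)
    if plen > len(seq):
        logger.warning(
            "primer %s (len %d) longer than sequence (len %d); no search performed",
            primer.name, plen, len(seq),
        )
        return []
    sets = [IUPAC_SETS[c] for c in pattern]
    hits: list[PrimerHit] = []
    for i in range(len(seq) - plen + 1):
        mism = 0
        for j in range(plen):
            if seq[i + j] not in sets[j]:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(PrimerHit(start=i + 1, mismatches=mism))
    return hits


def best_primer_hit(seq: str, primer: PrimerSpec, max_mismatch: int = 1) -> PrimerHit | None:
    """Best hit by fewest mismatches, then leftmost position."""
    hits = find_primer(seq, primer, max_mismatch)
    if not hits:
        return None
    return min(hits, key=lambda h: (h.mismatches, h.start))


def load_primer_table(path: str | Path) -> dict[str, PrimerSpec]:
    """Read a primer list: TSV columns name, sequence, orientation."""
    primers: dict[str, PrimerSpec] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
        name, sequence, orientation = parts
        primers[name] = PrimerSpec(name, sequence, orientation)  # type: ignore[arg-type]
    return primers


def builtin_primers() -> dict[str, PrimerSpec]:
    """Starter list of common 16S rRNA primers shipped as convenience data."""
    ref = resources.files("trflp.data").joinpath("primers.tsv")
    with resources.as_file(ref) as p:
        return load_primer_table(p)
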