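"""Restriction enzyme model and in silico digestion.

The terminal restriction fragment (T-RF) is defined on the *labeled*
strand only, because that is the strand a capillary electrophoresis size
standard measures.  Blunt/sticky-end geometry therefore reduces to a
single cut coordinate on the labeled strand: "cut at position p" means
cleavage of the phosphodiester bond between bases p and p+1 (1-based).

Recognition sites may be degenerate (IUPAC); the digested sequence must
be concrete.  For non-palindromic enzymes, matches of the site on the
bottom strand also cleave the labeled strand; the bottom-strand cut
offset (counted from the 5' end of the bottom-strand site) is converted
to labeled-strand coordinates.  Methylation sensitivity, star activity
and partial digestion are out of scope.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .iupac import IUPAC_SETS, reverse_complement, validate_iupac

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: recognition motif plus cut offsets.

    ``cut_offset_top`` is the number of bases between the 5' start of a
    top-strand site match and the top-strand cut (0 cuts before the
    site's first base; values < 0 or > len(site) describe outside
    cutters).  ``cut_offset_bottom`` locates the bottom-strand cut in
    the REBASE pair style, i.e. expressed in top-strand coordinates of
    the same site match (for HhaI ``GCG^C`` the pair is 3/1: top cut
    after base 3, bottom cut opposite base 1, leaving a 2-nt 3'
    overhang).  It is used to place labeled-strand cuts for matches of
    the reverse-complemented site of non-palindromic enzymes.
    """

    name: str
    site: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        validate_iupac(self.site, what=f"enzyme {self.name!r} site")

    @classmethod
    def from_cut_notation(cls, name: str, notation: str) -> "EnzymeSpec":
        """Build from caret notation, e.g. ``GCG^C`` (cut after 3 bases).

        The bottom-strand offset is derived assuming the cut geometry is
        symmetric about the site center (true for the common Type II
        enzymes shipped here): ``bottom = len(site) - top``.
        """
        if notation.count("^") != 1:
            raise ValueError(f"cut notation needs exactly one '^': {notation!r}")
        top = notation.index("^")
        site = notation.replace("^", "")
        return cls(name=name, site=site, cut_offset_top=top,
                   cut_offset_bottom=len(site) - top)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


@dataclass(frozen=True)
class CutList:
    """Sorted labeled-strand cut positions produced by one enzyme."""

    enzyme: EnzymeSpec
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("cut positions must be strictly increasing")


def _site_matches(seq: str, pattern: str) -> list[int]:
    """1-based starts of every (overlapping) IUPAC-pattern match."""
    sets = [IUPAC_SETS[c] for c in pattern]
    plen = len(pattern)
    out = []
    for i in range(len(seq) - plen + 1):
        for j, allowed in enumerate(sets):
            if seq[i + j] not in allowed:
                break
        else:
            out.append(i + 1)
    return out


def find_cut_positions(seq: str, enzyme: EnzymeSpec) -> CutList:
    """All labeled-strand cut positions of ``enzyme`` in ``seq``.

    Top-strand site matches starting at s cut at ``s - 1 + cut_offset_top``;
    bottom-strand matches (reverse complement of the site at start s on
    the labeled strand) cut at ``s - 1 + (len(site) - cut_offset_bottom)``.
    Palindromic sites yield coincident cuts which are merged.  Cuts
    falling outside [0, len(seq)] (outside cutters near the ends) are
    discarded with a warning.
    """
    n = len(seq)
    cuts: set[int] = set()
    for s in _site_matches(seq, enzyme.site):
        cuts.add(s - 1 + enzyme.cut_offset_top)
    rc_site = reverse_complement(enzyme.site)
    if rc_site != enzyme.site:
        for s in _site_matches(seq, rc_site):
            cuts.add(s - 1 + (len(enzyme.site) - enzyme.cut_offset_bottom))
    else:
        # palindromic: bottom-strand matches coincide with top-strand ones
        for s in _site_matches(seq, enzyme.site):
            cuts.add(s - 1 + (len(enzyme.site) - enzyme.cut_offset_bottom))
    kept = []
    for p in sorted(cuts):
        if 0 <= p <= n:
            kept.append(p)
        else:
            logger.warning("%s cut at %d outside sequence [0, %d]; discarded",
                           enzyme.name, p, n)
    return CutList(enzyme=enzyme, positions=tuple(kept))


def terminal_fragment(seq: str, label_pos: int, enzyme: EnzymeSpec) -> int | None:
    """Labeled-strand T-RF length from the labeled 5' base to the first cut.

    Returns ``(first cut p >= label_pos) - label_pos + 1`` -- the number
    of nucleotides from the labeled base through the last base before
    the cut -- or ``None`` when no cut lies at or after ``label_pos``.
    """
    if not 1 <= label_pos <= len(seq):
        raise ValueError(f"label_pos {label_pos} outside sequence of length {len(seq)}")
    positions = find_cut_positions(seq, enzyme).positions
    i = bisect_left(positions, label_pos)
    if i == len(positions):
        return None
    return positions[i] - label_pos + 1


def full_digest(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """Fragment lengths of a complete digestion (labeled-strand view).

    The fragments partition the sequence at every cut position; their
    lengths always sum to ``len(seq)``.
    """
    n = len(seq)
    bounds = [0]
    for p in find_cut_positions(seq, enzyme).positions:
        if 0 < p < n:
            bounds.append(p)
    bounds.append(n)
    return [b - a for a, b in zip(bounds, bounds[1:])]


def load_enzyme_table(path: str | Path) -> dict[str, EnzymeSpec]:
    """Read an enzyme flat file.

    Accepts either 4 columns (name, site, top offset, bottom offset) or
    2 columns (name, caret notation such as ``GCG^C``).
    """
    enzymes: dict[str, EnzymeSpec] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            enzymes[parts[0]] = EnzymeSpec.from_cut_notation(parts[0], parts[1])
        elif len(parts) == 4:
            enzymes[parts[0]] = EnzymeSpec(
                name=parts[0], site=parts[1],
                cut_offset_top=int(parts[2]), cut_offset_bottom=int(parts[3]),
            )
        else:
            raise ValueError(f"{path}:{lineno}: expected 2 or 4 fields, got {len(parts)}")
    return enzymes


def builtin_enzymes() -> dict[str, EnzymeSpec]:
    """The shipped curated enzyme set (CfoI/HhaI, HaeIII, AluI, MspI, RsaI, HinfI)."""
    ref = resources.files("trflp.data").joinpath("enzymes.tsv")
    with resources.as_file(ref) as p:
        return load_enzyme_table(p)
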