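"""Augmented reference 16S rRNA database: parsing, indexing, subsetting.

The reference set is a flat FASTA file whose headers carry, besides the
accession, the taxonomy lineage and the alignment columns of the first
and last non-gap character of each sequence in the source multiple
alignment:

    >accession|Bacteria;Proteobacteria;...|first_nongap_fwd|first_nongap_rev

Field and rank delimiters are configurable.  Bodies may contain the gap
characters ``-`` and ``.`` used by rRNA model alignments; sequences are
upper-cased and ``U`` is mapped to ``T`` on ingest.

Subsetting implements the reference-selection rule used throughout the
pipeline: keep full-length sequences of the requested domain (ungapped
length strictly greater than 1200 nt for Bacteria, 900 nt for Archaea)
that carry the labeled primer's site, and remember the primer anchor of
each retained record for later gap arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import PrimerHit, PrimerSpec, find_primer, normalize_sequence, reverse_complement

logger = logging.getLogger(__name__)

GAP_CHARS = "-."

#: Ungapped-length thresholds (strict: a record must be LONGER than this).
DEFAULT_MIN_LENGTH = {"Bacteria": 1200, "Archaea": 900}


@dataclass(frozen=True)
class HeaderDialect:
    """How augmented headers are delimited."""

    field_sep: str = "|"
    rank_sep: str = ";"


DEFAULT_DIALECT = HeaderDialect()


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference 16S sequence with taxonomy and alignment metadata.

    ``first_nongap_fwd`` / ``first_nongap_rev`` are 1-based columns of
    the first and last non-gap character in the source model alignment;
    they are retained for diagnostics.
    """

    id: str
    lineage: tuple[str, ...]
    aligned_seq: str
    first_nongap_fwd: int
    first_nongap_rev: int
    ungapped_seq: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        if not self.ungapped_seq:
            stripped = strip_gaps(self.aligned_seq)
            object.__setattr__(self, "ungapped_seq", stripped)
        if self.ungapped_seq != strip_gaps(self.aligned_seq):
            raise ValueError(f"{self.id}: ungapped_seq inconsistent with aligned_seq")
        if not self.lineage:
            raise ValueError(f"{self.id}: empty lineage")
        if self.lineage[0] not in ("Bacteria", "Archaea"):
            raise ValueError(
                f"{self.id}: first lineage rank must be Bacteria or Archaea, "
                f"got {self.lineage[0]!r}"
            )
        # the positions index the SOURCE model alignment (diagnostics only),
        # whose column count may exceed the stored body
        if not 1 <= self.first_nongap_fwd <= self.first_nongap_rev:
            raise ValueError(
                f"{self.id}: non-gap positions {self.first_nongap_fwd}/"
                f"{self.first_nongap_rev} out of order"
            )

    @property
    def domain(self) -> str:
        return self.lineage[0]

    def lineage_str(self, dialect: HeaderDialect = DEFAULT_DIALECT) -> str:
        return dialect.rank_sep.join(self.lineage)

    def header(self, dialect: HeaderDialect = DEFAULT_DIALECT) -> str:
        return dialect.field_sep.join(
            [self.id, self.lineage_str(dialect),
             str(self.first_nongap_fwd), str(self.first_nongap_rev)]
        )

    def reverse_complemented(self) -> "ReferenceRecord":
        """The same record on the opposite strand (reverse-primer mode).

        Gap columns reverse with the sequence; the first/last non-gap
        columns swap and are re-expressed from the new 5' end.
        """
        n = max(len(self.aligned_seq), self.first_nongap_rev)
        return ReferenceRecord(
            id=self.id,
            lineage=self.lineage,
            aligned_seq=reverse_complement_gapped(self.aligned_seq),
            first_nongap_fwd=n - self.first_nongap_rev + 1,
            first_nongap_rev=n - self.first_nongap_fwd + 1,
        )


def strip_gaps(aligned: str) -> str:
    out = aligned
    for g in GAP_CHARS:
        out = out.replace(g, "")
    return out


def reverse_complement_gapped(aligned: str) -> str:
    """Reverse-complement an aligned string, keeping gap characters."""
    comp = []
    for c in reversed(aligned):
        comp.append(c if c in GAP_CHARS else reverse_complement(c))
    return "".join(comp)


@dataclass(frozen=True)
class ParseIssue:
    """A diagnostic for one skipped or suspect FASTA entry."""

    line: int
    header: str
    message: str


def parse_reference_fasta(
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
) -> list[ReferenceRecord]:
    """Parse an augmented reference FASTA; malformed entries are skipped.

    Diagnostics (with header line numbers) are emitted through the
    module logger; use :func:`parse_reference_fasta_with_issues` to
    collect them programmatically.
    """
    records, issues = parse_reference_fasta_with_issues(path, dialect)
    for issue in issues:
        logger.warning("%s:%d: %s (header %r)", path, issue.line, issue.message, issue.header)
    return records


def parse_reference_fasta_with_issues(
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
) -> tuple[list[ReferenceRecord], list[ParseIssue]]:
    """As :func:`parse_reference_fasta`, returning (records, issues)."""
    path = Path(path)
    header_lines = [
        i for i, line in enumerate(path.read_text().splitlines(), start=1)
        if line.startswith(">")
    ]
    records: list[ReferenceRecord] = []
    issues: list[ParseIssue] = []
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        logger.warning("%s: no FASTA entries found", path)
        return records, issues
    for idx, entry in enumerate(entries):
        line = header_lines[idx] if idx < len(header_lines) else -1
        header = entry.description
        try:
            records.append(_record_from_entry(header, str(entry.seq), dialect))
        except ValueError as exc:
            issues.append(ParseIssue(line=line, header=header, message=str(exc)))
    return records, issues


def _record_from_entry(header: str, body: str, dialect: HeaderDialect) -> ReferenceRecord:
    parts = header.split(dialect.field_sep)
    if len(parts) != 4:
        raise ValueError(
            f"expected 4 {dialect.field_sep!r}-separated header fields "
            f"(id, lineage, first_nongap_fwd, first_nongap_rev), got {len(parts)}"
        )
    acc, lineage_s, fwd_s, rev_s = parts
    lineage = tuple(r.strip() for r in lineage_s.split(dialect.rank_sep) if r.strip())
    if not lineage:
        raise ValueError("missing taxonomy field")
    try:
        fwd, rev = int(fwd_s), int(rev_s)
    except ValueError:
        raise ValueError(f"non-integer alignment positions {fwd_s!r}/{rev_s!r}") from None
    aligned = normalize_sequence(body)
    return ReferenceRecord(
        id=acc, lineage=lineage, aligned_seq=aligned,
        first_nongap_fwd=fwd, first_nongap_rev=rev,
    )


def write_reference_fasta(
    records: list[ReferenceRecord],
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
    line_width: int = 70,
) -> None:
    """Write records back in the augmented-header dialect (round-trippable)."""
    seq_records = [
        SeqRecord(Seq(r.aligned_seq), id=r.header(dialect), description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seq_records)


def aligned_to_ungapped(record: ReferenceRecord, aligned_pos: int) -> int | None:
    """Map a 1-based alignment column to the 1-based ungapped position.

    Returns the count of non-gap characters at columns <= ``aligned_pos``
    when that column is itself a non-gap character, else ``None``.
    """
    if not 1 <= aligned_pos <= len(record.aligned_seq):
        raise ValueError(
            f"aligned position {aligned_pos} outside alignment of length "
            f"{len(record.aligned_seq)}"
        )
    if record.aligned_seq[aligned_pos - 1] in GAP_CHARS:
        return None
    prefix = record.aligned_seq[:aligned_pos]
    return len(prefix) - sum(prefix.count(g) for g in GAP_CHARS)


@dataclass
class ReferenceSubset:
    """References retained for one primer/domain analysis.

    Each retained record stores its best primer hit (fewest mismatches,
    then leftmost) -- the anchor for all later gap arithmetic.
    """

    records: list[ReferenceRecord]
    primer: PrimerSpec
    primer_hit_by_id: dict[str, PrimerHit]
    domain: str
    min_length: int

    def __post_init__(self) -> None:
        self.by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def build_subset(
    records: list[ReferenceRecord],
    primer: PrimerSpec,
    domain: str = "Bacteria",
    max_mismatch: int = 1,
    min_length: int | None = None,
) -> ReferenceSubset:
    """Select references usable for T-RF prediction with ``primer``.

    Keeps records whose first lineage rank equals ``domain``, whose
    ungapped length strictly exceeds the domain threshold (Bacteria
    1200 nt, Archaea 900 nt unless overridden), and in which the primer
    is found with at most ``max_mismatch`` substitutions.  Primer
    coverage is established by the fuzzy search itself rather than by
    arithmetic on the header alignment columns, so it is robust to
    references whose alignment drifts from the primer's model position.
    """
    if domain not in DEFAULT_MIN_LENGTH:
        raise ValueError(f"domain must be one of {sorted(DEFAULT_MIN_LENGTH)}, got {domain!r}")
    threshold = DEFAULT_MIN_LENGTH[domain] if min_length is None else min_length
    kept: list[ReferenceRecord] = []
    hits: dict[str, PrimerHit] = {}
    for rec in records:
        if rec.domain != domain:
            continue
        if len(rec.ungapped_seq) <= threshold:
            continue
        found = find_primer(rec.ungapped_seq, primer, max_mismatch)
        if not found:
            continue
        best = min(found, key=lambda h: (h.mismatches, h.start))
        kept.append(rec)
        hits[rec.id] = best
    if not kept:
        logger.warning(
            "reference subset is empty (domain=%s, min_length>%d, primer=%s)",
            domain, threshold, primer.name,
        )
    return ReferenceSubset(
        records=kept, primer=primer, primer_hit_by_id=hits,
        domain=domain, min_length=threshold,
    )
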