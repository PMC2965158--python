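"""Terminal-fragment size estimation for possibly 5'-truncated samples.

The central problem: directional Sanger reads of 16S rRNA clones
typically miss their first 10-30 bases, including the labeled primer,
so the T-RF cannot be read off the clone sequence alone.  The estimator
aligns each sample to its closest full-length reference, measures on
the reference how many nucleotides are missing between the primer's
labeled 5' base and the first aligned sample base (the "gap"), and adds
that gap to the distance from the sample's first base to its first
restriction cut:

    est_T-RF = gap + (first cut position in the sample)

When the sample itself carries no cut site -- or when the reference
shows that the cut falls inside the missing 5' region (``cut-in-gap``)
-- the estimate falls back to the reference's own terminal fragment.

All positions are 1-based inclusive; "cut at p" means cleavage between
bases p and p+1; fragment lengths include the primer's 5' base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .digest import EnzymeSpec, terminal_fragment
from .iupac import PrimerHit, PrimerSpec
from .refdb import ReferenceRecord, ReferenceSubset
from .search_align import AlignmentResult, ScoringParams, SearchHit, best_hits

logger = logging.getLogger(__name__)

METHOD_SAMPLE_SITE = "sample-site"
METHOD_REFERENCE = "reference-estimated"

FLAG_CUT_IN_GAP = "cut-in-gap"
FLAG_NO_PRIMER = "no-primer-on-ref"
FLAG_UNASSIGNABLE = "unassignable"
FLAG_NEGATIVE_GAP = "negative-gap"
FLAG_LOW_IDENTITY = "low-identity"

#: Percent-identity floor below which a prediction is flagged low-confidence.
DEFAULT_MIN_IDENTITY = 80.0


@dataclass(frozen=True)
class TRFPrediction:
    """One per-sample, per-enzyme, per-hit output row.

    ``ref_fragment_length`` is the T-RF of the closest reference itself;
    ``est_fragment_length`` the estimate for the sample; ``gap_length``
    the inferred missing 5' stretch; ``method`` records whether the
    sample's own cut site was used or the reference's fragment was
    adopted.
    """

    sample_id: str
    enzyme: str
    best_hit_id: str | None
    ref_fragment_length: int | None
    est_fragment_length: int | None
    gap_length: int | None
    percent_identity: float | None
    lineage: str | None
    method: str | None
    flags: frozenset[str] = frozenset()
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.method == METHOD_SAMPLE_SITE:
            assert self.gap_length is not None and self.est_fragment_length is not None
            if self.est_fragment_length < self.gap_length + 1:
                raise ValueError(
                    f"{self.sample_id}/{self.enzyme}: sample-site estimate "
                    f"{self.est_fragment_length} shorter than gap {self.gap_length} + 1"
                )
        if self.method == METHOD_REFERENCE:
            if self.est_fragment_length != self.ref_fragment_length:
                raise ValueError(
                    f"{self.sample_id}/{self.enzyme}: reference-estimated row must "
                    "carry the reference fragment length"
                )
        if self.gap_length is not None and self.gap_length < 0:
            raise ValueError("gap_length must be >= 0")


def reference_trf(record: ReferenceRecord, primer_hit: PrimerHit,
                  enzyme: EnzymeSpec) -> int | None:
    """T-RF of a full-length reference from its own primer anchor."""
    return terminal_fragment(record.ungapped_seq, primer_hit.start, enzyme)


def compute_gap(alignment: AlignmentResult, primer_hit: PrimerHit) -> tuple[int, bool]:
    """Missing 5' nucleotides between the primer and the aligned sample start.

    ``gap = alignment.ref_start - primer_hit.start - (alignment.sample_start - 1)``:
    the reference distance from the primer's labeled base to the first
    aligned column, minus any unaligned sample prefix (those bases are
    present sequence, not missing).  A negative value -- the sample
    apparently extends upstream of the primer -- is clamped to 0 and
    reported via the second return value.
    """
    gap = alignment.ref_start - primer_hit.start - (alignment.sample_start - 1)
    if gap < 0:
        return 0, True
    return gap, False


def _sample_pos_at_ref(alignment: AlignmentResult, ref_pos: int) -> int | None:
    """Sample position aligned to ungapped reference position ``ref_pos``."""
    if not alignment.ref_start <= ref_pos <= alignment.ref_end:
        return None
    s, r = alignment.sample_start - 1, alignment.ref_start - 1
    for cs, cr in zip(alignment.aligned_sample, alignment.aligned_ref):
        if cs != "-":
            s += 1
        if cr != "-":
            r += 1
            if r == ref_pos:
                return s if cs != "-" else None
    return None


def predict_for_hit(
    sample_id: str,
    sample_seq: str,
    hit: SearchHit,
    alignment: AlignmentResult,
    record: ReferenceRecord,
    primer_hit: PrimerHit | None,
    enzyme: EnzymeSpec,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> TRFPrediction:
    """Fragment-size estimate for one sample against one reference hit."""
    flags: set[str] = set()
    lineage = ";".join(record.lineage)
    if alignment.percent_identity < min_identity:
        flags.add(FLAG_LOW_IDENTITY)
    if primer_hit is None:
        flags.add(FLAG_NO_PRIMER)
        return TRFPrediction(
            sample_id=sample_id, enzyme=enzyme.name, best_hit_id=record.id,
            ref_fragment_length=None, est_fragment_length=None, gap_length=None,
            percent_identity=alignment.percent_identity, lineage=lineage,
            method=None, flags=frozenset(flags), rank=hit.rank,
        )

    ref_frag = reference_trf(record, primer_hit, enzyme)
    ref_cut_pos = None if ref_frag is None else primer_hit.start + ref_frag - 1
    gap, clamped = compute_gap(alignment, primer_hit)
    if clamped:
        flags.add(FLAG_NEGATIVE_GAP)

    if ref_cut_pos is not None and ref_cut_pos < alignment.ref_start:
        # the reference says the cut lies inside the sample's missing 5'
        # region; any site found on the sample would be a downstream one
        flags.add(FLAG_CUT_IN_GAP)
        method = METHOD_REFERENCE
        est = ref_frag
    else:
        start_pos = 1
        if clamped:
            anchored = _sample_pos_at_ref(alignment, primer_hit.start)
            if anchored is not None:
                start_pos = anchored
        cut_dist = (terminal_fragment(sample_seq, start_pos, enzyme)
                    if start_pos <= len(sample_seq) else None)
        if cut_dist is not None:
            # cut_dist counts from the searched base; in the clamped case
            # gap is 0 and the search starts at the primer-anchored base
            method = METHOD_SAMPLE_SITE
            est = gap + cut_dist
        else:
            method = METHOD_REFERENCE
            est = ref_frag

    return TRFPrediction(
        sample_id=sample_id, enzyme=enzyme.name, best_hit_id=record.id,
        ref_fragment_length=ref_frag, est_fragment_length=est,
        gap_length=gap, percent_identity=alignment.percent_identity,
        lineage=lineage, method=method, flags=frozenset(flags), rank=hit.rank,
    )


def _unassignable(sample_id: str, enzyme: EnzymeSpec) -> TRFPrediction:
    return TRFPrediction(
        sample_id=sample_id, enzyme=enzyme.name, best_hit_id=None,
        ref_fragment_length=None, est_fragment_length=None, gap_length=None,
        percent_identity=None, lineage=None, method=None,
        flags=frozenset({FLAG_UNASSIGNABLE}),
    )


def predict_trf(
    sample_id: str,
    sample_seq: str,
    primer: PrimerSpec,
    enzyme: EnzymeSpec,
    subset: ReferenceSubset,
    n_hits: int = 1,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    params: ScoringParams = ScoringParams(),
) -> list[TRFPrediction]:
    """Estimate the sample's T-RF against its ``n_hits`` closest references."""
    by_enzyme = predict_multi(
        sample_id, sample_seq, primer, [enzyme], subset,
        n_hits=n_hits, min_identity=min_identity, params=params,
    )
    return by_enzyme[enzyme.name]


def predict_multi(
    sample_id: str,
    sample_seq: str,
    primer: PrimerSpec,
    enzymes: list[EnzymeSpec],
    subset: ReferenceSubset,
    n_hits: int = 1,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    params: ScoringParams = ScoringParams(),
) -> dict[str, list[TRFPrediction]]:
    """Predictions for several enzymes sharing one homology search."""
    _, by_enzyme = predict_sample(
        sample_id, sample_seq, primer, enzymes, subset,
        n_hits=n_hits, min_identity=min_identity, params=params,
    )
    return by_enzyme


def predict_sample(
    sample_id: str,
    sample_seq: str,
    primer: PrimerSpec,
    enzymes: list[EnzymeSpec],
    subset: ReferenceSubset,
    n_hits: int = 1,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    params: ScoringParams = ScoringParams(),
) -> tuple[list[tuple[SearchHit, AlignmentResult]], dict[str, list[TRFPrediction]]]:
    """Closest-reference hits plus per-enzyme predictions for one sample.

    The closest-reference search is independent of the enzyme, so the
    alignments are computed once and reused for every enzyme.
    """
    if subset.primer != primer:
        raise ValueError("subset was built with a different primer")
    hits = best_hits(sample_seq, subset, n=n_hits, params=params)
    out: dict[str, list[TRFPrediction]] = {}
    for enzyme in enzymes:
        if not hits:
            out[enzyme.name] = [_unassignable(sample_id, enzyme)]
            continue
        rows = []
        for hit, aln in hits:
            record = subset.by_id[hit.ref_id]
            primer_hit = subset.primer_hit_by_id.get(hit.ref_id)
            rows.append(predict_for_hit(
                sample_id, sample_seq, hit, aln, record, primer_hit,
                enzyme, min_identity=min_identity,
            ))
        out[enzyme.name] = rows
    return hits, out


def assign_taxonomy(best_hit: ReferenceRecord, rank: int) -> str:
    """The hit's lineage truncated to ``rank`` ranks (full when deeper)."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    return ";".join(best_hit.lineage[:rank])


def truncate_lineage(lineage: str, rank: int, sep: str = ";") -> str:
    """Truncate a serialized lineage string to ``rank`` ranks."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    return sep.join(lineage.split(sep)[:rank])
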