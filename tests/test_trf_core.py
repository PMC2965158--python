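"""Fragment-size estimation for truncated samples (gap arithmetic)."""

import numpy as np
import pytest

from trflp.digest import EnzymeSpec, builtin_enzymes, terminal_fragment
from trflp.fixtures import generate_fixture
from trflp.iupac import PrimerHit, PrimerSpec
from trflp.refdb import ReferenceRecord, build_subset
from trflp.search_align import AlignmentResult
from trflp.trf_core import (
    FLAG_CUT_IN_GAP,
    FLAG_UNASSIGNABLE,
    METHOD_REFERENCE,
    METHOD_SAMPLE_SITE,
    assign_taxonomy,
    compute_gap,
    predict_multi,
    predict_trf,
    reference_trf,
)

CFO = EnzymeSpec("CfoI", "GCGC", 3, 1)


def ungapped_alignment(sample_start, sample_end, ref_start, ref_end, n):
    body = "A" * n
    return AlignmentResult(
        sample_start=sample_start, sample_end=sample_end,
        ref_start=ref_start, ref_end=ref_end,
        score=5.0 * n, percent_identity=100.0,
        aligned_sample=body, aligned_ref=body,
    )


def make_ref(seq, lineage="Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales"):
    return ReferenceRecord("ref1", tuple(lineage.split(";")), seq, 1, len(seq))


class TestReferenceTrf:
    def test_primer_to_first_cut(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq.replace("GCGC", "ATAT")
        # plant a site whose cut lands 150 nt after a primer at position 10
        pos = 10 - 1 + 150 - CFO.cut_offset_top  # 0-based site start
        seq = seq[:pos] + "GCGC" + seq[pos + 4:]
        rec = make_ref(seq)
        assert reference_trf(rec, PrimerHit(start=10, mismatches=0), CFO) == 150

    def test_no_cut_site_is_absent(self):
        rec = make_ref("ATATATAT" * 10)
        assert reference_trf(rec, PrimerHit(start=1, mismatches=0), CFO) is None

    def test_boundary_cut_at_primer(self):
        # cut at the primer base itself gives a fragment of 1
        enz = EnzymeSpec("e", "GCGC", 1, 3)
        rec = make_ref("GCGCAAAA")
        assert reference_trf(rec, PrimerHit(start=1, mismatches=0), enz) == 1


class TestComputeGap:
    @pytest.mark.parametrize(
        "ref_start,sample_start,primer_start,expected",
        [(30, 1, 10, 20), (10, 1, 10, 0), (30, 3, 10, 18)],
    )
    def test_gap_arithmetic(self, ref_start, sample_start, primer_start, expected):
        aln = ungapped_alignment(sample_start, sample_start + 99,
                                 ref_start, ref_start + 99, 100)
        gap, clamped = compute_gap(aln, PrimerHit(start=primer_start, mismatches=0))
        assert gap == expected
        assert clamped is False

    def test_negative_gap_clamped(self):
        aln = ungapped_alignment(1, 100, 5, 104, 100)
        gap, clamped = compute_gap(aln, PrimerHit(start=20, mismatches=0))
        assert gap == 0
        assert clamped is True


def _single_ref_setup(truncation, cut_depth, seed=0):
    """One reference with a known primer position and planted cut; a sample
    truncated by ``truncation`` nt from the primer's labeled base."""
    rng = np.random.default_rng(seed)
    primer = PrimerSpec("p", "ACGTACGTAC")
    prefix = "".join(rng.choice(list("ACGT"), size=30))
    body = "".join(rng.choice(list("ACGT"), size=1400)).replace("GCGC", "ATAT")
    seq = prefix + primer.sequence + body
    seq = seq.replace("GCGC", "ATAT")
    pos = 30 + cut_depth - CFO.cut_offset_top  # 0-based site start from primer base
    seq = seq[:pos] + "GCGC" + seq[pos + 4:]
    rec = ReferenceRecord("SRC01", ("Bacteria", "Proteobacteria"), seq, 1, len(seq))
    subset = build_subset([rec], primer, max_mismatch=0)
    assert len(subset) == 1
    amplicon = seq[30:]
    sample = amplicon[truncation:truncation + 600]
    return primer, subset, amplicon, sample


class TestPredict:
    def test_full_length_sample_gap_zero(self):
        primer, subset, amplicon, _ = _single_ref_setup(truncation=0, cut_depth=150)
        (pred,) = predict_trf("s", amplicon[:600], primer, CFO, subset)
        assert pred.method == METHOD_SAMPLE_SITE
        assert pred.gap_length == 0
        assert pred.est_fragment_length == pred.ref_fragment_length == 150

    def test_truncated_sample_recovers_true_size(self):
        primer, subset, amplicon, sample = _single_ref_setup(truncation=20, cut_depth=150)
        (pred,) = predict_trf("s", sample, primer, CFO, subset)
        assert pred.method == METHOD_SAMPLE_SITE
        assert pred.gap_length == 20
        assert pred.est_fragment_length == 150
        assert terminal_fragment(sample, 1, CFO) == 130

    @pytest.mark.parametrize("depth", range(0, 31, 3))
    def test_recovery_exact_for_all_truncation_depths(self, depth):
        primer, subset, amplicon, sample = _single_ref_setup(truncation=depth,
                                                             cut_depth=200)
        (pred,) = predict_trf("s", sample, primer, CFO, subset)
        assert pred.method == METHOD_SAMPLE_SITE
        assert pred.est_fragment_length == terminal_fragment(amplicon, 1, CFO) == 200

    def test_gap_monotone_in_truncation_depth(self):
        gaps = []
        for depth in range(0, 31, 5):
            primer, subset, _, sample = _single_ref_setup(truncation=depth,
                                                          cut_depth=300)
            (pred,) = predict_trf("s", sample, primer, CFO, subset)
            gaps.append(pred.gap_length)
        assert gaps == sorted(gaps)

    def test_cut_inside_gap_falls_back_to_reference(self):
        # the cut lies 15 nt from the primer; truncating 25 nt removes it
        primer, subset, amplicon, sample = _single_ref_setup(truncation=25,
                                                             cut_depth=15)
        (pred,) = predict_trf("s", sample, primer, CFO, subset)
        assert FLAG_CUT_IN_GAP in pred.flags
        assert pred.method == METHOD_REFERENCE
        assert pred.est_fragment_length == pred.ref_fragment_length == 15

    def test_no_cut_anywhere_uses_reference_estimate(self):
        primer, subset, _, sample = _single_ref_setup(truncation=20, cut_depth=1100)
        # sample reads only 600 nt: its own cut lies beyond the read end
        (pred,) = predict_trf("s", sample, primer, CFO, subset)
        assert pred.method == METHOD_REFERENCE
        assert pred.est_fragment_length == pred.ref_fragment_length == 1100

    def test_unassignable_sample_flagged(self):
        primer, subset, _, _ = _single_ref_setup(truncation=0, cut_depth=150)
        (pred,) = predict_trf("s", "TTTT" * 8, primer, CFO, subset)
        assert FLAG_UNASSIGNABLE in pred.flags
        assert pred.est_fragment_length is None
        assert pred.best_hit_id is None

    def test_consistency_est_recomputable(self):
        """sample-site estimates decompose as gap + sample cut distance."""
        primer, subset, _, sample = _single_ref_setup(truncation=17, cut_depth=250)
        (pred,) = predict_trf("s", sample, primer, CFO, subset)
        assert pred.method == METHOD_SAMPLE_SITE
        assert pred.est_fragment_length == pred.gap_length + terminal_fragment(sample, 1, CFO)

    def test_multi_enzyme_shares_search(self):
        enzymes = builtin_enzymes()
        trio = [enzymes["CfoI"], enzymes["HaeIII"], enzymes["AluI"]]
        bundle = generate_fixture(21, n_refs=10, n_samples=2)
        subset = build_subset(bundle.references, bundle.primer)
        sid, seq = next(iter(bundle.samples.items()))
        by_enzyme = predict_multi(sid, seq, bundle.primer, trio, subset, n_hits=2)
        assert set(by_enzyme) == {"CfoI", "HaeIII", "AluI"}
        hit_ids = {tuple(p.best_hit_id for p in rows) for rows in by_enzyme.values()}
        assert len(hit_ids) == 1  # same hits for every enzyme


class TestAssignTaxonomy:
    lineage = "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales"

    @pytest.mark.parametrize(
        "rank,expected",
        [
            (2, "Bacteria;Proteobacteria"),
            (10, "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales"),
            (1, "Bacteria"),
        ],
    )
    def test_truncation(self, rank, expected):
        rec = make_ref("ACGT" * 400, lineage=self.lineage)
        assert assign_taxonomy(rec, rank) == expected
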