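"""Peak matching, multi-enzyme consensus, tallies, relative abundance."""

import itertools

import numpy as np
import pytest

from trflp.peaks import (
    Peak,
    PeakMatch,
    PeakTable,
    correct_predicted_sizes,
    fit_size_drift,
    load_peak_table,
    match_to_peaks,
    multi_enzyme_consensus,
    relative_abundance,
    tally_taxa,
)
from trflp.trf_core import TRFPrediction, METHOD_SAMPLE_SITE


def pred(sample_id, est, enzyme="CfoI", lineage="Bacteria;Proteobacteria", rank=1):
    return TRFPrediction(
        sample_id=sample_id, enzyme=enzyme, best_hit_id="R1",
        ref_fragment_length=est, est_fragment_length=est, gap_length=0,
        percent_identity=100.0, lineage=lineage, method=METHOD_SAMPLE_SITE,
        rank=rank,
    )


def table(enzyme, *sizes):
    return PeakTable(enzyme=enzyme, peaks=tuple(Peak(size=s, area=1.0) for s in sizes))


class TestLoad:
    def test_load_sorts_and_parses(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("size,height,area\n150.2,900,12000\n63.0,400,5100\n")
        t = load_peak_table(p, "CfoI")
        assert t.sizes == [63.0, 150.2]
        assert t.has_areas

    def test_missing_area_column_disables_abundance(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("size,height\n100.0,50\n")
        t = load_peak_table(p, "CfoI")
        assert not t.has_areas
        with pytest.raises(ValueError):
            relative_abundance(t)

    def test_negative_size_row_rejected(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("size\n-5.0\n120.0\n")
        t = load_peak_table(p, "CfoI")
        assert t.sizes == [120.0]

    def test_no_parsable_rows_is_error(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("size\nxx\n")
        with pytest.raises(ValueError):
            load_peak_table(p, "CfoI")


class TestMatch:
    def test_match_within_tolerance(self):
        m = match_to_peaks([pred("s1", 148.7)], table("CfoI", 150.0), tolerance=2.0)
        assert len(m) == 1
        assert m[0].delta == pytest.approx(1.3)

    def test_no_match_outside_tolerance(self):
        assert match_to_peaks([pred("s1", 148.7)], table("CfoI", 150.0), 1.0) == []

    def test_equidistant_tie_goes_to_smaller_peak(self):
        m = match_to_peaks([pred("s1", 100)], table("CfoI", 98.5, 101.5), 2.0)
        assert m[0].peak_size == 98.5

    def test_enzyme_mismatch_raises(self):
        with pytest.raises(ValueError):
            match_to_peaks([pred("s1", 100, enzyme="AluI")], table("CfoI", 100), 2.0)

    def test_matching_stable_under_input_permutation(self):
        preds = [pred(f"s{i}", 100 + i) for i in range(6)]
        t = table("CfoI", 99.0, 103.0, 105.5)
        fwd = match_to_peaks(preds, t, 2.0)
        rev = match_to_peaks(list(reversed(preds)), t, 2.0)
        assert {(m.sample_id, m.peak_size) for m in fwd} == \
               {(m.sample_id, m.peak_size) for m in rev}

    def test_many_predictions_may_share_one_peak(self):
        preds = [pred("s1", 100), pred("s2", 101)]
        m = match_to_peaks(preds, table("CfoI", 100.5), 2.0)
        assert [x.peak_size for x in m] == [100.5, 100.5]


def matches(enzyme, *ids):
    return [PeakMatch(sample_id=i, enzyme=enzyme, peak_size=100, predicted=100,
                      delta=0.0, lineage="Bacteria") for i in ids]


class TestConsensus:
    by_enzyme = {
        "CfoI": matches("CfoI", "s1", "s2", "s3"),
        "HaeIII": matches("HaeIII", "s1", "s2"),
        "AluI": matches("AluI", "s1"),
    }

    def test_strict_intersection(self):
        assert multi_enzyme_consensus(self.by_enzyme, required=3) == {"s1"}

    def test_two_of_three(self):
        assert multi_enzyme_consensus(self.by_enzyme, required=2) == {"s1", "s2"}

    def test_union_with_required_one(self):
        assert multi_enzyme_consensus(self.by_enzyme, required=1) == {"s1", "s2", "s3"}

    def test_required_exceeding_enzymes_raises(self):
        with pytest.raises(ValueError):
            multi_enzyme_consensus(self.by_enzyme, required=4)

    def test_consensus_antimonotone_bruteforce(self):
        """consensus(k+1) is a subset of consensus(k) on random fixtures."""
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(12)]
        for _ in range(30):
            by_enz = {
                e: matches(e, *(i for i in ids if rng.random() < 0.5))
                for e in ("A", "B", "C", "D")
            }
            # brute-force: count supporting enzymes per id
            support = {
                i: sum(1 for ms in by_enz.values() if any(m.sample_id == i for m in ms))
                for i in ids
            }
            for k in range(1, 4):
                ck = multi_enzyme_consensus(by_enz, required=k)
                assert ck == {i for i, s in support.items() if s >= k}
                assert multi_enzyme_consensus(by_enz, required=k + 1) <= ck


class TestTally:
    def test_counts_and_total(self):
        preds = [
            pred("s1", 100, lineage="Bacteria;P;A;R;Roseobacter"),
            pred("s2", 100, lineage="Bacteria;P;A;R;Roseobacter"),
            pred("s3", 100, lineage="Bacteria;P;A;P;SAR11"),
        ]
        t = tally_taxa({"s1", "s2", "s3"}, preds, rank=5)
        assert t == {"Bacteria;P;A;R;Roseobacter": 2,
                     "Bacteria;P;A;P;SAR11": 1, "Total": 3}

    def test_empty_consensus(self):
        assert tally_taxa(set(), [], rank=2) == {"Total": 0}

    def test_totals_conserved_on_random_fixtures(self):
        rng = np.random.default_rng(6)
        taxa = [f"Bacteria;T{i}" for i in range(4)]
        for _ in range(25):
            n = int(rng.integers(1, 30))
            preds = [pred(f"s{i}", 100, lineage=taxa[int(rng.integers(4))])
                     for i in range(n)]
            consensus = {f"s{i}" for i in range(n) if rng.random() < 0.7}
            t = tally_taxa(consensus, preds, rank=2)
            assert t.pop("Total") == len(consensus) == sum(t.values())


class TestAbundance:
    def test_fractions(self):
        t = PeakTable("CfoI", (Peak(100, area=3.0), Peak(200, area=1.0)))
        assert relative_abundance(t) == {100: 0.75, 200: 0.25}

    def test_single_peak(self):
        assert relative_abundance(PeakTable("CfoI", (Peak(100, area=7.0),))) == {100: 1.0}

    def test_normalization_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(1, 15))
            sizes = np.sort(rng.uniform(50, 600, size=n))
            t = PeakTable("CfoI", tuple(
                Peak(float(s), area=float(rng.uniform(0.1, 100))) for s in sizes))
            assert sum(relative_abundance(t).values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_area_is_error(self):
        with pytest.raises(ValueError):
            relative_abundance(PeakTable("CfoI", (Peak(100, area=0.0),)))


class TestDriftCorrection:
    def test_linear_drift_recovered_from_anchors(self):
        # observed sizes drift as 1.5 + 0.99 * predicted
        anchors = [(p, 1.5 + 0.99 * p) for p in (80.0, 150.0, 320.0, 500.0)]
        a, b = fit_size_drift(anchors)
        assert a == pytest.approx(1.5, abs=1e-9)
        assert b == pytest.approx(0.99, abs=1e-12)
        assert correct_predicted_sizes([200.0], (a, b))[0] == pytest.approx(199.5)

    def test_too_few_anchors_raises(self):
        with pytest.raises(ValueError):
            fit_size_drift([(100.0, 101.0)])
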