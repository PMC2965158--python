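"""Non-interactive orchestration of the full analysis.

One run executes, per sample and enzyme: reference subsetting, seeded
closest-reference search, exact local alignment, fragment-size
estimation, taxonomy assignment, and optionally peak matching with
multi-enzyme consensus and a taxon tally.  All parameters come from a
:class:`RunConfig` (YAML-loadable; CLI flags override) and every output
is written as plain TSV/text so runs are scriptable and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml
from Bio import SeqIO

from . import peaks as peaks_mod
from .digest import EnzymeSpec, builtin_enzymes, load_enzyme_table
from .iupac import PrimerSpec, builtin_primers, load_primer_table, normalize_sequence
from .refdb import build_subset, parse_reference_fasta
from .search_align import ScoringParams, format_alignment_text
from .trf_core import TRFPrediction, predict_sample

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = [
    "sample_id", "enzyme", "best_hit_id", "ref_fragment_length",
    "est_fragment_length", "gap_length", "percent_identity", "lineage",
    "method", "flags", "rank",
]

NA = "NA"


@dataclass
class RunConfig:
    """Everything a run needs; the seed fixes all pseudo-randomness."""

    reference_fasta: str
    samples_fasta: str
    outdir: str
    primer_name: str = "27F"
    primer_sequence: str | None = None
    primer_orientation: str = "forward"
    enzymes: list[str] = field(default_factory=lambda: ["CfoI", "HaeIII", "AluI"])
    enzyme_file: str | None = None
    primer_file: str | None = None
    domain: str = "Bacteria"
    max_mismatch: int = 1
    min_length: int | None = None
    min_identity: float = 80.0
    tolerance: float = 2.0
    n_hits: int = 1
    tally_rank: int = 4
    consensus_required: int | None = None
    peak_tables: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolve_primer(self) -> PrimerSpec:
        if self.primer_sequence:
            return PrimerSpec(self.primer_name, self.primer_sequence,
                              self.primer_orientation)  # type: ignore[arg-type]
        table = builtin_primers()
        if self.primer_file:
            table.update(load_primer_table(self.primer_file))
        if self.primer_name not in table:
            raise ValueError(
                f"unknown primer {self.primer_name!r}; known: {sorted(table)}"
            )
        return table[self.primer_name]

    def resolve_enzymes(self) -> list[EnzymeSpec]:
        table = builtin_enzymes()
        if self.enzyme_file:
            table.update(load_enzyme_table(self.enzyme_file))
        missing = [e for e in self.enzymes if e not in table]
        if missing:
            raise ValueError(
                f"unknown enzyme(s) {missing}; known: {sorted(table)}"
            )
        return [table[e] for e in self.enzymes]


def read_sample_fasta(path: str | Path) -> dict[str, str]:
    """Plain sample FASTA -> {id: normalized sequence} (input order kept)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def render_prediction_row(pred: TRFPrediction) -> list[str]:
    def cell(v) -> str:
        if v is None:
            return NA
        if isinstance(v, float):
            return str(v)
        return str(v)

    return [
        pred.sample_id, pred.enzyme, cell(pred.best_hit_id),
        cell(pred.ref_fragment_length), cell(pred.est_fragment_length),
        cell(pred.gap_length), cell(pred.percent_identity),
        cell(pred.lineage), cell(pred.method),
        ",".join(sorted(pred.flags)) if pred.flags else "",
        cell(pred.rank),
    ]


def write_predictions_tsv(predictions: list[TRFPrediction], path: str | Path) -> None:
    """Tab-delimited export with header; absent values rendered ``NA``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for pred in predictions:
            fh.write("\t".join(render_prediction_row(pred)) + "\n")


def read_predictions_tsv(path: str | Path) -> list[TRFPrediction]:
    """Inverse of :func:`write_predictions_tsv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != PREDICTION_COLUMNS:
        raise ValueError(f"{path}: not a predictions TSV")

    def opt(v: str, conv):
        return None if v == NA else conv(v)

    out: list[TRFPrediction] = []
    for line in lines[1:]:
        c = dict(zip(PREDICTION_COLUMNS, line.split("\t")))
        out.append(TRFPrediction(
            sample_id=c["sample_id"], enzyme=c["enzyme"],
            best_hit_id=opt(c["best_hit_id"], str),
            ref_fragment_length=opt(c["ref_fragment_length"], int),
            est_fragment_length=opt(c["est_fragment_length"], int),
            gap_length=opt(c["gap_length"], int),
            percent_identity=opt(c["percent_identity"], float),
            lineage=opt(c["lineage"], str),
            method=opt(c["method"], str),
            flags=frozenset(c["flags"].split(",")) if c["flags"] else frozenset(),
            rank=opt(c["rank"], int),
        ))
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the whole analysis; returns the paths written.

    Per-sample failures are logged with sample context and skipped; the
    run raises only if every sample fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    primer = config.resolve_primer()
    enzymes = config.resolve_enzymes()

    references = parse_reference_fasta(config.reference_fasta)
    if primer.orientation == "reverse":
        # single forward code path: flip all sequences onto the labeled strand
        references = [r.reverse_complemented() for r in references]
        primer = primer.as_forward()
        samples = {
            sid: normalize_sequence(seq)[::-1].translate(str.maketrans("ACGT", "TGCA"))
            for sid, seq in read_sample_fasta(config.samples_fasta).items()
        }
    else:
        samples = read_sample_fasta(config.samples_fasta)

    subset = build_subset(
        references, primer, domain=config.domain,
        max_mismatch=config.max_mismatch, min_length=config.min_length,
    )
    logger.info("reference subset: %d of %d records retained",
                len(subset), len(references))

    predictions: list[TRFPrediction] = []
    aln_dump: list[str] = []
    n_failed = 0
    for sid, seq in samples.items():
        try:
            hits, by_enzyme = predict_sample(
                sid, seq, primer, enzymes, subset,
                n_hits=config.n_hits, min_identity=config.min_identity,
            )
        except Exception:
            logger.exception("sample %s failed; continuing", sid)
            n_failed += 1
            continue
        for hit, aln in hits:
            aln_dump.append(format_alignment_text(f"{sid} (hit {hit.rank})",
                                                  hit.ref_id, aln))
        for enzyme in enzymes:
            predictions.extend(by_enzyme[enzyme.name])
    if samples and n_failed == len(samples):
        raise RuntimeError("all samples failed; see log")

    paths: dict[str, Path] = {}
    paths["predictions"] = outdir / "predictions.tsv"
    write_predictions_tsv(predictions, paths["predictions"])
    paths["alignments"] = outdir / "alignments.txt"
    Path(paths["alignments"]).write_text("\n".join(aln_dump), encoding="utf-8")

    if config.peak_tables:
        matches_by_enzyme: dict[str, list[peaks_mod.PeakMatch]] = {}
        all_matches: list[peaks_mod.PeakMatch] = []
        for ename, ppath in config.peak_tables.items():
            table = peaks_mod.load_peak_table(ppath, ename)
            preds_e = [p for p in predictions if p.enzyme == ename]
            matches_by_enzyme[ename] = peaks_mod.match_to_peaks(
                preds_e, table, tolerance=config.tolerance
            )
            all_matches.extend(matches_by_enzyme[ename])
        required = config.consensus_required or len(matches_by_enzyme)
        consensus = peaks_mod.multi_enzyme_consensus(matches_by_enzyme, required)
        tally = peaks_mod.tally_taxa(consensus, predictions, rank=config.tally_rank)

        paths["matches"] = outdir / "matches.tsv"
        with open(paths["matches"], "w", encoding="utf-8") as fh:
            fh.write(f"# tolerance={config.tolerance}\n")
            fh.write("sample_id\tenzyme\tpeak_size\tpredicted\tdelta\tlineage\n")
            for m in all_matches:
                fh.write(f"{m.sample_id}\t{m.enzyme}\t{m.peak_size}\t"
                         f"{m.predicted}\t{m.delta}\t{m.lineage or NA}\n")
        paths["tally"] = outdir / "tally.tsv"
        with open(paths["tally"], "w", encoding="utf-8") as fh:
            fh.write(f"# chromatograms={','.join(sorted(matches_by_enzyme))} "
                     f"required={required} tolerance={config.tolerance}\n")
            fh.write("taxonomic_group\tn_sequences\n")
            for taxon, count in tally.items():
                fh.write(f"{taxon}\t{count}\n")

    paths["log"] = outdir / "run.log"
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write("# run parameters\n")
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
        fh.write(f"n_references: {len(references)}\n")
        fh.write(f"n_subset: {len(subset)}\n")
        fh.write(f"n_samples: {len(samples)}\n")
        fh.write(f"n_failed: {n_failed}\n")
        fh.write(f"n_predictions: {len(predictions)}\n")
    return paths
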