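"""Synthetic reference/sample/peak fixtures for download-free testing.

The generator emulates the study design the estimator targets: a
reference database of full-length 16S rRNA sequences grouped into taxa,
a clone library of directional reads whose first 10-30 bases (primer
included) are missing, and per-enzyme chromatogram peak tables whose
measured sizes jitter around the true fragment sizes and contain decoy
peaks.  Taxon structure is simulated by deriving every reference from a
per-taxon ancestor with a small substitution divergence; the primer
site and the planted restriction sites are kept intact so that a
taxon's T-RF is conserved, as it is for real lineages.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import EnzymeSpec, builtin_enzymes, terminal_fragment
from .iupac import IUPAC_SETS, PrimerSpec, builtin_primers
from .peaks import Peak, PeakTable, write_peak_table
from .refdb import ReferenceRecord, write_reference_fasta

BASES = np.array(list("ACGT"))

#: Default marine-bacterioplankton taxa (lineage, sampling weight).
DEFAULT_TAXA_PROFILE: list[tuple[str, float]] = [
    ("Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Roseobacter", 0.30),
    ("Bacteria;Proteobacteria;Alphaproteobacteria;Pelagibacterales;SAR11", 0.30),
    ("Bacteria;Proteobacteria;Gammaproteobacteria;Oceanospirillales;SAR86", 0.15),
    ("Bacteria;Cyanobacteria;Synechococcales;Synechococcaceae;Synechococcus", 0.15),
    ("Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae", 0.10),
]


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus its ground truth."""

    references: list[ReferenceRecord]
    samples: dict[str, str]
    truth: pd.DataFrame
    peak_tables: dict[str, PeakTable]
    primer: PrimerSpec
    enzymes: list[EnzymeSpec]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/TSV/CSV files; byte-identical for identical bundles."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["references"] = outdir / "references.fasta"
        write_reference_fasta(self.references, paths["references"])
        paths["samples"] = outdir / "samples.fasta"
        with open(paths["samples"], "w") as fh:
            for sid, seq in self.samples.items():
                fh.write(f">{sid}\n")
                for off in range(0, len(seq), 70):
                    fh.write(seq[off:off + 70] + "\n")
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for enzyme, table in self.peak_tables.items():
            p = outdir / f"peaks_{enzyme}.csv"
            write_peak_table(table, p)
            paths[f"peaks_{enzyme}"] = p
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _realize(rng: np.random.Generator, iupac: str) -> str:
    """A concrete realization of a degenerate IUPAC motif."""
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in iupac)


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: set[int]) -> str:
    """Substitute bases at ``rate`` outside protected 0-based positions."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _scrub_sites(
    rng: np.random.Generator,
    seq: list[str],
    enzymes: list[EnzymeSpec],
    zone: tuple[int, int],
    frozen: set[int],
) -> None:
    """Remove every recognition-site match overlapping ``zone`` (0-based,
    half-open) by resampling its non-frozen bases, in place."""
    lo, hi = zone
    for _ in range(200):
        dirty = False
        for enzyme in enzymes:
            patterns = {enzyme.site, _rc(enzyme.site)}
            for pattern in patterns:
                sets = [IUPAC_SETS[c] for c in pattern]
                start = max(0, lo - len(pattern) + 1)
                for i in range(start, min(hi, len(seq) - len(pattern) + 1)):
                    if all(seq[i + j] in sets[j] for j in range(len(pattern))):
                        editable = [i + j for j in range(len(pattern))
                                    if (i + j) not in frozen]
                        if not editable:
                            raise ValueError(
                                f"{enzyme.name} site inside the primer cannot be scrubbed"
                            )
                        k = editable[int(rng.integers(len(editable)))]
                        seq[k] = str(rng.choice(BASES))
                        dirty = True
        if not dirty:
            return
    raise ValueError("could not scrub recognition sites from the conserved zone")


def _rc(site: str) -> str:
    from .iupac import reverse_complement

    return reverse_complement(site)


def _insert_alignment_gaps(rng: np.random.Generator, seq: str) -> str:
    """Pad a sequence into a mock model alignment with '-'/'.' gap runs."""
    pieces = [rng.choice(["-", "."]) * int(rng.integers(5, 40))]
    cuts = sorted(rng.integers(1, len(seq), size=int(rng.integers(2, 6))))
    prev = 0
    for c in [*cuts, len(seq)]:
        pieces.append(seq[prev:int(c)])
        pieces.append(rng.choice(["-", "."]) * int(rng.integers(1, 15)))
        prev = int(c)
    return "".join(pieces)


def generate_fixture(
    seed: int,
    n_refs: int = 50,
    n_samples: int = 200,
    taxa_profile: list[tuple[str, float]] | None = None,
    enzymes: list[EnzymeSpec] | None = None,
    primer: PrimerSpec | None = None,
    mutation_rate: float = 0.0,
    ref_divergence: float = 0.02,
    truncation_range: tuple[int, int] = (10, 30),
    read_length_range: tuple[int, int] = (450, 600),
    ref_length_range: tuple[int, int] = (1250, 1450),
    cut_depth_range: tuple[int, int] = (80, 560),
    taxa_cut_depths: dict[str, dict[str, int]] | None = None,
    decoys_per_enzyme: int = 5,
    jitter: float = 0.5,
    conserved_5p: int = 40,
) -> FixtureBundle:
    """Generate references, truncated samples, truth table and peak tables.

    Parameters mirror the targeted study conditions: samples are
    5'-truncated by 10-30 nt, per-taxon references diverge by ~2%
    substitutions, optional sample ``mutation_rate`` models residual
    divergence between a clone and its closest reference, and peak
    sizes jitter by at most ``jitter`` nt around the true fragment
    sizes.  ``taxa_cut_depths`` pins the planted cut depth (nt from the
    primer's labeled base) per taxon and enzyme, e.g. to construct taxa
    that share a T-RF under one enzyme but not another.

    The first ``conserved_5p`` nucleotides downstream of the labeled
    primer base are kept free of recognition sites and excluded from
    the divergence model, mirroring the conserved helix regions that
    flank universal 16S primer sites; T-RFs that short would in any
    case fall below the lower detection bound of common size standards.
    Explicitly pinned cut depths (``taxa_cut_depths``) override the
    scrub, which is how cut-inside-the-gap scenarios are constructed.

    Each sample's ground-truth T-RF is the digestion of *that clone's*
    untruncated amplicon: the source reference's 5' prefix restored in
    front of the (possibly mutated) sequenced read, continued by the
    reference tail.
    """
    if n_refs < 2:
        raise ValueError("need at least 2 references")
    rng = np.random.default_rng(seed)
    profile = taxa_profile or DEFAULT_TAXA_PROFILE
    enzymes = enzymes if enzymes is not None else _default_enzymes()
    primer = primer or builtin_primers()["27F"]
    if primer.orientation != "forward":
        raise ValueError("fixtures are generated in forward-primer orientation")

    ancestors = []
    for lineage, _ in profile:
        ancestors.append(_make_ancestor(
            rng, lineage, primer, enzymes,
            ref_length_range, cut_depth_range,
            (taxa_cut_depths or {}).get(lineage),
            conserved_5p,
        ))

    weights = np.array([w for _, w in profile], dtype=float)
    weights /= weights.sum()
    taxon_of_ref = rng.choice(len(profile), size=n_refs, p=weights)
    references: list[ReferenceRecord] = []
    ref_meta: list[dict] = []
    for i in range(n_refs):
        anc = ancestors[int(taxon_of_ref[i])]
        seq = _mutate(rng, anc["seq"], ref_divergence, anc["protected"])
        aligned = _insert_alignment_gaps(rng, seq)
        nongap = [k for k, c in enumerate(aligned) if c not in "-."]
        references.append(ReferenceRecord(
            id=f"R{i:05d}",
            lineage=tuple(anc["lineage"].split(";")),
            aligned_seq=aligned,
            first_nongap_fwd=nongap[0] + 1,
            first_nongap_rev=nongap[-1] + 1,
        ))
        ref_meta.append({"primer_start": anc["primer_start"], "lineage": anc["lineage"]})

    samples: dict[str, str] = {}
    truth_rows: list[dict] = []
    lo_d, hi_d = truncation_range
    lo_r, hi_r = read_length_range
    for j in range(n_samples):
        ridx = int(rng.integers(n_refs))
        rec, meta = references[ridx], ref_meta[ridx]
        amplicon = rec.ungapped_seq[meta["primer_start"] - 1:]
        d = int(rng.integers(lo_d, hi_d + 1))
        read_len = int(rng.integers(lo_r, hi_r + 1))
        if d >= len(amplicon):
            raise ValueError("truncation exceeds amplicon length")
        read = amplicon[d:d + read_len]
        # the conserved primer-proximal zone stays identical to the source
        protected_read = set(range(max(0, conserved_5p - d)))
        read = _mutate(rng, read, mutation_rate, protected_read)
        # the clone's own full-length amplicon: restored 5' prefix, the
        # sequenced (possibly divergent) read, and the reference tail
        clone_amplicon = amplicon[:d] + read + amplicon[d + len(read):]
        sid = f"S{j:04d}"
        samples[sid] = read
        row = {
            "sample_id": sid, "source_ref": rec.id,
            "lineage": meta["lineage"], "truncation": d,
            "read_length": len(read),
        }
        for enzyme in enzymes:
            trf = terminal_fragment(clone_amplicon, 1, enzyme)
            if trf is not None and trf > len(clone_amplicon):
                raise ValueError(f"T-RF {trf} longer than amplicon for {rec.id}")
            row[f"trf_{enzyme.name}"] = trf
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    peak_tables: dict[str, PeakTable] = {}
    for enzyme in enzymes:
        col = truth[f"trf_{enzyme.name}"].dropna()
        true_sizes = sorted({int(v) for v in col})
        peaks = []
        for size in true_sizes:
            peaks.append(Peak(
                size=size + float(rng.uniform(-jitter, jitter)),
                height=float(np.round(rng.lognormal(6.0, 0.8), 1)),
                area=float(np.round(rng.lognormal(8.5, 0.8), 1)),
            ))
        n_decoys = 0
        while n_decoys < decoys_per_enzyme:
            size = float(np.round(rng.uniform(50, 620), 1))
            if all(abs(size - t) > 3.0 for t in true_sizes):
                peaks.append(Peak(
                    size=size,
                    height=float(np.round(rng.lognormal(4.5, 0.5), 1)),
                    area=float(np.round(rng.lognormal(6.5, 0.5), 1)),
                ))
                n_decoys += 1
        peak_tables[enzyme.name] = PeakTable(enzyme=enzyme.name, peaks=tuple(peaks))

    return FixtureBundle(
        references=references, samples=samples, truth=truth,
        peak_tables=peak_tables, primer=primer, enzymes=enzymes,
    )


def _default_enzymes() -> list[EnzymeSpec]:
    table = builtin_enzymes()
    return [table["CfoI"], table["HaeIII"], table["AluI"]]


def _make_ancestor(
    rng: np.random.Generator,
    lineage: str,
    primer: PrimerSpec,
    enzymes: list[EnzymeSpec],
    ref_length_range: tuple[int, int],
    cut_depth_range: tuple[int, int],
    pinned_depths: dict[str, int] | None,
    conserved_5p: int = 40,
) -> dict:
    """One taxon ancestor: prefix + concrete primer site + downstream body
    with one planted recognition site per enzyme at a randomized depth."""
    prefix_len = int(rng.integers(20, 61))
    total_len = int(rng.integers(*ref_length_range))
    primer_site = _realize(rng, primer.sequence)
    body_len = total_len - prefix_len - len(primer_site)
    seq = list(_random_seq(rng, prefix_len) + primer_site + _random_seq(rng, body_len))
    primer_start = prefix_len + 1  # 1-based position of the labeled base

    _scrub_sites(rng, seq, enzymes,
                 zone=(prefix_len, prefix_len + conserved_5p),
                 frozen=set(range(prefix_len, prefix_len + len(primer_site))))

    protected: set[int] = set(range(prefix_len, prefix_len + conserved_5p))
    protected.update(range(prefix_len, prefix_len + len(primer_site)))
    occupied: list[tuple[int, int]] = [(prefix_len, prefix_len + len(primer_site))]
    max_depth = min(cut_depth_range[1], total_len - primer_start - 20)
    planted_start: dict[str, int] = {}
    for enzyme in enzymes:
        if pinned_depths and enzyme.name in pinned_depths:
            depth = pinned_depths[enzyme.name]
        else:
            depth = int(rng.integers(cut_depth_range[0], max_depth + 1))
        if depth > total_len - primer_start:
            raise ValueError(
                f"cut depth {depth} for {enzyme.name} exceeds amplicon length"
            )
        site = _realize(rng, enzyme.site)
        # place the site so its top-strand cut lands `depth` nt from the
        # labeled base; shift right until clear of primer/earlier sites
        desired = (primer_start - 1) + (depth - enzyme.cut_offset_top)
        start0 = desired
        while any(start0 < e and start0 + len(site) > s for s, e in occupied):
            start0 += 10
        if pinned_depths and enzyme.name in pinned_depths and start0 != desired:
            raise ValueError(
                f"pinned cut depth {depth} for {enzyme.name} would overlap "
                "the primer or another planted site"
            )
        if start0 + len(site) > total_len:
            raise ValueError(f"no room to plant {enzyme.name} site at depth {depth}")
        seq[start0:start0 + len(site)] = list(site)
        occupied.append((start0, start0 + len(site)))
        protected.update(range(start0, start0 + len(site)))
        planted_start[enzyme.name] = start0

    # a pinned depth means the planted cut IS the first cut: clear any
    # accidental upstream site of that enzyme.  Iterate to a fixed point,
    # since scrubbing one enzyme's zone can create a site for another.
    pinned = [e for e in enzymes if pinned_depths and e.name in pinned_depths]
    for _ in range(50):
        before = "".join(seq)
        for enzyme in pinned:
            _scrub_sites(rng, seq, [enzyme],
                         zone=(prefix_len, planted_start[enzyme.name]),
                         frozen=protected)
        if "".join(seq) == before:
            break
    else:
        raise ValueError("could not clear accidental sites upstream of pinned cuts")

    return {
        "lineage": lineage,
        "seq": "".join(seq),
        "primer_start": primer_start,
        "protected": protected,
    }
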