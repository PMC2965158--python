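# Methods

## The problem

Terminal-Restriction Fragment Length Polymorphism (T-RFLP) fingerprints a
microbial community by PCR-amplifying the 16S rRNA gene with a
fluorescently labeled primer, digesting the amplicons with a restriction
endonuclease, and sizing only the labeled terminal fragments (T-RFs) on a
capillary sequencer. Each chromatogram peak aggregates every community
member whose first recognition site sits at the same distance from the
labeled primer. A fingerprint alone carries no taxonomy; attaching labels
to peaks requires predicting, for candidate sequences, the T-RF each would
produce.

The obstacle this package addresses is that candidate sequences —
directional Sanger reads of clone libraries, or 16S fragments mined from
metagenomes — are usually 5'-truncated: the first 10–30 bases, including
the primer site, are missing, so the T-RF cannot be read off the sequence
directly.

## The estimator

For a sample sequence *s* and a labeled primer *P*:

1. **Reference subsetting.** From a reference database of full-length
   16S sequences (FASTA with augmented headers carrying accession,
   lineage, and the first/last non-gap columns of the source model
   alignment), keep records of the requested domain whose ungapped length
   strictly exceeds 1200 nt (Bacteria) or 900 nt (Archaea) and in which a
   fuzzy IUPAC search locates *P* with at most `max_mismatch`
   substitutions (default 1). The best primer hit (fewest mismatches,
   then leftmost) is stored per record as the coordinate anchor.
2. **Closest-reference search.** Candidates are ranked by distinct
   shared *k*-mers (*k* = 11, top 25 kept; references sharing no *k*-mer
   are not candidates), then re-ranked by exact Smith–Waterman alignment.
   Final order: alignment score desc, seed count desc, accession asc.
3. **Gap measurement.** With the best hit's local alignment,

       gap = ref_start − primer_start − (sample_start − 1)

   i.e. the reference distance from the labeled primer base to the first
   aligned column, minus any unaligned sample prefix (those bases are
   present sequence, not missing). A negative gap — the sample apparently
   extending upstream of the primer — is clamped to 0 and flagged, and
   the sample-side search then starts at the base aligned to the primer
   start.
4. **Fragment estimate.** If the sample itself contains a recognition
   site, `est = gap + (first cut position in the sample)`
   (method `sample-site`). If it does not, or if the reference shows its
   first cut falls *inside* the missing 5' stretch
   (`ref_cut < ref_start`, flagged `cut-in-gap`), the reference's own
   terminal fragment is adopted (method `reference-estimated`).
5. **Taxonomy.** The best hit's lineage, optionally truncated to a rank
   depth, labels the prediction. Identities below 80% (configurable) are
   flagged low-confidence; the closest-hit label is a candidate, not a
   positive identification.

Peak labeling then matches predictions to observed chromatogram peaks
within a size tolerance (default ±2 nt; measured sizes are fractional and
drift from true nucleotide counts, and an optional linear drift correction
`observed = a + b·predicted` can be fitted on anchor pairs). Because
unrelated taxa can share a T-RF under one enzyme, a sequence's label is
only trusted when its predictions match observed peaks under at least two
enzymes (`multi_enzyme_consensus`, default: all enzymes supplied).

## Coordinate and scoring conventions

* All positions are 1-based inclusive; "cut at *p*" means cleavage
  between bases *p* and *p*+1; fragment lengths include the primer's 5'
  labeled base. T-RFs are defined on the labeled strand only, which is
  what the size standard measures.
* Enzyme definitions carry the recognition site (IUPAC, degenerate
  allowed) and the REBASE-style cut offset pair: top-strand offset from
  the site's 5' start, bottom-strand cut expressed in top-strand
  coordinates. Reverse-complement site matches of non-palindromic
  enzymes cut the labeled strand at `site_len − cut_offset_bottom` from
  the match start. Caret notation (`GCG^C`) is accepted and expanded
  assuming symmetric geometry. Methylation sensitivity and partial
  digestion are out of scope.
* Primer/subject degeneracy is asymmetric: primer codes are base sets;
  subject bases must be concrete, and an ambiguous subject base is a
  mismatch. Mismatches are substitutions only (fixed-length motifs).
* Alignment scoring: match +5, mismatch −4, gap open 10, gap extend 0.5
  (a gap of length L costs `10 + 0.5·L`). Percent identity counts
  identical columns over all alignment columns, gaps included. Traceback
  is deterministic (diagonal > up > left; earliest maximal cell in
  row-major order), so outputs are bit-reproducible. The inner loop is
  numba-compiled with a pure-Python fallback.
* Reverse-primer analyses reverse-complement references and samples once
  and run the identical forward code path.

## The synthetic data generator

`trflp.fixtures.generate_fixture` emulates the targeted study design
without any database download:

* A handful of marine bacterioplankton taxa (Roseobacter, SAR11, SAR86,
  *Synechococcus*, Flavobacteriaceae by default), each with a random
  ancestor sequence of 1250–1450 nt carrying a concrete realization of
  the primer (27F by default) after a 20–60 nt 5' flank, and one planted
  recognition site per enzyme at a random depth of 80–560 nt from the
  labeled base. References diverge from their taxon ancestor by 2%
  substitutions (primer and planted sites kept intact, as the
  corresponding stems are conserved in real rRNA); mock alignment gap
  runs (`-`/`.`) are inserted for the augmented headers.
* Samples are 5'-truncated reads: 10–30 nt removed ahead of a 450–600 nt
  read, optionally with additional point substitutions
  (``mutation_rate``) modeling residual clone-to-reference divergence.
* The ground truth for each sample is the digestion of *that clone's*
  untruncated amplicon — the source reference's 5' prefix restored in
  front of the (possibly mutated) read, continued by the reference tail.
  This is the quantity the method claims to recover; defining truth on
  the unmutated source instead would penalize the estimator for
  faithfully reporting a genuinely different restriction site in the
  clone.
* The first 40 nt downstream of the labeled base are kept free of
  recognition sites and excluded from the divergence model. Real T-RFs
  that short fall below the lower detection bound of common size
  standards, and the region flanking a universal primer site is strongly
  conserved; structurally, this guarantees the first cut site survives
  truncation, which is the precondition under which exact recovery is
  claimed. Explicitly pinned per-taxon cut depths override the scrub
  (that is how cut-inside-the-gap fixtures are built), and upstream
  accidental sites of pinned enzymes are removed to a fixed point so the
  pinned depth is the realized fragment.
* Peak tables contain each realized fragment size with uniform jitter of
  at most ±0.5 nt, log-normal heights/areas, and 5 decoy peaks per
  enzyme placed at least 3 nt from any true size.

Everything derives from one integer seed (NumPy `default_rng`); two runs
with the same seed write byte-identical files.

What the generator does **not** emulate: chimeras, indel sequencing
errors, primer-site divergence, pseudo-random community abundance
structure, multiple rRNA operons per genome, or electrophoretic
mobility bias beyond the linear drift model. Passing tests therefore
demonstrate the correctness of the coordinate arithmetic and search
machinery under realistic truncation and divergence, not robustness to
every artifact of real chromatograms.

## Problem sizes and numerics

The recovery experiments use 50 references × 200 samples × 3 enzymes
(CfoI, HaeIII, AluI), the oracle-equivalence suites ≥ 200 random
instances each (sequences ≤ 60 nt for alignment, ≤ 120 nt for digestion),
chosen as the smallest sizes at which every code path (multi-taxon
competition, seed ranking, degenerate sites, both site orientations) is
exercised. Alignment scores are float64; score equality against the
brute-force oracle is asserted to 1e-9. Ties in peak matching go to the
smaller peak size; ties in candidate ranking to the lexicographically
smaller accession; equal-score gap opening is preferred over extension.

## Known limitations

* The k-mer seeded search is exact-scoring but heuristic in candidate
  selection: a homolog sharing no 11-mer with the sample (< ~80%
  identity, roughly) is never aligned. For 16S data this is far below
  any useful assignment identity.
* One prediction row per hit is emitted (rank-ordered); summarizing
  alternate hits per sample is left to downstream tooling.
* Chromatogram peak calling from raw electropherograms (binary `.fsa`)
  is out of scope; peak tables are expected as CSV exports.
* The augmented reference header dialect
  (`>id|lineage|first_nongap_fwd|first_nongap_rev`) is this package's
  own, configurable, round-trippable convention; the non-gap columns
  refer to the source model alignment and are retained for diagnostics
  only.
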