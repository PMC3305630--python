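# Methods

## Coordinate and sequence conventions

Genomic coordinates are 1-based inclusive.  A CDS is stored in reading
direction: `start_coord` is the first coding base and `stop_coord` the last,
so a minus-strand CDS has `start_coord > stop_coord`; GFF3 I/O converts to
and from the usual `start <= end` + strand representation.  CDS spans include
the stop codon (the GFF3/GenBank habit), and `extract_and_translate` strips a
trailing stop; the pure arithmetic `coords_to_length` is
`(|stop − start| + 1)/3` regardless, so both span conventions are usable.
Translation uses NCBI table 11; a canonical initiator (ATG/GTG/TTG) is
rendered as Met at position 1 only.  Ambiguity codes translate to X, and
peptides containing X can never match evidence.  Reading frames are +1..+3
anchored at the replicon's first base and −1..−3 anchored at its last base.
Circular topology is stored but replicons are scanned as linear: replicon
ends act as virtual stop codons, so terminal partial segments are eligible
ORFs and a gene spanning the origin would be missed (a documented
limitation, not a silent one — the alternate "both bounding stops required"
mode is available as `require_both_stops`).

## Six-frame database

`enumerate_orfs` partitions each frame's translation at stop codons and
keeps inter-stop segments of ≥ `min_orf_aa` residues ("more than forty":
41 by default, the boundary is unit-tested).  ORF ids are
`{replicon}:{frame}:{span_start}-{span_end}`, self-describing and stable
across runs; FASTA headers additionally carry the placement fields so a
search database round-trips without the genome.

## Evidence model

The interchange format is a plain TSV of non-redundant peptide/ORF matches
(peptide, orf_id, p_value, rank, spectral_count, condition, tryptic_status)
rather than a search-engine export: the spectrum-scoring stage is out of
scope, and a documented TSV makes the simulator a drop-in evidence source.
Filtering keeps rank-1 records with *p* strictly below 0.005.  Peptides
whose sequence matches more than one ORF are mapped to all of them, flagged
shared, and never count toward the two-peptide validation rule — a
conservative parsimony that prevents spurious novel calls.  I and L are
distinct characters throughout (sequences come from the same database, so
no ambiguity can arise internally).  The decoy database is per-ORF full
sequence reversal; FDR is (distinct decoy ids)/(distinct target ids) at
peptide or protein level, with a spectral-count mode reported alongside,
and is NaN (not 0) when there are no target identifications.

A semi-tryptic N-terminal peptide from a GTG/TTG initiator starts with Met
in the mature protein but reads Val/Leu inside a stop-to-stop translation,
so mapping tolerates a position-0 M/V or M/L mismatch for `semi_N` peptides;
the canonical-codon check happens later against the genome.

## Classification cascade

Sequencing errors are resolved first, because the two fragment ORFs of a
frameshifted gene would otherwise be mis-called as novel genes.  A
frame-split candidate is a pair of peptide-bearing ORFs on one strand in
different frames whose supported spans are collinear and separated by at
most `frame_gap_max_nt` (600 nt; configurable — the observable split
distance is bounded by how far a shifted reading runs before hitting a
stop).  Pairs where either ORF contains an annotated same-frame CDS are
skipped: an annotated gene explains its own peptides, and peptide evidence
alone can never justify "fusing" a real gene with its neighbour.  A member
ORF supported by a single peptide must meet the stringent one-hit rule
(*p* < 3.2 × 10⁻⁵).  The resolver tries deleting every base in the
bracketed interval (insertions of each base are a secondary mode, tried
only when no deletion works, since observed frame splits trace back to
inserted bases); an edit is accepted when all supporting peptides fall in
one inter-stop segment of the re-translated window (±400 nt around the
supported spans).  Accepted positions with identical corrected proteins
collapse into one interval, then each interval is expanded over its
homopolymer run — removing any base of the run yields the identical edited
sequence, so the positions are provably equivalent.  When chained candidates
share a member ORF, only one can be real (a single-base edit makes exactly
one frame junction); the least ambiguous resolution wins: unique edit first,
then tightest search interval, then most supporting peptides.

Novel/wrong-CDS classification then runs on validated, unannotated,
unresolved ORFs.  Overlap means ≥ 1 shared nucleotide on either strand (the
strictest reading; wrong-CDS cases include opposite-strand overlaps).  A
validated ORF overlapping only undetected, homology-free annotated CDSs
displaces them; overlapping a *detected* CDS yields a conflict, which
`shorten_conflicting_cds` tries to dissolve by moving the detected gene's
start downstream — the shortened gene must still cover all its own peptides
(and a homology-supported region when one is supplied), otherwise the
conflict stands and is reported.

`choose_start` proposes the canonical codon (ATG/GTG/TTG) nearest upstream
of the most upstream supporting residue, scanning toward the bounding stop.
Choosing the nearest rather than the furthest codon deliberately avoids the
longest-ORF bias that produces wrong-start annotations in the first place;
homology-guided start refinement belongs to the ortho stage.  N-terminal
Met excision is not gated on the penultimate residue at classification time
(the codon categories record what was observed; users can apply the
A/C/G/P/S/T/V rule post hoc).  An N-terminal extension resting on a single
upstream peptide is likewise held to the one-hit p-value rule, which keeps
random false matches out of structural calls.

Calls are ordered deterministically by (replicon, leftmost coordinate,
category).

## Ortho-extension

The aligner is exact Smith-Waterman (Bio.Align, BLOSUM62, BLAST-style affine
cost: a gap of length k costs 11 + k), scored on a Karlin-Altschul scale
with published gapped parameters (K = 0.041, λ = 0.267).  The E-values are
approximate — thresholds are configurable and the tests assert threshold
behaviour on planted homologs, not engine-exact E-values.  Standard
12-column tabular hit files can be imported for real-genome runs.  Novel
proteins are searched against each subject's six-frame ORFs; hits whose
span overlaps an annotated subject CDS are suppressed (only unannotated
homologous regions are reportable).  For start propagation the best subject
homolog per query at E < 10⁻³⁰ is aligned; the N-terminal offset (subject
alignment start minus query alignment start, positive = subject annotated
too long) decides the verdict, and a correction is proposed only when a
canonical codon sits at the implied subject position — otherwise the case
is undecidable, never force-corrected.

## Synthetic study conditions

The generator packs 50 non-overlapping genes (80–250 codons) with 60–150 nt
spacers into 48 kb at 60% GC, start codons drawn at ATG/GTG/TTG =
0.94/0.05/0.01, on both strands.  The planted-error slate is 5 missed genes
(2 as one-hit wonders, 1 of those transcribed), 4 starts moved upstream and
4 downstream to another in-frame canonical codon, 3 spurious opposite-strand
CDSs each displacing a real gene, and 2 single-base insertions — roughly the
relative frequencies of the error classes a deep bacterial survey reports,
at toy scale.  Frameshifted genes are absent from the published annotation
entirely (a gene caller skips an ORF with an internal frame break).

Detection is a gene-level × peptide-level Bernoulli model
(0.85 × 0.75 by default) with negative-binomial spectral counts, the
simplest model producing one-hit wonders and realistic coverage spread.
True-match p-values are log-uniform on [10⁻⁹, 10⁻⁴] and false matches
uniform on [10⁻⁴, 0.05], so both the 0.005 and the 3.2 × 10⁻⁵ thresholds
are genuinely exercised.  Error-carrying genes are always expressed and
their diagnostic peptides always detected (`guarantee_error_evidence`): an
annotation error in a silent gene is undiscoverable in principle, so leaving
it to detection chance would measure the detector's luck rather than the
classifier's correctness; everything else stays stochastic.  Base insertions
are planted at tryptic-boundary codons so the flanking peptides bracket the
edit tightly; otherwise the set of reconciling single-base edits is provably
wider than the homopolymer run (any edit between the innermost peptides that
avoids an in-frame stop reconciles the frames) and no peptide-only evidence
can narrow it — the corresponding real-world disambiguation is resequencing,
which has no synthetic counterpart.  N-terminal peptides follow the
biological Met-excision rule (removed when residue 2 is A/C/G/P/S/T/V); TTG
genes emit an N-terminal peptide only in excised form.

Clade subjects substitute 10% of residues (uniform over the other 19),
re-draw synonymous codons and start/stop codons, shuffle intergenic
sequence, omit ~5% of genes from the subject annotation (the
unannotated-homolog situation) and plant start errors in 12% of annotated
subject genes, choosing another in-frame canonical codon 2–15 codons away
with no intervening stop.

What passing tests show — and what they do not: the synthetic data have no
spectra, no mass accuracy, no modifications, no retention times, no protein
inference ambiguity beyond shared sequences, i.i.d. codon composition, and
conveniently bracketed frameshifts.  Recovery at ≥ 0.9 recall/precision
therefore demonstrates the correctness of the mapping and classification
logic under the stated evidence model, not the end-to-end sensitivity of a
real MS/MS survey.

## Problem sizes and determinism

Default simulations use 48 kb / 50 genes; recovery statistics average 20
seeds and the clade statistics 20 seeds × 3 subjects — sizes chosen so the
full suite and the acceptance script each run in about a minute on one CPU
while every planted-error category still occurs dozens of times.  All
randomness flows from a single integer seed through
`numpy.random.default_rng` seed sequences; identical config + inputs + seed
reproduce byte-identical outputs (hash-compared in tests).  The pipeline
caches the search-database stage keyed by the genome digest recorded in the
run manifest.

## Known limitations

* Origin-spanning genes of circular replicons are not scanned (linear scan
  with virtual stops).
* Start-correction calls for unannotated (novel) genes report the nearest
  canonical codon covering the evidence; without homology the true start may
  lie further upstream.
* The one-hit-wonder rule depends on an externally supplied
  transcription-evidence table; the pipeline never infers transcription.
* E-values from the built-in aligner are on the right scale but not
  engine-exact; for publication-grade clade scans import external tabular
  hits.
* A frameshift whose fragments lack bracketing peptides within 600 nt is
  reported as a candidate at best; its edit interval may exceed the
  homopolymer run.
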