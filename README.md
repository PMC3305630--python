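# proteoseed

Proteogenomic re-annotation of bacterial genomes from shotgun MS/MS peptide
evidence, with ortho-proteogenomic propagation of the corrections to related
genomes.

Automated structural annotation of bacterial genomes misses small or
lineage-specific genes, picks wrong start codons (gene callers are biased
toward the longest open reading frame), occasionally annotates a spurious CDS
on the wrong strand, and inherits single-base sequencing errors that split a
real gene across two reading frames.  Peptides identified by tandem mass
spectrometry are direct evidence of translation: mapped back onto the genome
through a six-frame translation database they reveal each of these error
classes.  `proteoseed` implements that strategy as a reusable pipeline for
bioinformaticians working on bacterial (re-)annotation, and ships a synthetic
data generator that plants every error class with a ground-truth ledger so
the whole pipeline is testable without spectra.

## Method

1. **Six-frame database** — every maximal inter-stop ("stop-to-stop") segment
   of ≥ 41 residues, in all six reading frames, becomes a database entry
   (replicon ends act as virtual stops).  The database deliberately mixes all
   real CDSs with a large excess of aberrant translation products.
2. **Evidence mapping** — peptide-spectrum matches (rank 1, *p* < 0.005) are
   placed at every occurrence inside their matched ORF and converted to
   genomic coordinates; re-translation of the mapped span must reproduce the
   peptide.  A protein is *validated* by ≥ 2 distinct unshared peptides;
   single-peptide ORFs are *one-hit wonders* held to a stricter rule
   (*p* < 3.2 × 10⁻⁵, no overlap with any detected gene) and promoted only
   with orthogonal transcription evidence.  FDR is estimated against a
   reversed-sequence decoy database.
3. **Refinement calls** — validated unannotated ORFs become `novel_cds`
   (empty region) or `wrong_cds_replacement` (displacing an undetected,
   homology-free annotated CDS); strictly tryptic peptides upstream of an
   annotated start yield `nterm_extension`; semi-tryptic N-terminal peptides
   (initiator Met retained or excised, over ATG/GTG/TTG) yield
   `start_confirmed`/`start_corrected`; collinear peptide-bearing ORF pairs
   on one strand in different frames are tested for a single-base edit that
   fuses them into one protein (`sequence_error`, homopolymer-aware
   correction intervals).
4. **Ortho-extension** — novel proteins are searched against related genomes'
   six-frame ORFs (Smith-Waterman, BLOSUM62, affine 11/1 gaps, Karlin-Altschul
   E-values; cutoff E < 10⁻²⁰, annotated regions suppressed); certified
   N-termini are aligned to each relative's annotated proteome (E < 10⁻³⁰)
   and a nonzero N-terminal alignment offset with a canonical codon at the
   implied position proposes a start correction; the summary statistic is
   corrected / (confirmed + corrected + undecidable).

## Worked example

Generate a synthetic fixture (50 genes, 48 kb, planted errors of every
class) and run the full pipeline:

```bash
proteoseed simulate --seed 5 --outdir fx
cat > run.yaml <<EOF
genome: fx/genome.fa
annotation: fx/published.gff3
psms: fx/psms.tsv
decoy_psms: fx/decoy_psms.tsv
transcription: fx/transcription.tsv
clade_dir: fx/clade
outdir: out
EOF
proteoseed run --config run.yaml
cat out/summary.txt
```

```
proteoseed summary
==================
novel_cds: 4
nterm_extension: 4
one_hit_candidate: 1
sequence_error: 2
start_confirmed: 24
start_corrected: 4
wrong_cds_replacement: 3
start codon usage: ATG 96%, GTG 4%, TTG 0%
peptide_fdr_distinct: 0.19%
protein_fdr_distinct: 4.00%
peptide_fdr_spectral: 0.04%
clade start-correction rate: 13.8%
```

This seed planted 5 missing genes (two as one-hit wonders, one of which has
transcription evidence), 4 + 4 start-codon errors in each direction, 3
spurious CDSs and 2 single-base insertions — the summary recovers them:
3 plain novel genes plus 1 promoted one-hit wonder, 4 upstream extensions and
4 semi-tryptic start corrections, 3 replacements of spurious CDSs, and both
insertions.  `out/calls.tsv` holds one row per call, e.g.

```
target   category               start  stop  length_aa  peptides  coverage  displaced_locus
PG006    wrong_cds_replacement  8626   8339  95         9         85%       FAKE_002
PG001    novel_cds              9190   9477  95         15        96%
```

with a revised GFF3 in `out/revised.gff3` and the clade tables in
`out/clade_novel.tsv` / `out/clade_starts.tsv`.  Identical inputs and seed
reproduce byte-identical outputs.

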