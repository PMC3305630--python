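"""Ortho-proteogenomics: propagate novel genes and certified N-termini to
related genomes with a local protein alignment search.

The aligner is exact Smith-Waterman (BLOSUM62, affine 11/1 gaps) scored on a
Karlin-Altschul E-value scale with published gapped parameters, so the usual
translated-search thresholds (E < 1e-20 for novel genes, E < 1e-30 for
N-terminus propagation) behave the way practitioners expect.  Standard
12-column tabular hit files from an external search tool can be imported
instead for real-genome runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import (
    AnnotationSet,
    CANONICAL_STARTS,
    GenomeRecord,
    ProteoseedError,
    position_of_codon,
)
from .refinement import PipelineConfig, codon_at
from .sixframe import enumerate_orfs

__all__ = [
    "AlignmentParams",
    "HomologyHit",
    "CladeStartCall",
    "smith_waterman",
    "evalue",
    "find_unannotated_homologs",
    "propagate_start_corrections",
    "read_blast_tab",
]


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_K: float = 0.041
    karlin_lambda: float = 0.267
    seed_word_aa: int = 3  # retained for tabular-import compatibility


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load(params.matrix)
    # BLAST-style affine cost: a gap of length k costs open + k*extend
    a.open_gap_score = -(params.gap_open + params.gap_extend)
    a.extend_gap_score = -params.gap_extend
    return a


def smith_waterman(query_aa: str, subject_aa: str,
                   params: AlignmentParams = AlignmentParams()):
    """Optimal local alignment (raw score, alignment or None).

    Returns score 0 and no alignment for fully dissimilar sequences.
    """
    if not query_aa or not subject_aa:
        raise ProteoseedError("empty sequence")
    a = _aligner(params)
    score = a.score(query_aa, subject_aa)
    if score <= 0:
        return 0.0, None
    aln = next(iter(a.align(query_aa, subject_aa)))
    return float(score), aln


def evalue(raw_score: float, query_len: int, db_residues: int,
           params: AlignmentParams = AlignmentParams()) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_residues <= 0:
        raise ProteoseedError("lengths must be positive")
    return params.karlin_K * query_len * db_residues * math.exp(
        -params.karlin_lambda * raw_score
    )


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str  # genome/strain label
    subject_replicon: str
    subject_start: int  # reading-direction convention
    subject_stop: int
    raw_score: float
    e_value: float
    query_interval: tuple = (0, 0)  # aligned query residues, 0-based half-open
    subject_locus: str = ""


@dataclass(frozen=True)
class CladeStartCall:
    query_id: str
    subject_id: str
    subject_locus: str
    verdict: str  # confirmed | corrected | undecidable
    proposed_start: int | None = None
    offset_codons: int = 0
    e_value: float = math.inf


# ---------------------------------------------------------------------------
# novel-gene extension (translated search against six-frame ORFs)
# ---------------------------------------------------------------------------

def find_unannotated_homologs(
    novel_proteins: list[tuple],
    subject_genomes: dict,
    subject_annotations: dict,
    config: PipelineConfig = PipelineConfig(),
    params: AlignmentParams = AlignmentParams(),
    min_orf_aa: int = 41,
) -> list[HomologyHit]:
    """Search novel proteins against each subject genome's six-frame ORFs.

    Hits below the novel-gene E-value cutoff are kept unless their subject
    span overlaps an annotated CDS (only unannotated homologous regions are
    of interest).
    """
    hits = []
    aligner = _aligner(params)
    for subj_id, genome in subject_genomes.items():
        orfs = enumerate_orfs([genome], min_length_aa=min_orf_aa)
        n_db = sum(len(o.aa_sequence) for o in orfs)
        ann = subject_annotations.get(subj_id)
        for qid, qseq in novel_proteins:
            for orf in orfs:
                score = aligner.score(qseq, orf.aa_sequence)
                if score <= 0:
                    continue
                e = evalue(score, len(qseq), n_db, params)
                if not (e < config.evalue_novel):
                    continue
                aln = next(iter(aligner.align(qseq, orf.aa_sequence)))
                q_blocks, s_blocks = aln.aligned
                s_aa_start, s_aa_end = s_blocks[0][0], s_blocks[-1][-1]
                g_start = orf.aa_to_genomic(s_aa_start)
                g_end = orf.aa_to_genomic(s_aa_end - 1)
                g_end = g_end + 2 if orf.frame > 0 else g_end - 2
                left, right = min(g_start, g_end), max(g_start, g_end)
                if ann is not None and any(
                    c.replicon_id == orf.replicon_id
                    and max(left, c.left) <= min(right, c.right)
                    for c in ann
                ):
                    continue
                hits.append(
                    HomologyHit(qid, subj_id, orf.replicon_id, g_start, g_end,
                                float(score), e,
                                (int(q_blocks[0][0]), int(q_blocks[-1][-1])))
                )
    hits.sort(key=lambda h: (h.query_id, h.subject_id, h.e_value))
    return hits


# ---------------------------------------------------------------------------
# N-terminus propagation
# ---------------------------------------------------------------------------

def propagate_start_corrections(
    validated_nterm_proteins: list[tuple],
    subject_proteomes: dict,
    subject_genomes: dict,
    subject_annotations: dict,
    config: PipelineConfig = PipelineConfig(),
    params: AlignmentParams = AlignmentParams(),
) -> tuple[list[CladeStartCall], float]:
    """Check each certified N-terminus against annotated homologs in subjects.

    For every query protein with a certified N-terminal residue, the best
    homolog per subject at E below the propagation cutoff is aligned; a zero
    N-terminal offset (after trimming terminal gaps) confirms the subject
    annotation, otherwise a canonical codon at the implied subject start
    yields a correction, else the case is undecidable.  The summary rate is
    corrected / (confirmed + corrected + undecidable).
    """
    aligner = _aligner(params)
    calls = []
    for subj_id, proteome in subject_proteomes.items():
        genome = subject_genomes[subj_id]
        ann: AnnotationSet = subject_annotations[subj_id]
        n_db = sum(len(s) for _, s in proteome)
        for qid, qseq in validated_nterm_proteins:
            best = None
            for locus, sseq in proteome:
                if not sseq:
                    continue
                score = aligner.score(qseq, sseq)
                if best is None or score > best[0]:
                    best = (score, locus, sseq)
            if best is None or best[0] <= 0:
                continue
            score, locus, sseq = best
            e = evalue(score, len(qseq), n_db, params)
            if not (e < config.evalue_nterm):
                continue
            aln = next(iter(aligner.align(qseq, sseq)))
            q_blocks, s_blocks = aln.aligned
            offset = int(s_blocks[0][0]) - int(q_blocks[0][0])
            cds = ann.by_tag(locus)
            if offset == 0:
                calls.append(CladeStartCall(qid, subj_id, locus, "confirmed",
                                            cds.start_coord, 0, e))
                continue
            pos = position_of_codon(cds.start_coord, cds.strand, offset)
            lo, hi = min(pos, pos + 2 if cds.strand == "+" else pos - 2), \
                     max(pos, pos + 2 if cds.strand == "+" else pos - 2)
            if lo < 1 or hi > len(genome):
                calls.append(CladeStartCall(qid, subj_id, locus, "undecidable",
                                            None, offset, e))
                continue
            codon = codon_at(genome, pos, cds.strand)
            if codon in config.canonical_starts:
                calls.append(CladeStartCall(qid, subj_id, locus, "corrected",
                                            pos, offset, e))
            else:
                calls.append(CladeStartCall(qid, subj_id, locus, "undecidable",
                                            None, offset, e))
    total = len(calls)
    corrected = sum(1 for c in calls if c.verdict == "corrected")
    rate = corrected / total if total else 0.0
    return calls, rate


# ---------------------------------------------------------------------------
# external hit import (12-column tabular)
# ---------------------------------------------------------------------------

def read_blast_tab(path, query_lens: dict | None = None) -> list[HomologyHit]:
    """Import outfmt-6-compatible tabular hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ProteoseedError(f"{path}: expected 12 tabular columns")
        hits.append(
            HomologyHit(f[0], f[1], f[1], int(f[8]), int(f[9]),
                        float(f[11]), float(f[10]),
                        (int(f[6]) - 1, int(f[7])))
        )
    return hits
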