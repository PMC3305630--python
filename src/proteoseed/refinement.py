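"""Annotation refinement: turn mapped peptide evidence into categorized calls.

Categories emitted
------------------
* ``novel_cds`` — a validated stop-to-stop ORF in a region with no annotated
  gene (or a promoted one-hit wonder with transcription evidence).
* ``one_hit_candidate`` — a single-peptide ORF passing the stringent p-value
  rule, pending orthogonal (transcription) evidence.
* ``wrong_cds_replacement`` — a validated ORF that displaces an undetected,
  homology-free annotated CDS it overlaps.
* ``conflict`` — a validated ORF overlapping a *detected* annotated CDS;
  reported, not called, and handed to :func:`shorten_conflicting_cds`.
* ``nterm_extension`` — strictly tryptic peptides upstream of an annotated
  start push the start upstream.
* ``start_confirmed`` / ``start_corrected`` — semi-tryptic N-terminal peptide
  evidence confirming or moving an annotated start codon.
* ``sequence_error`` — peptides split across two frames reconciled by a
  single-base edit (an inserted base, in practice).

Overlap is defined as >= 1 shared nucleotide on either strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .evidence import MappedPeptide, ProteinEvidence
from .genome_model import (
    CANONICAL_STARTS,
    AnnotationSet,
    CdsAnnotation,
    GenomeRecord,
    reverse_complement,
)
from .sixframe import OrfDatabase, StopToStopOrf, cds_in_orf, orf_containing_cds

__all__ = [
    "PipelineConfig",
    "RefinementCall",
    "SequenceErrorCall",
    "FrameSplitCandidate",
    "classify_detected_orfs",
    "one_hit_wonder_candidates",
    "accept_with_transcription",
    "nterm_extension_scan",
    "choose_start",
    "validate_starts_semitryptic",
    "detect_frame_split_candidates",
    "resolve_sequence_error",
    "shorten_conflicting_cds",
    "start_codon_usage",
    "refine_all",
    "RefinementResult",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All numeric thresholds of the refinement pipeline in one place."""

    min_orf_aa: int = 41
    min_peptides_validate: int = 2
    one_hit_p_max: float = 3.2e-5
    psm_p_max: float = 0.005
    canonical_starts: tuple = CANONICAL_STARTS
    frame_gap_max_nt: int = 600
    evalue_novel: float = 1e-20
    evalue_nterm: float = 1e-30


@dataclass(frozen=True)
class SequenceErrorCall:
    """A single-base edit reconciling a frame-split coding region.

    ``correction_interval`` is the inclusive genomic interval of equivalent
    edit positions (a homopolymer run collapses to one interval: removing any
    of its bases yields the same corrected genome).
    """

    replicon_id: str
    correction_interval: tuple  # (low, high) inclusive, forward coords
    corrected_protein: str
    supporting_frames: tuple
    supporting_peptides: tuple
    edit_type: str = "deletion"  # deletion | insertion
    inserted_base: str = ""
    note: str = ""


@dataclass
class RefinementCall:
    category: str
    new_cds: CdsAnnotation | None = None
    displaced_locus: str | None = None
    locus_tag: str | None = None  # annotated locus a start call concerns
    orf_id: str | None = None
    evidence: dict = field(default_factory=dict)
    nterm_category: str = "none"
    start_codon: str = ""
    sequence_error: SequenceErrorCall | None = None
    note: str = ""

    @property
    def sort_key(self):
        if self.new_cds is not None:
            return (self.new_cds.replicon_id, self.new_cds.left, self.category)
        if self.sequence_error is not None:
            return (self.sequence_error.replicon_id,
                    self.sequence_error.correction_interval[0], self.category)
        return (self.evidence.get("replicon", ""), self.evidence.get("left", 0),
                self.category)


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def codon_at(genome: GenomeRecord, pos: int, strand: str) -> str:
    """Codon whose first base in reading direction sits at ``pos``."""
    if strand == "+":
        return genome.sequence[pos - 1 : pos + 2]
    return reverse_complement(genome.sequence[pos - 3 : pos])


def _overlap(a_left, a_right, b_left, b_right) -> bool:
    return max(a_left, b_left) <= min(a_right, b_right)


def _annotated_orf_ids(db: OrfDatabase, annotation: AnnotationSet) -> dict:
    """orf_id -> list of locus_tags whose CDS it contains (same frame)."""
    out: dict[str, list] = {}
    for cds in annotation:
        o = orf_containing_cds(db, cds)
        if o is not None:
            out.setdefault(o.orf_id, []).append(cds.locus_tag)
    return out


def _supported_aa_offset(orf: StopToStopOrf, genomic_pos: int) -> int:
    """aa offset (0-based) of the codon at a reading-direction position."""
    if orf.frame > 0:
        return (genomic_pos - orf.span_start) // 3
    return (orf.span_start - genomic_pos) // 3


def _orf_stop_coord(orf: StopToStopOrf, genome: GenomeRecord) -> int:
    """3' boundary for a proposed CDS: include the bounding stop codon."""
    if orf.frame > 0:
        return orf.span_end + 3 if orf.span_end + 3 <= len(genome) else orf.span_end
    return orf.span_end - 3 if orf.span_end - 3 >= 1 else orf.span_end


def _propose_cds(
    tag: str,
    orf: StopToStopOrf,
    first_supported_pos: int,
    genome: GenomeRecord,
    config: PipelineConfig,
) -> tuple[CdsAnnotation, str]:
    """Proposed CDS from a canonical start covering the evidence to the stop."""
    off = _supported_aa_offset(orf, first_supported_pos)
    start = choose_start(orf, off, genome, config)
    note = ""
    if start is None:
        start = orf.aa_to_genomic(off)
        note = "no_canonical_start_upstream"
    cds = CdsAnnotation(tag, orf.replicon_id, start,
                        _orf_stop_coord(orf, genome), source="proteogenomic")
    return cds, note


# ---------------------------------------------------------------------------
# novel / wrong-CDS classification
# ---------------------------------------------------------------------------

def classify_detected_orfs(
    evidence: list[ProteinEvidence],
    annotation: AnnotationSet,
    db: OrfDatabase,
    genomes: list[GenomeRecord],
    homology_support: dict | None = None,
    config: PipelineConfig = PipelineConfig(),
    exclude_orf_ids: set | None = None,
    tag_prefix: str = "PG",
) -> list[RefinementCall]:
    """Classify every validated, unannotated ORF.

    ``homology_support`` marks annotated loci with credible homologs; such
    loci are never displaced.  ``exclude_orf_ids`` removes ORFs already
    explained by a sequence-error call.
    """
    homology_support = homology_support or {}
    exclude_orf_ids = exclude_orf_ids or set()
    by_id = {g.replicon_id: g for g in genomes}
    annotated = _annotated_orf_ids(db, annotation)
    detected_tags = {t for oid, tags in annotated.items()
                     for t in tags
                     if any(e.orf_id == oid and e.status == "validated" for e in evidence)}
    calls = []
    n = 0
    for e in sorted(evidence, key=lambda e: e.orf_id):
        if e.status != "validated" or e.orf_id in annotated or e.orf_id in exclude_orf_ids:
            continue
        orf = db.get(e.orf_id)
        genome = by_id[orf.replicon_id]
        overlapped = [
            c for c in annotation
            if c.replicon_id == orf.replicon_id
            and _overlap(e.supported_left, e.supported_right, c.left, c.right)
        ]
        first_pos = e.supported_left if orf.frame > 0 else e.supported_right
        n += 1
        tag = f"{tag_prefix}{n:03d}"
        cds, note = _propose_cds(tag, orf, first_pos, genome, config)
        ev = {
            "peptides": sorted(e.distinct_peptides),
            "n_peptides": len(e.distinct_peptides),
            "spectra": e.total_spectra,
            "replicon": orf.replicon_id,
            "left": e.supported_left,
        }
        if not overlapped:
            calls.append(RefinementCall("novel_cds", new_cds=cds, orf_id=e.orf_id,
                                        evidence=ev, note=note))
            continue
        conflicting = [c for c in overlapped
                       if c.locus_tag in detected_tags or homology_support.get(c.locus_tag)]
        if conflicting:
            calls.append(
                RefinementCall("conflict", new_cds=cds, orf_id=e.orf_id,
                               displaced_locus=conflicting[0].locus_tag,
                               evidence={**ev, "conflicting_loci":
                                         [c.locus_tag for c in conflicting]},
                               note=note)
            )
        else:
            calls.append(
                RefinementCall("wrong_cds_replacement", new_cds=cds, orf_id=e.orf_id,
                               displaced_locus=overlapped[0].locus_tag,
                               evidence={**ev, "displaced_loci":
                                         [c.locus_tag for c in overlapped]},
                               note=note)
            )
    return calls


# ---------------------------------------------------------------------------
# one-hit wonders
# ---------------------------------------------------------------------------

def one_hit_wonder_candidates(
    evidence: list[ProteinEvidence],
    annotation: AnnotationSet,
    detected_spans: list[tuple],
    config: PipelineConfig = PipelineConfig(),
    db: OrfDatabase | None = None,
    genomes: list[GenomeRecord] | None = None,
    tag_prefix: str = "PG_OH",
) -> list[RefinementCall]:
    """Single-peptide ORFs passing the stringent p rule, isolated from any
    detected gene span (zero-nucleotide tolerance, either strand)."""
    by_id = {g.replicon_id: g for g in genomes} if genomes else {}
    annotated = _annotated_orf_ids(db, annotation) if db else {}
    calls = []
    n = 0
    for e in sorted(evidence, key=lambda e: e.orf_id):
        if e.status != "one_hit" or e.orf_id in annotated:
            continue
        if not (e.best_p_value < config.one_hit_p_max):
            continue
        orf = db.get(e.orf_id) if db else None
        repl = orf.replicon_id if orf else ""
        if any(r == repl and _overlap(e.supported_left, e.supported_right, lo, hi)
               for r, lo, hi in detected_spans):
            continue
        n += 1
        cds = note = None
        if orf is not None and by_id:
            first_pos = e.supported_left if orf.frame > 0 else e.supported_right
            cds, note = _propose_cds(f"{tag_prefix}{n:03d}", orf, first_pos,
                                     by_id[repl], config)
        calls.append(
            RefinementCall("one_hit_candidate", new_cds=cds, orf_id=e.orf_id,
                           evidence={"peptides": sorted(e.distinct_peptides),
                                     "best_p_value": e.best_p_value,
                                     "replicon": repl, "left": e.supported_left},
                           note=note or "")
        )
    return calls


def accept_with_transcription(
    candidates: list[RefinementCall],
    transcription_evidence: dict,
) -> list[RefinementCall]:
    """Promote one-hit candidates with transcription evidence to novel_cds."""
    known = {c.orf_id for c in candidates}
    for oid in transcription_evidence:
        if oid not in known:
            warnings.warn(f"transcription evidence for unknown ORF {oid}", stacklevel=2)
    out = []
    for c in candidates:
        if c.category == "one_hit_candidate" and transcription_evidence.get(c.orf_id):
            out.append(replace_call(c, category="novel_cds",
                                    note=(c.note + ";transcription_confirmed").strip(";")))
        else:
            out.append(c)
    return out


def replace_call(call: RefinementCall, **kw) -> RefinementCall:
    d = dict(call.__dict__)
    d.update(kw)
    return RefinementCall(**d)


# ---------------------------------------------------------------------------
# start-codon work
# ---------------------------------------------------------------------------

def choose_start(
    orf: StopToStopOrf,
    must_cover_aa_offset: int,
    genome: GenomeRecord,
    config: PipelineConfig = PipelineConfig(),
) -> int | None:
    """Nearest in-frame canonical start at or upstream of a required residue.

    Scans upstream toward the bounding stop; returns the genomic coordinate
    of the codon's first base, or None when no canonical codon exists.
    """
    for k in range(must_cover_aa_offset, -1, -1):
        pos = orf.aa_to_genomic(k)
        if codon_at(genome, pos, orf.strand) in config.canonical_starts:
            return pos
    return None


def nterm_extension_scan(
    mapped: list[MappedPeptide],
    annotation: AnnotationSet,
    db: OrfDatabase,
    genomes: list[GenomeRecord],
    config: PipelineConfig = PipelineConfig(),
    detected_spans: list[tuple] | None = None,
    peptide_pvalues: dict | None = None,
) -> list[RefinementCall]:
    """Strictly tryptic peptides upstream of an annotated start, in frame and
    inside the same stop-to-stop ORF, trigger an N-terminal extension.

    An extension resting on a single upstream peptide must meet the stringent
    one-hit p-value rule (``peptide_pvalues`` maps sequence to best p)."""
    by_id = {g.replicon_id: g for g in genomes}
    detected_spans = detected_spans or []
    calls = []
    for cds in annotation:
        orf = orf_containing_cds(db, cds)
        if orf is None:
            continue
        ups = [
            m for m in mapped
            if m.orf.orf_id == orf.orf_id
            and m.peptide.tryptic_status == "full"
            and not m.shared
            and ((orf.frame > 0 and m.genomic_start < cds.start_coord)
                 or (orf.frame < 0 and m.genomic_start > cds.start_coord))
        ]
        if not ups:
            continue
        up_seqs = {m.peptide.sequence for m in ups}
        if len(up_seqs) == 1 and peptide_pvalues is not None:
            p = peptide_pvalues.get(next(iter(up_seqs)), 1.0)
            if not (p < config.one_hit_p_max):
                continue
        genome = by_id[orf.replicon_id]
        if orf.frame > 0:
            most_upstream = min(m.genomic_start for m in ups)
        else:
            most_upstream = max(m.genomic_start for m in ups)
        off = _supported_aa_offset(orf, most_upstream)
        start = choose_start(orf, off, genome, config)
        ev = {"upstream_peptides": sorted({m.peptide.sequence for m in ups}),
              "replicon": orf.replicon_id, "left": min(m.left for m in ups)}
        if start is None:
            calls.append(RefinementCall("nterm_extension", locus_tag=cds.locus_tag,
                                        orf_id=orf.orf_id, evidence=ev,
                                        note="no_canonical_start_upstream"))
            continue
        # the extension itself must not run into another detected gene
        ext_left = min(start, cds.start_coord)
        ext_right = max(start, cds.start_coord)
        clash = any(
            r == orf.replicon_id and _overlap(ext_left, ext_right, lo, hi)
            and not _overlap(cds.left, cds.right, lo, hi)
            for r, lo, hi in detected_spans
        )
        if clash:
            calls.append(RefinementCall("nterm_extension", locus_tag=cds.locus_tag,
                                        orf_id=orf.orf_id, evidence=ev,
                                        note="extension_overlaps_detected_gene"))
            continue
        new_cds = CdsAnnotation(cds.locus_tag, cds.replicon_id, start,
                                cds.stop_coord, cds.product, "proteogenomic")
        calls.append(
            RefinementCall("nterm_extension", new_cds=new_cds, locus_tag=cds.locus_tag,
                           orf_id=orf.orf_id, evidence=ev,
                           start_codon=codon_at(genome, start, orf.strand))
        )
    return calls


def validate_starts_semitryptic(
    mapped: list[MappedPeptide],
    annotation: AnnotationSet,
    genomes: list[GenomeRecord],
    config: PipelineConfig = PipelineConfig(),
) -> list[RefinementCall]:
    """Classify semi-tryptic N-terminal peptides against annotated starts.

    A peptide beginning at residue 1 (initiator Met retained over a canonical
    codon) or residue 2 (Met excised, the codon immediately upstream being
    canonical) implies a start position; agreement with the annotation yields
    ``start_confirmed``, disagreement ``start_corrected`` at the implied
    canonical codon.  Implied starts without a canonical codon are rejected.
    """
    by_id = {g.replicon_id: g for g in genomes}
    # candidate starts per annotated CDS, keyed by locus
    per_locus: dict[str, list] = {}
    for m in mapped:
        if m.peptide.tryptic_status != "semi_N" or m.shared:
            continue
        orf = m.orf
        genome = by_id[orf.replicon_id]
        interp = _interpret_nterm_peptide(m, genome, config)
        if interp is None:
            continue
        implied_start, category, codon = interp
        for cds in annotation:
            if not cds_in_orf(orf, cds):
                continue
            per_locus.setdefault(cds.locus_tag, []).append(
                (implied_start, category, codon, m, cds)
            )
    calls = []
    for locus in sorted(per_locus):
        options = per_locus[locus]
        # prefer an interpretation agreeing with the annotation, then the
        # most upstream implied start (deterministic)
        cds = options[0][4]
        agreeing = [o for o in options if o[0] == cds.start_coord]
        if agreeing:
            implied, category, codon, m, cds = agreeing[0]
        else:
            strand = cds.strand
            options.sort(key=lambda o: o[0] if strand == "+" else -o[0])
            implied, category, codon, m, cds = options[0]
        ev = {"peptide": m.peptide.sequence, "replicon": cds.replicon_id,
              "left": cds.left}
        if implied == cds.start_coord:
            calls.append(RefinementCall("start_confirmed", locus_tag=locus,
                                        orf_id=m.orf.orf_id, evidence=ev,
                                        nterm_category=category, start_codon=codon))
        else:
            new_cds = CdsAnnotation(locus, cds.replicon_id, implied, cds.stop_coord,
                                    cds.product, "proteogenomic")
            calls.append(RefinementCall("start_corrected", new_cds=new_cds,
                                        locus_tag=locus, orf_id=m.orf.orf_id,
                                        evidence=ev, nterm_category=category,
                                        start_codon=codon))
    return calls


def _interpret_nterm_peptide(m: MappedPeptide, genome: GenomeRecord,
                             config: PipelineConfig):
    """(implied_start, nterm_category, start_codon) for a semi_N peptide."""
    orf = m.orf
    pep = m.peptide.sequence
    codon0 = codon_at(genome, m.genomic_start, orf.strand)
    if pep.startswith("M") and codon0 in config.canonical_starts:
        return m.genomic_start, f"{codon0}_met_retained", codon0
    # Met-removed interpretation: the codon one position upstream, still
    # inside the ORF, must be canonical
    up = m.genomic_start - 3 if orf.frame > 0 else m.genomic_start + 3
    aa_off = _supported_aa_offset(orf, m.genomic_start)
    if aa_off >= 1 and 1 <= min(up, up + 2) and max(up, up + 2) <= len(genome):
        codon_up = codon_at(genome, up, orf.strand)
        if codon_up in config.canonical_starts:
            return up, f"{codon_up}_met_removed", codon_up
    return None


def start_codon_usage(calls: list[RefinementCall]) -> dict:
    """Percentage usage of ATG/GTG/TTG over confirmed + corrected starts."""
    counts = {c: 0 for c in CANONICAL_STARTS}
    total = 0
    for call in calls:
        if call.category in ("start_confirmed", "start_corrected") and call.start_codon:
            counts[call.start_codon] = counts.get(call.start_codon, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {c: 100.0 * n / total for c, n in counts.items()}


# ---------------------------------------------------------------------------
# frame-split (sequencing-error) detection and resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSplitCandidate:
    """Two same-strand, different-frame peptide-bearing ORFs in collinear
    arrangement, suspected to encode one frameshifted protein."""

    replicon_id: str
    strand: str
    orf_upstream: StopToStopOrf  # 5' in reading direction
    orf_downstream: StopToStopOrf
    search_interval: tuple  # inclusive forward-coordinate interval
    supported_spans: tuple  # ((left, right), (left, right)) forward coords


def detect_frame_split_candidates(
    mapped: list[MappedPeptide],
    db: OrfDatabase,
    config: PipelineConfig = PipelineConfig(),
    annotation: AnnotationSet | None = None,
) -> list[FrameSplitCandidate]:
    """Pairs of peptide-bearing ORFs on one strand, in different frames, with
    collinear supported spans separated by at most ``frame_gap_max_nt``.

    Pairs where either ORF already contains an annotated CDS in its own frame
    are skipped: an annotated gene explains its peptides, and "fusing" a real
    gene with a neighbour by a hypothetical edit is never warranted by
    peptide evidence alone.
    """
    annotated = _annotated_orf_ids(db, annotation) if annotation is not None else {}
    spans: dict[str, tuple] = {}
    for m in mapped:
        if m.shared:
            continue
        oid = m.orf.orf_id
        lo, hi = spans.get(oid, (m.left, m.right))
        spans[oid] = (min(lo, m.left), max(hi, m.right))
    orf_ids = sorted(spans)
    out = []
    for i, a_id in enumerate(orf_ids):
        a = db.get(a_id)
        for b_id in orf_ids[i + 1:]:
            b = db.get(b_id)
            if a.replicon_id != b.replicon_id or a.strand != b.strand:
                continue
            if a.frame == b.frame:
                continue
            if a_id in annotated or b_id in annotated:
                continue
            (al, ar), (bl, br) = spans[a_id], spans[b_id]
            if al > bl:
                (a2, b2), (al, ar), (bl, br) = (b, a), (bl, br), (al, ar)
            else:
                a2, b2 = a, b
            if ar >= bl:  # supported spans overlap: not collinear
                continue
            gap = bl - ar - 1
            if gap > config.frame_gap_max_nt:
                continue
            upstream, downstream = (a2, b2) if a2.strand == "+" else (b2, a2)
            out.append(
                FrameSplitCandidate(
                    a2.replicon_id, a2.strand, upstream, downstream,
                    (ar + 1, bl - 1), ((al, ar), (bl, br)),
                )
            )
    out.sort(key=lambda c: (c.replicon_id, c.search_interval[0]))
    return out


def _segment_with_peptides(window_nt: str, peptides: list[str]) -> str | None:
    """Inter-stop segment (any of 3 frames) containing every peptide, or None."""
    from Bio.Seq import Seq

    best = None
    for f in range(3):
        sub = window_nt[f : f + (len(window_nt) - f) // 3 * 3]
        if len(sub) < 3:
            continue
        for seg in str(Seq(sub).translate(table=11)).split("*"):
            if all(p in seg for p in peptides):
                if best is None or len(seg) > len(best):
                    best = seg
    return best


def resolve_sequence_error(
    candidate: FrameSplitCandidate,
    genome: GenomeRecord,
    supporting_peptides: list[str],
    config: PipelineConfig = PipelineConfig(),
    window_pad: int = 400,
) -> list[SequenceErrorCall]:
    """Search the candidate interval for a single-base edit fusing the frames.

    Every position in the interval is tentatively deleted (then, failing
    that, every single-base insertion is tried); an edit is accepted when all
    supporting peptides fall into one inter-stop segment of the re-translated
    region.  Equivalent positions (homopolymer runs yielding an identical
    edited sequence) are collapsed into maximal intervals.  Solutions are
    ranked by corrected-protein length; ties are noted.
    """
    lo, hi = candidate.search_interval
    (al, _), (_, br) = candidate.supported_spans
    ws = max(1, al - window_pad)
    we = min(len(genome), br + window_pad)
    seq = genome.sequence

    def window_after_edit(edited: str, removed: bool) -> str:
        w_end = we - 1 if removed else we + 1
        win = edited[ws - 1 : w_end]
        return win if candidate.strand == "+" else reverse_complement(win)

    peptides = list(supporting_peptides)
    solutions: list[tuple] = []  # (pos, edit_type, base, protein)
    for p in range(lo, hi + 1):
        edited = seq[: p - 1] + seq[p:]
        prot = _segment_with_peptides(window_after_edit(edited, True), peptides)
        if prot is not None:
            solutions.append((p, "deletion", "", prot))
    if not solutions:
        for p in range(lo, hi + 1):
            for base in "ACGT":
                edited = seq[: p - 1] + base + seq[p - 1 :]
                prot = _segment_with_peptides(window_after_edit(edited, False), peptides)
                if prot is not None:
                    solutions.append((p, "insertion", base, prot))
    if not solutions:
        return []
    # collapse runs of consecutive positions with identical corrected protein
    groups: list[list] = []
    for sol in solutions:
        if (groups and groups[-1][-1][1] == sol[1] and groups[-1][-1][2] == sol[2]
                and groups[-1][-1][3] == sol[3] and sol[0] == groups[-1][-1][0] + 1):
            groups[-1].append(sol)
        else:
            groups.append([sol])
    frames = (candidate.orf_upstream.frame, candidate.orf_downstream.frame)
    calls = []
    seen = set()
    for g in groups:
        lo, hi = g[0][0], g[-1][0]
        edit_type, base = g[0][1], g[0][2]
        # homopolymer awareness: removing (or duplicating) any base of the
        # run containing the edit yields the identical edited sequence, even
        # where the run extends beyond the peptide-bracketed search interval
        run_base = seq[lo - 1] if edit_type == "deletion" else base
        if edit_type == "deletion" and all(seq[p - 1] == run_base
                                           for p in range(lo, hi + 1)):
            while lo > 1 and seq[lo - 2] == run_base:
                lo -= 1
            while hi < len(seq) and seq[hi] == run_base:
                hi += 1
        elif edit_type == "insertion":
            while lo > 1 and seq[lo - 2] == run_base:
                lo -= 1
            while hi < len(seq) and seq[hi - 1] == run_base:
                hi += 1
        key = (lo, hi, edit_type, base, g[0][3])
        if key in seen:
            continue
        seen.add(key)
        calls.append(
            SequenceErrorCall(genome.replicon_id, (lo, hi), g[0][3], frames,
                              tuple(peptides), edit_type, base)
        )
    calls.sort(key=lambda c: -len(c.corrected_protein))
    if len(calls) > 1 and len(calls[0].corrected_protein) == len(calls[1].corrected_protein):
        calls = [replace(calls[0], note="tie_with_alternative_solutions")] + calls[1:]
    return calls


# ---------------------------------------------------------------------------
# conflict resolution (shorten a detected CDS out of an overlap)
# ---------------------------------------------------------------------------

def shorten_conflicting_cds(
    detected_cds: CdsAnnotation,
    conflicting_call: RefinementCall,
    mapped: list[MappedPeptide],
    homology_region: tuple | None,
    genome: GenomeRecord,
    db: OrfDatabase,
    config: PipelineConfig = PipelineConfig(),
) -> RefinementCall:
    """Propose a later start for a detected CDS so a new call no longer
    overlaps it; the shortened CDS must still cover all its own peptides
    (and, if given, the homology-supported region)."""
    orf = orf_containing_cds(db, detected_cds)
    if orf is None:
        return RefinementCall("conflict", locus_tag=detected_cds.locus_tag,
                              note="no_containing_orf")
    own = [
        m for m in mapped
        if m.orf.orf_id == orf.orf_id and not m.shared
        and _overlap(m.left, m.right, detected_cds.left, detected_cds.right)
    ]
    other = conflicting_call.new_cds
    o_left = other.left if other else conflicting_call.evidence.get("left", 0)
    o_right = other.right if other else o_left
    if not own:
        return RefinementCall("conflict", locus_tag=detected_cds.locus_tag,
                              note="no_own_peptides")
    if detected_cds.strand == "+":
        first_pep = min(m.genomic_start for m in own)
    else:
        first_pep = max(m.genomic_start for m in own)
    off = _supported_aa_offset(orf, first_pep)
    for k in range(off, -1, -1):
        pos = orf.aa_to_genomic(k)
        # stop before entering the overlap region
        if detected_cds.strand == "+" and pos <= o_right:
            break
        if detected_cds.strand == "-" and pos >= o_left:
            break
        if codon_at(genome, pos, detected_cds.strand) not in config.canonical_starts:
            continue
        new_left = min(pos, detected_cds.stop_coord)
        new_right = max(pos, detected_cds.stop_coord)
        if homology_region is not None:
            if not (new_left <= homology_region[0] and homology_region[1] <= new_right):
                continue
        new_cds = CdsAnnotation(detected_cds.locus_tag, detected_cds.replicon_id,
                                pos, detected_cds.stop_coord,
                                detected_cds.product, "proteogenomic")
        return RefinementCall(
            "start_corrected", new_cds=new_cds, locus_tag=detected_cds.locus_tag,
            orf_id=orf.orf_id,
            evidence={"resolves_conflict_with": conflicting_call.orf_id,
                      "replicon": detected_cds.replicon_id, "left": new_left},
            start_codon=codon_at(genome, pos, detected_cds.strand),
            note="shortened_to_resolve_overlap",
        )
    return RefinementCall("conflict", locus_tag=detected_cds.locus_tag,
                          orf_id=orf.orf_id, note="irreconcilable_overlap")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    calls: list
    evidence: list
    mapped: list
    frame_split_candidates: list
    start_usage: dict


def refine_all(
    genomes: list[GenomeRecord],
    db: OrfDatabase,
    annotation: AnnotationSet,
    psms,
    config: PipelineConfig = PipelineConfig(),
    homology_support: dict | None = None,
    transcription_evidence: dict | None = None,
    tag_prefix: str = "PG",
) -> RefinementResult:
    """Run the full classification cascade on filtered PSM evidence."""
    from .evidence import aggregate_to_proteins, filter_psms, map_all_psms

    psms = filter_psms(psms, config.psm_p_max)
    mapped = map_all_psms(psms, db)
    evidence = aggregate_to_proteins(mapped, psms)
    by_id = {g.replicon_id: g for g in genomes}

    # 1) sequencing errors first: their ORFs must not become novel calls
    candidates = detect_frame_split_candidates(mapped, db, config, annotation)
    ev_by_orf = {e.orf_id: e for e in evidence}

    def member_ok(orf_id: str) -> bool:
        e = ev_by_orf.get(orf_id)
        if e is None:
            return False
        n = len(e.distinct_peptides)
        return n >= 2 or (n == 1 and e.best_p_value < config.one_hit_p_max)

    candidates = [c for c in candidates
                  if member_ok(c.orf_upstream.orf_id)
                  and member_ok(c.orf_downstream.orf_id)]
    resolved: list[tuple] = []  # (sort key, call, member orf ids)
    for cand in candidates:
        peps = sorted({
            m.peptide.sequence for m in mapped
            if m.orf.orf_id in (cand.orf_upstream.orf_id, cand.orf_downstream.orf_id)
            and not m.shared and m.peptide.tryptic_status == "full"
        })
        res = resolve_sequence_error(cand, by_id[cand.replicon_id], peps, config)
        if res:
            members = {cand.orf_upstream.orf_id, cand.orf_downstream.orf_id}
            lo, hi = cand.search_interval
            resolved.append((
                (len(res), hi - lo, -len(peps), lo),
                RefinementCall("sequence_error", sequence_error=res[0],
                               orf_id=cand.orf_upstream.orf_id,
                               evidence={"peptides": peps,
                                         "alternatives": len(res) - 1,
                                         "replicon": cand.replicon_id,
                                         "left": lo}),
                members))
    # Chained frame splits (candidates sharing a member ORF) are mutually
    # exclusive: a single-base edit makes exactly one frame junction.  Keep
    # the least ambiguous resolution first: a unique reconciling edit beats
    # one with alternative non-equivalent solutions, and a tightly bracketed
    # search interval beats a wide one ("fusing" two complete neighbouring
    # genes typically admits several edits spread over a wide gap).
    resolved.sort(key=lambda t: t[0])
    seq_error_calls = []
    resolved_orf_ids: set = set()
    for _key, call, members in resolved:
        if members & resolved_orf_ids:
            continue
        seq_error_calls.append(call)
        resolved_orf_ids.update(members)

    # 2) novel / wrong-CDS / conflict classification
    calls = classify_detected_orfs(evidence, annotation, db, genomes,
                                   homology_support, config,
                                   exclude_orf_ids=resolved_orf_ids,
                                   tag_prefix=tag_prefix)

    annotated = _annotated_orf_ids(db, annotation)
    validated_ids = {e.orf_id for e in evidence if e.status == "validated"}
    detected_spans = []
    for e in evidence:
        if e.status == "validated":
            repl = db.get(e.orf_id).replicon_id
            detected_spans.append((repl, e.supported_left, e.supported_right))
    for oid, tags in annotated.items():
        if oid in validated_ids:
            for t in tags:
                c = annotation.by_tag(t)
                detected_spans.append((c.replicon_id, c.left, c.right))

    # 3) one-hit wonders (+ optional transcription promotion)
    one_hits = one_hit_wonder_candidates(
        [e for e in evidence if e.orf_id not in resolved_orf_ids],
        annotation, detected_spans, config, db, genomes, tag_prefix=f"{tag_prefix}_OH",
    )
    if transcription_evidence:
        one_hits = accept_with_transcription(one_hits, transcription_evidence)

    # 4) start-codon work on annotated genes
    pvals: dict[str, float] = {}
    for p in psms:
        pvals[p.peptide_seq] = min(p.p_value, pvals.get(p.peptide_seq, 1.0))
    nterm = nterm_extension_scan(mapped, annotation, db, genomes, config,
                                 detected_spans, peptide_pvalues=pvals)
    semis = validate_starts_semitryptic(mapped, annotation, genomes, config)
    # a semi-tryptic verdict and an upstream-peptide extension can concern the
    # same locus; the strictly tryptic upstream evidence wins (it proves
    # translated sequence beyond any N-terminal peptide seen)
    ext_loci = {c.locus_tag for c in nterm if c.new_cds is not None}
    semis = [c for c in semis if c.locus_tag not in ext_loci]

    # 5) conflicts: try to shorten the detected gene out of the overlap
    resolved_conflicts = []
    final_calls = []
    for c in calls:
        if c.category != "conflict":
            final_calls.append(c)
            continue
        cds = annotation.by_tag(c.displaced_locus) if c.displaced_locus else None
        if cds is None:
            final_calls.append(c)
            continue
        fix = shorten_conflicting_cds(cds, c, mapped, None,
                                      by_id[cds.replicon_id], db, config)
        if fix.category == "start_corrected":
            # the new gene stands too
            final_calls.append(replace_call(c, category="novel_cds",
                                            displaced_locus=None,
                                            note=(c.note + ";conflict_resolved").strip(";")))
            resolved_conflicts.append(fix)
        else:
            final_calls.append(c)

    all_calls = (final_calls + one_hits + nterm + semis + seq_error_calls
                 + resolved_conflicts)
    all_calls.sort(key=lambda c: c.sort_key)
    usage = start_codon_usage(all_calls)
    return RefinementResult(all_calls, evidence, mapped, candidates, usage)
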