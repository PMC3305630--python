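"""Classifier behaviour: novel/wrong-CDS calls, one-hit wonders, start-codon
validation, frame-split resolution and conflict shortening, checked against
the simulator's ground-truth ledger and against hand-built scenarios."""

import pytest

from proteoseed.evidence import ProteinEvidence, filter_psms, map_all_psms
from proteoseed.genome_model import (
    CANONICAL_STARTS,
    CdsAnnotation,
    GenomeRecord,
    STOP_CODONS,
    extract_and_translate,
)
from proteoseed.refinement import (
    FrameSplitCandidate,
    PipelineConfig,
    accept_with_transcription,
    choose_start,
    codon_at,
    detect_frame_split_candidates,
    one_hit_wonder_candidates,
    refine_all,
    resolve_sequence_error,
    shorten_conflicting_cds,
    start_codon_usage,
    RefinementCall,
)
from proteoseed.sixframe import enumerate_orfs, orf_containing_cds
from proteoseed.synthetic import SimulationConfig, simulate_dataset, score_calls

CFG = PipelineConfig()


# ---------------------------------------------------------------------------
# choose_start
# ---------------------------------------------------------------------------

class TestChooseStart:
    def test_required_residue_itself_canonical(self, dataset):
        for cds in list(dataset.annotation_true)[:5]:
            orf = orf_containing_cds(dataset.db, cds)
            if orf is None:
                continue
            if cds.strand == "+":
                off = (cds.start_coord - orf.span_start) // 3
            else:
                off = (orf.span_start - cds.start_coord) // 3
            assert choose_start(orf, off, dataset.genome, CFG) == cds.start_coord

    def test_fuzzed_orfs_match_linear_scan_oracle(self, dataset, rng):
        for _ in range(100):
            orf = dataset.db.orfs[int(rng.integers(len(dataset.db)))]
            off = int(rng.integers(len(orf.aa_sequence)))
            got = choose_start(orf, off, dataset.genome, CFG)
            expected = None
            for k in range(off, -1, -1):
                pos = orf.aa_to_genomic(k)
                if codon_at(dataset.genome, pos, orf.strand) in CANONICAL_STARTS:
                    expected = pos
                    break
            assert got == expected


# ---------------------------------------------------------------------------
# classification against the planted ledger
# ---------------------------------------------------------------------------

class TestClassification:
    def test_novel_and_wrong_cds_recovered(self, dataset, refined):
        sc = score_calls(dataset.ledger, refined.calls)
        assert sc["novel_cds"]["recall"] == 1.0
        assert sc["wrong_cds_replacement"]["recall"] == 1.0

    def test_wrong_cds_records_displaced_fake_locus(self, dataset, refined):
        fakes = {p.details["fake_locus"] for p in dataset.ledger.planted
                 if p.category == "spurious_cds"}
        displaced = {c.displaced_locus for c in refined.calls
                     if c.category == "wrong_cds_replacement"}
        assert displaced <= fakes

    def test_new_cds_start_canonical_and_stop_at_stop_codon(self, dataset, refined):
        g = dataset.genome
        for c in refined.calls:
            if c.new_cds is None or c.note:
                continue
            assert codon_at(g, c.new_cds.start_coord, c.new_cds.strand) \
                in CANONICAL_STARTS
            # the proposed protein must translate cleanly (stop stripped)
            prot = extract_and_translate(g, c.new_cds)
            assert "*" not in prot

    def test_no_two_new_cds_overlap(self, refined):
        spans = [(c.new_cds.replicon_id, c.new_cds.left, c.new_cds.right)
                 for c in refined.calls
                 if c.new_cds is not None
                 and c.category in ("novel_cds", "wrong_cds_replacement")]
        spans.sort()
        for (r1, l1, h1), (r2, l2, h2) in zip(spans, spans[1:]):
            assert r1 != r2 or h1 < l2

    def test_validated_orf_partition(self, dataset, refined):
        """Every validated unannotated ORF gets exactly one structural call."""
        from proteoseed.refinement import _annotated_orf_ids

        annotated = _annotated_orf_ids(dataset.db, dataset.annotation_published)
        resolved = set()
        for c in refined.calls:
            if c.category == "sequence_error":
                resolved.update(o for o in (c.orf_id,) if o)
        structural = {}
        for c in refined.calls:
            if c.category in ("novel_cds", "wrong_cds_replacement", "conflict"):
                assert c.orf_id not in structural or c.note
                structural[c.orf_id] = c.category
        for e in refined.evidence:
            if e.status == "validated" and e.orf_id not in annotated:
                covered = (e.orf_id in structural or e.orf_id in resolved
                           or any(e.orf_id in (cand.orf_upstream.orf_id,
                                               cand.orf_downstream.orf_id)
                                  for cand in refined.frame_split_candidates))
                assert covered, e.orf_id


# ---------------------------------------------------------------------------
# one-hit wonders
# ---------------------------------------------------------------------------

class TestOneHitWonders:
    def _evidence(self, p):
        return ProteinEvidence("orfX", {"AAAK"}, set(), 3, p, "one_hit", 500, 530)

    def test_boundary_p_value_strictly_under(self, dataset):
        ok = one_hit_wonder_candidates([self._evidence(1e-6)],
                                       dataset.annotation_published, [], CFG)
        assert len(ok) == 1 and ok[0].category == "one_hit_candidate"
        boundary = one_hit_wonder_candidates([self._evidence(3.2e-5)],
                                             dataset.annotation_published, [], CFG)
        assert boundary == []

    def test_overlap_with_detected_span_excludes(self, dataset):
        ev = ProteinEvidence(dataset.db.orfs[0].orf_id, {"AAAK"}, set(), 3,
                             1e-6, "one_hit", 500, 530)
        spans = [(dataset.db.orfs[0].replicon_id, 520, 700)]
        assert one_hit_wonder_candidates([ev], dataset.annotation_published,
                                         spans, CFG, dataset.db,
                                         [dataset.genome]) == []

    def test_transcription_promotion(self):
        cand = RefinementCall("one_hit_candidate", orf_id="o1")
        other = RefinementCall("one_hit_candidate", orf_id="o2")
        out = accept_with_transcription([cand, other], {"o1": True})
        assert {c.orf_id: c.category for c in out} == {
            "o1": "novel_cds", "o2": "one_hit_candidate"}

    def test_promotions_match_planted_transcribed_subset(self, dataset, refined):
        transcribed = dataset.ledger.one_hit_transcribed
        silent = dataset.ledger.one_hit - transcribed
        by_stop = {(c.replicon_id, c.strand, c.stop_coord): c.locus_tag
                   for c in dataset.ledger.true_cds}
        promoted = set()
        for c in refined.calls:
            if c.category == "novel_cds" and "transcription_confirmed" in c.note:
                promoted.add(by_stop.get((c.new_cds.replicon_id, c.new_cds.strand,
                                          c.new_cds.stop_coord)))
        assert promoted == transcribed
        still_candidates = {c.orf_id for c in refined.calls
                            if c.category == "one_hit_candidate"}
        assert len(still_candidates) >= len(silent)


# ---------------------------------------------------------------------------
# start-codon validation
# ---------------------------------------------------------------------------

class TestStartValidation:
    def test_planted_start_errors_recovered_exactly(self, dataset, refined):
        sc = score_calls(dataset.ledger, refined.calls)
        assert sc["start_corrected"]["recall"] == 1.0
        assert sc["start_corrected"]["precision"] == 1.0

    def test_confirmed_and_corrected_partition(self, dataset, refined):
        planted = {p.locus_tag for p in dataset.ledger.planted
                   if p.category in ("wrong_start_long", "wrong_start_short")}
        for c in refined.calls:
            if c.category == "start_confirmed":
                assert c.locus_tag not in planted
            if c.category == "start_corrected" and "conflict" not in c.note:
                assert c.locus_tag in planted

    def test_nterm_categories_consistent_with_genome(self, dataset, refined):
        g = dataset.genome
        for c in refined.calls:
            if c.nterm_category == "none" or not c.start_codon:
                continue
            codon, fate = c.nterm_category.split("_", 1)
            assert codon == c.start_codon
            start = (c.new_cds.start_coord if c.new_cds is not None
                     else dataset.annotation_published.by_tag(c.locus_tag).start_coord)
            strand = "+" if c.category != "start_confirmed" and c.new_cds else None
            cds = (c.new_cds if c.new_cds is not None
                   else dataset.annotation_published.by_tag(c.locus_tag))
            assert codon_at(g, start, cds.strand) == codon

    def test_usage_table_fixture(self):
        calls = ([RefinementCall("start_confirmed", start_codon="ATG")] * 94
                 + [RefinementCall("start_corrected", start_codon="GTG")] * 5
                 + [RefinementCall("start_confirmed", start_codon="TTG")])
        usage = start_codon_usage(calls)
        assert usage == {"ATG": 94.0, "GTG": 5.0, "TTG": 1.0}

    def test_usage_all_atg_and_empty(self):
        calls = [RefinementCall("start_confirmed", start_codon="ATG")] * 7
        assert start_codon_usage(calls) == {"ATG": 100.0, "GTG": 0.0, "TTG": 0.0}
        assert start_codon_usage([]) == {}


# ---------------------------------------------------------------------------
# frame splits and sequencing errors
# ---------------------------------------------------------------------------

class TestSequenceErrors:
    def test_no_candidates_without_planted_insertions(self):
        cfg = SimulationConfig(seed=6, error_counts={
            "missed_gene": 0, "wrong_start_long": 0, "wrong_start_short": 0,
            "spurious_cds": 0, "base_insertion": 0}, n_one_hit=0,
            n_one_hit_transcribed=0, false_psm_rate=0.0)
        ds = simulate_dataset(cfg)
        psms = filter_psms(ds.psms)
        mapped = map_all_psms(psms, ds.db)
        cands = detect_frame_split_candidates(mapped, ds.db, CFG,
                                              ds.annotation_published)
        assert cands == []

    def test_opposite_strand_pairs_never_pair(self, refined):
        for cand in refined.frame_split_candidates:
            assert cand.orf_upstream.strand == cand.orf_downstream.strand

    def test_planted_insertion_interval_spans_homopolymer_run(self, dataset, refined):
        truth = {p.details["position"]: p.details["run_interval"]
                 for p in dataset.ledger.planted if p.category == "base_insertion"}
        seq_calls = [c for c in refined.calls if c.category == "sequence_error"]
        assert len(seq_calls) == len(truth)
        for c in seq_calls:
            lo, hi = c.sequence_error.correction_interval
            match = [run for pos, run in truth.items() if lo <= pos <= hi]
            assert match and (lo, hi) == match[0]
            assert c.sequence_error.edit_type == "deletion"

    def test_corrected_protein_contains_all_supporting_peptides(self, refined):
        for c in refined.calls:
            if c.category != "sequence_error":
                continue
            se = c.sequence_error
            assert all(p in se.corrected_protein for p in se.supporting_peptides)

    def test_applying_deletion_restores_single_orf(self, dataset, refined):
        """After the proposed deletion the locus re-translates into one
        stop-to-stop ORF carrying every supporting peptide: re-running the
        detector on the corrected genome finds nothing to fix there."""
        for c in refined.calls:
            if c.category != "sequence_error":
                continue
            se = c.sequence_error
            pos = se.correction_interval[0]
            fixed = GenomeRecord(
                dataset.genome.replicon_id,
                dataset.genome.sequence[: pos - 1] + dataset.genome.sequence[pos:])
            orfs = enumerate_orfs([fixed], 41)
            hosting = [o for o in orfs
                       if all(p in o.aa_sequence for p in se.supporting_peptides)]
            assert len(hosting) == 1

    def test_irreconcilable_candidate_returns_none(self, dataset):
        a, b = dataset.db.orfs[0], dataset.db.orfs[2]
        cand = FrameSplitCandidate(dataset.genome.replicon_id, "+", a, b,
                                   (a.right + 1, a.right + 2),
                                   ((a.left, a.right), (a.right + 40, a.right + 80)))
        out = resolve_sequence_error(cand, dataset.genome,
                                     ["WWWWWWWWCCCCCCCW", "WWWCWCWCWWK"], CFG)
        assert out == []


# ---------------------------------------------------------------------------
# conflict shortening (detected gene overlapping a new call)
# ---------------------------------------------------------------------------

class TestShortenConflict:
    def _scenario(self, dataset, peptide_offset_codons):
        """A detected annotated gene whose 5' region overlaps a new call;
        its own peptides begin peptide_offset_codons into the gene."""
        for cds in dataset.annotation_true:
            orf = orf_containing_cds(dataset.db, cds)
            if orf is None or cds.span_nt < 3 * 180:
                continue
            prot = extract_and_translate(dataset.genome, cds)
            from proteoseed.digestion import tryptic_digest
            peps = [p for p in tryptic_digest(prot, 0, 6, 40)
                    if p.start_offset >= peptide_offset_codons]
            if not peps:
                continue
            pep = peps[0]
            if cds.strand == "+":
                gs = cds.start_coord + 3 * pep.start_offset
                ge = gs + 3 * len(pep.sequence) - 1
            else:
                gs = cds.start_coord - 3 * pep.start_offset
                ge = gs - 3 * len(pep.sequence) + 1
            from proteoseed.evidence import MappedPeptide
            mapped = [MappedPeptide(pep, orf, gs, ge, orf.frame)]
            # conflicting new call occupying the gene's first ~30 codons
            if cds.strand == "+":
                other = CdsAnnotation("NEW", cds.replicon_id, cds.start_coord,
                                      cds.start_coord + 89)
            else:
                other = CdsAnnotation("NEW", cds.replicon_id, cds.start_coord,
                                      cds.start_coord - 89)
            call = RefinementCall("conflict", new_cds=other, orf_id="neworf")
            return cds, call, mapped, orf
        pytest.skip("no suitable gene in fixture")

    def test_shortening_resolves_overlap(self, dataset):
        cds, call, mapped, orf = self._scenario(dataset, 60)
        out = shorten_conflicting_cds(cds, call, mapped, None, dataset.genome,
                                      dataset.db, CFG)
        assert out.category == "start_corrected"
        new = out.new_cds
        # overlap eliminated and own peptide still covered
        assert not (max(new.left, call.new_cds.left)
                    <= min(new.right, call.new_cds.right))
        m = mapped[0]
        assert new.left <= m.left and m.right <= new.right

    def test_peptide_inside_overlap_is_irreconcilable(self, dataset):
        cds, call, mapped, orf = self._scenario(dataset, 60)
        # move the conflicting call so it covers the peptide region entirely
        m = mapped[0]
        if cds.strand == "+":
            other = CdsAnnotation("NEW", cds.replicon_id, cds.start_coord,
                                  m.right + (3 - (m.right - cds.start_coord + 1) % 3) % 3)
        else:
            span = cds.start_coord - m.left + 1
            other = CdsAnnotation("NEW", cds.replicon_id, cds.start_coord,
                                  m.left - (3 - span % 3) % 3)
        call = RefinementCall("conflict", new_cds=other, orf_id="neworf")
        out = shorten_conflicting_cds(cds, call, mapped, None, dataset.genome,
                                      dataset.db, CFG)
        assert out.category == "conflict"
        assert out.note == "irreconcilable_overlap"


def test_call_ordering_is_deterministic(refined):
    keys = [c.sort_key for c in refined.calls]
    assert keys == sorted(keys)
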