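import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from proteoseed.genome_model import extract_and_translate
from proteoseed.ortho import (
    AlignmentParams,
    evalue,
    find_unannotated_homologs,
    propagate_start_corrections,
    read_blast_tab,
    smith_waterman,
)
from proteoseed.refinement import PipelineConfig
from proteoseed.synthetic import SimulationConfig, generate_genome, simulate_clade

AA = "ACDEFGHIKLMNPQRSTVWY"
PARAMS = AlignmentParams()
BLOSUM = substitution_matrices.load("BLOSUM62")


def oracle_sw_affine(a: str, b: str, open_cost=12, extend_cost=1):
    """Gotoh local alignment score, independent dynamic program."""
    n, m = len(a), len(b)
    NEG = -10**9
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM[a[i - 1]][b[j - 1]]
            M[i][j] = max(0, M[i - 1][j - 1], Ix[i - 1][j - 1],
                          Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - extend_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - extend_cost)
            best = max(best, M[i][j])
    return float(best)


class TestSmithWaterman:
    def test_self_alignment_scores_diagonal_sum(self):
        q = "WCHKMNDEFT"
        score, aln = smith_waterman(q, q)
        assert score == sum(BLOSUM[c][c] for c in q)
        assert aln is not None

    def test_dissimilar_strings_score_zero(self):
        score, aln = smith_waterman("WWWW", "PPPP")
        assert score == 0.0 and aln is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            smith_waterman("", "ACD")

    def test_100_random_pairs_match_dp_oracle(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(5, 50))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(5, 50))))
            score, _ = smith_waterman(a, b)
            assert score == oracle_sw_affine(a, b)


class TestEvalue:
    def test_closed_form_unit_expect(self):
        m, n = 120, 1_000_000
        s = math.log(PARAMS.karlin_K * m * n) / PARAMS.karlin_lambda
        assert evalue(s, m, n) == pytest.approx(1.0, rel=1e-9)

    def test_doubling_database_doubles_expect(self):
        assert evalue(100, 50, 2_000_000) == pytest.approx(
            2 * evalue(100, 50, 1_000_000), rel=1e-12)

    def test_parameter_sweep_against_formula(self, rng):
        for _ in range(50):
            s = float(rng.uniform(20, 400))
            m = int(rng.integers(10, 2000))
            n = int(rng.integers(1000, 10**7))
            want = 0.041 * m * n * math.exp(-0.267 * s)
            assert evalue(s, m, n) == pytest.approx(want, rel=1e-12)


@pytest.fixture(scope="module")
def clade():
    cfg = SimulationConfig(seed=3)
    genome, ann, ledger = generate_genome(cfg)
    subjects = simulate_clade(genome, ann, ledger, cfg)
    return cfg, genome, ann, ledger, subjects


def _subject_maps(subjects):
    genomes = {g.replicon_id: g for g, _ in subjects}
    anns = {g.replicon_id: a for g, a in subjects}
    prots = {g.replicon_id: [(c.locus_tag, extract_and_translate(g, c)) for c in a]
             for g, a in subjects}
    return genomes, anns, prots


class TestFindUnannotatedHomologs:
    def test_lost_genes_reported_annotated_ones_suppressed(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        genomes, anns, _ = _subject_maps(subjects)
        lost = ledger.subject_lost_genes
        queries = sorted({t for s in lost for t in lost[s]})[:6]
        hits = find_unannotated_homologs(
            [(t, ledger.true_proteins[t]) for t in queries], genomes, anns)
        found = {(h.query_id, h.subject_id) for h in hits}
        for s, genes in lost.items():
            for t in set(genes) & set(queries):
                assert (t, s) in found
        # genes annotated in the subject are never reported
        for h in hits:
            assert h.query_id in lost[h.subject_id]
            assert h.e_value < PipelineConfig().evalue_novel

    def test_self_genome_fully_annotated_gives_no_hits(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        queries = [(t, ledger.true_proteins[t])
                   for t in list(ledger.true_proteins)[:3]]
        hits = find_unannotated_homologs(queries, {"self": genome},
                                         {"self": ann})
        assert hits == []

    def test_tightening_evalue_never_adds_hits(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        genomes, anns, _ = _subject_maps(subjects)
        lost = ledger.subject_lost_genes
        queries = [(t, ledger.true_proteins[t])
                   for s in lost for t in list(lost[s])[:2]]
        loose = find_unannotated_homologs(queries, genomes, anns,
                                          PipelineConfig(evalue_novel=1e-10))
        tight = find_unannotated_homologs(queries, genomes, anns,
                                          PipelineConfig(evalue_novel=1e-40))
        ids = lambda hs: {(h.query_id, h.subject_id, h.subject_start) for h in hs}  # noqa: E731
        assert ids(tight) <= ids(loose)


class TestPropagateStarts:
    def test_identity_clade_confirms_everything(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        prot = [(c.locus_tag, extract_and_translate(genome, c)) for c in ann]
        queries = prot[:10]
        calls, rate = propagate_start_corrections(
            queries, {"self": prot}, {"self": genome}, {"self": ann})
        assert rate == 0.0
        assert calls and all(c.verdict == "confirmed" for c in calls)

    def test_planted_corrections_recovered_exactly(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        genomes, anns, prots = _subject_maps(subjects)
        queries = list(ledger.true_proteins.items())
        calls, rate = propagate_start_corrections(queries, prots, genomes, anns)
        planted = ledger.subject_start_errors
        for c in calls:
            errs = planted.get(c.subject_id, {})
            if c.verdict == "corrected":
                assert c.subject_locus in errs
                assert c.proposed_start == errs[c.subject_locus][0]
        n_planted = sum(len(v) for v in planted.values())
        n_total = sum(len(a) for a in anns.values())
        assert rate == pytest.approx(n_planted / n_total, abs=0.03)

    def test_mutated_away_start_is_undecidable_not_forced(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        genomes, anns, prots = _subject_maps(subjects)
        subj_id = next(s for s, e in ledger.subject_start_errors.items() if e)
        locus, (true_start, _wrong) = next(
            iter(ledger.subject_start_errors[subj_id].items()))
        g = genomes[subj_id]
        cds = anns[subj_id].by_tag(locus)
        # destroy the canonical codon at the true start position
        if cds.strand == "+":
            i = true_start - 1
            seq = g.sequence[:i] + "CCC" + g.sequence[i + 3:]
        else:
            i = true_start - 3
            seq = g.sequence[:i] + "GGG" + g.sequence[i + 3:]
        from proteoseed.genome_model import GenomeRecord
        broken = GenomeRecord(subj_id, seq)
        query = [(locus, ledger.true_proteins[locus])]
        calls, _ = propagate_start_corrections(
            query, {subj_id: prots[subj_id]}, {subj_id: broken},
            {subj_id: anns[subj_id]})
        mine = [c for c in calls if c.subject_locus == locus]
        assert mine and mine[0].verdict in ("undecidable", "confirmed")
        assert mine[0].verdict != "corrected" or mine[0].proposed_start != true_start

    def test_verdict_partition(self, clade):
        cfg, genome, ann, ledger, subjects = clade
        genomes, anns, prots = _subject_maps(subjects)
        queries = list(ledger.true_proteins.items())[:20]
        calls, rate = propagate_start_corrections(queries, prots, genomes, anns)
        counts = {"confirmed": 0, "corrected": 0, "undecidable": 0}
        for c in calls:
            counts[c.verdict] += 1
        assert sum(counts.values()) == len(calls)
        assert rate == pytest.approx(
            counts["corrected"] / len(calls) if calls else 0.0)


def test_blast_tabular_import(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("q1\tsubjA\t92.3\t100\t7\t1\t1\t100\t500\t799\t1e-42\t210\n")
    h, = read_blast_tab(p)
    assert (h.query_id, h.subject_id) == ("q1", "subjA")
    assert (h.subject_start, h.subject_stop) == (500, 799)
    assert h.e_value == 1e-42
    assert h.query_interval == (0, 100)
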