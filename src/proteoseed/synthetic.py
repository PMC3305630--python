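"""Synthetic genomes with planted annotation errors, simulated peptide
evidence, and mutated clade genomes — all with a machine-readable ground
truth ledger.

What the generator emulates
---------------------------
A small bacterial replicon densely packed with non-overlapping protein-coding
genes on both strands (canonical ATG/GTG/TTG starts in a configurable mix,
GC-biased codon usage), a deliberately flawed "published" annotation carrying
one planted error per configured slot (missed genes, starts moved up- or
downstream to another in-frame canonical codon, spurious opposite-strand
CDSs displacing real genes, single-base insertions splitting a gene across
two reading frames), and a deep shotgun proteomics survey of the expressed
proteome (per-gene and per-peptide Bernoulli detection, negative-binomial
spectral counts, low p-values for true matches, a configurable false-match
rate mirrored in a reversed-decoy table).

Genes carrying planted errors are always expressed, and the diagnostic
peptides of each error class are always detected (``guarantee_error_evidence``):
an annotation error in a silent gene is undiscoverable in principle, so
leaving it to detection chance would test the detector's luck, not the
classifier.  Everything else stays stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.Data import CodonTable

from .digestion import tryptic_digest, cleavage_sites
from .evidence import PsmRecord
from .genome_model import (
    CANONICAL_STARTS,
    STOP_CODONS,
    AnnotationSet,
    CdsAnnotation,
    GenomeRecord,
    ProteoseedError,
    reverse_complement,
)
from .sixframe import OrfDatabase, StopToStopOrf, build_search_db, enumerate_orfs

__all__ = [
    "SimulationConfig",
    "PlantedError",
    "GroundTruthLedger",
    "SimulatedDataset",
    "generate_genome",
    "plant_errors",
    "simulate_psms",
    "simulate_clade",
    "simulate_dataset",
    "score_calls",
]

# Met-excision rule: initiator Met is removed when the penultimate residue is
# small (the canonical A/C/G/P/S/T/V rule)
_NME_RESIDUES = set("ACGPSTV")


@dataclass
class SimulationConfig:
    seed: int = 1
    genome_length_nt: int = 48_000
    n_genes: int = 50
    gc_content: float = 0.60
    start_codon_mix: tuple = (0.94, 0.05, 0.01)  # ATG, GTG, TTG
    gene_len_aa: tuple = (80, 250)
    spacer_nt: tuple = (60, 150)
    error_counts: dict = field(default_factory=lambda: {
        "missed_gene": 5,
        "wrong_start_long": 4,
        "wrong_start_short": 4,
        "spurious_cds": 3,
        "base_insertion": 2,
    })
    n_one_hit: int = 2  # subset of missed genes planted as one-hit wonders
    n_one_hit_transcribed: int = 1
    gene_detect_prob: float = 0.85
    peptide_detect_prob: float = 0.75
    nterm_peptide_prob: float = 0.60
    spectral_mean: float = 4.0
    spectral_dispersion: float = 2.0
    false_psm_rate: float = 0.01
    guarantee_error_evidence: bool = True
    replicon_id: str = "SIMCHR"
    # clade settings
    n_subjects: int = 3
    aa_divergence: float = 0.10
    subject_start_error_rate: float = 0.12
    gene_loss_prob: float = 0.05

    def validate(self):
        if not abs(sum(self.start_codon_mix) - 1.0) < 1e-9:
            raise ProteoseedError("start_codon_mix must sum to 1")
        for p in (self.gc_content, self.gene_detect_prob, self.peptide_detect_prob,
                  self.nterm_peptide_prob, self.false_psm_rate,
                  self.subject_start_error_rate, self.gene_loss_prob):
            if not 0 <= p <= 1:
                raise ProteoseedError(f"probability {p} outside [0, 1]")
        if not 0 <= self.aa_divergence <= 0.5:
            raise ProteoseedError("aa_divergence outside [0, 0.5]")


@dataclass
class PlantedError:
    category: str
    locus_tag: str
    details: dict = field(default_factory=dict)


@dataclass
class GroundTruthLedger:
    true_cds: AnnotationSet | None = None
    true_proteins: dict = field(default_factory=dict)
    planted: list = field(default_factory=list)
    expressed: set = field(default_factory=set)
    one_hit: set = field(default_factory=set)
    one_hit_transcribed: set = field(default_factory=set)
    false_psm_keys: list = field(default_factory=list)
    n_true_psm_rows: int = 0
    subject_start_errors: dict = field(default_factory=dict)
    subject_lost_genes: dict = field(default_factory=dict)

    def planted_by_category(self, category: str) -> list:
        return [p for p in self.planted if p.category == category]

    def to_tsv(self, path) -> None:
        lines = ["category\tlocus_tag\tdetails"]
        for p in self.planted:
            det = ";".join(f"{k}={v}" for k, v in sorted(p.details.items())
                           if k != "true_protein")
            lines.append(f"{p.category}\t{p.locus_tag}\t{det}")
        for tag in sorted(self.expressed):
            lines.append(f"expressed\t{tag}\t")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _codon_pools(gc: float):
    """Sense codons of table 11 with GC-biased sampling weights."""
    table = CodonTable.unambiguous_dna_by_id[11]
    sense = [c for c in table.forward_table]
    pb = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in sense])
    return sense, w / w.sum()


def _random_bases(rng, n: int, gc: float) -> str:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(["G", "C", "A", "T"], size=n, p=p))


@dataclass(frozen=True)
class _Gene:
    tag: str
    strand: str
    start_coord: int  # reading direction, includes the stop codon at the 3' end
    stop_coord: int
    protein: str


def generate_genome(config: SimulationConfig):
    """Pack non-overlapping genes on both strands into a random replicon.

    Returns (GenomeRecord, AnnotationSet of true CDSs, ledger seeded with the
    true proteins).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    sense, w = _codon_pools(config.gc_content)
    parts: list[str] = []
    genes: list[_Gene] = []
    cursor = 0  # bases emitted so far
    for i in range(config.n_genes):
        spacer = int(rng.integers(config.spacer_nt[0], config.spacer_nt[1] + 1))
        L = int(rng.integers(config.gene_len_aa[0], config.gene_len_aa[1] + 1))
        nt_len = 3 * (L + 1)
        if cursor + spacer + nt_len > config.genome_length_nt - 100:
            raise ProteoseedError(
                f"cannot pack {config.n_genes} genes into {config.genome_length_nt} nt"
            )
        start_codon = str(rng.choice(CANONICAL_STARTS, p=config.start_codon_mix))
        internal = "".join(rng.choice(sense, size=L - 1, p=w))
        stop = str(rng.choice(STOP_CODONS))
        coding = start_codon + internal + stop
        protein = "M" + str(Seq(internal).translate(table=11))
        strand = "+" if rng.random() < 0.5 else "-"
        left = cursor + spacer + 1
        right = left + nt_len - 1
        parts.append(_random_bases(rng, spacer, config.gc_content))
        parts.append(coding if strand == "+" else reverse_complement(coding))
        if strand == "+":
            genes.append(_Gene(f"SIM_{i + 1:04d}", "+", left, right, protein))
        else:
            genes.append(_Gene(f"SIM_{i + 1:04d}", "-", right, left, protein))
        cursor = right
    parts.append(_random_bases(rng, config.genome_length_nt - cursor, config.gc_content))
    genome = GenomeRecord(config.replicon_id, "".join(parts))
    cds = [CdsAnnotation(g.tag, config.replicon_id, g.start_coord, g.stop_coord)
           for g in genes]
    annotation = AnnotationSet(cds, (config.replicon_id,))
    ledger = GroundTruthLedger(
        true_cds=annotation,
        true_proteins={g.tag: g.protein for g in genes},
    )
    return genome, annotation, ledger


# ---------------------------------------------------------------------------
# error planting
# ---------------------------------------------------------------------------

def _upstream_canonical(genome: GenomeRecord, cds: CdsAnnotation,
                        max_codons: int = 40):
    """In-frame canonical codons upstream of a CDS start, stopping at the
    first in-frame stop (the bounding stop of the containing ORF)."""
    out = []
    step = -3 if cds.strand == "+" else 3
    pos = cds.start_coord
    for _ in range(max_codons):
        pos += step
        lo = pos if cds.strand == "+" else pos - 2
        hi = pos + 2 if cds.strand == "+" else pos
        if lo < 1 or hi > len(genome):
            break
        codon = (genome.sequence[pos - 1 : pos + 2] if cds.strand == "+"
                 else reverse_complement(genome.sequence[pos - 3 : pos]))
        if codon in STOP_CODONS:
            break
        if codon in CANONICAL_STARTS:
            out.append(pos)
    return out


def _internal_canonical(genome: GenomeRecord, cds: CdsAnnotation,
                        lo_aa: int, hi_aa: int):
    """In-frame canonical codons at residue indices [lo_aa, hi_aa] (0-based)."""
    out = []
    for k in range(lo_aa, hi_aa + 1):
        pos = cds.start_coord + 3 * k if cds.strand == "+" else cds.start_coord - 3 * k
        codon = (genome.sequence[pos - 1 : pos + 2] if cds.strand == "+"
                 else reverse_complement(genome.sequence[pos - 3 : pos]))
        if codon in CANONICAL_STARTS:
            out.append((k, pos))
    return out


def _shift_coord(x: int, insertions: list[int]) -> int:
    """Map an original coordinate into the insertion-mutated genome."""
    return x + sum(1 for q in insertions if q <= x)


def plant_errors(genome: GenomeRecord, annotation_true: AnnotationSet,
                 config: SimulationConfig, ledger: GroundTruthLedger | None = None):
    """Derive the flawed "published" annotation (and mutated genome).

    Returns (mutated genome, published AnnotationSet, ledger).  Error slots
    are filled from a shuffled pool of eligible genes; coordinates in the
    returned annotation and ledger refer to the *mutated* genome.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    if ledger is None:
        ledger = GroundTruthLedger(true_cds=annotation_true)
    genes = list(annotation_true)
    order = list(rng.permutation(len(genes)))
    taken: set = set()
    planted: list[PlantedError] = []
    published: dict[str, CdsAnnotation] = {c.locus_tag: c for c in genes}
    fakes: list[CdsAnnotation] = []
    insertion_positions: list[int] = []  # original coordinates

    def next_eligible(pred):
        for idx in order:
            c = genes[idx]
            if c.locus_tag in taken:
                continue
            r = pred(c)
            if r is not None:
                taken.add(c.locus_tag)
                return c, r
        return None, None

    counts = dict(config.error_counts)

    # --- missed genes (a subset become one-hit wonders downstream)
    for _ in range(counts.get("missed_gene", 0)):
        c, _r = next_eligible(lambda c: True)
        if c is None:
            break
        del published[c.locus_tag]
        planted.append(PlantedError("missed_gene", c.locus_tag))
    missed = [p.locus_tag for p in planted if p.category == "missed_gene"]
    ledger.one_hit = set(missed[: config.n_one_hit])
    ledger.one_hit_transcribed = set(missed[: config.n_one_hit_transcribed])

    # --- start moved upstream (annotation too long, the long-ORF bias)
    for _ in range(counts.get("wrong_start_long", 0)):
        def has_upstream(c):
            ups = _upstream_canonical(genome, c)
            ups = [p for p in ups if abs(p - c.start_coord) // 3 >= 3
                   and not _overlaps_other(c, p, genes)]
            return ups or None
        c, ups = next_eligible(has_upstream)
        if c is None:
            break
        pos = ups[int(rng.integers(len(ups)))]
        published[c.locus_tag] = CdsAnnotation(c.locus_tag, c.replicon_id, pos,
                                               c.stop_coord)
        planted.append(PlantedError("wrong_start_long", c.locus_tag,
                                    {"true_start": c.start_coord,
                                     "published_start": pos}))

    # --- start moved downstream (annotation too short)
    for _ in range(counts.get("wrong_start_short", 0)):
        def has_internal(c):
            prot = ledger.true_proteins.get(c.locus_tag, "")
            first = [p for p in tryptic_digest(prot, 1, 6, 40) if p.start_offset == 0]
            if not first:
                return None
            cands = _internal_canonical(genome, c, 12, 40)
            cands = [kv for kv in cands if kv[0] > len(first[0].sequence)]
            return cands or None
        c, cands = next_eligible(has_internal)
        if c is None:
            break
        k, pos = cands[int(rng.integers(len(cands)))]
        published[c.locus_tag] = CdsAnnotation(c.locus_tag, c.replicon_id, pos,
                                               c.stop_coord)
        planted.append(PlantedError("wrong_start_short", c.locus_tag,
                                    {"true_start": c.start_coord,
                                     "published_start": pos, "shift_codons": k}))

    # --- spurious CDS displacing a real gene (opposite strand, SPO0504-style)
    for i in range(counts.get("spurious_cds", 0)):
        c, _r = next_eligible(lambda c: True if c.span_nt >= 3 * 80 else None)
        if c is None:
            break
        del published[c.locus_tag]
        m = int(rng.integers(41, 61))  # fake length in codons
        off = int(rng.integers(0, c.span_nt - 3 * m))
        f_left = c.left + off
        f_right = f_left + 3 * m - 1
        fake_strand = "-" if c.strand == "+" else "+"
        fake = (CdsAnnotation(f"FAKE_{i + 1:03d}", c.replicon_id, f_right, f_left)
                if fake_strand == "-"
                else CdsAnnotation(f"FAKE_{i + 1:03d}", c.replicon_id, f_left, f_right))
        fakes.append(fake)
        planted.append(PlantedError("spurious_cds", c.locus_tag,
                                    {"fake_locus": fake.locus_tag}))

    # --- single-base insertions splitting a gene across frames; the gene is
    # absent from the published annotation (a frameshifted CDS is skipped at
    # the primary annotation stage).  The break is placed at a tryptic
    # boundary so the innermost flanking peptides bracket it tightly and the
    # set of reconciling edits collapses to the homopolymer run.
    for _ in range(counts.get("base_insertion", 0)):
        def boundary_breaks(c):
            prot = ledger.true_proteins.get(c.locus_tag, "")
            L = len(prot)
            if L < 150:
                return None
            peps = [p for p in tryptic_digest(prot, 0, 6, 40)]
            ends = {p.start_offset + len(p.sequence) for p in peps}
            starts = {p.start_offset for p in peps}
            ms = sorted(m for m in (ends & starts) if 60 <= m <= L - 60)
            return ms or None
        c, ms = next_eligible(boundary_breaks)
        if c is None:
            break
        m = ms[int(rng.integers(len(ms)))]  # break before residue index m
        q = c.start_coord + 3 * m if c.strand == "+" else c.start_coord - 3 * m + 1
        base = str(rng.choice(list("ACGT")))
        insertion_positions.append(q)
        del published[c.locus_tag]
        planted.append(PlantedError("base_insertion", c.locus_tag,
                                    {"position_orig": q, "base": base,
                                     "break_residue": m}))

    # --- apply insertions right-to-left, then shift every coordinate
    seq = genome.sequence
    for p, q in sorted(
        [(pl.details["position_orig"], pl.details["base"])
         for pl in planted if pl.category == "base_insertion"],
        reverse=True,
    ):
        seq = seq[: p - 1] + q + seq[p - 1 :]
    genome_mut = GenomeRecord(genome.replicon_id, seq, genome.topology)
    ins = sorted(insertion_positions)

    def shift_cds(c: CdsAnnotation) -> CdsAnnotation:
        return CdsAnnotation(c.locus_tag, c.replicon_id,
                             _shift_coord(c.start_coord, ins),
                             _shift_coord(c.stop_coord, ins),
                             c.product, c.source)

    published_cds = sorted((shift_cds(c) for c in list(published.values()) + fakes),
                           key=lambda c: c.left)
    published_set = AnnotationSet(published_cds, (genome.replicon_id,))
    true_shifted = AnnotationSet([shift_cds(c) for c in genes], (genome.replicon_id,))

    for pl in planted:
        if pl.category == "base_insertion":
            p_mut = _shift_coord(pl.details["position_orig"], [q for q in ins
                                 if q < pl.details["position_orig"]])
            b = genome_mut.sequence[p_mut - 1]
            lo = hi = p_mut
            while lo > 1 and genome_mut.sequence[lo - 2] == b:
                lo -= 1
            while hi < len(genome_mut) and genome_mut.sequence[hi] == b:
                hi += 1
            pl.details.update(position=p_mut, run_interval=(lo, hi), base=b)
        elif pl.category in ("wrong_start_long", "wrong_start_short"):
            pl.details["true_start"] = _shift_coord(pl.details["true_start"], ins)
            pl.details["published_start"] = _shift_coord(pl.details["published_start"], ins)

    ledger.true_cds = true_shifted
    ledger.planted = planted
    return genome_mut, published_set, ledger


def _overlaps_other(cds: CdsAnnotation, new_start: int, genes: list) -> bool:
    lo = min(new_start, cds.stop_coord)
    hi = max(new_start, cds.stop_coord)
    return any(g.locus_tag != cds.locus_tag
               and max(lo, g.left) <= min(hi, g.right) for g in genes)


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

def _nterm_semi_peptide(protein: str, start_codon: str):
    """(sequence, met_removed) of the plausible most-N-terminal peptide."""
    if len(protein) < 8:
        return None
    removed = protein[1] in _NME_RESIDUES
    if start_codon == "TTG" and not removed:
        return None  # keep to the observed category structure
    start = 1 if removed else 0
    sites = sorted(s + 1 for s in cleavage_sites(protein))
    for end in sites + [len(protein)]:
        if 6 <= end - start <= 40:
            return protein[start:end], removed
        if end - start > 40:
            return None
    return None


def _assign_orf(pep_seq: str, gene_left: int, gene_right: int, strand: str,
                orfs_by_strand: dict, allow_initiator: bool = False):
    """Locate a peptide in a stop-to-stop ORF overlapping the gene span."""
    variants = [pep_seq]
    if allow_initiator and pep_seq.startswith("M"):
        variants += ["V" + pep_seq[1:], "L" + pep_seq[1:]]
    for orf in orfs_by_strand.get(strand, ()):
        if orf.right < gene_left - 1000 or orf.left > gene_right + 1000:
            continue
        for v in variants:
            if v in orf.aa_sequence:
                return orf
    return None


def simulate_psms(genome_mut: GenomeRecord, db: OrfDatabase,
                  ledger: GroundTruthLedger, config: SimulationConfig):
    """Simulate the filtered evidence tables for the mutated genome.

    Returns (target PSMs, decoy PSMs, transcription evidence dict).  Fills
    ``ledger.expressed``, ``ledger.false_psm_keys``, ``ledger.n_true_psm_rows``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 37])
    orfs_by_strand: dict[str, list] = {"+": [], "-": []}
    for o in db.orfs:
        orfs_by_strand[o.strand].append(o)
    error_loci = {p.locus_tag: p for p in ledger.planted}
    conditions = ["exp_rich", "stat_rich", "uv_stress", "marine_broth"]
    nb_n = config.spectral_dispersion
    nb_p = nb_n / (nb_n + config.spectral_mean)

    rows: dict[tuple, PsmRecord] = {}
    transcription: dict[str, bool] = {}

    def emit(seq, orf_id, p, status):
        key = (seq, orf_id)
        spectra = 1 + int(rng.negative_binomial(nb_n, nb_p))
        if key in rows:
            old = rows[key]
            rows[key] = PsmRecord(seq, orf_id, min(old.p_value, p), 1,
                                  old.spectral_count + spectra, old.condition, status)
        else:
            rows[key] = PsmRecord(seq, orf_id, p, 1, spectra,
                                  str(rng.choice(conditions)), status)

    def true_p():
        return float(10 ** rng.uniform(-9, -4))

    for cds in ledger.true_cds:
        tag = cds.locus_tag
        protein = ledger.true_proteins.get(tag)
        if protein is None:
            continue
        err = error_loci.get(tag)
        forced = err is not None and config.guarantee_error_evidence
        if not forced and rng.random() >= config.gene_detect_prob:
            continue
        ledger.expressed.add(tag)
        peptides = tryptic_digest(protein, 1, 6, 40)
        if err is not None and err.category == "base_insertion":
            m = err.details["break_residue"]
            peptides = [p for p in peptides
                        if not (p.start_offset < m
                                and p.start_offset + len(p.sequence) > m)]
        if tag in ledger.one_hit:
            mid = [p for p in peptides if p.missed_cleavages == 0]
            pick = mid[len(mid) // 2] if mid else peptides[0]
            orf = _assign_orf(pick.sequence, cds.left, cds.right, cds.strand,
                             orfs_by_strand)
            if orf is not None:
                emit(pick.sequence, orf.orf_id, float(10 ** rng.uniform(-8, -5)),
                     "full")
                transcription[orf.orf_id] = tag in ledger.one_hit_transcribed
            continue
        chosen = [p for p in peptides if rng.random() < config.peptide_detect_prob]
        if forced:
            must = []
            if err.category == "wrong_start_short":
                must = [p for p in peptides if p.start_offset == 0][:1]
            elif err.category == "base_insertion":
                m = err.details["break_residue"]
                before = [p for p in peptides
                          if p.start_offset + len(p.sequence) <= m]
                after = [p for p in peptides if p.start_offset >= m]
                if before:
                    must.append(max(before, key=lambda p: p.start_offset))
                if after:
                    must.append(min(after, key=lambda p: p.start_offset))
            have = {(p.sequence, p.start_offset) for p in chosen}
            chosen += [p for p in must if (p.sequence, p.start_offset) not in have]
        for pep in chosen:
            orf = _assign_orf(pep.sequence, cds.left, cds.right, cds.strand,
                             orfs_by_strand)
            if orf is not None:
                emit(pep.sequence, orf.orf_id, true_p(), "full")
        # N-terminal semi-tryptic peptide
        start_codon = _start_codon_of(genome_mut, err, cds)
        want_nterm = (err is not None and err.category == "wrong_start_long"
                      and config.guarantee_error_evidence) \
            or rng.random() < config.nterm_peptide_prob
        if want_nterm and err is not None and err.category == "base_insertion":
            want_nterm = rng.random() < config.nterm_peptide_prob
        if want_nterm:
            semi = _nterm_semi_peptide(protein, start_codon)
            if semi is not None:
                seq, _removed = semi
                orf = _assign_orf(seq, cds.left, cds.right, cds.strand,
                                  orfs_by_strand, allow_initiator=True)
                if orf is not None:
                    emit(seq, orf.orf_id, true_p(), "semi_N")

    ledger.n_true_psm_rows = len(rows)

    # false target matches against random database entries
    n_false = int(rng.poisson(config.false_psm_rate * max(1, len(rows))))
    for _ in range(n_false):
        orf = db.orfs[int(rng.integers(len(db.orfs)))]
        peps = tryptic_digest(orf.aa_sequence, 0, 6, 40)
        if not peps:
            continue
        pep = peps[int(rng.integers(len(peps)))]
        p = float(rng.uniform(1e-4, 0.05))
        key = (pep.sequence, orf.orf_id)
        if key in rows:
            continue
        rows[key] = PsmRecord(pep.sequence, orf.orf_id, p, 1, 1,
                              str(rng.choice(conditions)), "full")
        ledger.false_psm_keys.append(key + (p,))

    # decoy table against the reversed database
    decoys: list[PsmRecord] = []
    n_decoy = int(rng.poisson(config.false_psm_rate * max(1, ledger.n_true_psm_rows)))
    for _ in range(n_decoy):
        orf = db.orfs[int(rng.integers(len(db.orfs)))]
        rev = orf.aa_sequence[::-1]
        peps = tryptic_digest(rev, 0, 6, 40)
        if not peps:
            continue
        pep = peps[int(rng.integers(len(peps)))]
        decoys.append(PsmRecord(pep.sequence, "REV_" + orf.orf_id,
                                float(rng.uniform(1e-4, 0.05)), 1, 1,
                                str(rng.choice(conditions)), "full"))
    target = sorted(rows.values(), key=lambda r: (r.orf_id, r.peptide_seq))
    return target, decoys, transcription


def _start_codon_of(genome: GenomeRecord, err, cds: CdsAnnotation) -> str:
    pos = cds.start_coord
    if err is not None and "true_start" in err.details:
        pos = err.details["true_start"]
    if cds.strand == "+":
        return genome.sequence[pos - 1 : pos + 2]
    return reverse_complement(genome.sequence[pos - 3 : pos])


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _synonymous_codons():
    table = CodonTable.unambiguous_dna_by_id[11]
    syn: dict[str, list] = {}
    for codon, aa in table.forward_table.items():
        syn.setdefault(aa, []).append(codon)
    return syn


def simulate_clade(genome: GenomeRecord, annotation_true: AnnotationSet,
                   ledger: GroundTruthLedger, config: SimulationConfig):
    """Derive subject genomes by aa-level substitution + back-translation.

    Subject annotations carry planted start errors at the configured rate;
    genes "lost" during subject annotation stay in the genome but are omitted
    from the annotation (the unannotated-homolog situation).  Returns a list
    of (GenomeRecord, AnnotationSet); the ledger records the planted subject
    start errors and lost genes.
    """
    config.validate()
    syn = _synonymous_codons()
    subjects = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, 53, s])
        subj_id = f"SUBJ{s + 1:02d}"
        parts: list[str] = []
        cursor = 0
        placed = []  # (tag, strand, left, right, lost)
        for cds in annotation_true:
            protein = ledger.true_proteins[cds.locus_tag]
            mutated = [protein[0]]
            for aa in protein[1:]:
                if rng.random() < config.aa_divergence:
                    choices = [a for a in _AA20 if a != aa]
                    mutated.append(choices[int(rng.integers(19))])
                else:
                    mutated.append(aa)
            codons = [str(rng.choice(CANONICAL_STARTS, p=config.start_codon_mix))]
            for aa in mutated[1:]:
                opts = syn[aa]
                codons.append(opts[int(rng.integers(len(opts)))])
            codons.append(str(rng.choice(STOP_CODONS)))
            coding = "".join(codons)
            spacer = int(rng.integers(config.spacer_nt[0], config.spacer_nt[1] + 1))
            left = cursor + spacer + 1
            right = left + len(coding) - 1
            parts.append(_random_bases(rng, spacer, config.gc_content))
            parts.append(coding if cds.strand == "+" else reverse_complement(coding))
            lost = rng.random() < config.gene_loss_prob
            placed.append((cds.locus_tag, cds.strand, left, right, lost,
                           "".join(mutated)))
            cursor = right
        parts.append(_random_bases(rng, 200, config.gc_content))
        subj_genome = GenomeRecord(subj_id, "".join(parts))

        annotated = [p for p in placed if not p[4]]
        n_err = int(round(config.subject_start_error_rate * len(annotated)))
        order = list(rng.permutation(len(annotated)))
        errors: dict[str, tuple] = {}
        cds_out = []
        for rank, idx in enumerate(order):
            tag, strand, left, right, _lost, _prot = annotated[idx]
            start = left if strand == "+" else right
            stop = right if strand == "+" else left
            cds = CdsAnnotation(tag, subj_id, start, stop)
            if len(errors) < n_err:
                moved = _plant_subject_start_error(subj_genome, cds, rng)
                if moved is not None:
                    errors[tag] = (start, moved.start_coord)
                    cds = moved
            cds_out.append(cds)
        cds_out.sort(key=lambda c: c.left)
        subjects.append((subj_genome, AnnotationSet(cds_out, (subj_id,))))
        ledger.subject_start_errors[subj_id] = errors
        ledger.subject_lost_genes[subj_id] = {
            (p[0]): (p[1], p[2], p[3], p[5]) for p in placed if p[4]
        }
    return subjects


def _plant_subject_start_error(genome: GenomeRecord, cds: CdsAnnotation, rng):
    """Move an annotated start to another in-frame canonical codon."""
    down = _internal_canonical(genome, cds, 2, 15)
    up = [p for p in _upstream_canonical(genome, cds, 15)
          if abs(p - cds.start_coord) // 3 >= 2]
    options = [("down", pos) for _k, pos in down] + [("up", pos) for pos in up]
    if not options:
        return None
    _kind, pos = options[int(rng.integers(len(options)))]
    return CdsAnnotation(cds.locus_tag, cds.replicon_id, pos, cds.stop_coord)


# ---------------------------------------------------------------------------
# one-call dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    genome: GenomeRecord  # mutated ("sequenced") genome
    annotation_published: AnnotationSet
    annotation_true: AnnotationSet  # coordinates in the mutated genome
    db: OrfDatabase
    psms: list
    decoy_psms: list
    transcription: dict
    ledger: GroundTruthLedger
    genome_true: GenomeRecord
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate genome + planted errors + evidence in one deterministic call."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config.seed = seed
    genome_true, annotation_true, ledger = generate_genome(config)
    genome_mut, published, ledger = plant_errors(genome_true, annotation_true,
                                                 config, ledger)
    orfs = enumerate_orfs([genome_mut])
    db = build_search_db(orfs)
    psms, decoys, transcription = simulate_psms(genome_mut, db, ledger, config)
    return SimulatedDataset(genome_mut, published, ledger.true_cds, db, psms,
                            decoys, transcription, ledger, genome_true, config)


# ---------------------------------------------------------------------------
# recovery scoring against the ledger
# ---------------------------------------------------------------------------

def score_calls(ledger: GroundTruthLedger, calls: list) -> dict:
    """Recall/precision per planted category, matched against the ledger.

    A novel/wrong-CDS call matches a planted gene when it proposes the same
    strand and 3' stop boundary; a start correction must hit the true start
    exactly; a sequence-error call matches when its correction interval
    contains the planted position.
    """
    true_by_stop = {}
    for c in ledger.true_cds:
        true_by_stop[(c.replicon_id, c.strand, c.stop_coord)] = c.locus_tag

    def gene_of_call(call):
        if call.new_cds is None:
            return None
        k = (call.new_cds.replicon_id, call.new_cds.strand, call.new_cds.stop_coord)
        return true_by_stop.get(k)

    out = {}

    # novel genes: planted missed genes, except one-hit wonders without
    # transcription evidence (planted as undiscoverable)
    truth_novel = {p.locus_tag for p in ledger.planted_by_category("missed_gene")
                   if p.locus_tag not in (ledger.one_hit - ledger.one_hit_transcribed)}
    pred_novel = {gene_of_call(c) for c in calls if c.category == "novel_cds"}
    out["novel_cds"] = _pr(truth_novel, pred_novel - {None},
                           sum(1 for c in calls if c.category == "novel_cds"))

    truth_wrong = {p.locus_tag for p in ledger.planted_by_category("spurious_cds")}
    pred_wrong = {gene_of_call(c) for c in calls
                  if c.category == "wrong_cds_replacement"}
    out["wrong_cds_replacement"] = _pr(
        truth_wrong, pred_wrong - {None},
        sum(1 for c in calls if c.category == "wrong_cds_replacement"))

    # start corrections: both planted directions; a call counts as correct
    # when it targets the planted locus and proposes the true start
    start_truth = {p.locus_tag: p.details["true_start"]
                   for p in ledger.planted
                   if p.category in ("wrong_start_long", "wrong_start_short")}
    correct_hits = set()
    n_start_calls = 0
    for c in calls:
        if c.category not in ("start_corrected", "nterm_extension"):
            continue
        if c.new_cds is None:
            continue
        n_start_calls += 1
        locus = c.locus_tag
        if locus in start_truth and c.new_cds.start_coord == start_truth[locus]:
            correct_hits.add(locus)
    out["start_corrected"] = _pr(set(start_truth), correct_hits, n_start_calls)

    ins = ledger.planted_by_category("base_insertion")
    n_seq_calls = sum(1 for c in calls if c.category == "sequence_error")
    hit, contained = set(), []
    for p in ins:
        pos = p.details["position"]
        for c in calls:
            if c.category != "sequence_error" or c.sequence_error is None:
                continue
            lo, hi = c.sequence_error.correction_interval
            if lo <= pos <= hi:
                hit.add(p.locus_tag)
                contained.append(True)
                break
        else:
            contained.append(False)
    out["sequence_error"] = _pr({p.locus_tag for p in ins}, hit, n_seq_calls)
    out["sequence_error"]["interval_containment"] = (
        sum(contained) / len(contained) if contained else float("nan"))
    return out


def _pr(truth: set, correct: set, n_calls: int) -> dict:
    tp = len(truth & correct)
    recall = tp / len(truth) if truth else float("nan")
    precision = tp / n_calls if n_calls else float("nan")
    return {"recall": recall, "precision": precision, "tp": tp,
            "n_truth": len(truth), "n_calls": n_calls}
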