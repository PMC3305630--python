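"""Peptide-spectrum-match evidence: ingestion, filtering, decoy FDR, mapping.

The interchange format is a plain TSV (one row per non-redundant peptide/ORF
assignment) rather than any search-engine export; the simulator writes the
same schema, so synthetic and real evidence enter the pipeline identically.

Schema (tab-separated, header required):
    peptide  orf_id  p_value  rank  spectral_count  condition  tryptic_status
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .digestion import Peptide
from .genome_model import ProteoseedError, FormatError
from .sixframe import OrfDatabase, StopToStopOrf

__all__ = [
    "PsmRecord",
    "MappedPeptide",
    "ProteinEvidence",
    "PSM_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
    "make_decoy_db",
    "decoy_fdr",
    "map_peptide_to_genome",
    "map_all_psms",
    "aggregate_to_proteins",
]

PSM_COLUMNS = [
    "peptide",
    "orf_id",
    "p_value",
    "rank",
    "spectral_count",
    "condition",
    "tryptic_status",
]


@dataclass(frozen=True)
class PsmRecord:
    peptide_seq: str
    orf_id: str
    p_value: float
    rank: int = 1
    spectral_count: int = 1
    condition: str = ""
    tryptic_status: str = "full"  # full | semi_N

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise FormatError(f"p_value {self.p_value} outside (0, 1]")
        if self.rank < 1:
            raise FormatError(f"rank {self.rank} < 1")
        if self.spectral_count < 1:
            raise FormatError(f"spectral_count {self.spectral_count} < 1")


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide placed on the genome through its stop-to-stop ORF."""

    peptide: Peptide
    orf: StopToStopOrf
    genomic_start: int  # first base in reading direction
    genomic_end: int  # last base in reading direction
    frame: int
    shared: bool = False

    @property
    def left(self) -> int:
        return min(self.genomic_start, self.genomic_end)

    @property
    def right(self) -> int:
        return max(self.genomic_start, self.genomic_end)


@dataclass
class ProteinEvidence:
    """Peptide support aggregated per stop-to-stop ORF.

    ``distinct_peptides`` holds unshared peptide sequences only (peptides
    occurring in several ORFs never count toward the two-peptide rule);
    ``shared_peptides`` keeps the rest for reporting.
    """

    orf_id: str
    distinct_peptides: set = field(default_factory=set)
    shared_peptides: set = field(default_factory=set)
    total_spectra: int = 0
    best_p_value: float = 1.0
    status: str = "unsupported"  # validated | one_hit | unsupported
    supported_left: int = 0
    supported_right: int = 0


# ---------------------------------------------------------------------------
# TSV I/O and filtering
# ---------------------------------------------------------------------------

def read_psm_table(path: str | Path) -> list[PsmRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out, bad = [], []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            out.append(
                PsmRecord(
                    str(row["peptide"]),
                    str(row["orf_id"]),
                    float(row["p_value"]),
                    int(row["rank"]),
                    int(row["spectral_count"]),
                    "" if pd.isna(row["condition"]) else str(row["condition"]),
                    str(row["tryptic_status"]),
                )
            )
        except (FormatError, ValueError) as exc:
            bad.append((lineno, str(exc)))
    if bad:
        warnings.warn(f"rejected {len(bad)} malformed PSM rows: {bad[:10]}", stacklevel=2)
    return out


def write_psm_table(psms: list[PsmRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (p.peptide_seq, p.orf_id, p.p_value, p.rank, p.spectral_count,
             p.condition, p.tryptic_status)
            for p in psms
        ],
        columns=PSM_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def filter_psms(psms: list[PsmRecord], p_threshold: float = 0.005) -> list[PsmRecord]:
    """Rank-1 records with p strictly below the identity threshold."""
    return [p for p in psms if p.rank == 1 and p.p_value < p_threshold]


# ---------------------------------------------------------------------------
# decoy database and FDR
# ---------------------------------------------------------------------------

def make_decoy_db(db: OrfDatabase) -> OrfDatabase:
    """Reverse every ORF sequence (full-sequence reversal, ids REV_-prefixed)."""
    rev = [
        StopToStopOrf("REV_" + o.orf_id, o.replicon_id, o.frame,
                      o.span_start, o.span_end, o.aa_sequence[::-1])
        for o in db.orfs
    ]
    return OrfDatabase(rev, [("REV_" + c, s[::-1]) for c, s in db.contaminants],
                       db.min_length_aa)


def decoy_fdr(
    target_psms: list[PsmRecord],
    decoy_psms: list[PsmRecord],
    level: str = "peptide",
    mode: str = "distinct",
) -> float:
    """Decoy-based FDR estimate at peptide or protein level.

    ``mode='distinct'`` counts distinct identifications (sequences or ORFs);
    ``mode='spectral'`` counts assigned spectra.  Returns NaN when there are
    no target identifications (undefined, deliberately distinct from 0).
    """
    if level not in ("peptide", "protein"):
        raise ValueError(level)

    def count(psms):
        if mode == "spectral":
            return sum(p.spectral_count for p in psms)
        if level == "peptide":
            return len({p.peptide_seq for p in psms})
        return len({p.orf_id for p in psms})

    n_target = count(target_psms)
    if n_target == 0:
        return math.nan
    return count(decoy_psms) / n_target


# ---------------------------------------------------------------------------
# peptide -> genome mapping
# ---------------------------------------------------------------------------

def _occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _semi_n_occurrences(orf_aa: str, pep: str) -> list[int]:
    """Extra matches for semi-tryptic N-terminal peptides starting with Met.

    A GTG/TTG initiator is read as Val/Leu inside a stop-to-stop translation
    but as Met in the mature protein, so a position-0 M/V or M/L mismatch is
    tolerated; the canonical-codon check happens later against the genome.
    """
    if not pep.startswith("M"):
        return []
    out = []
    for alt in ("V", "L"):
        out.extend(_occurrences(orf_aa, alt + pep[1:]))
    return sorted(set(out))


def map_peptide_to_genome(psm: PsmRecord, db: OrfDatabase) -> list[MappedPeptide]:
    """Place a PSM's peptide at every occurrence within its matched ORF."""
    if psm.orf_id not in db:
        raise ProteoseedError(f"{psm.orf_id}: not in ORF database")
    orf = db.get(psm.orf_id)
    offsets = _occurrences(orf.aa_sequence, psm.peptide_seq)
    if psm.tryptic_status == "semi_N":
        offsets = sorted(set(offsets) | set(_semi_n_occurrences(orf.aa_sequence, psm.peptide_seq)))
    if not offsets:
        raise ProteoseedError(
            f"peptide {psm.peptide_seq!r} not found in {psm.orf_id} (corrupt evidence)"
        )
    out = []
    for off in offsets:
        g_start = orf.aa_to_genomic(off)
        span = 3 * len(psm.peptide_seq) - 1
        g_end = g_start + span if orf.frame > 0 else g_start - span
        out.append(
            MappedPeptide(
                Peptide(psm.peptide_seq, off, psm.tryptic_status),
                orf, g_start, g_end, orf.frame,
            )
        )
    return out


def map_all_psms(psms: list[PsmRecord], db: OrfDatabase) -> list[MappedPeptide]:
    """Map every PSM; peptides occurring in multiple ORFs are flagged shared."""
    orfs_per_seq: dict[str, set] = {}
    for p in psms:
        orfs_per_seq.setdefault(p.peptide_seq, set()).add(p.orf_id)
    mapped = []
    for p in psms:
        shared = len(orfs_per_seq[p.peptide_seq]) > 1
        for m in map_peptide_to_genome(p, db):
            if shared:
                m = MappedPeptide(m.peptide, m.orf, m.genomic_start, m.genomic_end,
                                  m.frame, shared=True)
            mapped.append(m)
    return mapped


def aggregate_to_proteins(
    mapped: list[MappedPeptide],
    psms: list[PsmRecord],
) -> list[ProteinEvidence]:
    """Group mapped peptides by ORF and apply the two-peptide validation rule.

    Status is ``validated`` with >=2 distinct unshared peptide sequences,
    ``one_hit`` with exactly 1; spectral counts are summed over PSMs.
    """
    psm_info: dict[tuple, PsmRecord] = {}
    for p in psms:
        key = (p.peptide_seq, p.orf_id)
        if key not in psm_info or p.p_value < psm_info[key].p_value:
            psm_info[key] = p
    ev: dict[str, ProteinEvidence] = {}
    counted_spectra: dict[str, set] = {}
    for m in mapped:
        oid = m.orf.orf_id
        e = ev.setdefault(oid, ProteinEvidence(oid, supported_left=m.left,
                                               supported_right=m.right))
        seq = m.peptide.sequence
        if m.shared:
            e.shared_peptides.add(seq)
        else:
            e.distinct_peptides.add(seq)
        e.supported_left = min(e.supported_left, m.left)
        e.supported_right = max(e.supported_right, m.right)
        rec = psm_info.get((seq, oid))
        if rec is not None:
            e.best_p_value = min(e.best_p_value, rec.p_value)
            if seq not in counted_spectra.setdefault(oid, set()):
                counted_spectra[oid].add(seq)
                e.total_spectra += rec.spectral_count
    for e in ev.values():
        n = len(e.distinct_peptides)
        e.status = "validated" if n >= 2 else ("one_hit" if n == 1 else "unsupported")
    return sorted(ev.values(), key=lambda e: e.orf_id)
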