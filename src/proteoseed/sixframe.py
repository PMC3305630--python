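"""Stop-to-stop ORF enumeration in six frames and search-database construction.

An ORF here is a *maximal inter-stop segment*: the translated stretch between
two in-frame stop codons (replicon ends act as virtual stops).  Segments of at
least ``min_length_aa`` residues (default 41, i.e. "more than forty") enter
the database.  This deliberately includes a large number of spurious
translation products alongside every real CDS; the peptide evidence decides
which are real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .genome_model import (
    AnnotationSet,
    FormatError,
    GenomeRecord,
    ProteoseedError,
    frame_of_position,
    reverse_complement,
)

__all__ = [
    "StopToStopOrf",
    "OrfDatabase",
    "enumerate_orfs",
    "build_search_db",
    "build_restricted_db",
    "read_search_db",
    "orf_containing_cds",
]


@dataclass(frozen=True)
class StopToStopOrf:
    """A translated inter-stop segment in one of the six reading frames.

    ``span_start``/``span_end`` are the first and last translated base in
    reading direction (1-based inclusive); for minus frames span_start >
    span_end.  The bounding stop codons themselves are outside the span.
    """

    orf_id: str
    replicon_id: str
    frame: int
    span_start: int
    span_end: int
    aa_sequence: str

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def left(self) -> int:
        return min(self.span_start, self.span_end)

    @property
    def right(self) -> int:
        return max(self.span_start, self.span_end)

    def aa_to_genomic(self, aa_offset: int) -> int:
        """Genomic position (reading direction) of the first base of a residue."""
        if self.frame > 0:
            return self.span_start + 3 * aa_offset
        return self.span_start - 3 * aa_offset


def _orf_id(replicon: str, frame: int, span_start: int, span_end: int) -> str:
    return f"{replicon}:{frame:+d}:{span_start}-{span_end}"


@dataclass
class OrfDatabase:
    orfs: list[StopToStopOrf] = field(default_factory=list)
    contaminants: list[tuple] = field(default_factory=list)
    min_length_aa: int = 41

    def __post_init__(self):
        ids = [o.orf_id for o in self.orfs]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate orf_ids in database")
        self._index = {o.orf_id: o for o in self.orfs}

    def __len__(self):
        return len(self.orfs)

    def __contains__(self, orf_id: str) -> bool:
        return orf_id in self._index

    def get(self, orf_id: str) -> StopToStopOrf:
        return self._index[orf_id]

    @property
    def total_residues(self) -> int:
        return sum(len(o.aa_sequence) for o in self.orfs) + sum(
            len(s) for _, s in self.contaminants
        )


def enumerate_orfs(
    genomes: Iterable[GenomeRecord],
    min_length_aa: int = 41,
    require_both_stops: bool = False,
    table: int = 11,
) -> list[StopToStopOrf]:
    """Partition each replicon and frame at stop codons into eligible ORFs.

    ``require_both_stops=True`` drops terminal segments not bounded by a stop
    codon on both sides (replicon ends otherwise act as virtual stops).
    Output is sorted by (replicon, frame, leftmost coordinate).
    """
    if not genomes:
        raise ProteoseedError("no genomes supplied")
    out: list[StopToStopOrf] = []
    for g in genomes:
        L = len(g)
        for frame in (1, 2, 3, -1, -2, -3):
            offset = abs(frame) - 1
            strand_seq = g.sequence if frame > 0 else reverse_complement(g.sequence)
            sub = strand_seq[offset : offset + (L - offset) // 3 * 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate(table=table))
            n_codons = len(aa)
            pos = 0
            for seg in aa.split("*"):
                seg_start_codon = pos  # codon index within frame
                pos += len(seg) + 1
                if len(seg) < min_length_aa:
                    continue
                if require_both_stops:
                    preceded = seg_start_codon > 0
                    followed = seg_start_codon + len(seg) < n_codons
                    if not (preceded and followed):
                        continue
                # strand-sequence offsets of first/last translated base
                first_nt = offset + 3 * seg_start_codon
                last_nt = first_nt + 3 * len(seg) - 1
                if frame > 0:
                    span_start, span_end = first_nt + 1, last_nt + 1
                else:
                    span_start, span_end = L - first_nt, L - last_nt
                out.append(
                    StopToStopOrf(
                        _orf_id(g.replicon_id, frame, span_start, span_end),
                        g.replicon_id,
                        frame,
                        span_start,
                        span_end,
                        seg,
                    )
                )
    out.sort(key=lambda o: (o.replicon_id, o.frame, o.left))
    return out


# ---------------------------------------------------------------------------
# search database FASTA
# ---------------------------------------------------------------------------

def build_search_db(
    orfs: list[StopToStopOrf],
    contaminant_path: str | Path | None = None,
    out: str | Path | None = None,
    min_length_aa: int = 41,
) -> OrfDatabase:
    """Assemble the search database, optionally appending contaminants.

    FASTA headers encode ``orf_id|replicon|frame|span_start|span_end`` so the
    genomic placement of every entry is recoverable from the header alone.
    """
    contaminants = []
    if contaminant_path is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(contaminant_path), "fasta"):
            cid = rec.id if rec.id.startswith("CONTAM_") else f"CONTAM_{rec.id}"
            contaminants.append((cid, str(rec.seq).upper()))
    db = OrfDatabase(list(orfs), contaminants, min_length_aa)
    if out is not None:
        write_search_db(db, out)
    return db


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_search_db(db: OrfDatabase, path: str | Path) -> None:
    lines = []
    for o in db.orfs:
        lines.append(f">{o.orf_id}|{o.replicon_id}|{o.frame:+d}|{o.span_start}|{o.span_end}")
        lines.append(_wrap(o.aa_sequence))
    for cid, seq in db.contaminants:
        lines.append(f">{cid}")
        lines.append(_wrap(seq))
    Path(path).write_text("\n".join(lines) + "\n")


def read_search_db(path: str | Path) -> OrfDatabase:
    from Bio import SeqIO

    orfs, contaminants = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.startswith("CONTAM_"):
            contaminants.append((rec.id, str(rec.seq)))
            continue
        fields = rec.description.split("|")
        if len(fields) != 5:
            raise FormatError(f"{path}: header {rec.description!r} not a proteoseed DB header")
        orf_id, replicon, frame, s, e = fields
        orfs.append(StopToStopOrf(orf_id, replicon, int(frame), int(s), int(e), str(rec.seq)))
    return OrfDatabase(orfs, contaminants)


# ---------------------------------------------------------------------------
# restricted (second-pass) database
# ---------------------------------------------------------------------------

def cds_in_orf(orf: StopToStopOrf, cds) -> bool:
    """True when a CDS lies inside a stop-to-stop ORF in the ORF's own frame.

    The CDS stop codon (if included in its span) lies just outside the ORF
    span, so containment is tested on the coding part only (the trailing
    stop codon may stick out past the ORF span by exactly one codon).
    """
    if orf.replicon_id != cds.replicon_id or orf.strand != cds.strand:
        return False
    if (orf.span_start - cds.start_coord) % 3 != 0:
        return False
    if cds.strand == "+":
        return orf.left <= cds.left and cds.right <= orf.right + 3
    return cds.right <= orf.right and orf.left - 3 <= cds.left


def orf_containing_cds(db: OrfDatabase, cds) -> StopToStopOrf | None:
    """The stop-to-stop ORF containing a CDS in its own frame, if any."""
    for o in db.orfs:
        if cds_in_orf(o, cds):
            return o
    return None


def build_restricted_db(
    db: OrfDatabase,
    annotation: AnnotationSet,
    first_pass_hits: set[str] | Iterable[str] = (),
) -> OrfDatabase:
    """Second-pass database: annotated ORFs plus first-pass hit ORFs."""
    first_pass_hits = set(first_pass_hits)
    missing = first_pass_hits - {o.orf_id for o in db.orfs}
    if missing:
        raise ProteoseedError(f"first-pass hits not in database: {sorted(missing)[:5]}")
    keep: dict[str, StopToStopOrf] = {}
    import warnings as _warnings

    for cds in annotation:
        o = orf_containing_cds(db, cds)
        if o is None:
            _warnings.warn(f"{cds.locus_tag}: no containing stop-to-stop ORF", stacklevel=2)
            continue
        keep[o.orf_id] = o
    for oid in first_pass_hits:
        keep[oid] = db.get(oid)
    orfs = sorted(keep.values(), key=lambda o: (o.replicon_id, o.frame, o.left))
    return OrfDatabase(orfs, list(db.contaminants), db.min_length_aa)
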