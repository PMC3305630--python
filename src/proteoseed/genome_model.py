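"""Genome and CDS annotation data model, coordinate arithmetic, FASTA/GFF3 I/O.

Coordinate conventions used throughout the package:

* Genomic coordinates are 1-based and inclusive.
* A CDS is stored in *reading direction*: ``start_coord`` is the first coding
  base and ``stop_coord`` the last.  A minus-strand CDS therefore has
  ``start_coord > stop_coord``; GFF3 I/O converts to/from the usual
  start<=end + strand column representation.
* Reading frames are ``+1, +2, +3`` (forward strand, first codon starting at
  position 1, 2, 3) and ``-1, -2, -3`` (reverse complement, first codon
  starting at the last, second-to-last, third-to-last base of the replicon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteoseedError",
    "FormatError",
    "TranslationFault",
    "GenomeRecord",
    "CdsAnnotation",
    "AnnotationSet",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation",
    "coords_to_length",
    "extract_and_translate",
    "reverse_complement",
    "frame_of_position",
    "position_of_codon",
    "CANONICAL_STARTS",
    "STOP_CODONS",
]

CANONICAL_STARTS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")


class ProteoseedError(Exception):
    """Base class for all package errors."""


class FormatError(ProteoseedError):
    """Malformed or invalid input file."""


class TranslationFault(ProteoseedError):
    """A CDS span failed to translate cleanly.

    ``genomic_position`` carries the 1-based position (reading direction) of
    the first base of the offending codon; frameshift detection reuses it.
    """

    def __init__(self, message: str, genomic_position: int | None = None):
        super().__init__(message)
        self.genomic_position = genomic_position


@dataclass(frozen=True)
class GenomeRecord:
    """One replicon: identity, sequence and topology."""

    replicon_id: str
    sequence: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"replicon {self.replicon_id!r}: empty sequence")
        bad = set(self.sequence) - _IUPAC_DNA
        if bad:
            raise FormatError(
                f"replicon {self.replicon_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise FormatError(f"replicon {self.replicon_id!r}: bad topology")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsAnnotation:
    """A CDS in reading-direction convention (minus strand iff start > stop)."""

    locus_tag: str
    replicon_id: str
    start_coord: int
    stop_coord: int
    product: str = ""
    source: str = "original"  # or "proteogenomic"
    flags: tuple = ()

    def __post_init__(self):
        if self.start_coord == self.stop_coord:
            raise FormatError(f"{self.locus_tag}: start_coord == stop_coord")

    @property
    def strand(self) -> str:
        return "-" if self.start_coord > self.stop_coord else "+"

    @property
    def left(self) -> int:
        return min(self.start_coord, self.stop_coord)

    @property
    def right(self) -> int:
        return max(self.start_coord, self.stop_coord)

    @property
    def span_nt(self) -> int:
        return self.right - self.left + 1


@dataclass
class AnnotationSet:
    """A collection of CDS annotations over a set of replicons."""

    cds_list: list[CdsAnnotation] = field(default_factory=list)
    genome_ref: tuple = ()

    def __post_init__(self):
        tags = [c.locus_tag for c in self.cds_list]
        if len(tags) != len(set(tags)):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise FormatError(f"duplicate locus_tags: {dupes}")
        if self.genome_ref:
            known = set(self.genome_ref)
            for c in self.cds_list:
                if c.replicon_id not in known:
                    raise FormatError(
                        f"{c.locus_tag}: replicon {c.replicon_id!r} not in genome set"
                    )

    def __iter__(self):
        return iter(self.cds_list)

    def __len__(self):
        return len(self.cds_list)

    def by_tag(self, locus_tag: str) -> CdsAnnotation:
        for c in self.cds_list:
            if c.locus_tag == locus_tag:
                return c
        raise KeyError(locus_tag)


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def coords_to_length(start_coord: int, stop_coord: int) -> int:
    """Length in codons of an inclusive reading-direction span.

    Matches the "Length (aa)" arithmetic of a start/stop coordinate pair:
    (|stop - start| + 1) / 3.
    """
    span = abs(stop_coord - start_coord) + 1
    if span % 3:
        raise ProteoseedError(f"span {span} nt not divisible by 3")
    return span // 3


def frame_of_position(pos: int, strand: str, replicon_len: int) -> int:
    """Reading frame of the codon whose first base (reading direction) is pos."""
    if strand == "+":
        return (pos - 1) % 3 + 1
    return -(((replicon_len - pos) % 3) + 1)


def position_of_codon(span_start: int, strand: str, aa_index: int) -> int:
    """Genomic position (reading direction) of codon ``aa_index`` (0-based)."""
    return span_start + 3 * aa_index if strand == "+" else span_start - 3 * aa_index


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, topology: str = "linear") -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into GenomeRecords, uppercased."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(rec.id, str(rec.seq).upper(), topology))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_genome(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.sequence), id=g.replicon_id, description="") for g in genomes]
    SeqIO.write(recs, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# annotation I/O  (GFF3 and a minimal TSV dialect)
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, val = chunk.partition("=")
        out[key.strip()] = val.strip()
    return out


def _check_cds(cds: CdsAnnotation, genomes_by_id: dict) -> CdsAnnotation:
    flags = []
    rec = genomes_by_id.get(cds.replicon_id)
    if rec is not None and (cds.left < 1 or cds.right > len(rec)):
        warnings.warn(f"{cds.locus_tag}: CDS outside replicon bounds", stacklevel=3)
        flags.append("out_of_bounds")
    if cds.span_nt % 3:
        warnings.warn(f"{cds.locus_tag}: span not divisible by 3", stacklevel=3)
        flags.append("bad_phase")
    return replace(cds, flags=tuple(flags)) if flags else cds


def read_annotation(path: str | Path, genomes: list[GenomeRecord]) -> AnnotationSet:
    """Read CDS annotations from GFF3 or the 4-column TSV dialect.

    GFF3 minus-strand features (start<=end, strand '-') are converted to the
    internal start>stop reading-direction convention.  Out-of-bounds or
    phase-violating records are flagged and kept, with a warning.
    """
    path = Path(path)
    by_id = {g.replicon_id: g for g in genomes}
    text = path.read_text()
    cds = []
    if _looks_like_gff3(text):
        counter = 0
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            counter += 1
            a = _parse_gff3_attributes(attrs)
            tag = a.get("locus_tag") or a.get("ID") or f"CDS_{counter:05d}"
            start_i, end_i = int(start), int(end)
            if strand == "-":
                c = CdsAnnotation(tag, seqid, end_i, start_i, a.get("product", ""))
            else:
                c = CdsAnnotation(tag, seqid, start_i, end_i, a.get("product", ""))
            cds.append(_check_cds(c, by_id))
    else:
        lines = [l for l in text.splitlines() if l.strip()]
        header = lines[0].rstrip("\n").split("\t")
        required = ["locus_tag", "replicon", "start", "stop"]
        if [h.strip() for h in header[:4]] != required:
            raise FormatError(f"{path}: TSV header must start with {required}")
        for lineno, line in enumerate(lines[1:], 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 TSV columns")
            tag, repl, s, e = parts[:4]
            c = CdsAnnotation(tag, repl, int(s), int(e))
            cds.append(_check_cds(c, by_id))
    return AnnotationSet(cds, tuple(by_id))


def _looks_like_gff3(text: str) -> bool:
    if text.lstrip().startswith("##gff-version"):
        return True
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            return len(line.split("\t")) == 9
    return False


def write_annotation(annotation: AnnotationSet, path: str | Path, dialect: str = "gff3") -> None:
    path = Path(path)
    if dialect == "gff3":
        lines = ["##gff-version 3"]
        for c in annotation:
            strand = c.strand
            left, right = c.left, c.right
            attrs = f"ID={c.locus_tag};locus_tag={c.locus_tag}"
            if c.product:
                attrs += f";product={c.product}"
            lines.append(
                "\t".join(
                    [c.replicon_id, "proteoseed", "CDS", str(left), str(right),
                     ".", strand, "0", attrs]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "tsv":
        lines = ["locus_tag\treplicon\tstart\tstop\tproduct\tsource"]
        for c in annotation:
            lines.append(
                f"{c.locus_tag}\t{c.replicon_id}\t{c.start_coord}\t{c.stop_coord}"
                f"\t{c.product}\t{c.source}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def extract_and_translate(
    genome: GenomeRecord,
    cds: CdsAnnotation,
    table: int = 11,
    initiator_as_met: bool = True,
) -> str:
    """Extract a CDS span and translate it (bacterial table 11 by default).

    Minus-strand spans are reverse-complemented first.  A canonical initiator
    (ATG/GTG/TTG) is rendered as Met at position 1.  A trailing stop codon, if
    the span includes one, is stripped.  An internal stop raises
    :class:`TranslationFault` carrying the genomic position of the stop codon.
    """
    if cds.left < 1 or cds.right > len(genome):
        raise ProteoseedError(f"{cds.locus_tag}: CDS outside {genome.replicon_id}")
    nt = genome.sequence[cds.left - 1 : cds.right]
    if cds.strand == "-":
        nt = reverse_complement(nt)
    if len(nt) % 3:
        raise ProteoseedError(f"{cds.locus_tag}: span {len(nt)} nt not divisible by 3")
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        i = aa.index("*")
        pos = position_of_codon(cds.start_coord, cds.strand, i)
        raise TranslationFault(
            f"{cds.locus_tag}: internal stop codon at genomic position {pos}",
            genomic_position=pos,
        )
    if initiator_as_met and aa and nt[:3] in CANONICAL_STARTS:
        aa = "M" + aa[1:]
    return aa
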