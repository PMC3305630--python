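"""In-silico trypsin digestion (fully tryptic and N-terminal semi-tryptic).

Cleavage follows the Keil rule used by Mascot's "Trypsin" enzyme: after K or
R, except when the next residue is P.  Shared by the peptide-to-genome mapper
and the evidence simulator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyteomics import parser as _pyt_parser

__all__ = ["Peptide", "tryptic_digest", "semi_tryptic_nterm_candidates", "TRYPSIN_RULE"]

TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class Peptide:
    """A digestion product located within its parent protein."""

    sequence: str
    start_offset: int  # 0-based position in the parent protein
    tryptic_status: str = "full"  # full | semi_N | semi_C
    missed_cleavages: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide")
        if self.tryptic_status not in ("full", "semi_N", "semi_C"):
            raise ValueError(f"bad tryptic_status {self.tryptic_status!r}")


def cleavage_sites(protein: str) -> list[int]:
    """0-based indices of residues after which trypsin cleaves."""
    return [m.start() for m in re.finditer(TRYPSIN_RULE, protein)]


def _internal_missed(protein_sites: set[int], start: int, end_excl: int) -> int:
    # sites strictly inside the peptide (cleaving after the final residue is
    # the peptide's own C-terminal boundary, not a missed cleavage)
    return sum(1 for s in protein_sites if start <= s < end_excl - 1)


def tryptic_digest(
    protein: str,
    max_missed: int = 1,
    min_len: int = 6,
    max_len: int = 40,
) -> list[Peptide]:
    """Fully tryptic peptides with 0..max_missed missed cleavages.

    Deterministic order: by start offset, then length.
    """
    sites = set(cleavage_sites(protein))
    out: dict[tuple, Peptide] = {}  # a terminal K/R would otherwise duplicate
    for start, seq in _pyt_parser.icleave(
        protein, TRYPSIN_RULE, missed_cleavages=max_missed, min_length=max(min_len, 1)
    ):
        if len(seq) > max_len:
            continue
        out[(start, seq)] = Peptide(
            seq, start, "full", _internal_missed(sites, start, start + len(seq)))
    peps = sorted(out.values(), key=lambda p: (p.start_offset, len(p.sequence)))
    return peps


def semi_tryptic_nterm_candidates(
    protein: str,
    max_len: int = 40,
    min_len: int = 6,
    max_missed: int = 1,
) -> list[Peptide]:
    """Plausible most-N-terminal semi-tryptic peptides of a protein.

    The C-terminus must be a tryptic boundary (or the protein end) but the
    N-terminus is free — restricted to protein positions 1 and 2, the only
    starts consistent with an intact or Met-excised N-terminus.
    """
    n = len(protein)
    sites = set(cleavage_sites(protein))
    boundaries = sorted({s + 1 for s in sites} | {n})  # exclusive end offsets
    out = []
    for start in (0, 1):
        if start >= n:
            break
        for end in boundaries:
            if end <= start:
                continue
            length = end - start
            if length < min_len or length > max_len:
                continue
            if _internal_missed(sites, start, end) > max_missed:
                continue
            out.append(
                Peptide(protein[start:end], start, "semi_N",
                        _internal_missed(sites, start, end))
            )
    out.sort(key=lambda p: (p.start_offset, len(p.sequence)))
    return out
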