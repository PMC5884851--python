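"""Genetic codes, reading-frame inference, translation and ORF/GC screens.

Codon tables come from the NCBI numbering (Bio.Data.CodonTable); the default
throughout the package is table 5, the invertebrate mitochondrial code, the
appropriate code for insect cytb/cox1 fragments. A reading frame is described
by the number of alignment columns skipped before the first complete codon
(offset 0/1/2); when a fragment's frame is unknown it is inferred as the
forward frame with the fewest internal stop codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .errors import InputError, UndefinedContentError

BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino acid map; stops encoded as ``*``."""

    table_id: int
    codon_map: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise InputError("genetic code must map all 64 codons")
        if "*" not in self.codon_map.values():
            raise InputError("genetic code must contain at least one stop codon")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        try:
            tbl = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise InputError(f"unknown NCBI translation table {table_id}") from exc
        cmap = {}
        for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
            cmap[codon] = "*" if codon in tbl.stop_codons else tbl.forward_table[codon]
        return cls(table_id=table_id, codon_map=cmap)

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; ``X`` when the codon has gaps/ambiguity."""
        return self.codon_map.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon) == "*"


INVERTEBRATE_MITO = 5
STANDARD = 1


@dataclass(frozen=True)
class FrameSpec:
    """Reading frame: columns skipped before the first complete codon."""

    offset: int
    n_complete_codons: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.offset not in (0, 1, 2):
            raise InputError("frame offset must be 0, 1 or 2")

    @classmethod
    def for_length(cls, length: int, offset: int = 0, low_confidence: bool = False) -> "FrameSpec":
        return cls(offset=offset, n_complete_codons=max(0, (length - offset) // 3),
                   low_confidence=low_confidence)


def degap(seq: str) -> str:
    return seq.replace("-", "")


def _internal_stop_positions(seq: str, offset: int, code: GeneticCode) -> list[int]:
    """Indices of stop codons, excluding a stop in the final complete codon."""
    n = (len(seq) - offset) // 3
    stops = []
    for k in range(n):
        codon = seq[offset + 3 * k : offset + 3 * k + 3]
        if code.is_stop(codon):
            stops.append(k)
    if stops and stops[-1] == n - 1:
        stops.pop()
    return stops


def infer_frame(seq: str, code: GeneticCode) -> FrameSpec:
    """Pick the forward frame minimizing internal stops; ties go to the
    smallest offset. A ``low_confidence`` flag is set when every frame still
    has a stop and the sequence is too short (<6 nt) to disambiguate."""
    s = degap(seq).upper()
    if len(s) < 3:
        raise InputError("cannot infer a frame on fewer than 3 bases")
    counts = [len(_internal_stop_positions(s, off, code)) for off in (0, 1, 2)]
    best = min(range(3), key=lambda off: (counts[off], off))
    low = all(c >= 1 for c in counts) and len(s) < 6
    return FrameSpec.for_length(len(s), offset=best, low_confidence=low)


def translate(seq: str, frame: FrameSpec, code: GeneticCode) -> str:
    """Translate the complete codons of a (degapped) sequence.

    Stops become ``*``; any codon containing N or other non-ACGT characters
    becomes ``X``.
    """
    s = degap(seq).upper()
    n = (len(s) - frame.offset) // 3
    return "".join(
        code.aa(s[frame.offset + 3 * k : frame.offset + 3 * k + 3]) for k in range(max(0, n))
    )


@dataclass(frozen=True)
class OrfScreen:
    has_internal_stop: bool
    stop_positions: tuple[int, ...] = field(default_factory=tuple)
    has_indel: bool = False

    def passed(self) -> bool:
        return not (self.has_internal_stop or self.has_indel)


def screen_orf(hap_seq: str, frame: FrameSpec, code: GeneticCode) -> OrfScreen:
    """Stop-codon and indel screen for one aligned haplotype sequence.

    Any gap character counts as an indel relative to the alignment. The stop
    scan runs on the degapped sequence in the given frame; a stop in the final
    complete codon is tolerated (a fragment may legitimately end at a stop).
    """
    has_indel = "-" in hap_seq
    s = degap(hap_seq).upper()
    stops = tuple(_internal_stop_positions(s, frame.offset, code))
    return OrfScreen(has_internal_stop=bool(stops), stop_positions=stops, has_indel=has_indel)


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T), ignoring gaps and ambiguity codes entirely."""
    s = seq.upper()
    counts = {b: s.count(b) for b in BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedContentError("no unambiguous bases; GC content undefined")
    return (counts["G"] + counts["C"]) / denom
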