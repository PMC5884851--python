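"""Aligned-sequence I/O, end trimming, haplotype collapsing and prevalence testing.

The unit of work is an :class:`AlignedSeqSet`: a rectangular block of gapped
nucleotide sequences, optionally carrying a sampling-site label per record
(parsed from the FASTA description line). Population samples of a single gene
are collapsed into haplotypes — distinct sequences with member lists and
per-site counts — and haplotype frequencies across sites are compared with a
Pearson chi-square test of homogeneity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .errors import AlignmentError, DegenerateTableError, InputError

VALID_CHARS = set("ACGTN-")

#: Default rule: the site label is whatever follows the last ``|`` in the
#: FASTA description, e.g. ``>larva07|site2``. Returns None when absent.
DEFAULT_SITE_REGEX = re.compile(r"\|([^|]+)\s*$")


@dataclass(frozen=True)
class AlignedRecord:
    id: str
    seq: str
    site_label: str | None = None


@dataclass(frozen=True)
class AlignedSeqSet:
    """An alignment: equal-length nucleotide strings over {A,C,G,T,N,-}."""

    records: tuple[AlignedRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no records")
        length = len(self.records[0].seq)
        ids = set()
        for rec in self.records:
            if len(rec.seq) != length:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
                )
            if rec.id in ids:
                raise AlignmentError(f"duplicate record id {rec.id!r}")
            ids.add(rec.id)
            bad = set(rec.seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"record {rec.id!r} contains invalid characters {sorted(bad)}"
                )
        if length < 1:
            raise AlignmentError("alignment has zero columns")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, rec_id: str) -> AlignedRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise InputError(f"no record with id {rec_id!r}")

    def column(self, i: int) -> str:
        return "".join(r.seq[i] for r in self.records)


def _default_site_parser(description: str) -> str | None:
    m = DEFAULT_SITE_REGEX.search(description)
    return m.group(1).strip() if m else None


def read_alignment(
    path,
    site_parser: Callable[[str], str | None] | str | None = "default",
) -> AlignedSeqSet:
    """Read a gapped FASTA alignment.

    Parameters
    ----------
    path:
        FASTA file of equal-length, gapped nucleotide sequences.
    site_parser:
        ``"default"`` extracts the site label after the last ``|`` of the
        description; a regex string with one capture group overrides that
        rule; a callable receives the full description; ``None`` disables
        site labels.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    if site_parser == "default":
        parse = _default_site_parser
    elif site_parser is None:
        parse = lambda d: None  # noqa: E731
    elif isinstance(site_parser, str):
        rx = re.compile(site_parser)
        parse = lambda d: (m.group(1) if (m := rx.search(d)) else None)  # noqa: E731
    else:
        parse = site_parser
    out = []
    for rec in records:
        label = parse(rec.description)
        rec_id = rec.id.split("|")[0] if label is not None and "|" in rec.id else rec.id
        out.append(AlignedRecord(id=rec_id, seq=str(rec.seq).upper(), site_label=label))
    return AlignedSeqSet(records=tuple(out))


def write_alignment(aln: AlignedSeqSet, path) -> None:
    """Write an alignment to FASTA, encoding site labels as ``id|site``."""
    recs = []
    for r in aln.records:
        name = r.id if r.site_label is None else f"{r.id}|{r.site_label}"
        recs.append(SeqRecord(Seq(r.seq), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")


def trim_alignment(aln: AlignedSeqSet) -> AlignedSeqSet:
    """Drop ragged ends: leading/trailing columns holding any gap or N.

    Interior gap/N columns are left untouched; only the maximal clean core is
    retained. Raises :class:`AlignmentError` when no column survives.
    """
    ncol = aln.length
    dirty = [any(r.seq[i] in "-N" for r in aln.records) for i in range(ncol)]
    start = 0
    while start < ncol and dirty[start]:
        start += 1
    end = ncol
    while end > start and dirty[end - 1]:
        end -= 1
    if start >= end:
        raise AlignmentError("trimming removed every column of the alignment")
    if start == 0 and end == ncol:
        return aln
    return AlignedSeqSet(
        records=tuple(
            AlignedRecord(r.id, r.seq[start:end], r.site_label) for r in aln.records
        )
    )


@dataclass(frozen=True)
class Haplotype:
    """A distinct aligned sequence and the sampled individuals carrying it."""

    hap_id: str
    seq: str
    members: tuple[str, ...]
    counts_by_site: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return len(self.members)


def collapse_haplotypes(aln: AlignedSeqSet, n_matches_any: bool = False) -> list[Haplotype]:
    """Partition records by exact sequence identity.

    Haplotypes are ordered by descending frequency, ties broken by first
    appearance in the input; ids are assigned ``H1``, ``H2``, ... in that
    order. By default ``N`` is an ordinary mismatching symbol, so sequences
    differing only at an N are distinct haplotypes; ``n_matches_any=True``
    merges a sequence into an earlier group whenever it matches at every
    non-N position of both.
    """
    groups: list[list[AlignedRecord]] = []
    keys: list[str] = []
    for rec in aln.records:
        placed = False
        if n_matches_any:
            for gi, key in enumerate(keys):
                if all(a == b or a == "N" or b == "N" for a, b in zip(rec.seq, key)):
                    groups[gi].append(rec)
                    placed = True
                    break
        else:
            try:
                gi = keys.index(rec.seq)
            except ValueError:
                gi = -1
            if gi >= 0:
                groups[gi].append(rec)
                placed = True
        if not placed:
            keys.append(rec.seq)
            groups.append([rec])
    order = sorted(range(len(groups)), key=lambda gi: (-len(groups[gi]), gi))
    haps = []
    for rank, gi in enumerate(order, start=1):
        members = tuple(r.id for r in groups[gi])
        counts: dict[str, int] = {}
        for r in groups[gi]:
            if r.site_label is not None:
                counts[r.site_label] = counts.get(r.site_label, 0) + 1
        haps.append(
            Haplotype(hap_id=f"H{rank}", seq=keys[gi], members=members, counts_by_site=counts)
        )
    return haps


@dataclass(frozen=True)
class PrevalenceTest:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray  # haplotype x site counts
    hap_ids: tuple[str, ...]
    site_labels: tuple[str, ...]


def prevalence_test(haps: Sequence[Haplotype]) -> PrevalenceTest:
    """Pearson chi-square homogeneity test of haplotype frequencies across sites.

    No continuity correction is applied; expected counts come from the row and
    column margins and the p-value from the upper tail of the chi-square
    distribution with (rows-1)(cols-1) degrees of freedom.
    """
    sites = sorted({s for h in haps for s in h.counts_by_site})
    if len(haps) < 2 or len(sites) < 2:
        raise DegenerateTableError(
            "prevalence test needs at least two haplotypes and two site labels"
        )
    table = np.array(
        [[h.counts_by_site.get(s, 0) for s in sites] for h in haps], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return PrevalenceTest(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        table=table,
        hap_ids=tuple(h.hap_id for h in haps),
        site_labels=tuple(sites),
    )
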