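"""The numt decision procedure.

Each haplotype is screened three ways against trusted mitochondrial reference
sequences aligned to it:

1. ORF screen — internal stop codons or indels are disqualifying on their own.
2. GC content — informational by default; an optional bounds check.
3. Substitution-pattern screen — the pairwise codon-position profile against
   each reference is compared with mtDNA expectation intervals; a haplotype
   whose most suspicious comparison has at least ``k_outside`` of the six
   metrics beyond their intervals *on the pseudogene side* (too many
   pos1/pos2/tv3/nonsynonymous changes, too few pos3/ts3) is called a
   putative numt.

The k-of-6 rule operationalizes the qualitative published call ("deviated
significantly from the reference values"); the default k=3 separates a genuine
haplotype with one or two borderline metrics from pseudogenes with four or
more, and is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .alignio import AlignedSeqSet, Haplotype
from .codon import FrameSpec, GeneticCode, OrfScreen, gc_content, infer_frame, screen_orf
from .errors import ConfigurationError, InputError
from .profile import (
    MTDNA_EXPECTATION,
    DeviationReport,
    ReferenceExpectation,
    compare_to_reference,
    pair_profile,
)

logger = logging.getLogger(__name__)

GENUINE = "GENUINE"
PUTATIVE_NUMT = "PUTATIVE_NUMT"


@dataclass(frozen=True)
class ScreenConfig:
    reference_ids: tuple[str, ...] = ()
    k_outside: int = 3
    gc_bounds: tuple[float, float] | None = None
    table_id: int = 5
    frame_offset: int | None = None  # None -> infer from the first reference
    expectation: ReferenceExpectation = MTDNA_EXPECTATION

    def __post_init__(self) -> None:
        if not (1 <= self.k_outside <= 6):
            raise ConfigurationError("k_outside must be between 1 and 6")
        if self.gc_bounds is not None and not (self.gc_bounds[0] < self.gc_bounds[1]):
            raise ConfigurationError("gc_bounds must satisfy low < high")


@dataclass(frozen=True)
class NumtVerdict:
    hap_id: str
    verdict: str
    orf: OrfScreen
    gc: float
    gc_ok: bool | None  # None when no bounds configured
    reports: dict[str, DeviationReport]  # reference id -> report
    skipped_refs: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_outside(self) -> int:
        """Count of pseudogene-direction interval excursions, maximized
        across references (the most suspicious comparison governs).

        Excursions at the mtDNA-like extreme (e.g. zero nonsynonymous
        changes) do not count: a pseudogene reveals itself by too-high
        pos1/pos2/tv3/nonsynonymous shares and too-low pos3/ts3 shares,
        never by being cleaner than expectation.
        """
        return max((r.n_suspicious for r in self.reports.values()), default=0)


def _hap_sort_key(hap_id: str):
    if hap_id.startswith("H") and hap_id[1:].isdigit():
        return (0, int(hap_id[1:]), hap_id)
    return (1, 0, hap_id)


def _resolve_frame(cfg: ScreenConfig, refs: AlignedSeqSet, code: GeneticCode) -> FrameSpec:
    if cfg.frame_offset is not None:
        return FrameSpec.for_length(refs.length, offset=cfg.frame_offset)
    inferred = infer_frame(refs.records[0].seq, code)
    return FrameSpec.for_length(refs.length, offset=inferred.offset)


def screen_dataset(
    haps: Sequence[Haplotype], refs: AlignedSeqSet, cfg: ScreenConfig | None = None
) -> list[NumtVerdict]:
    """Screen every haplotype against every trusted reference.

    The references must be aligned to the haplotypes (same column count) and
    must pass their own ORF screen; a reference with an internal stop or indel
    is a configuration error, not evidence. Zero-divergence haplotype/reference
    pairs contribute no deviation report (logged and listed as skipped).
    Verdicts follow the invariant::

        PUTATIVE_NUMT  <=>  internal stop  OR  indel  OR  n_outside >= k_outside

    and come back ordered by haplotype id.
    """
    cfg = cfg or ScreenConfig()
    if not haps:
        raise InputError("no haplotypes to screen")
    code = GeneticCode.from_ncbi_id(cfg.table_id)
    use_refs = [
        r for r in refs.records if not cfg.reference_ids or r.id in cfg.reference_ids
    ]
    if not use_refs:
        raise ConfigurationError("no usable reference sequences in the reference set")
    if any(len(h.seq) != refs.length for h in haps):
        raise InputError("haplotypes and references are not aligned to the same length")
    frame = _resolve_frame(cfg, refs, code)
    for r in use_refs:
        orf = screen_orf(r.seq, frame, code)
        if not orf.passed():
            raise ConfigurationError(
                f"reference {r.id!r} fails its own ORF screen "
                f"(stops at {orf.stop_positions}, indel={orf.has_indel})"
            )

    verdicts = []
    for hap in haps:
        orf = screen_orf(hap.seq, frame, code)
        gc = gc_content(hap.seq)
        gc_ok = None
        if cfg.gc_bounds is not None:
            gc_ok = cfg.gc_bounds[0] <= gc <= cfg.gc_bounds[1]
        reports: dict[str, DeviationReport] = {}
        skipped = []
        for r in use_refs:
            prof = pair_profile(hap.seq, r.seq, frame, code)
            if prof.is_zero:
                logger.info(
                    "haplotype %s is identical to reference %s; comparison skipped",
                    hap.hap_id, r.id,
                )
                skipped.append(r.id)
                continue
            reports[r.id] = compare_to_reference(prof, cfg.expectation)
        n_out = max((rep.n_suspicious for rep in reports.values()), default=0)
        is_numt = orf.has_internal_stop or orf.has_indel or n_out >= cfg.k_outside
        verdicts.append(
            NumtVerdict(
                hap_id=hap.hap_id,
                verdict=PUTATIVE_NUMT if is_numt else GENUINE,
                orf=orf,
                gc=gc,
                gc_ok=gc_ok,
                reports=reports,
                skipped_refs=tuple(skipped),
            )
        )
    verdicts.sort(key=lambda v: _hap_sort_key(v.hap_id))
    return verdicts


def cross_compare(
    suspects: Sequence[Haplotype], cfg: ScreenConfig | None = None,
    frame: FrameSpec | None = None,
) -> dict[tuple[str, str], DeviationReport | None]:
    """Deviation reports for every unordered pair of suspect haplotypes.

    Pseudogene-vs-pseudogene comparisons carry their own signal: two numts
    differ from each other with the same uniform, nonsynonymous-rich pattern.
    Identical pairs are returned as None.
    """
    cfg = cfg or ScreenConfig()
    if len(suspects) < 2:
        raise InputError("cross comparison needs at least two suspects")
    code = GeneticCode.from_ncbi_id(cfg.table_id)
    if frame is None:
        off = cfg.frame_offset if cfg.frame_offset is not None else infer_frame(
            suspects[0].seq, code
        ).offset
        frame = FrameSpec.for_length(len(suspects[0].seq), offset=off)
    out: dict[tuple[str, str], DeviationReport | None] = {}
    for i in range(len(suspects)):
        for j in range(i + 1, len(suspects)):
            a, b = suspects[i], suspects[j]
            prof = pair_profile(a.seq, b.seq, frame, code)
            if prof.is_zero:
                logger.info("suspects %s and %s are identical; flagged", a.hap_id, b.hap_id)
                out[(a.hap_id, b.hap_id)] = None
            else:
                out[(a.hap_id, b.hap_id)] = compare_to_reference(prof, cfg.expectation)
    return out
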