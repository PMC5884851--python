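"""Per-pair codon-position substitution profiles and mtDNA expectation checks.

For an aligned pair of protein-coding sequences, every differing site inside a
complete codon is assigned its codon position; third-position differences are
split into transitions and transversions; and each differing site is classed
synonymous/nonsynonymous by a single-site swap evaluated on both codon
backgrounds. The resulting percentage profile is compared metric-by-metric
against published mtDNA expectation intervals (mean +/- confidence half-width):
genuine mitochondrial coding sequence concentrates change at third positions,
transition-biased and overwhelmingly synonymous, while nuclear pseudogene
copies accumulate substitutions uniformly, transversion- and
nonsynonymous-rich.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .codon import BASES, FrameSpec, GeneticCode
from .errors import ComparisonUndefinedError, InputError

UNAMBIG = set(BASES)

METRICS = ("pos1", "pos2", "pos3", "ts3", "tv3", "nonsyn")


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up, as printed tables do."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PairProfile:
    s1: int
    s2: int
    s3: int
    ts3: int
    tv3: int
    n_nonsyn: int
    n_syn: int
    n_unclassified: int = 0  # differing sites whose codon background was unusable
    n_discarded: int = 0     # differing sites outside complete codons

    @property
    def total(self) -> int:
        return self.s1 + self.s2 + self.s3

    @property
    def is_zero(self) -> bool:
        return self.total == 0

    def _pct(self, num: int, denom: int) -> float:
        if denom == 0:
            raise ComparisonUndefinedError("share undefined: zero denominator")
        return 100.0 * num / denom

    @property
    def share_pos1(self) -> float:
        return self._pct(self.s1, self.total)

    @property
    def share_pos2(self) -> float:
        return self._pct(self.s2, self.total)

    @property
    def share_pos3(self) -> float:
        return self._pct(self.s3, self.total)

    @property
    def share_ts3(self) -> float:
        return self._pct(self.ts3, self.ts3 + self.tv3)

    @property
    def share_tv3(self) -> float:
        return self._pct(self.tv3, self.ts3 + self.tv3)

    @property
    def share_nonsyn(self) -> float:
        return self._pct(self.n_nonsyn, self.total)

    def share(self, metric: str) -> float:
        return {
            "pos1": lambda: self.share_pos1,
            "pos2": lambda: self.share_pos2,
            "pos3": lambda: self.share_pos3,
            "ts3": lambda: self.share_ts3,
            "tv3": lambda: self.share_tv3,
            "nonsyn": lambda: self.share_nonsyn,
        }[metric]()

    def rounded_shares(self) -> dict[str, int]:
        """Integer display shares (half-up), mirroring published tables."""
        return {m: round_half_up(self.share(m)) for m in METRICS}


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def pair_profile(
    a: str, b: str, frame: FrameSpec, code: GeneticCode, nonsyn_rule: str = "any"
) -> PairProfile:
    """Profile every differing site of an aligned pair, codon by codon.

    Pairwise deletion applies as in the distance module: a site is scored only
    when both sequences carry an unambiguous base. A differing site is
    nonsynonymous iff swapping that one base — holding the other two codon
    positions at their state in the background sequence — changes the encoded
    amino acid in at least one of the two backgrounds (``nonsyn_rule="any"``,
    the default OR-rule, symmetric in the two sequences) or in every usable
    background (``nonsyn_rule="both"``, the stricter variant). Sites whose
    codon context is unusable in both backgrounds (gap/N at a flanking
    position) stay unclassified.
    """
    if nonsyn_rule not in ("any", "both"):
        raise InputError(f"unknown nonsyn_rule {nonsyn_rule!r}")
    if len(a) != len(b):
        raise InputError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    a = a.upper()
    b = b.upper()
    off = frame.offset
    n_codons = (len(a) - off) // 3
    s = [0, 0, 0]
    ts3 = tv3 = n_nonsyn = n_syn = n_uncl = n_disc = 0

    # differing comparable sites outside any complete codon -> discard tally
    covered = range(off, off + 3 * n_codons)
    for col in range(len(a)):
        if col in covered:
            continue
        if a[col] in UNAMBIG and b[col] in UNAMBIG and a[col] != b[col]:
            n_disc += 1

    for k in range(n_codons):
        start = off + 3 * k
        ca = a[start : start + 3]
        cb = b[start : start + 3]
        for p in range(3):
            x, y = ca[p], cb[p]
            if x not in UNAMBIG or y not in UNAMBIG or x == y:
                continue
            s[p] += 1
            if p == 2:
                if _is_transition(x, y):
                    ts3 += 1
                else:
                    tv3 += 1
            hits = []
            for bg in (ca, cb):
                ctx = [bg[0], bg[1], bg[2]]
                other = [q for q in range(3) if q != p]
                if any(ctx[q] not in UNAMBIG for q in other):
                    continue
                cx = ctx.copy()
                cy = ctx.copy()
                cx[p] = x
                cy[p] = y
                hits.append(code.aa("".join(cx)) != code.aa("".join(cy)))
            if not hits:
                n_uncl += 1
            elif any(hits) if nonsyn_rule == "any" else all(hits):
                n_nonsyn += 1
            else:
                n_syn += 1
    return PairProfile(s1=s[0], s2=s[1], s3=s[2], ts3=ts3, tv3=tv3,
                       n_nonsyn=n_nonsyn, n_syn=n_syn,
                       n_unclassified=n_uncl, n_discarded=n_disc)


@dataclass(frozen=True)
class ReferenceExpectation:
    """mtDNA expectation intervals: metric -> (mean %, confidence half-width)."""

    intervals: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = set(METRICS) - set(self.intervals)
        if missing:
            raise InputError(f"missing expectation intervals for {sorted(missing)}")
        for m, (mean, hw) in self.intervals.items():
            if not (0.0 <= mean <= 100.0) or hw <= 0:
                raise InputError(f"invalid interval for {m}: mean={mean}, half_width={hw}")

    def bounds(self, metric: str) -> tuple[float, float]:
        mean, hw = self.intervals[metric]
        return mean - hw, mean + hw


#: Published expectation intervals (alpha = 0.05) for genuine animal mtDNA
#: protein-coding sequence: substitution shares by codon position, the
#: transition/transversion split at third positions, and the nonsynonymous
#: share of all substitutions.
MTDNA_EXPECTATION = ReferenceExpectation(
    intervals={
        "pos1": (14.9, 9.4),
        "pos2": (4.5, 3.5),
        "pos3": (80.6, 21.0),
        "ts3": (84.9, 18.1),
        "tv3": (15.1, 7.6),
        "nonsyn": (7.47, 5.4),
    }
)


#: Direction in which each metric deviates in a pseudogene: uniform neutral
#: change inflates pos1/pos2 substitution shares, third-position
#: transversions and the nonsynonymous share, and deflates the
#: third-position share and its transition fraction.
NUMT_DIRECTION = {
    "pos1": +1,
    "pos2": +1,
    "pos3": -1,
    "ts3": -1,
    "tv3": +1,
    "nonsyn": +1,
}


@dataclass(frozen=True)
class MetricCheck:
    observed: float
    inside: bool
    exceedance: float  # (|obs - mean| - half_width)/half_width when outside, else 0
    suspicious: bool = False  # outside AND deviating in the pseudogene direction


@dataclass(frozen=True)
class DeviationReport:
    checks: dict[str, MetricCheck]
    skipped: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_outside(self) -> int:
        """Metrics outside their interval, either side."""
        return sum(1 for c in self.checks.values() if not c.inside)

    @property
    def n_suspicious(self) -> int:
        """Metrics outside their interval on the pseudogene-like side.

        A metric beyond its interval at the mtDNA-like extreme (e.g. a pair
        whose every substitution is a synonymous third-position transition,
        so pos2/tv3/nonsyn shares are 0) is not evidence for a numt and does
        not count here.
        """
        return sum(1 for c in self.checks.values() if c.suspicious)

    def outside_metrics(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.checks.items() if not c.inside)

    def suspicious_metrics(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.checks.items() if c.suspicious)


def compare_to_reference(
    profile: PairProfile, ref: ReferenceExpectation = MTDNA_EXPECTATION
) -> DeviationReport:
    """Test each profile metric for membership in its expectation interval.

    Each check records both plain interval membership (``inside``) and
    whether an excursion lies on the pseudogene-like side of the interval
    (``suspicious``); the screening verdict counts only the latter.
    ts3/tv3 are skipped (reported, not judged) when the pair has no
    third-position substitutions at all. A zero-divergence profile has no
    defined shares and raises.
    """
    if profile.is_zero:
        raise ComparisonUndefinedError("profile has no substitutions; comparison undefined")
    checks: dict[str, MetricCheck] = {}
    skipped = []
    for m in METRICS:
        if m in ("ts3", "tv3") and profile.ts3 + profile.tv3 == 0:
            skipped.append(m)
            continue
        obs = profile.share(m)
        mean, hw = ref.intervals[m]
        dev = abs(obs - mean)
        inside = dev <= hw
        exc = 0.0 if inside else (dev - hw) / hw
        susp = (not inside) and (NUMT_DIRECTION[m] * (obs - mean) > 0)
        checks[m] = MetricCheck(observed=obs, inside=inside, exceedance=exc, suspicious=susp)
    return DeviationReport(checks=checks, skipped=tuple(skipped))
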