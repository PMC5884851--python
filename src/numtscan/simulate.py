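"""Sequence-evolution simulator with known truth labels.

Generates the kind of data the screening pipeline assumes: a population sample
of near-identical haplotypes of a mitochondrial protein-coding fragment,
contaminated by one or more nuclear-pseudogene (numt) lineages. Two
substitution regimes drive an event-level proposal/acceptance process on a
stop-free codon sequence:

* **mt regime** — proposals mildly enriched at first/second positions are
  filtered by strong purifying selection (nonsynonymous acceptance
  ``omega`` << 1) and a high transition bias ``kappa``, so *accepted*
  substitutions concentrate at third positions, transition-rich and almost
  entirely synonymous.
* **numt regime** — a pseudogene evolves neutrally: uniform position rates,
  ``omega`` = 1, modest ``kappa``. Stop-creating proposals are rejected by
  default, mimicking young stop-free numts (switchable).

Branch lengths are calibrated in expected *accepted* substitutions per site:
each branch draws Poisson(t x L) accepted events and proposes until that many
events have been accepted. Every accepted event is tallied by codon position,
transition/transversion class and synonymous/nonsynonymous class, so realized
counts are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignio import AlignedRecord, AlignedSeqSet
from .codon import BASES, GeneticCode
from .errors import GenerationError, InputError

GENUINE = "GENUINE"
NUMT = "NUMT"

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class Regime:
    """Proposal/acceptance parameters for one evolutionary regime."""

    pos_rates: tuple[float, float, float]
    kappa: float
    omega: float
    reject_stops: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.pos_rates):
            raise InputError("position rate multipliers must be positive")
        if not (0.0 < self.omega <= 1.0):
            raise InputError("omega must lie in (0, 1]")
        if self.kappa <= 0:
            raise InputError("kappa must be positive")


#: Calibrated so realized (accepted-event) shares land near published mtDNA
#: expectations: ~19/3/78% by codon position, ~86% transitions at third
#: positions, ~9% nonsynonymous overall. Acceptance itself concentrates
#: change at third positions (under the invertebrate mitochondrial code every
#: third-position transition is synonymous), so the proposal multipliers and
#: transition bias stay mild.
MT_REGIME = Regime(pos_rates=(2.0, 1.0, 1.0), kappa=4.0, omega=0.03)

#: Neutral pseudogene regime: uniform positions, weak transition bias, no
#: selection; stop-free by default (young numts).
NUMT_REGIME = Regime(pos_rates=(1.0, 1.0, 1.0), kappa=2.0, omega=1.0)


@dataclass(frozen=True)
class RealizedCounts:
    """Tallies of accepted substitution events along one branch."""

    by_position: tuple[int, int, int] = (0, 0, 0)
    ts3: int = 0
    tv3: int = 0
    n_syn: int = 0
    n_nonsyn: int = 0

    @property
    def total(self) -> int:
        return sum(self.by_position)

    def position_shares(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            raise InputError("no accepted events; shares undefined")
        return tuple(100.0 * c / t for c in self.by_position)

    @property
    def share_ts3(self) -> float:
        s3 = self.ts3 + self.tv3
        if s3 == 0:
            raise InputError("no third-position events; share undefined")
        return 100.0 * self.ts3 / s3

    @property
    def share_nonsyn(self) -> float:
        if self.total == 0:
            raise InputError("no accepted events; share undefined")
        return 100.0 * self.n_nonsyn / self.total

    def merged(self, other: "RealizedCounts") -> "RealizedCounts":
        return RealizedCounts(
            by_position=tuple(
                a + b for a, b in zip(self.by_position, other.by_position)
            ),
            ts3=self.ts3 + other.ts3,
            tv3=self.tv3 + other.tv3,
            n_syn=self.n_syn + other.n_syn,
            n_nonsyn=self.n_nonsyn + other.n_nonsyn,
        )


def random_root(
    n_codons: int,
    code: GeneticCode,
    gc_target: float,
    rng: np.random.Generator,
    max_rounds: int = 10_000,
) -> str:
    """Stop-free codon sequence with expected GC equal to ``gc_target``.

    Bases are drawn independently with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1-gc)/2; codons that land on a stop are redrawn.
    """
    if not (0.0 < gc_target < 1.0):
        raise InputError("gc_target must lie strictly between 0 and 1")
    probs = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )  # A, C, G, T
    codons = []
    for _ in range(n_codons):
        for _round in range(max_rounds):
            idx = rng.choice(4, size=3, p=probs)
            codon = "".join(BASES[i] for i in idx)
            if not code.is_stop(codon):
                codons.append(codon)
                break
        else:
            raise GenerationError(
                f"could not draw a stop-free codon at gc_target={gc_target}"
            )
    return "".join(codons)


def evolve_branch(
    seq: str,
    regime: Regime,
    t: float,
    code: GeneticCode,
    rng: np.random.Generator,
) -> tuple[str, RealizedCounts]:
    """Evolve a stop-free codon sequence along a branch of length ``t``
    expected accepted substitutions per site.

    Poisson(t x L) accepted events are drawn; proposals (site by position
    multiplier, base by transition bias) are made until that many have been
    accepted. Synonymous proposals are always accepted, nonsynonymous ones
    with probability ``omega``, stop-creating ones never (when
    ``reject_stops``).
    """
    if t < 0:
        raise InputError("branch length must be non-negative")
    if len(seq) % 3 != 0:
        raise InputError("simulator sequences must be whole codons (frame 0)")
    L = len(seq)
    if t == 0 or L == 0:
        return seq, RealizedCounts()
    target = int(rng.poisson(t * L))
    if target == 0:
        return seq, RealizedCounts()
    chars = list(seq)
    w = np.array([regime.pos_rates[i % 3] for i in range(L)], dtype=float)
    p_site = w / w.sum()
    p_ts = regime.kappa / (regime.kappa + 2.0)
    by_pos = [0, 0, 0]
    ts3 = tv3 = n_syn = n_nonsyn = 0
    accepted = 0
    proposals = 0
    max_proposals = 1000 + 500 * target
    while accepted < target:
        proposals += 1
        if proposals > max_proposals:
            raise GenerationError(
                f"branch stalled: {accepted}/{target} acceptances after "
                f"{proposals} proposals (omega={regime.omega})"
            )
        site = int(rng.choice(L, p=p_site))
        old = chars[site]
        if rng.random() < p_ts:
            new = _TRANSITION[old]
            is_ts = True
        else:
            new = _TRANSVERSIONS[old][int(rng.integers(2))]
            is_ts = False
        ci = site // 3
        codon_old = "".join(chars[3 * ci : 3 * ci + 3])
        pos = site % 3
        codon_new = codon_old[:pos] + new + codon_old[pos + 1 :]
        if regime.reject_stops and code.is_stop(codon_new):
            continue
        syn = code.aa(codon_old) == code.aa(codon_new)
        if not syn and rng.random() >= regime.omega:
            continue
        chars[site] = new
        accepted += 1
        by_pos[pos] += 1
        if pos == 2:
            if is_ts:
                ts3 += 1
            else:
                tv3 += 1
        if syn:
            n_syn += 1
        else:
            n_nonsyn += 1
    return "".join(chars), RealizedCounts(
        by_position=tuple(by_pos), ts3=ts3, tv3=tv3, n_syn=n_syn, n_nonsyn=n_nonsyn
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults emulate the screening study's conditions: a ~276-bp (92-codon)
    cytb-like fragment, 24 sampled individuals (18 carrying the genuine
    mitochondrial haplotype, 6 a pseudogene) spread over three sampling
    sites, AT-rich composition (GC ~= 22.7%), and branch lengths of 0.1
    accepted substitutions per site separating root, genuine lineage,
    reference lineage and numt stem.
    """

    n_codons: int = 92
    gc_target: float = 0.227
    table_id: int = 5
    mt_regime: Regime = MT_REGIME
    numt_regime: Regime = NUMT_REGIME
    t_mt: float = 0.1
    t_ref: float = 0.1
    t_numt: float = 0.1
    t_numt_split: float = 0.05
    n_mt_samples: int = 18
    n_numt_samples: int = 6
    n_numt_lineages: int = 1
    site_labels: tuple[str, ...] = ("site1", "site2", "site3")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 2:
            raise InputError("n_codons must be at least 2")
        for t in (self.t_mt, self.t_ref, self.t_numt, self.t_numt_split):
            if t < 0:
                raise InputError("branch lengths must be non-negative")
        if self.n_mt_samples < 1 or self.n_numt_samples < 0:
            raise InputError("need at least one genuine sample")
        if self.n_numt_lineages < 1 and self.n_numt_samples > 0:
            raise InputError("numt samples require at least one numt lineage")


REFERENCE_ID = "REF_MT"


@dataclass(frozen=True)
class SimResult:
    alignment: AlignedSeqSet
    reference: AlignedSeqSet
    truth: dict[str, str]  # record id -> GENUINE | NUMT
    counts: dict[str, RealizedCounts] = field(default_factory=dict)
    root_seq: str = ""
    lineage_seqs: dict[str, str] = field(default_factory=dict)


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """One full simulated study: root, lineages, sampled individuals, truth.

    The genuine lineage, a trusted reference lineage (a congener standing in
    for independent mtDNA) and a numt stem all branch from one root; with
    more than one numt lineage the stem splits further by ``t_numt_split``.
    Individuals are duplicates of their lineage haplotype, assigned to
    sampling sites cyclically. Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    code = GeneticCode.from_ncbi_id(cfg.table_id)
    root = random_root(cfg.n_codons, code, cfg.gc_target, rng)
    counts: dict[str, RealizedCounts] = {}
    lineage_seqs: dict[str, str] = {}

    mt_seq, counts["mt"] = evolve_branch(root, cfg.mt_regime, cfg.t_mt, code, rng)
    ref_seq, counts["ref"] = evolve_branch(root, cfg.mt_regime, cfg.t_ref, code, rng)
    lineage_seqs["mt"] = mt_seq
    lineage_seqs[REFERENCE_ID] = ref_seq

    numt_seqs: list[str] = []
    if cfg.n_numt_samples > 0:
        stem, counts["numt_stem"] = evolve_branch(
            root, cfg.numt_regime, cfg.t_numt, code, rng
        )
        if cfg.n_numt_lineages == 1:
            numt_seqs = [stem]
            lineage_seqs["numt1"] = stem
        else:
            for k in range(cfg.n_numt_lineages):
                s, c = evolve_branch(stem, cfg.numt_regime, cfg.t_numt_split, code, rng)
                counts[f"numt{k + 1}"] = c
                lineage_seqs[f"numt{k + 1}"] = s
                numt_seqs.append(s)

    # individuals: genuine plus numts (round-robin over lineages), shuffled,
    # then dealt cyclically over the sites — equal site sizes, hypergeometric
    # haplotype-by-site counts under a homogeneous-prevalence truth
    pool: list[tuple[str, str]] = [(mt_seq, GENUINE)] * cfg.n_mt_samples
    for k in range(cfg.n_numt_samples):
        pool.append((numt_seqs[k % len(numt_seqs)], NUMT))
    pool = [pool[i] for i in rng.permutation(len(pool))]
    records = []
    truth = {}
    for idx, (seq, label) in enumerate(pool, start=1):
        rec_id = f"larva{idx:02d}"
        site = cfg.site_labels[(idx - 1) % len(cfg.site_labels)] if cfg.site_labels else None
        records.append(AlignedRecord(id=rec_id, seq=seq, site_label=site))
        truth[rec_id] = label
    alignment = AlignedSeqSet(records=tuple(records))
    reference = AlignedSeqSet(
        records=(AlignedRecord(id=REFERENCE_ID, seq=ref_seq, site_label=None),)
    )
    return SimResult(
        alignment=alignment,
        reference=reference,
        truth=truth,
        counts=counts,
        root_seq=root,
        lineage_seqs=lineage_seqs,
    )


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience: a copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
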