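"""Uncorrected (p) and Kimura 2-parameter pairwise distances.

Sites are compared under pairwise deletion: for each pair independently, only
columns where both sequences carry an unambiguous base (A/C/G/T) are scored.
Differences split into transitions (A<->G, C<->T; proportion P) and
transversions (proportion Q); the K2P distance corrects for multiple hits as

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

which is undefined (saturated) when either logarithm argument is <= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignio import AlignedSeqSet
from .errors import InputError, SaturationError

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
UNAMBIG = {"A", "C", "G", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass(frozen=True)
class PairDistance:
    n_compared: int
    n_diff: int
    n_ts: int
    n_tv: int
    saturated: bool = False
    _k2p: float | None = None

    @property
    def p_dist(self) -> float:
        return self.n_diff / self.n_compared

    @property
    def P(self) -> float:
        return self.n_ts / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_tv / self.n_compared

    @property
    def k2p(self) -> float:
        if self.saturated or self._k2p is None:
            raise SaturationError("K2P distance is undefined for this pair (saturated)")
        return self._k2p


def pair_distance(a: str, b: str) -> PairDistance:
    """Distance summary for two equal-length aligned sequences."""
    if len(a) != len(b):
        raise InputError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    a = a.upper()
    b = b.upper()
    n_comp = n_diff = n_ts = n_tv = 0
    for x, y in zip(a, b):
        if x not in UNAMBIG or y not in UNAMBIG:
            continue
        n_comp += 1
        if x != y:
            n_diff += 1
            if is_transition(x, y):
                n_ts += 1
            else:
                n_tv += 1
    if n_comp == 0:
        raise InputError("no comparable sites between the two sequences")
    try:
        d = k2p_from_pq(n_ts / n_comp, n_tv / n_comp)
        return PairDistance(n_comp, n_diff, n_ts, n_tv, saturated=False, _k2p=d)
    except SaturationError:
        return PairDistance(n_comp, n_diff, n_ts, n_tv, saturated=True, _k2p=None)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise-distance matrix; saturated cells are NaN."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str
    saturated_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.labels.index(i), self.labels.index(j)])

    def to_tsv(self, path) -> None:
        """Lower-triangular TSV (blank above the diagonal)."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = []
                for j in range(len(self.labels)):
                    if j > i:
                        cells.append("")
                    else:
                        v = self.values[i, j]
                        cells.append("nan" if np.isnan(v) else f"{v:.3f}")
                fh.write(lab + "\t" + "\t".join(cells) + "\n")

    def to_phylip(self, path) -> None:
        """Full square PHYLIP distance format for tree-building input."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(len(self.labels)))
                fh.write(f"{lab[:10]:<10} {row}\n")


def distance_matrix(aln: AlignedSeqSet, method: str = "k2p") -> DistanceMatrix:
    """All-pairs distances.

    ``method`` is one of ``"p"`` (proportion of differing sites), ``"ndiff"``
    (raw count of differing sites, as published distance tables often print)
    or ``"k2p"``. Saturated K2P cells are recorded as NaN rather than raising.
    """
    if method not in {"p", "ndiff", "k2p"}:
        raise InputError(f"unknown distance method {method!r}")
    if len(aln) < 2:
        raise InputError("distance matrix needs at least two sequences")
    labels = tuple(aln.ids())
    n = len(labels)
    vals = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            pd = pair_distance(aln.records[i].seq, aln.records[j].seq)
            if method == "p":
                v = pd.p_dist
            elif method == "ndiff":
                v = float(pd.n_diff)
            else:
                if pd.saturated:
                    v = float("nan")
                    saturated.append((labels[i], labels[j]))
                else:
                    v = pd.k2p
            vals[i, j] = vals[j, i] = v
    return DistanceMatrix(labels=labels, values=vals, method=method,
                          saturated_pairs=tuple(saturated))
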