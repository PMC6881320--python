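"""Pairwise sequence divergence: p-distance and Kimura 2-parameter distance.

The K2P model distinguishes transitions (A↔G, C↔T; proportion P) from
transversions (proportion Q) and corrects both for multiple hits:

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

Sites with a gap or ambiguity in either sequence are removed pair by pair
(pairwise deletion).  Saturated pairs — where a log argument is
non-positive — yield an undefined distance rather than a clamped number, so
a matrix cell can be NaN while its P and Q remain reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class DistancePair:
    """Site tallies and distances for one aligned sequence pair."""

    usable_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.usable_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.usable_sites

    @property
    def p_distance(self) -> float:
        return self.P + self.Q

    @property
    def k2p(self) -> Optional[float]:
        """K2P distance; ``None`` when the correction saturates."""
        w1 = 1.0 - 2.0 * self.P - self.Q
        w2 = 1.0 - 2.0 * self.Q
        if w1 <= 0.0 or w2 <= 0.0:
            return None
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)

    def standard_error(self) -> Optional[float]:
        """Large-sample SE of the K2P estimate (delta method)."""
        w1 = 1.0 - 2.0 * self.P - self.Q
        w2 = 1.0 - 2.0 * self.Q
        if w1 <= 0.0 or w2 <= 0.0 or self.usable_sites == 0:
            return None
        c1 = 1.0 / w1
        c2 = 1.0 / w2
        c3 = 0.5 * (c1 + c2)
        p, q = self.P, self.Q
        var = (c1 * c1 * p + c3 * c3 * q - (c1 * p + c3 * q) ** 2) / self.usable_sites
        return math.sqrt(var) if var > 0 else 0.0


def classify_site(a: str, b: str) -> Optional[str]:
    """``'identical'``, ``'transition'``, ``'transversion'`` or ``None``
    (site unusable under pairwise deletion)."""
    a, b = a.upper(), b.upper()
    if a not in _VALID or b not in _VALID:
        return None
    if a == b:
        return "identical"
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def site_tallies(a: str, b: str) -> DistancePair:
    """Tally usable/transition/transversion sites of an aligned pair."""
    if len(a) != len(b):
        raise AlignmentError(
            f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    aa = np.frombuffer(a.upper().encode(), dtype="S1")
    bb = np.frombuffer(b.upper().encode(), dtype="S1")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(aa, acgt) & np.isin(bb, acgt)
    av, bv = aa[valid], bb[valid]
    diff = av != bv
    # purine flag: A or G
    apur = (av == b"A") | (av == b"G")
    bpur = (bv == b"A") | (bv == b"G")
    transitions = int(np.sum(diff & (apur == bpur)))
    transversions = int(np.sum(diff & (apur != bpur)))
    return DistancePair(int(valid.sum()), transitions, transversions)


def k2p_distance(a: str, b: str) -> DistancePair:
    """K2P tallies and distance for one aligned pair (pairwise deletion).

    Raises when no usable site remains; a saturated correction leaves
    ``k2p`` undefined while P and Q stay available.
    """
    pair = site_tallies(a, b)
    if pair.usable_sites == 0:
        raise AlignmentError("no usable sites after pairwise deletion")
    return pair


def distance_matrix(seqs: Mapping[str, str] | Mapping[str, Mapping[str, str]],
                    mode: str = "k2p",
                    level: str = "concatenated") -> pd.DataFrame:
    """Symmetric pairwise distance matrix over named aligned sequences.

    ``seqs`` is either ``{name: sequence}`` (one block) or
    ``{gene: {name: sequence}}`` (per-gene blocks).  With
    ``level='concatenated'`` the gene blocks are joined per taxon before
    tallying; ``level='per-gene'`` returns a dict of matrices instead.
    ``mode`` is ``'k2p'`` or ``'p'``.  Saturated K2P cells are NaN.
    """
    if mode not in ("k2p", "p"):
        raise ValueError(f"unknown mode {mode!r}")
    first = next(iter(seqs.values()))
    blocked = isinstance(first, Mapping)
    if blocked and level == "per-gene":
        return {gene: distance_matrix(block, mode=mode)
                for gene, block in seqs.items()}
    if blocked:
        names = list(first)
        joined: dict[str, str] = {n: "" for n in names}
        for gene, block in seqs.items():
            if set(block) != set(names):
                raise AlignmentError(f"taxon set differs in block {gene!r}")
            lengths = {len(s) for s in block.values()}
            if len(lengths) > 1:
                raise AlignmentError(f"unequal lengths in gene block {gene!r}")
            for n in names:
                joined[n] += block[n]
        seqs = joined
    names = list(seqs)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            pair = k2p_distance(seqs[x], seqs[y])
            d = pair.k2p if mode == "k2p" else pair.p_distance
            val = math.nan if d is None else d
            mat.loc[x, y] = mat.loc[y, x] = val
    return mat
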