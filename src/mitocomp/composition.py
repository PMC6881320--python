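"""Base composition and strand-skew statistics.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed from base
occurrences on the (+) strand.  A negative AT skew therefore means the plus
strand carries more T than A — the usual situation on the major strand of
caenogastropod mitogenomes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotation import GenomeAnnotation, reverse_complement

_IUPAC = set("ACGTRYSWKMBDHVN")

#: the row order of the per-region composition report
DEFAULT_REGION_SPEC = ("whole", "PCGs", "per-gene", "tRNAs", "rrnS", "rrnL")


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionStats:
    """Base counts and derived composition statistics for one region.

    ``at_content`` is a percentage of unambiguous bases; the skews are
    dimensionless in [−1, 1] and ``None`` when their denominator is zero.
    Ambiguity codes are tallied in ``n_ambiguous`` and excluded from every
    denominator.
    """

    n_A: int
    n_T: int
    n_G: int
    n_C: int
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        return self.n_A + self.n_T + self.n_G + self.n_C + self.n_ambiguous

    @property
    def at_content(self) -> float:
        tot = self.n_A + self.n_T + self.n_G + self.n_C
        return 100.0 * (self.n_A + self.n_T) / tot

    @property
    def at_skew(self) -> Optional[float]:
        at = self.n_A + self.n_T
        return (self.n_A - self.n_T) / at if at else None

    @property
    def gc_skew(self) -> Optional[float]:
        gc = self.n_G + self.n_C
        return (self.n_G - self.n_C) / gc if gc else None

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(
            self.n_A + other.n_A, self.n_T + other.n_T,
            self.n_G + other.n_G, self.n_C + other.n_C,
            self.n_ambiguous + other.n_ambiguous)


def composition_stats(seq: str) -> CompositionStats:
    """Count bases of ``seq`` and derive A+T content and AT/GC skews.

    Case-insensitive; IUPAC ambiguity codes are allowed but only counted as
    ambiguous.  Raises on an empty or non-nucleotide input.
    """
    if not seq:
        raise CompositionError("empty sequence: statistics undefined")
    s = seq.upper()
    counts = Counter(s)
    bad = set(counts) - _IUPAC
    if bad:
        raise CompositionError(f"non-nucleotide characters: {sorted(bad)}")
    n_a, n_t = counts.get("A", 0), counts.get("T", 0)
    n_g, n_c = counts.get("G", 0), counts.get("C", 0)
    ambiguous = len(s) - n_a - n_t - n_g - n_c
    if n_a + n_t + n_g + n_c == 0:
        raise CompositionError("no unambiguous bases: statistics undefined")
    return CompositionStats(n_a, n_t, n_g, n_c, ambiguous)


def _region_sequences(g: GenomeAnnotation, spec: str,
                      gene_native_strand: bool) -> list[tuple[str, str]]:
    if g.sequence is None:
        raise CompositionError(f"{g.organism_label} carries no sequence")

    def feat_seq(f):
        return g.feature_sequence(f, gene_strand=gene_native_strand)

    if spec == "whole":
        return [("Whole genome", g.sequence)]
    if spec == "PCGs":
        return [("Protein coding genes",
                 "".join(feat_seq(f) for f in g.pcgs))]
    if spec == "tRNAs":
        return [("tRNAs", "".join(feat_seq(f) for f in g.features
                                  if f.gene_class == "tRNA"))]
    if spec == "per-gene":
        return [(f.name, feat_seq(f)) for f in g.pcgs]
    # single-gene lookup (rrnS, rrnL, or any annotated gene)
    return [(spec, feat_seq(g.get(spec)))]


def region_class_stats(g: GenomeAnnotation,
                       class_spec: Sequence[str] = DEFAULT_REGION_SPEC,
                       gene_native_strand: bool = False) -> pd.DataFrame:
    """Composition statistics per genome region class.

    ``class_spec`` entries are ``whole``, ``PCGs``, ``tRNAs``, ``per-gene``
    (expands to one row per protein gene) or any annotated gene name.
    Multi-gene classes are computed on the concatenated (+)-strand
    subsequences in annotation order; ``gene_native_strand=True`` switches
    to reading-orientation sequences instead.

    Returns a DataFrame indexed by region with count and statistic columns.
    """
    rows = []
    for spec in class_spec:
        for label, seq in _region_sequences(g, spec, gene_native_strand):
            st = composition_stats(seq)
            rows.append({
                "region": label,
                "length": st.length,
                "A": st.n_A, "T": st.n_T, "G": st.n_G, "C": st.n_C,
                "at_content": st.at_content,
                "at_skew": st.at_skew if st.at_skew is not None else math.nan,
                "gc_skew": st.gc_skew if st.gc_skew is not None else math.nan,
            })
    return pd.DataFrame(rows).set_index("region")


def composition_table(genomes: Iterable[GenomeAnnotation],
                      class_spec: Sequence[str] = DEFAULT_REGION_SPEC,
                      decimals: int = 2) -> pd.DataFrame:
    """Side-by-side composition report for several genomes.

    Columns are a MultiIndex (statistic, organism); values rounded to
    ``decimals`` for display (full precision is available from
    :func:`region_class_stats`).
    """
    parts = {}
    for g in genomes:
        t = region_class_stats(g, class_spec)
        parts[g.organism_label] = t[["at_content", "at_skew", "gc_skew"]]
    wide = pd.concat(parts, axis=1)  # (organism, stat)
    wide = wide.swaplevel(axis=1).sort_index(
        axis=1, level=0, sort_remaining=False)
    order = ["at_content", "at_skew", "gc_skew"]
    wide = wide.reindex(columns=order, level=0)
    return wide.round(decimals)
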