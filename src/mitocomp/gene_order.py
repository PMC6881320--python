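"""Circular mitochondrial gene orders as signed permutations.

A gene order is the sequence of (gene, strand) elements around the circle.
Two orders describe the same arrangement when one is a rotation — or a
whole-molecule flip (reversal with all strands inverted) — of the other,
since which strand is called (+) and where the record starts are arbitrary.
Comparison is therefore done on a canonical form anchored at a reference
gene (``cox1`` by convention) in (+) orientation.

The breakpoint distance counts gene adjacencies present in one order but
absent in the other; 0 iff the orders are equivalent.  Adjacencies are
signed (strand-aware) by default, matching the biological reading that an
inverted neighbor is a rearrangement even when the neighbor list is intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

Element = tuple[str, str]  # (gene name, '+' | '-')


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class GeneOrder:
    """An ordered circle of signed genes."""

    elements: tuple[Element, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        names = [g for g, _ in self.elements]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GeneOrderError(f"duplicate gene names: {dupes}")
        for g, s in self.elements:
            if s not in ("+", "-"):
                raise GeneOrderError(f"{g}: strand must be '+' or '-'")

    @classmethod
    def from_string(cls, text: str, circular: bool = True) -> "GeneOrder":
        """Parse the one-line format: comma-separated tokens, ``-`` prefix
        for minor-strand genes (``cox1,-trnM,rrnS``)."""
        elements = []
        for tok in text.strip().split(","):
            tok = tok.strip()
            if not tok:
                continue
            if tok.startswith("-"):
                elements.append((tok[1:], "-"))
            else:
                elements.append((tok.lstrip("+"), "+"))
        return cls(tuple(elements), circular)

    @classmethod
    def from_annotation(cls, g) -> "GeneOrder":
        """Gene order of a :class:`~mitocomp.annotation.GenomeAnnotation`."""
        return cls(tuple((f.name, f.strand) for f in g.features))

    def to_string(self) -> str:
        return ",".join(("-" if s == "-" else "") + g for g, s in self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.elements)

    def rotate(self, k: int) -> "GeneOrder":
        k %= len(self.elements)
        return GeneOrder(self.elements[k:] + self.elements[:k], self.circular)

    def flip(self) -> "GeneOrder":
        """Reverse reading direction and invert every strand (the same
        molecule described from the other strand)."""
        flipped = tuple((g, "+" if s == "-" else "-")
                        for g, s in reversed(self.elements))
        return GeneOrder(flipped, self.circular)


def canonicalize(order: GeneOrder, reference: str = "cox1") -> GeneOrder:
    """Rotate (and flip if needed) so ``reference`` comes first on (+).

    Deterministic: equivalent orders map to the identical element tuple.
    """
    for i, (g, s) in enumerate(order.elements):
        if g == reference:
            rotated = order.rotate(i)
            if s == "-":
                rotated = rotated.flip().rotate(len(order) - 1)
                # after flip the reference sits last; rotate it to front
            return rotated
    raise GeneOrderError(f"reference gene {reference!r} absent")


def orders_equivalent(a: GeneOrder, b: GeneOrder,
                      reference: Optional[str] = None,
                      name_map: Optional[Mapping[str, str]] = None) -> bool:
    """Whether two circular orders are the same arrangement.

    ``name_map`` renames genes of ``b`` before comparison (isotype naming
    differences between annotation sources).  Unequal gene sets raise with
    the symmetric difference listed.
    """
    b = _apply_name_map(b, name_map)
    _check_same_genes(a, b)
    ref = reference or a.elements[0][0]
    return canonicalize(a, ref).elements == canonicalize(b, ref).elements


def _apply_name_map(o: GeneOrder, name_map: Optional[Mapping[str, str]]) -> GeneOrder:
    if not name_map:
        return o
    return GeneOrder(tuple((name_map.get(g, g), s) for g, s in o.elements),
                     o.circular)


def _check_same_genes(a: GeneOrder, b: GeneOrder) -> None:
    if a.genes() != b.genes():
        diff = sorted(a.genes() ^ b.genes())
        raise GeneOrderError(f"gene sets differ; symmetric difference {diff}")


def signed_adjacencies(o: GeneOrder, signed: bool = True) -> set:
    """The set of neighbor pairs around the circle.

    A signed adjacency between consecutive elements x→y equals the
    adjacency seen from the other strand, −y→−x; each pair is stored under
    a canonical representative so orientation of reading does not matter.
    Unsigned mode keeps only the name pair.
    """
    elems = o.elements
    n = len(elems)
    adj = set()
    rng = range(n) if o.circular else range(n - 1)
    for i in rng:
        g1, s1 = elems[i]
        g2, s2 = elems[(i + 1) % n]
        if not signed:
            adj.add(frozenset((g1, g2)) if g1 != g2 else (g1, g2))
            continue
        fwd = ((g1, s1), (g2, s2))
        rev = ((g2, _inv(s2)), (g1, _inv(s1)))
        adj.add(min(fwd, rev))
    return adj


def _inv(s: str) -> str:
    return "+" if s == "-" else "-"


def breakpoint_distance(a: GeneOrder, b: GeneOrder,
                        signed: bool = True,
                        name_map: Optional[Mapping[str, str]] = None) -> int:
    """Number of adjacencies of ``a`` absent from ``b``.

    Symmetric on circles with equal gene sets (both orders then carry the
    same number of adjacencies).  0 iff the orders are equivalent up to
    rotation and whole-molecule flip.
    """
    b = _apply_name_map(b, name_map)
    _check_same_genes(a, b)
    return len(signed_adjacencies(a, signed) - signed_adjacencies(b, signed))
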