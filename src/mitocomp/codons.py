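"""Codon extraction, start/stop tabulation, RSCU and codon-class bias.

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp, stops TAA/TAG).
Synonymous families are derived from the table, so switching code changes
every downstream statistic consistently.

RSCU (relative synonymous codon usage) of a codon is its observed count
divided by the mean count of its synonymous family; 1 means no bias, and
the values of a family always sum to the family size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .annotation import GenomeAnnotation, GeneFeature

INVERTEBRATE_MITO = 5

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


class CodonError(ValueError):
    pass


def genetic_code(table_id: int = INVERTEBRATE_MITO) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def synonymous_families(table_id: int = INVERTEBRATE_MITO) -> dict[str, tuple[str, ...]]:
    """Partition of the sense codons into synonymous families, keyed by
    one-letter amino acid."""
    tab = genetic_code(table_id)
    fams: dict[str, list[str]] = {}
    for codon, aa in tab.forward_table.items():
        if set(codon) <= set("ACGT"):
            fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    """Codon counts with RSCU values under a given genetic code."""

    counts: dict[str, int]
    table_id: int = INVERTEBRATE_MITO
    rscu: dict[str, Optional[float]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_frame(self) -> pd.DataFrame:
        fams = synonymous_families(self.table_id)
        rows = []
        for aa, codons in fams.items():
            for c in codons:
                rows.append({"codon": to_rna(c), "aa": aa,
                             "count": self.counts.get(c, 0),
                             "rscu": self.rscu.get(c)})
        return pd.DataFrame(rows)


def extract_codons(g: GenomeAnnotation,
                   table_id: int = INVERTEBRATE_MITO) -> dict[str, list[str]]:
    """Codon list per protein gene, in reading order.

    Minus-strand genes are reverse-complemented first, so the first codon is
    the initiation codon and the last the terminator.  Genes whose span is
    not divisible by 3 are skipped.  Internal stop codons are tolerated (the
    annotation, not this scan, is then suspect) and can be found with
    :func:`internal_stops`.
    """
    out: dict[str, list[str]] = {}
    for f in g.pcgs:
        if f.length % 3:
            continue
        seq = g.feature_sequence(f)
        out[f.name] = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    return out


def internal_stops(codons: Mapping[str, Sequence[str]],
                   table_id: int = INVERTEBRATE_MITO) -> dict[str, list[int]]:
    """Positions (codon index) of stop codons before the terminator."""
    stops = set(genetic_code(table_id).stop_codons)
    return {
        gene: [i for i, c in enumerate(cs[:-1]) if c in stops]
        for gene, cs in codons.items()
        if any(c in stops for c in cs[:-1])
    }


def count_codons(g: GenomeAnnotation,
                 table_id: int = INVERTEBRATE_MITO,
                 per_gene: bool = False):
    """Sense-codon counts pooled over all PCGs (terminators excluded).

    With ``per_gene`` a dict of per-gene Counters is returned instead.
    """
    stops = set(genetic_code(table_id).stop_codons)
    by_gene = {
        gene: Counter(c for c in cs[:-1] if c not in stops)
        for gene, cs in extract_codons(g, table_id).items()
    }
    if per_gene:
        return by_gene
    pooled: Counter = Counter()
    for c in by_gene.values():
        pooled.update(c)
    return dict(pooled)


def rscu(counts: Mapping[str, int],
         table_id: int = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Relative synonymous codon usage from sense-codon counts.

    RSCU(c) = count(c) / mean count of c's synonymous family.  Families with
    zero total get ``None`` (undefined, not zero).  Stop codons in the input
    are rejected.
    """
    fams = synonymous_families(table_id)
    sense = {c for codons in fams.values() for c in codons}
    bad = set(counts) - sense
    if bad:
        raise CodonError(f"non-sense codons in counts: {sorted(bad)}")
    values: dict[str, Optional[float]] = {}
    for aa, codons in fams.items():
        tot = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            values[c] = (counts.get(c, 0) * len(codons) / tot) if tot else None
    return CodonUsageTable(dict(counts), table_id, values)


def classify_at_rich(codon: str) -> str:
    """Classify a codon as ``AT`` or ``GC`` rich by majority of positions.

    With three positions there are no ties: a codon with ≥2 A/T positions is
    A+T-rich, otherwise G+C-rich.  This majority rule is this package's
    definition of codon richness.
    """
    at = sum(1 for b in codon.upper().replace("U", "T") if b in "AT")
    return "AT" if at >= 2 else "GC"


def at_rich_ratio(counts: Mapping[str, int]) -> Optional[float]:
    """Occurrences of A+T-rich codons over occurrences of G+C-rich codons.

    ``None`` when no G+C-rich codon was used (undefined ratio).
    """
    if not counts:
        raise CodonError("empty codon counts")
    at = sum(n for c, n in counts.items() if classify_at_rich(c) == "AT")
    gc = sum(n for c, n in counts.items() if classify_at_rich(c) == "GC")
    return at / gc if gc else None


def start_stop_table(genomes: Sequence[GenomeAnnotation],
                     from_sequence: bool = False) -> tuple[pd.DataFrame, int]:
    """Start/termination codons of every protein gene across genomes.

    Codons come from the annotation by default; ``from_sequence`` re-derives
    them from the genome sequence (first and last codon of each gene).
    Returns the comparison table and the number of genes whose start or stop
    differs between any two genomes.
    """
    if not genomes:
        raise CodonError("no genomes given")
    name_sets = [tuple(f.name for f in g.pcgs) for g in genomes]
    names = set(name_sets[0])
    for g, ns in zip(genomes[1:], name_sets[1:]):
        if set(ns) != names:
            missing = names.symmetric_difference(ns)
            raise CodonError(
                f"PCG sets differ ({g.organism_label}): {sorted(missing)}")
    rows = []
    for name in name_sets[0]:
        row: dict[str, str] = {"gene": name}
        for g in genomes:
            f = g.get(name)
            if from_sequence:
                codons = extract_codons(g).get(name)
                start, stop = (codons[0], codons[-1]) if codons else (None, None)
            else:
                start, stop = f.start_codon, f.stop_codon
            row[f"{g.organism_label}:start"] = start
            row[f"{g.organism_label}:stop"] = stop
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    differing = 0
    for name, row in table.iterrows():
        starts = {row[c] for c in table.columns if c.endswith(":start")}
        stops = {row[c] for c in table.columns if c.endswith(":stop")}
        if len(starts) > 1 or len(stops) > 1:
            differing += 1
    return table, differing


def differing_codon_genes(genomes: Sequence[GenomeAnnotation]) -> list[str]:
    """Names of PCGs whose start or stop codon differs between genomes."""
    table, _ = start_stop_table(genomes)
    out = []
    for name, row in table.iterrows():
        starts = {row[c] for c in table.columns if c.endswith(":start")}
        stops = {row[c] for c in table.columns if c.endswith(":stop")}
        if len(starts) > 1 or len(stops) > 1:
            out.append(name)
    return out
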