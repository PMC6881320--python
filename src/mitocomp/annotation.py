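"""Data model and coordinate arithmetic for annotated circular mitogenomes.

Coordinates are 1-based and inclusive on both ends, matching the convention
of published mitogenome organization tables.  Conversion to 0-based
half-open slices happens only where a sequence is actually cut
(:meth:`GenomeAnnotation.feature_sequence`).

Features may not span the origin; on the circular genomes handled here the
annotation conventionally starts at ``cox1`` position 1, so no gene crosses
the junction.  The junction itself still contributes one intergenic spacer
(between the last and the first feature), which every scan here includes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

GENE_CLASSES = ("PCG", "tRNA", "rRNA")

#: the 13 canonical animal mitochondrial protein-coding genes
CANONICAL_PCGS = frozenset(
    {
        "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
        "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    }
)

EXPECTED_CENSUS = {"PCG": 13, "tRNA": 22, "rRNA": 2}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for structurally malformed annotations."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a mitochondrial genome.

    Parameters
    ----------
    name:
        Gene symbol (``cox1``, ``trnD``, ``rrnL`` ...).  tRNA isotypes that
        occur twice carry a numeric suffix (``trnL1``/``trnL2``).
    gene_class:
        One of ``PCG``, ``tRNA``, ``rRNA``.
    start, end:
        1-based inclusive coordinates, ``start <= end`` (origin-spanning
        features are not modeled).
    strand:
        ``'+'`` or ``'-'``; minus-strand genes are read on the reverse
        complement.
    start_codon, stop_codon:
        Initiation and termination codons for protein-coding genes, as the
        gene-strand 3-mers; ``None`` for RNA genes.
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(
                f"{self.name}: unknown gene class {self.gene_class!r}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.name}: need 1 <= start <= end, got "
                f"[{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        """Feature length in bp (end − start + 1)."""
        return self.end - self.start + 1


def feature_length(f: GeneFeature) -> int:
    """Length of a feature in nucleotides."""
    return f.length


@dataclass
class GenomeAnnotation:
    """A circular mitochondrial genome record: ordered features plus length.

    ``sequence``, when present, is the full (+)-strand nucleotide string of
    exactly ``genome_length`` characters.  Composition and codon analyses
    require it; pure geometry (spacers, lengths, gene order) does not.
    """

    organism_label: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None
    circular: bool = True

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise AnnotationError(
                    f"{self.organism_label}: sequence length "
                    f"{len(self.sequence)} != genome_length {self.genome_length}")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"gene {name!r} not annotated in {self.organism_label}")

    @property
    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == "PCG"]

    def census(self) -> dict[str, int]:
        out = {c: 0 for c in GENE_CLASSES}
        for f in self.features:
            out[f.gene_class] += 1
        return out

    def feature_sequence(self, f: GeneFeature | str, gene_strand: bool = True) -> str:
        """Nucleotide sequence of a feature.

        With ``gene_strand`` (default) minus-strand features are returned
        reverse-complemented, i.e. in reading orientation; otherwise the raw
        (+)-strand slice is returned.
        """
        if isinstance(f, str):
            f = self.get(f)
        if self.sequence is None:
            raise AnnotationError(
                f"{self.organism_label} carries no sequence")
        sub = self.sequence[f.start - 1:f.end]
        if gene_strand and f.strand == "-":
            sub = reverse_complement(sub)
        return sub

    def rotated(self, shift: int) -> "GenomeAnnotation":
        """Rotate all coordinates by ``shift`` (mod genome length).

        Features that would span the origin after rotation are disallowed.
        Used for invariance checks; the sequence, if any, is rotated too.
        """
        n = self.genome_length
        shift %= n
        moved = []
        for f in self.features:
            s = (f.start - 1 + shift) % n + 1
            e = (f.end - 1 + shift) % n + 1
            if e < s:
                raise AnnotationError(
                    f"rotation by {shift} makes {f.name} span the origin")
            moved.append(replace(f, start=s, end=e))
        seq = None
        if self.sequence is not None:
            seq = self.sequence[n - shift:] + self.sequence[:n - shift]
        return GenomeAnnotation(self.organism_label, n, moved, seq, self.circular)


@dataclass
class SpacerReport:
    """Signed intergenic spacings for every adjacent pair on the circle."""

    pairs: list[tuple[str, str, int]]
    overlap_count: int
    noncoding_count: int
    largest_gap: Optional[tuple[tuple[str, str], int]]
    size_range: Optional[tuple[int, int]]

    @property
    def total_intergenic(self) -> int:
        """Sum of positive spacings (total non-coding nucleotides)."""
        return sum(s for _, _, s in self.pairs if s > 0)


def spacing(upstream: GeneFeature, downstream: GeneFeature,
            genome_length: int, circular_junction: bool = False) -> int:
    """Signed intergenic spacing between two consecutive features.

    Positive values are non-coding nucleotides between the genes; negative
    values are overlapping nucleotides.  With ``circular_junction`` the
    spacer runs across the origin, from the last feature to the first.
    """
    if circular_junction:
        gap = (genome_length - upstream.end) + (downstream.start - 1)
    else:
        gap = downstream.start - upstream.end - 1
    if gap < 0 and -gap > min(upstream.length, downstream.length):
        raise AnnotationError(
            f"overlap of {-gap} bp between {upstream.name} and "
            f"{downstream.name} exceeds a feature length")
    return gap


def scan_spacers(g: GenomeAnnotation) -> SpacerReport:
    """Scan all adjacent pairs (circular junction included) for spacers.

    Returns one signed spacing per pair; the number of pairs equals the
    number of features, so Σ feature lengths + Σ spacings = genome length.
    """
    feats = g.features
    if not feats:
        raise AnnotationError("empty annotation")
    pairs: list[tuple[str, str, int]] = []
    for up, down in zip(feats, feats[1:]):
        pairs.append((up.name, down.name, spacing(up, down, g.genome_length)))
    pairs.append((feats[-1].name, feats[0].name,
                  spacing(feats[-1], feats[0], g.genome_length,
                          circular_junction=True)))
    positive = [((u, d), s) for u, d, s in pairs if s > 0]
    largest = max(positive, key=lambda x: x[1]) if positive else None
    size_range = ((min(s for _, s in positive), max(s for _, s in positive))
                  if positive else None)
    return SpacerReport(
        pairs=pairs,
        overlap_count=sum(1 for _, _, s in pairs if s < 0),
        noncoding_count=len(positive),
        largest_gap=largest,
        size_range=size_range,
    )


def protein_lengths(g: GenomeAnnotation) -> tuple[dict[str, int], int, list[str]]:
    """Amino acids encoded per protein gene, terminator excluded.

    Each PCG of span ``L`` (divisible by 3) encodes ``L/3 − 1`` amino acids;
    the subtracted codon is the terminator.  Genes whose span is not
    divisible by 3 are flagged and left out of the total.

    Returns ``(per_gene, total, flagged)``.
    """
    per_gene: dict[str, int] = {}
    flagged: list[str] = []
    total = 0
    for f in g.pcgs:
        if f.length % 3:
            flagged.append(f.name)
            continue
        aa = f.length // 3 - 1
        per_gene[f.name] = aa
        total += aa
    return per_gene, total, flagged


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding."""

    code: str
    severity: str  # "error" | "warning"
    message: str
    gene: Optional[str] = None


def validate_annotation(g: GenomeAnnotation) -> list[Finding]:
    """Structural validation; returns findings instead of raising.

    Checks coordinate ranges, sort order, name uniqueness, PCG codon
    presence and frame divisibility, pathological overlaps, and the
    13 PCG / 22 tRNA / 2 rRNA census expected of these genomes.
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    prev_start = 0
    for f in g.features:
        if f.end > g.genome_length:
            findings.append(Finding(
                "coord-out-of-range", "error",
                f"{f.name} ends at {f.end} > genome length {g.genome_length}",
                f.name))
        if f.start < prev_start:
            findings.append(Finding(
                "unsorted", "error", f"{f.name} out of order", f.name))
        prev_start = f.start
        if f.name in seen:
            findings.append(Finding(
                "duplicate-name", "error", f"{f.name} occurs twice", f.name))
        seen.add(f.name)
        if f.gene_class == "PCG":
            if f.length % 3:
                findings.append(Finding(
                    "frame", "error",
                    f"{f.name} span {f.length} not divisible by 3", f.name))
            if f.start_codon is None or f.stop_codon is None:
                findings.append(Finding(
                    "missing-codons", "warning",
                    f"{f.name} lacks start/stop codon annotation", f.name))
        elif f.start_codon is not None or f.stop_codon is not None:
            findings.append(Finding(
                "codons-on-rna", "warning",
                f"{f.name} is {f.gene_class} but carries codons", f.name))
    # overlaps longer than either partner indicate a malformed table
    feats = g.features
    for i, up in enumerate(feats):
        down = feats[(i + 1) % len(feats)]
        try:
            spacing(up, down, g.genome_length, circular_junction=(i == len(feats) - 1))
        except AnnotationError as exc:
            findings.append(Finding("bad-overlap", "error", str(exc), up.name))
    census = g.census()
    for cls, expected in EXPECTED_CENSUS.items():
        if census[cls] != expected:
            findings.append(Finding(
                "census", "warning",
                f"{census[cls]} {cls} features (expected {expected})"))
    return findings
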