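"""Bundled example annotations: two Strombidae mitogenome organization
tables (geometry only — the deposited nucleotide sequences are not
redistributed here, so these records carry no sequence)."""

from __future__ import annotations

from importlib import resources

from .annotation import GenomeAnnotation
from .io import read_annotation_tsv


def _load(fname: str, label: str, length: int) -> GenomeAnnotation:
    with resources.as_file(resources.files("mitocomp") / "data" / fname) as p:
        return read_annotation_tsv(p, organism_label=label, genome_length=length)


def harpago_chiragra() -> GenomeAnnotation:
    """Organization of the Harpago chiragra mitogenome (15,460 bp)."""
    return _load("harpago_chiragra.tsv", "Harpago chiragra", 15460)


def lambis_lambis() -> GenomeAnnotation:
    """Organization of the Lambis lambis mitogenome (15,481 bp)."""
    return _load("lambis_lambis.tsv", "Lambis lambis", 15481)
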