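"""Readers and writers: annotation TSV, GenBank flat files, FASTA.

The annotation TSV is one row per feature with columns
``gene  class  start  end  strand  start_codon  stop_codon`` (codon columns
empty for RNA genes) and a leading comment line carrying the record
metadata, so a genome round-trips losslessly::

    # organism=Harpago chiragra	genome_length=15460	circular=true

GenBank support maps CDS/tRNA/rRNA features onto the same model and
normalizes gene names to the lowercase community symbols (``cox1``,
``nad4l``, ``trnL1`` ...).
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationError, GeneFeature, GenomeAnnotation

_HEADER = ["gene", "class", "start", "end", "strand", "start_codon", "stop_codon"]

# --- gene-symbol normalization ---------------------------------------------

_PCG_ALIASES = {
    "cox1": ["cox1", "coxi", "co1", "coi", "cox-1"],
    "cox2": ["cox2", "coxii", "co2", "coii", "cox-2"],
    "cox3": ["cox3", "coxiii", "co3", "coiii", "cox-3"],
    "cytb": ["cytb", "cob", "cytochromeb", "cyt-b"],
    "atp6": ["atp6", "atpase6", "atp-6"],
    "atp8": ["atp8", "atpase8", "atp-8"],
    "nad1": ["nad1", "nd1", "nadh1"],
    "nad2": ["nad2", "nd2", "nadh2"],
    "nad3": ["nad3", "nd3", "nadh3"],
    "nad4": ["nad4", "nd4", "nadh4"],
    "nad4l": ["nad4l", "nd4l", "nadh4l"],
    "nad5": ["nad5", "nd5", "nadh5"],
    "nad6": ["nad6", "nd6", "nadh6"],
}
_RRNA_ALIASES = {
    "rrnS": ["rrns", "12s", "12srrna", "srrna", "s-rrna", "rns", "small"],
    "rrnL": ["rrnl", "16s", "16srrna", "lrrna", "l-rrna", "rnl", "large"],
}
_ALIAS_LOOKUP = {alias: sym
                 for sym, aliases in {**_PCG_ALIASES, **_RRNA_ALIASES}.items()
                 for alias in aliases}

# duplicated tRNA isotypes are disambiguated by anticodon, following the
# usual metazoan convention (Leu: tag/CUN = L1, taa/UUR = L2; Ser: gct/AGN
# = S1, tga/UCN = S2) with the anticodon spellings used in gastropod tables
_TRNA_ISOTYPE_BY_ANTICODON = {
    ("L", "tag"): "trnL1", ("L", "cta"): "trnL1",
    ("L", "taa"): "trnL2", ("L", "tta"): "trnL2",
    ("S", "gct"): "trnS1", ("S", "agc"): "trnS1",
    ("S", "tga"): "trnS2", ("S", "tca"): "trnS2",
}


def _squash(name: str) -> str:
    return re.sub(r"[\s_().]", "", name.lower())


def normalize_gene_name(raw: str, product: Optional[str] = None,
                        anticodon: Optional[str] = None) -> str:
    """Map a raw GenBank gene/product label to the community symbol.

    ``'ND4L'`` → ``nad4l``, ``'tRNA-Asp'`` → ``trnD``, 16S rRNA → ``rrnL``.
    Duplicate tRNA isotypes need an anticodon (or pre-suffixed name) to get
    their 1/2 suffix.  Unrecognized labels are returned squashed-lowercase.
    """
    for cand in filter(None, (raw, product)):
        s = _squash(cand)
        if s in _ALIAS_LOOKUP:
            return _ALIAS_LOOKUP[s]
        if re.search(r"16s|lrrna|largesubunit", s):
            return "rrnL"
        if re.search(r"12s|srrna|smallsubunit", s):
            return "rrnS"
        m = re.fullmatch(r"trn([a-z])([12]?)", s)
        if m:
            return f"trn{m.group(1).upper()}{m.group(2)}"
        m = re.search(r"trna-?([a-z]{3})", s)
        if m and m.group(1).capitalize() in protein_letters_3to1:
            one = protein_letters_3to1[m.group(1).capitalize()]
            if anticodon:
                key = (one, anticodon.lower())
                if key in _TRNA_ISOTYPE_BY_ANTICODON:
                    return _TRNA_ISOTYPE_BY_ANTICODON[key]
            return f"trn{one}"
    return _squash(raw)


# --- annotation TSV ---------------------------------------------------------


def read_annotation_tsv(path, organism_label: Optional[str] = None,
                        genome_length: Optional[int] = None,
                        sequence: Optional[str] = None) -> GenomeAnnotation:
    """Read an annotation table; metadata comes from the ``#`` header line
    unless overridden by arguments."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            for part in first[1:].strip().split("\t"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k.strip()] = v.strip()
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if header[:5] != _HEADER[:5]:
            raise AnnotationError(
                f"{path}: expected columns {_HEADER}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            vals += [""] * (len(_HEADER) - len(vals))
            rows.append(dict(zip(_HEADER, vals)))
    feats = [
        GeneFeature(
            name=r["gene"], gene_class=r["class"],
            start=int(r["start"]), end=int(r["end"]), strand=r["strand"],
            start_codon=r["start_codon"] or None,
            stop_codon=r["stop_codon"] or None)
        for r in rows
    ]
    label = organism_label or meta.get("organism") or path.stem
    length = genome_length or (int(meta["genome_length"])
                               if "genome_length" in meta else None)
    if length is None:
        length = max(f.end for f in feats)
    circular = meta.get("circular", "true").lower() != "false"
    return GenomeAnnotation(label, length, feats, sequence, circular)


def write_annotation_tsv(g: GenomeAnnotation, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# organism={g.organism_label}\tgenome_length={g.genome_length}"
                 f"\tcircular={'true' if g.circular else 'false'}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HEADER)
        for f in g.features:
            w.writerow([f.name, f.gene_class, f.start, f.end, f.strand,
                        f.start_codon or "", f.stop_codon or ""])


# --- GenBank ----------------------------------------------------------------

_CLASS_BY_FEATURE_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
_FEATURE_TYPE_BY_CLASS = {v: k for k, v in _CLASS_BY_FEATURE_TYPE.items()}


def read_genbank_record(path) -> GenomeAnnotation:
    """Read one GenBank flat file into a :class:`GenomeAnnotation`.

    CDS, tRNA and rRNA features are kept; names are normalized.  A missing
    ORIGIN sequence is an error, as is a truncated file (no partial object
    is returned).
    """
    import warnings

    from Bio import BiopythonParserWarning

    try:
        with warnings.catch_warnings():
            # a truncated file must fail loudly, not yield a partial object
            warnings.simplefilter("error", BiopythonParserWarning)
            record = SeqIO.read(str(path), "genbank")
    except BiopythonParserWarning as exc:
        raise AnnotationError(f"{path}: malformed GenBank record: {exc}") from exc
    seq = str(record.seq)
    if not seq or set(seq) == {"N"}:
        raise AnnotationError(f"{path}: record carries no ORIGIN sequence")
    feats = []
    for sf in record.features:
        cls = _CLASS_BY_FEATURE_TYPE.get(sf.type)
        if cls is None:
            continue
        raw = (sf.qualifiers.get("gene") or [None])[0]
        product = (sf.qualifiers.get("product") or [None])[0]
        anticodon = None
        note = (sf.qualifiers.get("anticodon") or sf.qualifiers.get("note") or [None])[0]
        if note:
            m = re.search(r"seq:\s*([acgtu]{3})", note.lower())
            anticodon = m.group(1).replace("u", "t") if m else None
        name = normalize_gene_name(raw or product or sf.type, product, anticodon)
        start = int(sf.location.start) + 1
        end = int(sf.location.end)
        strand = "-" if sf.location.strand == -1 else "+"
        start_codon = stop_codon = None
        if cls == "PCG":
            sub = seq[start - 1:end]
            if strand == "-":
                sub = str(Seq(sub).reverse_complement())
            start_codon, stop_codon = sub[:3], sub[-3:]
        feats.append(GeneFeature(name, cls, start, end, strand,
                                 start_codon, stop_codon))
    label = record.annotations.get("organism") or record.id
    return GenomeAnnotation(label, len(seq), feats, seq)


def write_genbank(g: GenomeAnnotation, path) -> None:
    """Write a genome (sequence required) as a GenBank flat file."""
    if g.sequence is None:
        raise AnnotationError("cannot write GenBank without a sequence")
    record = SeqRecord(
        Seq(g.sequence),
        id=re.sub(r"\W+", "_", g.organism_label)[:16] or "genome",
        name=re.sub(r"\W+", "_", g.organism_label)[:16] or "genome",
        description=f"{g.organism_label} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if g.circular else "linear",
            "organism": g.organism_label,
        },
    )
    for f in g.features:
        loc = FeatureLocation(f.start - 1, f.end,
                              strand=-1 if f.strand == "-" else 1)
        record.features.append(
            SeqFeature(loc, type=_FEATURE_TYPE_BY_CLASS[f.gene_class],
                       qualifiers={"gene": [f.name]}))
    SeqIO.write([record], str(path), "genbank")


# --- FASTA ------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Aligned or unaligned FASTA as ``{name: sequence}`` (order kept)."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")
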