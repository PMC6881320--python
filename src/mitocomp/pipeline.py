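"""End-to-end report generation over one or more annotated genomes.

The pipeline runs every analysis the inputs support and collects the
results into a :class:`ReportBundle` of DataFrames, each serializable to a
TSV with a stable column order.  Genomes without sequence still get the
geometry, codon-column and gene-order reports; composition, RSCU and
divergence need sequences (divergence additionally needs the genomes to be
an aligned pair, which holds for simulated pairs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import codons as _codons
from .annotation import GenomeAnnotation, protein_lengths, scan_spacers, validate_annotation
from .composition import composition_table
from .distance import distance_matrix
from .gene_order import GeneOrder, breakpoint_distance, orders_equivalent


@dataclass
class ReportBundle:
    """All tables the pipeline produced, keyed the way they are written."""

    organization: dict[str, pd.DataFrame] = field(default_factory=dict)
    composition: Optional[pd.DataFrame] = None
    rscu: Optional[pd.DataFrame] = None
    codon_comparison: Optional[pd.DataFrame] = None
    differing_codon_genes: Optional[list[str]] = None
    distances: Optional[pd.DataFrame] = None
    gene_order: Optional[pd.DataFrame] = None
    summary: dict = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    def write(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []

        def emit(df: pd.DataFrame, name: str) -> None:
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", float_format="%.4f")
            written.append(p)

        for label, df in self.organization.items():
            emit(df, f"organization_{_slug(label)}")
        if self.composition is not None:
            emit(self.composition, "composition")
        if self.rscu is not None:
            emit(self.rscu, "rscu")
        if self.codon_comparison is not None:
            emit(self.codon_comparison, "start_stop_codons")
        if self.distances is not None:
            emit(self.distances, "distance_k2p")
        if self.gene_order is not None:
            emit(self.gene_order, "gene_order")
        p = out_dir / "summary.json"
        p.write_text(json.dumps(self.summary, indent=2, sort_keys=True) + "\n")
        written.append(p)
        return written


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label.lower()).strip("_")


def organization_table(g: GenomeAnnotation) -> pd.DataFrame:
    """Per-gene organization table: coordinates, sizes, signed upstream
    spacers (the intergenic-nucleotides column), codons."""
    rep = scan_spacers(g)
    upstream_gap = {down: s for _, down, s in rep.pairs}
    per_aa, _, _ = protein_lengths(g)
    rows = []
    for f in g.features:
        rows.append({
            "gene": f.name, "class": f.gene_class,
            "from": f.start, "to": f.end, "strand": f.strand,
            "size_nt": f.length,
            "size_aa": per_aa.get(f.name, ""),
            "intergenic": upstream_gap[f.name],
            "start_codon": f.start_codon or "",
            "stop_codon": f.stop_codon or "",
        })
    return pd.DataFrame(rows).set_index("gene")


def run_pipeline(genomes: Sequence[GenomeAnnotation],
                 reference_gene: str = "cox1",
                 table_id: int = _codons.INVERTEBRATE_MITO) -> ReportBundle:
    """Run all applicable analyses over ``genomes``; see module docstring."""
    if not genomes:
        raise ValueError("need at least one genome")
    bundle = ReportBundle()
    with_seq = [g for g in genomes if g.sequence is not None]

    summary: dict = {"genomes": {}}
    for g in genomes:
        findings = validate_annotation(g)
        errors = [f for f in findings if f.severity == "error"]
        if errors:
            raise ValueError(
                f"{g.organism_label}: annotation errors: "
                + "; ".join(f.message for f in errors))
        rep = scan_spacers(g)
        per_aa, total_aa, flagged = protein_lengths(g)
        bundle.organization[g.organism_label] = organization_table(g)
        summary["genomes"][g.organism_label] = {
            "genome_length": g.genome_length,
            "census": g.census(),
            "overlap_count": rep.overlap_count,
            "noncoding_count": rep.noncoding_count,
            "largest_gap": list(rep.largest_gap) if rep.largest_gap else None,
            "noncoding_size_range": rep.size_range,
            "total_intergenic": rep.total_intergenic,
            "total_aa": total_aa,
            "frame_flagged": flagged,
            "warnings": [f.message for f in findings],
        }

    if len(genomes) >= 2:
        try:
            table, n_diff = _codons.start_stop_table(list(genomes))
            bundle.codon_comparison = table
            bundle.differing_codon_genes = _codons.differing_codon_genes(list(genomes))
            summary["differing_codon_gene_count"] = n_diff
            summary["differing_codon_genes"] = bundle.differing_codon_genes
        except _codons.CodonError as exc:
            bundle.notices.append(f"codon comparison skipped: {exc}")

        ref = genomes[0]
        rows = []
        for g in genomes[1:]:
            a = GeneOrder.from_annotation(ref)
            b = GeneOrder.from_annotation(g)
            rows.append({
                "genome_a": ref.organism_label, "genome_b": g.organism_label,
                "equivalent": orders_equivalent(a, b, reference=reference_gene),
                "breakpoints": breakpoint_distance(a, b),
            })
        bundle.gene_order = pd.DataFrame(rows)

    if with_seq:
        bundle.composition = composition_table(with_seq)
        frames = []
        ratios = {}
        for g in with_seq:
            counts = _codons.count_codons(g, table_id)
            t = _codons.rscu(counts, table_id).as_frame()
            t = t.rename(columns={"count": f"count:{g.organism_label}",
                                  "rscu": f"rscu:{g.organism_label}"})
            frames.append(t.set_index(["codon", "aa"]))
            r = _codons.at_rich_ratio(counts)
            ratios[g.organism_label] = r if r is not None else math.nan
        bundle.rscu = pd.concat(frames, axis=1).reset_index().set_index("codon")
        # majority-rule codon richness (>=2 of 3 positions A/T), this
        # package's working definition
        summary["at_rich_codon_ratio"] = ratios
    else:
        bundle.notices.append("composition/RSCU skipped: no genome carries sequence")

    if len(with_seq) >= 2:
        lengths = {len(g.sequence) for g in with_seq}
        if len(lengths) == 1:
            pooled = {}
            for g in with_seq:
                blocks = _codons.extract_codons(g, table_id)
                pooled[g.organism_label] = "".join(
                    "".join(cs) for _, cs in sorted(blocks.items()))
            plens = {len(s) for s in pooled.values()}
            if len(plens) == 1:
                bundle.distances = distance_matrix(pooled, mode="k2p")
                summary["k2p_concatenated_pcgs"] = {
                    f"{a}|{b}": (None if math.isnan(bundle.distances.loc[a, b])
                                 else round(float(bundle.distances.loc[a, b]), 6))
                    for i, a in enumerate(bundle.distances.index)
                    for b in bundle.distances.columns[i + 1:]
                }
            else:
                bundle.notices.append(
                    "divergence skipped: concatenated PCG lengths differ "
                    "(inputs are not aligned)")
        else:
            bundle.notices.append(
                "divergence skipped: genome lengths differ (inputs are not aligned)")

    summary["notices"] = bundle.notices
    bundle.summary = summary
    return bundle
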