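"""Strand-aware conversion classification and coding-consequence annotation.

Re-implements the variant-effect-predictor role for compact organelle
genomes: locate a site relative to stranded gene models, compute its codon
position along the coding strand (honoring CDS phase and part joins),
translate reference and edited codons under the standard genetic code (plant
mitochondria and plastids use the standard table), and classify the
amino-acid change by physicochemical class.

Conversions are reported twice: *observed* on the forward reference strand
(e.g. G>A) and *biological* after complementing onto the hosting gene's
coding strand (a G>A over a minus-strand gene is a biological C-to-U).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import GeneModel, Genome, cds_parts_by_gene
from .pileup_detect import CandidateSite, editing_efficiency

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "GAVLIMFW"},
    **{aa: "neutral" for aa in "PSTCYNQ"},
    **{aa: "hydrophilic" for aa in "DEKRH"},
}


def load_aa_classes(path: str | Path | None = None) -> dict[str, str]:
    """Residue -> class map from YAML; defaults to the packaged table.

    Every one of the 20 standard residues must be classified exactly once.
    """
    if path is None:
        source = resources.files("oredit.data").joinpath("aa_classes.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    table: dict[str, str] = {}
    for cls, residues in raw.items():
        for aa in residues:
            if aa in table:
                raise ValueError(f"residue {aa} classified twice")
            table[aa] = cls
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(table)
    if missing:
        raise ValueError(f"unclassified residues: {sorted(missing)}")
    return table


@dataclass(frozen=True)
class EditingSite:
    """A fully annotated editing site for one sample."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    sample: str
    observed_conversion: str
    biological_conversion: str
    gene_id: str | None
    region_class: str
    codon_position: int | None
    consequence: str
    aa_from: str | None
    aa_to: str | None
    aa_trend: str | None
    edited_reads: int
    total_reads: int
    efficiency: float | None


def classify_conversion(
    ref: str, alt: str, gene_strand: str | None
) -> tuple[str, str]:
    """(observed forward-strand conversion, strand-corrected biological type).

    The biological type is the conversion read on the hosting gene's coding
    strand; sites without a stranded gene context are read on the forward
    strand.
    """
    if ref == alt or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"invalid conversion {ref!r}>{alt!r}")
    observed = f"{ref}>{alt}"
    if gene_strand == "-":
        cref, calt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    else:
        cref, calt = ref, alt
    if (cref, calt) == ("C", "T"):
        biological = "C-to-U"
    elif (cref, calt) == ("A", "G"):
        biological = "A-to-I"
    else:
        biological = "other"
    return observed, biological


def locate(
    position: int,
    gene_models: Sequence[GeneModel],
    window: int = 5000,
) -> tuple[str | None, str]:
    """Assign a site to a gene and region class.

    Inside a CDS part -> (gene, CDS).  Within ``window`` bp 5' of a gene on
    its own strand -> upstream; within ``window`` 3' -> downstream; inside a
    gene body but outside its CDS -> intron.  Otherwise intergenic.  When
    several genes qualify the nearest wins; ties go to the smaller start
    coordinate.
    """
    cds_parts = cds_parts_by_gene(gene_models)
    genes = [g for g in gene_models if g.feature_kind == "gene"]
    if not genes:  # annotation with bare CDS rows: use their joined spans
        genes = [
            GeneModel(
                gene_id=gid, contig=parts[0].contig,
                start=min(p.start for p in parts),
                end=max(p.end for p in parts),
                strand=parts[0].strand, feature_kind="gene",
            )
            for gid, parts in cds_parts.items()
        ]

    candidates: list[tuple[int, int, str, str]] = []  # (distance, start, id, class)
    for gene in genes:
        parts = cds_parts.get(gene.gene_id, [])
        if any(p.overlaps(position) for p in parts):
            return gene.gene_id, "CDS"
        if gene.overlaps(position):
            candidates.append((0, gene.start, gene.gene_id, "intron"))
            continue
        if position < gene.start:
            dist = gene.start - position
            side = "upstream" if gene.strand == "+" else "downstream"
        else:
            dist = position - gene.end
            side = "downstream" if gene.strand == "+" else "upstream"
        if dist <= window:
            candidates.append((dist, gene.start, gene.gene_id, side))
    if not candidates:
        return None, "intergenic"
    dist, _start, gene_id, side = min(candidates)
    return gene_id, side


def _coding_positions(cds_parts: Sequence[GeneModel], strand: str) -> list[int]:
    """Genomic positions of the joined CDS in coding (5'->3') order."""
    parts = sorted(cds_parts, key=lambda p: p.start, reverse=(strand == "-"))
    positions: list[int] = []
    for p in parts:
        span = range(p.start, p.end + 1)
        positions.extend(reversed(span) if strand == "-" else span)
    return positions


def _first_phase(cds_parts: Sequence[GeneModel], strand: str) -> int:
    parts = sorted(cds_parts, key=lambda p: p.start, reverse=(strand == "-"))
    return parts[0].phase


def codon_position(
    position: int, cds_parts: Sequence[GeneModel], strand: str
) -> int:
    """1/2/3 offset of a genomic site within its codon, read on the coding
    strand and honoring the phase of the first CDS part."""
    coding = _coding_positions(cds_parts, strand)
    try:
        idx = coding.index(position)
    except ValueError:
        raise ValueError(f"position {position} is not inside the joined CDS")
    return (idx - _first_phase(cds_parts, strand)) % 3 + 1


def consequence(
    position: int,
    alt: str,
    genome: Genome,
    cds_parts: Sequence[GeneModel],
    strand: str,
    code: str | int = 1,
) -> tuple[str, str | None, str | None]:
    """Coding consequence of substituting ``alt`` (forward strand) at a CDS
    position: translate the reference and edited codons and classify.

    start_lost is emitted only when the initiator codon loses its Met;
    stop_gained when the edited codon becomes a stop.  Sites in an
    incomplete leading/trailing codon are reported without amino acids.
    """
    ref = genome.base(position)
    if alt == ref:
        raise ValueError("alt equals reference base; not a variant")
    coding = _coding_positions(cds_parts, strand)
    idx = coding.index(position)
    phase = _first_phase(cds_parts, strand)
    codon_idx = (idx - phase) // 3
    start = phase + 3 * codon_idx
    if idx < phase or start + 3 > len(coding):
        return "incomplete_codon_variant", None, None

    def coding_base(genomic_pos: int, substitute: bool) -> str:
        base = alt if substitute and genomic_pos == position else genome.base(
            genomic_pos
        )
        return _COMPLEMENT[base] if strand == "-" else base

    ref_codon = "".join(coding_base(coding[i], False) for i in range(start, start + 3))
    alt_codon = "".join(coding_base(coding[i], True) for i in range(start, start + 3))
    table = CodonTable.unambiguous_dna_by_id[int(code)] if str(code).isdigit() else code
    aa_from = str(Seq(ref_codon).translate(table=table))
    aa_to = str(Seq(alt_codon).translate(table=table))

    if codon_idx == 0 and aa_from == "M" and aa_to != "M":
        label = "start_lost"
    elif aa_to == "*" and aa_from != "*":
        label = "stop_gained"
    elif aa_from == "*" and aa_to != "*":
        label = "stop_lost"
    elif aa_from == aa_to:
        label = "synonymous"
    else:
        label = "missense"
    return label, aa_from, aa_to


def aa_trend(
    aa_from: str, aa_to: str, table: Mapping[str, str] | None = None
) -> str:
    """Physicochemical class transition, e.g. ``neutral->hydrophobic``."""
    table = DEFAULT_AA_CLASSES if table is None else table
    if aa_from not in table or aa_to not in table:
        raise ValueError(f"unclassifiable residues {aa_from!r}->{aa_to!r}")
    return f"{table[aa_from]}->{table[aa_to]}"


_REGION_CONSEQUENCE = {
    "upstream": "upstream_gene_variant",
    "downstream": "downstream_gene_variant",
    "intergenic": "intergenic_variant",
    "intron": "intron_variant",
}


def annotate_site(
    cand: CandidateSite,
    genome: Genome,
    gene_models: Sequence[GeneModel],
    sample: str,
    window: int = 5000,
    aa_table: Mapping[str, str] | None = None,
    code: str | int = 1,
) -> EditingSite:
    """Full annotation of one called site for one sample."""
    gene_id, region = locate(cand.position, gene_models, window)
    cds_by_gene = cds_parts_by_gene(gene_models)
    strand = None
    if gene_id is not None:
        parts = cds_by_gene.get(gene_id)
        strand = (
            parts[0].strand
            if parts
            else next(
                g.strand for g in gene_models
                if g.gene_id == gene_id and g.feature_kind == "gene"
            )
        )
    observed, biological = classify_conversion(cand.ref_base, cand.alt_base, strand)

    cpos: int | None = None
    csq = _REGION_CONSEQUENCE.get(region, "intergenic_variant")
    aa_from = aa_to = trend = None
    if region == "CDS":
        parts = cds_by_gene[gene_id]
        cpos = codon_position(cand.position, parts, strand)
        csq, aa_from, aa_to = consequence(
            cand.position, cand.alt_base, genome, parts, strand, code
        )
        if aa_from and aa_to and aa_from in (aa_table or DEFAULT_AA_CLASSES) and (
            aa_to in (aa_table or DEFAULT_AA_CLASSES)
        ):
            trend = aa_trend(aa_from, aa_to, aa_table)

    return EditingSite(
        contig=cand.contig,
        position=cand.position,
        ref_base=cand.ref_base,
        alt_base=cand.alt_base,
        sample=sample,
        observed_conversion=observed,
        biological_conversion=biological,
        gene_id=gene_id,
        region_class=region,
        codon_position=cpos,
        consequence=csq,
        aa_from=aa_from,
        aa_to=aa_to,
        aa_trend=trend,
        edited_reads=cand.edited_reads,
        total_reads=cand.total_reads,
        efficiency=editing_efficiency(cand),
    )


def annotate_sites(
    sites_by_sample: Mapping[tuple[str, str], Sequence[CandidateSite]],
    genome: Genome,
    gene_models: Sequence[GeneModel],
    window: int = 5000,
    aa_table: Mapping[str, str] | None = None,
    code: str | int = 1,
) -> list[EditingSite]:
    """Annotate every final site of every sample; sample label is
    ``genotype_condition``."""
    out = []
    for (genotype, condition), cands in sorted(sites_by_sample.items()):
        sample = f"{genotype}_{condition}"
        for cand in cands:
            out.append(
                annotate_site(
                    cand, genome, gene_models, sample, window, aa_table, code
                )
            )
    return out
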