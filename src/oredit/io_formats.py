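"""Readers and writers for the standard formats the pipeline touches.

Coordinate contract: every position in this package — in memory and in every
emitted artifact (VCF, TSV, GFF3, BED end coordinates excepted) — is 1-based
inclusive, the convention of GFF3 and VCF. ``Genome.base(pos)`` is the single
accessor for reference bases and enforces it.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file; the message names the offending record."""


@dataclass(frozen=True)
class Genome:
    """A named reference sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome {self.name!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.name!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based inclusive position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"on {self.name}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class GeneModel:
    """A stranded annotation interval (gene, CDS part, or other feature).

    ``start``/``end`` are 1-based inclusive; ``phase`` is the number of bases
    to skip at the 5' end of a CDS part before the first complete codon.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_kind: str = "gene"
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"feature {self.gene_id!r}: bad interval {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"feature {self.gene_id!r}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if self.feature_kind == "CDS" and self.phase not in {0, 1, 2}:
            raise FormatError(f"feature {self.gene_id!r}: bad phase {self.phase}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, position: int) -> bool:
        return self.start <= position <= self.end


def cds_parts_by_gene(models: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    """Group CDS parts by gene, each list in genomic order.

    A joined CDS whose total length is not a multiple of 3 is flagged with a
    warning (truncated or mis-annotated model) but kept.
    """
    parts: dict[str, list[GeneModel]] = {}
    for m in models:
        if m.feature_kind == "CDS":
            parts.setdefault(m.gene_id, []).append(m)
    for gene_id, plist in parts.items():
        plist.sort(key=lambda p: p.start)
        total = sum(len(p) for p in plist)
        if total % 3 != 0:
            logger.warning(
                "joined CDS of %s has length %d, not a multiple of 3",
                gene_id, total,
            )
    return parts


class AlignedRead(NamedTuple):
    """One aligned SAM record (1-based leftmost position)."""

    read_id: str
    contig: str
    position: int
    cigar: str
    sequence: str
    qualities: tuple[int, ...]
    mapping_quality: int
    is_duplicate: bool

    def reference_span(self) -> int:
        """Reference bases consumed by the CIGAR (M/D/N/=/X)."""
        span, num = 0, ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MDN=X":
                    span += int(num)
                num = ""
        return span

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_index_0based, reference_position_1based) for matches."""
        qpos, rpos, num = 0, self.position, ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "M=X":
                for i in range(n):
                    yield qpos + i, rpos + i
                qpos += n
                rpos += n
            elif ch in "IS":
                qpos += n
            elif ch in "DN":
                rpos += n
            # H/P consume nothing we track


def read_fasta(path: str | Path) -> list[Genome]:
    """Read FASTA records; sequences are upper-cased and U is mapped to T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            genomes.append(Genome(name=rec.id, sequence=seq))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genomes


def write_fasta(genomes: Sequence[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def _gff_gene_id(feature: gffutils.Feature) -> str:
    parents = feature.attributes.get("Parent")
    if parents:
        return parents[0]
    ids = feature.attributes.get("ID")
    if ids:
        return ids[0]
    return f"{feature.seqid}:{feature.start}-{feature.end}"


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read GFF3 features into :class:`GeneModel` records.

    gene and CDS rows keep their kind; everything else becomes ``other``.
    CDS rows are linked to their gene via Parent (mRNA intermediates are
    followed one level up when present).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} > end {end}"
                )

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # Map mRNA ID -> gene ID so CDS Parent=mRNA resolves to the gene.
    transcript_parent: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype in {"mRNA", "transcript"}:
            ids = feat.attributes.get("ID")
            parents = feat.attributes.get("Parent")
            if ids and parents:
                transcript_parent[ids[0]] = parents[0]

    models: list[GeneModel] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype == "gene":
            kind = "gene"
        elif feat.featuretype == "CDS":
            kind = "CDS"
        else:
            kind = "other"
        if kind == "CDS" and feat.strand not in {"+", "-"}:
            raise FormatError(
                f"{path}: CDS at {feat.seqid}:{feat.start}-{feat.end} has no "
                "strand; strand is required for coding annotation"
            )
        gene_id = _gff_gene_id(feat)
        gene_id = transcript_parent.get(gene_id, gene_id)
        phase = int(feat.frame) if feat.frame in {"0", "1", "2"} else 0
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else "+",
                feature_kind=kind,
                phase=phase,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/CDS models as GFF3 (CDS rows carry Parent=gene_id)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            if m.feature_kind == "gene":
                attrs = f"ID={m.gene_id}"
                ftype = "gene"
            elif m.feature_kind == "CDS":
                attrs = f"ID=cds-{m.gene_id};Parent={m.gene_id}"
                ftype = "CDS"
            else:
                attrs = f"ID={m.gene_id}"
                ftype = "region"
            phase = str(m.phase) if m.feature_kind == "CDS" else "."
            fh.write(
                "\t".join(
                    [
                        m.contig, "oredit", ftype, str(m.start), str(m.end),
                        ".", m.strand, phase, attrs,
                    ]
                )
                + "\n"
            )


def _cigar_query_length(cigar: str) -> int | None:
    length, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif num:
            if ch in "MIS=X":
                length += int(num)
            num = ""
        else:
            return None
    return length


def _filter_malformed_sam(path: Path) -> tuple[Path, int]:
    """Drop alignment lines whose CIGAR query length disagrees with the
    sequence (htslib aborts on them); returns (clean path, dropped count)."""
    dropped = 0
    clean = None
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("@"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 11 or cols[5] == "*" or cols[9] == "*":
            continue
        qlen = _cigar_query_length(cols[5])
        if qlen is not None and qlen != len(cols[9]):
            dropped += 1
    if dropped == 0:
        return path, 0
    clean = Path(tempfile.mkstemp(suffix=".sam")[1])
    with open(clean, "w") as out:
        for line in lines:
            if not line.startswith("@"):
                cols = line.rstrip("\n").split("\t")
                if (
                    len(cols) >= 11
                    and cols[5] != "*"
                    and cols[9] != "*"
                    and _cigar_query_length(cols[5]) not in (None, len(cols[9]))
                ):
                    continue
            out.write(line)
    return clean, dropped


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Iterate mapped primary alignments from a SAM file.

    Unmapped, secondary and supplementary records are skipped silently;
    records whose CIGAR query length disagrees with the sequence length are
    skipped with a logged count.
    """
    source, skipped_malformed = _filter_malformed_sam(Path(path))
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigarstring is None or rec.query_sequence is None:
                skipped_malformed += 1
                continue
            if rec.infer_query_length() != len(rec.query_sequence):
                skipped_malformed += 1
                continue
            quals = (
                tuple(rec.query_qualities)
                if rec.query_qualities is not None
                else tuple([255] * len(rec.query_sequence))
            )
            yield AlignedRead(
                read_id=rec.query_name,
                contig=rec.reference_name,
                position=rec.reference_start + 1,
                cigar=rec.cigarstring,
                sequence=rec.query_sequence.upper(),
                qualities=quals,
                mapping_quality=rec.mapping_quality,
                is_duplicate=rec.is_duplicate,
            )
    if skipped_malformed:
        logger.warning("%s: skipped %d malformed records", path, skipped_malformed)
        source.unlink(missing_ok=True)


@dataclass
class SampleSheet:
    """Sample metadata: one row per sequencing replicate.

    A *sample* in this pipeline is a (genotype, condition) unit; its
    replicates are merged for site discovery and checked individually for the
    all-replicates screen.
    """

    rows: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "genotype", "condition", "replicate", "alignment_path")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        bad_cond = set(self.rows["condition"]) - {"control", "treated"}
        if bad_cond:
            raise FormatError(f"sample sheet: unknown conditions {sorted(bad_cond)}")
        if (self.rows["replicate"].astype(int) < 1).any():
            raise FormatError("sample sheet: replicate ids must be positive")
        for (gt, cond), grp in self.rows.groupby(["genotype", "condition"]):
            reps = grp["replicate"].astype(int)
            if reps.duplicated().any():
                raise FormatError(
                    f"sample sheet: duplicate replicate ids in ({gt}, {cond})"
                )

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.rows["genotype"].unique())

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """(genotype, condition) -> alignment paths ordered by replicate."""
        out: dict[tuple[str, str], list[str]] = {}
        for (gt, cond), grp in self.rows.groupby(["genotype", "condition"]):
            grp = grp.sort_values("replicate")
            out[(gt, cond)] = list(grp["alignment_path"])
        return out

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site output


_VCF_INFO = [
    ("CONV", "String", "Observed forward-strand conversion ref>alt"),
    ("BIOTYPE", "String", "Strand-corrected biological conversion"),
    ("GENE", "String", "Host or nearest gene"),
    ("REGION", "String", "Region class (CDS/upstream/downstream/intergenic)"),
    ("CODONPOS", "Integer", "Position within codon (1-3)"),
    ("CSQ", "String", "Coding consequence"),
    ("AACHANGE", "String", "Amino-acid change from>to"),
    ("AATREND", "String", "Physicochemical class transition"),
    ("EDITED", "Integer", "Edited (alt) read support, replicates pooled"),
    ("DEPTH", "Integer", "Total filtered read depth, replicates pooled"),
    ("EFF", "Float", "Editing efficiency edited/depth"),
    ("SAMPLE", "String", "Sample (genotype_condition) the call belongs to"),
]


def write_vcf(sites, path: str | Path, genomes: Sequence[Genome]) -> None:
    """Write annotated editing sites as VCF 4.2 (one record per site x sample)."""
    header = pysam.VariantHeader()
    for g in genomes:
        header.contigs.add(g.name, length=len(g))
    for key, vtype, desc in _VCF_INFO:
        header.info.add(key, 1, vtype, desc)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda s: (s.contig, s.position, s.sample)):
            rec = vcf.new_record(
                contig=s.contig,
                start=s.position - 1,  # pysam takes 0-based; file shows 1-based
                alleles=(s.ref_base, s.alt_base),
            )
            rec.info["CONV"] = s.observed_conversion
            rec.info["BIOTYPE"] = s.biological_conversion
            if s.gene_id:
                rec.info["GENE"] = s.gene_id
            rec.info["REGION"] = s.region_class
            if s.codon_position is not None:
                rec.info["CODONPOS"] = s.codon_position
            rec.info["CSQ"] = s.consequence
            if s.aa_from and s.aa_to:
                rec.info["AACHANGE"] = f"{s.aa_from}>{s.aa_to}"
            if s.aa_trend:
                rec.info["AATREND"] = s.aa_trend.replace(" ", "_")
            rec.info["EDITED"] = s.edited_reads
            rec.info["DEPTH"] = s.total_reads
            if s.efficiency is not None:
                rec.info["EFF"] = round(s.efficiency, 6)
            rec.info["SAMPLE"] = s.sample
            vcf.write(rec)


def sites_to_frame(sites) -> pd.DataFrame:
    """Tidy one-row-per-site-x-sample table used by TSV export and summaries."""
    rows = []
    for s in sites:
        rows.append(
            {
                "contig": s.contig,
                "position": s.position,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "sample": s.sample,
                "observed_conversion": s.observed_conversion,
                "biological_conversion": s.biological_conversion,
                "gene_id": s.gene_id or "",
                "region_class": s.region_class,
                "codon_position": s.codon_position,
                "consequence": s.consequence,
                "aa_from": s.aa_from or "",
                "aa_to": s.aa_to or "",
                "aa_trend": s.aa_trend or "",
                "edited_reads": s.edited_reads,
                "total_reads": s.total_reads,
                "efficiency": s.efficiency,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["contig", "position", "sample"]).reset_index(
            drop=True
        )
    return frame


def write_site_table(sites, path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)
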