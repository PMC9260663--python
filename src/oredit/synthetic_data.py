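"""Synthetic organelle genomes and aligned reads with planted editing sites.

The generator emulates the study design this package targets: two rice
genotypes under a control and an alkaline-stress condition, three sequencing
replicates each, aligned to a small organelle genome.  Planted features are
of two kinds:

* *edits* — partial-frequency C-to-U events on a gene's coding strand
  (observed as C>T on plus-strand genes, G>A on minus-strand genes), with a
  per-site true efficiency drawn from a Beta law; stress-gain edits appear
  only under the treated condition;
* *SNPs* — genomic variants fixed at allele frequency 1.0 in every sample,
  the confounder the background-subtraction step must remove.

Coverage per site is Poisson (reads are placed uniformly), base miscalls are
independent per base, and reads carry no indels (all-match CIGAR), since
detection downstream is substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io_formats import (
    Genome,
    GeneModel,
    SampleSheet,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONDITIONS = ("control", "treated")


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the emulated study: a compact organelle genome, two
    genotypes x two conditions x three replicates at ~50x coverage, 60
    planted edits (40 constitutive + 20 stress-gain) and 20 fixed SNPs.
    """

    seed: int = 42
    genome_length: int = 20_000
    n_genes: int = 12
    n_constitutive_edits: int = 40
    n_stress_gain_edits: int = 20
    n_snps: int = 20
    n_a_to_i_edits: int = 0
    beta_alpha: float = 4.0
    beta_beta: float = 2.0
    efficiency_min: float = 0.0
    coverage_mean: float = 50.0
    read_length: int = 100
    error_rate: float = 0.005
    replicates: int = 3
    genotypes: tuple[str, ...] = ("CD", "WD")
    contig_name: str = "chrM"
    gene_length_range: tuple[int, int] = (300, 900)

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_constitutive_edits, self.n_stress_gain_edits,
            self.n_snps, self.n_a_to_i_edits, self.replicates,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("counts must be non-negative")
        if not 0.0 <= self.efficiency_min < 1.0:
            raise SimulationError("efficiency_min must be in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError("error_rate must be in [0, 1)")
        if self.read_length > self.genome_length:
            raise SimulationError("read length exceeds genome length")


@dataclass(frozen=True)
class PlantedFeature:
    """One ground-truth planted feature (1-based position)."""

    position: int
    kind: str                     # edit | snp
    strand: str                   # strand of hosting gene, or + for snps
    biological_conversion: str    # C-to-U | A-to-I | snp
    ref_base: str                 # forward strand
    alt_base: str                 # forward strand
    true_efficiency: float
    condition_specificity: str    # constitutive | treated_only
    gene_id: str = ""


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    features: list[PlantedFeature] = field(default_factory=list)

    def edits(self) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == "edit"]

    def snps(self) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == "snp"]

    def expected_in(self, condition: str) -> list[PlantedFeature]:
        """Edits whose signal is present under the given condition."""
        return [
            f for f in self.edits()
            if f.condition_specificity == "constitutive" or condition == "treated"
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": f.position,
                    "kind": f.kind,
                    "strand": f.strand,
                    "biological_conversion": f.biological_conversion,
                    "ref": f.ref_base,
                    "alt": f.alt_base,
                    "true_efficiency": f.true_efficiency,
                    "condition_specificity": f.condition_specificity,
                    "gene_id": f.gene_id,
                }
                for f in sorted(self.features, key=lambda f: f.position)
            ]
        )

    def write(self, tsv_path: str | Path, bed_path: str | Path, contig: str) -> None:
        frame = self.to_frame()
        frame.to_csv(tsv_path, sep="\t", index=False)
        with open(bed_path, "w") as fh:
            for _, row in frame.iterrows():
                fh.write(
                    f"{contig}\t{row.position - 1}\t{row.position}\t"
                    f"{row.kind}:{row.ref}>{row.alt}\n"
                )


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    """Deterministic child generator for a named stream of the master seed."""
    return np.random.default_rng([cfg.seed % 2**31, *stream])


def simulate_reference(cfg: SimulationConfig) -> tuple[Genome, list[GeneModel]]:
    """Random genome with non-overlapping stranded CDS genes.

    CDS lengths are multiples of 3 and at least one gene lands on each strand
    (when two or more genes are requested).
    """
    rng = _rng(cfg, 1)
    seq = "".join(chr(b) for b in rng.choice(_BASES, size=cfg.genome_length))
    genome = Genome(name=cfg.contig_name, sequence=seq)

    lo, hi = cfg.gene_length_range
    lengths = [int(rng.integers(lo // 3, hi // 3 + 1)) * 3 for _ in range(cfg.n_genes)]
    if sum(lengths) + 2 * cfg.n_genes > cfg.genome_length:
        raise SimulationError(
            f"cannot place {cfg.n_genes} genes of total length {sum(lengths)} "
            f"in a {cfg.genome_length} bp genome"
        )
    # Non-overlapping placement by partitioning the slack into random
    # inter-gene gaps (>=1 bp between genes), always feasible when the
    # total length fits.
    slack = cfg.genome_length - sum(lengths) - max(cfg.n_genes - 1, 0)
    weights = rng.dirichlet(np.ones(cfg.n_genes + 1)) if cfg.n_genes else []
    extra = np.floor(weights * slack).astype(int) if cfg.n_genes else []
    placements: list[tuple[int, int]] = []
    cursor = 1
    for i, length in enumerate(lengths):
        start = cursor + int(extra[i]) + (1 if i else 0)
        end = start + length - 1
        placements.append((start, end))
        cursor = end

    strands = list(rng.choice(["+", "-"], size=cfg.n_genes))
    if cfg.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[0] == "+" else "+"

    models: list[GeneModel] = []
    for i, ((start, end), strand) in enumerate(
        sorted(zip(placements, strands)), start=1
    ):
        gene_id = f"g{i:03d}"
        common = dict(
            gene_id=gene_id, contig=cfg.contig_name,
            start=start, end=end, strand=strand,
        )
        models.append(GeneModel(feature_kind="gene", **common))
        models.append(GeneModel(feature_kind="CDS", phase=0, **common))
    return genome, models


def _truncated_beta(
    rng: np.random.Generator, alpha: float, beta: float, minimum: float, n: int
) -> np.ndarray:
    """Beta(alpha, beta) draws rejected below ``minimum``."""
    out = np.empty(0)
    while out.size < n:
        draws = rng.beta(alpha, beta, size=max(4 * n, 16))
        out = np.concatenate([out, draws[draws > minimum]])
    return out[:n]


def plant_features(
    cfg: SimulationConfig, genome: Genome, genes: Sequence[GeneModel]
) -> SimTruth:
    """Choose planted edit and SNP positions and their true parameters.

    Edits are C-to-U on the hosting gene's coding strand: a plus-strand gene
    contributes forward-strand C>T, a minus-strand gene forward-strand G>A.
    Optional A-to-I edits are planted the same way from A (or T) positions.
    SNPs are placed anywhere at allele frequency 1.0.
    """
    rng = _rng(cfg, 2)
    cds = [g for g in genes if g.feature_kind == "CDS"]
    if not cds and (cfg.n_constitutive_edits or cfg.n_stress_gain_edits):
        raise SimulationError("no CDS features to host planted edits")

    def eligible(coding_base: str) -> list[tuple[int, str, str]]:
        """(position, strand, gene_id) where the coding-strand base matches."""
        wanted: list[tuple[int, str, str]] = []
        for part in cds:
            for pos in range(part.start, part.end + 1):
                fwd = genome.base(pos)
                coding = fwd if part.strand == "+" else _COMPLEMENT[fwd]
                if coding == coding_base:
                    wanted.append((pos, part.strand, part.gene_id))
        return wanted

    n_edits = cfg.n_constitutive_edits + cfg.n_stress_gain_edits
    taken: set[int] = set()
    features: list[PlantedFeature] = []

    def draw_edit_sites(
        pool: list[tuple[int, str, str]], n: int, conversion: str
    ) -> list[tuple[int, str, str]]:
        pool = [p for p in pool if p[0] not in taken]
        if len(pool) < n:
            raise SimulationError(
                f"only {len(pool)} eligible positions for {n} {conversion} edits"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = [pool[i] for i in idx]
        taken.update(p for p, _, _ in chosen)
        return chosen

    edit_sites = draw_edit_sites(eligible("C"), n_edits, "C-to-U")
    effs = _truncated_beta(
        rng, cfg.beta_alpha, cfg.beta_beta, cfg.efficiency_min, n_edits
    )
    for i, ((pos, strand, gene_id), eff) in enumerate(zip(edit_sites, effs)):
        ref = genome.base(pos)
        alt = "T" if strand == "+" else "A"
        features.append(
            PlantedFeature(
                position=pos, kind="edit", strand=strand,
                biological_conversion="C-to-U", ref_base=ref, alt_base=alt,
                true_efficiency=float(min(eff, 0.999)),
                condition_specificity=(
                    "constitutive" if i < cfg.n_constitutive_edits else "treated_only"
                ),
                gene_id=gene_id,
            )
        )

    if cfg.n_a_to_i_edits:
        ai_sites = draw_edit_sites(eligible("A"), cfg.n_a_to_i_edits, "A-to-I")
        ai_effs = _truncated_beta(
            rng, cfg.beta_alpha, cfg.beta_beta, cfg.efficiency_min,
            cfg.n_a_to_i_edits,
        )
        for (pos, strand, gene_id), eff in zip(ai_sites, ai_effs):
            ref = genome.base(pos)
            alt = "G" if strand == "+" else "C"
            features.append(
                PlantedFeature(
                    position=pos, kind="edit", strand=strand,
                    biological_conversion="A-to-I", ref_base=ref, alt_base=alt,
                    true_efficiency=float(min(eff, 0.999)),
                    condition_specificity="constitutive", gene_id=gene_id,
                )
            )

    if cfg.n_snps:
        free = [p for p in range(1, len(genome) + 1) if p not in taken]
        if len(free) < cfg.n_snps:
            raise SimulationError("not enough free positions for SNPs")
        snp_pos = rng.choice(len(free), size=cfg.n_snps, replace=False)
        for i in snp_pos:
            pos = free[int(i)]
            ref = genome.base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            taken.add(pos)
            features.append(
                PlantedFeature(
                    position=pos, kind="snp", strand="+",
                    biological_conversion="snp", ref_base=ref, alt_base=alt,
                    true_efficiency=1.0, condition_specificity="constitutive",
                )
            )

    return SimTruth(features=features)


def simulate_read_arrays(
    cfg: SimulationConfig,
    genome: Genome,
    truth: SimTruth,
    condition: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate's reads as (starts, base-code matrix).

    Reads are placed uniformly; at a planted position a covering read draws
    the alt base with probability ``true_efficiency`` (edits active under the
    condition) or 1.0 (SNPs); independent miscalls at ``error_rate`` are then
    overlaid, each to a uniformly chosen different base.
    """
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    length = len(genome)
    n_reads = int(round(cfg.coverage_mean * length / cfg.read_length))
    starts = rng.integers(1, length - cfg.read_length + 2, size=n_reads)
    genome_codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code_of[ord(b)] = i
    genome_codes = code_of[genome_codes]
    offsets = np.arange(cfg.read_length)
    bases = genome_codes[(starts[:, None] - 1) + offsets]

    active = [
        f for f in truth.features
        if f.kind == "snp"
        or f.condition_specificity == "constitutive"
        or condition == "treated"
    ]
    for f in active:
        covering = np.nonzero(
            (starts <= f.position) & (f.position < starts + cfg.read_length)
        )[0]
        if covering.size == 0:
            continue
        show_alt = rng.random(covering.size) < f.true_efficiency
        cols = f.position - starts[covering[show_alt]]
        bases[covering[show_alt], cols] = _BASE_INDEX[f.alt_base]

    if cfg.error_rate > 0:
        miscall = rng.random(bases.shape) < cfg.error_rate
        shifts = rng.integers(1, 4, size=int(miscall.sum()))
        bases[miscall] = (bases[miscall] + shifts) % 4
    return starts, bases


def _write_sam(
    path: Path,
    cfg: SimulationConfig,
    genome: Genome,
    starts: np.ndarray,
    bases: np.ndarray,
    read_prefix: str,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.name, "LN": len(genome)}],
    }
    base_bytes = _BASES[bases]
    cigar = [(0, cfg.read_length)]
    qual = pysam.qualitystring_to_array("I" * cfg.read_length)
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i in range(len(starts)):
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = f"{read_prefix}_{i}"
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = int(starts[i]) - 1
            rec.mapping_quality = 60
            rec.cigartuples = cigar
            rec.query_sequence = base_bytes[i].tobytes().decode()
            rec.query_qualities = qual
            sam.write(rec)


def simulate_alignments(
    cfg: SimulationConfig,
    genome: Genome,
    truth: SimTruth,
    condition: str,
    out_dir: str | Path,
    genotype: str | None = None,
) -> list[Path]:
    """Write one SAM per replicate for a (genotype, condition) sample.

    Replicate read streams are derived from the master seed by fixed offsets,
    so replicates differ from each other but the whole experiment is
    reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotype = genotype or cfg.genotypes[0]
    gi = list(cfg.genotypes).index(genotype) if genotype in cfg.genotypes else 0
    ci = CONDITIONS.index(condition)
    paths: list[Path] = []
    for rep in range(1, cfg.replicates + 1):
        rng = _rng(cfg, 3, gi, ci, rep)
        starts, bases = simulate_read_arrays(cfg, genome, truth, condition, rng)
        path = out_dir / f"{genotype}_{condition}_rep{rep}.sam"
        _write_sam(path, cfg, genome, starts, bases, f"{genotype}.{condition}.r{rep}")
        paths.append(path)
    return paths


def simulate_experiment(
    cfg: SimulationConfig, out_dir: str | Path
) -> dict[str, object]:
    """Full synthetic experiment on disk: reference, truth, reads, sample sheet."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_reference(cfg)
    truth = plant_features(cfg, genome, genes)

    fasta = out_dir / "reference.fa"
    gff = out_dir / "annotation.gff3"
    write_fasta([genome], fasta)
    write_gff3(genes, gff)
    truth.write(out_dir / "truth.tsv", out_dir / "truth.bed", genome.name)

    rows = []
    for genotype in cfg.genotypes:
        for condition in CONDITIONS:
            paths = simulate_alignments(
                cfg, genome, truth, condition, out_dir / "alignments", genotype
            )
            for rep, path in enumerate(paths, start=1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{condition}_rep{rep}",
                        "genotype": genotype,
                        "condition": condition,
                        "replicate": rep,
                        "alignment_path": str(path),
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows))
    sheet.write(out_dir / "samples.tsv")
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "sample_sheet": sheet,
        "fasta": fasta,
        "gff3": gff,
    }
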