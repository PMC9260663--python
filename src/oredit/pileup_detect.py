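"""Pileup construction and dual-evidence RNA-editing-site calling.

The calling strategy mirrors the two-arm design used for organellar editing
surveys: a *site-level* arm (variant-caller-like: per-position binomial test
of the majority alternative allele against the sequencing error rate) and a
*read-cluster* arm (editing-caller-like: same-conversion mismatches shared
across reads, optionally clustered in a window).  Only sites found by both
arms survive.  Genomic SNPs are then removed against the genotype-matched
control background, and three screening criteria are applied:

1. a site must be supported by more than five edited reads (replicates of a
   sample pooled),
2. the ratio of edited reads to total mapped reads must exceed 50%,
3. the site must be present in every replicate of the sample.

A *sample* is a (genotype, condition) unit; its replicates are merged for
discovery and checked individually for criterion 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import AlignedRead, Genome, SampleSheet, read_sam

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = "ACGT"


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for pileup filtering, calling and screening.

    ``min_edited_reads`` = 6 encodes the "more than five edited reads"
    screen; ``min_ratio`` the >50% edited-read fraction; background modes:
    ``fixed_allele`` removes homozygous-SNP signatures (alt fraction >=
    ``snp_fixation_threshold`` in every sufficiently covered sample of a
    genotype), ``difference`` removes treated-sample calls present at any
    support in the genotype's control.
    """

    min_edited_reads: int = 6
    min_ratio: float = 0.5
    require_all_replicates: bool = True
    min_depth: int = 10
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    exclude_duplicates: bool = True
    error_rate_null: float = 0.005
    binom_alpha: float = 0.01
    cluster_window: int = 100
    background_mode: str = "fixed_allele"
    snp_fixation_threshold: float = 0.95
    max_edits_per_read: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_ratio <= 1.0:
            raise ValueError("min_ratio must be in (0, 1]")
        if self.min_edited_reads < 1 or self.min_depth < 1:
            raise ValueError("thresholds must be positive")
        if self.background_mode not in {"difference", "fixed_allele"}:
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base tallies over the filtered covering reads."""

    contig: str
    position: int
    ref_base: str
    base_counts: dict[str, int]
    per_read_edits: tuple[int, ...] = ()

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class CandidateSite:
    contig: str
    position: int
    ref_base: str
    alt_base: str
    edited_reads: int
    total_reads: int
    replicate_support: tuple[int, ...] = ()
    detector_flags: frozenset = frozenset()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.alt_base)


def editing_efficiency(site: CandidateSite) -> float | None:
    """Edited reads / total mapped reads; None when there is no coverage."""
    if site.total_reads == 0:
        return None
    return site.edited_reads / site.total_reads


class Pileup:
    """Base counts over a genome, plus the per-read mismatch lists that the
    read-cluster arm and the per-read-edit-count accessor consume."""

    def __init__(self, genome: Genome):
        self.contig = genome.name
        self.genome = genome
        self.length = len(genome)
        codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            lut[ord(b)] = i
        self.ref_codes = lut[codes]  # index 0 = position 1
        self.counts = np.zeros((self.length, 4), dtype=np.int64)
        # one entry per kept read: (start, span, mismatch positions, alt codes)
        self.read_records: list[tuple[int, int, np.ndarray, np.ndarray]] = []

    # -- accessors ---------------------------------------------------------

    def depth(self, position: int) -> int:
        return int(self.counts[position - 1].sum())

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[position - 1, _BASE_INDEX[base]])

    def column(self, position: int) -> PileupColumn:
        row = self.counts[position - 1]
        per_read = tuple(
            len(mpos)
            for start, span, mpos, _ in self.read_records
            if start <= position < start + span
        )
        return PileupColumn(
            contig=self.contig,
            position=position,
            ref_base=self.genome.base(position),
            base_counts={b: int(row[i]) for b, i in _BASE_INDEX.items() if row[i]},
            per_read_edits=per_read,
        )

    def merged_with(self, others: Sequence["Pileup"]) -> "Pileup":
        out = Pileup(self.genome)
        out.counts = self.counts.copy()
        out.read_records = list(self.read_records)
        for other in others:
            if other.contig != self.contig:
                raise ValueError(
                    f"cannot merge pileups of {self.contig!r} and {other.contig!r}"
                )
            out.counts += other.counts
            out.read_records.extend(other.read_records)
        return out


def build_pileup(
    alignments: Iterable[AlignedRead], genome: Genome, cfg: DetectionConfig
) -> Pileup:
    """Tally bases from filtered reads.

    Duplicate-flagged reads, mapping quality below ``min_mapping_quality``,
    base calls below ``min_base_quality`` and N bases are excluded.  Reads
    aligned to a different contig than the genome are a fatal error.
    """
    pile = Pileup(genome)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i

    for read in alignments:
        if read.contig != genome.name:
            raise ValueError(
                f"alignment contig {read.contig!r} does not match genome "
                f"{genome.name!r}"
            )
        if cfg.exclude_duplicates and read.is_duplicate:
            continue
        if read.mapping_quality < cfg.min_mapping_quality:
            continue

        codes = lut[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
        quals = np.asarray(read.qualities)
        if read.cigar == f"{len(read.sequence)}M":
            positions = read.position + np.arange(len(read.sequence))
        else:
            pairs = list(read.aligned_pairs())
            if not pairs:
                continue
            qidx = np.array([q for q, _ in pairs])
            positions = np.array([r for _, r in pairs])
            codes = codes[qidx]
            quals = quals[qidx]
        in_range = (positions >= 1) & (positions <= pile.length)
        keep = in_range & (codes >= 0) & (quals >= cfg.min_base_quality)
        positions, codes = positions[keep], codes[keep]
        mism = codes != pile.ref_codes[positions - 1]
        if cfg.max_edits_per_read is not None and int(mism.sum()) > cfg.max_edits_per_read:
            continue
        np.add.at(pile.counts, (positions - 1, codes), 1)
        span = read.reference_span()
        pile.read_records.append(
            (read.position, span, positions[mism], codes[mism])
        )
    return pile


# ---------------------------------------------------------------------------
# Detectors


def _majority_alt(pile: Pileup):
    """Per-position majority alternative allele; ties are multi-allelic.

    Returns (positions0, alt_codes, alt_counts, depths, tie_mask) over
    positions with at least one non-reference base.
    """
    depths = pile.counts.sum(axis=1)
    alt_counts = pile.counts.copy()
    rows = np.arange(pile.length)
    valid_ref = pile.ref_codes >= 0
    alt_counts[rows[valid_ref], pile.ref_codes[valid_ref]] = 0
    k = alt_counts.max(axis=1)
    has_alt = (k > 0) & valid_ref
    pos0 = np.nonzero(has_alt)[0]
    alt_code = alt_counts[pos0].argmax(axis=1)
    ties = (alt_counts[pos0] == k[pos0, None]).sum(axis=1) > 1
    return pos0, alt_code, k[pos0], depths[pos0], ties


def detect_site_level(pile: Pileup, cfg: DetectionConfig) -> list[CandidateSite]:
    """Variant-caller-like arm: binomial test of the majority alt allele.

    A position is a candidate iff depth >= ``min_depth``, the one-sided
    binomial tail P(X >= k | n, error_rate_null) is below ``binom_alpha``,
    and the site is bi-allelic (a unique majority alternative allele;
    exact ties are flagged multi-allelic and excluded).
    """
    pos0, alt_code, k, n, ties = _majority_alt(pile)
    ok = (n >= cfg.min_depth) & ~ties
    if pos0.size:
        tail = stats.binom.sf(k - 1, n, cfg.error_rate_null)
        ok &= tail < cfg.binom_alpha
    out = []
    for p0, ac, kk, nn in zip(pos0[ok], alt_code[ok], k[ok], n[ok]):
        out.append(
            CandidateSite(
                contig=pile.contig,
                position=int(p0) + 1,
                ref_base=_INDEX_BASE[pile.ref_codes[p0]],
                alt_base=_INDEX_BASE[ac],
                edited_reads=int(kk),
                total_reads=int(nn),
                detector_flags=frozenset({"site_level"}),
            )
        )
    return out


def detect_read_cluster(
    alignments: Iterable[AlignedRead] | None,
    genome: Genome,
    cfg: DetectionConfig,
    pileup: Pileup | None = None,
) -> list[CandidateSite]:
    """Editing-caller-like arm based on shared same-conversion mismatches.

    Per read, mismatches are grouped by conversion type (ref>alt).  A
    position is a candidate iff at least 2 distinct reads carry the same
    conversion there and another same-conversion mismatch position lies
    within ``cluster_window`` bp, OR the position alone is supported by
    ``min_edited_reads`` same-conversion reads.  Support counts are then
    taken from the pileup (single source of truth).
    """
    if pileup is None:
        if alignments is None:
            raise ValueError("need alignments or a prebuilt pileup")
        pileup = build_pileup(alignments, genome, cfg)

    # distinct-read support per (position, ref_code, alt_code)
    support: dict[tuple[int, int, int], int] = {}
    for _start, _span, mpos, malt in pileup.read_records:
        for p, a in zip(mpos, malt):
            key = (int(p), int(pileup.ref_codes[p - 1]), int(a))
            support[key] = support.get(key, 0) + 1

    by_conv: dict[tuple[int, int], list[int]] = {}
    for (p, r, a) in support:
        by_conv.setdefault((r, a), []).append(p)

    out = []
    for (r, a), positions in by_conv.items():
        positions = np.array(sorted(positions))
        for p in positions:
            n_reads = support[(int(p), r, a)]
            near = np.abs(positions - p) <= cfg.cluster_window
            clustered = n_reads >= 2 and int(near.sum()) >= 2
            if clustered or n_reads >= cfg.min_edited_reads:
                out.append(
                    CandidateSite(
                        contig=pileup.contig,
                        position=int(p),
                        ref_base=_INDEX_BASE[r],
                        alt_base=_INDEX_BASE[a],
                        edited_reads=pileup.base_count(int(p), _INDEX_BASE[a]),
                        total_reads=pileup.depth(int(p)),
                        detector_flags=frozenset({"read_cluster"}),
                    )
                )
    out.sort(key=lambda c: c.position)
    return out


def overlap_candidates(
    a: Sequence[CandidateSite], b: Sequence[CandidateSite]
) -> list[CandidateSite]:
    """Intersection on (contig, position, alt); detector flags are unioned.

    Both detectors draw support counts from the same pileup, so counts agree
    and the operation is symmetric.
    """
    b_by_key = {c.key: c for c in b}
    out = []
    for c in a:
        other = b_by_key.get(c.key)
        if other is None:
            continue
        out.append(
            replace(c, detector_flags=c.detector_flags | other.detector_flags)
        )
    out.sort(key=lambda c: (c.contig, c.position, c.alt_base))
    return out


def attach_replicate_support(
    candidates: Sequence[CandidateSite], replicate_pileups: Sequence[Pileup]
) -> list[CandidateSite]:
    """Fill each candidate's per-replicate edited-read counts."""
    out = []
    for c in candidates:
        vec = tuple(
            p.base_count(c.position, c.alt_base) for p in replicate_pileups
        )
        out.append(replace(c, replicate_support=vec))
    return out


# ---------------------------------------------------------------------------
# Background subtraction and screening


SampleKey = tuple[str, str]  # (genotype, condition)


def subtract_background(
    candidates_by_sample: Mapping[SampleKey, Sequence[CandidateSite]],
    cfg: DetectionConfig,
    pileups_by_sample: Mapping[SampleKey, Pileup],
) -> dict[SampleKey, list[CandidateSite]]:
    """Remove genotype-fixed genomic SNPs using control-sample background.

    ``fixed_allele`` (default): a candidate is removed from all samples of a
    genotype iff its alt fraction is >= ``snp_fixation_threshold`` in every
    sample of that genotype with depth >= ``min_depth`` — the signature of a
    homozygous SNP; partial-frequency shared sites survive as constitutive
    editing.  ``difference``: treated-sample candidates present at any
    support in the genotype's control are removed; control samples keep
    their own calls.
    """
    genotypes = {gt for gt, _ in candidates_by_sample}
    for gt in genotypes:
        if (gt, "control") not in candidates_by_sample:
            raise ValueError(f"genotype {gt!r} has no control sample")

    result: dict[SampleKey, list[CandidateSite]] = {}
    if cfg.background_mode == "difference":
        for key, cands in candidates_by_sample.items():
            gt, cond = key
            if cond != "treated":
                result[key] = list(cands)
                continue
            control_pile = pileups_by_sample[(gt, "control")]
            result[key] = [
                c for c in cands
                if control_pile.base_count(c.position, c.alt_base) == 0
            ]
        return result

    # fixed_allele
    fixed_by_genotype: dict[str, set] = {}
    for gt in genotypes:
        sample_keys = [k for k in candidates_by_sample if k[0] == gt]
        keys = {c.key for k in sample_keys for c in candidates_by_sample[k]}
        fixed = set()
        for key in keys:
            _contig, pos, alt = key
            fractions = []
            for sk in sample_keys:
                pile = pileups_by_sample[sk]
                depth = pile.depth(pos)
                if depth >= cfg.min_depth:
                    fractions.append(pile.base_count(pos, alt) / depth)
            if fractions and all(
                f >= cfg.snp_fixation_threshold for f in fractions
            ):
                fixed.add(key)
        fixed_by_genotype[gt] = fixed

    for key, cands in candidates_by_sample.items():
        fixed = fixed_by_genotype[key[0]]
        result[key] = [c for c in cands if c.key not in fixed]
    return result


def apply_screens(
    candidates: Sequence[CandidateSite], cfg: DetectionConfig
) -> list[CandidateSite]:
    """Apply the three screening criteria to one sample's candidates.

    Kept iff pooled edited reads > 5 (``>= min_edited_reads``), pooled
    edited/total ratio strictly above ``min_ratio``, and — when
    ``require_all_replicates`` — at least one edited read in every replicate.
    """
    out = []
    for c in candidates:
        if c.edited_reads < cfg.min_edited_reads:
            continue
        if c.total_reads == 0 or c.edited_reads / c.total_reads <= cfg.min_ratio:
            continue
        if cfg.require_all_replicates and c.replicate_support:
            if any(s < 1 for s in c.replicate_support):
                continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Sample- and experiment-level drivers


def detect_sample(
    replicate_alignments: Sequence[Sequence[AlignedRead]],
    genome: Genome,
    cfg: DetectionConfig,
) -> tuple[list[CandidateSite], Pileup, list[Pileup]]:
    """Dual-arm discovery on one sample's merged replicates.

    Returns (overlap candidates with per-replicate support, merged pileup,
    per-replicate pileups).  Screening and background subtraction are
    separate steps.
    """
    rep_piles = [build_pileup(reads, genome, cfg) for reads in replicate_alignments]
    merged = rep_piles[0].merged_with(rep_piles[1:])
    site_level = detect_site_level(merged, cfg)
    clustered = detect_read_cluster(None, genome, cfg, pileup=merged)
    overlap = overlap_candidates(site_level, clustered)
    overlap = attach_replicate_support(overlap, rep_piles)
    return overlap, merged, rep_piles


def detect_experiment(
    sample_sheet: SampleSheet,
    genome: Genome,
    cfg: DetectionConfig,
) -> tuple[dict[SampleKey, list[CandidateSite]], dict[str, dict]]:
    """Full calling chain over every (genotype, condition) sample.

    Returns final screened sites per sample and a per-sample stage-count log
    (candidates per arm, after overlap, after background, after screens).
    """
    stage_log: dict[str, dict] = {}
    overlap_by_sample: dict[SampleKey, list[CandidateSite]] = {}
    piles_by_sample: dict[SampleKey, Pileup] = {}
    for key, paths in sample_sheet.groups().items():
        reads = [list(read_sam(p)) for p in paths]
        overlap, merged, _reps = detect_sample(reads, genome, cfg)
        overlap_by_sample[key] = overlap
        piles_by_sample[key] = merged
        stage_log["_".join(key)] = {"overlap_candidates": len(overlap)}

    filtered = subtract_background(overlap_by_sample, cfg, piles_by_sample)
    final: dict[SampleKey, list[CandidateSite]] = {}
    for key, cands in filtered.items():
        name = "_".join(key)
        stage_log[name]["after_background"] = len(cands)
        final[key] = apply_screens(cands, cfg)
        stage_log[name]["final_sites"] = len(final[key])
        logger.info("sample %s: %s", name, stage_log[name])
    return final, stage_log
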