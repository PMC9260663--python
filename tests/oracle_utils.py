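"""Independent brute-force oracles used by the equivalence tests.

These deliberately avoid the package's pileup and annotation code paths:
the detection oracle counts bases literally from SAM text and applies the
screening criteria verbatim; the annotation oracle re-translates the whole
mutated CDS and diffs the protein sequences.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def literal_base_counts(
    sam_path: str,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> dict[int, dict[str, int]]:
    """Per-position base tallies parsed directly from SAM text.

    Applies the same read/base filters the pipeline documents: skips
    unmapped/secondary/supplementary/duplicate records, mapping quality
    below threshold, low-quality base calls and N bases.  Reads must be
    all-match (the simulator emits no indels).
    """
    counts: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & (0x4 | 0x100 | 0x400 | 0x800):
                continue
            if int(f[4]) < min_mapping_quality:
                continue
            pos, cigar, seq, qual = int(f[3]), f[5], f[9], f[10]
            assert cigar == f"{len(seq)}M", "oracle handles all-match reads only"
            for i, (base, q) in enumerate(zip(seq, qual)):
                if ord(q) - 33 < min_base_quality or base == "N":
                    continue
                counts[pos + i][base] += 1
    return counts


def brute_force_final_sites(
    sam_paths: Sequence[str],
    genome_sequence: str,
    min_depth: int = 10,
    min_edited_reads: int = 6,
    min_ratio: float = 0.5,
) -> set[tuple[int, str, str]]:
    """Literal application of the screening criteria to one sample.

    Replicates are pooled for support; a site needs a unique majority
    alternative allele, depth >= ``min_depth``, strictly more than
    ``min_edited_reads - 1`` pooled edited reads, an edited/total ratio
    strictly above ``min_ratio``, and at least one edited read in every
    replicate.
    """
    per_rep = [literal_base_counts(p) for p in sam_paths]
    merged: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for rep in per_rep:
        for pos, bases in rep.items():
            for base, n in bases.items():
                merged[pos][base] += n

    final = set()
    for pos, bases in merged.items():
        ref = genome_sequence[pos - 1]
        depth = sum(bases.values())
        alts = {b: c for b, c in bases.items() if b != ref and c > 0}
        if not alts or depth < min_depth:
            continue
        top_count = max(alts.values())
        top = [b for b, c in alts.items() if c == top_count]
        if len(top) > 1:
            continue  # exact tie: multi-allelic
        alt = top[0]
        if top_count < min_edited_reads:
            continue
        if top_count / depth <= min_ratio:
            continue
        if any(rep.get(pos, {}).get(alt, 0) < 1 for rep in per_rep):
            continue
        final.add((pos, ref, alt))
    return final


def retranslate_cds(
    genome_sequence: str,
    cds_parts,
    strand: str,
    position: int,
    alt: str,
) -> tuple[int, int, str, str]:
    """Whole-CDS re-translation oracle for a substitution inside a CDS.

    Returns (codon_index_0based, codon_position_1to3, aa_from, aa_to) by
    mutating the genome, rebuilding the joined coding sequence and
    translating reference and mutant proteins in full.
    """
    mutated = genome_sequence[: position - 1] + alt + genome_sequence[position:]

    def coding_sequence(seq: str) -> str:
        parts = sorted(cds_parts, key=lambda p: p.start)
        joined = "".join(seq[p.start - 1 : p.end] for p in parts)
        if strand == "-":
            joined = joined.translate(_COMP)[::-1]
        return joined

    ref_cds = coding_sequence(genome_sequence)
    alt_cds = coding_sequence(mutated)
    diff = [i for i in range(len(ref_cds)) if ref_cds[i] != alt_cds[i]]
    assert len(diff) == 1
    idx = diff[0]
    ref_protein = str(Seq(ref_cds).translate())
    alt_protein = str(Seq(alt_cds).translate())
    codon_idx = idx // 3
    return codon_idx, idx % 3 + 1, ref_protein[codon_idx], alt_protein[codon_idx]
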