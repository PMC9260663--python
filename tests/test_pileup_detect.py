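import dataclasses

import numpy as np
import pytest

from conftest import make_read, reads_at
from oredit.pileup_detect import (
    CandidateSite,
    DetectionConfig,
    apply_screens,
    build_pileup,
    detect_read_cluster,
    detect_sample,
    detect_site_level,
    editing_efficiency,
    overlap_candidates,
    subtract_background,
)
from oredit.synthetic_data import (
    SimulationConfig,
    plant_features,
    simulate_read_arrays,
    simulate_reference,
)

CFG = DetectionConfig()


def _alt_of(genome, pos):
    return "T" if genome.base(pos) != "T" else "A"


class TestBuildPileup:
    def test_all_reference_reads(self, toy_genome):
        reads = reads_at(toy_genome, 100, n_ref=10, n_alt=0, alt="T")
        pile = build_pileup(reads, toy_genome, CFG)
        col = pile.column(100)
        assert col.base_counts == {toy_genome.base(100): 10}
        assert col.depth == 10

    def test_mixed_counts(self, toy_genome):
        alt = _alt_of(toy_genome, 100)
        reads = reads_at(toy_genome, 100, n_ref=4, n_alt=6, alt=alt)
        pile = build_pileup(reads, toy_genome, CFG)
        assert pile.depth(100) == 10
        assert pile.base_count(100, alt) == 6

    def test_low_quality_base_excluded(self, toy_genome):
        alt = _alt_of(toy_genome, 100)
        (read,) = reads_at(toy_genome, 100, n_ref=0, n_alt=1, alt=alt, length=20)
        quals = list(read.qualities)
        quals[100 - read.position] = 5
        read = read._replace(qualities=tuple(quals))
        pile = build_pileup([read], toy_genome, CFG)
        assert pile.base_count(100, alt) == 0
        assert pile.depth(100) == 0

    def test_duplicate_and_low_mq_reads_excluded(self, toy_genome):
        reads = reads_at(toy_genome, 100, 2, 0, "T", is_duplicate=True)
        reads += reads_at(toy_genome, 100, 2, 0, "T", mapping_quality=5)
        pile = build_pileup(reads, toy_genome, CFG)
        assert pile.depth(100) == 0

    def test_contig_mismatch_is_fatal(self, toy_genome):
        read = make_read(10, "ACGT", contig="chrC")
        with pytest.raises(ValueError, match="chrC"):
            build_pileup([read], toy_genome, CFG)

    def test_n_bases_never_counted(self, toy_genome):
        read = make_read(100, "N" * 10)
        pile = build_pileup([read], toy_genome, CFG)
        assert pile.depth(105) == 0


class TestSiteLevel:
    def test_strong_alt_is_candidate(self, toy_genome):
        # P(X >= 6 | n=10, p=0.005) ~ 3e-12 << 0.01
        alt = _alt_of(toy_genome, 100)
        pile = build_pileup(
            reads_at(toy_genome, 100, 4, 6, alt), toy_genome, CFG
        )
        (cand,) = detect_site_level(pile, CFG)
        assert (cand.position, cand.alt_base, cand.edited_reads) == (100, alt, 6)

    def test_single_mismatch_in_deep_column_is_noise(self, toy_genome):
        # closed form: P(X >= 1 | n=50, p=0.005) = 1 - 0.995^50 ~ 0.22 > alpha
        alt = _alt_of(toy_genome, 100)
        pile = build_pileup(
            reads_at(toy_genome, 100, 49, 1, alt), toy_genome, CFG
        )
        assert detect_site_level(pile, CFG) == []

    def test_below_min_depth_never_candidate(self, toy_genome):
        alt = _alt_of(toy_genome, 100)
        pile = build_pileup(
            reads_at(toy_genome, 100, 0, 5, alt), toy_genome, CFG
        )
        assert detect_site_level(pile, CFG) == []

    def test_exact_allele_tie_excluded(self, toy_genome):
        ref = toy_genome.base(100)
        alts = [b for b in "ACGT" if b != ref][:2]
        reads = reads_at(toy_genome, 100, 4, 5, alts[0])
        reads += reads_at(toy_genome, 100, 0, 5, alts[1])
        pile = build_pileup(reads, toy_genome, CFG)
        assert detect_site_level(pile, CFG) == []


class TestReadCluster:
    def test_six_shared_mismatches_candidate(self, toy_genome):
        alt = _alt_of(toy_genome, 100)
        reads = reads_at(toy_genome, 100, 0, 6, alt)
        cands = detect_read_cluster(reads, toy_genome, CFG)
        assert [(c.position, c.alt_base) for c in cands] == [(100, alt)]

    def test_lone_mismatch_not_candidate(self, toy_genome):
        alt = _alt_of(toy_genome, 100)
        reads = reads_at(toy_genome, 100, 0, 1, alt)
        assert detect_read_cluster(reads, toy_genome, CFG) == []

    def test_two_nearby_positions_cluster(self, toy_genome):
        # hand enumeration: 3 reads each at two same-type positions 40 bp
        # apart -> both pass via the window rule, neither alone reaches 6
        p1, p2 = 100, 140
        ref1, ref2 = toy_genome.base(p1), toy_genome.base(p2)
        # force the same conversion type at both positions
        alt = next(b for b in "ACGT" if b != ref1 and b != ref2)
        reads = reads_at(toy_genome, p1, 0, 3, alt)
        reads += reads_at(toy_genome, p2, 0, 3, alt)
        cands = detect_read_cluster(reads, toy_genome, CFG)
        positions = {c.position for c in cands}
        if ref1 == ref2:  # same conversion type: clustering applies
            assert positions == {p1, p2}
        else:  # different types never cluster together
            assert positions == set()


class TestOverlap:
    def _cand(self, pos, alt="T", flags=("site_level",)):
        return CandidateSite(
            contig="chrM", position=pos, ref_base="C", alt_base=alt,
            edited_reads=6, total_reads=10, detector_flags=frozenset(flags),
        )

    def test_disjoint_empty(self):
        assert overlap_candidates([self._cand(1)], [self._cand(2)]) == []

    def test_identity_and_flag_union(self):
        a = [self._cand(5, flags=("site_level",))]
        b = [self._cand(5, flags=("read_cluster",))]
        (merged,) = overlap_candidates(a, b)
        assert merged.detector_flags == {"site_level", "read_cluster"}

    def test_symmetry(self):
        a = [self._cand(1), self._cand(5)]
        b = [self._cand(5), self._cand(9)]
        assert overlap_candidates(a, b) == overlap_candidates(b, a)


def _sample_pileups(genome, spec):
    """spec: {(genotype, condition): [(pos, n_ref, n_alt, alt), ...]}"""
    piles, cands = {}, {}
    for key, sites in spec.items():
        reads = []
        for pos, n_ref, n_alt, alt in sites:
            reads += reads_at(genome, pos, n_ref, n_alt, alt)
        pile = build_pileup(reads, genome, CFG)
        piles[key] = pile
        cands[key] = [
            CandidateSite(
                contig=genome.name, position=pos, ref_base=genome.base(pos),
                alt_base=alt, edited_reads=pile.base_count(pos, alt),
                total_reads=pile.depth(pos),
            )
            for pos, n_ref, n_alt, alt in sites
            if n_alt > 0
        ]
    return piles, cands


class TestBackground:
    def test_fixed_snp_removed_in_both_modes(self, toy_genome):
        alt = _alt_of(toy_genome, 200)
        spec = {
            ("CD", "control"): [(200, 0, 20, alt)],
            ("CD", "treated"): [(200, 0, 20, alt)],
        }
        piles, cands = _sample_pileups(toy_genome, spec)
        for mode in ["difference", "fixed_allele"]:
            cfg = dataclasses.replace(CFG, background_mode=mode)
            out = subtract_background(cands, cfg, piles)
            assert out[("CD", "treated")] == []

    def test_treated_only_edit_retained(self, toy_genome):
        alt = _alt_of(toy_genome, 200)
        spec = {
            ("CD", "control"): [(200, 20, 0, alt)],
            ("CD", "treated"): [(200, 8, 12, alt)],
        }
        piles, cands = _sample_pileups(toy_genome, spec)
        for mode in ["difference", "fixed_allele"]:
            cfg = dataclasses.replace(CFG, background_mode=mode)
            out = subtract_background(cands, cfg, piles)
            assert len(out[("CD", "treated")]) == 1

    def test_constitutive_edit_mode_dependent(self, toy_genome):
        alt = _alt_of(toy_genome, 200)
        spec = {
            ("CD", "control"): [(200, 8, 12, alt)],
            ("CD", "treated"): [(200, 8, 12, alt)],
        }
        piles, cands = _sample_pileups(toy_genome, spec)
        diff = subtract_background(
            cands, dataclasses.replace(CFG, background_mode="difference"), piles
        )
        assert diff[("CD", "treated")] == []          # shared with control
        assert len(diff[("CD", "control")]) == 1      # control keeps its call
        fixed = subtract_background(
            cands, dataclasses.replace(CFG, background_mode="fixed_allele"), piles
        )
        assert len(fixed[("CD", "treated")]) == 1     # partial frequency: kept
        assert len(fixed[("CD", "control")]) == 1

    def test_missing_control_is_fatal(self, toy_genome):
        alt = _alt_of(toy_genome, 200)
        piles, cands = _sample_pileups(
            toy_genome, {("CD", "treated"): [(200, 0, 20, alt)]}
        )
        with pytest.raises(ValueError, match="control"):
            subtract_background(cands, CFG, piles)


class TestScreens:
    def _cand(self, edited, total, support):
        return CandidateSite(
            contig="chrM", position=1, ref_base="C", alt_base="T",
            edited_reads=edited, total_reads=total,
            replicate_support=tuple(support),
        )

    @pytest.mark.parametrize(
        "edited, total, support, kept",
        [
            (6, 10, (2, 2, 2), True),    # boundary: just above "more than five"
            (5, 10, (2, 2, 1), False),   # five edited reads is not enough
            (12, 20, (6, 6, 0), False),  # missing from one replicate
            (12, 24, (4, 4, 4), False),  # ratio exactly 0.5 is not > 50%
            (13, 24, (5, 4, 4), True),
        ],
    )
    def test_three_criteria(self, edited, total, support, kept):
        out = apply_screens([self._cand(edited, total, support)], CFG)
        assert (len(out) == 1) is kept

    def test_replicate_check_can_be_disabled(self):
        cfg = dataclasses.replace(CFG, require_all_replicates=False)
        out = apply_screens([self._cand(12, 20, (6, 6, 0))], cfg)
        assert len(out) == 1


@pytest.mark.parametrize(
    "edited, total, expected",
    [(21, 42, 0.5), (0, 30, 0.0), (30, 30, 1.0), (0, 0, None)],
)
def test_editing_efficiency(edited, total, expected):
    site = CandidateSite(
        contig="chrM", position=1, ref_base="C", alt_base="T",
        edited_reads=edited, total_reads=total,
    )
    assert editing_efficiency(site) == expected


def _simulated_sample_reads(seed=101):
    cfg = SimulationConfig(
        seed=seed, genome_length=4000, n_genes=4, n_constitutive_edits=8,
        n_stress_gain_edits=0, n_snps=0, coverage_mean=30.0,
    )
    genome, models = simulate_reference(cfg)
    truth = plant_features(cfg, genome, models)
    rng = np.random.default_rng(seed)
    replicate_reads = []
    for _rep in range(3):
        starts, bases = simulate_read_arrays(cfg, genome, truth, "control", rng)
        reads = [
            make_read(int(s), "".join("ACGT"[b] for b in row), contig=genome.name)
            for s, row in zip(starts, bases)
        ]
        replicate_reads.append(reads)
    return genome, replicate_reads


class TestChainInvariants:
    def test_final_subset_of_overlap_subset_of_detectors(self):
        genome, reps = _simulated_sample_reads()
        overlap, merged, _ = detect_sample(reps, genome, CFG)
        site_level = {c.key for c in detect_site_level(merged, CFG)}
        cluster = {
            c.key for c in detect_read_cluster(None, genome, CFG, pileup=merged)
        }
        overlap_keys = {c.key for c in overlap}
        final_keys = {c.key for c in apply_screens(overlap, CFG)}
        assert final_keys <= overlap_keys
        assert overlap_keys <= site_level
        assert overlap_keys <= cluster

    def test_raising_min_ratio_is_monotone(self):
        genome, reps = _simulated_sample_reads()
        overlap, _, _ = detect_sample(reps, genome, CFG)
        counts = [
            len(apply_screens(overlap, dataclasses.replace(CFG, min_ratio=r)))
            for r in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)
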