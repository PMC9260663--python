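import numpy as np
import pytest

from oredit.io_formats import read_sam
from oredit.synthetic_data import (
    PlantedFeature,
    SimTruth,
    SimulationConfig,
    SimulationError,
    plant_features,
    simulate_alignments,
    simulate_experiment,
    simulate_reference,
)

SMALL = SimulationConfig(
    seed=3, genome_length=3000, n_genes=4, n_constitutive_edits=6,
    n_stress_gain_edits=3, n_snps=3, coverage_mean=30.0,
)


class TestReference:
    def test_deterministic_under_seed(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate_experiment(SMALL, a)
        simulate_experiment(SMALL, b)
        for name in ["reference.fa", "annotation.gff3",
                     "alignments/CD_treated_rep2.sam"]:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_infeasible_gene_count(self):
        with pytest.raises(SimulationError):
            simulate_reference(
                SimulationConfig(seed=1, genome_length=300, n_genes=50)
            )

    def test_default_gene_structure(self):
        genome, models = simulate_reference(SimulationConfig(seed=5))
        cds = [m for m in models if m.feature_kind == "CDS"]
        assert len(cds) == 12
        assert all(len(m) % 3 == 0 for m in cds)
        assert {m.strand for m in cds} == {"+", "-"}
        assert len(genome) == 20_000


class TestPlantFeatures:
    def test_minus_strand_edit_is_forward_g_to_a(self):
        genome, models = simulate_reference(SMALL)
        truth = plant_features(SMALL, genome, models)
        minus = [f for f in truth.edits() if f.strand == "-"]
        assert minus, "expected at least one minus-strand edit"
        for f in minus:
            assert (f.ref_base, f.alt_base) == ("G", "A")
            assert genome.base(f.position) == "G"
            assert f.biological_conversion == "C-to-U"

    def test_no_snps_requested(self):
        cfg = SimulationConfig(
            seed=2, genome_length=3000, n_genes=3,
            n_constitutive_edits=4, n_stress_gain_edits=0, n_snps=0,
        )
        genome, models = simulate_reference(cfg)
        truth = plant_features(cfg, genome, models)
        assert truth.snps() == []
        assert all(f.true_efficiency < 1.0 for f in truth.edits())

    def test_beta_law_mean_matches_closed_form(self):
        # Beta(4, 2) has mean 4/6 = 2/3
        cfg = SimulationConfig(
            seed=11, genome_length=20_000, n_genes=12,
            n_constitutive_edits=200, n_stress_gain_edits=0, n_snps=0,
        )
        genome, models = simulate_reference(cfg)
        truth = plant_features(cfg, genome, models)
        effs = [f.true_efficiency for f in truth.edits()]
        assert len(effs) == 200
        assert abs(np.mean(effs) - 2 / 3) < 0.05

    def test_positions_distinct(self):
        genome, models = simulate_reference(SMALL)
        truth = plant_features(SMALL, genome, models)
        positions = [f.position for f in truth.features]
        assert len(positions) == len(set(positions))


def _alt_fraction(sam_path, genome, position, alt):
    n_alt = depth = 0
    for read in read_sam(sam_path):
        offset = position - read.position
        if 0 <= offset < len(read.sequence):
            depth += 1
            n_alt += read.sequence[offset] == alt
    return n_alt, depth


class TestAlignments:
    def test_no_features_no_errors_gives_clean_pileup(self, tmp_path):
        cfg = SimulationConfig(
            seed=9, genome_length=1500, n_genes=2, n_constitutive_edits=0,
            n_stress_gain_edits=0, n_snps=0, error_rate=0.0,
            coverage_mean=20.0, replicates=1,
        )
        genome, models = simulate_reference(cfg)
        truth = plant_features(cfg, genome, models)
        (path,) = simulate_alignments(cfg, genome, truth, "control", tmp_path)
        for read in read_sam(path):
            expected = genome.sequence[read.position - 1 : read.position - 1 + 100]
            assert read.sequence == expected

    def test_snp_fraction_near_one(self, tmp_path):
        cfg = SimulationConfig(
            seed=13, genome_length=1500, n_genes=2, n_constitutive_edits=0,
            n_stress_gain_edits=0, n_snps=2, error_rate=0.005,
            coverage_mean=60.0, replicates=1,
        )
        genome, models = simulate_reference(cfg)
        truth = plant_features(cfg, genome, models)
        (path,) = simulate_alignments(cfg, genome, truth, "control", tmp_path)
        for snp in truth.snps():
            n_alt, depth = _alt_fraction(path, genome, snp.position, snp.alt_base)
            assert depth > 10
            assert n_alt / depth > 0.9

    def test_edit_fraction_tracks_true_efficiency(self, tmp_path):
        # binomial CI: at coverage 500 the observed fraction of a 0.6 edit
        # lies within +/-0.07 of the truth with overwhelming probability
        cfg = SimulationConfig(
            seed=21, genome_length=2400, n_genes=2, n_constitutive_edits=0,
            n_stress_gain_edits=0, n_snps=0, coverage_mean=500.0, replicates=1,
        )
        genome, models = simulate_reference(cfg)
        cds = next(m for m in models if m.feature_kind == "CDS" and m.strand == "+")
        position = next(
            p for p in range(cds.start, cds.end + 1) if genome.base(p) == "C"
        )
        truth = SimTruth(
            features=[
                PlantedFeature(
                    position=position, kind="edit", strand="+",
                    biological_conversion="C-to-U", ref_base="C", alt_base="T",
                    true_efficiency=0.6, condition_specificity="constitutive",
                    gene_id=cds.gene_id,
                )
            ]
        )
        (path,) = simulate_alignments(cfg, genome, truth, "control", tmp_path)
        n_alt, depth = _alt_fraction(path, genome, position, "T")
        assert abs(n_alt / depth - 0.6) < 0.07

    def test_treated_only_edit_absent_in_control(self, tmp_path):
        cfg = SimulationConfig(
            seed=17, genome_length=1500, n_genes=2, n_constitutive_edits=0,
            n_stress_gain_edits=2, n_snps=0, error_rate=0.0,
            coverage_mean=40.0, replicates=1,
        )
        genome, models = simulate_reference(cfg)
        truth = plant_features(cfg, genome, models)
        (ctrl,) = simulate_alignments(cfg, genome, truth, "control", tmp_path / "c")
        (trt,) = simulate_alignments(cfg, genome, truth, "treated", tmp_path / "t")
        for edit in truth.edits():
            n_ctrl, _ = _alt_fraction(ctrl, genome, edit.position, edit.alt_base)
            n_trt, depth = _alt_fraction(trt, genome, edit.position, edit.alt_base)
            assert n_ctrl == 0
            assert n_trt > 0 and depth > 0

    def test_truth_sam_consistency_within_4_sigma(self, tmp_path):
        """Brute-force alt recounts at planted positions match the binomial
        model n*p +/- 4*sqrt(n*p*(1-p))."""
        cfg = SimulationConfig(
            seed=29, genome_length=2500, n_genes=3, n_constitutive_edits=5,
            n_stress_gain_edits=0, n_snps=2, coverage_mean=80.0,
            replicates=1, error_rate=0.0,
        )
        genome, models = simulate_reference(cfg)
        truth = plant_features(cfg, genome, models)
        (path,) = simulate_alignments(cfg, genome, truth, "control", tmp_path)
        for f in truth.features:
            n_alt, depth = _alt_fraction(path, genome, f.position, f.alt_base)
            p = f.true_efficiency
            sigma = np.sqrt(depth * p * (1 - p))
            assert abs(n_alt - depth * p) <= 4 * sigma + 1e-9
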