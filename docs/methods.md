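# Methods

This note documents the models, rules and numerical choices behind
`oredit`, and what the synthetic experiments do and do not establish.

## Calling model

A pileup column with filtered depth *n* and majority alternative-allele
count *k* is treated under two complementary error models.

**Site-level arm.** Sequencing miscalls are independent Bernoulli events at
rate `error_rate_null` (default 0.005, a typical post-filter Illumina
substitution rate). A column is a candidate when the exact one-sided
binomial tail P(X ≥ k | n, p) falls below `binom_alpha` (default 0.01),
depth is at least `min_depth` (default 10), and the majority alternative
allele is unique. Exact ties between alternative alleles are flagged
multi-allelic and excluded rather than broken arbitrarily: a genuine edit
produces one alternative base, and a tie at calling depth is a sign of
noise or mapping artefact.

**Read-cluster arm.** Editing enzymes act on specific transcript positions,
so genuine edits recur across independent reads and often co-occur with
nearby edits of the same conversion type. A position is a candidate when at
least two distinct reads carry the same-type mismatch there and another
same-type mismatch position lies within `cluster_window` (default 100 bp),
or when a single position alone is supported by `min_edited_reads` reads of
one conversion.

Only the intersection of the two arms is carried forward; support counts
are always taken from the pileup, never from detector-internal tallies, so
the two arms cannot disagree about *k* and *n*.

**Unit of analysis.** A *sample* is one (genotype, condition) combination.
Its replicates are merged for discovery — at organelle mapping rates a
single replicate's organelle coverage is limiting — and re-examined
individually for the replicate-presence screen. Pooled support is the sum
of per-replicate counts, the exact equivalent of calling on a merged
alignment.

**Background subtraction.** Genomic SNPs shared between DNA and RNA must
not be called as editing. Two modes are provided because control samples
can be read either as pure background or as biological samples in their own
right:

* `fixed_allele` (default) removes a candidate from all samples of a
  genotype when its alternative-allele fraction is ≥ `snp_fixation_threshold`
  (default 0.95) in every sample of that genotype with depth ≥ `min_depth`
  — the signature of a homozygous SNP. Partial-frequency sites shared by
  control and treated samples survive as constitutive editing, so control
  samples retain reportable calls.
* `difference` removes treated-sample candidates present at any support in
  the genotype's control, the strict stressed-minus-control reading; it
  also removes constitutive editing from treated samples by construction.

The 0.95 threshold is tested on per-sample merged pileups (~150× at the
default 50× per replicate), where a true homozygous SNP fails it with
probability ≪ 10⁻⁴ at a 0.5% error rate.

**Screens.** Final sites must have (1) strictly more than five pooled
edited reads, (2) a pooled edited/total ratio strictly above `min_ratio`
(default 0.5), and (3) at least one edited read in every replicate (when
`require_all_replicates` is on). The "more than five edited reads" screen
is deliberately read as site-level read support; a per-read cap on edit
counts would discard evidence rather than require it, and is available
separately as `max_edits_per_read` (off by default). With defaults, the
screens are strictly stronger than either detector on the pooled pileup,
which is what makes the literal brute-force oracle comparison in the tests
an exact-equality check rather than an approximation.

**Efficiency.** Editing efficiency is k/n on the pooled sample pileup,
undefined (missing) at zero depth. At 150× pooled depth its binomial
standard error is ≤ 0.041, which bounds the achievable RMSE against planted
truth.

## Read and base filters

Duplicate-flagged reads and mapping quality < 20 are excluded from pileups
(configurable); base calls below Q20 and N bases never count as reference
or edited support. Coordinates are 1-based inclusive everywhere, in memory
and in every emitted artifact, matching GFF3 and VCF.

## Annotation

Conversions are reported both as observed on the forward reference strand
and strand-corrected onto the hosting gene's coding strand; a forward G>A
over a minus-strand gene is a biological C-to-U. Whether forward G>A calls
outside gene context are antisense C-to-U events or artefacts cannot be
decided from read data alone, so intergenic sites keep their forward-strand
reading and the class `other`.

Gene context uses 5 kb upstream/downstream windows (the default window of
common effect predictors); the nearest qualifying gene wins, ties go to the
smaller start coordinate. Codon position is counted along the coding strand
of the joined CDS, honoring the phase of the first part in coding order.
Consequences come from translating the reference and edited codon under the
standard genetic code — the code used by plant mitochondria and plastids —
with the table id configurable. `start_lost` is emitted only when the
initiator codon loses Met; internal ATG codons are ordinary missense
targets. Stop codons contain no C, so C-to-U edits never produce
`stop_lost`; the label exists for completeness.

Amino-acid classes (hydrophobic G A V L I M F W; neutral P S T C Y N Q;
hydrophilic D E K R H) ship as a YAML config, not hard-coded, so an
alternative scale (e.g. Kyte–Doolittle binning) can be substituted; under
the default table the canonical organellar changes Pro→Leu, Pro→Ser,
Thr→Ile and Ser→Leu are neutral→hydrophobic or neutral→neutral as expected.

## Synthetic data

The generator emulates the target study design: two genotypes × two
conditions × three replicates on a compact organelle genome. Defaults:
20 kb genome, 12 non-overlapping stranded CDS genes of 300–900 bp (lengths
multiples of 3), 40 constitutive + 20 stress-gain C-to-U edits with
efficiencies drawn from Beta(4, 2) (mean 2/3, the upper-half skew typical
of organellar editing), 20 genomic SNPs at allele frequency 1.0, 100 bp
all-match reads at 50 reads/base mean coverage (uniform placement, hence
per-site Poisson coverage), and independent miscalls at 0.005/base to a
uniformly chosen other base. `efficiency_min` truncates the Beta law from
below (0 by default; the parameter-recovery experiments use 0.55 so that
every planted edit is recoverable in principle under the >50% ratio
screen). An optional `n_a_to_i_edits` plants the minor A-to-I class the
same way. One master seed drives named child streams (reference, planting,
each genotype × condition × replicate), so replicates differ but the whole
experiment is bit-reproducible.

What the simulation does **not** model: mapping ambiguity between organelle
and nuclear copies (numts/plastid insertions), strand-specific library
artefacts, indels and splicing, coverage autocorrelation along transcripts,
and quality-score miscalibration. Passing the recovery tests therefore
demonstrates the correctness of the counting, testing and screening logic
under the stated error model — not robustness to alignment artefacts,
which upstream mapping QC must provide on real data.

## Expression and group statistics

FPKM = count × 10⁹ / (length_bp × total_mapped). Log fold change is
log₂((FPKM_t + c)/(FPKM_c + c)) with pseudocount c = 1 on the FPKM scale to
tame zeros (configurable). qPCR relative quantification averages replicate
Ct vectors on the Ct scale, then ΔΔCt = (Ct_target − Ct_ref)_treated −
(Ct_target − Ct_ref)_control and fold = 2^−ΔΔCt; the exponent sign is a
flag because the unsigned notation also circulates. Efficiency groups are
compared with Welch's unequal-variance two-sided t-test (the safer default
when variances differ between conditions), with stars at p < 0.05/0.01/0.001;
two exactly constant groups are handled as the zero-variance limit (p = 1
when means agree, p = 0 otherwise). Per-gene read counting assigns a read
to a gene on ≥ 1 bp overlap and discards reads touching two or more genes
as ambiguous. Differential-expression significance testing is out of scope;
the tables are consumable by dedicated DE tools.

## Summary-table fixtures

The packaged fixtures transcribe the study's printed per-(organelle,
sample) site totals and the per-gene (sample, gene, conversion, occurrence)
table verbatim, including four inconsistent gene spellings (`rsp2`,
`rsp12`, `apt6`, `apt1`); an explicit alias map normalises them, and only
then do the printed distinct-gene tallies (mitochondria 19/23/19/20)
reproduce. Chloroplast edited-gene counting uses (gene, type)-entry
convention, mitochondria distinct-gene convention — the pair of conventions
under which the printed totals are internally consistent. The `occurrence`
column is carried through as sites-per-gene-per-sample, not re-derived from
sequence. The per-conversion fixture uses the per-organelle breakdown
(chloroplast A>G = 20), which is the self-consistent variant of the printed
totals.

## Problem sizes and determinism

The shipped test-suite and acceptance-script experiments run at the design
scale of the emulated study (20 kb × 50× × 12 samples) or below (3–9 kb
instances for oracle-equivalence sweeps over 20 seeds); these sizes give
pooled depths (~150×) at which every acceptance margin has several standard
deviations of headroom, and complete in seconds on one core. All
randomness flows from explicit seeds; re-running any pipeline with the same
config and seed reproduces byte-identical TSV outputs.

## Known limitations

* Plain SAM input only (desk-scale; a BAM adapter would be a thin addition).
* Substitution-only detection; reads with indels contribute their matched
  bases but indel editing is not called.
* The read-cluster arm is a deliberately simple re-statement of
  cluster-based editing callers; it does not re-map reads against an edited
  transcriptome.
* `difference` background mode removes constitutive editing from treated
  samples by design; interpret per-sample totals under that mode
  accordingly.
* Multi-allelic positions are excluded, so a site that is simultaneously a
  low-frequency SNP and an edit is not callable.
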