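# Methods

This note documents the models and procedures implemented in `mhce`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The synthetic study and its conditions

All stages are exercised against data from `mhce.simulate`, which emulates
the structure of an MHC-E vaccine-cohort study rather than any particular
sequencing run. The generator's defaults *are* the study conditions; they
are not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_animals` | 59 | cohort size (the genotyping table's total) |
| `allele_config_counts` | 27/20/5/6/1 | animals with G1 only / +G3 / +G2 / +G2_LTR / +G2+G2_LTR |
| `g2_divergence` | 0.05 | substitution rate of the G2/G2_LTR ancestors from the G1 amplicon |
| `ltr_length`, `ltr_offset` | 700 bp, 20 bp | solo-LTR insertion defining G2_LTR |
| `g3_deletion_length` | 600 bp | deletion spanning most of intron 5 and all of exon 6 (G3) |
| `n_exons` | 8 | canonical locus structure |
| `canonical_isoform_fraction` | 0.75 | molar share of the canonical isoform (FL support ~75%) |
| `fl_depth` / `human_fl_depth` | 123 / 2050 | full-length read depths of the two catalogs |
| `coverage_mean` | 10,000 | pooled per-base mRNA-seq coverage of the locus |
| `connection_error_rate` | 0.02 | fraction of variant-connection reads supporting a wrong phase |
| `n_samples_per_animal` | 9 | pre-challenge timepoints (W0D0 … W88D0) |
| `ld_cluster_sizes` | 21, 18, 4, 4, 2, 1×6 | planted LD clusters among the 55 common variants |
| `n_rare_variants` | 58 | additional variants kept below the MAF filter (113 total) |
| `group_expression_props` | G2 0.25, G2_LTR 0.125, G3 0.05 | expression shares of the non-G1 groups |

The eight-exon locus uses fixed exon lengths (130, 270, 276, 276, 120, 33,
48, 1500 nt) and intron lengths (120, 200, 250, 400, 600, 100, 150 nt),
chosen so that internal coding exons are codon-sized (clean exon skipping),
intron 4 is frame-breaking when retained (400 mod 3 ≠ 0), and intron 5 can
absorb a 600 bp deletion that removes exon 6 without touching exon 5. GT–AG
motifs are planted at every junction, an ATG 72 nt before the end of exon 1
starts the ORF, the canonical stop sits 12 nt into exon 8 (in-frame stops
upstream are scrubbed), and a 20 nt poly-A tract mid-way through the 3' UTR
provides an intrapriming site for curation fixtures. The macaque catalog
holds the canonical model plus 12 alternatives drawn from a fixed event
menu (exon skips, a retained intron, an intron-5 exonization, 3' UTR
splits, and combinations); the human locus is the macaque locus mutated at
5% (junctions protected) with three planted indels in intron interiors and
upstream sequence, and its catalog is the lifted macaque catalog plus 7
human-only models (first-intron retentions, extra UTR splits) — so every
macaque junction chain exists in the human catalog by construction, at a
deliberately scaled-down catalog size (20 vs the tens of isoforms a real
human dataset yields).

Cohort structure: animals are assigned to outcome × vaccine-group strata in
the packaged genotyping-table layout (when the configuration counts match
its totals) and shuffled by seed. Each animal carries two G1 haplotypes.
Within each LD cluster every variant shares one Bernoulli "form" indicator
per chromosome (cluster frequency ~U(0.2, 0.45)), which makes within-cluster
r exactly ±1 and across-cluster r small; rare variants get 1–7 carrier
chromosomes, pinning their MAF under the 0.1 filter. Carriers of G2,
G2_LTR and G3 have one haplotype forced to a designated big-cluster form,
which both plants complete linkage between each non-G1 group and one G1
subtype label and mildly correlates the two major clusters (measured
|r| ≈ 0.13, far from the clustering cut). Haplotype expression imbalance is
drawn once per animal (hap-1 share ~U(0.56, 0.70)) and jittered per sample
(SD 0.02, clipped ≥ 0.52) so the dominant haplotype is consistent across
samples — the signal the block-merging rule relies on.

What the generator does **not** emulate: read-level sequences (evidence is
summarized counts), mapping bias and repeat-driven multimapping (the k-mer
blacklist stage therefore usually masks nothing on synthetic data),
indel variants in the phased variant set (all planted variants are SNPs;
the variant-effect tally handles indel types but the cohort does not plant
them), within-group allelic polymorphism beyond the two G1 haplotypes, and
any longitudinal change in expression. Passing tests therefore demonstrate
the correctness of the algorithms under the stated noise model, not
robustness to alignment artifacts of real mRNA-seq.

## Isoform curation

Junction correction snaps a model junction to a canonical junction when
both donor and acceptor lie within `max_shift` (default 10 bp, nearest
wins) and, when the locus sequence is supplied, the canonical site carries
the GT–AG motif. A snap that would empty an exon is refused and flagged.
The canonical junction set must come from the reference annotation, not
from the raw catalog's own canonical model (which may itself be
misaligned). Intrapriming uses the downstream 20 bp window and A-fraction
0.6 on the transcript strand; rescue copies the furthest 3' end among
junction-identical, non-intraprimed models. End clustering is
single-linkage on gaps ≤ 50 nt, per locus across all isoforms regardless
of junction chain, members snapping to the annotation-extending extreme.
The driver runs correct → rescue → collapse → cluster → collapse; it is
deterministic, idempotent, and conserves total FL support. On raw catalogs
built from truth with ≤ 3 bp jitter at canonical junctions, an intraprimed
truncation, and near-duplicate ends, it recovers the true catalog exactly
(the generator only jitters junctions shared with the canonical chain,
since nothing anchors a wholly novel junction).

ORF annotation translates from the canonical start in spliced coordinates
and maps retained coding positions back to canonical exons for domain
labels (exon 1 signal peptide, 2–4 the α1–α3 domains, 5 transmembrane,
6–7 cytoplasmic, 8 mostly 3' UTR). Frameshift is structural: any genomic
position of the canonical CDS retained by the model at a different
spliced-frame offset. "Premature stop" means the translated protein is
shorter than canonical, which includes frame-preserving exon skips that
reach the canonical stop early.

## Cross-species comparison

The coordinate map is built column-by-column from one pairwise global
alignment (any aligner; a Needleman–Wunsch helper via Biopython's
`PairwiseAligner` is included for fixtures) and is strictly monotone by
construction. A model lifts only if every exon boundary maps; otherwise it
is flagged rather than partially converted. Perfect isoform match =
identical junction chain; ends are ignored because they are subject to the
50 nt clustering. Rarefaction draws `depth` reads (default 123) with
replacement, 10,000 replicates, and reports mean/SD of distinct isoforms;
the closed form Σᵢ 1−(1−pᵢ)^depth is kept as an independent oracle.

## Allele typing

Classification precedence is structural first: LTR insertion → G2_LTR;
exon-6 deletion → G3; then the divergence band [0.02, 0.10] → G2; beyond
0.20 → unassigned with a warning; otherwise G1. Divergence is
substitutions over aligned columns (indels excluded), measured after
excising a detected LTR so the insertion cannot masquerade as divergence.
Repeat detection is true local alignment (Smith–Waterman, match 2,
mismatch −3, gap −5/−2) of each library consensus against the 5' upstream
segment — a semi-global scan would misscore partial fragments — requiring
span ≥ 500 bp and identity ≥ 0.8. Deletion detection aligns the allele to
the reference with edlib; because unit-cost edit distance fragments long
deletions around chance one-base matches, deletion runs separated by ≤ 20
matched bases are merged before testing that a run ≥ 400 bp contains the
whole exon-6 interval.

Trees: neighbor joining follows the Saitou–Nei Q-criterion with
lowest-index tie-breaking and branch lengths clamped at zero (additive
matrices are recovered exactly). Maximum-likelihood refinement uses
Jukes–Cantor likelihood via Felsenstein pruning on compressed site
patterns, per-edge bounded Brent branch-length optimization, and NNI hill
climbing that accepts the first improving rearrangement and stops when
none improves; the returned likelihood never falls below the input's.
Classical MDS is Torgerson double-centering on distance = 1 − identity,
dropping negative-eigenvalue components with a warning. Multiple alignment
is an input contract: identity and tree functions consume pre-aligned
sequences.

## Phasing

Transcript ends with pooled coverage below 10,000× are trimmed (ends only;
interior dips are retained). Bases with ≥ 25% of coverage (inclusive) are
called; one call is homozygous, two heterozygous, more demotes the
position. Phasing builds a maximum-spanning forest over heterozygous pairs
weighted by total connection support and propagates each edge's majority
configuration from an arbitrary root; ties resolve to the parallel
configuration, and no statistical pruning of edges is applied. Conflict
screening averages, per variant, the conflicting-read fraction over
in-block edges with ≥ 100 reads and demotes variants above 20% to IUPAC
ambiguity. Block merging pairs the higher-coverage haplotypes per sample
and requires the identical orientation in *all* samples; a sample with
exactly tied coverages vetoes the merge. "Phased fraction" counts
heterozygous calls in the primary block net of demotions; comparisons with
truth are always made up to a global flip. Haplotig–allele matching is
greedy by fewest mismatches over the comparable region (excluding masked
positions), after collapsing haplotigs that differ only at 3' UTR
positions.

## Expression

The EM treats equivalence-class counts as a mixture over isoforms with
length-normalized assignment: within class C a read is credited to member
i with weight θᵢ/ℓᵢ (θ read fractions, ℓ effective length = transcript
length; no fragment-length modeling). Reported proportions are molar
(θᵢ/ℓᵢ renormalized). Convergence: max θ change < 1e−8 or 1000 iterations;
the log-likelihood Σ_C n_C log Σ_{i∈C} θᵢ/ℓᵢ is non-decreasing by the EM
construction. Uncertainty comes from 25 multinomial bootstrap resamples of
the class counts; the point estimate is the renormalized bootstrap mean.
This is consistent with the generator, which draws reads per isoform
∝ pᵢℓᵢ and assigns them to fixed-width (100 nt) shared-junction regions or
the isoform-unique remainder — under that model the EM's fixed point is
the truth, and with 10⁵ reads the per-isoform recovery error is < 0.01.
A class region must be common to all its members for the mixture to be
well-specified; class schemes with member-dependent region sizes bias the
estimates, which is why the generator uses junction windows of one fixed
width. TPM is locus-restricted (proportion × 10⁶ over the locus contigs
only), since inputs are locus-level counts.

Rank-sum trend tests are exact (Mann–Whitney enumeration) for untied
samples up to n = 12 per group and normal-approximated with tie correction
otherwise; all-tied inputs return p = 1.

## Association

MAF filtering is strict (> 0.1). LD uses phased haplotypes directly:
D = p_AB − p_A p_B and r = D/√(p_A q_A p_B q_B) (equivalently the Pearson
correlation of the binary haplotype vectors). Variant clustering is
complete-linkage on distance 1 − r², cut at height 0.35, with a post-pass
splitting any size-2 cluster whose pair is not in complete LD into
singletons; the metric is configurable (1 − r, 1 − |r|, 1 − r²) because a
cut at 0.35 "implicitly requiring correlation 0.9" is only internally
consistent for the 1 − r² form among these (0.35 ≈ 1 − 0.81), which is why
1 − r² is the default.

Fisher 2×2 is the probability-mass-at-most-observed two-sided convention
(scipy's implementation, validated against exhaustive hypergeometric
enumeration for every table with total ≤ 30). The RxC test enumerates all
tables with the observed margins recursively (budget-capped) and sums
probabilities ≤ the observed (relative tolerance 1e−7); a seeded
permutation Monte-Carlo mode covers larger tables. BH is the step-up
q-value with capping. Genotype scans collapse 0/1/2 minor-allele dosages
to homozygous-major vs carrier, test against protection outcome within the
O/S/X vaccine groups (or against vaccine group across all four), and apply
BH per scan.

A permutation check of the cluster scan's type-I behaviour is part of the
test and acceptance runs: over 1000 outcome permutations the rejection
rate at α = 0.05 measures ≈ 0.03, not 0.05. That is the expected behaviour
of a valid exact test on discrete tables — attainable p-values below 0.05
are sparse, so P(p ≤ 0.05) sits below the nominal level — and it is
reported as measured rather than adjusted away (a mid-p or randomized test
would trade exactness for calibration and is not used here).

Hydropathy profiles use the Kyte–Doolittle scale with a 9-residue window
centered on each residue and truncated at the ends (one score per residue)
and positions normalized to [0, 1] by i/(L−1). SAP counting translates
reference and alternate codons at in-CDS SNPs and deduplicates identical
amino-acid changes.

## Problem sizes and determinism

The default test and acceptance runs use the full 59-animal cohort for
typing, phasing and association (~2,000 heterozygous calls phased,
~45 connection pairs × 9 samples per animal), one animal-timepoint for the
in-cohort EM example plus a dedicated 10⁵-read EM recovery run, 10,000
rarefaction replicates, and 1000 scan permutations; the whole acceptance
script completes in roughly half a minute on one CPU. Every stochastic
step takes an explicit seed or generator; regenerating a bundle with the
same seed is byte-identical, and derived seeds stay below 2³¹.

## Known limitations

- The phaser assumes summarized connection counts; it does not model
  read-length distributions, so connectivity is governed by the
  generator's 400 bp span rule plus coverage, not by splice-aware reads.
- ML tree search is adequate for tens of taxa; it re-optimizes branch
  lengths per NNI candidate with short sweeps and would be slow for
  hundreds of leaves.
- The RxC exact test is enumeration-based and intended for the cohort's
  small tables (total ≤ ~100); larger tables need the Monte-Carlo mode.
- Divergence-based typing assumes amplicons are globally alignable to the
  G1 reference; chimeric or heavily rearranged alleles would be flagged
  unassigned rather than resolved.
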