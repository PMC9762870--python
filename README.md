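# mhce

Analysis toolkit for the genetics and alternative splicing of the
non-classical MHC class Ib locus **MHC-E** (*HLA-E* in humans, *Mamu-E* in
rhesus macaques), built around a fully synthetic cohort generator so that
every stage is testable end to end with known ground truth.

MHC-E restricts the unconventional CD8+ T-cell responses elicited by
CMV-vectored SIV vaccines in rhesus macaques, which makes its isoform
repertoire, allelic structure, and gene duplications directly relevant to
vaccine-protection phenotypes. The package implements the computational
side of such a study:

- **Isoform curation** — long-read transcript models are corrected against
  the reference annotation (splice junctions snapped within a 10 bp window
  onto canonical GT–AG sites), 3' ends truncated by intrapriming (oligo-dT
  mispriming on genomic A-rich tracts; A-fraction ≥ 0.6 in the downstream
  20-mer) are rescued from junction-identical models, redundancies are
  collapsed with full-length (FL) read support summed, and transcript
  start/end sites are clustered single-linkage within 50 nt, each member
  taking the annotation-extending extreme.
- **Cross-species comparison** — the two species' loci are aligned once;
  the alignment defines a monotone coordinate converter used to lift exon
  coordinates, compare catalogs junction-by-junction (perfect match =
  identical junction chain), infer incomplete 5' ends from matched models,
  and compare spliceosome complexity by resampling FL counts at a fixed
  depth (10,000 replicates; mean/SD of distinct isoforms detected,
  E = Σᵢ 1−(1−pᵢ)^depth in closed form).
- **Allele typing** — ~3.2 kb amplicon haplotypes are classified into four
  structural groups: G1 (reference-like), G2 (~5% diverged; divergence band
  0.02–0.10 over aligned columns), G2_LTR (G2 plus a ~700 bp solo LTR
  insertion ~20 bp after the amplicon 5' end; local repeat-library match,
  span ≥ 500 bp, identity ≥ 0.8), and G3 (a 600 bp deletion removing exon 6;
  alignment gap ≥ 400 bp containing the exon-6 span). Relationships are
  summarized by per-segment identity matrices, classical (Torgerson) MDS,
  and neighbor-joining / Jukes–Cantor maximum-likelihood trees with NNI
  search.
- **RNA-seq haplotype phasing** — heterozygous base calls (≥ 25% of
  coverage, after trimming transcript ends below 10,000× pooled coverage
  and masking multimapping-prone regions by 76-mer uniqueness) are phased
  over a maximum-spanning forest of pairwise read connections with
  majority-configuration propagation; blocks merge only on a unanimous
  per-sample dominant-haplotype orientation across all 9 samples; variants
  averaging > 20% conflicting connections (over edges with ≥ 100 reads) are
  demoted to IUPAC ambiguity codes; the primary block is expanded with
  homozygous calls into two full-length *haplotigs*, which are then matched
  greedily (fewest mismatches first) to amplicon alleles and merged across
  the exon 7–8 intron into contiguous allele sequences with 3' UTRs.
- **Expression** — allele-group proportions from per-group read counts,
  within-group allelic counts from variant-overlap read tags, and relative
  isoform abundances by EM over equivalence classes (length-normalized
  assignment, 25 multinomial bootstraps, point estimate = bootstrap mean),
  plus Spearman correlations and exact Wilcoxon rank-sum trend tests.
- **Association** — minor-allele-frequency filtering (MAF > 0.1), pairwise
  LD (D = p_AB − p_A p_B, r = D/√(p_A q_A p_B q_B)) on phased haplotypes,
  complete-linkage clustering of variants on 1 − r² cut at 0.35 (size-2
  clusters not in complete LD split), Fisher exact tests (2×2 and exact
  RxC by enumeration, seeded Monte-Carlo fallback) with Benjamini–Hochberg
  FDR, duplication/protection tests, Kyte–Doolittle hydropathy profiles of
  the transmembrane domain, and per-region variant/SAP tallies.

The **synthetic generator** (`mhce.simulate`) emulates the study design: a
59-animal cohort whose allele configurations follow the packaged
genotyping table (27 exclusively G1 / 20 with G3 / 5 with G2 / 6 with
G2_LTR / 1 with both), 9 pre-challenge samples per animal, ~10⁴× locus
coverage, 2% connection error, 113 variants organized into LD clusters of
sizes 21, 18, 4, 4, … and group expression shares of ~25% (G2), ~12.5%
(G2_LTR) and ~5% (G3). Everything derives from a single seed and
regenerates byte-identically.

## Worked example

```bash
mhce associate --seed 1 --out assoc.json
# G2_LTR vs protection p = 0.0211
```

`assoc.json` then contains:

```json
{
 "cluster_sizes": [21, 18, 4, 4, 2, 1, 1, 1, 1, 1, 1],
 "duplication_protection_p": 0.7596704429215754,
 "g2ltr_protection_p": 0.02113966577948427,
 "min_cluster_q": 1.0,
 "n_pass_maf": 55,
 "n_variants": 113
}
```

Reading: of 113 planted G1 variants, 55 pass the MAF > 0.1 filter; LD
clustering recovers the planted cluster structure exactly (two major
clusters of 21 and 18 variants); carrying a G2_LTR allele associates with
lack of protection among the O/S/X vaccine groups at p ≈ 0.021 (printed as
0.02 at two decimals), while overall locus duplication does not (p ≈ 0.76),
and no individual variant cluster reaches significance after FDR
correction (min q = 1.0) — the generator plants no genotype–outcome effect
beyond the G2_LTR configuration margins.

Other subcommands: `mhce sim` (write all synthetic inputs + truth),
`curate`, `crossmap`, `type-alleles`, `phase`, `express`, `report`.
Every stage is also available as a library function under
`mhce.pipeline`.

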