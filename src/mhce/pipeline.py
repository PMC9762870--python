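"""End-to-end analysis stages over generated (or equivalently formatted)
inputs: phasing per animal, cohort allele typing, group expression and EM
isoform abundance, and the variant-genetics/association scan.

Each ``run_*`` function consumes the generator's truth bundle or the file
representations written from it, and returns plain result objects; the CLI
is a thin wrapper over these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alleles as al
from . import association as assoc
from . import expression as expr
from . import phasing as ph
from .simulate import CohortTruth, PhasingObservations, SimConfig, TruthBundle

__all__ = [
    "PhasingResult", "run_phasing_animal", "run_phasing",
    "run_typing", "run_expression", "build_variant_records",
    "run_association", "load_genotyping_table",
    "genotyping_tallies", "g2ltr_protection_table",
]


def load_genotyping_table() -> pd.DataFrame:
    """Packaged cohort genotyping table, expanded to one row per animal.

    Columns: animal, vaccine_group, outcome, allele_config.
    """
    from importlib import resources
    with resources.files("mhce").joinpath(
            "data/genotyping_table.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    configs = [c for c in table.columns
               if c not in ("outcome", "vaccine_group")]
    rows = []
    for _, row in table.iterrows():
        for cfg in configs:
            rows.extend(
                (row["vaccine_group"], row["outcome"], cfg)
                for _ in range(int(row[cfg])))
    return pd.DataFrame(
        [(f"A{k + 1:03d}", g, o, c)
         for k, (g, o, c) in enumerate(rows)],
        columns=["animal", "vaccine_group", "outcome", "allele_config"])


# ---------------------------------------------------------------------------
# phasing


@dataclass
class PhasingResult:
    animal: str
    retained: tuple
    calls: list
    blocks: list
    primary: ph.HaplotypeBlock
    haplotigs: tuple
    n_het: int
    n_phased: int

    @property
    def phased_fraction(self) -> float:
        return self.n_phased / self.n_het if self.n_het else 1.0


def run_phasing_animal(obs: PhasingObservations, reference: str,
                       min_cov: int = 10000, call_fraction: float = 0.25,
                       min_support: int = 100, max_conflict: float = 0.20
                       ) -> PhasingResult:
    """Phase one animal from summarized observations.

    Trims low-coverage transcript ends, calls bases at the fractional
    threshold, phases heterozygous calls over the connection graph
    (maximum-spanning forest, majority propagation), screens conflicting
    variants, merges blocks by unanimous per-sample coverage orientation,
    and expands the primary block into two haplotig sequences.
    """
    lo, hi = ph.pool_and_trim_coverage(obs.coverage, min_cov=min_cov)
    idx = np.arange(lo, hi)
    calls = ph.call_bases(obs.base_counts[lo:hi], positions=idx,
                          call_fraction=call_fraction)
    call_by_pos = {c.position: c for c in calls}
    het = [c for c in calls if c.zygosity == "het"]
    het_pos = {c.position for c in het}

    graph = ph.ConnectionGraph()
    for row in obs.connections.itertuples(index=False):
        pi, pj = int(row.pos_i), int(row.pos_j)
        if pi not in het_pos or pj not in het_pos:
            continue
        ci, cj = call_by_pos[pi], call_by_pos[pj]
        try:
            a = ci.bases.index(row.base_i)
            b = cj.bases.index(row.base_j)
        except ValueError:
            continue          # read supports an uncalled base
        mat = np.zeros((2, 2))
        mat[a, b] = row.count
        graph.add(row.sample, pi, pj, mat)

    blocks = ph.phase_blocks(graph, het_positions=het)
    blocks = [ph.screen_conflicts(b, graph, min_support=min_support,
                                  max_conflict=max_conflict)
              for b in blocks]
    blocks = [b for b in blocks if b.positions]

    depths: dict = {}
    for row in obs.allele_depths.itertuples(index=False):
        pos = int(row.pos)
        if pos not in het_pos:
            continue
        c = call_by_pos[pos]
        if row.base not in c.bases:
            continue
        d = depths.setdefault(row.sample, {}).setdefault(pos, [0.0, 0.0])
        d[c.bases.index(row.base)] += row.count

    def coverage_fn(block):
        return ph.block_haplotype_coverage(block, depths)

    if len(blocks) > 1:
        blocks = ph.merge_blocks(blocks, coverage_fn)
    if not blocks:
        primary = ph.HaplotypeBlock(positions=[], orientation={}, calls={})
    else:
        primary = max(blocks, key=lambda b: len(b.positions))
    haplotigs = ph.expand_haplotigs(primary, calls, reference)
    n_het = len(het)
    demoted = set(primary.ambiguous)
    n_phased = len([p for p in primary.positions if p not in demoted])
    return PhasingResult(animal=obs.animal, retained=(lo, hi), calls=calls,
                         blocks=blocks, primary=primary,
                         haplotigs=haplotigs, n_het=n_het,
                         n_phased=n_phased)


def run_phasing(bundle: TruthBundle, animals=None) -> dict:
    obs = bundle.phasing or {}
    if animals is None:
        animals = list(obs)
    return {a: run_phasing_animal(obs[a], bundle.cohort.transcript_ref)
            for a in animals}


# ---------------------------------------------------------------------------
# typing


def run_typing(bundle: TruthBundle,
               thresholds: al.TypingThresholds | None = None) -> dict:
    """Classify every cohort allele; report per-allele calls and accuracy."""
    locus = bundle.locus
    cohort = bundle.cohort
    amp_s, amp_e = locus.amplicon
    e6 = (locus.exon6[0] - amp_s, locus.exon6[1] - amp_s)
    upstream_end = locus.exons[0][0] - amp_s
    library = {"LTR5B": locus.repeat_library["LTR5B"]}
    g1_refs = [cohort.amplicon_ref]
    calls, correct = {}, 0
    for animal in cohort.animals:
        for allele_id, seq in cohort.allele_seqs[animal].items():
            region_end = upstream_end
            if len(seq) > len(cohort.amplicon_ref):
                region_end += len(seq) - len(cohort.amplicon_ref)
            allele = al.AlleleSequence(
                allele_id=allele_id, animal_id=animal, sequence=seq,
                segments={"5p_upstream": (0, region_end + 50)})
            call = al.classify_allele_group(
                allele, g1_refs, library, cohort.amplicon_ref, e6,
                thresholds)
            calls[allele_id] = call
            if call.group == cohort.allele_labels[allele_id]:
                correct += 1
    accuracy = correct / len(calls) if calls else 1.0
    cohort_calls = {
        a: {"groups": set(cohort.allele_groups[a]),
            "g1_subtypes": set(cohort.g1_subtypes[a])}
        for a in cohort.animals}
    linkage = al.detect_group_linkage(cohort_calls)
    return {"calls": calls, "accuracy": accuracy, "linkage": linkage}


# ---------------------------------------------------------------------------
# expression


def run_expression(bundle: TruthBundle, em_samples: int = 1,
                   n_bootstrap: int = 25, seed: int = 0) -> dict:
    """Group proportions per sample and EM isoform abundances.

    EM is run on the first ``em_samples`` animal/timepoint class tables
    (they share the truth proportions; one suffices for recovery checks).
    """
    ex = bundle.expression
    gc = ex["group_counts"]
    prop_rows = []
    for (animal, tp), sub in gc.groupby(["animal", "timepoint"],
                                        sort=True):
        counts = dict(zip(sub["group"], sub["count"]))
        props = expr.group_proportions(counts)
        for g, p in props.items():
            prop_rows.append((animal, tp, g, p))
    props_df = pd.DataFrame(prop_rows,
                            columns=["animal", "timepoint", "group",
                                     "proportion"])
    lengths = ex["isoform_lengths"]
    cc = ex["class_counts"]
    abundances = {}
    keys = list(cc.groupby(["animal", "timepoint"], sort=True).groups)
    for key in keys[:em_samples]:
        sub = cc[(cc["animal"] == key[0]) & (cc["timepoint"] == key[1])]
        classes: dict = {}
        for c, n in zip(sub["class"], sub["count"]):
            key_c = frozenset(c.split(","))
            classes[key_c] = classes.get(key_c, 0) + int(n)
        abundances[key] = expr.em_abundance(classes, lengths=lengths,
                                            n_bootstrap=n_bootstrap,
                                            seed=seed)
    return {"group_proportions": props_df, "abundances": abundances}


# ---------------------------------------------------------------------------
# association


def build_variant_records(cohort: CohortTruth) -> tuple:
    """Variant records (minor-allele dosage) and the haplotype matrix."""
    animals = cohort.animals
    hap_matrix = np.stack([cohort.haplotypes[a][h]
                           for a in animals for h in (0, 1)])
    n_var = hap_matrix.shape[1]
    records = []
    minor = np.zeros_like(hap_matrix)
    for k in range(n_var):
        col = hap_matrix[:, k]
        freq = col.mean()
        minor_col = col if freq <= 0.5 else 1 - col
        minor[:, k] = minor_col
        dosage = minor_col.reshape(-1, 2).sum(axis=1)
        records.append(assoc.VariantRecord(
            variant_id=f"v{k:03d}", position=cohort.variant_positions[k],
            vtype="SNP", ref=cohort.variant_ref[k],
            alt=cohort.variant_alt[k], genotypes=dosage))
    return records, minor


def run_association(bundle: TruthBundle, maf_threshold: float = 0.1,
                    cut_height: float = 0.35) -> dict:
    """MAF filter, LD clustering, and protection/vaccine-group scans."""
    cohort = bundle.cohort
    records, minor_haps = build_variant_records(cohort)
    kept = assoc.maf_filter(records, threshold=maf_threshold)
    kept_idx = [int(v.variant_id[1:]) for v in kept]
    r = assoc.ld_matrix(minor_haps[:, kept_idx])
    clusters = assoc.cluster_variants(r, [v.variant_id for v in kept],
                                      cut_height=cut_height)

    meta = cohort.metadata.set_index("animal").loc[cohort.animals]
    outcome = meta["outcome"].to_numpy()
    vgroup = meta["vaccine_group"].to_numpy()
    osx = np.isin(vgroup, ["O", "S", "X"]) & \
        np.isin(outcome, ["protected", "not_protected"])

    geno_by_id = {v.variant_id: v.genotypes for v in kept}
    cluster_geno = {}
    for cl in clusters:
        rep = cl.members[0]
        cluster_geno[f"cluster{cl.cluster_id:02d}"] = geno_by_id[rep]
    scan_variants = assoc.genotype_association_scan(
        geno_by_id, outcome, scope=osx)
    scan_clusters = assoc.genotype_association_scan(
        cluster_geno, outcome, scope=osx)

    groups_by_animal = {a: set(cohort.allele_groups[a])
                        for a in cohort.animals}
    dup = assoc.duplication_association(groups_by_animal, outcome,
                                        scope=osx)
    g2ltr = assoc.duplication_association(groups_by_animal, outcome,
                                          scope=osx,
                                          target_groups=("G2_LTR",))
    return {
        "records": records, "kept": kept, "r_matrix": r,
        "clusters": clusters, "scan_variants": scan_variants,
        "scan_clusters": scan_clusters, "duplication": dup,
        "g2ltr": g2ltr, "scope_osx": osx,
    }


# ---------------------------------------------------------------------------
# genotyping-table worked examples


def genotyping_tallies(metadata: pd.DataFrame) -> dict:
    """Column tallies of the genotyping table."""
    cfg = metadata["allele_config"]
    return {
        "exclusive_g1": int((cfg == "G1").sum()),
        "g2_carriers": int(cfg.str.contains("G2(?!_)", regex=True).sum()),
        "g2ltr_carriers": int(cfg.str.contains("G2_LTR").sum()),
        "g3_carriers": int(cfg.str.contains("G3").sum()),
        "duplicated": int((cfg != "G1").sum()),
    }


def g2ltr_protection_table(metadata: pd.DataFrame) -> np.ndarray:
    """2x2 table: G2_LTR presence x protection outcome, groups O/S/X.

    Rows: G2_LTR absent / present; columns: protected / not protected.
    """
    sub = metadata[metadata["vaccine_group"].isin(["O", "S", "X"])
                   & metadata["outcome"].isin(["protected",
                                               "not_protected"])]
    has = sub["allele_config"].str.contains("G2_LTR")
    prot = sub["outcome"] == "protected"
    return np.array([
        [int((~has & prot).sum()), int((~has & ~prot).sum())],
        [int((has & prot).sum()), int((has & ~prot).sum())],
    ])
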