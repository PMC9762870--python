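"""Synthetic cohort and data generator with known ground truth.

Emulates the structure of a rhesus MHC-E vaccine-cohort study: an 8-exon
canonical locus with alternatively spliced isoforms dominated by the
canonical form; a homologous human locus for cross-species comparison; a
59-animal cohort whose allele-group configurations follow the study's
genotyping table (27 animals exclusively G1; 20 with G3; 5 with G2; 6 with
G2_LTR; 1 with G2+G2_LTR); G2-family alleles ~5% diverged from the G1
ancestor, G2_LTR alleles additionally carrying a ~700 bp LTR insertion
~20 bp after the amplicon 5' end, and G3 alleles a 600 bp deletion
removing exon 6; G1 variants organized into correlated (LD) clusters;
per-sample phasing observations (coverage ~10^4x, noisy pairwise variant
connections, consistent haplotype expression imbalance across 9 samples);
and expression truth with fixed allele-group proportions and
equivalence-class read counts.

Every emitted observation is derivable from the returned truth bundle, and
regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .isoforms import IsoformCatalog, TranscriptModel
from .crossmap import build_coordinate_map, convert_model

__all__ = [
    "SimConfig", "LocusTruth", "CohortTruth", "TruthBundle",
    "GENOTYPING_STRATA", "toy_repeat_library", "generate_locus",
    "generate_cohort", "simulate_fl_reads", "simulate_phasing_observations",
    "simulate_expression", "generate_all", "make_raw_catalog",
    "TIMEPOINTS",
]

TIMEPOINTS = ["W0D0", "W0D1", "W0D3", "W0D7",
              "W18D0", "W18D1", "W18D3", "W18D7", "W88D0"]

# genotyping table: (protection outcome, vaccine group) -> counts per
# allele configuration, in the order G1 / G1+G3 / G1+G2 / G1+G2_LTR /
# G1+G2+G2_LTR.  Column totals: 27, 20, 5, 6, 1 (59 animals).
GENOTYPING_STRATA = [
    ("protected", "O", (4, 4, 1, 0, 0)),
    ("protected", "S", (2, 4, 1, 0, 0)),
    ("protected", "X", (4, 1, 1, 0, 0)),
    ("not_protected", "O", (2, 1, 0, 2, 1)),
    ("not_protected", "S", (3, 2, 0, 2, 0)),
    ("not_protected", "X", (3, 4, 1, 1, 0)),
    ("not_protected", "E", (6, 4, 1, 1, 0)),
    ("exposed_uninfected", "E", (3, 0, 0, 0, 0)),
]

CONFIG_ORDER = ("G1", "G1+G3", "G1+G2", "G1+G2_LTR", "G1+G2+G2_LTR")

DOMAIN_MAP = {1: "signal", 2: "Alpha1", 3: "Alpha2", 4: "Alpha3",
              5: "TM", 6: "cytoplasmic", 7: "cytoplasmic", 8: None}

_BASES = np.array(list("ACGT"))


def _default_counts():
    return {"G1": 27, "G1+G3": 20, "G1+G2": 5, "G1+G2_LTR": 6,
            "G1+G2+G2_LTR": 1}


def _default_props():
    return {"G2": 0.25, "G2_LTR": 0.125, "G3": 0.05}


@dataclass
class SimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    seed: int = 0
    n_animals: int = 59
    allele_config_counts: dict = field(default_factory=_default_counts)
    g2_divergence: float = 0.05
    ltr_length: int = 700
    ltr_offset: int = 20
    g3_deletion_length: int = 600
    n_exons: int = 8
    canonical_isoform_fraction: float = 0.75
    n_alt_isoforms: int = 12
    n_human_extra_isoforms: int = 7
    fl_depth: int = 123
    human_fl_depth: int = 2050
    coverage_mean: int = 10000
    connection_error_rate: float = 0.02
    connection_max_span: int = 400
    n_samples_per_animal: int = 9
    ld_cluster_sizes: list = field(
        default_factory=lambda: [21, 18, 4, 4, 2, 1, 1, 1, 1, 1, 1])
    n_rare_variants: int = 58
    group_expression_props: dict = field(default_factory=_default_props)
    species_divergence: float = 0.05
    n_expression_reads: int = 20000
    planted_repeats: tuple = ("AluJb", "AluY", "AluSx3")

    def __post_init__(self):
        if sum(self.allele_config_counts.values()) != self.n_animals:
            raise ValueError("allele configuration counts must sum to "
                             "n_animals")
        for frac in (self.g2_divergence, self.canonical_isoform_fraction,
                     self.species_divergence):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0 <= self.connection_error_rate < 0.5:
            raise ValueError("connection error rate must be in [0, 0.5)")
        if self.ltr_length <= 0 or self.g3_deletion_length <= 0:
            raise ValueError("structural feature lengths must be positive")
        if self.n_exons < 2:
            raise ValueError("need at least two exons")
        for g, p in self.group_expression_props.items():
            if not 0 <= p <= 1:
                raise ValueError(f"expression proportion for {g} not in "
                                 "[0, 1]")


def toy_repeat_library() -> dict:
    """Small fixed repeat-consensus library (deterministic)."""
    rng = np.random.default_rng(715)
    return {
        "LTR5B": "".join(rng.choice(_BASES, size=700)),
        "AluJb": "".join(rng.choice(_BASES, size=300)),
        "AluY": "".join(rng.choice(_BASES, size=300)),
        "AluSx3": "".join(rng.choice(_BASES, size=300)),
    }


# ---------------------------------------------------------------------------
# locus


@dataclass
class LocusTruth:
    locus_seq: str
    human_seq: str
    alignment: tuple
    exons: list
    introns: list
    cds_start: int
    cds_end: int
    domain_map: dict
    repeats: list
    amplicon: tuple
    exon6: tuple
    upstream_len: int
    catalog: IsoformCatalog
    human_catalog: IsoformCatalog
    isoform_props: dict
    human_props: dict
    repeat_library: dict
    a_tract: tuple

    @property
    def canonical(self) -> TranscriptModel:
        return self.catalog.canonical

    def transcript_regions(self) -> list:
        """Named canonical-transcript regions (5' UTR, domains, 3' UTR)."""
        can = self.canonical
        t_cds_start = can.genomic_to_transcript(self.cds_start)
        regions = [("5pUTR", (0, t_cds_start))]
        offset = 0
        for idx, (s, e) in enumerate(can.exons, start=1):
            label = self.domain_map.get(idx)
            t_s, t_e = offset, offset + (e - s)
            offset = t_e
            if label is None:
                continue
            lo = max(t_s, t_cds_start)
            if lo < t_e:
                if regions and regions[-1][0] == label:
                    regions[-1] = (label, (regions[-1][1][0], t_e))
                else:
                    regions.append((label, (lo, t_e)))
        t_cds_end = can.genomic_to_transcript(self.cds_end - 1) + 1
        # trim the last coding region at the stop and add the 3' UTR
        trimmed = []
        for name, (s, e) in regions:
            if name != "5pUTR" and s >= t_cds_end:
                continue
            if name != "5pUTR" and e > t_cds_end:
                e = t_cds_end
            trimmed.append((name, (s, e)))
        trimmed.append(("3pUTR", (t_cds_end, can.spliced_length())))
        return trimmed


_EXON_LENGTHS_8 = [130, 270, 276, 276, 120, 33, 48, 1500]
_INTRON_LENGTHS_8 = [120, 200, 250, 400, 600, 100, 150]


def _structure(n_exons: int) -> tuple:
    if n_exons == 8:
        return list(_EXON_LENGTHS_8), list(_INTRON_LENGTHS_8)
    exon_lengths = [130] + [120] * (n_exons - 2) + [600]
    intron_lengths = [150] * (n_exons - 1)
    return exon_lengths, intron_lengths


def _mutate(seq: str, rate: float, rng, protected=frozenset()) -> str:
    out = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)),
                           replace=False)
    for p in sorted(int(x) for x in positions):
        if p in protected:
            continue
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[int(rng.integers(3))]
    return "".join(out)


def generate_locus(config: SimConfig, rng=None) -> LocusTruth:
    """Build both species' loci, the canonical annotation, planted repeats,
    and the true isoform catalogs."""
    if config.n_exons < 2:
        raise ValueError("need at least two exons")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    exon_lengths, intron_lengths = _structure(config.n_exons)
    upstream, downstream = 300, 200
    seq = rng.choice(_BASES, size=upstream + sum(exon_lengths)
                     + sum(intron_lengths) + downstream)

    exons, introns = [], []
    pos = upstream
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lengths):
            introns.append((pos, pos + intron_lengths[i]))
            pos += intron_lengths[i]
    for (s, e) in introns:
        seq[s:s + 2] = list("GT")
        seq[e - 2:e] = list("AG")

    # canonical ORF: starts inside exon 1, stops shortly into the last exon
    coding_tail = 72 if config.n_exons == 8 else 60
    cds_start = exons[0][1] - coding_tail
    seq[cds_start:cds_start + 3] = list("ATG")
    last = exons[-1]
    stop_g = last[0] + 12
    # scrub in-frame stops from the spliced coding sequence
    coding_positions = []
    for (s, e) in exons[:-1]:
        coding_positions.extend(range(max(s, cds_start), e))
    coding_positions.extend(range(last[0], stop_g))
    for k in range(0, len(coding_positions) - 2, 3):
        tri = (coding_positions[k], coding_positions[k + 1],
               coding_positions[k + 2])
        codon = "".join(seq[p] for p in tri)
        if codon in ("TAA", "TAG", "TGA"):
            seq[tri[2]] = "C"
    seq[stop_g:stop_g + 3] = list("TAA")
    cds_end = stop_g + 3

    # A-rich tract in the 3' UTR for intrapriming fixtures
    a_tract_start = last[0] + (last[1] - last[0]) // 2
    seq[a_tract_start:a_tract_start + 20] = ["A"] * 20
    a_tract = (a_tract_start, a_tract_start + 20)

    library = toy_repeat_library()
    repeats = []
    if "AluJb" in config.planted_repeats:
        s0 = 10
        seq[s0:s0 + 150] = list(library["AluJb"][:150])
        repeats.append(("MamuE_locus", s0, s0 + 150, "AluJb", "+"))
    if "AluY" in config.planted_repeats:
        s0 = 170
        seq[s0:s0 + 120] = list(library["AluY"][:120])
        repeats.append(("MamuE_locus", s0, s0 + 120, "AluY", "+"))
    if "AluSx3" in config.planted_repeats and len(introns) >= 5:
        i5s, i5e = introns[4]
        mid = (i5s + i5e) // 2 - 60
        from .isoforms import revcomp
        seq[mid:mid + 120] = list(revcomp(library["AluSx3"][:120]))
        repeats.append(("MamuE_locus", mid, mid + 120, "AluSx3", "-"))

    locus_seq = "".join(seq)

    catalog, props = _make_catalog(exons, introns, config, "MamuE")
    # intrapriming/repeat planting must not break the canonical junctions
    amp_start = max(0, exons[0][0] - 250)
    e7 = exons[min(6, len(exons) - 1)]
    amp_end = min(len(locus_seq), e7[1] + 50) if len(exons) >= 8 else \
        min(len(locus_seq), exons[-1][0])
    exon6 = exons[5] if len(exons) >= 7 else exons[len(exons) - 2]

    # homologous human locus: substitutions + intron indels, junctions kept
    protected = set()
    for (s, e) in introns:
        protected.update(range(s, s + 2))
        protected.update(range(e - 2, e))
    for (s, e) in exons:
        protected.update((s, e - 1))
    protected.update(range(cds_start, cds_start + 3))
    human = _mutate(locus_seq, config.species_divergence, rng, protected)
    # deletions inside intron interiors (recorded implicitly by alignment)
    aligned_mac = []
    aligned_hum = []
    del_intervals = []
    if len(introns) >= 3:
        (i2s, i2e) = introns[1]
        del_intervals.append((i2s + 60, i2s + 72))
        (i3s, i3e) = introns[2]
        del_intervals.append((i3s + 100, i3s + 109))
    mac_aln = list(locus_seq)
    hum_aln = list(human)
    for (ds, de) in del_intervals:
        for p in range(ds, de):
            hum_aln[p] = "-"
    # an insertion in the human upstream region
    ins = "".join(rng.choice(_BASES, size=15))
    ins_at = 260
    mac_gapped = "".join(mac_aln[:ins_at]) + "-" * 15 + \
        "".join(mac_aln[ins_at:])
    hum_gapped = "".join(hum_aln[:ins_at]) + ins + "".join(hum_aln[ins_at:])
    human_seq = hum_gapped.replace("-", "")
    alignment = (mac_gapped, hum_gapped)

    cmap = build_coordinate_map(alignment)
    human_models = []
    for m in catalog:
        hm = convert_model(cmap, m)
        if "unconvertible" in hm.flags:
            continue
        human_models.append(replace(hm, id="HLA-" + m.id.split("-")[-1]))
    human_models = _add_human_extras(human_models, config)
    human_catalog = IsoformCatalog(models=human_models,
                                   locus_id="HLAE_locus",
                                   canonical_id=human_models[0].id)
    human_props = _isoform_props(len(human_models), 0.87)
    human_props = dict(zip([m.id for m in human_models], human_props))

    return LocusTruth(
        locus_seq=locus_seq, human_seq=human_seq, alignment=alignment,
        exons=exons, introns=introns, cds_start=cds_start, cds_end=cds_end,
        domain_map=dict(DOMAIN_MAP), repeats=repeats,
        amplicon=(amp_start, amp_end), exon6=exon6, upstream_len=upstream,
        catalog=catalog, human_catalog=human_catalog,
        isoform_props=dict(zip([m.id for m in catalog], props)),
        human_props=human_props, repeat_library=library, a_tract=a_tract)


def _isoform_props(n: int, canonical_fraction: float) -> list:
    rest = 1.0 - canonical_fraction
    weights = [0.5 ** k for k in range(n - 1)]
    total = sum(weights)
    return [canonical_fraction] + [rest * w / total for w in weights]


def _make_catalog(exons, introns, config, prefix) -> tuple:
    """Canonical + alternative models from a deterministic event menu."""
    canonical = TranscriptModel(id=f"{prefix}-1", exons=list(exons))
    models = [canonical]
    n_e = len(exons)
    menu = []
    if n_e >= 8:
        last = exons[-1]
        utr_junction = [(last[0], last[1] - last[0])]
        alt3 = (last[0] + 200, last[0] + 500)   # intron within the last exon

        def skip(i):
            return [e for k, e in enumerate(exons, 1) if k != i]

        def retained(i):
            out = []
            for k, e in enumerate(exons, 1):
                if k == i:
                    out.append((e[0], exons[i][1]))
                elif k == i + 1:
                    continue
                else:
                    out.append(e)
            return out

        def split_utr(ex):
            out = []
            for e in ex:
                if e[0] <= alt3[0] and e[1] >= alt3[1]:
                    out.append((e[0], alt3[0]))
                    out.append((alt3[1], e[1]))
                else:
                    out.append(e)
            return out

        i5s, i5e = introns[4]
        novel = (i5s + 150, i5s + 230)

        def with_novel(ex):
            out = sorted(ex + [novel])
            return out

        skip56 = [e for k, e in enumerate(exons, 1) if k not in (5, 6)]
        menu = [
            skip(6),                         # drops exon 6
            skip(5),                         # drops the TM exon
            skip56,
            retained(4),                     # retained intron 4 (frameshift)
            with_novel(list(exons)),         # exonization inside intron 5
            split_utr(list(exons)),          # alternative 3' UTR splicing
            split_utr(skip(6)),
            split_utr(skip(5)),
            split_utr(retained(4)),
            with_novel(skip(6)),
            split_utr(skip56),
            with_novel(split_utr(list(exons))),
        ]
    else:
        for i in range(2, n_e):
            menu.append([e for k, e in enumerate(exons, 1) if k != i])
    for k, ex in enumerate(menu[:config.n_alt_isoforms], start=2):
        models.append(TranscriptModel(id=f"{prefix}-{k}", exons=ex))
    props = _isoform_props(len(models), config.canonical_isoform_fraction)
    return IsoformCatalog(models=models, locus_id="MamuE_locus",
                          canonical_id=canonical.id), props


def _add_human_extras(models, config):
    """Human-only isoforms: retained first intron and extra UTR variants."""
    out = list(models)
    canonical = models[0]
    exons = canonical.exons
    k = len(out) + 1
    extras = []
    if len(exons) >= 3:
        ri1 = [(exons[0][0], exons[1][1])] + list(exons[2:])
        extras.append(ri1)
        ri1b = [(exons[0][0], exons[1][1])] + list(exons[2:-1]) + \
            [(exons[-1][0], exons[-1][0] + 300)]
        extras.append(ri1b)
    last = exons[-1]
    for shift in (250, 350, 450, 550, 650):
        cut = (last[0] + shift, last[0] + shift + 120)
        if cut[1] < last[1]:
            ex = list(exons[:-1]) + [(last[0], cut[0]), (cut[1], last[1])]
            extras.append(ex)
    for ex in extras[:config.n_human_extra_isoforms]:
        out.append(TranscriptModel(id=f"HLA-x{k}", exons=ex))
        k += 1
    return out


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortTruth:
    animals: list
    metadata: pd.DataFrame
    variant_positions: list           # canonical-transcript coordinates
    variant_ref: list
    variant_alt: list
    variant_cluster: list             # cluster index or -1 (rare)
    haplotypes: dict                  # animal -> (2, n_var) 0/1 array
    hap_share: dict                   # (animal, sample idx) -> hap0 share
    g1_subtypes: dict                 # animal -> set of subtype labels
    allele_groups: dict               # animal -> tuple of groups
    allele_seqs: dict                 # animal -> {allele id: sequence}
    allele_labels: dict               # allele id -> group
    amplicon_ref: str
    transcript_ref: str
    g2_ancestor: str = ""
    g2ltr_ancestor: str = ""
    g3_allele: str = ""

    def haplotig_truth(self, animal) -> tuple:
        """The two true haplotig sequences on the canonical transcript."""
        h = self.haplotypes[animal]
        seqs = []
        for hap in (0, 1):
            s = list(self.transcript_ref)
            for k, pos in enumerate(self.variant_positions):
                if h[hap, k]:
                    s[pos] = self.variant_alt[k]
            seqs.append("".join(s))
        return tuple(seqs)

    def het_positions(self, animal) -> list:
        h = self.haplotypes[animal]
        return [self.variant_positions[k]
                for k in range(h.shape[1]) if h[0, k] != h[1, k]]


_SUBTYPE_BY_FORM = {(0, 0): "E*02:01", (0, 1): "E*02:02",
                    (1, 0): "E*02:11", (1, 1): "E*02:04"}
# forced big-cluster forms creating complete linkage with G1 subtypes
_FORCED_FORM = {"G2": (0, 1), "G2_LTR": (1, 0), "G3": (1, 1)}


def generate_cohort(config: SimConfig, locus: LocusTruth,
                    rng=None) -> CohortTruth:
    """Animals, allele configurations, G1 haplotypes, and allele sequences.

    Allele configurations are assigned to outcome/vaccine-group strata in a
    fixed order and shuffled by seed.  Non-G1 carriers have one haplotype
    forced to a designated big-cluster form, planting complete linkage
    between each non-G1 group and one G1 subtype.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    counts = config.allele_config_counts
    if sum(counts.values()) != config.n_animals:
        raise ValueError("allele configuration counts must sum to n_animals")

    # stratum assignment: the genotyping-table layout when it matches,
    # otherwise round-robin over vaccine groups with alternating outcome
    rows = []
    if dict(counts) == _default_counts() and config.n_animals == 59:
        for outcome, group, per_config in GENOTYPING_STRATA:
            for cfg_name, n in zip(CONFIG_ORDER, per_config):
                rows.extend((outcome, group, cfg_name) for _ in range(n))
    else:
        groups = ["O", "S", "X", "E"]
        outs = ["protected", "not_protected"]
        i = 0
        for cfg_name in CONFIG_ORDER:
            for _ in range(counts.get(cfg_name, 0)):
                rows.append((outs[i % 2], groups[i % 4], cfg_name))
                i += 1
    order = rng.permutation(len(rows))
    animals = [f"Rh{i + 1:03d}" for i in range(config.n_animals)]
    metadata = pd.DataFrame(
        [(animals[k], rows[j][1], rows[j][0], rows[j][2])
         for k, j in enumerate(order)],
        columns=["animal", "vaccine_group", "outcome", "allele_config"])

    canonical = locus.canonical
    transcript_ref = canonical.spliced_sequence(locus.locus_seq)
    L = len(transcript_ref)

    n_clusters = len(config.ld_cluster_sizes)
    n_cluster_vars = sum(config.ld_cluster_sizes)
    n_var = n_cluster_vars + config.n_rare_variants
    positions = np.sort(rng.choice(np.arange(80, L - 80), size=n_var,
                                   replace=False))
    cluster_of = np.full(n_var, -1, dtype=int)
    shuffled = rng.permutation(n_var)
    k = 0
    for c, size in enumerate(config.ld_cluster_sizes):
        for _ in range(size):
            cluster_of[shuffled[k]] = c
            k += 1
    ref = [transcript_ref[p] for p in positions]
    alt = []
    for r in ref:
        choices = [b for b in "ACGT" if b != r]
        alt.append(choices[int(rng.integers(3))])

    cluster_freqs = rng.uniform(0.2, 0.45, size=n_clusters)
    rare_idx = np.nonzero(cluster_of < 0)[0]
    n_chrom = 2 * config.n_animals
    rare_carriers = {int(i): rng.choice(n_chrom,
                                        size=int(rng.integers(1, 8)),
                                        replace=False)
                     for i in rare_idx}

    def hap_from_forms(forms, chrom_index):
        h = np.zeros(n_var, dtype=np.int8)
        for c in range(n_clusters):
            if forms[c]:
                h[cluster_of == c] = 1
        for i, carriers in rare_carriers.items():
            if chrom_index in carriers:
                h[i] = 1
        return h

    haplotypes, g1_subtypes, allele_groups = {}, {}, {}
    hap_forms = {}
    chrom = 0
    for _, row in metadata.iterrows():
        animal = row["animal"]
        groups = tuple(row["allele_config"].split("+"))
        allele_groups[animal] = groups
        forced = [g for g in groups if g in _FORCED_FORM]
        forms = []
        for hap in (0, 1):
            if hap < len(forced):
                big = _FORCED_FORM[forced[hap]]
            else:
                big = (int(rng.random() < cluster_freqs[0]),
                       int(rng.random() < cluster_freqs[1])
                       if n_clusters > 1 else 0)
            others = tuple(int(rng.random() < cluster_freqs[c])
                           for c in range(2, n_clusters))
            forms.append(big + others)
        h = np.stack([hap_from_forms(forms[0], chrom),
                      hap_from_forms(forms[1], chrom + 1)])
        chrom += 2
        haplotypes[animal] = h
        hap_forms[animal] = forms
        g1_subtypes[animal] = {
            _SUBTYPE_BY_FORM[(f[0], f[1] if n_clusters > 1 else 0)]
            for f in forms}

    # per-sample haplotype expression imbalance, consistent in direction
    hap_share = {}
    for animal in animals:
        base = rng.uniform(0.56, 0.70)
        for s in range(config.n_samples_per_animal):
            hap_share[(animal, s)] = float(
                np.clip(base + rng.normal(0, 0.02), 0.52, 0.95))

    # allele sequences on the amplicon
    amp_s, amp_e = locus.amplicon
    amplicon_ref = locus.locus_seq[amp_s:amp_e]
    g2_anc = _mutate(amplicon_ref, config.g2_divergence, rng)
    g2ltr_core = _mutate(amplicon_ref, config.g2_divergence, rng)
    ltr = locus.repeat_library["LTR5B"][:config.ltr_length]
    off = config.ltr_offset
    g2ltr_anc = g2ltr_core[:off] + ltr + g2ltr_core[off:]
    e6s, e6e = locus.exon6
    del_end = min(e6e - amp_s + 10, len(amplicon_ref))
    del_start = max(0, del_end - config.g3_deletion_length)
    g3_allele = amplicon_ref[:del_start] + amplicon_ref[del_end:]

    genomic_of = {}
    for k_i, p in enumerate(positions):
        genomic_of[k_i] = canonical.transcript_to_genomic(int(p))

    allele_seqs, allele_labels = {}, {}
    for animal in animals:
        seqs = {}
        h = haplotypes[animal]
        g1_variants = []
        for hap in (0, 1):
            s = list(amplicon_ref)
            for k_i in range(n_var):
                g = genomic_of[k_i]
                if h[hap, k_i] and g is not None and amp_s <= g < amp_e:
                    s[g - amp_s] = alt[k_i]
            g1_variants.append("".join(s))
        if g1_variants[0] == g1_variants[1]:
            seqs[f"{animal}_G1a"] = g1_variants[0]
        else:
            seqs[f"{animal}_G1a"] = g1_variants[0]
            seqs[f"{animal}_G1b"] = g1_variants[1]
        for g in allele_groups[animal]:
            if g == "G2":
                seqs[f"{animal}_G2"] = g2_anc
            elif g == "G2_LTR":
                seqs[f"{animal}_G2LTR"] = g2ltr_anc
            elif g == "G3":
                seqs[f"{animal}_G3"] = g3_allele
        for name in seqs:
            tag = name.split("_")[1]
            allele_labels[name] = "G2_LTR" if tag == "G2LTR" else \
                ("G1" if tag.startswith("G1") else tag)
        allele_seqs[animal] = seqs

    return CohortTruth(
        animals=animals, metadata=metadata,
        variant_positions=[int(p) for p in positions],
        variant_ref=ref, variant_alt=alt,
        variant_cluster=[int(c) for c in cluster_of],
        haplotypes=haplotypes, hap_share=hap_share,
        g1_subtypes=g1_subtypes, allele_groups=allele_groups,
        allele_seqs=allele_seqs, allele_labels=allele_labels,
        amplicon_ref=amplicon_ref, transcript_ref=transcript_ref,
        g2_ancestor=g2_anc, g2ltr_ancestor=g2ltr_anc, g3_allele=g3_allele)


# ---------------------------------------------------------------------------
# observations


def simulate_fl_reads(true_proportions, depth: int, seed=None) -> np.ndarray:
    """Multinomial full-length read counts at a fixed depth."""
    p = np.asarray(true_proportions, dtype=float)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    return rng.multinomial(depth, p)


@dataclass
class PhasingObservations:
    """Summarized phasing evidence for one animal."""

    animal: str
    coverage: np.ndarray              # (n_samples, L) per-base depth
    base_counts: np.ndarray           # (L, 4) pooled A/C/G/T counts
    connections: pd.DataFrame         # sample, pos_i, pos_j, base_i, base_j,
                                      # count
    allele_depths: pd.DataFrame       # sample, pos, base, count


def simulate_phasing_observations(cohort: CohortTruth, config: SimConfig,
                                  rng=None, animals=None) -> dict:
    """Coverage, pooled base counts, pairwise connections, allelic depths.

    Connections are emitted for heterozygous pairs within
    ``connection_max_span`` on the transcript; a fraction
    ``connection_error_rate`` of reads supports a wrong configuration.
    Coverage has mean ``coverage_mean`` (pooled across samples) with
    depressed ends.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if animals is None:
        animals = cohort.animals
    L = len(cohort.transcript_ref)
    n_s = config.n_samples_per_animal
    per_sample_mean = config.coverage_mean / n_s
    ramp = np.ones(L)
    edge = min(40, L // 4)
    ramp[:edge] = np.linspace(0.03, 1.0, edge)
    ramp[-edge:] = np.linspace(1.0, 0.03, edge)
    err = config.connection_error_rate
    base_idx = {b: i for i, b in enumerate("ACGT")}

    out = {}
    for animal in animals:
        hap = cohort.haplotypes[animal]
        het = cohort.het_positions(animal)
        hap_base = {}
        for k, pos in enumerate(cohort.variant_positions):
            b0 = cohort.variant_alt[k] if hap[0, k] else cohort.variant_ref[k]
            b1 = cohort.variant_alt[k] if hap[1, k] else cohort.variant_ref[k]
            hap_base[pos] = (b0, b1)

        coverage = rng.poisson(per_sample_mean * ramp, size=(n_s, L))
        shares = np.array([cohort.hap_share[(animal, s)]
                           for s in range(n_s)])

        base_counts = np.zeros((L, 4), dtype=np.int64)
        pooled = coverage.sum(axis=0)
        ref_arr = np.array([base_idx[b] for b in cohort.transcript_ref])
        # start from reference everywhere, then overwrite variant positions
        np.add.at(base_counts, (np.arange(L), ref_arr), pooled)
        for k, pos in enumerate(cohort.variant_positions):
            b0, b1 = hap_base[pos]
            base_counts[pos, :] = 0
            n0 = rng.binomial(coverage[:, pos], shares).sum()
            base_counts[pos, base_idx[b0]] += n0
            base_counts[pos, base_idx[b1]] += int(pooled[pos]) - n0
        # low-rate sequencing noise spread across the other bases
        noise = rng.binomial(pooled, 0.002)
        for p in np.nonzero(noise)[0]:
            b = int(rng.integers(4))
            base_counts[p, b] += noise[p]

        conn_rows = []
        depth_rows = []
        for s in range(n_s):
            rho = shares[s]
            for pos in het:
                n = rng.poisson(per_sample_mean)
                n0 = rng.binomial(n, rho)
                b0, b1 = hap_base[pos]
                depth_rows.append((s, pos, b0, n0))
                depth_rows.append((s, pos, b1, n - n0))
            for a_i in range(len(het)):
                for b_i in range(a_i + 1, len(het)):
                    pi, pj = het[a_i], het[b_i]
                    if pj - pi > config.connection_max_span:
                        break
                    n = rng.poisson(per_sample_mean)
                    n0 = rng.binomial(n, rho)
                    n1 = n - n0
                    e0 = rng.binomial(n0, err)
                    e1 = rng.binomial(n1, err)
                    bi0, bi1 = hap_base[pi]
                    bj0, bj1 = hap_base[pj]
                    counts = {
                        (bi0, bj0): n0 - e0, (bi1, bj1): n1 - e1,
                    }
                    # errors flip one side of the pair
                    e0a = rng.binomial(e0, 0.5)
                    e1a = rng.binomial(e1, 0.5)
                    counts[(bi0, bj1)] = counts.get((bi0, bj1), 0) \
                        + e0a + (e1 - e1a)
                    counts[(bi1, bj0)] = counts.get((bi1, bj0), 0) \
                        + (e0 - e0a) + e1a
                    for (bx, by), c in sorted(counts.items()):
                        if c > 0:
                            conn_rows.append((s, pi, pj, bx, by, int(c)))
        connections = pd.DataFrame(
            conn_rows,
            columns=["sample", "pos_i", "pos_j", "base_i", "base_j",
                     "count"])
        allele_depths = pd.DataFrame(
            depth_rows, columns=["sample", "pos", "base", "count"])
        out[animal] = PhasingObservations(
            animal=animal, coverage=coverage, base_counts=base_counts,
            connections=connections, allele_depths=allele_depths)
    return out


# ---------------------------------------------------------------------------
# expression


def _equivalence_classes(catalog: IsoformCatalog) -> list:
    """Unique class per isoform plus junction-sharing classes."""
    classes = [frozenset([m.id]) for m in catalog]
    junc_members: dict = {}
    for m in catalog:
        for j in m.junctions:
            junc_members.setdefault(j, set()).add(m.id)
    for members in junc_members.values():
        if len(members) > 1:
            classes.append(frozenset(members))
    return sorted(set(classes), key=lambda c: tuple(sorted(c)))


def simulate_expression(cohort: CohortTruth, locus: LocusTruth,
                        config: SimConfig, rng=None,
                        per_animal_props: dict | None = None) -> dict:
    """Group counts, allele-tag counts, and equivalence-class counts.

    Group read counts are multinomial around the configured group
    proportions restricted to each animal's alleles (remainder to G1).
    Equivalence-class counts are drawn from the true isoform proportions
    with length-weighted read probabilities; each shared splice junction
    contributes a fixed-width region whose reads are compatible with every
    isoform carrying that junction, and the remainder of each isoform is
    unique to it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if per_animal_props:
        for animal, props in per_animal_props.items():
            missing = set(props) - set(cohort.allele_groups[animal])
            if missing:
                raise ValueError(
                    f"{animal}: expression proportions for absent "
                    f"groups {sorted(missing)}")

    catalog = locus.catalog
    iso_ids = [m.id for m in catalog]
    lengths = np.array([m.spliced_length() for m in catalog], dtype=float)
    mol = np.array([locus.isoform_props[i] for i in iso_ids])
    theta = mol * lengths
    theta = theta / theta.sum()
    classes = _equivalence_classes(catalog)
    unique_class = {next(iter(c)): ci for ci, c in enumerate(classes)
                    if len(c) == 1}
    shared_by_iso = {i: [ci for ci, c in enumerate(classes)
                         if len(c) > 1 and i in c] for i in iso_ids}
    # each shared junction contributes a fixed-width compatible region
    junction_window = 100.0
    class_prob_by_iso = {}
    for idx, i in enumerate(iso_ids):
        shared = shared_by_iso[i]
        p_shared = junction_window / lengths[idx]
        p_unique = 1.0 - p_shared * len(shared)
        cis = shared + [unique_class[i]]
        pvec = np.array([p_shared] * len(shared) + [p_unique])
        class_prob_by_iso[i] = (cis, pvec)

    group_rows, tag_rows, class_rows = [], [], []
    for animal in cohort.animals:
        groups = cohort.allele_groups[animal]
        props = dict(per_animal_props.get(animal, {})) if per_animal_props \
            else {}
        for g in groups:
            if g != "G1" and g not in props:
                props[g] = config.group_expression_props.get(g, 0.0)
        g1_prop = 1.0 - sum(props.values())
        order = list(groups)
        pvec = np.array([g1_prop if g == "G1" else props[g] for g in order])
        for t, tp in enumerate(TIMEPOINTS[:config.n_samples_per_animal]):
            draw = rng.multinomial(config.n_expression_reads, pvec)
            for g, c in zip(order, draw):
                group_rows.append((animal, tp, g, int(c)))
            g1_reads = int(draw[order.index("G1")])
            # within-G1 allelic tags when two distinct G1 alleles exist
            if len([a for a in cohort.allele_seqs[animal]
                    if "G1" in a]) == 2:
                rho = cohort.hap_share[(animal,
                                        t % config.n_samples_per_animal)]
                n_qc = rng.binomial(g1_reads, 0.01)
                n_multi = rng.binomial(g1_reads - n_qc, 0.005)
                rest = g1_reads - n_qc - n_multi
                n_inf = rng.binomial(rest, 0.4)
                n_ref = rng.binomial(n_inf, rho)
                tag_rows.extend([
                    (animal, tp, "ref_only", int(n_ref)),
                    (animal, tp, "alt_only", int(n_inf - n_ref)),
                    (animal, tp, "common", int(rest - n_inf)),
                    (animal, tp, "multi", int(n_multi)),
                    (animal, tp, "qc_fail", int(n_qc)),
                ])
            # equivalence classes over G1 isoform reads
            iso_draw = rng.multinomial(g1_reads, theta)
            for i, n_i in zip(iso_ids, iso_draw):
                if n_i == 0:
                    continue
                cis, cvec = class_prob_by_iso[i]
                alloc = rng.multinomial(n_i, cvec)
                for ci, c in zip(cis, alloc):
                    if c > 0:
                        class_rows.append(
                            (animal, tp, ",".join(sorted(classes[ci])),
                             int(c)))
    return {
        "group_counts": pd.DataFrame(
            group_rows, columns=["animal", "timepoint", "group", "count"]),
        "tag_counts": pd.DataFrame(
            tag_rows, columns=["animal", "timepoint", "code", "count"]),
        "class_counts": pd.DataFrame(
            class_rows, columns=["animal", "timepoint", "class", "count"]),
        "classes": classes,
        "isoform_lengths": dict(zip(iso_ids, lengths.tolist())),
    }


# ---------------------------------------------------------------------------
# raw catalogs for curation fixtures


def make_raw_catalog(locus: LocusTruth, rng=None, max_jitter: int = 3,
                     fl_depth: int | None = None,
                     seed: int | None = None) -> IsoformCatalog:
    """A long-read-like catalog whose curation recovers the truth exactly.

    Injects junction jitter (only at junctions shared with the canonical
    chain, within the correction window), an intraprimed truncation of the
    canonical model ending at the planted A-tract, and near-duplicate end
    variation within the end-clustering window.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = locus.catalog
    canonical_junc = set(truth.canonical.junctions)
    counts = simulate_fl_reads(
        [locus.isoform_props[m.id] for m in truth],
        fl_depth if fl_depth is not None else 123, rng)
    models = []
    for m, fl in zip(truth, counts):
        fl = int(fl)
        jittered = []
        for (s, e) in m.exons:
            jittered.append([s, e])
        for k, (d, a) in enumerate(m.junctions):
            if (d, a) in canonical_junc and rng.random() < 0.5:
                jittered[k][1] = d + int(rng.integers(1, max_jitter + 1))
                jittered[k + 1][0] = a - int(rng.integers(1, max_jitter + 1))
        main_fl = fl
        extra = []
        if m.id == truth.canonical_id and fl >= 2:
            # an intraprimed truncation ending at the A-tract
            trunc = [list(e) for e in m.exons]
            trunc[-1][1] = locus.a_tract[0]
            extra.append(TranscriptModel(
                id=m.id + "_trunc", exons=[tuple(e) for e in trunc],
                fl_count=fl // 3, strand=m.strand))
            main_fl = fl - fl // 3
        if fl >= 4:
            # a near-duplicate with ends jittered within the cluster window
            dup = [list(e) for e in jittered]
            dup[0][0] += int(rng.integers(5, 30))
            dup[-1][1] -= int(rng.integers(5, 30))
            extra.append(TranscriptModel(
                id=m.id + "_dup", exons=[tuple(e) for e in dup],
                fl_count=fl // 4, strand=m.strand))
            main_fl = main_fl - fl // 4
        models.append(TranscriptModel(
            id=m.id, exons=[tuple(e) for e in jittered], fl_count=main_fl,
            strand=m.strand))
        models.extend(extra)
    return IsoformCatalog(models=models, locus_id=truth.locus_id,
                          canonical_id=truth.canonical_id)


# ---------------------------------------------------------------------------
# driver


@dataclass
class TruthBundle:
    """Everything the generator knows; all observations derive from it."""

    config: SimConfig
    locus: LocusTruth
    cohort: CohortTruth
    fl_counts: dict
    human_fl_counts: dict
    expression: dict
    phasing: dict | None = None

    def summary(self) -> dict:
        cfg = self.cohort.metadata["allele_config"].value_counts().to_dict()
        return {
            "n_animals": len(self.cohort.animals),
            "allele_configs": cfg,
            "n_isoforms": len(self.locus.catalog),
            "n_human_isoforms": len(self.locus.human_catalog),
            "n_variants": len(self.cohort.variant_positions),
            "cluster_sizes": list(self.config.ld_cluster_sizes),
        }


def generate_all(config: SimConfig, with_phasing: bool = True,
                 phasing_animals=None) -> TruthBundle:
    """Run the full generator: locus, cohort, reads, observations."""
    rng = np.random.default_rng(config.seed)
    locus = generate_locus(config, rng)
    cohort = generate_cohort(config, locus, rng)
    fl = simulate_fl_reads([locus.isoform_props[m.id]
                            for m in locus.catalog], config.fl_depth, rng)
    hfl = simulate_fl_reads([locus.human_props[m.id]
                             for m in locus.human_catalog],
                            config.human_fl_depth, rng)
    expression = simulate_expression(cohort, locus, config, rng)
    phasing = None
    if with_phasing:
        phasing = simulate_phasing_observations(cohort, config, rng,
                                                animals=phasing_animals)
    return TruthBundle(
        config=config, locus=locus, cohort=cohort,
        fl_counts=dict(zip([m.id for m in locus.catalog],
                           [int(c) for c in fl])),
        human_fl_counts=dict(zip([m.id for m in locus.human_catalog],
                                 [int(c) for c in hfl])),
        expression=expression, phasing=phasing)
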