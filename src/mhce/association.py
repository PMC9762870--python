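"""Variant genetics of the dominant allele group and cohort association.

Covers minor-allele-frequency filtering, pairwise linkage disequilibrium
(D and r from phased haplotypes), hierarchical variant clustering on an
LD-derived distance, exact contingency tests (2x2 and small RxC, with a
seeded Monte-Carlo fallback), Benjamini–Hochberg FDR, genotype/duplication
association scans, Kyte–Doolittle hydropathy profiles of the
transmembrane domain, and per-region variant/SAP tallies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .isoforms import CODON_TABLE

__all__ = [
    "VariantRecord", "LDResult", "VariantCluster", "TestResult",
    "maf_filter", "ld_pair", "ld_matrix", "cluster_variants",
    "fisher_exact_2x2", "fisher_exact_rxc", "bh_fdr",
    "genotype_association_scan", "duplication_association",
    "hydropathy_profile", "count_variant_effects", "KYTE_DOOLITTLE",
]

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class VariantRecord:
    """A biallelic variant with per-animal minor-allele dosage genotypes."""

    variant_id: str
    position: int
    vtype: str                       # SNP / insertion / deletion
    ref: str
    alt: str
    genotypes: np.ndarray            # 0/1/2 minor-allele count per animal

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=int)

    @property
    def maf(self) -> float:
        f = self.genotypes.mean() / 2.0
        return float(min(f, 1.0 - f))


@dataclass
class LDResult:
    pair: tuple
    D: float
    r: float


@dataclass
class VariantCluster:
    cluster_id: int
    members: list
    complete_ld: bool

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TestResult:
    name: str
    table: np.ndarray
    p: float
    q: float | None = None
    flags: set = field(default_factory=set)


def maf_filter(variants: list, threshold: float = 0.1) -> list:
    """Retain variants with MAF strictly above the threshold."""
    return [v for v in variants if v.maf > threshold]


def ld_pair(hap_a, hap_b) -> LDResult:
    """D and r for two biallelic sites from phased haplotypes (0/1 coded).

    D = p_AB - p_A p_B; r = D / sqrt(p_A q_A p_B q_B).  Either site being
    monomorphic leaves r undefined (error).
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors differ in length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic site; r undefined")
    pab = np.mean(a * b)
    d = pab - pa * pb
    r = d / math.sqrt(pa * (1 - pa) * pb * (1 - pb))
    return LDResult(pair=(0, 1), D=float(d), r=float(r))


def ld_matrix(haplotypes) -> np.ndarray:
    """Pairwise r matrix from a (n_haplotypes, n_variants) 0/1 array."""
    h = np.asarray(haplotypes, dtype=float)
    if np.any((h.std(axis=0)) == 0):
        raise ValueError("monomorphic site in haplotype matrix")
    return np.corrcoef(h, rowvar=False)


def cluster_variants(r_matrix, variant_ids=None, cut_height: float = 0.35,
                     metric: str = "r2") -> list:
    """Cluster variants by LD with complete linkage.

    Distance is 1-r^2 by default (``metric`` may also be ``r`` or
    ``abs_r``); the tree is cut at ``cut_height``; any resulting cluster
    of size two whose pair is not in complete LD (|r| < 1) is split into
    singletons.  Clusters are ordered by decreasing size.
    """
    r = np.asarray(r_matrix, dtype=float)
    n = r.shape[0]
    if n == 0:
        return []
    if variant_ids is None:
        variant_ids = list(range(n))
    if metric == "r2":
        dist = 1.0 - r ** 2
    elif metric == "r":
        dist = 1.0 - r
    elif metric == "abs_r":
        dist = 1.0 - np.abs(r)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    if n == 1:
        flat = np.array([1])
    else:
        link = hierarchy.linkage(squareform(dist, checks=False),
                                 method="complete")
        flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    groups: dict = {}
    for vid, cl in zip(variant_ids, flat):
        groups.setdefault(cl, []).append(vid)
    index = {v: k for k, v in enumerate(variant_ids)}
    clusters = []
    for members in groups.values():
        if len(members) == 2:
            i, j = index[members[0]], index[members[1]]
            if abs(r[i, j]) < 1.0 - 1e-9:
                clusters.append([members[0]])
                clusters.append([members[1]])
                continue
        clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), [index[v] for v in m]))
    out = []
    for k, members in enumerate(clusters, start=1):
        idxs = [index[v] for v in members]
        complete = all(abs(r[i, j]) >= 1.0 - 1e-9
                       for a, i in enumerate(idxs) for j in idxs[a + 1:])
        out.append(VariantCluster(cluster_id=k, members=members,
                                  complete_ld=complete))
    return out


# ---------------------------------------------------------------------------
# exact tests and FDR


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (probability-mass-at-most-observed rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 integer table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_table_prob(t, lgam_margins, lgam_total):
    return lgam_margins - lgam_total - sum(
        math.lgamma(x + 1) for x in t.flat)


def fisher_exact_rxc(table, max_tables: int = 2_000_000,
                     monte_carlo: bool = False, n_samples: int = 100_000,
                     seed: int | None = None, rel_tol: float = 1e-7
                     ) -> float:
    """Exact two-sided RxC test by enumeration over fixed margins.

    All-zero rows/columns are dropped; a 2x2 table delegates to the 2x2
    routine.  p sums the probabilities of all margin-compatible tables
    whose probability does not exceed the observed one (within
    ``rel_tol``).  Tables beyond the enumeration budget raise unless
    ``monte_carlo`` is set, in which case a seeded permutation sample
    estimates p.
    """
    t = np.asarray(table, dtype=int)
    if np.any(t < 0):
        raise ValueError("negative counts")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    total = int(t.sum())
    lgam_margins = (sum(math.lgamma(r + 1) for r in rows)
                    + sum(math.lgamma(c + 1) for c in cols))
    lgam_total = math.lgamma(total + 1)
    logp_obs = _log_table_prob(t, lgam_margins, lgam_total)
    cutoff = logp_obs + math.log1p(rel_tol)

    if monte_carlo:
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(cols)), cols)
        hits = 0
        for _ in range(n_samples):
            rng.shuffle(labels)
            sim = np.zeros_like(t)
            start = 0
            for ri, r in enumerate(rows):
                seg = labels[start:start + r]
                for ci in range(len(cols)):
                    sim[ri, ci] = np.sum(seg == ci)
                start += r
            if _log_table_prob(sim, lgam_margins, lgam_total) <= cutoff:
                hits += 1
        return (hits + 1) / (n_samples + 1)

    n_rows, n_cols = t.shape
    psum = 0.0
    count = 0

    def recurse(row_idx, col_remaining, logp_partial):
        nonlocal psum, count
        count += 1
        if count > max_tables:
            raise RuntimeError(
                "enumeration budget exceeded; use monte_carlo=True "
                "with a seed")
        if row_idx == n_rows - 1:
            if np.any(col_remaining < 0):
                return
            logp = logp_partial - sum(
                math.lgamma(x + 1) for x in col_remaining)
            if logp <= cutoff:
                psum += math.exp(logp)
            return
        r = rows[row_idx]

        def fill(ci, remaining, partial_cells, logcells):
            if ci == n_cols - 1:
                last = remaining
                if last < 0 or last > col_remaining[ci]:
                    return
                cells = partial_cells + [last]
                recurse(row_idx + 1,
                        col_remaining - np.array(cells),
                        logcells - math.lgamma(last + 1))
                return
            hi = min(remaining, col_remaining[ci])
            for x in range(hi + 1):
                fill(ci + 1, remaining - x, partial_cells + [x],
                     logcells - math.lgamma(x + 1))

        fill(0, int(r), [], logp_partial)

    recurse(0, cols.astype(int).copy(),
            lgam_margins - lgam_total)
    return float(min(psum, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# cohort scans


def genotype_association_scan(genotypes: dict, labels, scope=None) -> list:
    """Exact association of each variant/cluster genotype with a label.

    ``genotypes``: id -> per-animal 0/1/2 dosage.  Genotypes are collapsed
    to homozygous-major (0) versus carrier (1 or 2).  Binary labels give a
    2x2 Fisher test; multi-level labels (e.g. vaccine group) an exact RxC
    test.  ``scope`` is a boolean mask restricting the animals used.  BH
    correction is applied across the scan.
    """
    labels = np.asarray(labels)
    if scope is None:
        scope = np.ones(labels.shape, dtype=bool)
    scope = np.asarray(scope, dtype=bool)
    if scope.sum() == 0:
        raise ValueError("empty scope")
    levels = sorted(set(labels[scope].tolist()))
    results = []
    for name in sorted(genotypes):
        g = np.asarray(genotypes[name])[scope]
        lab = labels[scope]
        carrier = (g > 0).astype(int)
        table = np.zeros((2, len(levels)), dtype=int)
        for gi in (0, 1):
            for li, lv in enumerate(levels):
                table[gi, li] = int(np.sum((carrier == gi) & (lab == lv)))
        flags = set()
        if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
            p = 1.0
            flags.add("uninformative")
        elif len(levels) == 2:
            p = fisher_exact_2x2(table)
        else:
            p = fisher_exact_rxc(table)
        results.append(TestResult(name=name, table=table, p=p, flags=flags))
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def duplication_association(groups_by_animal: dict, labels, scope=None,
                            target_groups=("G2", "G2_LTR", "G3")
                            ) -> TestResult:
    """Locus-duplication presence/absence versus a binary label.

    Animals carrying any allele from ``target_groups`` form the duplicated
    class (pass ``("G2_LTR",)`` for the LTR-specific test).
    """
    animals = sorted(groups_by_animal)
    labels = np.asarray(labels)
    if scope is None:
        scope = np.ones(len(animals), dtype=bool)
    scope = np.asarray(scope, dtype=bool)
    dup = np.array([bool(set(groups_by_animal[a]) & set(target_groups))
                    for a in animals])
    lab = labels[scope]
    dup = dup[scope]
    levels = sorted(set(lab.tolist()))
    table = np.zeros((2, len(levels)), dtype=int)
    for di in (0, 1):
        for li, lv in enumerate(levels):
            table[di, li] = int(np.sum((dup == bool(di)) & (lab == lv)))
    flags = set()
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        p, flags = 1.0, {"uninformative"}
    elif len(levels) == 2:
        p = fisher_exact_2x2(table)
    else:
        p = fisher_exact_rxc(table)
    name = "+".join(target_groups)
    return TestResult(name=f"duplication[{name}]", table=table, p=p,
                      flags=flags)


# ---------------------------------------------------------------------------
# hydropathy and variant effects


def hydropathy_profile(tm_sequence: str, window: int = 9) -> tuple:
    """Sliding-window Kyte–Doolittle profile with positions in [0, 1].

    The window is centered on each residue and truncated at the ends, so
    the profile has one score per residue; positions are (i)/(L-1).
    """
    seq = tm_sequence.upper()
    L = len(seq)
    if L < window:
        raise ValueError("sequence shorter than the smoothing window")
    values = np.array([KYTE_DOOLITTLE[aa] for aa in seq])
    half = window // 2
    scores = np.empty(L)
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        scores[i] = values[lo:hi].mean()
    positions = np.arange(L) / (L - 1) if L > 1 else np.zeros(1)
    return positions, scores


def count_variant_effects(variants: list, reference: str, cds_start: int,
                          cds_end: int, regions: list) -> dict:
    """Tally variants per transcript region and count unique SAPs.

    ``regions``: list of (name, (start, end)) on the reference transcript.
    A SAP is a distinct amino-acid change induced by an in-CDS SNP
    (synonymous SNPs count as variants only); identical changes from
    different SNPs are deduplicated.
    """
    tallies: dict = {name: {"SNP": 0, "insertion": 0, "deletion": 0}
                     for name, _ in regions}
    saps = set()
    for v in variants:
        region = None
        for name, (s, e) in regions:
            if s <= v.position < e:
                region = name
                break
        if region is None:
            raise ValueError(f"variant {v.variant_id} at {v.position} "
                             "outside annotated regions")
        tallies[region][v.vtype] += 1
        if v.vtype == "SNP" and cds_start <= v.position < cds_end:
            off = v.position - cds_start
            codon_i = off // 3
            frame = off % 3
            c0 = cds_start + 3 * codon_i
            codon = list(reference[c0:c0 + 3].upper())
            if len(codon) < 3:
                continue
            ref_aa = CODON_TABLE.get("".join(codon), "X")
            codon[frame] = v.alt.upper()
            alt_aa = CODON_TABLE.get("".join(codon), "X")
            if ref_aa != alt_aa:
                saps.add((codon_i + 1, ref_aa, alt_aa))
    return {"tallies": tallies, "sap_count": len(saps),
            "saps": sorted(saps)}
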