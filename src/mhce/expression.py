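"""Allele-group, allelic, and isoform-level expression quantification.

Read evidence arrives summarized: per-read variant-overlap tags for
within-group allelic counts, per-group read counts for group proportions,
and equivalence-class counts (reads compatible with a set of isoforms) for
isoform abundances.  Isoform abundance uses a plain EM over equivalence
classes with length-normalized assignment probabilities, with a multinomial
bootstrap of class counts; the reported point estimate is the renormalized
mean of the bootstrap replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ReadAssignment", "IsoformAbundance", "assign_reads",
    "group_proportions", "em_abundance", "spearman_correlation",
    "rank_sum_trend", "locus_tpm",
]

_VALID_CODES = {"ref_only", "alt_only", "common", "multi", "qc_fail"}


@dataclass
class ReadAssignment:
    """Counts after applying the variant-tag assignment rules."""

    ref: int = 0
    alt: int = 0
    common: int = 0
    discarded: int = 0
    errors: int = 0


def assign_reads(records) -> ReadAssignment:
    """Assign reads to alleles from variant-overlap tags.

    ``records``: iterable of codes (or (read id, code) pairs).  ref_only ->
    reference allele, alt_only -> alternate allele, common -> shared pool;
    multi-variant conflicts and QC failures are discarded; unknown codes
    are discarded and counted as errors.
    """
    out = ReadAssignment()
    for rec in records:
        code = rec[1] if isinstance(rec, (tuple, list)) else rec
        if code == "ref_only":
            out.ref += 1
        elif code == "alt_only":
            out.alt += 1
        elif code == "common":
            out.common += 1
        elif code in _VALID_CODES:
            out.discarded += 1
        else:
            out.discarded += 1
            out.errors += 1
    return out


def group_proportions(counts: dict) -> dict:
    """Per-group proportions of total locus expression."""
    total = sum(counts.values())
    if total <= 0:
        warnings.warn("zero total count; proportions undefined")
        return {g: float("nan") for g in counts}
    return {g: c / total for g, c in counts.items()}


def locus_tpm(counts: dict, lengths: dict | None = None) -> dict:
    """Locus-restricted TPM over the locus contigs only.

    With per-contig effective lengths the counts are length-normalized
    first; otherwise TPM is proportion x 1e6.
    """
    if lengths:
        rate = {g: counts[g] / lengths[g] for g in counts}
    else:
        rate = dict(counts)
    total = sum(rate.values())
    if total <= 0:
        warnings.warn("zero total count; TPM undefined")
        return {g: float("nan") for g in counts}
    return {g: 1e6 * r / total for g, r in rate.items()}


@dataclass
class IsoformAbundance:
    """EM abundance estimates with bootstrap uncertainty."""

    ids: list
    proportions: np.ndarray          # mean of bootstraps, renormalized
    em_estimate: np.ndarray          # single EM fit on the observed counts
    bootstrap: np.ndarray            # (n_bootstrap, n_isoforms)
    log_likelihoods: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return dict(zip(self.ids, self.proportions.tolist()))


def _em(class_members, class_counts, inv_len, n_iso,
        max_iter=1000, tol=1e-8, track_ll=False):
    """EM over read fractions theta; within-class assignment is
    length-normalized (weight theta_i / len_i)."""
    theta = np.full(n_iso, 1.0 / n_iso)
    total = class_counts.sum()
    lls = []
    for _ in range(max_iter):
        n = np.zeros(n_iso)
        ll = 0.0
        for members, count in zip(class_members, class_counts):
            w = theta[members] * inv_len[members]
            s = w.sum()
            if s <= 0:
                continue
            n[members] += count * w / s
            if track_ll:
                ll += count * np.log(max(s, 1e-300))
        new_theta = n / total
        if track_ll:
            lls.append(ll)
        if np.max(np.abs(new_theta - theta)) < tol:
            theta = new_theta
            break
        theta = new_theta
    # convert read fractions to molar proportions via effective lengths
    rho = theta * inv_len
    s = rho.sum()
    rho = rho / s if s > 0 else rho
    return rho, lls


def em_abundance(classes: dict, lengths: dict | None = None,
                 n_bootstrap: int = 25, seed: int | None = None,
                 max_iter: int = 1000, tol: float = 1e-8
                 ) -> IsoformAbundance:
    """EM isoform proportions from equivalence-class read counts.

    ``classes``: mapping isoform-id-set -> read count; ``lengths``:
    effective length per isoform (default 1, i.e. read fractions).  Within
    a class a read is fractionally assigned proportionally to current
    read-fraction estimates; the reported proportions are molar
    (read fraction / effective length, renormalized).  The bootstrap
    resamples class counts multinomially and reruns EM; the point estimate
    is the renormalized bootstrap mean.
    """
    ids = sorted({i for cls in classes for i in cls})
    if not ids or sum(classes.values()) <= 0:
        raise ValueError("need at least one class with positive count")
    idx = {i: k for k, i in enumerate(ids)}
    keys = sorted(classes, key=lambda c: tuple(sorted(c)))
    class_members = [np.array([idx[i] for i in sorted(c)]) for c in keys]
    class_counts = np.array([classes[c] for c in keys], dtype=float)
    if np.any(class_counts < 0):
        raise ValueError("negative class count")
    if lengths is None:
        inv_len = np.ones(len(ids))
    else:
        inv_len = np.array([1.0 / lengths[i] for i in ids])

    point, lls = _em(class_members, class_counts, inv_len, len(ids),
                     max_iter, tol, track_ll=True)
    rng = np.random.default_rng(seed)
    total = int(class_counts.sum())
    p = class_counts / class_counts.sum()
    boot = np.zeros((n_bootstrap, len(ids)))
    for b in range(n_bootstrap):
        resampled = rng.multinomial(total, p).astype(float)
        boot[b], _ = _em(class_members, resampled, inv_len, len(ids),
                         max_iter, tol)
    mean = boot.mean(axis=0)
    s = mean.sum()
    mean = mean / s if s > 0 else mean
    return IsoformAbundance(ids=ids, proportions=mean, em_estimate=point,
                            bootstrap=boot, log_likelihoods=lls)


def spearman_correlation(x, y) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant series; Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def rank_sum_trend(baseline, timepoint, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p comparing a timepoint with baseline.

    Exact enumeration for small untied samples (both sizes <=
    ``exact_max_n``); otherwise the normal approximation with tie
    correction.  All values tied across both groups gives p = 1.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(timepoint, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) <= exact_max_n and len(y) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
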