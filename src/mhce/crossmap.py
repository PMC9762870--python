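"""Cross-species isoform comparison through an alignment coordinate map.

The macaque and human MHC-E loci are aligned pairwise once; the alignment
defines a strictly monotone coordinate converter used to lift transcript
models from one genome to the other.  Lifted catalogs are compared at the
splice-junction level (junction sharing and whole-chain perfect matches),
incomplete 5' ends are inferred from matched models of the other species,
and spliceosome complexity is compared by resampling full-length read
counts at a fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align

from .isoforms import IsoformCatalog, TranscriptModel

__all__ = [
    "CoordinateMap", "MatchReport", "align_sequences",
    "build_coordinate_map", "convert_model", "match_isoforms",
    "infer_5p_ends", "resample_detection", "expected_detection",
]


@dataclass
class CoordinateMap:
    """Monotone position correspondence between two aligned sequences."""

    a_pos: np.ndarray
    b_pos: np.ndarray
    gaps_a: list = field(default_factory=list)  # intervals of A absent in B
    gaps_b: list = field(default_factory=list)  # intervals of B absent in A

    def __post_init__(self):
        self.a_pos = np.asarray(self.a_pos, dtype=int)
        self.b_pos = np.asarray(self.b_pos, dtype=int)
        if np.any(np.diff(self.a_pos) <= 0) or np.any(np.diff(self.b_pos) <= 0):
            raise ValueError("coordinate map is not strictly monotone")
        self._a2b = dict(zip(self.a_pos.tolist(), self.b_pos.tolist()))
        self._b2a = dict(zip(self.b_pos.tolist(), self.a_pos.tolist()))

    def a_to_b(self, pos: int):
        """Map an A position to B; None when it falls in a B-gap."""
        return self._a2b.get(pos)

    def b_to_a(self, pos: int):
        return self._b2a.get(pos)

    def invert(self) -> "CoordinateMap":
        return CoordinateMap(self.b_pos, self.a_pos,
                             gaps_a=self.gaps_b, gaps_b=self.gaps_a)


def build_coordinate_map(alignment) -> CoordinateMap:
    """Build a converter from a pairwise alignment.

    ``alignment`` is a pair of equal-length gapped strings covering both
    sequences end to end.
    """
    aln_a, aln_b = alignment
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned strings differ in length")
    a_pos, b_pos = [], []
    gaps_a, gaps_b = [], []
    i = j = 0
    for ca, cb in zip(aln_a, aln_b):
        if ca != "-" and cb != "-":
            a_pos.append(i)
            b_pos.append(j)
            i += 1
            j += 1
        elif ca != "-":
            if gaps_a and gaps_a[-1][1] == i:
                gaps_a[-1] = (gaps_a[-1][0], i + 1)
            else:
                gaps_a.append((i, i + 1))
            i += 1
        elif cb != "-":
            if gaps_b and gaps_b[-1][1] == j:
                gaps_b[-1] = (gaps_b[-1][0], j + 1)
            else:
                gaps_b.append((j, j + 1))
            j += 1
    return CoordinateMap(np.array(a_pos), np.array(b_pos),
                         gaps_a=gaps_a, gaps_b=gaps_b)


def align_sequences(seq_a: str, seq_b: str) -> tuple:
    """Global Needleman–Wunsch alignment returning gapped strings.

    Used to build coordinate maps for fixtures; any external aligner's
    output can be substituted.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def convert_model(cmap: CoordinateMap, model: TranscriptModel
                  ) -> TranscriptModel:
    """Lift a model's exon boundaries through the coordinate map.

    Exon ends (exclusive) are mapped via their last base.  If any boundary
    falls in an alignment gap the model is returned flagged
    ``unconvertible``.
    """
    new_exons = []
    for s, e in model.exons:
        ms = cmap.a_to_b(s)
        me = cmap.a_to_b(e - 1)
        if ms is None or me is None:
            return replace(model, flags=set(model.flags) | {"unconvertible"})
        new_exons.append((ms, me + 1))
    return replace(model, exons=new_exons)


@dataclass
class MatchReport:
    """Junction-level comparison of two catalogs in one coordinate system."""

    perfect_matches: list          # (query id, target id)
    shared_junctions: set
    novel_junctions: set           # in query, absent from target
    per_isoform: dict              # query id -> dict

    @property
    def n_perfect(self) -> int:
        return len(self.perfect_matches)


def match_isoforms(query: IsoformCatalog, target: IsoformCatalog
                   ) -> MatchReport:
    """Compare junction chains of a lifted catalog against a target catalog.

    A perfect match is an identical junction chain (ends may differ within
    the clustering window).  Models flagged unconvertible are skipped.
    """
    target_junc = target.junction_set()
    target_chains = {m.junctions: m.id for m in target}
    perfect, per_isoform = [], {}
    shared, novel = set(), set()
    for m in query:
        if "unconvertible" in m.flags:
            continue
        mj = set(m.junctions)
        sh, nv = mj & target_junc, mj - target_junc
        shared |= sh
        novel |= nv
        hit = target_chains.get(m.junctions)
        if hit is not None:
            perfect.append((m.id, hit))
        per_isoform[m.id] = {
            "shared_junctions": sorted(sh),
            "novel_junctions": sorted(nv),
            "perfect_match": hit,
        }
    return MatchReport(perfect_matches=perfect, shared_junctions=shared,
                       novel_junctions=novel, per_isoform=per_isoform)


def infer_5p_ends(incomplete: TranscriptModel, matched: TranscriptModel
                  ) -> TranscriptModel:
    """Restore missing 5' exons from a matched model of the other species.

    Requires the incomplete model's junction chain to be a 3'-anchored
    suffix of the matched chain (both already in one coordinate system).
    """
    ji, jm = incomplete.junctions, matched.junctions
    if incomplete.strand != matched.strand:
        raise ValueError("strand mismatch")
    if len(ji) > len(jm) or (len(ji) and jm[len(jm) - len(ji):] != ji):
        raise ValueError("junction chains are not 3'-anchored compatible")
    if len(ji) == len(jm):
        return incomplete
    n_missing = len(jm) - len(ji)
    if incomplete.strand == "+":
        exons = list(matched.exons[:n_missing])
        first = incomplete.exons[0]
        exons.append((matched.exons[n_missing][0], first[1]))
        exons.extend(incomplete.exons[1:])
    else:
        exons = list(incomplete.exons[:-1])
        last = incomplete.exons[-1]
        exons.append((last[0], matched.exons[-(n_missing + 1)][1]))
        exons.extend(matched.exons[len(matched.exons) - n_missing:])
    flags = set(incomplete.flags) - {"incomplete_5p"}
    return replace(incomplete, exons=exons, source="inferred", flags=flags)


def resample_detection(fl_counts, depth: int = 123, reps: int = 10000,
                       seed: int | None = None) -> tuple:
    """Mean and SD of distinct isoforms seen at a fixed resampling depth.

    Each replicate draws ``depth`` reads with replacement with
    probabilities proportional to ``fl_counts`` and counts the distinct
    isoforms observed.
    """
    counts = np.asarray(fl_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative FL counts")
    if counts.sum() == 0:
        raise ValueError("all-zero FL counts")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    p = counts / counts.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(depth, p, size=reps)
    detected = (draws > 0).sum(axis=1)
    return float(detected.mean()), float(detected.std(ddof=1))


def expected_detection(fl_counts, depth: int = 123) -> float:
    """Closed-form expectation sum_i 1 - (1 - p_i)^depth."""
    counts = np.asarray(fl_counts, dtype=float)
    p = counts / counts.sum()
    return float(np.sum(1.0 - (1.0 - p) ** depth))
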