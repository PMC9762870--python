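"""Read-backed haplotype phasing of the dominant MHC-E locus from RNA-seq.

Evidence arrives as summarized observations on the canonical transcript:
per-base coverage, per-base base counts, and per-sample pairwise variant
connections (read counts supporting each phase configuration of two
heterozygous sites).  The phaser: trims low-coverage transcript ends,
masks multimapping-prone regions by exact k-mer lookup, calls bases at a
fractional-coverage threshold, builds a maximum-spanning forest over
connection support and propagates the majority configuration, merges
blocks whose per-sample dominant-haplotype orientation agrees unanimously,
demotes variants whose connections conflict with the phase, and expands
the primary block into two full-length haplotig sequences with IUPAC codes
at unresolved sites.  Haplotigs are then matched against amplicon alleles
by minimal mismatches and merged with the allele across the linking
intron.

Phase is defined only up to a global flip; comparisons must be made up to
haplotype relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "VariantCall", "ConnectionGraph", "HaplotypeBlock", "IUPAC",
    "pool_and_trim_coverage", "kmer_blacklist", "call_bases",
    "phase_blocks", "merge_blocks", "screen_conflicts", "expand_haplotigs",
    "collapse_haplotigs", "match_haplotigs_to_alleles",
    "merge_allele_with_utr", "block_haplotype_coverage",
]

IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}

_BASES = ("A", "C", "G", "T")


@dataclass
class VariantCall:
    """Base call at one transcript position (25%-coverage rule)."""

    position: int
    bases: tuple                 # called bases, descending support
    fractions: tuple
    zygosity: str                # hom / het / ambiguous


@dataclass
class ConnectionGraph:
    """Pairwise phase evidence between heterozygous positions.

    ``edges``: (pos_i, pos_j) with pos_i < pos_j -> per-sample dict
    sample -> 2x2 count matrix n[a][b] = reads carrying called base ``a``
    of i with called base ``b`` of j (indices into each site's called-base
    pair).
    """

    edges: dict = field(default_factory=dict)

    def add(self, sample, pos_i, pos_j, counts):
        if pos_j < pos_i:
            pos_i, pos_j = pos_j, pos_i
            counts = np.asarray(counts).T
        key = (pos_i, pos_j)
        per = self.edges.setdefault(key, {})
        per[sample] = per.get(sample, np.zeros((2, 2))) + np.asarray(
            counts, dtype=float)

    def totals(self, pos_i, pos_j) -> np.ndarray:
        key = (pos_i, pos_j) if pos_i < pos_j else (pos_j, pos_i)
        mats = self.edges.get(key, {})
        total = np.zeros((2, 2))
        for m in mats.values():
            total += m
        if pos_j < pos_i:
            total = total.T
        return total

    def nodes(self):
        out = set()
        for i, j in self.edges:
            out.add(i)
            out.add(j)
        return out


@dataclass
class HaplotypeBlock:
    """Phased heterozygous positions; orientation 0/1 per position.

    hap1 base at p = calls[p].bases[orientation[p]].  Defined up to a
    global flip.  ``ambiguous`` collects demoted positions, ``unevaluated``
    positions that had no qualifying conflict-screen edges.
    """

    positions: list
    orientation: dict
    calls: dict
    ambiguous: list = field(default_factory=list)
    unevaluated: list = field(default_factory=list)

    def hap_bases(self, p):
        o = self.orientation[p]
        b = self.calls[p].bases
        return b[o], b[1 - o]

    def flip(self) -> "HaplotypeBlock":
        return HaplotypeBlock(
            positions=list(self.positions),
            orientation={p: 1 - o for p, o in self.orientation.items()},
            calls=self.calls, ambiguous=list(self.ambiguous),
            unevaluated=list(self.unevaluated))


# ---------------------------------------------------------------------------
# coverage trimming and k-mer masking


def pool_and_trim_coverage(tracks, min_cov: int = 10000) -> tuple:
    """Retained transcript interval after end-trimming pooled coverage.

    Coverage is summed across samples; the maximal prefix and suffix with
    pooled depth below ``min_cov`` are removed.  Interior dips are kept
    (the rule trims ends only).
    """
    if len(tracks) == 0:
        raise ValueError("need at least one coverage track")
    pooled = np.sum(np.asarray(tracks, dtype=float), axis=0)
    above = np.nonzero(pooled >= min_cov)[0]
    if above.size == 0:
        raise ValueError("all positions below the coverage threshold")
    return int(above[0]), int(above[-1]) + 1


def kmer_blacklist(target_seqs: dict, background, k: int = 76) -> dict:
    """Mask positions covered only by k-mers repeated in the background.

    ``background`` is a sequence or dict of sequences (normally including
    the targets' own source contigs).  A position is kept when at least one
    overlapping k-mer of the target occurs at most once in the background;
    otherwise it is masked as multimapping-prone.  Returns target id ->
    list of masked (start, end) intervals.
    """
    if isinstance(background, str):
        background = {"background": background}
    counts: dict = {}
    for seq in background.values():
        if len(seq) < k:
            raise ValueError("background sequence shorter than k")
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            counts[km] = counts.get(km, 0) + 1
    out = {}
    for name, seq in target_seqs.items():
        if len(seq) < k:
            raise ValueError(f"target {name!r} shorter than k={k}")
        n = len(seq)
        unique_cover = np.zeros(n, dtype=bool)
        for i in range(n - k + 1):
            if counts.get(seq[i:i + k], 0) <= 1:
                unique_cover[i:i + k] = True
        masked = []
        run = None
        for pos in range(n):
            if not unique_cover[pos]:
                run = (run[0], pos + 1) if run else (pos, pos + 1)
            elif run:
                masked.append(run)
                run = None
        if run:
            masked.append(run)
        out[name] = masked
    return out


# ---------------------------------------------------------------------------
# base calling


def call_bases(base_counts, positions=None,
               call_fraction: float = 0.25) -> list:
    """Call bases at each position at a fractional-coverage threshold.

    ``base_counts``: array (n_positions, 4) of A/C/G/T counts.  Bases with
    fraction >= ``call_fraction`` (inclusive) are called; one call is a
    homozygous site, two a heterozygous site, more than two demotes the
    position to ambiguous with a warning.
    """
    base_counts = np.asarray(base_counts, dtype=float)
    if positions is None:
        positions = range(base_counts.shape[0])
    calls = []
    for pos, row in zip(positions, base_counts):
        total = row.sum()
        if total <= 0:
            continue
        frac = row / total
        called = [(f, b) for f, b in zip(frac, _BASES)
                  if f >= call_fraction]
        called.sort(key=lambda t: (-t[0], t[1]))
        bases = tuple(b for _, b in called)
        fracs = tuple(f for f, _ in called)
        if len(bases) == 1:
            zyg = "hom"
        elif len(bases) == 2:
            zyg = "het"
        else:
            zyg = "ambiguous"
            warnings.warn(f"position {pos}: {len(bases)} bases pass "
                          f"{call_fraction:.0%}; demoted to ambiguous")
        calls.append(VariantCall(position=int(pos), bases=bases,
                                 fractions=fracs, zygosity=zyg))
    return calls


# ---------------------------------------------------------------------------
# phasing


def _edge_config(totals: np.ndarray) -> tuple:
    """(same_orientation, support, conflict) from a 2x2 count matrix."""
    parallel = totals[0, 0] + totals[1, 1]
    cross = totals[0, 1] + totals[1, 0]
    same = parallel >= cross      # tie resolves to parallel
    support = parallel + cross
    conflict = cross if same else parallel
    return same, support, conflict


def phase_blocks(graph: ConnectionGraph, het_positions=None) -> list:
    """Phase by maximum-spanning forest and majority propagation.

    Edges are weighted by total connection support; within each spanning
    tree the majority configuration of each edge propagates orientations
    from an arbitrary root.  Isolated heterozygous positions become
    singleton blocks.  No statistical pruning of edges is applied.
    """
    g = nx.Graph()
    calls = {}
    if het_positions:
        for c in het_positions:
            if isinstance(c, VariantCall):
                if c.zygosity != "het":
                    continue
                g.add_node(c.position)
                calls[c.position] = c
            else:
                g.add_node(c)
    for (i, j), per in graph.edges.items():
        if het_positions and (i not in g.nodes or j not in g.nodes):
            continue
        total = sum(m.sum() for m in per.values())
        g.add_edge(i, j, weight=total)
    for n in graph.nodes():
        if not het_positions:
            g.add_node(n)
    blocks = []
    for comp in sorted(nx.connected_components(g), key=min):
        sub = g.subgraph(comp)
        forest = nx.maximum_spanning_tree(sub, weight="weight")
        root = min(comp)
        orientation = {root: 0}
        for u, v in nx.bfs_edges(forest, root):
            same, _, _ = _edge_config(graph.totals(u, v))
            orientation[v] = orientation[u] if same else 1 - orientation[u]
        blocks.append(HaplotypeBlock(
            positions=sorted(comp), orientation=orientation, calls=calls))
    return blocks


def screen_conflicts(block: HaplotypeBlock, graph: ConnectionGraph,
                     min_support: int = 100,
                     max_conflict: float = 0.20) -> HaplotypeBlock:
    """Demote variants whose phase conflicts with their connections.

    For each variant, edges to other in-block variants carrying at least
    ``min_support`` reads are examined; if the average conflicting-read
    fraction exceeds ``max_conflict`` the variant is removed from the
    block and recorded as ambiguous.  Variants with no qualifying edge are
    retained but flagged unevaluated.
    """
    in_block = set(block.positions)
    demoted, unevaluated = [], []
    for p in block.positions:
        fracs = []
        for q in block.positions:
            if q == p:
                continue
            totals = graph.totals(*sorted((p, q)))
            support = totals.sum()
            if support < min_support:
                continue
            parallel = totals[0, 0] + totals[1, 1]
            cross = totals[0, 1] + totals[1, 0]
            same_assigned = block.orientation[p] == block.orientation[q]
            conflict = cross if same_assigned else parallel
            fracs.append(conflict / support)
        if not fracs:
            unevaluated.append(p)
        elif float(np.mean(fracs)) > max_conflict:
            demoted.append(p)
    keep = [p for p in block.positions if p not in demoted]
    return HaplotypeBlock(
        positions=keep,
        orientation={p: block.orientation[p] for p in keep},
        calls=block.calls,
        ambiguous=sorted(set(block.ambiguous) | set(demoted)),
        unevaluated=unevaluated)


def block_haplotype_coverage(block: HaplotypeBlock, allele_depths) -> dict:
    """Per-sample read depth of each block haplotype.

    ``allele_depths``: sample -> {position: (depth of called base 1, depth
    of called base 2)}.  Depths of the bases assigned to each haplotype are
    summed over the block's positions.
    """
    out = {}
    for sample, depths in allele_depths.items():
        c1 = c2 = 0.0
        for p in block.positions:
            if p not in depths:
                continue
            d = depths[p]
            o = block.orientation[p]
            c1 += d[o]
            c2 += d[1 - o]
        out[sample] = (c1, c2)
    return out


def merge_blocks(blocks: list, coverage_fn) -> list:
    """Merge blocks whose dominant-haplotype pairing is unanimous.

    ``coverage_fn(block)`` returns sample -> (cov hap1, cov hap2).  For a
    candidate pair of blocks, each sample orients them by pairing the
    higher-coverage haplotypes; the merge happens only when every sample
    yields the same relative orientation, and a sample with exactly equal
    coverages vetoes it.  Pairs are retried until no merge applies.
    """
    blocks = [b for b in blocks]
    merged = True
    while merged and len(blocks) > 1:
        merged = False
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                rel = _consensus_orientation(coverage_fn(blocks[i]),
                                             coverage_fn(blocks[j]))
                if rel is None:
                    continue
                b2 = blocks[j] if rel == 0 else blocks[j].flip()
                b1 = blocks[i]
                blocks = [b for k, b in enumerate(blocks) if k not in (i, j)]
                blocks.append(HaplotypeBlock(
                    positions=sorted(b1.positions + b2.positions),
                    orientation={**b1.orientation, **b2.orientation},
                    calls={**b1.calls, **b2.calls},
                    ambiguous=sorted(set(b1.ambiguous) | set(b2.ambiguous)),
                    unevaluated=sorted(set(b1.unevaluated)
                                       | set(b2.unevaluated))))
                merged = True
                break
            if merged:
                break
    return sorted(blocks, key=lambda b: (-len(b.positions), b.positions))


def _consensus_orientation(cov1: dict, cov2: dict):
    """0/1 if all samples orient the two blocks identically, else None."""
    rels = set()
    for sample in cov1:
        if sample not in cov2:
            return None
        a1, a2 = cov1[sample]
        b1, b2 = cov2[sample]
        if a1 == a2 or b1 == b2:
            return None       # no consensus contribution from this sample
        rels.add(0 if (a1 > a2) == (b1 > b2) else 1)
        if len(rels) > 1:
            return None
    return rels.pop() if rels else None


# ---------------------------------------------------------------------------
# haplotig expansion and allele integration


def expand_haplotigs(primary: HaplotypeBlock, calls: list,
                     reference: str) -> tuple:
    """Expand the primary block into two full-length haplotig sequences.

    Homozygous calls are applied to both haplotigs; phased heterozygous
    positions receive their haplotype bases; heterozygous positions outside
    the primary block (or demoted) receive the IUPAC code of their called
    bases in both haplotigs.
    """
    h1, h2 = list(reference), list(reference)
    in_block = set(primary.positions)
    seen_hom = set()
    for c in calls:
        if c.zygosity == "hom":
            seen_hom.add(c.position)
    for c in calls:
        p = c.position
        if c.zygosity == "hom":
            h1[p] = h2[p] = c.bases[0]
        elif c.zygosity == "het":
            if p in seen_hom:
                raise ValueError(f"position {p} both hom- and het-called")
            if p in in_block:
                b1, b2 = primary.hap_bases(p)
                h1[p], h2[p] = b1, b2
            else:
                code = IUPAC[frozenset(c.bases)]
                h1[p] = h2[p] = code
        else:  # ambiguous
            code = IUPAC.get(frozenset(c.bases), "N")
            h1[p] = h2[p] = code
    return "".join(h1), "".join(h2)


def collapse_haplotigs(haplotigs: dict, utr_interval: tuple) -> dict:
    """Collapse haplotigs that differ only at 3' UTR positions."""
    lo, hi = utr_interval
    items = sorted(haplotigs.items())
    out = {}
    for name, seq in items:
        dup = None
        for kept_name, kept_seq in out.items():
            if len(kept_seq) == len(seq) and all(
                    a == b or lo <= p < hi
                    for p, (a, b) in enumerate(zip(kept_seq, seq))):
                dup = kept_name
                break
        if dup is None:
            out[name] = seq
    return out


def match_haplotigs_to_alleles(haplotigs: dict, alleles: dict,
                               comparable_positions=None,
                               excluded_positions=()) -> list:
    """Greedy minimal-mismatch pairing of haplotigs with allele sequences.

    Sequences are assumed to share a coordinate system; comparison runs
    over ``comparable_positions`` (default: the full overlap) minus
    ``excluded_positions``.  The globally best pair is fixed first, then
    the best among the remainder, and so on.  Returns a list of
    (haplotig id, allele id, mismatches).
    """
    if not haplotigs and not alleles:
        return []
    excluded = set(excluded_positions)

    def mismatches(h, a):
        pos = comparable_positions
        if pos is None:
            pos = range(min(len(h), len(a)))
        return sum(1 for p in pos
                   if p not in excluded and p < len(h) and p < len(a)
                   and h[p].upper() != a[p].upper())

    scores = {(hn, an): mismatches(hs, asq)
              for hn, hs in haplotigs.items()
              for an, asq in alleles.items()}
    pairs = []
    free_h, free_a = set(haplotigs), set(alleles)
    while free_h and free_a:
        (hn, an) = min(((h, a) for h in sorted(free_h)
                        for a in sorted(free_a)),
                       key=lambda k: (scores[k], k))
        pairs.append((hn, an, scores[(hn, an)]))
        free_h.discard(hn)
        free_a.discard(an)
    return pairs


def merge_allele_with_utr(allele_seq: str, haplotig_utr: str,
                          linking_intron: str | None) -> tuple:
    """Concatenate allele + linking intron + haplotig 3' UTR.

    Returns (sequence, junction coordinates) where the junction dict gives
    the start of the linking intron and of the 3' UTR exon in the merged
    sequence.
    """
    if linking_intron is None:
        raise ValueError("linking intronic sequence is required")
    if not haplotig_utr:
        warnings.warn("empty 3' UTR; merged sequence is allele + intron only")
    seq = allele_seq + linking_intron + haplotig_utr
    junctions = {
        "intron_start": len(allele_seq),
        "utr_exon_start": len(allele_seq) + len(linking_intron),
    }
    return seq, junctions
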