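"""Typing of MHC-E amplicon alleles and allele-relationship summaries.

Amplicon haplotypes fall into four structural groups: full-length alleles
close to the reference (G1), full-length alleles ~5% diverged (G2), G2-like
alleles carrying a ~700 bp solo LTR insertion just downstream of the
amplicon 5' end (G2_LTR), and alleles with a ~600 bp deletion removing the
canonical exon 6 (G3).  Classification is by structural evidence with the
precedence LTR > exon-6 deletion > divergence band, then relationships are
summarized by per-segment identity, classical MDS, and neighbor-joining /
Jukes–Cantor maximum-likelihood trees.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "AlleleSequence", "AlleleGroupCall", "TypingThresholds", "Tree",
    "detect_ltr_insertion", "detect_exon6_deletion", "classify_allele_group",
    "pairwise_segment_identity", "classical_mds", "jc_distance",
    "nj_tree", "ml_refine", "detect_group_linkage", "sequence_divergence",
]


@dataclass
class AlleleSequence:
    """One amplicon haplotype with optional named segment intervals."""

    allele_id: str
    animal_id: str
    sequence: str
    segments: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty allele sequence")


@dataclass
class AlleleGroupCall:
    group: str                      # G1 / G2 / G2_LTR / G3 / unassigned
    ltr_hit: tuple | None = None    # (position, length)
    exon6_deletion: tuple | None = None
    divergence_to_g1: float = 0.0


@dataclass
class TypingThresholds:
    ltr_min_length: int = 500
    ltr_min_identity: float = 0.8
    min_deletion: int = 400
    g2_band: tuple = (0.02, 0.10)
    max_divergence: float = 0.20


def _cigar_stats(cigar: str) -> dict:
    out = {"=": 0, "X": 0, "I": 0, "D": 0}
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out[ch] += int(n)
            n = ""
    return out


def sequence_divergence(seq: str, ref: str) -> float:
    """Substitution divergence over aligned (non-gap) columns."""
    res = edlib.align(seq, ref, mode="NW", task="path")
    st = _cigar_stats(res["cigar"])
    aligned = st["="] + st["X"]
    return st["X"] / aligned if aligned else 1.0


_LOCAL_ALIGNER = None


def _local_aligner():
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        from Bio import Align
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -2
        _LOCAL_ALIGNER = a
    return _LOCAL_ALIGNER


def detect_ltr_insertion(allele, repeat_library: dict,
                         min_length: int = 500,
                         min_identity: float = 0.8):
    """Best local repeat-consensus hit in the allele's 5' upstream segment.

    Each consensus is locally aligned (Smith–Waterman) against the
    segment; the best-scoring hit with matched span >= ``min_length`` and
    identity (matches over local alignment columns) >= ``min_identity``
    is returned as (position, length), else None.
    """
    if isinstance(allele, AlleleSequence):
        seq = allele.sequence
        region = allele.segments.get("5p_upstream")
    else:
        seq, region = allele, None
    if region is not None:
        lo, hi = region
        target = seq[lo:hi]
    else:
        lo, target = 0, seq
    if not target:
        return None
    aligner = _local_aligner()
    best = None
    for name in sorted(repeat_library):
        consensus = repeat_library[name]
        alns = aligner.align(target, consensus)
        if len(alns) == 0:
            continue
        aln = alns[0]
        c = aln.counts()
        cols = c.gaps + c.identities + c.mismatches
        identities = c.identities
        identity = identities / cols if cols else 0.0
        t_start = int(aln.aligned[0][0][0])
        t_end = int(aln.aligned[0][-1][1])
        span = t_end - t_start
        if span >= min_length and identity >= min_identity:
            if best is None or aln.score > best[0]:
                best = (aln.score, lo + t_start, span)
    if best is None:
        return None
    return (best[1], best[2])


def detect_exon6_deletion(allele, canonical_ref: str, exon6_interval: tuple,
                          min_deletion: int = 400):
    """Alignment gap >= ``min_deletion`` containing the whole exon-6 span.

    ``exon6_interval`` is in reference coordinates.  Returns (ref position,
    length) or None.
    """
    seq = allele.sequence if isinstance(allele, AlleleSequence) else allele
    if not seq:
        raise ValueError("cannot align an empty allele")
    res = edlib.align(seq, canonical_ref, mode="NW", task="path")
    # Edit-distance alignment fragments long deletions around chance
    # single-base matches; merge deletion runs separated by short matched
    # stretches into one deleted region before testing containment.
    ref_pos = 0
    n = ""
    runs = []          # (ref start, ref end, deleted bases)
    for ch in res["cigar"]:
        if ch.isdigit():
            n += ch
            continue
        length = int(n)
        n = ""
        if ch in "=X":
            ref_pos += length
        elif ch == "D":  # absent from the allele, present in the reference
            if runs and ref_pos - runs[-1][1] <= 20:
                s, _, deleted = runs[-1]
                runs[-1] = (s, ref_pos + length, deleted + length)
            else:
                runs.append((ref_pos, ref_pos + length, length))
            ref_pos += length
        # 'I': allele-only sequence, reference does not advance
    e6s, e6e = exon6_interval
    for (s, e, deleted) in runs:
        if deleted >= min_deletion and s <= e6s and e >= e6e:
            return (s, deleted)
    return None


def classify_allele_group(allele, g1_references: list, repeat_library: dict,
                          canonical_ref: str, exon6_interval: tuple,
                          thresholds: TypingThresholds | None = None
                          ) -> AlleleGroupCall:
    """Classify one amplicon allele into G1/G2/G2_LTR/G3.

    Precedence: LTR insertion -> G2_LTR; exon-6 deletion -> G3; divergence
    to the closest G1 reference within the G2 band -> G2; above
    ``max_divergence`` -> unassigned (warning); otherwise G1.  Divergence
    is substitutions over aligned columns, computed after excising a
    detected LTR so the insertion itself does not inflate it.
    """
    th = thresholds or TypingThresholds()
    if not g1_references:
        raise ValueError("at least one G1 reference is required")
    seq = allele.sequence if isinstance(allele, AlleleSequence) else allele

    ltr = detect_ltr_insertion(allele, repeat_library,
                               th.ltr_min_length, th.ltr_min_identity)
    core = seq
    if ltr is not None:
        pos, length = ltr
        core = seq[:pos] + seq[pos + length:]
    div = min(sequence_divergence(core, ref) for ref in g1_references)
    if ltr is not None:
        return AlleleGroupCall("G2_LTR", ltr_hit=ltr, divergence_to_g1=div)
    deletion = detect_exon6_deletion(seq, canonical_ref, exon6_interval,
                                     th.min_deletion)
    if deletion is not None:
        return AlleleGroupCall("G3", exon6_deletion=deletion,
                               divergence_to_g1=div)
    if div > th.max_divergence:
        warnings.warn(f"allele divergence {div:.3f} exceeds "
                      f"{th.max_divergence}; unassigned")
        return AlleleGroupCall("unassigned", divergence_to_g1=div)
    lo, hi = th.g2_band
    if lo <= div <= hi:
        return AlleleGroupCall("G2", divergence_to_g1=div)
    return AlleleGroupCall("G1", divergence_to_g1=div)


# ---------------------------------------------------------------------------
# segment identity and MDS


def pairwise_segment_identity(aligned_seqs: list, segment: tuple | None = None
                              ) -> np.ndarray:
    """Identity matrix over pre-aligned sequences (gapped, equal length).

    Identity = matches / columns where both sequences have a base, after
    trimming each pair's terminal-gap overhangs; restricted to the given
    alignment-column ``segment`` if provided.
    """
    if segment is not None and segment[0] >= segment[1]:
        raise ValueError("empty segment")
    seqs = [s if segment is None else s[segment[0]:segment[1]]
            for s in aligned_seqs]
    if any(not s for s in seqs):
        raise ValueError("empty segment")
    n = len(seqs)
    mat = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = seqs[i], seqs[j]
        lo = 0
        hi = len(a)
        while lo < hi and (a[lo] == "-" or b[lo] == "-") and \
                (_is_terminal_gap(a, lo) or _is_terminal_gap(b, lo)):
            lo += 1
        while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-") and \
                (_is_terminal_gap(a, hi - 1) or _is_terminal_gap(b, hi - 1)):
            hi -= 1
        matches = cols = 0
        for ca, cb in zip(a[lo:hi], b[lo:hi]):
            if ca == "-" or cb == "-":
                continue
            cols += 1
            if ca.upper() == cb.upper():
                matches += 1
        ident = matches / cols if cols else 0.0
        mat[i, j] = mat[j, i] = ident
    return mat


def _is_terminal_gap(s: str, i: int) -> bool:
    if s[i] != "-":
        return False
    return set(s[:i + 1]) == {"-"} or set(s[i:]) == {"-"}


def classical_mds(identity_matrix: np.ndarray, dims: int = 2,
                  tol: float = 1e-8) -> np.ndarray:
    """Torgerson MDS on distance = 1 - identity.

    Double-centers the squared distances and embeds on the leading
    nonnegative eigenvectors; substantially negative eigenvalues among the
    leading ones trigger a warning and are dropped (coordinate set to 0).
    """
    m = np.asarray(identity_matrix, dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
        raise ValueError("identity matrix must be square symmetric")
    d = 1.0 - m
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if vals[k] > tol:
            coords[:, k] = vecs[:, k] * math.sqrt(vals[k])
        elif vals[k] < -tol:
            warnings.warn("negative eigenvalue in classical MDS; "
                          "component dropped")
    return coords


# ---------------------------------------------------------------------------
# distances and trees


def jc_distance(p_mismatch: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3) for p in [0, 0.75)."""
    if not 0 <= p_mismatch < 0.75:
        raise ValueError("mismatch fraction must be in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p_mismatch / 3.0)


class Tree:
    """Unrooted tree with branch lengths, stored as an adjacency map.

    Leaves are labeled nodes; internal nodes are integers.  Supports the
    operations the pipeline needs: leaf-to-leaf path lengths, newick
    export, splits (for topology comparison), and neighbor lookups.
    """

    def __init__(self):
        self.adj: dict = {}     # node -> {neighbor: branch length}
        self.leaves: list = []

    def add_edge(self, u, v, length: float):
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    def remove_edge(self, u, v):
        del self.adj[u][v]
        del self.adj[v][u]

    def edge_length(self, u, v) -> float:
        return self.adj[u][v]

    def set_edge_length(self, u, v, length: float):
        self.adj[u][v] = length
        self.adj[v][u] = length

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v, ln in nbrs.items():
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    yield u, v, ln

    def distance(self, a, b) -> float:
        """Path length between two nodes."""
        stack = [(a, None, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == b:
                return dist
            for nbr, ln in self.adj[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + ln))
        raise KeyError(f"no path {a} -> {b}")

    def splits(self) -> set:
        """Nontrivial bipartitions of the leaf set, for topology equality."""
        leafset = frozenset(self.leaves)
        out = set()
        for u, v, _ in self.edges():
            side = frozenset(self._leaves_beyond(v, u))
            if 1 < len(side) < len(leafset) - 1:
                out.add(min(side, leafset - side, key=sorted))
        return out

    def _leaves_beyond(self, node, parent):
        found = []
        stack = [(node, parent)]
        while stack:
            n, p = stack.pop()
            nbrs = [x for x in self.adj[n] if x != p]
            if not nbrs:
                found.append(n)
            for x in nbrs:
                stack.append((x, n))
        return found

    def newick(self) -> str:
        # root at the first internal node (or first leaf for 2-taxon trees)
        internal = [n for n in self.adj if n not in self.leaves]
        root = internal[0] if internal else self.leaves[0]

        def fmt(node, parent):
            children = [n for n in self.adj[node] if n != parent]
            if not children:
                return f"{node}:{self.adj[node][parent]:.6f}"
            inner = ",".join(fmt(c, node) for c in children)
            if parent is None:
                return f"({inner});"
            return f"({inner}):{self.adj[node][parent]:.6f}"

        return fmt(root, None)

    def copy(self) -> "Tree":
        t = Tree()
        t.leaves = list(self.leaves)
        t.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        return t


def nj_tree(distance_matrix, labels: list | None = None) -> Tree:
    """Neighbor joining (Saitou–Nei) with lowest-index tie breaking.

    Branch lengths are clamped at zero.  Additive matrices are recovered
    exactly (path lengths equal input distances).
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    tree = Tree()
    tree.leaves = list(labels)
    if n == 2:
        mid = 0
        tree.add_edge(labels[0], mid, max(d[0, 1] / 2, 0.0))
        tree.add_edge(labels[1], mid, max(d[0, 1] / 2, 0.0))
        return tree

    active = list(labels)
    dist = {(a, b): d[i, j] for i, a in enumerate(labels)
            for j, b in enumerate(labels) if i != j}
    next_internal = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist[(a, b)] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        a, b = active[i], active[j]
        node = next_internal
        next_internal += 1
        la = 0.5 * dist[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist[(a, b)] - la
        tree.add_edge(a, node, max(la, 0.0))
        tree.add_edge(b, node, max(lb, 0.0))
        for c in active:
            if c in (a, b):
                continue
            dnew = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
            dist[(node, c)] = dist[(c, node)] = max(dnew, 0.0)
        active = [c for c in active if c not in (a, b)]
        active.append(node)
    a, b, c = active
    node = next_internal
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    tree.add_edge(a, node, max(la, 0.0))
    tree.add_edge(b, node, max(lb, 0.0))
    tree.add_edge(c, node, max(lc, 0.0))
    return tree


# -- Jukes–Cantor likelihood with NNI hill climbing -------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _site_patterns(alignment: dict, leaves):
    cols = list(zip(*(alignment[lf] for lf in leaves)))
    if not cols:
        raise ValueError("alignment has zero columns")
    patterns: dict = {}
    for col in cols:
        patterns[col] = patterns.get(col, 0) + 1
    return patterns


def _jc_prob(t: float) -> tuple:
    e = math.exp(-4.0 * t / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def _leaf_vectors(patterns: dict, leaves) -> tuple:
    """Per-leaf conditional likelihood arrays of shape (n_patterns, 4)."""
    cols = list(patterns)
    counts = np.array([patterns[c] for c in cols], dtype=float)
    vecs = {}
    for k, leaf in enumerate(leaves):
        arr = np.zeros((len(cols), 4))
        for p, col in enumerate(cols):
            idx = _BASE_IDX.get(col[k].upper())
            if idx is None:
                arr[p, :] = 1.0    # ambiguity: sum over states
            else:
                arr[p, idx] = 1.0
        vecs[leaf] = arr
    return vecs, counts


def _log_likelihood(tree: Tree, leaf_vecs: dict, counts: np.ndarray) -> float:
    internal = [n for n in tree.adj if n not in tree.leaves]
    root = internal[0] if internal else tree.leaves[0]

    def partial(node, parent):
        children = [n for n in tree.adj[node] if n != parent]
        if not children:
            return leaf_vecs[node]
        vec = None
        for c in children:
            ps, pd = _jc_prob(tree.adj[node][c])
            child = partial(c, node)
            s = child.sum(axis=1, keepdims=True)
            term = ps * child + pd * (s - child)
            vec = term if vec is None else vec * term
        return vec

    lik = 0.25 * partial(root, None).sum(axis=1)
    return float(np.dot(counts, np.log(np.maximum(lik, 1e-300))))


def _optimize_branches(tree: Tree, leaf_vecs: dict, counts,
                       passes: int = 2) -> float:
    from scipy.optimize import minimize_scalar
    ll = _log_likelihood(tree, leaf_vecs, counts)
    for _ in range(passes):
        for u, v, _ln in list(tree.edges()):
            def neg(t):
                tree.set_edge_length(u, v, t)
                return -_log_likelihood(tree, leaf_vecs, counts)
            res = minimize_scalar(neg, bounds=(1e-8, 10.0), method="bounded",
                                  options={"xatol": 1e-6})
            if -res.fun >= ll:
                tree.set_edge_length(u, v, float(res.x))
                ll = -res.fun
            else:
                tree.set_edge_length(u, v, _ln)
    return ll


def _nni_candidates(tree: Tree):
    leafset = set(tree.leaves)
    for u, v, _ in list(tree.edges()):
        if u in leafset or v in leafset:
            continue
        u_nbrs = [n for n in tree.adj[u] if n != v]
        v_nbrs = [n for n in tree.adj[v] if n != u]
        if len(u_nbrs) < 2 or len(v_nbrs) < 1:
            continue
        # two alternative topologies: swap one u-subtree with one v-subtree
        yield (u, v, u_nbrs[1], v_nbrs[0])
        if len(v_nbrs) > 1:
            yield (u, v, u_nbrs[1], v_nbrs[1])


def _apply_nni(tree: Tree, u, v, a, b):
    la = tree.edge_length(u, a)
    lb = tree.edge_length(v, b)
    tree.remove_edge(u, a)
    tree.remove_edge(v, b)
    tree.add_edge(u, b, lb)
    tree.add_edge(v, a, la)


def ml_refine(tree: Tree, alignment: dict, opt_passes: int = 2) -> Tree:
    """Improve a tree by NNI hill climbing under Jukes–Cantor likelihood.

    Branch lengths are optimized one edge at a time (bounded scalar
    optimization); each NNI neighborhood is scanned and the best improving
    rearrangement accepted until none improves.  The returned tree's
    likelihood is never below the input tree's.
    """
    leaves = sorted(tree.leaves)
    missing = [lf for lf in leaves if lf not in alignment]
    if missing:
        raise ValueError(f"alignment lacks leaves: {missing}")
    patterns = _site_patterns(alignment, leaves)
    leaf_vecs, counts = _leaf_vectors(patterns, leaves)
    best = tree.copy()
    best_ll = _optimize_branches(best, leaf_vecs, counts, passes=opt_passes)
    improved = True
    while improved:
        improved = False
        for (u, v, a, b) in _nni_candidates(best):
            cand = best.copy()
            _apply_nni(cand, u, v, a, b)
            ll = _optimize_branches(cand, leaf_vecs, counts, passes=1)
            if ll > best_ll + 1e-9:
                best, best_ll = cand, ll
                improved = True
                break
    best.log_likelihood = best_ll
    return best


# ---------------------------------------------------------------------------
# group linkage


def detect_group_linkage(cohort_calls: dict) -> dict:
    """Complete-linkage scan between non-G1 groups and G1 subtypes.

    ``cohort_calls``: animal id -> {"groups": set of allele groups,
    "g1_subtypes": set of G1 subtype labels}.  For each non-G1 group,
    reports whether some single G1 subtype co-occurs in every carrier.
    """
    out = {}
    for group in ("G2", "G2_LTR", "G3"):
        carriers = [a for a, c in cohort_calls.items()
                    if group in c["groups"]]
        if not carriers:
            out[group] = {"evaluable": False, "complete_linkage": False,
                          "subtype": None}
            continue
        common = set.intersection(
            *(set(cohort_calls[a]["g1_subtypes"]) for a in carriers))
        out[group] = {
            "evaluable": True,
            "complete_linkage": bool(common),
            "subtype": sorted(common)[0] if common else None,
            "n_carriers": len(carriers),
        }
    return out
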