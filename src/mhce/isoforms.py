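"""Curation of long-read transcript models into an isoform catalog.

Transcript models arrive from long-read sequencing with three systematic
artifacts: splice junctions locally misaligned by indel errors, 3' ends
truncated by intrapriming on genomic A-rich tracts, and redundant models
produced by both.  The curation pipeline corrects junctions against the
reference annotation, rescues intraprimed 3' ends using junction-compatible
donor models, collapses redundancies, and clusters transcript start/end
sites within a fixed window.  Coding potential is annotated by translating
each model from the canonical start codon and mapping retained exons to
protein domains.

All coordinates are 0-based half-open on the locus; GTF conversion happens
at I/O time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "IsoformCatalog",
    "ProteinAnnotation",
    "correct_junctions",
    "detect_intrapriming",
    "extend_intraprimed_3p",
    "collapse_redundant",
    "cluster_ends",
    "predict_orf_domains",
    "classify_splicing_events",
    "curate",
]

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a locus."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self):
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class TranscriptModel:
    """One transcript model: ordered exons plus full-length read support.

    ``exons`` are (start, end) half-open pairs sorted by genomic coordinate
    and non-overlapping.  ``flags`` hold curation state: ``intraprimed``,
    ``incomplete_5p``, ``junction_corrected``, ``junction_snap_skipped``,
    ``extended_3p``, ``unconvertible``.
    """

    id: str
    exons: list
    strand: str = "+"
    fl_count: int = 0
    source: str = "long_read"
    flags: set = field(default_factory=set)

    def __post_init__(self):
        self.exons = [tuple(e) for e in self.exons]
        if self.fl_count < 0:
            raise ValueError("fl_count must be >= 0")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.id}: empty exon [{s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")

    @property
    def junctions(self) -> tuple:
        """Ordered (donor, acceptor) = (exon end, next exon start) pairs."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tts(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, locus_seq: str) -> str:
        seq = "".join(locus_seq[s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq

    def genomic_to_transcript(self, pos: int):
        """Transcript offset of a genomic position, or None if intronic."""
        off = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            if self.strand == "+":
                if s <= pos < e:
                    return off + (pos - s)
            else:
                if s <= pos < e:
                    return off + (e - 1 - pos)
            off += e - s
        return None

    def transcript_to_genomic(self, off: int):
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            if off < e - s:
                return s + off if self.strand == "+" else e - 1 - off
            off -= e - s
        return None


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class IsoformCatalog:
    """A set of transcript models on one locus with a designated canonical."""

    models: list
    locus_id: str = "locus"
    canonical_id: str | None = None
    merged_members: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [m.id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate model ids in catalog")
        if self.canonical_id is not None and self.models and \
                self.canonical_id not in ids:
            raise ValueError(f"canonical model {self.canonical_id!r} absent")

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    def get(self, model_id: str) -> TranscriptModel:
        for m in self.models:
            if m.id == model_id:
                return m
        raise KeyError(model_id)

    @property
    def canonical(self) -> TranscriptModel:
        return self.get(self.canonical_id)

    def junction_set(self) -> set:
        return set(itertools.chain.from_iterable(m.junctions for m in self))


@dataclass
class ProteinAnnotation:
    """Coding annotation of a model relative to the canonical ORF."""

    coding: bool
    protein: str = ""
    cds_by_exon: list = field(default_factory=list)
    domains: tuple = ()
    premature_stop: bool = False
    frameshift: bool = False


# ---------------------------------------------------------------------------
# junction correction


def correct_junctions(model: TranscriptModel, canonical_junctions,
                      max_shift: int = 10, locus_seq: str | None = None,
                      require_motif: bool = True) -> TranscriptModel:
    """Snap junctions to nearby canonical junctions.

    A junction is moved when a canonical junction lies within ``max_shift``
    on both the donor and acceptor side and (when ``locus_seq`` is given and
    ``require_motif``) the canonical site carries the GT–AG motif.  Snaps
    that would empty an exon are skipped and flagged.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    canonical_junctions = sorted(set(canonical_junctions))
    new_exons = [list(e) for e in model.exons]
    changed = skipped = False
    for k, (d, a) in enumerate(model.junctions):
        best = None
        for (dc, ac) in canonical_junctions:
            shift = max(abs(d - dc), abs(a - ac))
            if shift <= max_shift and (best is None or shift < best[0]):
                if require_motif and locus_seq is not None and \
                        not _has_gt_ag(locus_seq, dc, ac, model.strand):
                    continue
                best = (shift, dc, ac)
        if best is None or best[0] == 0:
            continue
        _, dc, ac = best
        # donor replaces exon k end; acceptor replaces exon k+1 start
        if dc <= new_exons[k][0] or ac >= new_exons[k + 1][1]:
            skipped = True
            continue
        new_exons[k][1] = dc
        new_exons[k + 1][0] = ac
        changed = True
    flags = set(model.flags)
    if changed:
        flags.add("junction_corrected")
    if skipped:
        flags.add("junction_snap_skipped")
    return replace(model, exons=[tuple(e) for e in new_exons], flags=flags)


def _has_gt_ag(locus_seq: str, donor: int, acceptor: int, strand: str) -> bool:
    if strand == "+":
        return (locus_seq[donor:donor + 2].upper() == "GT"
                and locus_seq[acceptor - 2:acceptor].upper() == "AG")
    return (locus_seq[donor:donor + 2].upper() == "CT"
            and locus_seq[acceptor - 2:acceptor].upper() == "AC")


# ---------------------------------------------------------------------------
# intrapriming


def detect_intrapriming(model: TranscriptModel, locus_seq: str,
                        window: int = 20, a_frac: float = 0.6) -> bool:
    """True iff the genomic window downstream of the 3' end is A-rich.

    The window is read on the transcript strand (A downstream on +, T
    upstream on -) and truncated at the locus boundary; an empty window is
    never intraprimed.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if model.strand == "+":
        tts = model.exons[-1][1]
        seg = locus_seq[tts:tts + window].upper()
        base = "A"
    else:
        tts = model.exons[0][0]
        seg = locus_seq[max(0, tts - window):tts].upper()
        base = "T"
    if not seg:
        return False
    return seg.count(base) / len(seg) >= a_frac


def extend_intraprimed_3p(model: TranscriptModel,
                          catalog: IsoformCatalog) -> TranscriptModel:
    """Replace a truncated 3' end with that of a junction-identical donor.

    Donors are catalog models that share the full junction chain and are not
    themselves flagged intraprimed; the furthest 3' end among donors wins.
    Without a compatible donor the model is returned unchanged.
    """
    donors = [m for m in catalog
              if m.id != model.id and "intraprimed" not in m.flags
              and m.junctions == model.junctions and m.strand == model.strand]
    if not donors:
        return model
    exons = [list(e) for e in model.exons]
    flags = set(model.flags) - {"intraprimed"}
    flags.add("extended_3p")
    if model.strand == "+":
        new_end = max(m.exons[-1][1] for m in donors)
        exons[-1][1] = max(exons[-1][1], new_end)
    else:
        new_start = min(m.exons[0][0] for m in donors)
        exons[0][0] = min(exons[0][0], new_start)
    return replace(model, exons=[tuple(e) for e in exons], flags=flags)


# ---------------------------------------------------------------------------
# collapsing and end clustering


def collapse_redundant(catalog: IsoformCatalog) -> IsoformCatalog:
    """Merge models with identical exon structure, summing FL support.

    The representative keeps the id of the member with the highest fl_count
    (ties: first in catalog order); merged member ids are recorded.
    """
    groups: dict = {}
    for m in catalog:
        groups.setdefault((tuple(m.exons), m.strand), []).append(m)
    merged = []
    members = dict(catalog.merged_members)
    for group in groups.values():
        rep = max(group, key=lambda m: m.fl_count)
        total = sum(m.fl_count for m in group)
        flags = set().union(*(m.flags for m in group))
        merged.append(replace(rep, fl_count=total, flags=flags))
        if len(group) > 1:
            members[rep.id] = sorted(m.id for m in group)
    canonical = catalog.canonical_id
    if canonical is not None and all(m.id != canonical for m in merged):
        # canonical was absorbed into another representative
        for rep_id, mem in members.items():
            if canonical in mem:
                canonical = rep_id
                break
    return IsoformCatalog(models=merged, locus_id=catalog.locus_id,
                          canonical_id=canonical, merged_members=members)


def _single_linkage_1d(values, window: int):
    """Group sorted unique values whose successive gaps are <= window."""
    uniq = sorted(set(values))
    clusters, cur = [], [uniq[0]]
    for v in uniq[1:]:
        if v - cur[-1] <= window:
            cur.append(v)
        else:
            clusters.append(cur)
            cur = [v]
    clusters.append(cur)
    return clusters


def cluster_ends(catalog: IsoformCatalog, window: int = 50) -> IsoformCatalog:
    """Cluster TSS and TTS coordinates, snapping members to the extreme.

    Single-linkage in one dimension with gap <= ``window``; every member
    takes the annotation-extending extreme of its cluster (5'-most TSS,
    3'-most TTS).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not catalog.models:
        return catalog
    # extending extreme is the genomic min start / max end on either strand
    # (on minus the roles of TSS and TTS swap but the extremes coincide)
    starts = [m.exons[0][0] for m in catalog]
    ends = [m.exons[-1][1] for m in catalog]
    start_map = {v: min(cl) for cl in _single_linkage_1d(starts, window)
                 for v in cl}
    end_map = {v: max(cl) for cl in _single_linkage_1d(ends, window)
               for v in cl}
    new_models = []
    for m in catalog:
        exons = [list(e) for e in m.exons]
        exons[0][0] = start_map[exons[0][0]]
        exons[-1][1] = end_map[exons[-1][1]]
        new_models.append(replace(m, exons=[tuple(e) for e in exons]))
    return replace(catalog, models=new_models)


# ---------------------------------------------------------------------------
# coding potential


def predict_orf_domains(model: TranscriptModel, locus_seq: str,
                        cds_start: int, domain_map: dict,
                        canonical: TranscriptModel) -> ProteinAnnotation:
    """Translate a model from the canonical start and map exons to domains.

    ``cds_start`` is the genomic position of the A of the canonical ATG;
    ``domain_map`` maps 1-based canonical exon index to a domain label
    (labels mapping to None, e.g. the 3' UTR exon, are not domains).
    Frameshift is declared when any genomic coding position shared with the
    canonical model sits at a different spliced-frame offset.
    """
    t0 = model.genomic_to_transcript(cds_start)
    if t0 is None:
        return ProteinAnnotation(coding=False)

    def translate(m, start_off):
        tx = m.spliced_sequence(locus_seq)
        aas = []
        for i in range(start_off, len(tx) - 2, 3):
            aa = CODON_TABLE.get(tx[i:i + 3].upper(), "X")
            if aa == "*":
                return "".join(aas), True
            aas.append(aa)
        return "".join(aas), False

    c0 = canonical.genomic_to_transcript(cds_start)
    if model.exons == canonical.exons:
        protein, stop_found = translate(model, t0)
        canon_len = len(protein)
    else:
        protein, stop_found = translate(model, t0)
        canon_len = len(translate(canonical, c0)[0])
    n_coding_nt = 3 * len(protein) + (3 if stop_found else 0)
    premature = stop_found and len(protein) < canon_len

    # frameshift is structural: any genomic position of the canonical CDS
    # retained by the model but at a different spliced-frame offset
    canon_cds_nt = 3 * canon_len + 3
    canon_frame = {}
    for off in range(c0, min(c0 + canon_cds_nt, canonical.spliced_length())):
        canon_frame[canonical.transcript_to_genomic(off)] = (off - c0) % 3
    frameshift = False
    for off in range(t0, model.spliced_length()):
        g = model.transcript_to_genomic(off)
        if g in canon_frame and (off - t0) % 3 != canon_frame[g]:
            frameshift = True
            break

    # translated genomic region -> retained domains
    coding_g = set()
    for off in range(t0, min(t0 + n_coding_nt, model.spliced_length())):
        coding_g.add(model.transcript_to_genomic(off))
    domains = []
    for idx, (s, e) in enumerate(canonical.exons, start=1):
        label = domain_map.get(idx)
        if label is None:
            continue
        if any(g is not None and s <= g < e for g in coding_g):
            if label not in domains:
                domains.append(label)

    cds_by_exon = []
    for (s, e) in model.exons:
        inside = sorted(g for g in coding_g if g is not None and s <= g < e)
        if inside:
            cds_by_exon.append((inside[0], inside[-1] + 1))
        else:
            cds_by_exon.append(None)
    return ProteinAnnotation(coding=True, protein=protein,
                             cds_by_exon=cds_by_exon, domains=tuple(domains),
                             premature_stop=premature, frameshift=frameshift)


# ---------------------------------------------------------------------------
# splicing event classification


def classify_splicing_events(model: TranscriptModel,
                             canonical: TranscriptModel,
                             utr_start: int | None = None) -> set:
    """Describe a model's splicing relative to the canonical chain.

    Events: ``("exon_skip", i)`` canonical exon i absent and bridged by a
    model intron; ``("retained_intron", i)`` canonical intron i contained in
    a model exon; ``("novel_exon", (s, e))`` model exon inside a canonical
    intron with both junctions non-canonical; ``("alt_3utr",)`` any
    non-canonical junction at or past ``utr_start`` (default: start of the
    last canonical exon).
    """
    events = set()
    if model.exons == canonical.exons:
        return events
    if utr_start is None:
        utr_start = canonical.exons[-1][0]
    cjunc = set(canonical.junctions)
    mjunc = set(model.junctions)
    cexons = canonical.exons
    cintrons = [(e0, s1) for (_, e0), (s1, _) in zip(cexons, cexons[1:])]

    for i, (s, e) in enumerate(cexons, start=1):
        if i == 1 or i == len(cexons):
            continue
        overlapped = any(ms < e and s < me for ms, me in model.exons)
        bridged = any(d <= s and a >= e for d, a in model.junctions)
        if not overlapped and bridged:
            events.add(("exon_skip", i))

    for i, (isrt, iend) in enumerate(cintrons, start=1):
        for (ms, me) in model.exons:
            if ms < isrt and me > iend:
                events.add(("retained_intron", i))
                break

    for (ms, me) in model.exons:
        if any(ms < e and s < me for s, e in cexons):
            continue
        inside = any(isrt <= ms and me <= iend for isrt, iend in cintrons)
        left = any(a == ms for _, a in cjunc)
        right = any(d == me for d, _ in cjunc)
        if inside and not left and not right:
            events.add(("novel_exon", (ms, me)))

    for (d, a) in mjunc - cjunc:
        if d >= utr_start:
            events.add(("alt_3utr",))
            break
    return events


# ---------------------------------------------------------------------------
# curation driver


def curate(catalog: IsoformCatalog, locus_seq: str,
           canonical_junctions=None,
           max_shift: int = 10, end_window: int = 50,
           intraprime_window: int = 20, a_frac: float = 0.6,
           require_motif: bool = True) -> IsoformCatalog:
    """Full curation: correct junctions, rescue intraprimed 3' ends,
    collapse redundancies, cluster TSS/TTS, and collapse again.

    ``canonical_junctions`` is the junction set of the reference
    annotation; it defaults to the catalog's own canonical model, but raw
    long-read catalogs should pass the reference annotation since their
    canonical model may itself be misaligned.  Deterministic and
    idempotent on its own output; total FL support is conserved.
    """
    if canonical_junctions is None:
        canonical_junctions = catalog.canonical.junctions if \
            catalog.canonical_id else ()
    corrected = [
        correct_junctions(m, canonical_junctions, max_shift, locus_seq,
                          require_motif=require_motif)
        for m in catalog
    ]
    stage = replace(catalog, models=corrected)
    flagged = []
    for m in stage:
        if detect_intrapriming(m, locus_seq, intraprime_window, a_frac):
            m = replace(m, flags=set(m.flags) | {"intraprimed"})
        flagged.append(m)
    stage = replace(stage, models=flagged)
    extended = [
        extend_intraprimed_3p(m, stage) if "intraprimed" in m.flags else m
        for m in stage
    ]
    stage = replace(stage, models=extended)
    stage = collapse_redundant(stage)
    stage = cluster_ends(stage, end_window)
    return collapse_redundant(stage)
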