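"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; GTF 1-based inclusive with gene_id/transcript_id (and
fl_count/source carried as attributes so catalogs round-trip losslessly);
BED 0-based half-open; a minimal VCF v4.2 with phased diploid genotypes;
TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .isoforms import IsoformCatalog, TranscriptModel

__all__ = [
    "read_fasta", "write_fasta", "read_gtf", "write_gtf",
    "read_bed", "write_bed", "read_vcf", "write_vcf",
    "read_tsv", "write_tsv", "read_json", "write_json",
]


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gtf(catalog: IsoformCatalog, path, gene_id: str = "MHC-E") -> None:
    lines = []
    for m in catalog:
        attrs = (f'gene_id "{gene_id}"; transcript_id "{m.id}"; '
                 f'fl_count "{m.fl_count}"; source_type "{m.source}";')
        for s, e in m.exons:
            lines.append("\t".join([
                catalog.locus_id, "mhce", "exon", str(s + 1), str(e),
                ".", m.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_attrs(field: str) -> dict:
    out = {}
    for part in field.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path, canonical_id: str | None = None) -> IsoformCatalog:
    exons: dict = {}
    meta: dict = {}
    locus_id = "locus"
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[2] != "exon":
            continue
        locus_id = f[0]
        attrs = _gtf_attrs(f[8])
        tid = attrs["transcript_id"]
        exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
        meta[tid] = (f[6], int(attrs.get("fl_count", 0)),
                     attrs.get("source_type", "long_read"))
    models = []
    for tid, ex in exons.items():
        strand, fl, source = meta[tid]
        models.append(TranscriptModel(id=tid, exons=sorted(ex), strand=strand,
                                      fl_count=fl, source=source))
    return IsoformCatalog(models=models, locus_id=locus_id,
                          canonical_id=canonical_id)


def write_bed(intervals, path) -> None:
    """``intervals``: iterable of (chrom, start, end, name[, strand])."""
    lines = []
    for iv in intervals:
        chrom, start, end, name = iv[:4]
        strand = iv[4] if len(iv) > 4 else "+"
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path) -> list:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) > 5 else "+"
        out.append((f[0], int(f[1]), int(f[2]), f[3], strand))
    return out


def write_vcf(variants, samples, genotypes, path, contig="MamuE1") -> None:
    """Write a VCF v4.2 with phased GT.

    ``variants``: list of (pos0, ref, alt, vid); ``genotypes``: array-like of
    shape (n_variants, n_samples, 2) of 0/1 allele indices.
    """
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    lines = list(header)
    for i, (pos0, ref, alt, vid) in enumerate(variants):
        gts = "\t".join(f"{int(a)}|{int(b)}" for a, b in genotypes[i])
        lines.append(f"{contig}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t"
                     f".\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path):
    """Return (variants, samples, genotypes) as written by :func:`write_vcf`."""
    variants, genotypes, samples = [], [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line:
            continue
        f = line.split("\t")
        if line.startswith("#CHROM"):
            samples = f[9:]
            continue
        variants.append((int(f[1]) - 1, f[3], f[4], f[2]))
        row = []
        for gt in f[9:]:
            a, _, b = gt.partition("|")
            row.append((int(a), int(b)))
        genotypes.append(row)
    return variants, samples, genotypes


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
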