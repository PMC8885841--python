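"""File formats: FASTA, GFF3, BED6, narrowPeak, bedGraph, TSV.

Internal coordinates are 0-based half-open; GFF3 is written/read 1-based
inclusive and BED/bedGraph 0-based half-open.  All writers emit
deterministic text (fixed float formatting, sorted records) so identical
runs produce byte-identical artifacts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

from .core import AnnotatedGenome, Gene, KineticTable, ReadSet, TECopy, \
    TandemRepeat


# ------------------------------------------------------------------- FASTA

def write_fasta(genome_or_contigs, path) -> None:
    contigs = genome_or_contigs.contigs \
        if isinstance(genome_or_contigs, AnnotatedGenome) \
        else genome_or_contigs
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(contigs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# -------------------------------------------------------------------- GFF3

def _gff_line(contig, source, ftype, start0, end0, score, strand, attrs):
    return "\t".join([
        contig, source, ftype, str(start0 + 1), str(end0), score, strand,
        ".", ";".join(f"{k}={v}" for k, v in attrs)])


def write_annotations_gff3(genome: AnnotatedGenome, path) -> None:
    """Gene models (with CDS/UTR/intron/promoter subfeatures), TE copies
    and tandem repeats as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for name, seq in sorted(genome.contigs.items()):
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
        attrs = [("ID", g.name), ("te_gene", str(g.is_te_gene).lower()),
                 ("expression_class", g.expression_class)]
        lines.append(_gff_line(g.contig, "dnamod", "gene", g.start, g.end,
                               ".", g.strand, attrs))
        mrna_id = g.name + ".t1"
        lines.append(_gff_line(g.contig, "dnamod", "mRNA", g.start, g.end,
                               ".", g.strand,
                               [("ID", mrna_id), ("Parent", g.name)]))
        sub = []
        for s, e in g.exons:
            sub.append(("CDS", s, e))
        for s, e in g.introns:
            sub.append(("intron", s, e))
        if g.utr5:
            sub.append(("five_prime_UTR", *g.utr5))
        if g.utr3:
            sub.append(("three_prime_UTR", *g.utr3))
        if g.promoter:
            sub.append(("promoter", *g.promoter))
        for ftype, s, e in sorted(sub, key=lambda x: (x[1], x[0])):
            lines.append(_gff_line(g.contig, "dnamod", ftype, s, e, ".",
                                   g.strand, [("Parent", mrna_id)]))
    for t in sorted(genome.te_copies, key=lambda t: (t.contig, t.start)):
        lines.append(_gff_line(
            t.contig, "dnamod", "transposable_element", t.start, t.end, ".",
            t.strand, [("ID", t.name), ("family", t.family),
                       ("consensus_length", str(t.consensus_length)),
                       ("integrity", f"{t.integrity:.4f}")]))
    for r in sorted(genome.tandem_repeats, key=lambda r: (r.contig, r.start)):
        lines.append(_gff_line(
            r.contig, "dnamod", "tandem_repeat", r.start, r.end, ".", "+",
            [("ID", r.name), ("unit_length", str(r.unit_length))]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations_gff3(path, contigs: dict[str, str]) -> AnnotatedGenome:
    """Rebuild an AnnotatedGenome from a GFF3 written by this package."""
    genes: dict[str, Gene] = {}
    mrna_to_gene: dict[str, str] = {}
    tes: list[TECopy] = []
    trs: list[TandemRepeat] = []
    for feat in DataIterator(str(path)):
        start0, end0 = feat.start - 1, feat.end
        if feat.featuretype == "gene":
            gid = feat.attributes["ID"][0]
            genes[gid] = Gene(
                gid, feat.seqid, start0, end0, feat.strand, [], [], None,
                None, None,
                is_te_gene=feat.attributes.get("te_gene",
                                               ["false"])[0] == "true",
                expression_class=feat.attributes.get(
                    "expression_class", ["high"])[0])
        elif feat.featuretype == "mRNA":
            mrna_to_gene[feat.attributes["ID"][0]] = \
                feat.attributes["Parent"][0]
        elif feat.featuretype in ("CDS", "intron", "five_prime_UTR",
                                  "three_prime_UTR", "promoter"):
            gid = mrna_to_gene.get(feat.attributes["Parent"][0])
            if gid is None or gid not in genes:
                continue
            g = genes[gid]
            if feat.featuretype == "CDS":
                g.exons.append((start0, end0))
            elif feat.featuretype == "intron":
                g.introns.append((start0, end0))
            elif feat.featuretype == "five_prime_UTR":
                g.utr5 = (start0, end0)
            elif feat.featuretype == "three_prime_UTR":
                g.utr3 = (start0, end0)
            else:
                g.promoter = (start0, end0)
        elif feat.featuretype == "transposable_element":
            tes.append(TECopy(
                feat.attributes["ID"][0], feat.attributes["family"][0],
                int(feat.attributes["consensus_length"][0]), feat.seqid,
                start0, end0, feat.strand))
        elif feat.featuretype == "tandem_repeat":
            trs.append(TandemRepeat(
                feat.attributes["ID"][0], feat.seqid, start0, end0,
                int(feat.attributes["unit_length"][0])))
    for g in genes.values():
        g.exons.sort()
        g.introns.sort()
    genome = AnnotatedGenome(contigs, list(genes.values()), tes, trs)
    genome.validate()
    return genome


def write_calls_gff3(calls: pd.DataFrame, path) -> None:
    """Modification calls in a SMRT-report-style GFF3."""
    lines = ["##gff-version 3"]
    for row in calls.itertuples(index=False):
        attrs = [("coverage", str(int(row.coverage))),
                 ("IPDRatio", f"{row.ipd_ratio:.4f}")]
        if not pd.isna(row.fraction):
            attrs.append(("frac", f"{row.fraction:.4f}"))
        lines.append(_gff_line(
            row.contig, "dnamod", row.mark, int(row.pos), int(row.pos) + 1,
            f"{row.score:.2f}", row.strand, attrs))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------- BED

def write_reads_bed(reads: ReadSet, path) -> None:
    df = reads.reads
    with open(path, "w") as fh:
        for i, (contig, start, end, strand) in enumerate(
                df[["contig", "start", "end", "strand"]].itertuples(
                    index=False, name=None)):
            fh.write(f"{contig}\t{start}\t{end}\t{reads.assay}_{i}\t0"
                     f"\t{strand}\n")


def read_reads_bed(path, assay: str | None = None) -> ReadSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: not a BED record")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            strand = parts[5] if len(parts) >= 6 else "+"
            rows.append((parts[0], start, end, strand))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "strand"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return ReadSet(assay or Path(path).stem, df)


def write_peaks_narrowpeak(peaks_df: pd.DataFrame, path,
                           name_prefix: str = "peak") -> None:
    """narrowPeak-style BED: chrom start end name score . signal -log10p
    -1 summit-offset."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks_df.itertuples(index=False)):
            neglogp = row.score / 10.0
            fh.write("\t".join([
                row.contig, str(int(row.start)), str(int(row.end)),
                f"{name_prefix}_{i + 1}", str(int(min(row.score * 10, 1000))),
                ".", f"{row.score:.3f}", f"{neglogp:.3f}", "-1",
                str(int(row.summit - row.start))]) + "\n")


def read_peaks_narrowpeak(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            start, end = int(p[1]), int(p[2])
            rows.append((p[0], start, end, start + int(p[9]),
                         10.0 ** (-float(p[7])), float(p[6])))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "summit",
                                       "p_value", "score"])


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(track, path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(track.bins):
            vec = track.bins[contig]
            clen = track.contig_lengths.get(contig,
                                            len(vec) * track.bin_size)
            for i, v in enumerate(vec):
                s = i * track.bin_size
                e = min(s + track.bin_size, clen)
                fh.write(f"{contig}\t{s}\t{e}\t{v:.6g}\n")


# --------------------------------------------------------------------- TSV

def write_methylome_tsv(methylome: pd.DataFrame, path) -> None:
    """Truth methylome as 6-column BED-like TSV (0-based, strand, mark,
    fraction)."""
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tmark\tfraction\tstrand\n")
        for row in methylome.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos}\t{row.pos + 1}\t{row.mark}"
                     f"\t{row.fraction:.6g}\t{row.strand}\n")


def read_methylome_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return pd.DataFrame({"contig": df["contig"], "pos": df["start"],
                         "strand": df["strand"], "mark": df["mark"],
                         "fraction": df["fraction"]})


def write_kinetics_tsv(table: KineticTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tstrand\tcoverage\tcontrol_log_mu"
                 "\tcontrol_sigma\tnative_ipds\tcontrol_ipds\n")
        for i, row in enumerate(table.sites.itertuples(index=False)):
            nat = ",".join(f"{v:.6g}" for v in table.native_ipds[i])
            ctl = table.control_ipds[i]
            ctl_s = "." if ctl is None else ",".join(
                f"{v:.6g}" for v in ctl)
            fh.write(f"{row.contig}\t{row.pos}\t{row.strand}\t{row.coverage}"
                     f"\t{row.control_log_mu:.6g}\t{row.control_sigma:.6g}"
                     f"\t{nat}\t{ctl_s}\n")


def read_kinetics_tsv(path) -> KineticTable:
    sites_rows, native, control = [], [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            p = line.rstrip("\n").split("\t")
            sites_rows.append((p[0], int(p[1]), p[2], int(p[3]),
                               float(p[4]), float(p[5])))
            native.append(np.array([float(v) for v in p[6].split(",")])
                          if p[6] else np.empty(0))
            control.append(None if p[7] == "." else
                           np.array([float(v) for v in p[7].split(",")]))
    sites = pd.DataFrame(sites_rows, columns=[
        "contig", "pos", "strand", "coverage", "control_log_mu",
        "control_sigma"])
    return KineticTable(sites, native, control)


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out = out.rename(columns={"pos": "pos0", "fraction_class": "class"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"pos0": "pos", "class": "fraction_class"})
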