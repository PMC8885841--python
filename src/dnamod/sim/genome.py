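"""Synthetic annotated genome: contigs with gene models, TE copies and
tandem repeats.

The layout algorithm tiles non-overlapping feature blocks (genes, TE
copies, tandem-repeat arrays) onto contigs separated by random intergenic
gaps.  TE copies are 5'-anchored prefixes of a per-family random consensus,
so copy integrity (span / consensus length) is exact by construction:
full >= 0.95, medium in [0.5, 0.9), short in [0.1, 0.5).  TE-derived genes
carry a TE insertion inside one intron and are flagged ``is_te_gene``.
"""

from __future__ import annotations

import numpy as np

from ..config import SimConfig, TEFamilyConfig
from ..core import AnnotatedGenome, Gene, TandemRepeat, TECopy, revcomp

BASES = np.array(["A", "C", "G", "T"])


class SizingError(ValueError):
    """Configured features cannot fit in the configured genome length."""


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _cpg_rich_seq(rng: np.random.Generator, length: int, gc: float,
                  cpg_g_prob: float) -> str:
    """Background-composition sequence with the base after each C drawn as
    G with probability ``cpg_g_prob`` (first-order CpG enrichment)."""
    if cpg_g_prob <= 0:
        return _random_seq(rng, length, gc)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # conditional distribution after a C: G gets cpg_g_prob, the rest keep
    # their relative background frequencies
    rest = base_p.copy()
    rest[2] = 0.0
    after_c = rest / rest.sum() * (1 - cpg_g_prob)
    after_c[2] = cpg_g_prob
    out = list(rng.choice(BASES, size=length, p=base_p))
    cum = np.cumsum(after_c)
    draws = rng.random(length)
    for i in range(1, length):
        if out[i - 1] == "C":
            out[i] = BASES[min(int(np.searchsorted(cum, draws[i],
                                                   side="right")), 3)]
    return "".join(out)


def _sample_gene_segments(rng, gs, te_insert_len: int):
    """Segment list in transcript order: (kind, length) tuples."""
    n_exons = 1 + rng.poisson(max(gs.n_exons_mean - 1.0, 0.0))
    if te_insert_len > 0:
        n_exons = max(n_exons, 2)  # need an intron to host the insertion
    exon_lens = 50 + rng.poisson(max(gs.exon_length_mean - 50, 1),
                                 size=n_exons)
    intron_lens = 60 + rng.poisson(max(gs.intron_length_mean - 60, 1),
                                   size=max(n_exons - 1, 0))
    segments = [("utr5", gs.utr5_length)]
    te_intron = int(rng.integers(len(intron_lens))) if te_insert_len else -1
    for i, el in enumerate(exon_lens):
        segments.append(("exon", int(el)))
        if i < len(intron_lens):
            ilen = int(intron_lens[i])
            if i == te_intron:
                segments.append(("intron_te", ilen + te_insert_len))
            else:
                segments.append(("intron", ilen))
    segments.append(("utr3", gs.utr3_length))
    return segments


def _integrity_for_class(rng, klass: str) -> float:
    if klass == "full":
        return float(rng.uniform(0.95, 1.0))
    if klass == "medium":
        return float(rng.uniform(0.5, 0.9))
    return float(rng.uniform(0.1, 0.5))


def simulate_genome(config: SimConfig) -> AnnotatedGenome:
    """Generate a deterministic annotated genome from ``config``."""
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 101]))
    gs = config.gene_structure

    # family consensus sequences (CpG-enriched methylation targets)
    consensus = {fam.name: _cpg_rich_seq(rng, fam.consensus_length,
                                         config.gc_content,
                                         config.te_consensus_cpg_boost)
                 for fam in config.te_families}

    # --- build blocks -----------------------------------------------------
    blocks = []  # (kind, length, payload)
    n_te_genes = int(round(config.n_genes * gs.te_gene_fraction))
    te_gene_flags = np.zeros(config.n_genes, dtype=bool)
    if n_te_genes:
        if not config.te_families:
            raise SizingError("te_gene_fraction > 0 requires a TE family")
        te_gene_flags[rng.choice(config.n_genes, size=n_te_genes,
                                 replace=False)] = True
    insert_fam = (config.te_families[gs.te_gene_insert_family]
                  if config.te_families else None)
    for gi in range(config.n_genes):
        is_te = bool(te_gene_flags[gi])
        ins_len = min(gs.te_gene_insert_length,
                      insert_fam.consensus_length) if is_te else 0
        segs = _sample_gene_segments(rng, gs, ins_len)
        length = sum(l for _, l in segs)
        blocks.append(("gene", length,
                       {"segments": segs, "is_te_gene": is_te,
                        "insert_len": ins_len,
                        "strand": "+" if rng.random() < 0.5 else "-",
                        "expression_class":
                            "high" if rng.random() < 0.5 else "low"}))
    for fam in config.te_families:
        for klass, count in (("full", fam.n_full), ("medium", fam.n_medium),
                             ("short", fam.n_short)):
            for _ in range(count):
                integ = _integrity_for_class(rng, klass)
                length = max(30, int(round(integ * fam.consensus_length)))
                blocks.append(("te", length,
                               {"family": fam.name,
                                "consensus_length": fam.consensus_length,
                                "strand": "+" if rng.random() < 0.5 else "-"}))
    tr = config.tandem_repeats
    for _ in range(tr.n_arrays):
        length = int(rng.integers(tr.array_length_min,
                                  tr.array_length_max + 1))
        blocks.append(("tr", length, {"unit_length": tr.unit_length}))

    total_block_len = sum(l for _, l, _ in blocks)
    if total_block_len + 2 * (len(blocks) + config.n_contigs) > \
            config.genome_length:
        raise SizingError(
            f"features require {total_block_len} bp plus gaps but the genome "
            f"is only {config.genome_length} bp")

    # --- assign blocks to contigs and lay out with random gaps ------------
    order = rng.permutation(len(blocks))
    base_len = config.genome_length // config.n_contigs
    contig_lens = [base_len] * config.n_contigs
    contig_lens[-1] += config.genome_length - base_len * config.n_contigs
    per_contig: list[list] = [[] for _ in range(config.n_contigs)]
    used = [0] * config.n_contigs
    ci = 0
    for bi in order:
        kind, length, payload = blocks[bi]
        placed = False
        for attempt in range(config.n_contigs):
            c = (ci + attempt) % config.n_contigs
            need = used[c] + length + (len(per_contig[c]) + 2)
            if need <= contig_lens[c]:
                per_contig[c].append(blocks[bi])
                used[c] += length
                ci = (c + 1) % config.n_contigs
                placed = True
                break
        if not placed:
            raise SizingError(
                f"could not place a {kind} block of {length} bp; "
                "reduce feature counts or enlarge the genome")

    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    te_copies: list[TECopy] = []
    tandem_repeats: list[TandemRepeat] = []
    gene_idx = te_idx = tr_idx = 0

    for c in range(config.n_contigs):
        cname = f"contig_{c + 1}"
        clen = contig_lens[c]
        cblocks = per_contig[c]
        leftover = clen - sum(l for _, l, _ in cblocks)
        n_gaps = len(cblocks) + 1
        gaps = rng.multinomial(leftover, np.full(n_gaps, 1.0 / n_gaps))
        seq = list(_random_seq(rng, clen, config.gc_content))
        cursor = 0
        for i, (kind, length, payload) in enumerate(cblocks):
            cursor += int(gaps[i])
            start, end = cursor, cursor + length
            if kind == "gene":
                gene_idx += 1
                gene, inner_te = _realize_gene(
                    f"gene_{gene_idx:04d}", cname, start, payload,
                    gs, insert_fam, rng)
                genes.append(gene)
                if inner_te is not None:
                    te_idx += 1
                    inner_te.name = f"te_{te_idx:04d}"
                    te_copies.append(inner_te)
                    _write_te_seq(seq, inner_te, consensus)
            elif kind == "te":
                te_idx += 1
                copy = TECopy(f"te_{te_idx:04d}", payload["family"],
                              payload["consensus_length"], cname, start, end,
                              payload["strand"])
                te_copies.append(copy)
                _write_te_seq(seq, copy, consensus)
            else:
                tr_idx += 1
                unit = _random_seq(rng, payload["unit_length"],
                                   config.gc_content)
                arr = (unit * (length // len(unit) + 1))[:length]
                seq[start:end] = list(arr)
                tandem_repeats.append(
                    TandemRepeat(f"tr_{tr_idx:04d}", cname, start, end,
                                 payload["unit_length"]))
            cursor = end
        contigs[cname] = "".join(seq)

    genome = AnnotatedGenome(contigs, genes, te_copies, tandem_repeats)
    clip_promoters(genome)
    genome.validate()
    return genome


def _write_te_seq(seq: list, copy: TECopy, consensus: dict[str, str]) -> None:
    s = consensus[copy.family][:copy.length]
    if copy.strand == "-":
        s = revcomp(s)
    seq[copy.start:copy.end] = list(s)


def _realize_gene(name, contig, start, payload, gs, insert_fam, rng):
    """Convert transcript-order segments into genomic-coordinate features."""
    segs = payload["segments"]
    strand = payload["strand"]
    genomic = segs if strand == "+" else segs[::-1]
    cursor = start
    exons, introns = [], []
    utr5 = utr3 = None
    te_span = None
    for kind, length in genomic:
        span = (cursor, cursor + length)
        if kind == "exon":
            exons.append(span)
        elif kind.startswith("intron"):
            introns.append(span)
            if kind == "intron_te":
                ins = payload["insert_len"]
                off = (length - ins) // 2
                te_span = (cursor + off, cursor + off + ins)
        elif kind == "utr5":
            utr5 = span
        else:
            utr3 = span
        cursor += length
    end = cursor
    gene = Gene(name, contig, start, end, strand, sorted(exons),
                sorted(introns), utr5, utr3, None,
                is_te_gene=payload["is_te_gene"],
                expression_class=payload["expression_class"])
    # promoter: fixed span upstream of the TSS, clipped at contig bounds
    if strand == "+":
        gene.promoter = (max(0, start - gs.promoter_span), start)
    else:
        gene.promoter = (end, end + gs.promoter_span)
    inner_te = None
    if te_span is not None:
        inner_te = TECopy("", insert_fam.name, insert_fam.consensus_length,
                          contig, te_span[0], te_span[1],
                          "+" if rng.random() < 0.5 else "-")
    return gene, inner_te


def clip_promoters(genome: AnnotatedGenome) -> None:
    """Clip promoter annotations to contig bounds (in place)."""
    lens = genome.contig_lengths()
    for g in genome.genes:
        if g.promoter is None:
            continue
        s, e = g.promoter
        s, e = max(0, s), min(lens[g.contig], e)
        g.promoter = (s, e) if s < e else None
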