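"""Simulated sequencing observations as alignment intervals.

Reads are emitted as BED-like (contig, start, end, strand) alignments —
5' prefixes of simulated fragments — standing in for mapped reads.

* DIP-seq: fragments drawn uniformly (length 200-400 bp); the odds of
  antibody capture grow with the summed fraction of matching methyl marks a
  fragment covers, on top of a background capture weight for unmethylated
  fragments (residual IgG binding).  The input assay skips capture.
* ChIP-seq: H3K4me3 fragment centres are bimodal around the TSS of
  expressed genes; H3K9me3/H3K27me3 are uniform over TE bodies plus a
  configurable flanking spread; the rest of the library is uniform
  background.
* RNA-seq: per-gene read counts are multinomial with rates =
  log-normal baseline x exonic length, repressed for TE-derived genes
  carrying 4mC and elevated for genes with 6mA nearby.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..core import AnnotatedGenome, ReadSet, empty_reads

DIP_ASSAYS = ("dip4mC", "dip6mA", "input")
CHIP_MARKS = ("H3K4me3", "H3K9me3", "H3K27me3")


def _reads_frame(contig, start, end, strand):
    return pd.DataFrame({"contig": contig,
                         "start": np.asarray(start, dtype=np.int64),
                         "end": np.asarray(end, dtype=np.int64),
                         "strand": strand})


def _fragments_to_reads(contig, fs, fe, read_length, rng):
    """5' prefix of each fragment on a random strand."""
    strand = np.where(rng.random(len(fs)) < 0.5, "+", "-")
    rl = np.minimum(read_length, fe - fs)
    start = np.where(strand == "+", fs, fe - rl)
    end = start + rl
    return _reads_frame(contig, start, end, strand)


def _draw_fragments(rng, names, lens, n, fmin, fmax):
    lengths = np.array([lens[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    flen = rng.integers(fmin, fmax + 1, size=n)
    clen = np.array([lens[c] for c in names])[ci]
    flen = np.minimum(flen, clen)
    fs = (rng.random(n) * (clen - flen + 1)).astype(np.int64)
    contig = np.array(names, dtype=object)[ci]
    return contig, fs, fs + flen


def simulate_dipseq(genome: AnnotatedGenome, methylome: pd.DataFrame,
                    config: SimConfig) -> dict[str, ReadSet]:
    """Return ReadSets for the dip4mC, dip6mA and input assays."""
    config.validate()
    dc = config.dip
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    lens = genome.contig_lengths()
    names = sorted(lens)

    # per-mark cumulative fraction sums for fast fragment weighting
    mark_index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for mark in ("4mC", "6mA"):
        sub = methylome[methylome["mark"] == mark]
        per = {}
        for contig, grp in sub.groupby("contig"):
            order = np.argsort(grp["pos"].to_numpy(), kind="stable")
            pos = grp["pos"].to_numpy()[order]
            cum = np.concatenate([[0.0],
                                  np.cumsum(grp["fraction"].to_numpy()[order])])
            per[str(contig)] = (pos, cum)
        mark_index[mark] = per

    out: dict[str, ReadSet] = {}
    for assay in DIP_ASSAYS:
        if dc.library_size == 0 or not names:
            out[assay] = empty_reads(assay)
            continue
        if assay == "input":
            contig, fs, fe = _draw_fragments(
                rng, names, lens, dc.library_size,
                dc.fragment_length_min, dc.fragment_length_max)
        else:
            mark = "4mC" if assay == "dip4mC" else "6mA"
            n_cand = dc.library_size * dc.oversample
            contig, fs, fe = _draw_fragments(
                rng, names, lens, n_cand,
                dc.fragment_length_min, dc.fragment_length_max)
            w = np.full(n_cand, dc.background_weight)
            per = mark_index[mark]
            for cname in names:
                if cname not in per:
                    continue
                pos, cum = per[cname]
                sel = np.nonzero(contig == cname)[0]
                lo = np.searchsorted(pos, fs[sel], side="left")
                hi = np.searchsorted(pos, fe[sel], side="left")
                w[sel] += dc.capture_enrichment * (cum[hi] - cum[lo])
            pick = rng.choice(n_cand, size=dc.library_size, replace=True,
                              p=w / w.sum())
            contig, fs, fe = contig[pick], fs[pick], fe[pick]
        reads = _fragments_to_reads(contig, fs, fe, dc.read_length, rng)
        out[assay] = ReadSet(assay, reads)
    return out


def simulate_chipseq(genome: AnnotatedGenome,
                     config: SimConfig) -> dict[str, ReadSet]:
    """Return ReadSets for each histone mark plus chip_input."""
    config.validate()
    cc = config.chip
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    lens = genome.contig_lengths()
    names = sorted(lens)
    expressed = [g for g in genome.genes if g.expression_class == "high"]
    half = cc.fragment_length // 2

    def clip_fragments(contig, centers):
        clen = np.array([lens[c] for c in contig])
        fs = np.clip(centers - half, 0, None)
        fe = np.minimum(fs + cc.fragment_length, clen)
        fs = np.maximum(fe - cc.fragment_length, 0)
        keep = fe - fs >= cc.read_length
        return contig[keep], fs[keep], fe[keep]

    out: dict[str, ReadSet] = {}
    for assay in CHIP_MARKS + ("chip_input",):
        if cc.library_size == 0 or not names:
            out[assay] = empty_reads(assay)
            continue
        n_bg = cc.library_size if assay == "chip_input" else int(
            round(cc.library_size * cc.background_fraction))
        n_sig = cc.library_size - n_bg
        targets_exist = (len(expressed) > 0 if assay == "H3K4me3"
                         else len(genome.te_copies) > 0)
        if assay == "chip_input" or not targets_exist:
            n_bg, n_sig = cc.library_size, 0

        parts = []
        if n_sig > 0:
            if assay == "H3K4me3":
                gi = rng.integers(len(expressed), size=n_sig)
                tss = np.array([expressed[i].tss for i in gi])
                sign = np.array([1 if expressed[i].strand == "+" else -1
                                 for i in gi])
                side = np.where(rng.random(n_sig) < 0.5, -1, 1)
                offset = side * cc.tss_offset + rng.normal(
                    0.0, cc.tss_sd, size=n_sig)
                centers = (tss + sign * offset).astype(np.int64)
                contig = np.array([expressed[i].contig for i in gi],
                                  dtype=object)
            else:
                tes = genome.te_copies
                weights = np.array([t.length + 2 * cc.te_spread
                                    for t in tes], dtype=float)
                ti = rng.choice(len(tes), size=n_sig,
                                p=weights / weights.sum())
                starts = np.array([tes[i].start for i in ti])
                ends = np.array([tes[i].end for i in ti])
                lo = starts - cc.te_spread
                hi = ends + cc.te_spread
                centers = (lo + rng.random(n_sig) * (hi - lo)).astype(
                    np.int64)
                contig = np.array([tes[i].contig for i in ti], dtype=object)
            centers = np.clip(centers, 0, None)
            parts.append(clip_fragments(contig, centers))
        if n_bg > 0:
            contig, fs, fe = _draw_fragments(rng, names, lens, n_bg,
                                             cc.fragment_length,
                                             cc.fragment_length)
            parts.append((contig, fs, fe))
        contig = np.concatenate([p[0] for p in parts])
        fs = np.concatenate([p[1] for p in parts])
        fe = np.concatenate([p[2] for p in parts])
        # top up fragments lost to contig-edge clipping so library size holds
        while len(fs) < cc.library_size:
            c2, s2, e2 = _draw_fragments(rng, names, lens,
                                         cc.library_size - len(fs),
                                         cc.fragment_length,
                                         cc.fragment_length)
            contig = np.concatenate([contig, c2])
            fs = np.concatenate([fs, s2])
            fe = np.concatenate([fe, e2])
        reads = _fragments_to_reads(contig, fs, fe, cc.read_length, rng)
        out[assay] = ReadSet(assay, reads)
    return out


def simulate_rnaseq(genome: AnnotatedGenome, methylome: pd.DataFrame,
                    config: SimConfig) -> tuple[ReadSet, pd.DataFrame]:
    """Return (rnaseq ReadSet, per-gene truth expression table)."""
    config.validate()
    rc = config.rnaseq
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))
    genes = genome.genes
    if not genes:
        return empty_reads("rnaseq"), pd.DataFrame(
            columns=["gene", "contig", "exonic_length", "baseline",
                     "te_gene", "has_4mC", "has_6mA", "rate", "counts"])
    for g in genes:
        if g.exonic_length <= 0:
            raise ValueError(f"gene {g.name} has zero exonic length")

    m4 = methylome[methylome["mark"] == "4mC"]
    m6 = methylome[methylome["mark"] == "6mA"]
    pos4 = {c: np.sort(grp["pos"].to_numpy())
            for c, grp in m4.groupby("contig")}
    pos6 = {c: np.sort(grp["pos"].to_numpy())
            for c, grp in m6.groupby("contig")}

    def any_in(index, contig, lo, hi):
        pos = index.get(contig)
        if pos is None:
            return False
        i = np.searchsorted(pos, lo, side="left")
        return bool(i < len(pos) and pos[i] < hi)

    rows = []
    for g in genes:
        has4 = any_in(pos4, g.contig, g.start, g.end)
        has6 = any_in(pos6, g.contig, g.start - rc.window,
                      g.end + rc.window)
        baseline = float(np.exp(rng.normal(0.0, rc.baseline_sigma_log)))
        baseline *= 1.0 if g.expression_class == "high" else 0.2
        rate = baseline * g.exonic_length
        if g.is_te_gene and has4:
            rate *= rc.repression_4mC
        if has6:
            rate *= rc.activation_6mA
        rows.append((g.name, g.contig, g.exonic_length, baseline,
                     g.is_te_gene, has4, has6, rate))
    truth = pd.DataFrame(rows, columns=["gene", "contig", "exonic_length",
                                        "baseline", "te_gene", "has_4mC",
                                        "has_6mA", "rate"])
    rates = truth["rate"].to_numpy()
    counts = rng.multinomial(rc.library_size, rates / rates.sum()) \
        if rc.library_size > 0 else np.zeros(len(genes), dtype=int)
    truth["counts"] = counts

    # place reads within single exonic spans
    contig_col, starts = [], []
    for g, n in zip(genes, counts):
        if n == 0:
            continue
        spans = [(s, e) for s, e in g.exonic_spans()
                 if e - s >= rc.read_length]
        if not spans:
            spans = [(g.start, max(g.start + 1, g.end - rc.read_length))]
        w = np.array([e - s for s, e in spans], dtype=float)
        si = rng.choice(len(spans), size=n, p=w / w.sum())
        for i in si:
            s, e = spans[i]
            hi = max(s + 1, e - rc.read_length + 1)
            starts.append(int(rng.integers(s, hi)))
            contig_col.append(g.contig)
    lens = genome.contig_lengths()
    starts = np.asarray(starts, dtype=np.int64)
    contig_col = np.asarray(contig_col, dtype=object)
    ends = np.array([min(s + rc.read_length, lens[c])
                     for s, c in zip(starts, contig_col)], dtype=np.int64) \
        if len(starts) else np.empty(0, dtype=np.int64)
    strand = np.where(rng.random(len(starts)) < 0.5, "+", "-")
    reads = _reads_frame(contig_col, starts, ends, strand)
    return ReadSet("rnaseq", reads), truth
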