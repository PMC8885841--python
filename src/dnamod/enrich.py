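"""Coverage tracks and enrichment peak calling.

Reads are extended to a fixed length from their 5' end in read orientation
and binned (default 10-bp bins); tracks can be RPGC-normalized (mean 1x
coverage over an effective genome size) and compared IP-vs-input as a
per-bin log2 ratio.  Peaks are called with a global-Poisson model in the
spirit of MACS' "nomodel nolambda" mode: per-bin overlapping-read counts
are tested against the genome-wide background rate, significant bins
(default p < 1e-5) are merged across gaps up to the fragment length, and
short peaks are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotatedGenome, ReadSet


@dataclass
class CoverageTrack:
    """Per-contig binned coverage.  Values are mean per-bp coverage in the
    bin (raw mode: overlapping extended-read bp / bin_size)."""

    bins: dict[str, np.ndarray]
    bin_size: int
    normalization: str = "raw"
    read_extension: int = 0
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def total_bp(self) -> float:
        return float(sum((v * self.bin_size).sum()
                         for v in self.bins.values()))

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (self.bin_size == other.bin_size and
                set(self.bins) == set(other.bins) and
                all(len(self.bins[c]) == len(other.bins[c])
                    for c in self.bins))


@dataclass
class Peak:
    contig: str
    start: int
    end: int
    summit: int
    p_value: float
    score: float


def extend_reads(reads: pd.DataFrame, read_extension: int,
                 contig_lengths: dict[str, int]) -> pd.DataFrame:
    """Extend each read to ``read_extension`` bp from its 5' end in read
    orientation, clipped at contig bounds."""
    r = reads.copy()
    plus = (r["strand"] == "+").to_numpy()
    start = r["start"].to_numpy().copy()
    end = r["end"].to_numpy().copy()
    end[plus] = start[plus] + read_extension
    start[~plus] = end[~plus] - read_extension
    clen = r["contig"].map(contig_lengths).to_numpy()
    r["start"] = np.clip(start, 0, clen)
    r["end"] = np.clip(end, 0, clen)
    return r[r["end"] > r["start"]]


def bin_coverage(reads: ReadSet, genome: AnnotatedGenome, bin_size: int = 10,
                 read_extension: int | None = None) -> CoverageTrack:
    """Binned per-bp pileup of extended reads.

    Each bin value is (overlapping extended-read bp in bin) / bin_size, so
    a 50-bp read on a 10-bp grid increments exactly 5 bins by 1.
    """
    lens = genome.contig_lengths()
    if read_extension is None:
        read_extension = int((reads.reads["end"] -
                              reads.reads["start"]).max()) \
            if len(reads.reads) else 0
    if len(reads.reads) and \
            read_extension < int((reads.reads["end"] -
                                  reads.reads["start"]).max()):
        raise ValueError("read_extension must be >= the read length")
    bins = {}
    ext = extend_reads(reads.reads, read_extension, lens) \
        if len(reads.reads) else reads.reads
    for contig, clen in sorted(lens.items()):
        n_bins = -(-clen // bin_size)
        diff = np.zeros(clen + 1)
        sub = ext[ext["contig"] == contig] if len(ext) else ext
        if len(sub):
            np.add.at(diff, sub["start"].to_numpy(), 1.0)
            np.add.at(diff, sub["end"].to_numpy(), -1.0)
        perbp = np.cumsum(diff[:-1])
        padded = np.zeros(n_bins * bin_size)
        padded[:clen] = perbp
        bins[contig] = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    return CoverageTrack(bins, bin_size, "raw", read_extension, dict(lens))


def normalize_rpgc(track: CoverageTrack,
                   effective_genome_size: int | None = None) -> CoverageTrack:
    """Scale bins so mean coverage over the effective genome equals 1x."""
    if effective_genome_size is None:
        effective_genome_size = sum(track.contig_lengths.values())
    total = track.total_bp()
    if total <= 0:
        raise ValueError("cannot RPGC-normalize a zero-coverage track")
    factor = effective_genome_size / total
    return CoverageTrack({c: v * factor for c, v in track.bins.items()},
                         track.bin_size, "RPGC", track.read_extension,
                         dict(track.contig_lengths))


def log2_ratio(ip: CoverageTrack, control: CoverageTrack,
               pseudocount: float = 1.0) -> CoverageTrack:
    """Per-bin log2((ip + psi) / (input + psi)) on matching grids."""
    if not ip.same_grid(control):
        raise ValueError("IP and input tracks are on different bin grids")
    bins = {c: np.log2((ip.bins[c] + pseudocount) /
                       (control.bins[c] + pseudocount))
            for c in ip.bins}
    return CoverageTrack(bins, ip.bin_size, "log2ratio", ip.read_extension,
                         dict(ip.contig_lengths))


def _read_overlap_counts(reads: pd.DataFrame, clen: int,
                         bin_size: int) -> np.ndarray:
    """Number of reads overlapping each bin (diff-array over bin indices)."""
    n_bins = -(-clen // bin_size)
    diff = np.zeros(n_bins + 1)
    if len(reads):
        first = reads["start"].to_numpy() // bin_size
        last = (reads["end"].to_numpy() - 1) // bin_size
        np.add.at(diff, first, 1.0)
        np.add.at(diff, last + 1, -1.0)
    return np.cumsum(diff[:-1])


def bin_read_counts(reads: ReadSet, genome: AnnotatedGenome,
                    bin_size: int = 10,
                    read_extension: int | None = None
                    ) -> dict[str, np.ndarray]:
    """Per-bin counts of overlapping extended reads (the peak-caller's
    test statistic)."""
    lens = genome.contig_lengths()
    if read_extension is None:
        read_extension = int((reads.reads["end"] -
                              reads.reads["start"]).max()) \
            if len(reads.reads) else 0
    ext = extend_reads(reads.reads, read_extension, lens) \
        if len(reads.reads) else reads.reads
    counts = {}
    for contig, clen in sorted(lens.items()):
        sub = ext[ext["contig"] == contig] if len(ext) else ext
        counts[contig] = _read_overlap_counts(sub, clen, bin_size)
    return counts


def bin_pvalues(reads: ReadSet, genome: AnnotatedGenome,
                bin_size: int = 10, read_extension: int | None = None
                ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """(counts, one-sided Poisson upper-tail p-values) per bin against the
    genome-wide background rate."""
    counts = bin_read_counts(reads, genome, bin_size, read_extension)
    total = sum(c.sum() for c in counts.values())
    n_total = sum(len(c) for c in counts.values())
    lam = total / n_total if n_total else 0.0
    if lam <= 0:
        raise ValueError("zero background rate: no reads to call peaks from")
    pvals = {c: stats.poisson.sf(v - 1, lam) for c, v in counts.items()}
    return counts, pvals


def call_peaks(reads: ReadSet, genome: AnnotatedGenome, *,
               bin_size: int = 10, read_extension: int | None = None,
               p_threshold: float = 1e-5, min_gap: int = 300,
               min_width: int = 150) -> list[Peak]:
    """Global-Poisson peak caller.

    Per-bin counts of overlapping extended reads are tested against the
    genome-wide mean rate (one-sided Poisson upper tail, no local lambda);
    significant bins are merged when separated by <= ``min_gap`` bp and
    peaks narrower than ``min_width`` are dropped.  The summit is the
    centre of the (leftmost) maximal-count bin.
    """
    lens = genome.contig_lengths()
    counts, all_pvals = bin_pvalues(reads, genome, bin_size, read_extension)

    gap_bins = max(min_gap // bin_size, 0)
    peaks: list[Peak] = []
    for contig in sorted(counts):
        c = counts[contig]
        pvals = all_pvals[contig]
        sig = np.nonzero(pvals < p_threshold)[0]
        if len(sig) == 0:
            continue
        # merge significant bins across small gaps
        breaks = np.nonzero(np.diff(sig) > gap_bins + 1)[0]
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks, [len(sig) - 1]])
        for si, ei in zip(seg_starts, seg_ends):
            b0, b1 = int(sig[si]), int(sig[ei])
            start = b0 * bin_size
            end = min((b1 + 1) * bin_size, lens[contig])
            if end - start < min_width:
                continue
            window = c[b0:b1 + 1]
            rel = int(np.argmax(window))  # leftmost maximal bin
            summit_bin = b0 + rel
            summit = min(summit_bin * bin_size + bin_size // 2,
                         lens[contig] - 1)
            p = float(pvals[b0:b1 + 1].min())
            score = 1000.0 if p <= 0 else float(-10.0 * np.log10(p))
            peaks.append(Peak(contig, start, end, summit, p, score))
    return peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.contig, p.start, p.end, p.summit, p.p_value, p.score)
         for p in peaks],
        columns=["contig", "start", "end", "summit", "p_value", "score"])
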