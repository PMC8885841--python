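"""Sequence-context statistics around modification sites.

Windows of ±flank bp are extracted around each call, read on the modified
strand (minus-strand sites are reverse-complemented), so the centre base
is always C for 4mC and A for 6mA.  Doublet/triplet composition is
tabulated at the centre, and k-mer over-representation against a matched
random background is scored with one-sided Fisher's exact tests with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AnnotatedGenome, revcomp

CENTER_BASE = {"4mC": "C", "6mA": "A"}


@dataclass
class ContextWindowSet:
    """Per-site windows of length 2*flank+1 on the modified strand."""

    windows: list[str]
    flank: int
    mark: str | None = None
    n_dropped_edge: int = 0
    n_rejected_center: int = 0

    def __len__(self) -> int:
        return len(self.windows)


def extract_context(calls: pd.DataFrame, genome: AnnotatedGenome,
                    flank: int = 10,
                    expect_mark: str | None = None) -> ContextWindowSet:
    """Strand-aware window extraction around call positions.

    Windows truncated at contig edges are dropped (counted); sites whose
    centre base does not match the mark are rejected with a warning count.
    """
    windows = []
    dropped = rejected = 0
    for contig, pos, strand, mark in calls[
            ["contig", "pos", "strand", "mark"]].itertuples(
            index=False, name=None):
        seq = genome.contigs[contig]
        if pos - flank < 0 or pos + flank + 1 > len(seq):
            dropped += 1
            continue
        win = seq[pos - flank:pos + flank + 1]
        if strand == "-":
            win = revcomp(win)
        want = CENTER_BASE.get(expect_mark or mark)
        if want is not None and win[flank] != want:
            rejected += 1
            continue
        windows.append(win)
    if rejected:
        warnings.warn(f"{rejected} sites rejected: centre base does not "
                      "match the mark")
    return ContextWindowSet(windows, flank, expect_mark, dropped, rejected)


def doublet_triplet_stats(windows: ContextWindowSet,
                          doublet_offset: int = 0) -> dict[str, pd.Series]:
    """Proportions of the doublet at (centre, centre+1) and of the triplets
    (centre-1..centre+1) and (centre..centre+2).

    ``doublet_offset=-1`` switches the doublet to (centre-1, centre) for
    marks whose signature sits 5' of the modified base (e.g. GA for 6mA).
    """
    if windows.flank < 2:
        raise ValueError("doublet/triplet statistics need flank >= 2")
    c = windows.flank
    doublets: dict[str, int] = {}
    trip_l: dict[str, int] = {}
    trip_r: dict[str, int] = {}
    for w in windows.windows:
        if doublet_offset == 0:
            d = w[c:c + 2]
        else:
            d = w[c - 1:c + 1]
        doublets[d] = doublets.get(d, 0) + 1
        tl = w[c - 1:c + 2]
        tr = w[c:c + 3]
        trip_l[tl] = trip_l.get(tl, 0) + 1
        trip_r[tr] = trip_r.get(tr, 0) + 1

    def norm(counts):
        s = pd.Series(counts, dtype=float).sort_values(ascending=False)
        return s / s.sum() if s.sum() else s

    return {"doublet": norm(doublets),
            "triplet_left": norm(trip_l),
            "triplet_right": norm(trip_r)}


def sample_background_windows(genome: AnnotatedGenome, center_base: str,
                              flank: int, n: int,
                              seed: int = 0) -> ContextWindowSet:
    """Random genome positions with the given centre base, either strand —
    the matched background for k-mer enrichment."""
    rng = np.random.default_rng(seed)
    names = sorted(genome.contigs)
    lens = [len(genome.contigs[c]) for c in names]
    probs = np.asarray(lens, dtype=float) / sum(lens)
    comp = revcomp(center_base)
    windows = []
    attempts = 0
    while len(windows) < n and attempts < 200 * n:
        attempts += 1
        ci = rng.choice(len(names), p=probs)
        seq = genome.contigs[names[ci]]
        if len(seq) < 2 * flank + 1:
            continue
        pos = int(rng.integers(flank, len(seq) - flank))
        base = seq[pos]
        if base == center_base:
            windows.append(seq[pos - flank:pos + flank + 1])
        elif base == comp:
            windows.append(revcomp(seq[pos - flank:pos + flank + 1]))
    return ContextWindowSet(windows, flank)


def kmer_enrichment(foreground: ContextWindowSet,
                    background: ContextWindowSet,
                    k_range: tuple[int, ...] = (2, 3, 4),
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-k-mer presence/absence 2x2 Fisher enrichment of foreground
    windows over background, BH-corrected across all tested k-mers.

    K-mers absent from both sets are excluded.  Output is sorted by
    q-value then descending odds ratio.
    """
    if len(background) < len(foreground):
        warnings.warn("background smaller than foreground; enrichment "
                      "estimates will be noisy")
    n_fg, n_bg = len(foreground.windows), len(background.windows)
    rows = []
    for k in k_range:
        fg_counts: dict[str, int] = {}
        bg_counts: dict[str, int] = {}
        for counts, wins in ((fg_counts, foreground.windows),
                             (bg_counts, background.windows)):
            for w in wins:
                seen = {w[i:i + k] for i in range(len(w) - k + 1)}
                for kmer in seen:
                    counts[kmer] = counts.get(kmer, 0) + 1
        for kmer in sorted(set(fg_counts) | set(bg_counts)):
            a = fg_counts.get(kmer, 0)
            b = bg_counts.get(kmer, 0)
            if a == 0 and b == 0:
                continue
            table = [[a, n_fg - a], [b, n_bg - b]]
            odds, p = stats.fisher_exact(table, alternative="greater")
            rows.append({"kmer": kmer, "k": k, "fg_present": a,
                         "fg_total": n_fg, "bg_present": b,
                         "bg_total": n_bg, "odds_ratio": float(odds),
                         "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df) == 0:
        df["q_value"] = pd.Series(dtype=float)
        return df
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["q_value", "odds_ratio"],
                        ascending=[True, False], kind="stable")
    return df.reset_index(drop=True)
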