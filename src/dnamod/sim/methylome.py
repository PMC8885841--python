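"""Plant a ground-truth methylome onto an annotated genome.

4mC is planted on cytosines (either strand) inside intact TE copies and
tandem repeats, weighted by dinucleotide context (CpG/CpA favoured) and by
an exponential decay from the TE 5' boundary; per-site fractions have a
point mass at 1.0 plus a high-skewed Beta tail.  6mA is planted genome-wide
on adenines with GA-context weighting and a broader Beta fraction
distribution.  Methylation is mostly single-strand: a configurable small
fraction of positions receive a partner record on the opposite strand at
the palindromic doublet (CpG for 4mC, ApT for 6mA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..core import AnnotatedGenome, METHYLOME_COLUMNS, empty_methylome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _contig_arrays(genome: AnnotatedGenome) -> dict[str, np.ndarray]:
    return {name: np.frombuffer(seq.encode(), dtype="S1")
            for name, seq in genome.contigs.items()}


def _te_class(copy) -> str:
    r = copy.integrity
    if r < 0.5:
        return "te_short"
    if r < 0.9:
        return "te_medium"
    return "te_full"


def _draw_fractions(rng, n, full_prob, beta):
    frac = rng.beta(beta[0], beta[1], size=n)
    full = rng.random(n) < full_prob
    frac[full] = 1.0
    return np.clip(frac, 1e-6, 1.0)


def plant_methylome(genome: AnnotatedGenome,
                    config: SimConfig) -> pd.DataFrame:
    """Return a TrueMethylome DataFrame (contig, pos, strand, mark, fraction)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    arrays = _contig_arrays(genome)
    s = config.symmetric_fraction
    pair_q = s / (2.0 - s) if s < 1.0 else 1.0

    frames = []
    rec_4mc = _plant_4mc(genome, config, arrays, rng, pair_q)
    if rec_4mc is not None:
        frames.append(rec_4mc)
    rec_6ma = _plant_6ma(genome, config, arrays, rng, pair_q)
    if rec_6ma is not None:
        frames.append(rec_6ma)

    if not frames:
        return empty_methylome()
    meth = pd.concat(frames, ignore_index=True)
    meth = meth.drop_duplicates(subset=["contig", "pos", "strand", "mark"])
    meth = meth.sort_values(["contig", "pos", "strand"], kind="stable")
    return meth.reset_index(drop=True)[METHYLOME_COLUMNS]


# --------------------------------------------------------------------- 4mC

def _plant_4mc(genome, config, arrays, rng, pair_q):
    cfg = config.meth_4mC
    if cfg.site_rate == 0:
        return None
    units = []  # (contig, start, end, te_strand or None, unit_weight)
    classes = set(cfg.target_feature_classes)
    for copy in genome.te_copies:
        if _te_class(copy) in classes:
            uw = min(copy.integrity, 1.0) ** cfg.integrity_weight_power
            units.append((copy.contig, copy.start, copy.end, copy.strand,
                          uw))
    if "tandem_repeat" in classes:
        for tr in genome.tandem_repeats:
            units.append((tr.contig, tr.start, tr.end, None, 1.0))
    if not units:
        raise ValueError(
            "no eligible 4mC target features for classes "
            f"{sorted(classes)}: the genome has no matching TE copies or "
            "tandem repeats")

    cw = cfg.context_weights
    contigs, positions, strands, weights = [], [], [], []
    for contig, start, end, te_strand, unit_w in units:
        if rng.random() >= cfg.copy_methylation_prob:
            continue
        arr = arrays[contig]
        span = arr[start:end]
        # plus strand: C at p, doublet = seq[p:p+2]
        rel = np.nonzero(span == b"C")[0]
        for p_rel in rel:
            p = start + int(p_rel)
            nxt = arr[p + 1].decode() if p + 1 < len(arr) else "N"
            w = unit_w * cw.get("C" + nxt, 1.0)
            w *= _decay(p, start, end, te_strand, cfg.te_5prime_decay_bp)
            contigs.append(contig)
            positions.append(p)
            strands.append("+")
            weights.append(w)
        # minus strand: C on minus <=> G on plus; next base on minus is the
        # complement of the plus base immediately 5' of p
        rel = np.nonzero(span == b"G")[0]
        for p_rel in rel:
            p = start + int(p_rel)
            nxt = _COMP.get(arr[p - 1].decode(), "N") if p > 0 else "N"
            w = unit_w * cw.get("C" + nxt, 1.0)
            w *= _decay(p, start, end, te_strand, cfg.te_5prime_decay_bp)
            contigs.append(contig)
            positions.append(p)
            strands.append("-")
            weights.append(w)
    if not positions:
        raise ValueError("no eligible cytosines in the 4mC target features")

    weights = np.asarray(weights, dtype=float)
    p_plant = np.minimum(cfg.site_rate * weights / weights.mean(), 1.0)
    keep = rng.random(len(weights)) < p_plant
    contigs = np.asarray(contigs, dtype=object)[keep]
    positions = np.asarray(positions, dtype=np.int64)[keep]
    strands = np.asarray(strands, dtype=object)[keep]
    frac = _draw_fractions(rng, keep.sum(), cfg.fully_methylated_prob,
                           cfg.fraction_beta)
    df = pd.DataFrame({"contig": contigs, "pos": positions,
                       "strand": strands, "mark": "4mC", "fraction": frac})
    df = _collapse_palindromic(df, arrays, rng, mark="4mC")
    partners = _symmetric_partners(df, arrays, rng, pair_q, mark="4mC")
    return pd.concat([df, partners], ignore_index=True) if len(partners) \
        else df


def _decay(p, start, end, te_strand, scale):
    if te_strand is None:
        return 1.0
    d = p - start if te_strand == "+" else end - 1 - p
    return float(np.exp(-d / scale))


# --------------------------------------------------------------------- 6mA

def _plant_6ma(genome, config, arrays, rng, pair_q):
    cfg = config.meth_6mA
    if cfg.site_rate == 0:
        return None
    contigs, positions, strands, weights = [], [], [], []
    for contig, arr in arrays.items():
        n = len(arr)
        # plus strand adenines
        pos = np.nonzero(arr == b"A")[0]
        pos = pos[(pos > 0) & (pos < n - 1)]
        if len(pos):
            w = np.ones(len(pos))
            w[arr[pos - 1] == b"G"] *= cfg.prev_g_weight
            w[arr[pos + 1] == b"A"] *= cfg.next_a_weight
            contigs.extend([contig] * len(pos))
            positions.extend(pos.tolist())
            strands.extend(["+"] * len(pos))
            weights.extend(w.tolist())
        # minus strand adenines (plus-strand T); on the minus strand the 5'
        # neighbour sits at plus position p+1 and the 3' neighbour at p-1
        pos = np.nonzero(arr == b"T")[0]
        pos = pos[(pos > 0) & (pos < n - 1)]
        if len(pos):
            w = np.ones(len(pos))
            w[arr[pos + 1] == b"C"] *= cfg.prev_g_weight   # minus-prev == G
            w[arr[pos - 1] == b"T"] *= cfg.next_a_weight   # minus-next == A
            contigs.extend([contig] * len(pos))
            positions.extend(pos.tolist())
            strands.extend(["-"] * len(pos))
            weights.extend(w.tolist())
    if not positions:
        raise ValueError("no eligible adenines in the genome for 6mA")

    weights = np.asarray(weights, dtype=float)
    p_plant = np.minimum(cfg.site_rate * weights / weights.mean(), 1.0)
    keep = rng.random(len(weights)) < p_plant
    df = pd.DataFrame({
        "contig": np.asarray(contigs, dtype=object)[keep],
        "pos": np.asarray(positions, dtype=np.int64)[keep],
        "strand": np.asarray(strands, dtype=object)[keep],
        "mark": "6mA",
        "fraction": _draw_fractions(rng, int(keep.sum()),
                                    cfg.fully_methylated_prob,
                                    cfg.fraction_beta),
    })
    df = _collapse_palindromic(df, arrays, rng, mark="6mA")
    partners = _symmetric_partners(df, arrays, rng, pair_q, mark="6mA")
    return pd.concat([df, partners], ignore_index=True) if len(partners) \
        else df


# ------------------------------------------------------------- symmetry

def _collapse_palindromic(df, arrays, rng, mark):
    """Keep one strand when both strands of a palindromic doublet were
    planted independently, so pairing is governed solely by the configured
    symmetric fraction."""
    if len(df) == 0:
        return df
    center, nxt = ("C", "G") if mark == "4mC" else ("A", "T")
    keys = set(zip(df["contig"], df["pos"], df["strand"]))
    drop = set()
    for contig, pos, strand in sorted(keys):
        if strand != "+":
            continue
        partner = (contig, pos + 1, "-")
        if partner in keys and (contig, pos, "+") not in drop \
                and partner not in drop:
            seq = arrays[contig]
            if pos + 1 < len(seq) and seq[pos] == center.encode() \
                    and seq[pos + 1] == nxt.encode():
                drop.add((contig, pos, "+") if rng.random() < 0.5
                         else partner)
    if not drop:
        return df
    mask = [
        (c, p, s) not in drop
        for c, p, s in zip(df["contig"], df["pos"], df["strand"])]
    return df[mask].reset_index(drop=True)


def _symmetric_partners(df, arrays, rng, pair_q, mark):
    """Opposite-strand partner records at palindromic doublets.

    4mC pairs across a CpG (plus C at p with minus C at p+1); 6mA pairs
    across an ApT.  Non-palindromic contexts have no opposite-strand
    partner position of the right base identity, so they stay asymmetric.
    """
    if pair_q == 0 or len(df) == 0:
        return pd.DataFrame(columns=df.columns)
    center, partner_next = (b"C", b"G") if mark == "4mC" else (b"A", b"T")
    partners = []
    avail = np.zeros(len(df), dtype=bool)
    for i, (contig, pos, strand, _, frac) in enumerate(
            df.itertuples(index=False, name=None)):
        arr = arrays[contig]
        if strand == "+":
            q = pos + 1
            if q < len(arr) and arr[q] == partner_next:
                avail[i] = True
                partners.append((contig, q, "-", mark, frac))
                continue
        else:
            q = pos - 1
            if q >= 0 and arr[q] == center:
                avail[i] = True
                partners.append((contig, q, "+", mark, frac))
                continue
        partners.append(None)
    # compensate for sites with no palindromic partner context so the
    # realized fraction of paired positions matches the configured target
    pi = avail.mean()
    if pi == 0:
        return pd.DataFrame(columns=df.columns)
    q_eff = min(1.0, pair_q / pi)
    draws = rng.random(len(df))
    rows = [p for p, a, u in zip(partners, avail, draws)
            if a and u < q_eff and p is not None]
    return pd.DataFrame(rows, columns=df.columns)


# ------------------------------------------------------------- clusters

def methylation_clusters(methylome: pd.DataFrame, gap: int = 300,
                         mark: str | None = None) -> pd.DataFrame:
    """Group planted marks into clusters (positions closer than ``gap``).

    Returns a DataFrame with contig, start, end, center (median mark
    position) and n_sites — the planted "methylated regions" that DIP-seq
    peak calling is expected to recover.
    """
    m = methylome if mark is None else methylome[methylome["mark"] == mark]
    rows = []
    for contig, grp in m.groupby("contig", sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for si, ei in zip(starts, ends):
            chunk = pos[si:ei + 1]
            rows.append((contig, int(chunk[0]), int(chunk[-1]) + 1,
                         float(np.median(chunk)), len(chunk)))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "center",
                                       "n_sites"])
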