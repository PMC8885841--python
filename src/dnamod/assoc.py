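"""Feature-association statistics.

Covers the figure-analog analyses of the pipeline: site/read occupancy
profiles around feature anchors, length-normalized metaprofiles,
annotation-normalized modification densities, ±window peak-feature
intersections, genometric spatial correlation (bp-Jaccard / nearest
distance with a relocation permutation null), TE-integrity stratification,
DIP x ChIP peak co-localization, strand-symmetry of calls, observed/expected
CpG ratios, RPKM and expression-group hypothesis tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotatedGenome, TECopy
from .enrich import CoverageTrack
from .intervals import (as_intervals, jaccard_bp, merge_intervals,
                        nearest_distances, relocate_intervals, total_bp,
                        window_association)

__all__ = [
    "ProfileMatrix", "occupancy_profile", "metaprofile", "fraction_profile",
    "normalized_density", "density_table", "window_intersect", "jaccard_bp",
    "SpatialCorrResult", "permutation_spatial_test", "classify_te_integrity",
    "density_by_integrity", "colocalization_fractions",
    "summit_signal_profile", "strand_symmetry", "cpg_obs_exp", "rpkm",
    "log2_rpkm", "GroupTestResult", "expression_group_tests",
]


# ----------------------------------------------------------------- profiles

@dataclass
class ProfileMatrix:
    """Per-feature binned values.

    ``values`` is n_features x n_bins.  For occupancy profiles the entries
    are item counts and ``profile()`` is column sum / n_features (IP
    occupancy).  For fraction profiles ``values`` holds per-bin fraction
    sums and ``counts`` the number of contributing calls; ``profile()`` is
    the masked mean (bins with no calls report 0 with mask False).
    """

    values: np.ndarray
    bin_size: int
    flank: int
    n_body_bins: int = 0
    counts: Optional[np.ndarray] = None
    n_skipped: int = 0

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def profile(self) -> np.ndarray:
        if self.counts is None:
            return self.values.sum(axis=0) / max(self.n_features, 1)
        totals = self.counts.sum(axis=0)
        out = np.zeros(self.n_bins)
        nz = totals > 0
        out[nz] = self.values.sum(axis=0)[nz] / totals[nz]
        return out

    def mask(self) -> np.ndarray:
        if self.counts is None:
            return np.ones(self.n_bins, dtype=bool)
        return self.counts.sum(axis=0) > 0


def _item_positions(items) -> pd.DataFrame:
    """Items as (contig, pos): site tables pass through, read/interval
    tables are reduced to their midpoints."""
    if "pos" in items.columns:
        return items[["contig", "pos"]]
    mid = (items["start"].to_numpy() + items["end"].to_numpy()) // 2
    return pd.DataFrame({"contig": items["contig"].to_numpy(), "pos": mid})


def _feature_anchor(row, anchor: str) -> int:
    strand = row.get("strand", "+")
    if anchor == "summit":
        return int(row["summit"])
    if anchor in ("5prime", "TSS"):
        return int(row["start"]) if strand == "+" else int(row["end"]) - 1
    if anchor == "TTS":
        return int(row["end"]) - 1 if strand == "+" else int(row["start"])
    raise ValueError(f"unknown anchor {anchor!r}")


def occupancy_profile(items: pd.DataFrame, features: pd.DataFrame,
                      flank: int = 2500, bin_size: int = 25,
                      anchor: str = "5prime") -> ProfileMatrix:
    """Item counts in fixed bins around a per-feature anchor.

    Feature strand flips the axis so upstream is always on the left.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if len(features) == 0:
        raise ValueError("occupancy_profile requires at least one feature")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(features), n_bins))
    pos_df = _item_positions(items)
    by_contig = {c: np.sort(g["pos"].to_numpy())
                 for c, g in pos_df.groupby("contig")}
    for fi, (_, row) in enumerate(features.iterrows()):
        pos = by_contig.get(row["contig"])
        if pos is None:
            continue
        a = _feature_anchor(row, anchor)
        # prefilter with a 1-bp margin: the exact oriented-window bound is
        # enforced by the bin-index check after strand mirroring
        lo = np.searchsorted(pos, a - flank - 1, side="left")
        hi = np.searchsorted(pos, a + flank + 1, side="left")
        offs = pos[lo:hi] - a
        if row.get("strand", "+") == "-":
            offs = -offs  # mirror so upstream stays left
        idx = (offs + flank) // bin_size
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(values[fi], idx[ok].astype(int), 1.0)
    return ProfileMatrix(values, bin_size, flank)


def metaprofile(items: pd.DataFrame, features: pd.DataFrame,
                flank: int = 2500, bin_size: int = 25,
                n_body_bins: int = 100) -> ProfileMatrix:
    """Scaled-body profile: absolute-bp flanks, bodies rescaled 0-100%."""
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    fb = flank // bin_size
    n_bins = 2 * fb + n_body_bins
    keep = features[(features["end"] - features["start"]) > 0]
    n_skipped = len(features) - len(keep)
    if n_skipped:
        warnings.warn(f"metaprofile skipped {n_skipped} zero-length features")
    values = np.zeros((len(keep), n_bins))
    pos_df = _item_positions(items)
    by_contig = {c: np.sort(g["pos"].to_numpy())
                 for c, g in pos_df.groupby("contig")}
    for fi, (_, row) in enumerate(keep.iterrows()):
        pos = by_contig.get(row["contig"])
        if pos is None:
            continue
        start, end = int(row["start"]), int(row["end"])
        L = end - start
        lo = np.searchsorted(pos, start - flank, side="left")
        hi = np.searchsorted(pos, end + flank, side="left")
        for p in pos[lo:hi]:
            if row.get("strand", "+") == "+":
                d = p - start
            else:
                d = (end - 1) - p
            if d < 0:
                if d < -flank:
                    continue
                idx = (d + flank) // bin_size
            elif d < L:
                idx = fb + min(int(d / L * n_body_bins), n_body_bins - 1)
            else:
                dd = d - L
                if dd >= flank:
                    continue
                idx = fb + n_body_bins + dd // bin_size
            values[fi, int(idx)] += 1.0
    return ProfileMatrix(values, bin_size, flank, n_body_bins,
                         n_skipped=n_skipped)


def fraction_profile(calls: pd.DataFrame, anchors: pd.DataFrame,
                     flank: int = 3000, bin_size: int = 25) -> ProfileMatrix:
    """Mean methylation fraction per bin around anchor positions."""
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(anchors), n_bins))
    counts = np.zeros((len(anchors), n_bins))
    sub = calls.dropna(subset=["fraction"])
    by_contig = {c: (g["pos"].to_numpy(), g["fraction"].to_numpy())
                 for c, g in sub.groupby("contig")}
    for ai, (_, row) in enumerate(anchors.iterrows()):
        entry = by_contig.get(row["contig"])
        if entry is None:
            continue
        pos, frac = entry
        a = int(row["pos"]) if "pos" in row else int(row["summit"])
        offs = pos - a
        idx = (offs + flank) // bin_size
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(values[ai], idx[ok].astype(int), frac[ok])
        np.add.at(counts[ai], idx[ok].astype(int), 1.0)
    return ProfileMatrix(values, bin_size, flank, counts=counts)


# ------------------------------------------------------------------ density

def _sites_in_intervals(sites: pd.DataFrame,
                        intervals: pd.DataFrame) -> np.ndarray:
    """Boolean per site: inside any (merged) interval."""
    merged = merge_intervals(intervals) if len(intervals) else intervals
    out = np.zeros(len(sites), dtype=bool)
    for contig, grp in merged.groupby("contig") if len(merged) else []:
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sel = sites["contig"].to_numpy() == contig
        pos = sites["pos"].to_numpy()[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        out[sel] = inside
    return out


def normalized_density(sites: pd.DataFrame, annotations: pd.DataFrame,
                       genome_fraction: float,
                       n_annotations: int | None = None) -> dict:
    """(sites in class / number of annotations) / genome fraction."""
    if genome_fraction <= 0:
        raise ValueError("genome_fraction must be > 0")
    n_ann = len(annotations) if n_annotations is None else n_annotations
    if n_ann == 0:
        return {"n_sites": 0, "n_annotations": 0,
                "genome_fraction": genome_fraction,
                "normalized_density": float("nan"), "undefined": True}
    n_sites = int(_sites_in_intervals(sites, annotations).sum())
    return {"n_sites": n_sites, "n_annotations": n_ann,
            "genome_fraction": genome_fraction,
            "normalized_density": (n_sites / n_ann) / genome_fraction,
            "undefined": False}


def density_table(calls: pd.DataFrame,
                  genome: AnnotatedGenome) -> pd.DataFrame:
    """Per-mark, per-feature-class normalized modification density
    (genes / TEs / tandem repeats), with genome fractions measured from the
    annotation spans."""
    gsize = genome.total_length
    classes = {
        "genes": pd.DataFrame(
            [(g.contig, g.start, g.end) for g in genome.genes],
            columns=["contig", "start", "end"]),
        "TE": pd.DataFrame(
            [(t.contig, t.start, t.end) for t in genome.te_copies],
            columns=["contig", "start", "end"]),
        "TR": pd.DataFrame(
            [(r.contig, r.start, r.end) for r in genome.tandem_repeats],
            columns=["contig", "start", "end"]),
    }
    rows = []
    for mark, grp in calls.groupby("mark", sort=True):
        for cname, ann in classes.items():
            frac = total_bp(ann) / gsize if len(ann) else 0.0
            if frac == 0:
                rows.append({"mark": mark, "feature_class": cname,
                             "n_sites": 0, "n_annotations": len(ann),
                             "genome_fraction": 0.0,
                             "normalized_density": float("nan"),
                             "undefined": True})
                continue
            row = normalized_density(grp, ann, frac)
            row.update({"mark": mark, "feature_class": cname})
            rows.append(row)
    cols = ["mark", "feature_class", "n_sites", "n_annotations",
            "genome_fraction", "normalized_density", "undefined"]
    return pd.DataFrame(rows)[cols]


# ----------------------------------------------------------- intersections

def window_intersect(items: pd.DataFrame, features: pd.DataFrame,
                     window: int = 500) -> tuple[int, np.ndarray]:
    """Associate items with a feature class when within ±window bp
    (overlap counts as distance 0).  Returns (count, per-item labels)."""
    iv = items
    if "pos" in items.columns and "start" not in items.columns:
        iv = pd.DataFrame({"contig": items["contig"],
                           "start": items["pos"],
                           "end": items["pos"] + 1})
    fv = features
    if "pos" in features.columns and "start" not in features.columns:
        fv = pd.DataFrame({"contig": features["contig"],
                           "start": features["pos"],
                           "end": features["pos"] + 1})
    labels = window_association(iv, fv, window)
    return int(labels.sum()), labels


# ------------------------------------------------------- spatial correlation

@dataclass
class SpatialCorrResult:
    statistic: str
    observed: float
    p_value: float
    n_permutations: int
    direction: str
    null_values: np.ndarray = field(repr=False,
                                    default_factory=lambda: np.empty(0))


def permutation_spatial_test(query: pd.DataFrame, reference: pd.DataFrame,
                             genome: AnnotatedGenome,
                             statistic: str = "jaccard",
                             n_permutations: int = 999,
                             seed: int = 0) -> SpatialCorrResult:
    """Relocation permutation test of query-reference spatial association.

    The null relocates query intervals uniformly, preserving lengths and
    contig assignment.  For ``jaccard`` large values indicate association
    (p counts null >= observed); for ``mean_nearest_distance`` small values
    do (p counts null <= observed).  p has the +1 permutation floor.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if statistic not in ("jaccard", "mean_nearest_distance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    lens = genome.contig_lengths()
    rng = np.random.default_rng(seed)

    def stat(q):
        if statistic == "jaccard":
            return jaccard_bp(q, reference)
        d = nearest_distances(q, reference)
        d = d[np.isfinite(d)]
        return float(d.mean()) if len(d) else float("nan")

    observed = stat(query)
    null = np.empty(n_permutations)
    if statistic == "jaccard":
        null = _jaccard_null(query, reference, lens, n_permutations, rng)
    else:
        for i in range(n_permutations):
            null[i] = stat(relocate_intervals(query, lens, rng))
    if statistic == "jaccard":
        extreme = int(np.sum(null >= observed))
        direction = "greater"
    else:
        extreme = int(np.sum(null <= observed))
        direction = "less"
    p = (1 + extreme) / (n_permutations + 1)
    return SpatialCorrResult(statistic, float(observed), float(p),
                             n_permutations, direction, null)


def _jaccard_null(query, reference, lens, n_permutations, rng):
    """Array-based relocation null for the bp-Jaccard statistic.

    Uses |A n B| = |A| + |B| - |A u B| with vectorized per-contig merges,
    equivalent to relocate_intervals + jaccard_bp but without the
    per-permutation DataFrame churn.
    """
    from .intervals import merge_arrays

    q = as_intervals(query)
    ref = merge_intervals(reference)
    ref_by = {}
    bp_ref = 0
    for contig, grp in ref.groupby("contig"):
        rs = grp["start"].to_numpy()
        re = grp["end"].to_numpy()
        ref_by[contig] = (rs, re)
        bp_ref += int((re - rs).sum())
    q_by = {}
    for contig, grp in q.groupby("contig"):
        lengths = (grp["end"] - grp["start"]).to_numpy()
        clen = lens[contig]
        if np.any(lengths > clen):
            raise ValueError(f"query interval exceeds contig {contig}")
        q_by[contig] = (lengths, clen)

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        bp_q = bp_union = 0
        # contigs with reference but no query still contribute to the union
        seen = set()
        for contig, (lengths, clen) in q_by.items():
            starts = (rng.random(len(lengths)) *
                      (clen - lengths + 1)).astype(np.int64)
            qs, qe = merge_arrays(starts, starts + lengths)
            bp_q += int((qe - qs).sum())
            rs, re = ref_by.get(contig, (np.empty(0, np.int64),
                                         np.empty(0, np.int64)))
            us, ue = merge_arrays(np.concatenate([qs, rs]),
                                  np.concatenate([qe, re]))
            bp_union += int((ue - us).sum())
            seen.add(contig)
        for contig, (rs, re) in ref_by.items():
            if contig not in seen:
                bp_union += int((re - rs).sum())
        if bp_q == 0 and bp_ref == 0:
            null[i] = float("nan")
        else:
            null[i] = (bp_q + bp_ref - bp_union) / bp_union
    return null


# ------------------------------------------------------------ TE integrity

def classify_te_integrity(copy_span_length: int, consensus_length: int,
                          full_threshold: float = 0.9) -> str:
    """short < 0.5, medium [0.5, full_threshold), full >= full_threshold of
    the consensus length.  Ratios above 1.2 flag a suspect annotation but
    classify full."""
    if consensus_length <= 0:
        raise ValueError("consensus_length must be > 0")
    r = copy_span_length / consensus_length
    if r > 1.2:
        warnings.warn(
            f"copy/consensus ratio {r:.2f} > 1.2; annotation suspect")
        return "full"
    if r < 0.5:
        return "short"
    if r < full_threshold:
        return "medium"
    return "full"


def density_by_integrity(calls: pd.DataFrame,
                         te_copies: Sequence[TECopy],
                         full_threshold: float = 0.9) -> pd.DataFrame:
    """Mean ± SD of per-copy overlapping call counts per integrity class."""
    by_contig = {c: np.sort(g["pos"].to_numpy())
                 for c, g in calls.groupby("contig")}
    counts: dict[str, list[int]] = {"full": [], "medium": [], "short": []}
    for copy in te_copies:
        klass = classify_te_integrity(copy.length, copy.consensus_length,
                                      full_threshold)
        pos = by_contig.get(copy.contig, np.empty(0))
        n = int(np.searchsorted(pos, copy.end, side="left") -
                np.searchsorted(pos, copy.start, side="left"))
        counts[klass].append(n)
    rows = []
    for klass in ("full", "medium", "short"):
        vals = np.asarray(counts[klass], dtype=float)
        if len(vals) == 0:
            rows.append({"integrity_class": klass, "n_copies": 0,
                         "mean_count": float("nan"), "sd_count": float("nan"),
                         "empty": True})
        else:
            rows.append({"integrity_class": klass, "n_copies": len(vals),
                         "mean_count": float(vals.mean()),
                         "sd_count": float(vals.std(ddof=0)),
                         "empty": False})
    return pd.DataFrame(rows)


# --------------------------------------------------------- co-localization

def colocalization_fractions(
        dip_peaks: pd.DataFrame,
        chip_peak_sets: dict[str, pd.DataFrame],
        combined: dict[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Percent of DIP peaks intersecting >=1 peak of each chromatin class
    (and of configured class unions, e.g. H3K9me3+H3K27me3)."""
    combined = combined or {}
    n = len(dip_peaks)
    rows = []
    targets: dict[str, pd.DataFrame] = dict(chip_peak_sets)
    for name, members in combined.items():
        targets[name] = pd.concat(
            [as_intervals(chip_peak_sets[m]) for m in members],
            ignore_index=True)
    for name, peaks in targets.items():
        if n == 0:
            rows.append({"class": name, "n_overlapping": 0,
                         "percent": float("nan"), "undefined": True})
            continue
        _, labels = window_intersect(as_intervals(dip_peaks),
                                     as_intervals(peaks), window=0)
        rows.append({"class": name, "n_overlapping": int(labels.sum()),
                     "percent": 100.0 * labels.sum() / n,
                     "undefined": False})
    return pd.DataFrame(rows)


def summit_signal_profile(summits: pd.DataFrame, track: CoverageTrack,
                          flank: int = 3000) -> ProfileMatrix:
    """Mean track value per bin in ±flank around peak summits (summits
    whose window leaves the track are skipped and counted)."""
    b = track.bin_size
    k = flank // b
    n_bins = 2 * k
    rows, skipped = [], 0
    for contig, pos in summits[["contig", summits.columns[1]]].itertuples(
            index=False, name=None):
        vec = track.bins.get(contig)
        if vec is None:
            skipped += 1
            continue
        center = int(pos) // b
        if center - k < 0 or center + k > len(vec):
            skipped += 1
            continue
        rows.append(vec[center - k:center + k])
    values = np.vstack(rows) if rows else np.zeros((0, n_bins))
    return ProfileMatrix(values, b, flank, n_skipped=skipped)


# ------------------------------------------------------------ strand symmetry

_PALINDROME = {"4mC": ("C", "G"), "6mA": ("A", "T")}


def strand_symmetry(calls: pd.DataFrame,
                    genome: AnnotatedGenome) -> pd.DataFrame:
    """Fraction of modified positions whose opposite-strand partner is also
    called.  Pairing is at the palindromic doublet (plus-strand site at p
    with minus-strand site at p+1 across CpG for 4mC, ApT for 6mA);
    non-palindromic contexts have no opposite-strand position of the right
    base identity, so they count as asymmetric.
    """
    rows = []
    for mark, grp in calls.groupby("mark", sort=True):
        center, nxt = _PALINDROME[mark]
        keys = set(zip(grp["contig"], grp["pos"], grp["strand"]))
        paired = 0
        for contig, pos, strand in keys:
            seq = genome.contigs[contig]
            if strand == "+":
                partner = (contig, pos + 1, "-")
                ok = pos + 1 < len(seq) and seq[pos] == center \
                    and seq[pos + 1] == nxt
            else:
                partner = (contig, pos - 1, "+")
                ok = pos - 1 >= 0 and seq[pos - 1] == center \
                    and seq[pos] == nxt
            if ok and partner in keys:
                paired += 1
        n = len(keys)
        rows.append({"mark": mark, "n_positions": n, "n_paired": paired,
                     "symmetric_fraction": paired / n if n else 0.0})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ CpG obs/exp

def cpg_obs_exp(sequence: str, window: int) -> pd.DataFrame:
    """Per-window observed/expected CpG ratio: (N_CpG * L) / (N_C * N_G).

    Windows with no C or no G report NaN with the ``undefined`` flag.
    The final partial window is kept.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    rows = []
    for start in range(0, len(sequence), window):
        chunk = sequence[start:start + window]
        L = len(chunk)
        n_c = chunk.count("C")
        n_g = chunk.count("G")
        n_cpg = chunk.count("CG")
        if n_c * n_g == 0:
            rows.append((start, start + L, n_cpg, n_c, n_g,
                         float("nan"), True))
        else:
            rows.append((start, start + L, n_cpg, n_c, n_g,
                         n_cpg * L / (n_c * n_g), False))
    return pd.DataFrame(rows, columns=["start", "end", "n_cpg", "n_c",
                                       "n_g", "obs_exp", "undefined"])


# ------------------------------------------------------------- expression

def rpkm(counts, exon_length_bp, total_mapped) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    exon_length_bp = np.asarray(exon_length_bp, dtype=float)
    if np.any(exon_length_bp <= 0):
        raise ValueError("exon length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    out = np.asarray(counts, dtype=float) / (exon_length_bp / 1000.0) \
        / (total_mapped / 1e6)
    return float(out) if out.ndim == 0 else out


def log2_rpkm(values, pseudocount: float = 1.0) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + pseudocount)


@dataclass
class GroupTestResult:
    test: str
    group_stats: pd.DataFrame
    statistic: float
    p_value: float
    tukey: Optional[pd.DataFrame] = None
    skipped_groups: list = field(default_factory=list)


def expression_group_tests(expr: pd.DataFrame, group_col: str,
                           value_col: str = "log2_rpkm",
                           kind: str = "auto") -> GroupTestResult:
    """Two-group Student's t-test (two-tailed) or one-way ANOVA with
    Tukey's post hoc on an expression table.

    ``kind='auto'`` picks the t-test for two groups and ANOVA otherwise.
    Groups with fewer than 2 members are skipped and flagged.
    """
    groups, skipped = {}, []
    for name, grp in expr.groupby(group_col, sort=True):
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            skipped.append(name)
        else:
            groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")
    stats_rows = [{"group": name, "n": len(v), "mean": float(v.mean()),
                   "sd": float(v.std(ddof=1))}
                  for name, v in groups.items()]
    gs = pd.DataFrame(stats_rows)
    if kind == "auto":
        kind = "ttest" if len(groups) == 2 else "anova"
    if kind == "ttest":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly two groups")
        a, b = groups.values()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return GroupTestResult("student_t_two_tailed", gs, float(t),
                               float(p), skipped_groups=skipped)
    f, p = stats.f_oneway(*groups.values())
    res = stats.tukey_hsd(*groups.values())
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "mean_diff": float(groups[names[i]].mean() -
                                            groups[names[j]].mean()),
                         "p_adj": float(res.pvalue[i, j])})
    return GroupTestResult("anova_tukey", gs, float(f), float(p),
                           tukey=pd.DataFrame(rows),
                           skipped_groups=skipped)
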