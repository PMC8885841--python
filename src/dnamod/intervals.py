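"""Small numpy interval layer (0-based half-open, per-contig).

Interval sets are DataFrames with columns contig, start, end.  All
operations self-merge their inputs first, so overlapping or bookended
records never double-count base pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["contig", "start", "end"]


def as_intervals(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj[INTERVAL_COLUMNS].copy()
    return pd.DataFrame(obj, columns=INTERVAL_COLUMNS)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per contig (bookended intervals are joined)."""
    parts = []
    for contig, grp in as_intervals(df).groupby("contig", sort=True):
        arr = grp[["start", "end"]].to_numpy()
        if np.any(arr[:, 0] >= arr[:, 1]):
            bad = arr[arr[:, 0] >= arr[:, 1]][0]
            raise ValueError(f"invalid interval [{bad[0]}, {bad[1]})")
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        # a new merged run starts where start exceeds the running max end
        run_end = np.maximum.accumulate(arr[:, 1])
        new_run = np.empty(len(arr), dtype=bool)
        new_run[0] = True
        new_run[1:] = arr[1:, 0] > run_end[:-1]
        starts = arr[new_run, 0]
        ends = np.maximum.reduceat(arr[:, 1], np.nonzero(new_run)[0])
        parts.append(pd.DataFrame({"contig": contig, "start": starts,
                                   "end": ends}))
    if not parts:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    return pd.concat(parts, ignore_index=True)[INTERVAL_COLUMNS]


def merge_arrays(starts: np.ndarray,
                 ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized union of (start, end) arrays on one contig."""
    if len(starts) == 0:
        return starts, ends
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    new = np.empty(len(s), dtype=bool)
    new[0] = True
    new[1:] = s[1:] > run_end[:-1]
    idx = np.nonzero(new)[0]
    return s[new], np.maximum.reduceat(e, idx)


def total_bp(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum()) if len(m) else 0


def intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    ma, mb = merge_intervals(a), merge_intervals(b)
    bp = 0
    for contig, ga in ma.groupby("contig"):
        gb = mb[mb["contig"] == contig]
        if len(gb) == 0:
            continue
        sa = ga["start"].to_numpy(); ea = ga["end"].to_numpy()
        sb = gb["start"].to_numpy(); eb = gb["end"].to_numpy()
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                bp += hi - lo
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return int(bp)


def jaccard_bp(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """|A n B| / |A u B| in base pairs after per-set self-merge.

    Returns NaN (the undefined flag) when both sets are empty.
    """
    la, lb = total_bp(a), total_bp(b)
    if la == 0 and lb == 0:
        return float("nan")
    inter = intersect_bp(a, b)
    union = la + lb - inter
    return inter / union


def _gap_distance(s1, e1, s2, e2) -> int:
    """Distance between two intervals; 0 when they overlap or touch."""
    if e1 <= s2:
        return int(s2 - e1)
    if e2 <= s1:
        return int(s1 - e2)
    return 0


def nearest_distances(query: pd.DataFrame,
                      reference: pd.DataFrame) -> np.ndarray:
    """Per-query distance to the nearest reference interval (same contig);
    inf when the contig has no reference features."""
    q = as_intervals(query)
    ref_by = {c: g[["start", "end"]].to_numpy()
              for c, g in merge_intervals(reference).groupby("contig")}
    out = np.full(len(q), np.inf)
    for idx, (contig, s, e) in enumerate(
            q.itertuples(index=False, name=None)):
        arr = ref_by.get(contig)
        if arr is None or len(arr) == 0:
            continue
        starts = arr[:, 0]
        j = int(np.searchsorted(starts, s))
        best = np.inf
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(arr):
                best = min(best, _gap_distance(s, e, arr[k, 0], arr[k, 1]))
        # overlap can involve an earlier long interval; scan left while
        # candidates can still beat the current best
        k = j - 2
        while k >= 0 and starts[k] > s - best:
            best = min(best, _gap_distance(s, e, arr[k, 0], arr[k, 1]))
            k -= 1
        out[idx] = best
    return out


def window_association(items: pd.DataFrame, features: pd.DataFrame,
                       window: int = 500) -> np.ndarray:
    """Boolean per-item label: within ``window`` bp of (or overlapping) any
    feature.  Overlap counts as distance 0."""
    if window < 0:
        raise ValueError("window must be >= 0")
    d = nearest_distances(items, features)
    return d <= window


def relocate_intervals(intervals: pd.DataFrame,
                       contig_lengths: dict[str, int],
                       rng: np.random.Generator) -> pd.DataFrame:
    """Randomly relocate intervals preserving lengths and contig
    assignment (for permutation nulls)."""
    df = as_intervals(intervals)
    lengths = (df["end"] - df["start"]).to_numpy()
    clen = df["contig"].map(contig_lengths).to_numpy()
    if np.any(lengths > clen):
        i = int(np.argmax(lengths > clen))
        raise ValueError(f"interval of {lengths[i]} bp exceeds contig "
                         f"{df['contig'].iloc[i]}")
    starts = (rng.random(len(df)) * (clen - lengths + 1)).astype(np.int64)
    out = df.copy()
    out["start"] = starts
    out["end"] = starts + lengths
    return out
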