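"""Kinetic modification calling: IPD ratios, Phred-scaled scores, filters,
and per-site methylation-fraction estimation.

A site's IPD ratio is mean(native IPD) / mean(control IPD).  The
modification quality score (mQv) is a Phred-scaled one-sided test that
native log-IPDs exceed the control: with an in-silico control (known
log-scale mean) a one-sample t-test, with sampled control observations a
one-sided Welch test; score = -10*log10(p).  The retained-call rule mirrors
standard SMRT methylome filtering: sites under 10x coverage are dropped,
calls require mQv >= 22, and primary calls additionally require 20x
coverage.  The mark is assigned from the reference base on the tested
strand (C -> 4mC, A -> 6mA; other bases are discarded).

Fractions are estimated by classifying each pass to the nearer of the
unmodified / modified log-IPD component means (the midpoint rule, optimal
for equal-variance log-normal components).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotatedGenome, KineticTable

SCORE_CAP = 120.0

CALL_COLUMNS = ["contig", "pos", "strand", "mark", "coverage", "ipd_ratio",
                "score", "fraction", "fraction_class", "primary"]


@dataclass
class CallFilter:
    """Coverage/score thresholds for retaining and calling sites."""

    min_coverage_retain: int = 10
    primary_min_coverage: int = 20
    min_score: float = 22.0
    fraction_min_coverage: int = 10

    def __post_init__(self) -> None:
        if self.primary_min_coverage < self.min_coverage_retain:
            raise ValueError(
                "primary_min_coverage must be >= min_coverage_retain")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")

    @property
    def alpha(self) -> float:
        """Per-site test level implied by the score threshold."""
        return 10.0 ** (-self.min_score / 10.0)


def compute_ipd_ratio(native_ipds, control) -> float:
    """mean(native) / mean(control); ``control`` may be observations or a
    linear-scale model mean."""
    native = np.asarray(native_ipds, dtype=float)
    if native.size == 0:
        raise ValueError("IPD ratio is undefined at a site with no passes")
    control_mean = (float(control) if np.isscalar(control)
                    else float(np.mean(control)))
    if control_mean <= 0:
        raise ValueError("control mean IPD must be > 0")
    return float(native.mean() / control_mean)


def score_site(native_ipds, control_ipds=None, *, control_log_mu=None,
               cap: float = SCORE_CAP) -> float:
    """Phred-scaled one-sided evidence that native log-IPDs exceed control.

    Exactly one of ``control_ipds`` (sampled observations, Welch test) or
    ``control_log_mu`` (in-silico control, one-sample t) must be given.
    """
    x = np.log(np.asarray(native_ipds, dtype=float))
    if x.size < 2:
        raise ValueError("scoring requires at least 2 native observations")
    if (control_ipds is None) == (control_log_mu is None):
        raise ValueError("supply control_ipds or control_log_mu, not both")
    if control_ipds is not None:
        y = np.log(np.asarray(control_ipds, dtype=float))
        if y.size < 2:
            raise ValueError("scoring requires >= 2 control observations")
        if np.var(x) == 0 and np.var(y) == 0:
            p = 1.0 if x.mean() <= y.mean() else 0.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False,
                                   alternative="greater")
            p = float(p)
    else:
        mu = float(control_log_mu)
        sd = x.std(ddof=1)
        if sd == 0.0:
            p = 1.0 if x.mean() <= mu else 0.0
        else:
            t = (x.mean() - mu) / (sd / math.sqrt(x.size))
            p = float(stats.t.sf(t, df=x.size - 1))
    if p <= 0.0:
        return cap
    return float(min(max(-10.0 * math.log10(p), 0.0), cap))


def estimate_fraction(native_ipds, unmodified_log_mu: float,
                      modified_log_mu: float) -> float:
    """Fraction of passes classified to the modified component (midpoint
    rule on log-IPDs)."""
    x = np.log(np.asarray(native_ipds, dtype=float))
    if x.size == 0:
        raise ValueError("fraction undefined at zero coverage")
    if modified_log_mu <= unmodified_log_mu:
        raise ValueError("modified component mean must exceed unmodified")
    threshold = 0.5 * (unmodified_log_mu + modified_log_mu)
    return float(np.mean(x > threshold))


FRACTION_CLASSES = ("sub_threshold", "low", "moderate", "high")


def classify_fraction(fraction):
    """Bin fractions: [0.1,0.5) low, [0.5,0.8) moderate, [0.8,1] high;
    below 0.1 is sub_threshold (excluded from the three classes)."""
    arr = np.asarray(fraction, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    out = np.full(arr.shape, "sub_threshold", dtype=object)
    out[(arr >= 0.1) & (arr < 0.5)] = "low"
    out[(arr >= 0.5) & (arr < 0.8)] = "moderate"
    out[arr >= 0.8] = "high"
    if np.isscalar(fraction) or arr.ndim == 0:
        return str(out.item() if arr.ndim == 0 else out[0])
    return out


def call_modifications(kinetics: KineticTable, genome: AnnotatedGenome,
                       call_filter: CallFilter | None = None, *,
                       modified_ipd_multiplier: float = 3.0,
                       keep_nonsignificant: bool = False) -> pd.DataFrame:
    """Call 4mC/6mA sites from a kinetic table.

    Returns a DataFrame with :data:`CALL_COLUMNS`, sorted by (contig, pos,
    strand).  The call list contains sites with coverage >= the retain
    threshold, score >= min_score and IPD ratio > 1; ``primary`` marks
    calls additionally meeting the 20x coverage rule.  With
    ``keep_nonsignificant`` every retained, base-compatible site is
    returned with an ``is_call`` column (useful for calibration).
    """
    f = call_filter or CallFilter()
    lens = genome.contig_lengths()
    log_shift = math.log(modified_ipd_multiplier)
    rows = []
    sites = kinetics.sites
    for i, (contig, pos, strand, coverage, mu, sigma) in enumerate(
            zip(sites["contig"], sites["pos"], sites["strand"],
                sites["coverage"], sites["control_log_mu"],
                sites["control_sigma"])):
        pos = int(pos)
        if contig not in lens or not (0 <= pos < lens[contig]):
            raise ValueError(f"site {contig}:{pos} outside the genome")
        if coverage < f.min_coverage_retain:
            continue
        base = genome.base_at(contig, pos, strand)
        if base == "C":
            mark = "4mC"
        elif base == "A":
            mark = "6mA"
        else:
            continue
        native = kinetics.native_ipds[i]
        control = kinetics.control_ipds[i]
        if control is not None:
            ratio = compute_ipd_ratio(native, control)
            score = score_site(native, control)
            unmod_mu = float(np.mean(np.log(control)))
        else:
            # in-silico control: linear mean of lognormal(mu, sigma)
            control_mean = math.exp(mu + 0.5 * sigma * sigma)
            ratio = compute_ipd_ratio(native, control_mean)
            score = score_site(native, control_log_mu=mu)
            unmod_mu = float(mu)
        if coverage >= f.fraction_min_coverage:
            fraction = estimate_fraction(native, unmod_mu,
                                         unmod_mu + log_shift)
        else:
            fraction = np.nan
        rows.append((contig, pos, strand, mark, int(coverage), ratio,
                     score, fraction))

    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "mark",
                                     "coverage", "ipd_ratio", "score",
                                     "fraction"])
    df["is_call"] = (df["score"] >= f.min_score) & (df["ipd_ratio"] > 1.0)
    df["primary"] = df["is_call"] & \
        (df["coverage"] >= f.primary_min_coverage)
    frac_class = np.full(len(df), "", dtype=object)
    ok = df["fraction"].notna().to_numpy()
    if ok.any():
        frac_class[ok] = classify_fraction(df.loc[ok, "fraction"].to_numpy())
    df["fraction_class"] = frac_class
    if not keep_nonsignificant:
        df = df[df["is_call"]].drop(columns=["is_call"])
        df = df[CALL_COLUMNS]
    df = df.sort_values(["contig", "pos", "strand"], kind="stable")
    return df.reset_index(drop=True)


def apply_filter(calls: pd.DataFrame,
                 call_filter: CallFilter | None = None) -> pd.DataFrame:
    """Re-apply the retain/score thresholds to an existing call table
    (idempotent on an already-filtered table)."""
    f = call_filter or CallFilter()
    keep = (calls["coverage"] >= f.min_coverage_retain) & \
        (calls["score"] >= f.min_score) & (calls["ipd_ratio"] > 1.0)
    out = calls[keep].copy()
    out["primary"] = out["coverage"] >= f.primary_min_coverage
    return out.reset_index(drop=True)


def fraction_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-mark fraction summary: mean fraction, class counts, high:low
    ratio (inf when no low sites) and percent fully methylated."""
    rows = []
    for mark, grp in calls.groupby("mark", sort=True):
        frac = grp["fraction"].dropna()
        if len(frac) == 0:
            continue
        classes = classify_fraction(frac.to_numpy())
        n_low = int(np.sum(classes == "low"))
        n_mod = int(np.sum(classes == "moderate"))
        n_high = int(np.sum(classes == "high"))
        n_sub = int(np.sum(classes == "sub_threshold"))
        high_low = (n_high / n_low) if n_low else math.inf
        rows.append({
            "mark": mark,
            "n_sites": int(len(frac)),
            "mean_fraction": float(frac.mean()),
            "n_sub_threshold": n_sub,
            "n_low": n_low,
            "n_moderate": n_mod,
            "n_high": n_high,
            "high_low_ratio": high_low,
            "percent_fully_methylated":
                float(100.0 * np.mean(frac.to_numpy() == 1.0)),
        })
    return pd.DataFrame(rows)
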