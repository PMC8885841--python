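"""Simulate per-site polymerase kinetics (inter-pulse durations).

Per-pass IPDs at an unmodified site are log-normal(mu=0, sigma); at a
modified site with fraction f each pass is modified independently with
probability f and its median IPD is multiplied by the configured
multiplier.  The table carries the planted sites plus a subsample of
unmodified background sites so the caller's false-positive behaviour is
observable.  The in-silico control is the known log-scale model (mu=0,
sigma); sampled control observations are optional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..core import AnnotatedGenome, KineticTable


def simulate_kinetics(genome: AnnotatedGenome, methylome: pd.DataFrame,
                      config: SimConfig) -> KineticTable:
    config.validate()
    kc = config.kinetics
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    lens = genome.contig_lengths()

    # site list: planted sites first, then background sites not in the truth
    planted = methylome[["contig", "pos", "strand"]].copy()
    planted["fraction"] = methylome["fraction"].to_numpy()
    taken = set(zip(methylome["contig"], methylome["pos"],
                    methylome["strand"]))
    bg_rows = []
    if kc.n_background_sites > 0 and lens:
        names = sorted(lens)
        lengths = np.array([lens[n] for n in names], dtype=float)
        probs = lengths / lengths.sum()
        # oversample, then drop collisions with planted sites
        n_draw = int(kc.n_background_sites * 1.2) + 10
        ci = rng.choice(len(names), size=n_draw, p=probs)
        for c in ci:
            contig = names[c]
            pos = int(rng.integers(lens[contig]))
            strand = "+" if rng.random() < 0.5 else "-"
            if (contig, pos, strand) in taken:
                continue
            taken.add((contig, pos, strand))
            bg_rows.append((contig, pos, strand, 0.0))
            if len(bg_rows) == kc.n_background_sites:
                break
    bg = pd.DataFrame(bg_rows, columns=["contig", "pos", "strand",
                                        "fraction"])
    parts = [p for p in (planted, bg) if len(p)]
    sites = pd.concat(parts, ignore_index=True) if parts else planted
    sites = sites.sort_values(["contig", "pos", "strand"],
                              kind="stable").reset_index(drop=True)

    log_mult = float(np.log(kc.ipd_multiplier))
    coverage = rng.poisson(kc.mean_passes, size=len(sites))
    native, control = [], []
    for cov, frac in zip(coverage, sites["fraction"].to_numpy()):
        if cov == 0:
            native.append(np.empty(0))
            control.append(None if kc.control_mode == "model"
                           else np.empty(0))
            continue
        mod = rng.random(cov) < frac
        logs = rng.normal(0.0, kc.sigma_log, size=cov)
        logs[mod] += log_mult
        native.append(np.exp(logs))
        if kc.control_mode == "sampled":
            control.append(np.exp(rng.normal(0.0, kc.sigma_log,
                                             size=kc.control_passes)))
        else:
            control.append(None)

    out = sites[["contig", "pos", "strand"]].copy()
    out["coverage"] = coverage
    out["control_log_mu"] = 0.0
    out["control_sigma"] = kc.sigma_log
    table = KineticTable(out.reset_index(drop=True), native, control)
    # sites with zero passes are unobserved and never enter the table
    keep = out["coverage"].to_numpy() > 0
    if not keep.all():
        table = KineticTable(
            out[keep].reset_index(drop=True),
            [a for a, k in zip(native, keep) if k],
            [c for c, k in zip(control, keep) if k])
    return table
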