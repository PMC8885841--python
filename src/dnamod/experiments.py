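"""Reproducible study-condition experiments.

Each function sets up a defined synthetic condition (a configuration of
the simulator), runs the relevant pipeline stages, and measures a summary
quantity: caller calibration and recovery, fraction-estimation accuracy,
peak/summit recovery and null false-positive behaviour, spatial-correlation
calibration and power, the direction-level findings (densities, integrity
stratification, chromatin context of DIP summits, expression grouping,
context doublets) and end-to-end determinism.  The acceptance script and
the acceptance tests both drive these functions.

Seeds passed in are mixed with fixed stream labels, so every experiment is
reproducible from a single integer.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, enrich, modcall, motifs
from .config import (ChipConfig, DipConfig, KineticsConfig, RnaseqConfig,
                     SimConfig, TandemRepeatConfig, TEFamilyConfig)
from .core import empty_methylome
from .intervals import as_intervals
from .sim import (methylation_clusters, plant_methylome, simulate_chipseq,
                  simulate_dipseq, simulate_genome, simulate_kinetics,
                  simulate_rnaseq)


def _mix(seed: int, label: int) -> int:
    return int(np.random.SeedSequence([seed, label]).generate_state(1)[0]
               % (2 ** 31))


# ------------------------------------------------------- caller calibration

def null_calibration(seed: int, n_sites: int = 25000) -> dict:
    """Type-I behaviour of the caller on null kinetics (multiplier 1.0)."""
    cfg = SimConfig(seed=_mix(seed, 1))
    cfg.meth_4mC.site_rate = 0.0
    cfg.meth_6mA.site_rate = 0.0
    cfg.kinetics = KineticsConfig(ipd_multiplier=1.0,
                                  n_background_sites=n_sites)
    genome = simulate_genome(cfg)
    kin = simulate_kinetics(genome, empty_methylome(), cfg)
    tested = modcall.call_modifications(kin, genome,
                                        keep_nonsignificant=True)
    rate = float(tested["is_call"].mean())
    alpha = 10.0 ** -2.2
    bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / len(tested))
    return {"null_call_rate": rate, "n_tested": int(len(tested)),
            "alpha": alpha, "bound": bound, "pass": rate <= bound}


def caller_recovery(seed: int) -> dict:
    """Recall/precision of the caller against the planted truth on the
    default 200-kb simulation (multiplier 3, sigma 0.4, 25x passes,
    fully-methylated planting)."""
    cfg = SimConfig(seed=_mix(seed, 2))
    cfg.meth_4mC.fully_methylated_prob = 1.0
    cfg.meth_6mA.fully_methylated_prob = 1.0
    cfg.meth_6mA.fraction_beta = (50.0, 1e-9)  # degenerate at ~1
    genome = simulate_genome(cfg)
    meth = plant_methylome(genome, cfg)
    meth["fraction"] = 1.0
    kin = simulate_kinetics(genome, meth, cfg)
    calls = modcall.call_modifications(kin, genome)
    truth = set(zip(meth["contig"], meth["pos"], meth["strand"]))
    called = set(zip(calls["contig"], calls["pos"], calls["strand"]))
    tp = len(truth & called)
    return {"recall": tp / len(truth), "precision": tp / len(called),
            "n_truth": len(truth), "n_called": len(called)}


# -------------------------------------------------------- fraction recovery

def fraction_recovery(seed: int, n_per_level: int = 1000,
                      coverage: float = 50.0) -> dict:
    """Accuracy of per-site fraction estimates at planted levels
    {0.25, 0.5, 0.75, 1.0} at ~50x coverage."""
    levels = (0.25, 0.5, 0.75, 1.0)
    cfg = SimConfig(seed=_mix(seed, 3), genome_length=400000, n_contigs=1,
                    n_genes=0, te_families=[],
                    tandem_repeats=TandemRepeatConfig(n_arrays=0))
    cfg.gene_structure.te_gene_fraction = 0.0
    cfg.kinetics = KineticsConfig(mean_passes=coverage,
                                  n_background_sites=0)
    genome = simulate_genome(cfg)
    seq = genome.contigs["contig_1"]
    c_pos = np.array([i for i, b in enumerate(seq) if b == "C"])
    rng = np.random.default_rng(_mix(seed, 4))
    need = n_per_level * len(levels)
    pos = rng.choice(c_pos, size=need, replace=False)
    meth = pd.DataFrame({
        "contig": "contig_1", "pos": np.sort(pos), "strand": "+",
        "mark": "4mC",
        "fraction": rng.permutation(np.repeat(levels, n_per_level))})
    kin = simulate_kinetics(genome, meth, cfg)
    calls = modcall.call_modifications(kin, genome, keep_nonsignificant=True)
    merged = calls.merge(meth, on=["contig", "pos", "strand"],
                         suffixes=("", "_true"))
    merged = merged.dropna(subset=["fraction"])
    out: dict = {"per_level": {}}
    agree_total = n_total = 0
    for f in levels:
        sub = merged[merged["fraction_true"] == f]
        mae = float(np.mean(np.abs(sub["fraction"] - f)))
        true_class = modcall.classify_fraction(f)
        est_class = modcall.classify_fraction(sub["fraction"].to_numpy())
        agree = int(np.sum(est_class == true_class))
        agree_total += agree
        n_total += len(sub)
        out["per_level"][f] = {"mae": mae, "n": int(len(sub)),
                               "class_agreement": agree / len(sub)}
    out["max_mae"] = max(v["mae"] for v in out["per_level"].values())
    out["class_agreement"] = agree_total / n_total
    return out


# ------------------------------------------------------------ peak recovery

def peak_recovery_config(seed: int) -> SimConfig:
    """Compact-cluster DIP condition: fully-methylated 4mC confined to
    point-like clusters at TE 5' ends (decay 50 bp), 10x capture."""
    cfg = SimConfig(seed=seed)
    cfg.meth_4mC.target_feature_classes = ("te_full", "te_medium")
    cfg.meth_4mC.te_5prime_decay_bp = 50.0
    cfg.meth_4mC.fully_methylated_prob = 1.0
    cfg.meth_6mA.site_rate = 0.0
    cfg.dip = DipConfig(capture_enrichment=10.0)
    return cfg


def peak_recovery(seed: int, n_replicates: int = 3) -> dict:
    """Planted-cluster recovery and summit localization of the DIP peak
    caller, plus the null per-bin false-positive count."""
    n_clusters = n_recovered = n_summits = n_close = 0
    for rep in range(n_replicates):
        cfg = peak_recovery_config(_mix(seed, 50 + rep))
        genome = simulate_genome(cfg)
        meth = plant_methylome(genome, cfg)
        reads = simulate_dipseq(genome, meth, cfg)
        peaks = enrich.peaks_to_frame(enrich.call_peaks(
            reads["dip4mC"], genome, read_extension=cfg.dip.read_length))
        clusters = methylation_clusters(meth, gap=300, mark="4mC")
        clusters = clusters[clusters["n_sites"] >= 3]
        n_clusters += len(clusters)
        for row in clusters.itertuples():
            hit = peaks[(peaks["contig"] == row.contig) &
                        (peaks["end"] > row.start - 200) &
                        (peaks["start"] < row.end + 200)]
            if len(hit):
                n_recovered += 1
        for p in peaks.itertuples():
            cc = clusters[clusters["contig"] == p.contig]
            if len(cc):
                n_summits += 1
                if (cc["center"] - p.summit).abs().min() <= 100:
                    n_close += 1

    # null condition: capture odds equal to background
    cfg = peak_recovery_config(_mix(seed, 60))
    cfg.dip.capture_enrichment = 0.0
    genome = simulate_genome(cfg)
    meth = plant_methylome(genome, cfg)
    reads = simulate_dipseq(genome, meth, cfg)
    counts, pvals = enrich.bin_pvalues(reads["dip4mC"], genome,
                                       bin_size=10,
                                       read_extension=cfg.dip.read_length)
    n_bins = sum(len(v) for v in pvals.values())
    n_sig = int(sum((v < 1e-5).sum() for v in pvals.values()))
    expected = 1e-5 * n_bins
    null_bound = expected + 3 * math.sqrt(expected)
    return {"cluster_recovery": n_recovered / n_clusters,
            "summit_within_100bp": n_close / n_summits,
            "n_clusters": n_clusters, "n_summits": n_summits,
            "null_significant_bins": n_sig, "null_n_bins": n_bins,
            "null_bound": null_bound}


# ------------------------------------------------------ interval oracles

def _brute_bin_coverage(rows, length, bin_size, ext):
    perbp = np.zeros(length)
    for _, s, e, strand in rows:
        if strand == "+":
            lo, hi = s, min(s + ext, length)
        else:
            lo, hi = max(e - ext, 0), e
        perbp[lo:hi] += 1
    n_bins = -(-length // bin_size)
    out = np.zeros(n_bins)
    for b in range(n_bins):
        out[b] = perbp[b * bin_size:(b + 1) * bin_size].sum() / bin_size
    return out


def _brute_jaccard(a, b):
    def cover(df):
        s = set()
        for contig, lo, hi in df.itertuples(index=False):
            s.update((contig, p) for p in range(lo, hi))
        return s
    A, B = cover(a), cover(b)
    if not A and not B:
        return float("nan")
    return len(A & B) / len(A | B)


def _brute_window(items, feats, window):
    out = []
    for _, it in items.iterrows():
        hit = False
        for _, f in feats.iterrows():
            if it["contig"] != f["contig"]:
                continue
            if it["end"] <= f["start"]:
                d = f["start"] - it["end"]
            elif f["end"] <= it["start"]:
                d = it["start"] - f["end"]
            else:
                d = 0
            if d <= window:
                hit = True
        out.append(hit)
    return np.array(out)


def _brute_occupancy(sites, feats, flank, bin_size):
    n_bins = 2 * flank // bin_size
    out = np.zeros((len(feats), n_bins))
    for fi, (_, f) in enumerate(feats.iterrows()):
        a = f["start"] if f["strand"] == "+" else f["end"] - 1
        for _, s in sites.iterrows():
            if s["contig"] != f["contig"]:
                continue
            off = s["pos"] - a
            if f["strand"] == "-":
                off = -off
            if -flank <= off < flank:
                out[fi, (off + flank) // bin_size] += 1
    return out


def interval_oracles(seed: int, n_instances: int = 100) -> dict:
    """Exact agreement of the interval primitives with per-bp / all-pairs
    brute-force oracles on random instances (<= 50 kb)."""
    from .core import AnnotatedGenome, ReadSet
    from .intervals import jaccard_bp, window_association
    rng = np.random.default_rng(_mix(seed, 5))
    mism = {"bin_coverage": 0, "jaccard": 0, "window_intersect": 0,
            "occupancy_profile": 0}
    for _ in range(n_instances):
        length = int(rng.integers(2000, 8000))
        genome = AnnotatedGenome({"c1": "A" * length}, [], [], [])
        n_reads = int(rng.integers(1, 80))
        starts = rng.integers(0, length - 60, n_reads)
        rows = [("c1", int(s), int(s) + 50,
                 "+" if rng.random() < 0.5 else "-") for s in starts]
        reads = ReadSet("x", pd.DataFrame(
            rows, columns=["contig", "start", "end", "strand"]))
        ext = int(rng.integers(50, 200))
        bsz = int(rng.choice([10, 25, 50]))
        track = enrich.bin_coverage(reads, genome, bsz, ext)
        if not np.allclose(track.bins["c1"],
                           _brute_bin_coverage(rows, length, bsz, ext)):
            mism["bin_coverage"] += 1

        def rand_iv(n, maxlen):
            s = rng.integers(0, length - maxlen, n)
            l = rng.integers(1, maxlen, n)
            return pd.DataFrame({"contig": "c1", "start": s,
                                 "end": s + l})
        a, b = rand_iv(int(rng.integers(0, 15)) + 1, 300), \
            rand_iv(int(rng.integers(0, 15)) + 1, 300)
        got = jaccard_bp(a, b)
        want = _brute_jaccard(a, b)
        if not (math.isnan(got) and math.isnan(want)) and \
                abs(got - want) > 1e-12:
            mism["jaccard"] += 1

        items = rand_iv(20, 200)
        feats = rand_iv(8, 300)
        w = int(rng.integers(0, 500))
        if not (window_association(items, feats, w) ==
                _brute_window(items, feats, w)).all():
            mism["window_intersect"] += 1

        sites = pd.DataFrame({"contig": "c1",
                              "pos": rng.integers(0, length, 60)})
        fdf = rand_iv(4, 400)
        fdf["strand"] = np.where(rng.random(4) < 0.5, "+", "-")
        pm = assoc.occupancy_profile(sites, fdf, flank=500, bin_size=25)
        if not np.array_equal(pm.values,
                              _brute_occupancy(sites, fdf, 500, 25)):
            mism["occupancy_profile"] += 1
    mism["total_mismatches"] = int(sum(mism.values()))
    mism["n_instances"] = n_instances
    return mism


# ------------------------------------------------- spatial correlation

def spatial_power_and_calibration(seed: int, n_runs: int = 50) -> dict:
    """Power on a TE-planted query (999 permutations) and calibration on
    uniformly relocated queries (rate of p > 0.05 over seeded runs)."""
    cfg = SimConfig(seed=_mix(seed, 6))
    cfg.meth_6mA.site_rate = 0.0
    genome = simulate_genome(cfg)
    meth = plant_methylome(genome, cfg)
    te_iv = pd.DataFrame([(t.contig, t.start, t.end)
                          for t in genome.te_copies],
                         columns=["contig", "start", "end"])
    m4 = meth[meth["mark"] == "4mC"]
    query = pd.DataFrame({"contig": m4["contig"], "start": m4["pos"],
                          "end": m4["pos"] + 1}).head(300)
    power = assoc.permutation_spatial_test(
        query, te_iv, genome, "jaccard", n_permutations=999,
        seed=_mix(seed, 7))
    rng = np.random.default_rng(_mix(seed, 8))
    lens = genome.contig_lengths()
    n_ok = 0
    for run in range(n_runs):
        from .intervals import relocate_intervals
        uq = relocate_intervals(query, lens, rng)
        r = assoc.permutation_spatial_test(
            uq, te_iv, genome, "jaccard", n_permutations=199,
            seed=_mix(seed, 100 + run))
        if r.p_value > 0.05:
            n_ok += 1
    return {"te_query_p": power.p_value,
            "te_query_jaccard": power.observed,
            "uniform_p_gt_005_rate": n_ok / n_runs,
            "n_runs": n_runs}


# ----------------------------------------------------- direction checks

def direction_checks(seed: int) -> dict:
    """Direction-level reproduction of the headline findings on the
    default simulation: 4mC density TE > genes, integrity ordering,
    heterochromatic context of 4mC DIP summits, and CpG/CpA doublets."""
    cfg = SimConfig(seed=_mix(seed, 9))
    genome = simulate_genome(cfg)
    meth = plant_methylome(genome, cfg)
    kin = simulate_kinetics(genome, meth, cfg)
    calls = modcall.call_modifications(kin, genome)
    out: dict = {}

    dens = assoc.density_table(calls, genome).set_index(
        ["mark", "feature_class"])
    out["density_4mC_TE"] = float(
        dens.loc[("4mC", "TE"), "normalized_density"])
    out["density_4mC_genes"] = float(
        dens.loc[("4mC", "genes"), "normalized_density"])
    out["density_ratio_te_genes"] = \
        out["density_4mC_TE"] / max(out["density_4mC_genes"], 1e-12)

    integ = assoc.density_by_integrity(
        calls[calls["mark"] == "4mC"], genome.te_copies).set_index(
        "integrity_class")
    out["integrity_mean_full"] = float(integ.loc["full", "mean_count"])
    out["integrity_mean_medium"] = float(integ.loc["medium", "mean_count"])
    out["integrity_mean_short"] = float(integ.loc["short", "mean_count"])

    dip = simulate_dipseq(genome, meth, cfg)
    chip = simulate_chipseq(genome, cfg)
    peaks4 = enrich.peaks_to_frame(enrich.call_peaks(
        dip["dip4mC"], genome, read_extension=cfg.dip.read_length))
    input_track = enrich.normalize_rpgc(enrich.bin_coverage(
        chip["chip_input"], genome, 10, cfg.chip.read_length))
    centers = {}
    for mark in ("H3K4me3", "H3K9me3", "H3K27me3"):
        ip = enrich.normalize_rpgc(enrich.bin_coverage(
            chip[mark], genome, 10, cfg.chip.read_length))
        track = enrich.log2_ratio(ip, input_track)
        pm = assoc.summit_signal_profile(
            peaks4[["contig", "summit"]], track, flank=3000)
        prof = pm.profile()
        mid = len(prof) // 2
        centers[mark] = float(np.mean(prof[mid - 5:mid + 5]))
    out["summit_log2_H3K4me3"] = centers["H3K4me3"]
    out["summit_log2_H3K9me3"] = centers["H3K9me3"]
    out["summit_log2_H3K27me3"] = centers["H3K27me3"]

    m4 = calls[calls["mark"] == "4mC"]
    windows = motifs.extract_context(m4, genome, flank=5,
                                     expect_mark="4mC")
    doublets = motifs.doublet_triplet_stats(windows)["doublet"]
    out["top_doublets"] = list(doublets.index[:2])
    out["doublet_cg_ca_share"] = float(
        doublets.get("CG", 0.0) + doublets.get("CA", 0.0))
    bg = motifs.sample_background_windows(genome, "C", 5,
                                          n=5 * len(windows),
                                          seed=_mix(seed, 10))
    enr = motifs.kmer_enrichment(windows, bg, k_range=(2,))
    out["cg_kmer_q"] = float(
        enr.set_index("kmer").loc["CG", "q_value"])
    return out


def expression_study_config(seed: int) -> SimConfig:
    """Expression-grouping condition: ~800 genes (half TE-derived carrying
    an intact TE insertion methylated with probability 0.5), sparse
    genome-wide 6mA so that roughly half the genes carry a mark within
    the +-500 bp association window."""
    cfg = SimConfig(
        seed=seed, genome_length=2500000, n_contigs=4, n_genes=800,
        te_families=[TEFamilyConfig("Gypsy", 2000, 0, 0, 0)],
        tandem_repeats=TandemRepeatConfig(n_arrays=0),
        rnaseq=RnaseqConfig(library_size=300000),
    )
    cfg.gene_structure.te_gene_fraction = 0.5
    cfg.gene_structure.te_gene_insert_length = 2000
    cfg.meth_4mC.copy_methylation_prob = 0.5
    cfg.meth_4mC.target_feature_classes = ("te_full", "te_medium")
    cfg.meth_6mA.site_rate = 3.8e-4
    cfg.kinetics.n_background_sites = 0
    return cfg


def expression_direction(seed: int) -> dict:
    """Two-tailed t-tests on log2 RPKM: 4mC-marked TE genes vs unmarked TE
    genes, and 6mA-marked vs unmarked (non-TE) genes."""
    cfg = expression_study_config(_mix(seed, 11))
    genome = simulate_genome(cfg)
    meth = plant_methylome(genome, cfg)
    _, truth = simulate_rnaseq(genome, meth, cfg)
    truth["rpkm"] = assoc.rpkm(truth["counts"], truth["exonic_length"],
                               int(truth["counts"].sum()))
    truth["log2_rpkm"] = assoc.log2_rpkm(truth["rpkm"])
    out = {}
    te = truth[truth["te_gene"]]
    r4 = assoc.expression_group_tests(te, "has_4mC")
    gs4 = r4.group_stats.set_index("group")
    out["t4_p"] = r4.p_value
    out["t4_group_n"] = {str(k): int(v)
                         for k, v in gs4["n"].items()}
    out["mean_log2rpkm_4mC"] = float(gs4.loc[True, "mean"])
    out["mean_log2rpkm_no4mC"] = float(gs4.loc[False, "mean"])
    nonte = truth[~truth["te_gene"]]
    r6 = assoc.expression_group_tests(nonte, "has_6mA")
    gs6 = r6.group_stats.set_index("group")
    out["t6_p"] = r6.p_value
    out["t6_group_n"] = {str(k): int(v)
                         for k, v in gs6["n"].items()}
    out["mean_log2rpkm_6mA"] = float(gs6.loc[True, "mean"])
    out["mean_log2rpkm_no6mA"] = float(gs6.loc[False, "mean"])
    return out


# ----------------------------------------------------------- determinism

def determinism_check(seed: int, workdir) -> dict:
    """Full pipeline run twice with one seed: byte-identical reports."""
    from .pipeline import RunConfig, run_pipeline
    workdir = Path(workdir)
    cfg_kw = dict(
        genome_length=80000, n_contigs=2, n_genes=12,
        te_families=[TEFamilyConfig("Gypsy", 2000, 2, 2, 6)],
        tandem_repeats=TandemRepeatConfig(n_arrays=2),
        kinetics=KineticsConfig(n_background_sites=3000),
        dip=DipConfig(library_size=15000),
        chip=ChipConfig(library_size=15000),
        rnaseq=RnaseqConfig(library_size=40000),
    )
    reports = []
    for tag in ("a", "b"):
        cfg = RunConfig(sim=SimConfig(seed=_mix(seed, 12), **cfg_kw),
                        outdir=str(workdir / tag))
        run_pipeline(cfg)
        reports.append((workdir / tag / "report.json").read_bytes())
    return {"identical_reports": reports[0] == reports[1]}
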