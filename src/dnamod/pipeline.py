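"""Pipeline orchestration: simulate -> call -> peaks -> associate -> motifs.

``run_pipeline`` executes the enabled stages in dependency order from one
:class:`RunConfig`, writes every artifact under the output directory and
returns a machine-readable report (parameter echo, per-file checksums and
summary statistics).  All randomness derives from the config seed, so a
rerun with the same config reproduces byte-identical artifacts and report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assoc, enrich, io, modcall, motifs
from .config import SimConfig, config_to_dict, save_config
from .core import AnnotatedGenome
from .sim import (CHIP_MARKS, methylation_clusters, plant_methylome,
                  simulate_chipseq, simulate_dipseq, simulate_genome,
                  simulate_kinetics, simulate_rnaseq)

log = logging.getLogger("dnamod.pipeline")

ALL_STAGES = ("simulate", "callmods", "peaks", "associate", "motifs")


class StageDependencyError(RuntimeError):
    """An enabled stage is missing an upstream artifact."""


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "dnamod_run"
    stages: tuple[str, ...] = ALL_STAGES
    bin_size: int = 10
    peak_p_threshold: float = 1e-5
    peak_min_gap: int = 300
    peak_min_width: int = 150
    association_window: int = 500
    n_permutations: int = 199
    kmer_k_range: tuple[int, ...] = (2, 3)
    motif_flank: int = 10
    make_plots: bool = False

    def validate(self) -> None:
        self.sim.validate()
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.peak_p_threshold < 1):
            raise ValueError("peak_p_threshold must be in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else str(v)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the run report (also written to
    ``<outdir>/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]
    report: dict = {
        "software": {"name": "dnamod", "version": __version__},
        "parameters": {
            "seed": config.sim.seed,
            "stages": stages,
            "bin_size": config.bin_size,
            "peak_p_threshold": config.peak_p_threshold,
            "peak_min_gap": config.peak_min_gap,
            "peak_min_width": config.peak_min_width,
            "association_window": config.association_window,
            "n_permutations": config.n_permutations,
            "sim": config_to_dict(config.sim),
        },
        "stages": {},
        "checksums": {},
        "summary": {},
    }
    artifacts: dict[str, Path] = {}

    def emit(name: str, path: Path) -> Path:
        artifacts[name] = path
        return path

    state: dict = {}

    if "simulate" in stages:
        log.info("stage simulate: genome %d bp, seed %d",
                 config.sim.genome_length, config.sim.seed)
        genome = simulate_genome(config.sim)
        methylome = plant_methylome(genome, config.sim)
        kinetics = simulate_kinetics(genome, methylome, config.sim)
        dip = simulate_dipseq(genome, methylome, config.sim)
        chip = simulate_chipseq(genome, config.sim)
        rna, expr_truth = simulate_rnaseq(genome, methylome, config.sim)
        state.update(genome=genome, methylome=methylome, kinetics=kinetics,
                     dip=dip, chip=chip, rna=rna, expr_truth=expr_truth)
        io.write_fasta(genome, emit("genome_fasta", outdir / "genome.fasta"))
        io.write_annotations_gff3(
            genome, emit("annotations_gff3", outdir / "annotations.gff3"))
        io.write_methylome_tsv(
            methylome, emit("methylome_tsv", outdir / "methylome.tsv"))
        io.write_kinetics_tsv(
            kinetics, emit("kinetics_tsv", outdir / "kinetics.tsv"))
        for assay, rs in {**dip, **chip, "rnaseq": rna}.items():
            io.write_reads_bed(rs, emit(f"reads_{assay}",
                                        outdir / f"reads_{assay}.bed"))
        expr_truth.to_csv(
            emit("expression_truth", outdir / "expression_truth.tsv"),
            sep="\t", index=False, float_format="%.6g")
        save_config(config.sim, emit("config_yaml", outdir / "config.yaml"))
        report["stages"]["simulate"] = {
            "n_genes": len(genome.genes),
            "n_te_copies": len(genome.te_copies),
            "n_tandem_repeats": len(genome.tandem_repeats),
            "n_methylome_records": int(len(methylome)),
            "n_kinetic_sites": len(kinetics),
            "reads_per_assay": {a: rs.total_reads
                                for a, rs in {**dip, **chip,
                                              "rnaseq": rna}.items()},
        }

    if "callmods" in stages:
        _require(state, ("genome", "kinetics"), "callmods", "simulate")
        log.info("stage callmods: %d kinetic sites", len(state["kinetics"]))
        calls = modcall.call_modifications(
            state["kinetics"], state["genome"],
            modified_ipd_multiplier=config.sim.kinetics.ipd_multiplier)
        state["calls"] = calls
        io.write_calls_tsv(calls, emit("calls_tsv", outdir / "calls.tsv"))
        io.write_calls_gff3(calls, emit("calls_gff3", outdir / "calls.gff3"))
        summary = modcall.fraction_summary(calls)
        summary.to_csv(emit("fraction_summary",
                            outdir / "fraction_summary.tsv"),
                       sep="\t", index=False, float_format="%.6g")
        report["stages"]["callmods"] = {
            "n_calls": int(len(calls)),
            "calls_per_mark": {str(k): int(v) for k, v in
                               calls["mark"].value_counts().items()},
            "n_primary": int(calls["primary"].sum()),
            "fraction_summary": _jsonable(
                summary.to_dict(orient="records")),
        }

    if "peaks" in stages:
        _require(state, ("genome", "dip", "chip"), "peaks", "simulate")
        log.info("stage peaks: p < %g", config.peak_p_threshold)
        genome = state["genome"]
        peak_sets: dict[str, pd.DataFrame] = {}
        for assay in ("dip4mC", "dip6mA") + CHIP_MARKS:
            rs = state["dip"].get(assay) or state["chip"].get(assay)
            ext = (config.sim.dip.read_length if assay.startswith("dip")
                   else config.sim.chip.read_length)
            peaks = enrich.call_peaks(
                rs, genome, bin_size=config.bin_size, read_extension=ext,
                p_threshold=config.peak_p_threshold,
                min_gap=config.peak_min_gap,
                min_width=config.peak_min_width)
            pdf = enrich.peaks_to_frame(peaks)
            peak_sets[assay] = pdf
            io.write_peaks_narrowpeak(
                pdf, emit(f"peaks_{assay}",
                          outdir / f"peaks_{assay}.narrowPeak"),
                name_prefix=assay)
        state["peak_sets"] = peak_sets
        # RPGC + log2-ratio tracks for the ChIP marks (vs chip input)
        tracks: dict[str, enrich.CoverageTrack] = {}
        input_track = enrich.normalize_rpgc(enrich.bin_coverage(
            state["chip"]["chip_input"], genome, config.bin_size,
            config.sim.chip.read_length))
        for mark in CHIP_MARKS:
            ip = enrich.normalize_rpgc(enrich.bin_coverage(
                state["chip"][mark], genome, config.bin_size,
                config.sim.chip.read_length))
            tracks[mark] = enrich.log2_ratio(ip, input_track)
            io.write_bedgraph(tracks[mark],
                              emit(f"log2ratio_{mark}",
                                   outdir / f"log2ratio_{mark}.bedGraph"))
        state["log2_tracks"] = tracks
        report["stages"]["peaks"] = {
            "peak_counts": {a: int(len(p)) for a, p in peak_sets.items()},
        }

    if "associate" in stages:
        _require(state, ("genome", "methylome", "calls", "peak_sets",
                         "log2_tracks", "expr_truth"),
                 "associate", "simulate/callmods/peaks")
        log.info("stage associate")
        report["stages"]["associate"] = _associate_stage(
            state, config, outdir, emit)

    if "motifs" in stages:
        _require(state, ("genome", "calls"), "motifs", "simulate/callmods")
        log.info("stage motifs")
        report["stages"]["motifs"] = _motifs_stage(state, config, outdir,
                                                   emit)

    if config.make_plots:
        _make_plots(state, outdir)

    report["summary"] = _overall_summary(report)
    report["checksums"] = {name: _sha256(path)
                           for name, path in sorted(artifacts.items())}
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2,
                                      sort_keys=True) + "\n")
    return report


def _require(state, keys, stage, upstream):
    missing = [k for k in keys if k not in state]
    if missing:
        raise StageDependencyError(
            f"stage '{stage}' requires upstream stage(s) '{upstream}' "
            f"(missing: {', '.join(missing)})")


def _associate_stage(state, config, outdir: Path, emit) -> dict:
    genome: AnnotatedGenome = state["genome"]
    calls: pd.DataFrame = state["calls"]
    peak_sets = state["peak_sets"]
    out: dict = {}

    dens = assoc.density_table(calls, genome)
    dens.to_csv(emit("density_table", outdir / "density_table.tsv"),
                sep="\t", index=False, float_format="%.6g")
    out["density_table"] = _jsonable(dens.to_dict(orient="records"))

    integ = assoc.density_by_integrity(calls[calls["mark"] == "4mC"],
                                       genome.te_copies)
    integ.to_csv(emit("integrity_table", outdir / "integrity_table.tsv"),
                 sep="\t", index=False, float_format="%.6g")
    out["integrity_table_4mC"] = _jsonable(integ.to_dict(orient="records"))

    sym = assoc.strand_symmetry(calls, genome)
    sym.to_csv(emit("strand_symmetry", outdir / "strand_symmetry.tsv"),
               sep="\t", index=False, float_format="%.6g")
    out["strand_symmetry"] = _jsonable(sym.to_dict(orient="records"))

    # DIP peak summit log2-ratio profiles against each ChIP mark
    profiles = {}
    for assay in ("dip4mC", "dip6mA"):
        summits = peak_sets[assay][["contig", "summit"]]
        for mark, track in state["log2_tracks"].items():
            pm = assoc.summit_signal_profile(summits, track, flank=3000)
            profiles[f"{assay}_vs_{mark}"] = pm
    prof_rows = []
    for name, pm in profiles.items():
        prof = pm.profile()
        prof_rows.append({
            "profile": name, "n_summits": pm.n_features,
            "center_mean": float(np.mean(
                prof[len(prof) // 2 - 5:len(prof) // 2 + 5]))
            if pm.n_features else float("nan"),
        })
        pd.DataFrame({"bin": np.arange(len(prof)), "value": prof}).to_csv(
            emit(f"summit_profile_{name}",
                 outdir / f"summit_profile_{name}.tsv"),
            sep="\t", index=False, float_format="%.6g")
    out["summit_profiles"] = _jsonable(prof_rows)

    # spatial correlation of 4mC calls vs TE annotations
    te_iv = pd.DataFrame([(t.contig, t.start, t.end)
                          for t in genome.te_copies],
                         columns=["contig", "start", "end"])
    m4 = calls[calls["mark"] == "4mC"]
    if len(m4) and len(te_iv):
        q = pd.DataFrame({"contig": m4["contig"], "start": m4["pos"],
                          "end": m4["pos"] + 1})
        sc = assoc.permutation_spatial_test(
            q, te_iv, genome, statistic="jaccard",
            n_permutations=config.n_permutations, seed=config.sim.seed)
        out["spatial_4mC_vs_TE"] = {"observed_jaccard": sc.observed,
                                    "p_value": sc.p_value,
                                    "n_permutations": sc.n_permutations}

    # DIP x ChIP co-localization
    coloc_rows = []
    for assay in ("dip4mC", "dip6mA"):
        cf = assoc.colocalization_fractions(
            peak_sets[assay],
            {m: peak_sets[m] for m in CHIP_MARKS},
            combined={"H3K9me3+H3K27me3": ("H3K9me3", "H3K27me3")})
        cf.insert(0, "dip_assay", assay)
        coloc_rows.append(cf)
    coloc = pd.concat(coloc_rows, ignore_index=True)
    coloc.to_csv(emit("colocalization", outdir / "colocalization.tsv"),
                 sep="\t", index=False, float_format="%.6g")
    out["colocalization"] = _jsonable(coloc.to_dict(orient="records"))

    # expression grouping
    expr = state["expr_truth"].copy()
    total = int(expr["counts"].sum())
    tests = {}
    if total > 0:
        expr["rpkm"] = assoc.rpkm(expr["counts"], expr["exonic_length"],
                                  total)
        expr["log2_rpkm"] = assoc.log2_rpkm(expr["rpkm"])
        # peak-proximity grouping: genes with/without a 6mA DIP peak
        # within the association window (the operational definition used
        # alongside the truth-table site grouping)
        gene_spans = pd.DataFrame(
            [(g.name, g.contig, g.start, g.end) for g in genome.genes],
            columns=["gene", "contig", "start", "end"])
        merged = expr.merge(gene_spans, on=["gene", "contig"], how="left")
        _, near6 = assoc.window_intersect(
            merged[["contig", "start", "end"]], peak_sets["dip6mA"],
            window=config.association_window)
        expr["near_6mA_peak"] = near6
        expr.to_csv(emit("expression_table", outdir / "expression_table.tsv"),
                    sep="\t", index=False, float_format="%.6g")
        for label, frame, col in (
                ("6mA_genes", expr[~expr["te_gene"]], "has_6mA"),
                ("6mA_peak_genes", expr[~expr["te_gene"]],
                 "near_6mA_peak"),
                ("4mC_te_genes", expr[expr["te_gene"]], "has_4mC")):
            try:
                r = assoc.expression_group_tests(frame, col)
                tests[label] = {
                    "test": r.test, "statistic": r.statistic,
                    "p_value": r.p_value,
                    "group_stats": _jsonable(
                        r.group_stats.to_dict(orient="records")),
                }
            except ValueError as exc:
                tests[label] = {"skipped": str(exc)}
    out["expression_tests"] = tests

    # fraction histogram (analysis-stage analog of the fraction plot)
    frac = calls["fraction"].dropna().to_numpy()
    edges = np.linspace(0, 1, 21)
    hist, _ = np.histogram(frac, bins=edges)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                  "count": hist}).to_csv(
        emit("fraction_histogram", outdir / "fraction_histogram.tsv"),
        sep="\t", index=False, float_format="%.6g")

    # observed/expected CpG ratio per contig (1-kb windows)
    cpg_rows = []
    for name, seq in sorted(genome.contigs.items()):
        t = assoc.cpg_obs_exp(seq, 1000)
        cpg_rows.append({"contig": name,
                         "mean_obs_exp": float(t["obs_exp"].mean())})
    out["cpg_obs_exp"] = _jsonable(cpg_rows)
    return out


def _motifs_stage(state, config, outdir: Path, emit) -> dict:
    genome = state["genome"]
    calls = state["calls"]
    out: dict = {}
    for mark in ("4mC", "6mA"):
        sub = calls[calls["mark"] == mark]
        if len(sub) == 0:
            out[mark] = {"skipped": "no calls"}
            continue
        windows = motifs.extract_context(sub, genome, config.motif_flank,
                                         expect_mark=mark)
        stats_tbl = motifs.doublet_triplet_stats(windows)
        doublets = stats_tbl["doublet"]
        doublets.rename("proportion").to_csv(
            emit(f"doublets_{mark}", outdir / f"doublets_{mark}.tsv"),
            sep="\t", index_label="doublet", float_format="%.6g")
        bg = motifs.sample_background_windows(
            genome, motifs.CENTER_BASE[mark], config.motif_flank,
            n=5 * len(windows), seed=config.sim.seed + 7)
        enr = motifs.kmer_enrichment(windows, bg,
                                     k_range=config.kmer_k_range)
        enr.to_csv(emit(f"kmer_enrichment_{mark}",
                        outdir / f"kmer_enrichment_{mark}.tsv"),
                   sep="\t", index=False, float_format="%.6g")
        out[mark] = {
            "n_windows": len(windows),
            "top_doublets": _jsonable(doublets.head(4).to_dict()),
            "top_kmers": _jsonable(
                enr.head(5)[["kmer", "odds_ratio", "q_value"]]
                .to_dict(orient="records")),
        }
    return out


def _overall_summary(report: dict) -> dict:
    s: dict = {}
    stages = report["stages"]
    if "callmods" in stages:
        s["calls_per_mark"] = stages["callmods"]["calls_per_mark"]
    if "peaks" in stages:
        s["peak_counts"] = stages["peaks"]["peak_counts"]
    if "associate" in stages:
        a = stages["associate"]
        s["density_table"] = a.get("density_table")
        s["expression_p_values"] = {
            k: v.get("p_value") for k, v in
            a.get("expression_tests", {}).items() if "p_value" in v}
    return s


def _make_plots(state, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "calls" in state:
        frac = state["calls"]["fraction"].dropna()
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.hist(frac, bins=20, color="#4c72b0")
        ax.set_xlabel("methylation fraction")
        ax.set_ylabel("sites")
        fig.tight_layout()
        fig.savefig(outdir / "fraction_histogram.png", dpi=100)
        plt.close(fig)


# ------------------------------------------------------------- validation

def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Well-formedness diagnostics for FASTA/GFF3/BED inputs.

    ``paths`` maps kinds ('fasta', 'gff3', 'bed') to file paths; 'gff3'
    checks need 'fasta' for coordinate bounds.  Returns a list of
    diagnostics dicts with 'severity' in {'fatal', 'warning'}.
    """
    diags: list[dict] = []
    contigs: dict[str, str] = {}
    if "fasta" in paths:
        try:
            contigs = io.read_fasta(paths["fasta"])
            if not contigs:
                diags.append({"severity": "fatal", "file": paths["fasta"],
                              "message": "no FASTA records"})
        except Exception as exc:  # malformed FASTA
            diags.append({"severity": "fatal", "file": paths["fasta"],
                          "message": f"unreadable FASTA: {exc}"})
    if "gff3" in paths:
        try:
            with open(paths["gff3"]) as fh:
                for ln, line in enumerate(fh, 1):
                    if line.startswith("#") or not line.strip():
                        continue
                    p = line.rstrip("\n").split("\t")
                    if len(p) != 9:
                        diags.append({"severity": "fatal",
                                      "file": paths["gff3"], "line": ln,
                                      "message": "GFF3 record must have "
                                                 "9 columns"})
                        continue
                    start, end = int(p[3]), int(p[4])
                    if start < 1 or end < start:
                        diags.append({"severity": "fatal",
                                      "file": paths["gff3"], "line": ln,
                                      "message": f"bad coordinates "
                                                 f"{start}..{end}"})
                    if p[6] not in ("+", "-", "."):
                        diags.append({"severity": "fatal",
                                      "file": paths["gff3"], "line": ln,
                                      "message": f"bad strand {p[6]!r}"})
                    if contigs and p[0] in contigs and \
                            end > len(contigs[p[0]]):
                        diags.append({
                            "severity": "fatal", "file": paths["gff3"],
                            "line": ln,
                            "message": f"feature {p[0]}:{start}..{end} "
                                       f"exceeds contig length "
                                       f"{len(contigs[p[0]])}"})
                    if contigs and p[0] not in contigs:
                        diags.append({"severity": "warning",
                                      "file": paths["gff3"], "line": ln,
                                      "message": f"unknown contig {p[0]}"})
        except (OSError, ValueError) as exc:
            diags.append({"severity": "fatal", "file": paths["gff3"],
                          "message": str(exc)})
    if "bed" in paths:
        try:
            with open(paths["bed"]) as fh:
                for ln, line in enumerate(fh, 1):
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    p = line.rstrip("\n").split("\t")
                    if len(p) < 3:
                        diags.append({"severity": "fatal",
                                      "file": paths["bed"], "line": ln,
                                      "message": "BED needs >= 3 columns"})
                        continue
                    start, end = int(p[1]), int(p[2])
                    if start >= end:
                        diags.append({"severity": "fatal",
                                      "file": paths["bed"], "line": ln,
                                      "message": f"start {start} >= "
                                                 f"end {end}"})
                    if len(p) >= 6 and p[5] not in ("+", "-", "."):
                        diags.append({"severity": "fatal",
                                      "file": paths["bed"], "line": ln,
                                      "message": f"bad strand {p[5]!r}"})
        except (OSError, ValueError) as exc:
            diags.append({"severity": "fatal", "file": paths["bed"],
                          "message": str(exc)})
    return diags
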