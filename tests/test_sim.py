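"""Simulator tests: genome layout, methylome planting, kinetics, read sets."""

import numpy as np
import pandas as pd
import pytest

from dnamod import io
from dnamod.config import (DipConfig, SimConfig, TandemRepeatConfig,
                           TEFamilyConfig)
from dnamod.core import empty_methylome, revcomp
from dnamod.sim import (SizingError, methylation_clusters, plant_methylome,
                        simulate_chipseq, simulate_dipseq, simulate_genome,
                        simulate_kinetics, simulate_rnaseq)

from conftest import small_config


# ----------------------------------------------------------------- genome

def test_empty_annotation_config_gives_empty_genome():
    cfg = SimConfig(seed=1, genome_length=20000, n_contigs=1, n_genes=0,
                    te_families=[],
                    tandem_repeats=TandemRepeatConfig(n_arrays=0))
    g = simulate_genome(cfg)
    assert g.genes == [] and g.te_copies == [] and g.tandem_repeats == []
    assert g.total_length == 20000


def test_te_copy_counts_and_integrity_classes():
    cfg = SimConfig(seed=2, genome_length=60000, n_contigs=1, n_genes=0,
                    te_families=[TEFamilyConfig("fam", 3000, 2, 0, 5)],
                    tandem_repeats=TandemRepeatConfig(n_arrays=0))
    cfg.gene_structure.te_gene_fraction = 0.0
    g = simulate_genome(cfg)
    assert len(g.te_copies) == 7
    short = [t for t in g.te_copies if t.integrity < 0.5]
    assert len(short) == 5
    assert all(t.integrity >= 0.95 for t in g.te_copies if t not in short)


def test_same_seed_gives_identical_fasta_and_gff3(tmp_path):
    files = []
    for run in ("a", "b"):
        g = simulate_genome(small_config(seed=9))
        fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
        io.write_fasta(g, fa)
        io.write_annotations_gff3(g, gff)
        files.append((fa.read_bytes(), gff.read_bytes()))
    assert files[0] == files[1]


def test_oversized_features_raise_sizing_error():
    cfg = SimConfig(seed=0, genome_length=5000, n_contigs=1, n_genes=0,
                    te_families=[TEFamilyConfig("fam", 3000, 5, 0, 0)],
                    tandem_repeats=TandemRepeatConfig(n_arrays=0))
    cfg.gene_structure.te_gene_fraction = 0.0
    with pytest.raises(SizingError):
        simulate_genome(cfg)


def test_subfeatures_nested_and_te_sequences_are_consensus_prefixes(genome):
    for g in genome.genes:
        for s, e in g.exons + g.introns:
            assert g.start <= s < e <= g.end
        if g.strand == "+":
            assert g.promoter[1] == g.start
        else:
            assert g.promoter[0] == g.end
    # full copies of one family share their 5' sequence (consensus prefix)
    fams = {}
    for t in genome.te_copies:
        seq = genome.contigs[t.contig][t.start:t.end]
        if t.strand == "-":
            seq = revcomp(seq)
        fams.setdefault(t.family, []).append(seq)
    for copies in fams.values():
        shortest = min(len(c) for c in copies)
        prefixes = {c[:shortest] for c in copies}
        assert len(prefixes) == 1


def test_gff3_round_trip(genome, tmp_path):
    path = tmp_path / "ann.gff3"
    io.write_annotations_gff3(genome, path)
    back = io.read_annotations_gff3(path, genome.contigs)
    assert len(back.genes) == len(genome.genes)
    assert len(back.te_copies) == len(genome.te_copies)
    orig = {g.name: g for g in genome.genes}
    for g in back.genes:
        o = orig[g.name]
        assert (g.start, g.end, g.strand, g.is_te_gene) == \
            (o.start, o.end, o.strand, o.is_te_gene)
        assert sorted(g.exons) == sorted(o.exons)


# --------------------------------------------------------------- methylome

def test_zero_planting_rate_gives_empty_methylome(genome):
    cfg = small_config()
    cfg.meth_4mC.site_rate = 0.0
    cfg.meth_6mA.site_rate = 0.0
    m = plant_methylome(genome, cfg)
    assert len(m) == 0


def test_4mc_records_confined_to_target_features(genome):
    cfg = small_config()
    cfg.meth_4mC.target_feature_classes = ("te_full", "te_medium")
    cfg.meth_6mA.site_rate = 0.0
    m = plant_methylome(genome, cfg)
    spans = [(t.contig, t.start, t.end) for t in genome.te_copies
             if t.integrity >= 0.5]
    for contig, pos in m[["contig", "pos"]].itertuples(index=False):
        assert any(c == contig and s <= pos < e for c, s, e in spans)


def test_base_identity_matches_mark(genome, methylome):
    for row in methylome.itertuples(index=False):
        base = genome.base_at(row.contig, row.pos, row.strand)
        assert base == ("C" if row.mark == "4mC" else "A")


def test_point_mass_fraction_distribution(genome):
    cfg = small_config()
    cfg.meth_4mC.fully_methylated_prob = 1.0
    cfg.meth_6mA.site_rate = 0.0
    m = plant_methylome(genome, cfg)
    assert len(m) > 100
    assert (m["fraction"] == 1.0).all()


def test_no_eligible_features_raises():
    cfg = SimConfig(seed=3, genome_length=20000, n_contigs=1, n_genes=2,
                    te_families=[],
                    tandem_repeats=TandemRepeatConfig(n_arrays=0))
    cfg.gene_structure.te_gene_fraction = 0.0
    cfg.meth_4mC.target_feature_classes = ("te_full",)
    g = simulate_genome(cfg)
    with pytest.raises(ValueError, match="te_full"):
        plant_methylome(g, cfg)


def test_methylation_clusters_group_nearby_marks():
    m = pd.DataFrame({
        "contig": ["c1"] * 5, "pos": [100, 150, 200, 900, 950],
        "strand": "+", "mark": "4mC", "fraction": 1.0})
    cl = methylation_clusters(m, gap=300)
    assert len(cl) == 2
    assert cl.iloc[0]["center"] == 150 and cl.iloc[0]["n_sites"] == 3


# ---------------------------------------------------------------- kinetics

def test_kinetics_ratio_matches_multiplier(genome):
    cfg = small_config()
    cfg.meth_4mC.fully_methylated_prob = 1.0
    cfg.meth_6mA.site_rate = 0.0
    cfg.kinetics.mean_passes = 50
    cfg.kinetics.n_background_sites = 0
    m = plant_methylome(genome, cfg)
    k = simulate_kinetics(genome, m, cfg)
    sigma = cfg.kinetics.sigma_log
    control_mean = np.exp(0.5 * sigma ** 2)
    ratios = [np.mean(ip) / control_mean for ip in k.native_ipds
              if len(ip) >= 30]
    assert 2.5 < np.mean(ratios) < 3.5


def test_zero_passes_absent_from_table(genome, methylome):
    cfg = small_config()
    cfg.kinetics.mean_passes = 0.0
    cfg.kinetics.n_background_sites = 100
    k = simulate_kinetics(genome, methylome, cfg)
    assert len(k) == 0


def test_kinetics_tsv_round_trip(genome, methylome, tmp_path):
    cfg = small_config()
    cfg.kinetics.n_background_sites = 50
    k = simulate_kinetics(genome, methylome.head(20), cfg)
    path = tmp_path / "k.tsv"
    io.write_kinetics_tsv(k, path)
    back = io.read_kinetics_tsv(path)
    assert len(back) == len(k)
    pd.testing.assert_frame_equal(
        back.sites[["contig", "pos", "strand", "coverage"]],
        k.sites[["contig", "pos", "strand", "coverage"]])
    for a, b in zip(back.native_ipds, k.native_ipds):
        assert np.allclose(a, b, rtol=1e-4)


# ------------------------------------------------------------------- reads

def test_dip_conservation_and_empty_library(genome, methylome):
    cfg = small_config()
    rs = simulate_dipseq(genome, methylome, cfg)
    for assay, reads in rs.items():
        assert reads.total_reads == cfg.dip.library_size
        reads.validate(genome.contig_lengths())
    cfg.dip = DipConfig(library_size=0)
    rs0 = simulate_dipseq(genome, methylome, cfg)
    assert all(r.total_reads == 0 for r in rs0.values())


def test_dip_null_capture_matches_input(genome, methylome):
    from dnamod.enrich import bin_coverage, normalize_rpgc
    cfg = small_config()
    cfg.dip.capture_enrichment = 0.0
    cfg.dip.library_size = 20000
    rs = simulate_dipseq(genome, methylome, cfg)
    ip = normalize_rpgc(bin_coverage(rs["dip4mC"], genome, 200, 50))
    inp = normalize_rpgc(bin_coverage(rs["input"], genome, 200, 50))
    diffs = np.concatenate([ip.bins[c] - inp.bins[c] for c in ip.bins])
    assert abs(np.mean(diffs)) < 0.05
    assert np.percentile(np.abs(diffs), 95) < 1.0


def test_dip_pileup_concentrates_on_methylated_cluster():
    from dnamod.enrich import bin_coverage
    cfg = small_config(seed=4)
    cfg.meth_6mA.site_rate = 0.0
    cfg.meth_4mC.target_feature_classes = ("te_full",)
    cfg.meth_4mC.te_5prime_decay_bp = 50.0
    cfg.dip.library_size = 20000
    g = simulate_genome(cfg)
    m = plant_methylome(g, cfg)
    rs = simulate_dipseq(g, m, cfg)
    track = bin_coverage(rs["dip4mC"], g, 50, 50)
    best = max(((c, int(np.argmax(v)) * 50) for c, v in track.bins.items()),
               key=lambda t: track.bins[t[0]][t[1] // 50])
    clusters = methylation_clusters(m, gap=300)
    d = [abs(best[1] - row.center) for row in clusters.itertuples()
         if row.contig == best[0]]
    assert d and min(d) < 400


def test_chip_conservation_and_tss_enrichment(genome):
    from dnamod.enrich import bin_coverage
    cfg = small_config()
    cfg.chip.library_size = 30000
    rs = simulate_chipseq(genome, cfg)
    for assay, reads in rs.items():
        assert reads.total_reads == cfg.chip.library_size
        reads.validate(genome.contig_lengths())
    track = bin_coverage(rs["H3K4me3"], genome, 100, 75)
    tss_vals, all_vals = [], []
    for g in genome.genes:
        if g.expression_class != "high":
            continue
        vec = track.bins[g.contig]
        b = g.tss // 100
        lo, hi = max(b - 10, 0), min(b + 10, len(vec))
        tss_vals.append(vec[lo:hi].mean())
    for vec in track.bins.values():
        all_vals.append(vec.mean())
    assert np.mean(tss_vals) > 2 * np.mean(all_vals)


def test_chip_without_tes_has_no_heterochromatin_signal():
    cfg = SimConfig(seed=5, genome_length=30000, n_contigs=1, n_genes=4,
                    te_families=[],
                    tandem_repeats=TandemRepeatConfig(n_arrays=0))
    cfg.gene_structure.te_gene_fraction = 0.0
    cfg.chip.library_size = 10000
    g = simulate_genome(cfg)
    rs = simulate_chipseq(g, cfg)
    from dnamod.enrich import bin_coverage
    k9 = bin_coverage(rs["H3K9me3"], g, 500, 75).bins["contig_1"]
    # uniform background: no bin wildly above the mean
    assert k9.max() < 3 * k9.mean()


def test_rnaseq_counts_and_read_placement(genome, methylome):
    cfg = small_config()
    reads, truth = simulate_rnaseq(genome, methylome, cfg)
    assert reads.total_reads == cfg.rnaseq.library_size
    assert truth["counts"].sum() == cfg.rnaseq.library_size
    spans = []
    for g in genome.genes:
        spans.extend((g.contig, s, e) for s, e in g.exonic_spans())
    sample = reads.reads.head(200)
    for contig, start, end, _ in sample.itertuples(index=False):
        assert any(c == contig and s <= start and end <= e + 1
                   for c, s, e in spans)


def test_rnaseq_repression_direction_recovered():
    cfg = small_config(seed=12)
    cfg.n_genes = 30
    cfg.genome_length = 150000
    cfg.gene_structure.te_gene_fraction = 0.5
    cfg.meth_4mC.copy_methylation_prob = 0.5
    cfg.rnaseq.library_size = 100000
    g = simulate_genome(cfg)
    m = plant_methylome(g, cfg)
    _, truth = simulate_rnaseq(g, m, cfg)
    te = truth[truth["te_gene"]]
    with4 = te[te["has_4mC"]]
    without = te[~te["has_4mC"]]
    assert len(with4) >= 3 and len(without) >= 3
    norm = truth["counts"] / truth["exonic_length"]
    assert norm[with4.index].mean() < norm[without.index].mean()
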