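"""Interval statistics, profiles, densities, spatial correlation and
expression grouping, each checked against brute-force or closed-form
oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnamod import assoc
from dnamod.core import AnnotatedGenome, TECopy
from dnamod.enrich import CoverageTrack
from dnamod.intervals import (jaccard_bp, merge_intervals, total_bp,
                              window_association)


def iv(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


# ----------------------------------------------------------------- jaccard

def test_jaccard_hand_cases():
    a = iv([("c1", 0, 100)])
    b = iv([("c1", 50, 150)])
    assert jaccard_bp(a, b) == pytest.approx(50 / 150)
    assert jaccard_bp(a, a) == 1.0
    assert jaccard_bp(a, iv([("c1", 500, 600)])) == 0.0
    assert math.isnan(jaccard_bp(iv([]), iv([])))


def brute_jaccard(a, b, length=400):
    def cover(df):
        s = set()
        for contig, lo, hi in df.itertuples(index=False):
            s.update((contig, p) for p in range(lo, hi))
        return s
    A, B = cover(a), cover(b)
    if not A and not B:
        return float("nan")
    return len(A & B) / len(A | B)


interval_lists = st.lists(
    st.tuples(st.sampled_from(["c1", "c2"]), st.integers(0, 380),
              st.integers(1, 20)),
    min_size=0, max_size=12).map(
    lambda rows: iv([(c, s, s + l) for c, s, l in rows]))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(interval_lists, interval_lists)
def test_jaccard_matches_per_bp_oracle_and_is_symmetric(a, b):
    got = jaccard_bp(a, b)
    want = brute_jaccard(a, b)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want)
        assert jaccard_bp(b, a) == pytest.approx(got)
        assert 0.0 <= got <= 1.0


def test_merge_joins_bookended_and_total_bp():
    m = merge_intervals(iv([("c1", 0, 10), ("c1", 10, 20), ("c1", 30, 40)]))
    assert m[["start", "end"]].to_numpy().tolist() == [[0, 20], [30, 40]]
    assert total_bp(iv([("c1", 0, 10), ("c1", 5, 15)])) == 15


# ----------------------------------------------------- window association

def test_window_intersect_boundaries():
    feats = iv([("c1", 1000, 2000)])
    inside = pd.DataFrame({"contig": ["c1"], "pos": [1500]})
    n, labels = assoc.window_intersect(inside, feats, window=0)
    assert n == 1 and labels[0]
    near = pd.DataFrame({"contig": ["c1"], "pos": [2500]})
    assert assoc.window_intersect(near, feats, window=500)[0] == 1
    far = pd.DataFrame({"contig": ["c1"], "pos": [2501]})
    assert assoc.window_intersect(far, feats, window=500)[0] == 0
    with pytest.raises(ValueError):
        assoc.window_intersect(near, feats, window=-1)


def brute_window(items, feats, window):
    """All-pairs gap check: distance between half-open intervals is the
    number of bases strictly between them (0 when overlapping/touching)."""
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


def test_window_association_matches_all_pairs_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        items = iv([("c1", int(s), int(s) + int(l))
                    for s, l in zip(rng.integers(0, 5000, 40),
                                    rng.integers(1, 300, 40))])
        feats = iv([("c1", int(s), int(s) + int(l))
                    for s, l in zip(rng.integers(0, 5000, 15),
                                    rng.integers(1, 400, 15))])
        w = int(rng.integers(0, 600))
        got = window_association(items, feats, w)
        assert (got == brute_window(items, feats, w)).all()


# ---------------------------------------------------------------- profiles

def test_occupancy_profile_manual_oracle():
    feats = pd.DataFrame({
        "contig": ["c1", "c1", "c1"],
        "start": [1000, 3000, 5000],
        "end": [1400, 3400, 5400],
        "strand": ["+", "-", "+"]})
    sites = pd.DataFrame({
        "contig": ["c1"] * 7,
        "pos": [950, 1000, 1050, 3399, 3450, 5000, 5399]})
    pm = assoc.occupancy_profile(sites, feats, flank=100, bin_size=50,
                                 anchor="5prime")
    # anchors: 1000 (+), 3399 (-), 5000 (+); bins cover [-100, 100)
    want = np.zeros((3, 4))
    want[0, 1] = 1   # 950 -> offset -50
    want[0, 2] = 1   # 1000 -> offset 0
    want[0, 3] = 1   # 1050 -> offset +50
    want[1, 2] = 1   # 3399 on '-' -> oriented offset 0
    want[1, 0] = 1   # 3450 on '-' -> oriented offset -51 (upstream)
    want[2, 2] = 1   # 5000 offset 0
    assert np.array_equal(pm.values, want)
    assert pm.profile().sum() * pm.n_features == pytest.approx(6)


def test_occupancy_profile_conservation_property():
    rng = np.random.default_rng(8)
    feats = pd.DataFrame({"contig": "c1",
                          "start": rng.integers(2000, 40000, 10),
                          "strand": np.where(rng.random(10) < 0.5, "+", "-")})
    feats["end"] = feats["start"] + 500
    sites = pd.DataFrame({"contig": "c1",
                          "pos": rng.integers(0, 45000, 400)})
    pm = assoc.occupancy_profile(sites, feats, flank=1000, bin_size=25)
    in_windows = 0
    for _, f in feats.iterrows():
        a = f["start"] if f["strand"] == "+" else f["end"] - 1
        in_windows += ((sites["pos"] >= a - 1000) &
                       (sites["pos"] < a + 1000)).sum()
    assert pm.values.sum() == in_windows
    with pytest.raises(ValueError):
        assoc.occupancy_profile(sites, feats, flank=1001, bin_size=25)


def test_metaprofile_body_scaling():
    feats = pd.DataFrame({"contig": ["c1", "c1"], "start": [1000, 5000],
                          "end": [1100, 5200], "strand": ["+", "+"]})
    sites = pd.DataFrame({"contig": ["c1", "c1"], "pos": [1025, 5050]})
    pm = assoc.metaprofile(sites, feats, flank=100, bin_size=50,
                           n_body_bins=10)
    fb = 2
    # both sites at 25% of the body -> same body bin regardless of length
    assert pm.values[0, fb + 2] == 1 and pm.values[1, fb + 2] == 1
    mid = pd.DataFrame({"contig": ["c1"], "pos": [1050]})
    pm2 = assoc.metaprofile(mid, feats.iloc[[0]], flank=100, bin_size=50,
                            n_body_bins=10)
    assert pm2.values[0, fb + 5] == 1


def test_metaprofile_skips_zero_length_features():
    feats = pd.DataFrame({"contig": ["c1", "c1"], "start": [100, 300],
                          "end": [200, 300], "strand": ["+", "+"]})
    sites = pd.DataFrame({"contig": ["c1"], "pos": [150]})
    with pytest.warns(UserWarning, match="zero-length"):
        pm = assoc.metaprofile(sites, feats, flank=100, bin_size=50,
                               n_body_bins=4)
    assert pm.n_skipped == 1 and pm.n_features == 1


def test_fraction_profile_masked_mean():
    calls = pd.DataFrame({"contig": ["c1", "c1", "c1"],
                          "pos": [1010, 1015, 1100],
                          "fraction": [1.0, 0.5, 0.8]})
    anchors = pd.DataFrame({"contig": ["c1"], "pos": [1000]})
    pm = assoc.fraction_profile(calls, anchors, flank=200, bin_size=25)
    prof = pm.profile()
    bin_of = lambda p: (p - 1000 + 200) // 25
    assert prof[bin_of(1010)] == pytest.approx(0.75)
    assert prof[bin_of(1100)] == pytest.approx(0.8)
    assert not pm.mask()[0]
    assert prof[0] == 0.0


# ----------------------------------------------------------------- density

def test_normalized_density_formula():
    sites = pd.DataFrame({"contig": ["c1"] * 1000,
                          "pos": np.arange(1000) % 500})
    ann = iv([("c1", 0, 500)])
    row = assoc.normalized_density(sites, ann, genome_fraction=0.533,
                                   n_annotations=2000)
    assert row["normalized_density"] == pytest.approx((1000 / 2000) / 0.533)
    assert assoc.normalized_density(
        sites.iloc[:0], ann, 0.5)["normalized_density"] == 0.0
    undef = assoc.normalized_density(sites, iv([]), 0.5)
    assert undef["undefined"] and math.isnan(undef["normalized_density"])
    with pytest.raises(ValueError):
        assoc.normalized_density(sites, ann, 0.0)


def test_uniform_planting_gives_comparable_densities():
    rng = np.random.default_rng(9)
    L = 100000
    sites = pd.DataFrame({"contig": "c1", "pos": rng.integers(0, L, 4000)})
    a = iv([("c1", 0, 30000)])
    b = iv([("c1", 50000, 65000)])
    da = assoc.normalized_density(sites, a, 30000 / L)["normalized_density"]
    db = assoc.normalized_density(sites, b, 15000 / L)["normalized_density"]
    assert da == pytest.approx(db, rel=0.15)


# ------------------------------------------------------------ TE integrity

def test_classify_te_integrity_rules():
    assert assoc.classify_te_integrity(400, 1000) == "short"
    assert assoc.classify_te_integrity(700, 1000) == "medium"
    assert assoc.classify_te_integrity(1000, 1000) == "full"
    assert assoc.classify_te_integrity(900, 1000) == "full"
    with pytest.warns(UserWarning, match="suspect"):
        assert assoc.classify_te_integrity(1300, 1000) == "full"
    with pytest.raises(ValueError):
        assoc.classify_te_integrity(100, 0)


def test_density_by_integrity_manual_oracle():
    tes = [TECopy("t1", "f", 1000, "c1", 0, 1000, "+"),      # full
           TECopy("t2", "f", 1000, "c1", 2000, 2950, "+"),   # full
           TECopy("t3", "f", 1000, "c1", 4000, 4700, "+"),   # medium
           TECopy("t4", "f", 1000, "c1", 6000, 6300, "+"),   # short
           TECopy("t5", "f", 1000, "c1", 8000, 8400, "+")]   # short
    calls = pd.DataFrame({"contig": "c1",
                          "pos": [10, 20, 2100, 4100, 4200, 4300]})
    t = assoc.density_by_integrity(calls, tes).set_index("integrity_class")
    assert t.loc["full", "mean_count"] == pytest.approx(1.5)
    assert t.loc["full", "sd_count"] == pytest.approx(0.5)
    assert t.loc["medium", "mean_count"] == pytest.approx(3.0)
    assert t.loc["short", "mean_count"] == 0.0
    empty = assoc.density_by_integrity(calls, [])
    assert empty["empty"].all()


# --------------------------------------------------------- co-localization

def test_colocalization_trivial_and_brute_force():
    dip = iv([("c1", 0, 100), ("c1", 500, 600), ("c1", 900, 950)])
    whole = {"all": iv([("c1", 0, 10000)])}
    t = assoc.colocalization_fractions(dip, whole)
    assert t.iloc[0]["percent"] == 100.0
    disjoint = {"none": iv([("c1", 5000, 6000)])}
    assert assoc.colocalization_fractions(dip, disjoint).iloc[0]["percent"] \
        == 0.0
    rng = np.random.default_rng(4)
    sets = {"a": iv([("c1", int(s), int(s) + 80)
                     for s in rng.integers(0, 3000, 10)]),
            "b": iv([("c1", int(s), int(s) + 80)
                     for s in rng.integers(0, 3000, 10)])}
    peaks = iv([("c1", int(s), int(s) + 60)
                for s in rng.integers(0, 3000, 20)])
    t = assoc.colocalization_fractions(
        peaks, sets, combined={"a+b": ("a", "b")}).set_index("class")
    for name, members in (("a", ["a"]), ("b", ["b"]), ("a+b", ["a", "b"])):
        target = pd.concat([sets[m] for m in members])
        want = brute_window(peaks, target, 0).sum()
        assert t.loc[name, "n_overlapping"] == want
    undef = assoc.colocalization_fractions(iv([]), sets)
    assert undef["undefined"].all()


def test_summit_signal_profile_slice_and_skip():
    track = CoverageTrack({"c1": np.arange(100, dtype=float)}, 10,
                          "log2ratio", 50, {"c1": 1000})
    summits = pd.DataFrame({"contig": ["c1", "c1"], "summit": [500, 30]})
    pm = assoc.summit_signal_profile(summits, track, flank=200)
    assert pm.n_skipped == 1          # summit at 30 has no full window
    assert np.array_equal(pm.values[0], np.arange(30, 70, dtype=float))
    zero = CoverageTrack({"c1": np.zeros(100)}, 10, "log2ratio", 50,
                         {"c1": 1000})
    pz = assoc.summit_signal_profile(
        pd.DataFrame({"contig": ["c1"], "summit": [500]}), zero, 200)
    assert (pz.profile() == 0).all()


# ------------------------------------------------------------- symmetry

def test_strand_symmetry_toy_cases(toy_genome):
    empty = pd.DataFrame({"contig": [], "pos": [], "strand": [],
                          "mark": []})
    assert len(assoc.strand_symmetry(empty, toy_genome)) == 0
    seq = toy_genome.contigs["c1"]
    p = seq.find("CG")
    calls = pd.DataFrame({"contig": ["c1", "c1"], "pos": [p, p + 1],
                          "strand": ["+", "-"], "mark": ["4mC", "4mC"]})
    t = assoc.strand_symmetry(calls, toy_genome)
    assert t.iloc[0]["symmetric_fraction"] == 1.0
    lone = assoc.strand_symmetry(calls.iloc[[0]], toy_genome)
    assert lone.iloc[0]["symmetric_fraction"] == 0.0


def test_strand_symmetry_recovers_planted_rate(genome):
    from conftest import small_config
    from dnamod.sim import plant_methylome
    fracs = []
    for seed in range(6):
        cfg = small_config(seed=seed)
        cfg.symmetric_fraction = 0.1
        m = plant_methylome(genome, cfg)
        t = assoc.strand_symmetry(m, genome)
        fracs.append(
            (t["n_paired"].sum()) / t["n_positions"].sum())
    est = float(np.mean(fracs))
    n = 6 * 2000
    assert abs(est - 0.1) <= 3 * math.sqrt(0.1 * 0.9 / n) + 0.01


# ------------------------------------------------------------- CpG obs/exp

def test_cpg_obs_exp_hand_and_undefined():
    t = assoc.cpg_obs_exp("CGCG", 4)
    assert t.iloc[0]["obs_exp"] == pytest.approx(2.0)
    t2 = assoc.cpg_obs_exp("ATATGGGG", 8)
    assert t2.iloc[0]["undefined"] and math.isnan(t2.iloc[0]["obs_exp"])
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=200000))
    t3 = assoc.cpg_obs_exp(seq, 200000)
    assert t3.iloc[0]["obs_exp"] == pytest.approx(1.0, abs=0.05)
    with pytest.raises(ValueError):
        assoc.cpg_obs_exp("ACGT", 0)


# ------------------------------------------------------------- expression

def test_rpkm_definition_and_errors():
    assert assoc.rpkm(100, 1000, 10 ** 6) == pytest.approx(100.0)
    assert assoc.rpkm(0, 1000, 10 ** 6) == 0.0
    counts = np.array([10, 20, 0, 5, 100])
    lens = np.array([500, 2000, 100, 1000, 250])
    got = assoc.rpkm(counts, lens, 135)
    want = counts / (lens / 1000) / (135 / 1e6)
    assert np.allclose(got, want)
    with pytest.raises(ValueError):
        assoc.rpkm(1, 0, 100)
    with pytest.raises(ValueError):
        assoc.rpkm(1, 100, 0)


def test_ttest_matches_textbook_formula():
    expr = pd.DataFrame({"log2_rpkm": [1, 2, 3, 4, 5, 6.0],
                         "grp": [0, 0, 0, 1, 1, 1]})
    r = assoc.expression_group_tests(expr, "grp")
    # pooled-variance two-sample t for {1,2,3} vs {4,5,6}
    sp2 = 1.0
    t = (2.0 - 5.0) / math.sqrt(sp2 * (2 / 3))
    assert r.statistic == pytest.approx(t)
    assert r.p_value == pytest.approx(0.021312, abs=1e-4)
    same = pd.DataFrame({"log2_rpkm": [1, 2, 3, 1, 2, 3.0],
                         "grp": [0, 0, 0, 1, 1, 1]})
    r2 = assoc.expression_group_tests(same, "grp")
    assert r2.statistic == 0.0 and r2.p_value == pytest.approx(1.0)


def test_anova_with_tukey_and_skipped_groups():
    rng = np.random.default_rng(5)
    expr = pd.DataFrame({
        "log2_rpkm": np.concatenate([rng.normal(5, 1, 30),
                                     rng.normal(2, 1, 30),
                                     rng.normal(2, 1, 30),
                                     [9.0]]),
        "grp": ["H3K4me3"] * 30 + ["H3K9me3"] * 30 + ["none"] * 30
               + ["tiny"]})
    r = assoc.expression_group_tests(expr, "grp")
    assert r.test == "anova_tukey" and r.p_value < 1e-6
    assert r.skipped_groups == ["tiny"]
    pair = r.tukey.set_index(["group_a", "group_b"])
    assert pair.loc[("H3K4me3", "H3K9me3"), "p_adj"] < 0.01
    assert pair.loc[("H3K9me3", "none"), "p_adj"] > 0.05


# --------------------------------------------------- spatial correlation

def make_genome(length=20000):
    return AnnotatedGenome({"c1": "A" * length}, [], [], [])


def test_permutation_identity_query_hits_floor():
    g = make_genome()
    ref = iv([("c1", 2000, 2500), ("c1", 8000, 9000), ("c1", 15000, 15300)])
    r = assoc.permutation_spatial_test(ref, ref, g, "jaccard",
                                       n_permutations=999, seed=1)
    assert r.p_value == pytest.approx(1 / 1000)
    assert r.observed == 1.0


def test_permutation_distance_floor_at_99():
    g = make_genome(500000)
    ref = iv([("c1", 5000, 5100)])
    query = iv([("c1", 5010, 5030), ("c1", 5050, 5060)])
    r = assoc.permutation_spatial_test(query, ref, g,
                                       "mean_nearest_distance",
                                       n_permutations=99, seed=2)
    assert r.observed == 0.0
    assert r.p_value == pytest.approx(0.01)
    with pytest.raises(ValueError):
        assoc.permutation_spatial_test(query, ref, g, "jaccard",
                                       n_permutations=10)


def test_permutation_oversized_query_raises():
    g = make_genome(1000)
    with pytest.raises(ValueError):
        assoc.permutation_spatial_test(iv([("c1", 0, 5000)]),
                                       iv([("c1", 0, 10)]), g,
                                       n_permutations=99)
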