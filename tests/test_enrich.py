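"""Coverage tracks, normalization, log2 ratio and Poisson peak calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnamod.core import AnnotatedGenome, ReadSet, empty_reads
from dnamod.enrich import (bin_coverage, call_peaks, log2_ratio,
                           normalize_rpgc, peaks_to_frame)

from conftest import make_reads


def flat_genome(length=5000, name="c1"):
    return AnnotatedGenome({name: "A" * length}, [], [], [])


def test_empty_readset_gives_zero_track():
    g = flat_genome()
    track = bin_coverage(empty_reads("x"), g, 10, 50)
    assert all((v == 0).all() for v in track.bins.values())


def test_single_read_hits_exactly_five_bins():
    g = flat_genome()
    track = bin_coverage(make_reads([("c1", 100, 150, "+")]), g, 10, 50)
    v = track.bins["c1"]
    assert (v[10:15] == 1.0).all()
    assert v.sum() == pytest.approx(5.0)


def test_read_extension_from_five_prime_end():
    g = flat_genome()
    plus = bin_coverage(make_reads([("c1", 100, 150, "+")]), g, 10, 100)
    minus = bin_coverage(make_reads([("c1", 100, 150, "-")]), g, 10, 100)
    assert (plus.bins["c1"][10:20] == 1.0).all()   # extends rightward
    assert (minus.bins["c1"][5:15] == 1.0).all()   # extends leftward
    with pytest.raises(ValueError):
        bin_coverage(make_reads([("c1", 0, 50, "+")]), g, 10, 20)


def brute_force_track(reads, length, bin_size, ext):
    perbp = np.zeros(length)
    for contig, s, e, strand in reads:
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


def test_bin_coverage_matches_per_bp_oracle():
    rng = np.random.default_rng(11)
    length = 3000
    g = flat_genome(length)
    for _ in range(20):
        rows = [("c1", int(s), int(s) + 50,
                 "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(0, length - 50, size=100)]
        track = bin_coverage(make_reads(rows), g, 10, 80)
        assert np.allclose(track.bins["c1"],
                           brute_force_track(rows, length, 10, 80))


def test_rpgc_identity_scale_invariance_and_uniform():
    g = flat_genome(1000)
    rows = [("c1", i, i + 50, "+") for i in range(0, 951, 1)]
    # uniform-ish coverage; duplicate library leaves RPGC unchanged
    t1 = normalize_rpgc(bin_coverage(make_reads(rows), g, 10, 50))
    t2 = normalize_rpgc(bin_coverage(make_reads(rows + rows), g, 10, 50))
    assert np.allclose(t1.bins["c1"], t2.bins["c1"])
    again = normalize_rpgc(t1)
    assert np.allclose(again.bins["c1"], t1.bins["c1"])
    # exact 4x coverage everywhere -> all bins 1.0 after RPGC
    rows4 = [("c1", 0, 1000, "+")] * 4
    t4 = normalize_rpgc(bin_coverage(make_reads(rows4), g, 10, 1000))
    assert np.allclose(t4.bins["c1"], 1.0)
    with pytest.raises(ValueError):
        normalize_rpgc(bin_coverage(empty_reads("x"), g, 10, 50))


def test_log2_ratio_formula_and_grid_check():
    g = flat_genome(500)
    rng = np.random.default_rng(1)
    rows_a = [("c1", int(s), int(s) + 50, "+")
              for s in rng.integers(0, 450, 200)]
    rows_b = [("c1", int(s), int(s) + 50, "+")
              for s in rng.integers(0, 450, 100)]
    a = bin_coverage(make_reads(rows_a), g, 10, 50)
    b = bin_coverage(make_reads(rows_b), g, 10, 50)
    r = log2_ratio(a, b, pseudocount=1.0)
    expect = np.log2((a.bins["c1"] + 1.0) / (b.bins["c1"] + 1.0))
    assert np.allclose(r.bins["c1"], expect)
    same = log2_ratio(a, a)
    assert np.allclose(same.bins["c1"], 0.0)
    big = log2_ratio(
        bin_coverage(make_reads(rows_a * 40), g, 10, 50),
        bin_coverage(make_reads(rows_a * 20), g, 10, 50))
    assert np.median(big.bins["c1"]) == pytest.approx(1.0, abs=0.15)
    coarse = bin_coverage(make_reads(rows_b), g, 20, 50)
    with pytest.raises(ValueError):
        log2_ratio(a, coarse)


def test_uniform_background_yields_no_peaks():
    g = flat_genome(20000)
    rng = np.random.default_rng(5)
    rows = [("c1", int(s), int(s) + 50, "+")
            for s in rng.integers(0, 19950, 4000)]
    peaks = call_peaks(make_reads(rows), g, read_extension=50)
    assert peaks == []


def test_single_hot_region_gives_one_peak_with_poisson_p():
    g = flat_genome(20000)
    rng = np.random.default_rng(6)
    rows = [("c1", int(s), int(s) + 50, "+")
            for s in rng.integers(0, 19950, 2000)]
    hot = [("c1", int(s), int(s) + 50, "+")
           for s in rng.integers(5000, 5200, 400)]
    peaks = call_peaks(make_reads(rows + hot), g, read_extension=50,
                       min_width=50)
    assert len(peaks) == 1
    p = peaks[0]
    assert 4800 <= p.start <= p.summit <= p.end <= 5500
    # p-value equals the Poisson upper tail at the summit count
    reads = rows + hot
    counts = np.zeros(2000)
    for _, s, e, _ in reads:
        counts[s // 10:(e - 1) // 10 + 1] += 1
    lam = counts.mean()
    k = counts[p.start // 10:(p.end - 1) // 10 + 1].max()
    assert p.p_value == pytest.approx(float(stats.poisson.sf(k - 1, lam)),
                                      rel=1e-6)


def test_peak_threshold_monotonicity_and_sorted_disjoint():
    g = flat_genome(30000)
    rng = np.random.default_rng(7)
    rows = [("c1", int(s), int(s) + 50, "+")
            for s in rng.integers(0, 29950, 3000)]
    for center in (4000, 12000, 21000):
        rows += [("c1", int(s), int(s) + 50, "+")
                 for s in rng.integers(center, center + 150, 300)]
    loose = peaks_to_frame(call_peaks(make_reads(rows), g,
                                      read_extension=50, p_threshold=1e-3))
    strict = peaks_to_frame(call_peaks(make_reads(rows), g,
                                       read_extension=50, p_threshold=1e-8))
    assert len(strict) <= len(loose)
    # strict peak regions are contained in loose regions
    for _, s in strict.iterrows():
        assert ((loose["start"] <= s["start"]) &
                (loose["end"] >= s["end"])).any()
    arr = loose.sort_values("start")
    assert (arr["start"].to_numpy()[1:] >= arr["end"].to_numpy()[:-1]).all()


def test_zero_reads_peak_calling_raises():
    with pytest.raises(ValueError):
        call_peaks(empty_reads("x"), flat_genome(), read_extension=50)
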