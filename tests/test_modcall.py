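"""Modification caller: IPD ratios, scores, filters, fraction estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dnamod.core import AnnotatedGenome, KineticTable
from dnamod.modcall import (CallFilter, apply_filter, call_modifications,
                            classify_fraction, compute_ipd_ratio,
                            estimate_fraction, fraction_summary, score_site)


def make_table(rows):
    """rows: (contig, pos, strand, native_ipds array)."""
    sites = pd.DataFrame(
        [(c, p, s, len(n)) for c, p, s, n in rows],
        columns=["contig", "pos", "strand", "coverage"])
    sites["control_log_mu"] = 0.0
    sites["control_sigma"] = 0.4
    return KineticTable(sites, [np.asarray(n, dtype=float)
                                for _, _, _, n in rows],
                        [None] * len(rows))


GENOME = AnnotatedGenome(
    contigs={"c1": "C" * 50 + "A" * 50 + "G" * 50 + "T" * 50},
    genes=[], te_copies=[], tandem_repeats=[])


def test_ipd_ratio_definition_and_errors():
    assert compute_ipd_ratio([2.0, 2.0], 1.0) == pytest.approx(2.0)
    assert compute_ipd_ratio([1.0, 3.0], [2.0, 2.0]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_ipd_ratio([], 1.0)
    with pytest.raises(ValueError):
        compute_ipd_ratio([1.0], 0.0)


def test_score_is_phred_scaled_one_sided_p():
    rng = np.random.default_rng(0)
    x = np.exp(rng.normal(0.3, 0.4, size=30))
    logs = np.log(x)
    t = (logs.mean() - 0.0) / (logs.std(ddof=1) / math.sqrt(30))
    p = stats.t.sf(t, df=29)
    assert score_site(x, control_log_mu=0.0) == \
        pytest.approx(-10 * math.log10(p))


def test_score_degenerate_inputs_do_not_nan():
    assert score_site([1.0, 1.0, 1.0], control_log_mu=0.0) == 0.0
    high = score_site([3.0, 3.0, 3.0], control_log_mu=0.0)
    assert np.isfinite(high) and high > 0
    assert score_site([1.0, 1.0], [1.0, 1.0]) == 0.0


def test_score_null_calibration_rate():
    rng = np.random.default_rng(42)
    n_sites, cov = 20000, 25
    logs = rng.normal(0.0, 0.4, size=(n_sites, cov))
    scores = np.empty(n_sites)
    mean = logs.mean(axis=1)
    sd = logs.std(axis=1, ddof=1)
    t = mean / (sd / math.sqrt(cov))
    p = stats.t.sf(t, df=cov - 1)
    scores = -10 * np.log10(p)
    rate = float(np.mean(scores >= 22))
    alpha = 10 ** -2.2
    assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_sites)


def test_call_filters_and_mark_assignment():
    strong = np.exp(np.random.default_rng(1).normal(1.2, 0.4, 25))
    weak_cov = strong[:8]
    table = make_table([
        ("c1", 5, "+", weak_cov),          # coverage 8 -> dropped
        ("c1", 6, "+", strong),            # C -> 4mC primary
        ("c1", 60, "+", strong),           # A -> 6mA primary
        ("c1", 110, "+", strong),          # G on + -> discarded
        ("c1", 110, "-", strong),          # G on + is C on - -> 4mC
        ("c1", 20, "+", strong[:15]),      # cov 15: call but not primary
    ])
    calls = call_modifications(table, GENOME)
    keys = set(zip(calls["pos"], calls["strand"]))
    assert (5, "+") not in keys and (110, "+") not in keys
    assert {(6, "+"), (60, "+"), (110, "-"), (20, "+")} == keys
    by = calls.set_index(["pos", "strand"])
    assert by.loc[(6, "+"), "mark"] == "4mC"
    assert by.loc[(60, "+"), "mark"] == "6mA"
    assert by.loc[(110, "-"), "mark"] == "4mC"
    assert bool(by.loc[(6, "+"), "primary"])
    assert not bool(by.loc[(20, "+"), "primary"])


def test_call_outside_genome_raises():
    strong = np.exp(np.random.default_rng(2).normal(1.2, 0.4, 25))
    table = make_table([("c1", 99999, "+", strong)])
    with pytest.raises(ValueError, match="outside"):
        call_modifications(table, GENOME)


def test_filter_idempotence():
    rng = np.random.default_rng(3)
    rows = [("c1", i, "+", np.exp(rng.normal(rng.uniform(0, 1.5), 0.4,
                                             rng.integers(10, 40))))
            for i in range(40)]
    calls = call_modifications(make_table(rows), GENOME)
    refiltered = apply_filter(calls)
    pd.testing.assert_frame_equal(calls, refiltered)


def test_classify_fraction_bins_and_errors():
    assert classify_fraction(1.0) == "high"
    assert classify_fraction(0.8) == "high"
    assert classify_fraction(0.6) == "moderate"
    assert classify_fraction(0.5) == "moderate"
    assert classify_fraction(0.1) == "low"
    assert classify_fraction(0.05) == "sub_threshold"
    assert list(classify_fraction([0.3, 0.79])) == ["low", "moderate"]
    with pytest.raises(ValueError):
        classify_fraction(1.5)


def test_estimate_fraction_extremes_and_errors():
    mod = np.exp(np.log(3) + np.zeros(20))
    unmod = np.ones(20)
    assert estimate_fraction(mod, 0.0, np.log(3)) == 1.0
    assert estimate_fraction(unmod, 0.0, np.log(3)) == 0.0
    with pytest.raises(ValueError):
        estimate_fraction([], 0.0, 1.0)
    with pytest.raises(ValueError):
        estimate_fraction([1.0], 1.0, 0.5)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.05, 20.0), min_size=1, max_size=60),
       st.randoms(use_true_random=False))
def test_fraction_estimator_order_invariant_and_bounded(ipds, rnd):
    f1 = estimate_fraction(ipds, 0.0, math.log(3))
    shuffled = list(ipds)
    rnd.shuffle(shuffled)
    assert estimate_fraction(shuffled, 0.0, math.log(3)) == f1
    assert 0.0 <= f1 <= 1.0


def test_fraction_summary_hand_arithmetic():
    calls = pd.DataFrame({"mark": ["4mC"] * 4,
                          "fraction": [1.0, 1.0, 0.5, 0.5]})
    s = fraction_summary(calls).iloc[0]
    assert s["mean_fraction"] == pytest.approx(0.75)
    assert s["percent_fully_methylated"] == pytest.approx(50.0)
    assert s["n_high"] == 2 and s["n_moderate"] == 2 and s["n_low"] == 0
    assert math.isinf(s["high_low_ratio"])
    single = fraction_summary(pd.DataFrame({"mark": ["6mA"],
                                            "fraction": [0.74]}))
    assert single.iloc[0]["mean_fraction"] == pytest.approx(0.74)
    assert len(fraction_summary(pd.DataFrame({"mark": [], "fraction": []}))) \
        == 0


def test_recall_monotone_in_coverage_and_multiplier():
    """Recall never decreases along a coverage x effect-size grid."""
    rng = np.random.default_rng(7)
    n_sites = 300
    recalls = {}
    for cov in (10, 20, 40):
        for mult in (1.5, 2.0, 3.0):
            shift = math.log(mult)
            logs = rng.normal(shift, 0.4, size=(n_sites, cov))
            mean = logs.mean(axis=1)
            sd = logs.std(axis=1, ddof=1)
            p = stats.t.sf(mean / (sd / math.sqrt(cov)), df=cov - 1)
            recalls[(cov, mult)] = float(np.mean(-10 * np.log10(p) >= 22))
    for cov in (10, 20, 40):
        assert recalls[(cov, 1.5)] <= recalls[(cov, 2.0)] + 0.05
        assert recalls[(cov, 2.0)] <= recalls[(cov, 3.0)] + 0.05
    for mult in (1.5, 2.0, 3.0):
        assert recalls[(10, mult)] <= recalls[(20, mult)] + 0.05
        assert recalls[(20, mult)] <= recalls[(40, mult)] + 0.05


def test_welch_path_with_sampled_control():
    rng = np.random.default_rng(8)
    native = np.exp(rng.normal(1.1, 0.4, 30))
    control = np.exp(rng.normal(0.0, 0.4, 50))
    s = score_site(native, control)
    assert s > 22
    null = score_site(np.exp(rng.normal(0, 0.4, 30)),
                      np.exp(rng.normal(0, 0.4, 50)))
    assert null < s
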