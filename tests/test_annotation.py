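"""annotation: windowed signals, CGI context, overlaps, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agescreen import (
    IntervalSet,
    ProbeCoordinates,
    SignalTrack,
    ValidationError,
)
from agescreen.annotation import (
    aggregate_replicates,
    classify_cgi_context,
    compare_continuous,
    enrichment_test,
    overlap_categorical,
    rna_pre_scaling,
    rna_signal,
    window_mean_signal,
    zscore,
)


def _coords(positions, chroms=None, prefix="cg"):
    n = len(positions)
    chroms = chroms if chroms is not None else ["chrS"] * n
    return ProbeCoordinates(pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(positions, dtype=np.int64)},
        index=pd.Index([f"{prefix}{i:04d}" for i in range(n)], name="probe_id")))


def _track(rows, label="generic"):
    return SignalTrack(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value"]),
        statistic_label=label)


def _intervals(rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _brute_force_window_mean(track, chrom, pos, half):
    per = track.by_chrom()
    lo, hi = max(pos - half, 0), pos + half + 1
    if chrom not in per:
        return np.nan
    starts, ends, values = per[chrom]
    total = 0.0
    for base in range(lo, hi):
        for s, e, v in zip(starts, ends, values):
            if s <= base < e:
                total += v
                break
    return total / (hi - lo)


# ---------------------------------------------------------------------------
# Windowed continuous signal
# ---------------------------------------------------------------------------


def test_window_mean_half_covered():
    # value 4 over exactly half the window bases -> mean 2
    half = 10  # window of 21 bases [90, 111)
    track = _track([("chrS", 90, 111, 4.0)])
    # cover only 10 of 21: restrict track to [90,100)
    track = _track([("chrS", 90, 100, 4.0)])
    out = window_mean_signal(track, _coords([100]), half_width=half)
    assert out.iloc[0] == pytest.approx(4.0 * 10 / 21)


def test_window_mean_fully_covered_constant():
    track = _track([("chrS", 0, 1000, 2.5)])
    out = window_mean_signal(track, _coords([500]), half_width=200)
    assert out.iloc[0] == pytest.approx(2.5)


def test_window_mean_truncated_at_zero():
    track = _track([("chrS", 0, 1000, 1.0)])
    # pos 50 with half-width 200: window [0, 251), fully covered
    out = window_mean_signal(track, _coords([50]), half_width=200)
    assert out.iloc[0] == pytest.approx(1.0)


def test_window_mean_absent_chromosome_nan():
    track = _track([("chr1", 0, 100, 1.0)])
    out = window_mean_signal(track, _coords([50], chroms=["chr2"]),
                             half_width=10)
    assert np.isnan(out.iloc[0])


def test_window_mean_matches_brute_force_random():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n_iv = rng.integers(1, 12)
        starts = np.sort(rng.choice(np.arange(0, 2000, 5), size=n_iv,
                                    replace=False))
        ends = starts + rng.integers(1, 40, size=n_iv)
        ends = np.minimum(ends, np.append(starts[1:], 10**6))
        keep = starts < ends
        track = _track([("chrS", int(s), int(e), float(v))
                        for s, e, v in zip(starts[keep], ends[keep],
                                           rng.normal(size=keep.sum()))])
        positions = rng.integers(0, 2100, size=4)
        half = int(rng.integers(1, 60))
        out = window_mean_signal(track, _coords(positions), half_width=half)
        for pos, got in zip(positions, out):
            want = _brute_force_window_mean(track, "chrS", int(pos), half)
            assert got == pytest.approx(want, abs=1e-9)


def test_window_mean_chrom_sizes_truncation():
    track = _track([("chrS", 0, 100, 3.0)])
    # chromosome ends at 100: window [95, 100) has 5 bases, all covered
    out = window_mean_signal(track, _coords([99]), half_width=4,
                             chrom_sizes={"chrS": 100})
    assert out.iloc[0] == pytest.approx(3.0)


def test_window_half_width_must_be_positive():
    track = _track([("chrS", 0, 10, 1.0)])
    with pytest.raises(ValidationError):
        window_mean_signal(track, _coords([5]), half_width=0)


# ---------------------------------------------------------------------------
# Z-scores, replicates, RNA
# ---------------------------------------------------------------------------


def test_zscore_oracle():
    assert np.allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])


def test_zscore_degenerate():
    with pytest.raises(ValidationError, match="zero standard deviation"):
        zscore([2.0, 2.0, 2.0])
    with pytest.raises(ValidationError, match=">= 2"):
        zscore([1.0])


def test_aggregate_replicates_is_mean_of_zscores():
    idx = pd.Index([f"cg{i}" for i in range(4)])
    z1 = pd.Series([1.0, -1.0, 0.5, -0.5], index=idx)
    z2 = pd.Series([0.0, 2.0, -1.0, -1.0], index=idx)
    nfc = aggregate_replicates([z1, z2])
    assert np.allclose(nfc, (z1 + z2) / 2)
    assert nfc.name == "NFC"


def test_rna_pre_scaling_examples():
    assert rna_pre_scaling(3.0, 4.0) == pytest.approx(3.0)  # log2(8)
    assert rna_pre_scaling(0.0, 0.0) == 0.0


def test_rna_signal_matches_composition_oracle():
    rng = np.random.default_rng(3)
    positions = [100, 300, 500, 700]
    plus = _track([("chrS", p - 50, p + 51, float(v)) for p, v in
                   zip(positions, rng.uniform(0, 5, 4))], "sur+")
    minus = _track([("chrS", p - 50, p + 51, float(v)) for p, v in
                    zip(positions, rng.uniform(0, 5, 4))], "sur-")
    coords = _coords(positions)
    nre = rna_signal(plus, minus, coords, half_width=20)
    wp = window_mean_signal(plus, coords, 20)
    wm = window_mean_signal(minus, coords, 20)
    expected = zscore(np.log2(1 + wp.to_numpy() + wm.to_numpy()))
    assert np.allclose(nre.to_numpy(), expected)


def test_rna_signal_rejects_negative_values():
    plus = _track([("chrS", 0, 10, -1.0)], "sur+")
    minus = _track([("chrS", 0, 10, 1.0)], "sur-")
    with pytest.raises(ValidationError, match="negative signal"):
        rna_signal(plus, minus, _coords([5]))


# ---------------------------------------------------------------------------
# Categorical context
# ---------------------------------------------------------------------------


def test_overlap_half_open_boundaries():
    ivs = _intervals([("chrS", 100, 200)])
    out = overlap_categorical(_coords([99, 100, 199, 200]), ivs)
    assert out.tolist() == [False, True, True, False]


def test_overlap_matches_brute_force():
    rng = np.random.default_rng(8)
    starts = rng.integers(0, 5000, size=25)
    ends = starts + rng.integers(1, 300, size=25)
    ivs = _intervals([("chrS", int(s), int(e)) for s, e in zip(starts, ends)])
    positions = rng.integers(0, 5500, size=200)
    out = overlap_categorical(_coords(positions), ivs)
    for pos, got in zip(positions, out):
        want = any(s <= pos < e for s, e in zip(starts, ends))
        assert bool(got) == want


def test_overlap_missing_chromosome_false():
    ivs = _intervals([("chr1", 0, 100)])
    out = overlap_categorical(_coords([50], chroms=["chr2"]), ivs)
    assert not out.iloc[0]


def test_cgi_context_boundary_cases():
    cgis = _intervals([("chrS", 10000, 11000)])
    positions = [10500,          # inside -> island
                 10999, 11000,   # last base in, first base out
                 11500,          # shore
                 12999,          # d = 2000 -> shore (boundary rule)
                 13000,          # d = 2001 -> shelf
                 13500,          # shelf
                 14999,          # d = 4000 -> shelf (boundary rule)
                 15000,          # d = 4001 -> open-sea
                 16000,          # open sea
                 9999, 8000, 6000]  # left side: d=1 shore, d=2000 shore, d=4000 shelf
    out = classify_cgi_context(_coords(positions), cgis)
    expected = ["island", "island", "shore", "shore", "shore", "shelf",
                "shelf", "shelf", "open-sea", "open-sea",
                "shore", "shore", "shelf"]
    assert out.tolist() == expected


def test_cgi_context_partition_and_order_invariance():
    rng = np.random.default_rng(12)
    starts = np.sort(rng.choice(np.arange(0, 10**6, 100), 30, replace=False))
    cgi_rows = [("chrS", int(s), int(s + 500)) for s in starts]
    positions = rng.integers(0, 10**6, size=500)
    coords = _coords(positions)
    a = classify_cgi_context(coords, _intervals(cgi_rows))
    b = classify_cgi_context(coords, _intervals(cgi_rows[::-1]))
    assert a.equals(b)
    assert set(a.unique()) <= {"island", "shore", "shelf", "open-sea"}
    assert a.notna().all()


def test_cgi_context_nearest_of_two_islands():
    cgis = _intervals([("chrS", 0, 100), ("chrS", 10000, 10100)])
    # pos 3000: d=2901 to the left island, 7000 to the right -> shelf
    out = classify_cgi_context(_coords([3000, 1500, 9000]), cgis)
    assert out.tolist() == ["shelf", "shore", "shore"]


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def _feature(universe, with_feature):
    return pd.Series([p in with_feature for p in universe],
                     index=list(universe))


def test_enrichment_equal_proportions_or_one():
    universe = [f"cg{i}" for i in range(1100)]
    subset = universe[:100]
    with_feature = set(universe[:10]) | set(universe[100:200])
    feat = _feature(universe, with_feature)
    res = enrichment_test(subset, universe, feat)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.subset_with == 10 and res.control_with == 100
    assert (res.subset_with + res.subset_without + res.control_with
            + res.control_without) == len(universe)


def test_enrichment_8_2_2_8_oracle():
    universe = [f"cg{i}" for i in range(20)]
    subset = universe[:10]
    with_feature = set(universe[:8]) | set(universe[10:12])
    res = enrichment_test(subset, universe, _feature(universe, with_feature))
    assert res.odds_ratio == pytest.approx(16.0)
    # full hypergeometric enumeration with fixed margins
    N, K, n = 20, 10, 10
    p_obs = stats.hypergeom.pmf(8, N, K, n)
    p_manual = sum(stats.hypergeom.pmf(a, N, K, n)
                   for a in range(max(0, n + K - N), min(K, n) + 1)
                   if stats.hypergeom.pmf(a, N, K, n) <= p_obs * (1 + 1e-7))
    assert res.p_raw == pytest.approx(p_manual, rel=1e-10)


def test_enrichment_haldane_on_degenerate_table():
    universe = [f"cg{i}" for i in range(20)]
    subset = universe[:5]
    feat = _feature(universe, set(universe))  # feature present everywhere
    res = enrichment_test(subset, universe, feat)
    assert res.haldane
    assert res.odds_ratio == pytest.approx((5.5 * 0.5) / (0.5 * 15.5))
    assert res.p_raw == pytest.approx(1.0)


def test_enrichment_bonferroni_and_flag():
    universe = [f"cg{i}" for i in range(40)]
    subset = universe[:20]
    with_feature = set(universe[:18]) | set(universe[20:22])
    feat = _feature(universe, with_feature)
    res1 = enrichment_test(subset, universe, feat, n_tests=1)
    res5 = enrichment_test(subset, universe, feat, n_tests=5)
    assert res5.p_adjusted == pytest.approx(min(1.0, res1.p_raw * 5))
    assert res1.significant == (res1.p_raw < 0.01)


def test_enrichment_input_validation():
    universe = ["a", "b", "c"]
    feat = _feature(universe, {"a"})
    with pytest.raises(ValidationError, match="empty probe subset"):
        enrichment_test([], universe, feat)
    with pytest.raises(ValidationError, match="contained in the universe"):
        enrichment_test(["z"], universe, feat)
    with pytest.raises(ValidationError, match="empty control"):
        enrichment_test(universe, universe, feat)


def test_designed_enhancer_enrichment(default_cohort):
    cohort = default_cohort
    roles = cohort.truth.probe_roles
    subset = list(roles.index[roles["role"] == "disease-hypo"])
    res = enrichment_test(subset, list(roles.index), roles["in_enhancer"],
                          feature_name="enhancer")
    assert res.odds_ratio > 1.0
    assert res.p_adjusted < 0.01


def test_enhancer_or_near_designed_odds_at_20k_probes():
    from agescreen import SimulationConfig, generate_cohort

    cfg = SimulationConfig(seed=77, n_probes=20000)
    roles = generate_cohort(cfg).truth.probe_roles
    subset = list(roles.index[roles["role"] == "disease-hypo"])
    res = enrichment_test(subset, list(roles.index), roles["in_enhancer"])
    designed = cfg.enhancer_odds
    assert designed / 2 <= res.odds_ratio <= designed * 2
    assert res.p_adjusted < 0.01


# ---------------------------------------------------------------------------
# Continuous comparisons
# ---------------------------------------------------------------------------


def test_compare_continuous_3v3_extreme():
    res = compare_continuous([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.median_subset == 5.0 and res.median_control == 2.0
    assert res.n_subset == 3 and res.n_control == 3


def test_compare_continuous_all_tied():
    res = compare_continuous([2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.p_value == 1.0
    assert res.all_tied


def test_compare_continuous_nan_dropped():
    res = compare_continuous([1.0, np.nan, 3.0], [2.0, 4.0])
    assert res.n_subset == 2 and res.n_control == 2


def test_compare_continuous_null_pvalues_uniform():
    # identical distributions: p-values pass a KS test against uniform
    rng = np.random.default_rng(33)
    pvals = [compare_continuous(rng.normal(size=9), rng.normal(size=10)).p_value
             for _ in range(400)]
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.05
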