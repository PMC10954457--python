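"""Per-nucleotide analytics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from probescape import (
    AnalysisError,
    InteractionSet,
    Profile,
    SecondaryStructure,
    SequenceRecord,
)
from probescape import profile_analysis as pa


def seq_of(n):
    return SequenceRecord("s", "ACGU" * (n // 4) + "ACGU"[: n % 4])


def profile_of(values, stderr=None, nodata=None):
    values = np.asarray(values, float)
    return Profile(seq_of(values.size), values, stderr=stderr, nodata=nodata)


# --- normalization -----------------------------------------------------------

def test_percentile_normalization_arithmetic():
    values = np.arange(1.0, 101.0)
    out = pa.normalize_values(values, method="percentile")
    # divide by mean(91..99) = 95
    assert out[94] == pytest.approx(1.0)
    assert out[0] == pytest.approx(1.0 / 95.0)


def test_percentile_normalization_constant_vector():
    out = pa.normalize_values(np.full(20, 3.5), method="percentile")
    assert np.allclose(out, 1.0)


def test_normalization_needs_ten_values():
    with pytest.raises(AnalysisError, match="10"):
        pa.normalize_values(np.array([1.0] * 9))
    with pytest.raises(AnalysisError, match="10"):
        pa.normalize_values(np.full(20, np.nan))


def test_boxplot_normalization_discards_outliers():
    values = np.concatenate([np.linspace(0.1, 2.0, 99), [1000.0]])
    out = pa.normalize_values(values, method="boxplot")
    # the outlier must not dominate the factor
    assert np.nanmax(out[:-1]) < 2.0


# --- windowed median ---------------------------------------------------------

def oracle_windowed_median(values, w, edge="truncate"):
    values = np.asarray(values, float)
    n = values.size
    half = w // 2
    out = np.full(n, np.nan)
    for c in range(n):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if edge == "nodata" and hi - lo < w:
            continue
        window = values[lo:hi]
        window = window[np.isfinite(window)]
        if window.size:
            out[c] = np.median(np.sort(window))
    return out


def test_windowed_median_hand_example():
    out = pa.windowed_median([1, 2, 3, 100, 5], pa.WindowParams(w=3))
    assert out.tolist() == [1.5, 2, 3, 5, 52.5]


def test_windowed_median_constant_and_w1():
    assert np.allclose(pa.windowed_median(np.full(10, 7.0), pa.WindowParams(w=3)), 7.0)
    vals = np.arange(5.0)
    assert np.allclose(pa.windowed_median(vals, pa.WindowParams(w=1)), vals)


def test_even_window_rejected():
    with pytest.raises(AnalysisError, match="odd"):
        pa.WindowParams(w=4)


def test_windowed_median_matches_sort_oracle_on_random_vectors(rng):
    for _ in range(1000):
        n = int(rng.integers(3, 40))
        values = rng.normal(size=n)
        values[rng.random(n) < 0.15] = np.nan
        w = int(rng.choice([1, 3, 5, 9]))
        edge = str(rng.choice(["truncate", "nodata"]))
        ours = pa.windowed_median(values, pa.WindowParams(w=w, edge=edge))
        theirs = oracle_windowed_median(values, w, edge)
        assert np.allclose(ours, theirs, equal_nan=True)


# --- Shannon entropy ---------------------------------------------------------

def _pairprobs(n, rows):
    df = pd.DataFrame(rows, columns=["i", "j", "probability"])
    return InteractionSet(seq_of(n), df, default_metric="probability")


def test_entropy_examples():
    s = pa.shannon_entropy(_pairprobs(10, [(2, 8, 1.0)]))
    assert s.values[1] == 0.0          # p=1 contributes nothing
    assert s.values[0] == 0.0          # no partners
    s = pa.shannon_entropy(_pairprobs(10, [(2, 8, 0.5), (2, 9, 0.5)]))
    assert s.values[1] == pytest.approx(-2 * 0.5 * np.log10(0.5), abs=1e-9)


def test_entropy_matches_direct_summation_and_is_nonnegative(rng):
    for _ in range(1000):
        n = int(rng.integers(6, 25))
        k = int(rng.integers(1, 8))
        rows = []
        for _ in range(k):
            i = int(rng.integers(1, n))
            j = int(rng.integers(i + 1, n + 1))
            rows.append((i, j, float(rng.uniform(0.01, 1.0))))
        iset = _pairprobs(n, pd.DataFrame(rows, columns=["i", "j", "probability"])
                          .drop_duplicates(["i", "j"]))
        s = pa.shannon_entropy(iset)
        direct = np.zeros(n)
        for _, row in iset.data.iterrows():
            t = -row["probability"] * np.log10(row["probability"])
            direct[int(row["i"]) - 1] += t
            direct[int(row["j"]) - 1] += t
        assert np.allclose(s.values, direct)
        assert (s.values >= 0).all()


def test_entropy_maximal_for_equiprobable_partners():
    # k equiprobable partners summing to 1 give entropy log10(k)
    k = 4
    rows = [(1, 2 + m, 1.0 / k) for m in range(k)]
    s = pa.shannon_entropy(_pairprobs(10, rows))
    assert s.values[0] == pytest.approx(np.log10(k), abs=1e-12)


# --- lowSS -------------------------------------------------------------------

def oracle_lowss_positions(react, entropy, w, r_max, s_max):
    mr = oracle_windowed_median(react, w)
    ms = oracle_windowed_median(entropy, w)
    with np.errstate(invalid="ignore"):
        return (mr < r_max) & (ms < s_max)


def _lowss_fixture(n=200, block=(50, 120)):
    react = np.full(n, 0.9)
    entropy = np.full(n, 0.5)
    lo, hi = block
    react[lo - 1: hi] = 0.05
    entropy[lo - 1: hi] = 0.02
    return profile_of(react), profile_of(entropy)


def test_lowss_all_low_is_one_region():
    react = profile_of(np.full(200, 0.1))
    entropy = profile_of(np.full(200, 0.01))
    regions = pa.find_lowss(react, entropy, pa.LowSSParams())
    assert [(r.start, r.end, r.index) for r in regions] == [(1, 200, 1)]


def test_lowss_all_high_is_zero_regions():
    react = profile_of(np.full(200, 0.9))
    entropy = profile_of(np.full(200, 0.01))
    assert pa.find_lowss(react, entropy, pa.LowSSParams()) == []


def test_lowss_block_matches_bruteforce_window_oracle():
    react, entropy = _lowss_fixture()
    params = pa.LowSSParams(window=pa.WindowParams(w=51))
    regions = pa.find_lowss(react, entropy, params)
    oracle = oracle_lowss_positions(react.values, entropy.values, 51, 0.4, 0.15)
    starts_ends = []
    pos = np.flatnonzero(oracle) + 1
    if pos.size:
        breaks = np.flatnonzero(np.diff(pos) > 1)
        starts = [pos[0]] + [pos[b + 1] for b in breaks]
        ends = [pos[b] for b in breaks] + [pos[-1]]
        starts_ends = list(zip(starts, ends))
    assert [(r.start, r.end) for r in regions] == starts_ends
    assert len(regions) == 1


def test_lowss_monotone_in_thresholds():
    react, entropy = _lowss_fixture()
    base = pa.find_lowss(react, entropy, pa.LowSSParams(r_max=0.4, s_max=0.15))
    wider = pa.find_lowss(react, entropy, pa.LowSSParams(r_max=0.8, s_max=0.6))
    base_pos = {p for r in base for p in range(r.start, r.end + 1)}
    wider_pos = {p for r in wider for p in range(r.start, r.end + 1)}
    assert base_pos <= wider_pos


def test_lowss_merge_gap():
    n = 300
    react = np.full(n, 0.9)
    entropy = np.full(n, 0.5)
    for lo, hi in ((40, 110), (114, 180)):
        react[lo - 1: hi] = 0.05
        entropy[lo - 1: hi] = 0.02
    params = pa.LowSSParams(window=pa.WindowParams(w=11))
    split = pa.find_lowss(profile_of(react), profile_of(entropy), params)
    params_merged = pa.LowSSParams(window=pa.WindowParams(w=11), merge_gap=20)
    merged = pa.find_lowss(profile_of(react), profile_of(entropy), params_merged)
    assert len(merged) < len(split) or len(split) == 1


# --- deltaSHAPE-style difference detection -----------------------------------

def test_delta_identical_profiles_no_sites():
    values = np.linspace(0, 2, 60)
    err = np.full(60, 0.05)
    a = profile_of(values, stderr=err)
    b = profile_of(values.copy(), stderr=err.copy())
    result = pa.delta_shape(a, b)
    assert not result.sites.any()


def test_delta_detects_contiguous_gain():
    values = np.full(60, 0.5)
    err = np.full(60, 0.01)
    shifted = values.copy()
    shifted[20:30] += 2.0
    a = profile_of(shifted, stderr=err)
    b = profile_of(values, stderr=err)
    result = pa.delta_shape(a, b)
    flagged = set(np.flatnonzero(result.sites) + 1)
    core = set(range(23, 29))  # inside the block, clear of smoothing edges
    assert core <= flagged
    assert flagged <= set(range(17, 34))  # nothing outside the smoothed block


def test_delta_huge_errors_suppress_sites():
    values = np.full(60, 0.5)
    shifted = values.copy()
    shifted[20:30] += 2.0
    a = profile_of(shifted, stderr=np.full(60, 50.0))
    b = profile_of(values, stderr=np.full(60, 50.0))
    assert not pa.delta_shape(a, b).sites.any()


def test_delta_requires_stderr():
    a = profile_of(np.zeros(20))
    b = profile_of(np.zeros(20), stderr=np.full(20, 0.1))
    with pytest.raises(AnalysisError, match="standard errors"):
        pa.delta_shape(a, b)


# --- windowed AUROC ----------------------------------------------------------

def oracle_auroc(values, positives):
    pos = values[positives]
    neg = values[~positives]
    if pos.size == 0 or neg.size == 0:
        return np.nan
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (pos.size * neg.size)


def test_auroc_hand_example():
    values = np.array([0.1, 0.2, 0.15, 0.9])
    positives = np.array([False, False, True, True])
    assert pa.auroc(values, positives) == pytest.approx(0.75)


def test_auroc_edges():
    v = np.array([0.1, 0.2, 0.8, 0.9])
    assert pa.auroc(v, np.array([False, False, True, True])) == 1.0
    assert pa.auroc(np.full(6, 1.0),
                    np.array([True, False] * 3)) == pytest.approx(0.5)


def test_windowed_auroc_matches_exhaustive_pair_counting(rng):
    checked = 0
    for _ in range(60):
        n = int(rng.integers(10, 30))
        seq = seq_of(n)
        values = rng.normal(size=n)
        paired = rng.random(n) < 0.5
        pairs = set()
        idx = np.flatnonzero(paired) + 1
        for a, b in zip(idx[::2], idx[1::2]):
            pairs.add((int(a), int(b)))
        paired = np.zeros(n, dtype=bool)
        for i, j in pairs:
            paired[i - 1] = paired[j - 1] = True
        ss = SecondaryStructure(sequence=seq, pairs=pairs)
        prof = Profile(seq, values)
        w = int(rng.choice([5, 9, 15]))
        track = pa.windowed_auroc(prof, ss, pa.WindowParams(w=w))
        half = w // 2
        for c in range(n):
            lo, hi = max(0, c - half), min(n, c + half + 1)
            expected = oracle_auroc(values[lo:hi], ~paired[lo:hi])
            got = track.values[c]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
                checked += 1
    assert checked >= 1000


# --- regression --------------------------------------------------------------

def test_regression_identity_and_affine():
    values = np.linspace(0.1, 2.0, 30)
    a = profile_of(values)
    same = pa.compare_profiles(a, profile_of(values.copy()))
    assert (same.r, same.slope, same.intercept) == pytest.approx((1.0, 1.0, 0.0))
    affine = pa.compare_profiles(a, profile_of(2 * values + 1))
    assert affine.r == pytest.approx(1.0)
    assert affine.slope == pytest.approx(2.0)
    assert affine.intercept == pytest.approx(1.0)


def test_regression_r_matches_covariance_formula():
    x = np.array([0.1, 0.4, 0.2, 0.9, 1.4, 0.3, 0.8, 1.1, 0.05, 0.6])
    y = np.array([0.2, 0.3, 0.25, 1.1, 1.2, 0.2, 0.9, 1.0, 0.1, 0.5])
    result = pa.compare_profiles(profile_of(x), profile_of(y))
    r_direct = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
    assert result.r == pytest.approx(r_direct, abs=1e-12)
    assert result.n == 10


def test_regression_symmetry_and_slope_product():
    rng = np.random.default_rng(7)
    x = rng.normal(size=40)
    y = 0.6 * x + rng.normal(scale=0.4, size=40)
    ab = pa.compare_profiles(profile_of(x), profile_of(y))
    ba = pa.compare_profiles(profile_of(y), profile_of(x))
    assert ab.r == pytest.approx(ba.r)
    assert ab.slope * ba.slope == pytest.approx(ab.r ** 2)
    assert ab.slope * ba.slope <= 1.0


def test_regression_needs_three_shared_positions():
    nod = np.array([False, False, True, True])
    a = Profile(seq_of(4), [1, 2, 3, 4], nodata=nod)
    b = Profile(seq_of(4), [1, 2, 3, 4], nodata=np.array([True, False, False, False]))
    with pytest.raises(AnalysisError, match="3"):
        pa.compare_profiles(a, b)
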