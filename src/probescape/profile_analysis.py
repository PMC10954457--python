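"""Per-nucleotide analytics.

Covers reactivity normalization, windowed medians, Shannon entropy of
pairing probabilities, detection of low-reactivity/low-entropy (lowSS)
regions, error-aware two-condition difference detection (deltaSHAPE-style),
windowed AUROC of a profile against a structure model, and inter-profile
regression.

Conventions: windows are centred and odd-length (default 51 nt, the
community standard for long-RNA median smoothing); entropy uses log base
10, consistent with the 0.15 lowSS threshold; no-data positions are
excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InteractionSet, Profile, SecondaryStructure, SequenceRecord
from .errors import AnalysisError


@dataclass
class WindowParams:
    """Centred window of odd length ``w``; ``edge`` is 'truncate' (shrink
    the window at sequence ends) or 'nodata' (ends become no-data)."""

    w: int = 51
    edge: str = "truncate"

    def __post_init__(self) -> None:
        if self.w < 1 or self.w % 2 == 0:
            raise AnalysisError(f"window length must be odd and >= 1, got {self.w}")
        if self.edge not in ("truncate", "nodata"):
            raise AnalysisError(f"edge policy {self.edge!r} not truncate|nodata")


@dataclass
class LowSSParams:
    """Thresholds for lowSS calling: windowed median reactivity < r_max and
    windowed median Shannon entropy < s_max."""

    r_max: float = 0.4
    s_max: float = 0.15
    window: WindowParams = field(default_factory=WindowParams)
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.s_max <= 0:
            raise AnalysisError("lowSS thresholds must be positive")


@dataclass
class LowSSRegion:
    start: int
    end: int
    index: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int
    table: pd.DataFrame  # paired values, for KDE rendering


@dataclass
class DeltaShapeResult:
    difference: np.ndarray   # smoothed a - smoothed b
    z_factor: np.ndarray
    standard_score: np.ndarray
    sites: np.ndarray        # boolean site mask


@dataclass
class AurocTrack:
    values: np.ndarray  # per-position AUROC, NaN where a window lacks a class
    window: int


def _check_same_sequence(a, b, what="profiles") -> None:
    sa = getattr(a, "sequence", a)
    sb = getattr(b, "sequence", b)
    if not sa.matches(sb):
        raise AnalysisError(
            f"{what} are on different sequences ({sa.id!r} vs {sb.id!r})"
        )


def normalize_values(raw: np.ndarray, method: str = "boxplot") -> np.ndarray:
    """Normalize raw reactivities to the conventional ~0-2 scale.

    boxplot: exclude outliers above Q3 + 1.5*IQR (capped at 10% of the
    data), then divide by the mean of the top 10% of what remains.
    percentile: divide by the mean of values between the 90th and 99th
    percentiles.  Requires >= 10 finite values.
    """
    raw = np.asarray(raw, dtype=float)
    valid = raw[np.isfinite(raw)]
    if valid.size < 10:
        raise AnalysisError(
            f"normalization needs >= 10 valid values, got {valid.size}"
        )
    if method == "percentile":
        p90, p99 = np.percentile(valid, [90, 99])
        window = valid[(valid >= p90) & (valid <= p99)]
        factor = window.mean()
    elif method == "boxplot":
        q1, q3 = np.percentile(valid, [25, 75])
        cutoff = q3 + 1.5 * (q3 - q1)
        srt = np.sort(valid)
        n_out = int((srt > cutoff).sum())
        n_out = min(n_out, valid.size // 10)  # outlier count capped at 10%
        kept = srt[: valid.size - n_out] if n_out else srt
        top = kept[-max(1, kept.size // 10):]
        factor = top.mean()
    else:
        raise AnalysisError(f"unknown normalization method {method!r}")
    if factor == 0 or not np.isfinite(factor):
        raise AnalysisError("normalization factor is zero or undefined")
    return raw / factor


def normalize_profile(profile: Profile, method: str = "boxplot") -> Profile:
    source = profile.raw if profile.raw is not None else profile.values
    values = normalize_values(np.where(profile.nodata, np.nan, source), method)
    stderr = None
    if profile.stderr is not None:
        # errors scale with the values
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.nanmedian(values / np.where(source == 0, np.nan, source))
        stderr = profile.stderr * scale
    return Profile(profile.sequence, values, raw=source, stderr=stderr,
                   nodata=profile.nodata.copy(), metric=profile.metric,
                   breakpoints=profile.breakpoints, colors=profile.colors)


def windowed_median(values: np.ndarray, params: WindowParams | None = None,
                    nodata: np.ndarray | None = None) -> np.ndarray:
    """Centred running median; no-data excluded per window; all-no-data
    windows give NaN."""
    params = params or WindowParams()
    values = np.asarray(values, dtype=float)
    if nodata is not None:
        values = np.where(np.asarray(nodata, bool), np.nan, values)
    series = pd.Series(values)
    out = series.rolling(params.w, center=True, min_periods=1).median().to_numpy()
    if params.edge == "nodata":
        half = params.w // 2
        if half:
            out[:half] = np.nan
            out[-half:] = np.nan
    return out


def windowed_median_profile(profile: Profile,
                            params: WindowParams | None = None) -> np.ndarray:
    return windowed_median(profile.values, params, nodata=profile.nodata)


def shannon_entropy(pairprobs: InteractionSet) -> Profile:
    """Per-nucleotide Shannon entropy s_i = -sum_j p_ij log10 p_ij.

    The sum runs over every recorded partner of i in either orientation;
    positions with no recorded partner have zero entropy (a fully resolved
    pairing state).
    """
    if "probability" not in pairprobs.data.columns:
        raise AnalysisError(
            "interaction set has no 'probability' statistic; "
            f"available: {pairprobs.statistic_names}"
        )
    n = pairprobs.sequence.length
    s = np.zeros(n)
    p = pairprobs.data["probability"].to_numpy(float)
    terms = -p * np.log10(p)
    for (i, j), t in zip(pairprobs.data[["i", "j"]].to_numpy(int), terms):
        s[i - 1] += t
        s[j - 1] += t
    return Profile(pairprobs.sequence, s, metric="shannon_entropy",
                   nodata=np.zeros(n, dtype=bool))


def find_lowss(reactivity: Profile, entropy: Profile,
               params: LowSSParams | None = None) -> list[LowSSRegion]:
    """Contiguous regions where both windowed medians are below threshold.

    A position is low iff its windowed median reactivity < r_max AND its
    windowed median entropy < s_max (windows where either median is
    undefined are never low).  Maximal runs become regions numbered
    5'-to-3'; runs separated by fewer than ``merge_gap`` nt are merged.
    """
    params = params or LowSSParams()
    _check_same_sequence(reactivity, entropy)
    med_r = windowed_median_profile(reactivity, params.window)
    med_s = windowed_median_profile(entropy, params.window)
    with np.errstate(invalid="ignore"):
        low = (med_r < params.r_max) & (med_s < params.s_max)
    low = np.asarray(low, bool)
    runs: list[list[int]] = []
    start = None
    for pos in range(1, low.size + 1):
        if low[pos - 1] and start is None:
            start = pos
        elif not low[pos - 1] and start is not None:
            runs.append([start, pos - 1])
            start = None
    if start is not None:
        runs.append([start, low.size])
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [LowSSRegion(start=s, end=e, index=k + 1)
            for k, (s, e) in enumerate(merged)]


def _smooth(values: np.ndarray, nodata: np.ndarray, w: int) -> np.ndarray:
    masked = np.where(nodata, np.nan, values)
    return pd.Series(masked).rolling(w, center=True, min_periods=1).mean().to_numpy()


def delta_shape(profile_a: Profile, profile_b: Profile, smoothing: int = 5,
                z_multiplier: float = 1.96, score_cutoff: float = 1.0,
                min_hits: int = 3, span: int = 5) -> DeltaShapeResult:
    """Error-aware detection of reactivity differences between conditions.

    Values and standard errors of both profiles are smoothed over centred
    ``smoothing``-nt windows; the smoothed difference d_i gets a Z-factor
    1 - z_multiplier*(sem_a + sem_b)/|d_i| and a standard score from the
    distribution of d.  A position is a site when its Z-factor is positive,
    its |standard score| >= score_cutoff, and at least ``min_hits`` of the
    ``span`` surrounding positions also qualify.
    """
    _check_same_sequence(profile_a, profile_b)
    for name, p in (("first", profile_a), ("second", profile_b)):
        if p.stderr is None:
            raise AnalysisError(f"{name} profile has no standard errors")
    sa = _smooth(profile_a.values, profile_a.nodata, smoothing)
    sb = _smooth(profile_b.values, profile_b.nodata, smoothing)
    ea = _smooth(profile_a.stderr, profile_a.nodata, smoothing)
    eb = _smooth(profile_b.stderr, profile_b.nodata, smoothing)
    d = sa - sb
    with np.errstate(divide="ignore", invalid="ignore"):
        z_factor = 1.0 - z_multiplier * (ea + eb) / np.abs(d)
    finite = np.isfinite(d)
    mu, sd = np.nanmean(d[finite]), np.nanstd(d[finite])
    standard = (d - mu) / sd if sd > 0 else np.zeros_like(d)
    hits = (z_factor > 0) & (np.abs(standard) >= score_cutoff) & finite
    counts = pd.Series(hits.astype(float)).rolling(
        span, center=True, min_periods=1).sum().to_numpy()
    sites = hits & (counts >= min_hits)
    return DeltaShapeResult(difference=d, z_factor=z_factor,
                            standard_score=standard, sites=sites)


def auroc(values: np.ndarray, positives: np.ndarray) -> float:
    """AUROC of values separating a boolean positive class, ties counted
    half (Mann-Whitney convention).  NaN if a class is missing."""
    values = np.asarray(values, float)
    positives = np.asarray(positives, bool)
    pos, neg = values[positives], values[~positives]
    if pos.size == 0 or neg.size == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return u / (pos.size * neg.size)


def windowed_auroc(profile: Profile, ss: SecondaryStructure,
                   params: WindowParams | None = None) -> AurocTrack:
    """Per-position windowed AUROC of reactivity classifying unpaired
    (positive class) vs paired nucleotides."""
    params = params or WindowParams()
    _check_same_sequence(profile, ss)
    n = profile.sequence.length
    paired = ss.paired_mask()
    valid = ~profile.nodata & np.isfinite(profile.values)
    half = params.w // 2
    out = np.full(n, np.nan)
    for center in range(n):
        lo, hi = max(0, center - half), min(n, center + half + 1)
        if params.edge == "nodata" and hi - lo < params.w:
            continue
        sel = valid[lo:hi]
        if not sel.any():
            continue
        out[center] = auroc(profile.values[lo:hi][sel], ~paired[lo:hi][sel])
    return AurocTrack(values=out, window=params.w)


def compare_profiles(profile_a: Profile, profile_b: Profile) -> RegressionResult:
    """Least-squares regression and Pearson r over co-valid positions."""
    valid = (~profile_a.nodata & ~profile_b.nodata &
             np.isfinite(profile_a.values) & np.isfinite(profile_b.values))
    n = int(valid.sum())
    if n < 3:
        raise AnalysisError(f"profiles share only {n} valid positions (need >= 3)")
    x, y = profile_a.values[valid], profile_b.values[valid]
    fit = stats.linregress(x, y)
    table = pd.DataFrame({
        "position": np.arange(1, profile_a.sequence.length + 1)[valid],
        "a": x, "b": y,
    })
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), n=n, table=table)
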