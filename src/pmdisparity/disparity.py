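"""Absolute and relative exposure-disparity statistics.

Absolute disparity is the spread of a concentration distribution, measured
as the 99th-minus-1st percentile (the trimming itself is the outlier
exclusion). Relative disparity between two subgroups is a standardized mean
difference on natural-log district-level PWCs:

    z = (M1 - M2) / S_pooled,
    S_pooled = sqrt(((n1-1) S1^2 + (n2-1) S2^2) / (n1 + n2 - 2))

with normal-theory CI and two-sided p from the Hedges-Olkin large-sample
standard error of a standardized mean difference. A |z| at or below 0.01 is
flagged negligible. Distributional differences between subgroup-weighted
cluster exposure distributions are tested with a weighted two-sample
Kolmogorov-Smirnov statistic whose p-value uses effective sample sizes
(sum w)^2 / sum w^2; with unit weights it reproduces the classical
asymptotic test exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_SCHEME

logger = logging.getLogger(__name__)

NEGLIGIBLE_Z = 0.01


# --------------------------------------------------------------------------
# quantiles

def weighted_quantile(values, q, weights=None) -> np.ndarray:
    """Linear-interpolation quantiles, with a weighted generalization.

    Unweighted input uses the standard linear (Hyndman-Fan type 7)
    convention. With weights, sorted values get plotting positions
    p_k = (C_k - w_k) / (S - w_last) from cumulative weights C_k (total S,
    w_last the weight of the largest value), which reduce exactly to the
    type-7 positions (k-1)/(n-1) under equal weights.
    """
    x = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantiles must be in [0, 1]")
    if weights is None:
        return np.quantile(x, q, method="linear")
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative, match values, and not all be zero")
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    denom = cw[-1] - ws[-1]
    if denom <= 0:  # single effective point
        return np.full(q.shape, xs[np.argmax(ws > 0)] if (ws > 0).any() else np.nan)
    p = (cw - ws) / denom
    return np.interp(q, p, xs)


# --------------------------------------------------------------------------
# absolute disparity

@dataclass
class AbsoluteDisparity:
    """Percentile-range spread of a concentration distribution."""

    p01: float
    p99: float
    value: float  # p99 - p01
    n: int
    region_id: str | None = None
    stratum: str | None = None
    subgroup: str | None = None


def absolute_disparity(values, weights=None, lower: float = 0.01,
                       upper: float = 0.99, **meta) -> AbsoluteDisparity:
    """99th-minus-1st percentile of the exposure distribution.

    Percentiles use linear interpolation; weighted quantiles when weights
    are given. Requires at least two finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values")
    w = None if weights is None else np.asarray(weights, dtype=float)[finite]
    x = x[finite]
    lo, hi = weighted_quantile(x, [lower, upper], w)
    return AbsoluteDisparity(p01=float(lo), p99=float(hi),
                             value=float(hi - lo), n=int(x.size), **meta)


# --------------------------------------------------------------------------
# relative disparity (standardized mean difference on log PWCs)

@dataclass
class ZScoreResult:
    """Standardized mean difference of log district PWCs between two groups."""

    z: float
    m1: float
    m2: float
    s1: float
    s2: float
    n1: int
    n2: int
    s_pooled: float
    ci95: tuple[float, float]
    p_value: float
    negligible: bool
    degenerate: bool = False


def z_score(pwc_group1, pwc_group2,
            negligible_threshold: float = NEGLIGIBLE_Z) -> ZScoreResult:
    """Relative disparity between two vectors of positive district PWCs.

    Inputs are natural-log transformed; z = (M1 - M2)/S_pooled. A positive z
    means group 1's PWCs are higher (by z pooled standard deviations). CI
    and p use the Hedges-Olkin standard error
    sqrt((n1+n2)/(n1 n2) + z^2 / (2 (n1+n2-2))). When both groups are
    exactly constant the statistic is defined as 0 with ``degenerate=True``.
    """
    a = np.asarray(pwc_group1, dtype=float)
    b = np.asarray(pwc_group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two district PWCs")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("PWCs must be positive (log transform)")
    la, lb = np.log(a), np.log(b)
    n1, n2 = la.size, lb.size
    m1, m2 = la.mean(), lb.mean()
    s1, s2 = la.std(ddof=1), lb.std(ddof=1)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    s_pooled = float(np.sqrt(sp2))
    if s_pooled == 0:
        return ZScoreResult(z=0.0, m1=float(m1), m2=float(m2), s1=float(s1),
                            s2=float(s2), n1=n1, n2=n2, s_pooled=0.0,
                            ci95=(0.0, 0.0), p_value=1.0, negligible=True,
                            degenerate=True)
    z = float((m1 - m2) / s_pooled)
    se = float(np.sqrt((n1 + n2) / (n1 * n2) + z**2 / (2 * (n1 + n2 - 2))))
    crit = stats.norm.ppf(0.975)
    ci = (z - crit * se, z + crit * se)
    p = float(2 * stats.norm.sf(abs(z) / se))
    return ZScoreResult(z=z, m1=float(m1), m2=float(m2), s1=float(s1),
                        s2=float(s2), n1=n1, n2=n2, s_pooled=s_pooled,
                        ci95=ci, p_value=p,
                        negligible=abs(z) <= negligible_threshold)


# --------------------------------------------------------------------------
# weighted Kolmogorov-Smirnov

@dataclass
class KSResult:
    d: float
    p_value: float
    n_eff1: float
    n_eff2: float


def ks_compare(sample1, sample2, weights1=None, weights2=None) -> KSResult:
    """Weighted two-sample KS test.

    D is the sup-distance between the weighted empirical CDFs. The p-value
    uses the asymptotic two-sample distribution with effective sample sizes
    n_eff = (sum w)^2 / sum w^2 substituted for the counts; with unit
    weights both D and p match the classical asymptotic test.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both samples must be nonempty")
    w1 = np.ones(x1.size) if weights1 is None else np.asarray(weights1, dtype=float)
    w2 = np.ones(x2.size) if weights2 is None else np.asarray(weights2, dtype=float)
    if (w1 < 0).any() or (w2 < 0).any():
        raise ValueError("weights must be non-negative")
    t1, t2 = w1.sum(), w2.sum()
    if t1 == 0 or t2 == 0:
        raise ValueError("zero total weight")
    grid = np.unique(np.concatenate([x1, x2]))
    o1 = np.argsort(x1, kind="mergesort")
    o2 = np.argsort(x2, kind="mergesort")
    c1 = np.concatenate([[0.0], np.cumsum(w1[o1]) / t1])
    c2 = np.concatenate([[0.0], np.cumsum(w2[o2]) / t2])
    f1 = c1[np.searchsorted(x1[o1], grid, side="right")]
    f2 = c2[np.searchsorted(x2[o2], grid, side="right")]
    d = float(np.abs(f1 - f2).max())
    n1e = t1**2 / (w1**2).sum()
    n2e = t2**2 / (w2**2).sum()
    en = n1e * n2e / (n1e + n2e)
    p = float(np.clip(stats.kstwo.sf(d, int(round(en))), 0.0, 1.0))
    return KSResult(d=d, p_value=p, n_eff1=float(n1e), n_eff2=float(n2e))


# --------------------------------------------------------------------------
# burdened-district counts

def count_burdened_districts(exposures: pd.DataFrame, clusters: pd.DataFrame,
                             partition: str, reference: str,
                             alpha: float = 0.1,
                             scheme: Mapping[str, Sequence[str]] | None = None,
                             stratum: str | None = None) -> pd.DataFrame:
    """Districts where each subgroup's PWC exceeds the reference's (p < alpha).

    Direction is the sign of PWC_subgroup - PWC_reference within the
    district; significance is a weighted KS test between the subgroup- and
    reference-weighted cluster exposure distributions (weights = effective
    populations). Districts with fewer than two clusters, or zero effective
    population for either subgroup, are not evaluable. Returns one row per
    non-reference subgroup with ``n_higher_significant`` and
    ``n_evaluable``.
    """
    scheme = dict(scheme or DEFAULT_SCHEME)
    if partition not in scheme:
        raise ValueError(f"unknown partition {partition!r}")
    groups = list(scheme[partition])
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not in partition {partition!r}")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    df = exposures.merge(clusters, on="cluster_id", how="inner")
    if stratum is not None:
        df = df[df["stratum"] == stratum]
    rows = []
    for g in groups:
        if g == reference:
            continue
        n_sig = 0
        n_eval = 0
        for _, d in df.groupby("district_id"):
            if len(d) < 2:
                logger.info("district with <2 clusters excluded")
                continue
            conc = d["concentration"].to_numpy()
            pg = (d["sample_weight"] * d[g]).to_numpy()
            pr = (d["sample_weight"] * d[reference]).to_numpy()
            if pg.sum() == 0 or pr.sum() == 0:
                continue
            n_eval += 1
            pwc_g = (conc * pg).sum() / pg.sum()
            pwc_r = (conc * pr).sum() / pr.sum()
            if pwc_g > pwc_r and alpha > 0:
                ks = ks_compare(conc, conc, pg, pr)
                if ks.p_value < alpha:
                    n_sig += 1
        rows.append({"partition": partition, "subgroup": g,
                     "reference": reference, "stratum": stratum or "all",
                     "n_higher_significant": n_sig, "n_evaluable": n_eval})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# percentile-band population shares

BANDS = ("lt_p34", "p34_p66", "gt_p66")


def band_shares(exposures: pd.DataFrame, clusters: pd.DataFrame,
                scheme: Mapping[str, Sequence[str]] | None = None,
                quantiles: tuple[float, float] = (0.34, 0.66),
                ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Subgroup population shares within exposure percentile bands.

    Band thresholds are the weighted 34th/66th percentiles of cluster
    exposure (weights = total sample weight). Within each band, a
    subgroup's share is its effective population divided by its partition's
    total effective population in the band, in percent; shares within a
    partition and band sum to 100. Bands are (<P34), [P34, P66], (>P66).
    """
    scheme = dict(scheme or DEFAULT_SCHEME)
    df = exposures.merge(clusters, on="cluster_id", how="inner")
    conc = df["concentration"].to_numpy()
    w = df["sample_weight"].to_numpy()
    lo, hi = weighted_quantile(conc, list(quantiles), w)
    band_of = np.where(conc < lo, "lt_p34", np.where(conc > hi, "gt_p66", "p34_p66"))
    rows = []
    for band in BANDS:
        mask = band_of == band
        if not mask.any():
            logger.warning("empty band %s; shares undefined", band)
            continue
        for partition, groups in scheme.items():
            pops = {g: (w[mask] * df.loc[mask, g].to_numpy()).sum() for g in groups}
            total = sum(pops.values())
            for g in groups:
                share = 100.0 * pops[g] / total if total > 0 else float("nan")
                rows.append({"band": band, "partition": partition,
                             "subgroup": g, "share": share})
    return pd.DataFrame(rows), (float(lo), float(hi))


# --------------------------------------------------------------------------
# temporal change and spatial-scale ratio

@dataclass
class DisparityChange:
    percent: float          # 100 * (|z2| - |z1|) / |z1|
    sign_flip: bool
    undefined: bool         # baseline |z1| negligible


def disparity_change(z_round1: ZScoreResult | float, z_round2: ZScoreResult | float,
                     negligible_threshold: float = NEGLIGIBLE_Z) -> DisparityChange:
    """Percent change in |z| between rounds; undefined on negligible baseline."""
    z1 = z_round1.z if isinstance(z_round1, ZScoreResult) else float(z_round1)
    z2 = z_round2.z if isinstance(z_round2, ZScoreResult) else float(z_round2)
    flip = (z1 * z2) < 0
    if abs(z1) <= negligible_threshold:
        return DisparityChange(percent=float("nan"), sign_flip=flip, undefined=True)
    pct = 100.0 * (abs(z2) - abs(z1)) / abs(z1)
    return DisparityChange(percent=float(pct), sign_flip=bool(flip), undefined=False)


def scale_ratio(z_state: float, z_national: float,
                negligible_threshold: float = NEGLIGIBLE_Z) -> float:
    """State-to-national z ratio; >1 means disparity grows at finer scale.

    Raises when the national z is negligible (ratio undefined); a negative
    ratio indicates a direction reversal between scales.
    """
    zs = z_state.z if isinstance(z_state, ZScoreResult) else float(z_state)
    zn = z_national.z if isinstance(z_national, ZScoreResult) else float(z_national)
    if abs(zn) <= negligible_threshold:
        raise ValueError("national z is negligible; scale ratio undefined")
    return float(zs / zn)
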