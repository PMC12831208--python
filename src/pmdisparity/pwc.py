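"""Population-weighted concentrations (PWC) by region, stratum and subgroup.

For a region with m clusters, the PWC of subgroup k is

    PWC_k = sum_j C_j * P_jk / sum_j P_jk

where C_j is the cluster-level concentration and P_jk the subgroup's
effective population at cluster j, operationalized as the cluster's survey
expansion weight times the subgroup's composition fraction. Higher-level
PWCs (state, SDI region, national) pool clusters directly rather than
averaging district PWCs. The coefficient of variation attached to
supra-district rows is the sd/mean of the district-level subgroup PWCs they
pool; district rows carry the population-weighted CV of their cluster
concentrations.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SCHEME
from .stratification import sdi_class

logger = logging.getLogger(__name__)

PWC_COLUMNS = ["region_id", "region_level", "stratum", "partition",
               "subgroup", "pwc", "cv", "n_clusters"]

#: pseudo-subgroup meaning "everyone": effective population = sample weight.
OVERALL = "overall"


def compute_pwc(concentrations: np.ndarray, weights: np.ndarray,
                fractions: np.ndarray | None = None) -> float:
    """Eq.-style weighted mean: sum(C*w*f) / sum(w*f).

    Returns NaN (with a log message) when the subgroup's effective
    population is all zero; raises on empty input.
    """
    c = np.asarray(concentrations, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.size == 0:
        raise ValueError("region contains no clusters")
    p = w if fractions is None else w * np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("effective populations must be non-negative")
    total = p.sum()
    if total == 0:
        logger.warning("all-zero subgroup population; PWC undefined")
        return float("nan")
    return float((c * p).sum() / total)


def _weighted_cv(values: np.ndarray, weights: np.ndarray) -> float:
    total = weights.sum()
    if total == 0 or values.size < 2:
        return float("nan")
    mean = (values * weights).sum() / total
    var = (weights * (values - mean) ** 2).sum() / total
    return float(np.sqrt(var) / mean) if mean != 0 else float("nan")


def _region_key(level: str, clusters: pd.DataFrame,
                sdi_by_state: Mapping[str, float] | None) -> pd.Series:
    if level == "district":
        return clusters["district_id"]
    if level == "state":
        return clusters["state_id"]
    if level == "national":
        return pd.Series("india", index=clusters.index)
    if level == "sdi_region":
        if sdi_by_state is None:
            raise ValueError("sdi_region level requires sdi_by_state mapping")
        return clusters["state_id"].map(lambda s: sdi_class(sdi_by_state[s]))
    raise ValueError(f"unknown region level {level!r}")


def pwc_table(exposures: pd.DataFrame, clusters: pd.DataFrame,
              levels: Sequence[str] = ("district", "state", "national"),
              strata: Sequence[str] = ("urban", "rural"),
              scheme: Mapping[str, Sequence[str]] | None = None,
              sdi_by_state: Mapping[str, float] | None = None,
              include_overall: bool = True) -> pd.DataFrame:
    """PWC and CV per region x stratum x subgroup.

    Empty region/stratum cells are omitted (and logged); subgroups with zero
    effective population in a region yield NaN PWC rows so the absence is
    visible rather than silently dropped.
    """
    scheme = dict(scheme or DEFAULT_SCHEME)
    df = exposures.merge(clusters, on="cluster_id", how="inner", validate="one_to_one")
    if len(df) != len(exposures):
        raise ValueError("exposures and clusters tables do not match on cluster_id")

    jobs: list[tuple[str, str | None]] = [(p, g) for p, gs in scheme.items() for g in gs]
    if include_overall:
        jobs = [(OVERALL, OVERALL)] + jobs

    rows = []
    for level in levels:
        keys = _region_key(level, df, sdi_by_state)
        for region_id, region_df in df.groupby(keys, sort=True):
            for stratum in strata:
                sub = region_df[region_df["stratum"] == stratum]
                if sub.empty:
                    logger.info("no %s clusters in %s %s; row omitted",
                                stratum, level, region_id)
                    continue
                conc = sub["concentration"].to_numpy()
                w = sub["sample_weight"].to_numpy()
                for partition, group in jobs:
                    frac = None if group == OVERALL else sub[group].to_numpy()
                    p = w if frac is None else w * frac
                    pwc = compute_pwc(conc, w, frac) if p.sum() > 0 else float("nan")
                    if level == "district":
                        cv = _weighted_cv(conc, p) if p.sum() > 0 else float("nan")
                    else:
                        cv = float("nan")  # filled from district PWCs below
                    rows.append({
                        "region_id": region_id, "region_level": level,
                        "stratum": stratum, "partition": partition,
                        "subgroup": group, "pwc": pwc, "cv": cv,
                        "n_clusters": len(sub),
                    })
    out = pd.DataFrame(rows, columns=PWC_COLUMNS)

    # CV of supra-district rows = sd/mean of the district PWCs they pool.
    need_cv = [lv for lv in levels if lv != "district"]
    if need_cv:
        district = pwc_table(exposures, clusters, levels=("district",),
                             strata=strata, scheme=scheme,
                             sdi_by_state=sdi_by_state,
                             include_overall=include_overall) \
            if "district" not in levels else out[out["region_level"] == "district"]
        dist_to_state = clusters.drop_duplicates("district_id").set_index("district_id")["state_id"]
        for idx, row in out[out["region_level"].isin(need_cv)].iterrows():
            d = district[(district["stratum"] == row["stratum"])
                         & (district["subgroup"] == row["subgroup"])]
            if row["region_level"] == "state":
                d = d[d["region_id"].map(dist_to_state) == row["region_id"]]
            elif row["region_level"] == "sdi_region":
                cats = dist_to_state.map(lambda s: sdi_class(sdi_by_state[s]))
                d = d[d["region_id"].map(cats) == row["region_id"]]
            vals = d["pwc"].dropna().to_numpy()
            if vals.size >= 2 and vals.mean() != 0:
                out.at[idx, "cv"] = float(vals.std(ddof=1) / vals.mean())
    return out


def write_pwc_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_pwc_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
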