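"""End-to-end orchestration: two survey rounds, disparity tables, sensitivity.

``run_pipeline`` executes generate -> extract -> PWC -> disparity ->
stratification for each round and packages the outputs (PWC tables,
absolute disparities, z-score tables at national/SDI-region/state level,
percentile-band shares, burdened-district counts, between-round change and
concordance diagnostics) with full provenance. ``sensitivity_sweep``
re-extracts exposures under each buffer policy and compares PWC and z
estimates against the baseline policy.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULT_SCHEME, RunConfig, SimulationConfig
from .disparity import (
    ZScoreResult,
    absolute_disparity,
    band_shares,
    count_burdened_districts,
    disparity_change,
    z_score,
)
from .exposure import assign_cluster_exposure
from .pwc import pwc_table
from .stratification import collapse_settlement, concordance, sdi_class
from .synthetic import (
    generate_clusters,
    generate_concentration_field,
    generate_sdi_values,
    generate_settlement_raster,
)

logger = logging.getLogger(__name__)

ZSCORE_COLUMNS = ["round_id", "level", "region_id", "stratum", "partition",
                  "subgroup", "reference", "z", "ci_lo", "ci_hi", "p_value",
                  "n1", "n2", "negligible"]


@dataclass
class RoundResult:
    round_id: str
    clusters: pd.DataFrame
    exposures: pd.DataFrame        # baseline policy
    pwc: pd.DataFrame
    zscores: pd.DataFrame
    absolute: pd.DataFrame
    bands: pd.DataFrame
    band_thresholds: tuple[float, float]
    burdened: pd.DataFrame
    concordance_agreement: float
    concordance_kappa: float


@dataclass
class ReportBundle:
    rounds: dict[str, RoundResult]
    change: pd.DataFrame
    sdi_by_state: dict[str, float]
    provenance: dict

    def hash(self) -> str:
        """Stable digest over every result table (provenance excluded)."""
        h = hashlib.sha256()
        for rid in sorted(self.rounds):
            r = self.rounds[rid]
            for tbl in (r.clusters, r.exposures, r.pwc, r.zscores,
                        r.absolute, r.bands, r.burdened):
                h.update(tbl.to_csv(index=False, float_format="%.12g").encode())
        h.update(self.change.to_csv(index=False, float_format="%.12g").encode())
        return h.hexdigest()


def _district_pwc_vectors(pwc_df: pd.DataFrame, stratum: str, subgroup: str,
                          districts: pd.Index | None = None) -> pd.Series:
    d = pwc_df[(pwc_df["region_level"] == "district")
               & (pwc_df["stratum"] == stratum)
               & (pwc_df["subgroup"] == subgroup)]
    s = d.set_index("region_id")["pwc"].dropna()
    if districts is not None:
        s = s[s.index.isin(districts)]
    return s


def compute_zscore_table(pwc_df: pd.DataFrame, clusters: pd.DataFrame,
                         references: Mapping[str, str],
                         sdi_by_state: Mapping[str, float],
                         levels=("national", "sdi_region", "state"),
                         strata=("urban", "rural"),
                         negligible_threshold: float = 0.01,
                         round_id: str = "round1") -> pd.DataFrame:
    """z for each non-reference subgroup vs its reference, per region/stratum.

    District-level subgroup PWCs are the samples entering the standardized
    mean difference; a region's z uses the districts belonging to it, with
    the pair restricted to districts where both subgroups have a defined
    PWC. Regions with fewer than two such districts are skipped.
    """
    dist_state = clusters.drop_duplicates("district_id").set_index("district_id")["state_id"]
    region_of = {
        "national": lambda: pd.Series("india", index=dist_state.index),
        "state": lambda: dist_state,
        "sdi_region": lambda: dist_state.map(lambda s: sdi_class(sdi_by_state[s])),
    }
    rows = []
    for level in levels:
        keys = region_of[level]()
        for region_id in sorted(keys.unique()):
            districts = keys[keys == region_id].index
            for stratum in strata:
                for partition, groups in DEFAULT_SCHEME.items():
                    ref = references[partition]
                    ref_pwc = _district_pwc_vectors(pwc_df, stratum, ref, districts)
                    for g in groups:
                        if g == ref:
                            continue
                        g_pwc = _district_pwc_vectors(pwc_df, stratum, g, districts)
                        common = ref_pwc.index.intersection(g_pwc.index)
                        if len(common) < 2:
                            logger.info("skipping %s/%s/%s vs %s: <2 districts",
                                        region_id, stratum, g, ref)
                            continue
                        res = z_score(ref_pwc[common].to_numpy(),
                                      g_pwc[common].to_numpy(),
                                      negligible_threshold=negligible_threshold)
                        rows.append({
                            "round_id": round_id, "level": level,
                            "region_id": region_id, "stratum": stratum,
                            "partition": partition, "subgroup": g,
                            "reference": ref, "z": res.z,
                            "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                            "p_value": res.p_value, "n1": res.n1, "n2": res.n2,
                            "negligible": res.negligible,
                        })
    return pd.DataFrame(rows, columns=ZSCORE_COLUMNS)


def _absolute_table(exposures: pd.DataFrame, clusters: pd.DataFrame,
                    round_id: str) -> pd.DataFrame:
    df = exposures.merge(clusters, on="cluster_id", how="inner")
    rows = []
    for stratum, sub in df.groupby("stratum"):
        if len(sub) < 2:
            continue
        ad = absolute_disparity(sub["concentration"].to_numpy(),
                                weights=sub["sample_weight"].to_numpy())
        rows.append({"round_id": round_id, "region_id": "india",
                     "stratum": stratum, "subgroup": "overall",
                     "p01": ad.p01, "p99": ad.p99, "value": ad.value,
                     "n": ad.n})
    return pd.DataFrame(rows)


def _run_round(sim: SimulationConfig, cfg: RunConfig, round_id: str) -> RoundResult:
    conc = generate_concentration_field(sim)
    settlement = generate_settlement_raster(sim, conc)
    clusters = generate_clusters(sim, conc, settlement)
    sdi_vals = generate_sdi_values(sim)
    sdi_by_state = {f"S{i:02d}": float(v) for i, v in enumerate(sdi_vals)}

    exposures = assign_cluster_exposure(clusters, conc, cfg.baseline, round_id=round_id)
    pwc_df = pwc_table(exposures, clusters,
                       levels=("district", "state", "national", "sdi_region"),
                       sdi_by_state=sdi_by_state)
    zs = compute_zscore_table(pwc_df, clusters, cfg.references, sdi_by_state,
                              levels=cfg.levels,
                              negligible_threshold=cfg.negligible_threshold,
                              round_id=round_id)
    absolute = _absolute_table(exposures, clusters, round_id)
    bands, thresholds = band_shares(exposures, clusters)
    burdened = pd.concat([
        count_burdened_districts(exposures, clusters, p, r, alpha=cfg.alpha)
        for p, r in cfg.references.items()
    ], ignore_index=True)

    # concordance: settlement-derived label at the cluster location vs the
    # cluster's declared stratum (independent classifications of the same site)
    binary = collapse_settlement(settlement)
    ghsl_label = np.where(
        [binary.value_at(x, y) == 1.0 for x, y in zip(clusters["x"], clusters["y"])],
        "urban", "rural")
    conc_res = concordance(ghsl_label, clusters["stratum"].to_numpy(),
                           weights=clusters["sample_weight"].to_numpy())
    logger.info("round %s: %d clusters, concordance %.3f",
                round_id, len(clusters), conc_res.agreement)
    return RoundResult(round_id=round_id, clusters=clusters, exposures=exposures,
                       pwc=pwc_df, zscores=zs, absolute=absolute, bands=bands,
                       band_thresholds=thresholds, burdened=burdened,
                       concordance_agreement=conc_res.agreement,
                       concordance_kappa=conc_res.kappa)


def _round2_sim(cfg: RunConfig) -> SimulationConfig:
    changes: dict = {"seed": cfg.sim.seed + 1_000_003}
    if cfg.round2_tilt is not None:
        changes["tilt"] = cfg.round2_tilt
    if cfg.round2_conc_mean is not None:
        changes["conc_mean"] = cfg.round2_conc_mean
    if cfg.round2_conc_sd is not None:
        changes["conc_sd"] = cfg.round2_conc_sd
    return replace(cfg.sim, **changes)


def run_pipeline(cfg: RunConfig, two_rounds: bool = True) -> ReportBundle:
    """Execute the full analysis and return a :class:`ReportBundle`.

    Deterministic under ``cfg.sim.seed``: the same config reproduces
    byte-identical tables (see :meth:`ReportBundle.hash`).
    """
    r1 = _run_round(cfg.sim, cfg, "round1")
    rounds = {"round1": r1}
    change = pd.DataFrame()
    if two_rounds:
        r2 = _run_round(_round2_sim(cfg), cfg, "round2")
        rounds["round2"] = r2
        change = change_table(r1.zscores, r2.zscores,
                              negligible_threshold=cfg.negligible_threshold)
    sdi_vals = generate_sdi_values(cfg.sim)
    provenance = {
        "package_version": __version__,
        "seed": cfg.sim.seed,
        "alpha": cfg.alpha,
        "negligible_threshold": cfg.negligible_threshold,
        "baseline_policy": cfg.baseline_policy,
        "policies": {p.name: [p.urban_radius_km, p.rural_radius_km] for p in cfg.policies},
        "references": dict(cfg.references),
        "levels": list(cfg.levels),
        "sim": {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cfg.sim).items()},
    }
    return ReportBundle(rounds=rounds, change=change,
                        sdi_by_state={f"S{i:02d}": float(v)
                                      for i, v in enumerate(sdi_vals)},
                        provenance=provenance)


def change_table(zs1: pd.DataFrame, zs2: pd.DataFrame,
                 negligible_threshold: float = 0.01) -> pd.DataFrame:
    """Percent change in |z| between rounds for every matching comparison."""
    keys = ["level", "region_id", "stratum", "partition", "subgroup", "reference"]
    merged = zs1.merge(zs2, on=keys, suffixes=("_1", "_2"))
    rows = []
    for row in merged.itertuples(index=False):
        ch = disparity_change(row.z_1, row.z_2,
                              negligible_threshold=negligible_threshold)
        rows.append({**{k: getattr(row, k) for k in keys},
                     "z_round1": row.z_1, "z_round2": row.z_2,
                     "pct_change": ch.percent, "sign_flip": ch.sign_flip,
                     "undefined": ch.undefined})
    return pd.DataFrame(rows)


def sensitivity_sweep(cfg: RunConfig) -> pd.DataFrame:
    """National PWC and z per buffer policy, with deltas against baseline.

    Flags comparisons whose z changes sign relative to the baseline policy
    (expected when baseline subgroup differences sit near zero).
    """
    if len(cfg.policies) < 2:
        raise ValueError("sensitivity sweep needs at least two policies")
    sim = cfg.sim
    conc = generate_concentration_field(sim)
    settlement = generate_settlement_raster(sim, conc)
    clusters = generate_clusters(sim, conc, settlement)
    sdi_vals = generate_sdi_values(sim)
    sdi_by_state = {f"S{i:02d}": float(v) for i, v in enumerate(sdi_vals)}

    per_policy = {}
    for policy in cfg.policies:
        exposures = assign_cluster_exposure(clusters, conc, policy)
        pwc_df = pwc_table(exposures, clusters, levels=("district", "national"))
        zs = compute_zscore_table(pwc_df, clusters, cfg.references, sdi_by_state,
                                  levels=("national",),
                                  negligible_threshold=cfg.negligible_threshold)
        nat = pwc_df[pwc_df["region_level"] == "national"]
        per_policy[policy.name] = (nat, zs)

    base_nat, base_zs = per_policy[cfg.baseline_policy]
    zkeys = ["stratum", "partition", "subgroup"]
    rows = []
    for name, (nat, zs) in per_policy.items():
        m = nat.merge(base_nat, on=["region_id", "stratum", "partition", "subgroup"],
                      suffixes=("", "_base"))
        zm = zs.merge(base_zs, on=zkeys, suffixes=("", "_base"))
        zlookup = {(r.stratum, r.partition, r.subgroup): r for r in zm.itertuples(index=False)}
        for r in m.itertuples(index=False):
            zr = zlookup.get((r.stratum, r.partition, r.subgroup))
            rows.append({
                "policy": name, "stratum": r.stratum, "partition": r.partition,
                "subgroup": r.subgroup, "pwc": r.pwc,
                "pwc_delta": r.pwc - r.pwc_base,
                "z": zr.z if zr is not None else float("nan"),
                "z_delta": (zr.z - zr.z_base) if zr is not None else float("nan"),
                "sign_flip": bool(zr.z * zr.z_base < 0) if zr is not None else False,
            })
    return pd.DataFrame(rows)
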