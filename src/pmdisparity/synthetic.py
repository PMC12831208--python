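"""Synthetic inputs with known ground truth.

Generates everything the restricted real inputs would provide: a spatially
autocorrelated positive concentration field, a 7-class settlement raster, a
table of geocoded survey clusters nested in districts within states (with
expansion weights and subgroup compositions), per-state socio-demographic
index values, and a direct simulator of district log-concentration pairs for
effect-size recovery experiments. Disparity structure is injected by tilting
one subgroup's composition toward high-concentration locations with a
logistic function of the local concentration's percentile rank, so the
ground-truth direction and strength of every downstream disparity statistic
is known by construction.

All generators are pure functions of (config, seed): a fixed seed reproduces
outputs exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import (
    DEFAULT_BASELINE_SHARES,
    DEFAULT_SCHEME,
    SimulationConfig,
)
from .rasters import Raster

CLUSTER_COLUMNS = [
    "cluster_id", "state_id", "district_id", "x", "y",
    "stratum", "sample_weight",
]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_concentration_field(config: SimulationConfig) -> Raster:
    """Smooth positive annual-mean concentration field.

    White noise is convolved with a Gaussian kernel of width
    ``correlation_length_km``, affinely rescaled so the realized grid has
    exactly the configured mean and sd, then clipped into ``conc_range``
    (clipping perturbs the realized moments slightly).
    """
    rng = _rng(config, 1)
    nrows, ncols = config.grid_shape
    if config.conc_sd == 0:
        vals = np.full((nrows, ncols), config.conc_mean)
    else:
        noise = rng.standard_normal((nrows, ncols))
        sigma = config.correlation_length_km / config.cell_size_km
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect") if sigma > 0 else noise
        sd = smooth.std()
        if sd == 0:  # pathological tiny grid
            vals = np.full((nrows, ncols), config.conc_mean)
        else:
            vals = config.conc_mean + config.conc_sd * (smooth - smooth.mean()) / sd
    vals = np.clip(vals, config.conc_range[0], config.conc_range[1])
    return Raster(vals, origin=(0.0, 0.0), cell_size=config.cell_size_km)


def generate_settlement_raster(config: SimulationConfig, raster: Raster) -> Raster:
    """7-class settlement raster aligned with the concentration grid.

    An independent smoothed field is sliced at its own quantiles so class
    marginals match ``settlement_props`` and classes form contiguous
    patches. Lower class numbers (denser settlement) sit at higher field
    values.
    """
    rng = _rng(config, 2)
    noise = rng.standard_normal(raster.shape)
    sigma = max(config.correlation_length_km / config.cell_size_km / 2.0, 1.0)
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    # cumulative proportions from class 7 (least settled, lowest field values) up
    props = np.asarray(config.settlement_props)
    cum_from_bottom = np.cumsum(props[::-1])[:-1]  # breaks between classes 7..1
    qs = np.quantile(fieldv, cum_from_bottom)
    classes = 7 - np.searchsorted(qs, fieldv, side="left")
    return Raster(classes.astype(float), origin=raster.origin,
                  cell_size=raster.cell_size, crs_mode=raster.crs_mode)


def _block_layout(n_blocks: int, row_range: tuple[int, int], col_range: tuple[int, int]):
    """Tile an index window into n_blocks near-square sub-rectangles."""
    br = int(np.floor(np.sqrt(n_blocks)))
    while n_blocks % br:
        br -= 1
    bc = n_blocks // br
    nrows = row_range[1] - row_range[0]
    ncols = col_range[1] - col_range[0]
    if br > nrows or bc > ncols:
        raise ValueError(
            f"cannot tile {n_blocks} blocks into a {nrows}x{ncols} cell window"
        )
    row_edges = np.linspace(row_range[0], row_range[1], br + 1).astype(int)
    col_edges = np.linspace(col_range[0], col_range[1], bc + 1).astype(int)
    blocks = []
    for i in range(br):
        for j in range(bc):
            blocks.append(((row_edges[i], row_edges[i + 1]),
                           (col_edges[j], col_edges[j + 1])))
    return blocks


def generate_sdi_values(config: SimulationConfig) -> np.ndarray:
    """Per-state SDI in (0, 1), spanning the low/middle/high categories."""
    if config.sdi_values is not None:
        return np.asarray(config.sdi_values, dtype=float)
    rng = _rng(config, 3)
    return rng.uniform(0.40, 0.75, size=config.n_states)


def generate_clusters(config: SimulationConfig, raster: Raster,
                      settlement: Raster | None = None) -> pd.DataFrame:
    """Survey cluster table nested in districts within states.

    States tile the grid into near-square blocks; districts tile each state
    block; cluster locations are uniform within their district block. The
    urban/rural stratum follows the settlement raster at the location, with
    a configurable flip rate emulating the independent survey-side
    classification. Weights are log-normal; compositions are Dirichlet
    within each partition. A nonzero ``config.tilt`` is applied via
    :func:`inject_disparity` after generation.

    Returns a DataFrame with one row per cluster: identifiers, location,
    stratum, sample weight, and one fraction column per subgroup.
    """
    if settlement is None:
        settlement = generate_settlement_raster(config, raster)
    rng = _rng(config, 4)
    nrows, ncols = raster.shape
    state_blocks = _block_layout(config.n_states, (0, nrows), (0, ncols))
    records = []
    x0, y0 = raster.origin
    cs = raster.cell_size
    for s, ((r0, r1), (c0, c1)) in enumerate(state_blocks):
        district_blocks = _block_layout(config.districts_per_state, (r0, r1), (c0, c1))
        for d, ((dr0, dr1), (dc0, dc1)) in enumerate(district_blocks):
            for k in range(config.clusters_per_district):
                x = x0 + rng.uniform(dc0, dc1) * cs
                y = y0 + rng.uniform(dr0, dr1) * cs
                cls = settlement.value_at(x, y)
                stratum = "urban" if cls <= 4 else "rural"
                if config.stratum_flip_rate > 0 and rng.random() < config.stratum_flip_rate:
                    stratum = "rural" if stratum == "urban" else "urban"
                mu, sig = config.weight_lognormal_params
                weight = float(rng.lognormal(mu, sig))
                records.append({
                    "cluster_id": f"S{s:02d}D{d}C{k:03d}",
                    "state_id": f"S{s:02d}",
                    "district_id": f"S{s:02d}D{d}",
                    "x": x, "y": y,
                    "stratum": stratum,
                    "sample_weight": weight,
                })
    df = pd.DataFrame.from_records(records)
    for partition, groups in DEFAULT_SCHEME.items():
        shares = np.asarray(DEFAULT_BASELINE_SHARES[partition])
        alpha = config.dirichlet_concentration * shares
        fracs = rng.dirichlet(alpha, size=len(df))
        for j, g in enumerate(groups):
            df[g] = fracs[:, j]
    if config.tilt != 0.0:
        df = inject_disparity(
            df, raster, config.tilt_partition, config.tilt_subgroup,
            config.tilt, stratum=config.tilt_stratum,
        )
    return df


def inject_disparity(clusters: pd.DataFrame, raster: Raster, partition: str,
                     subgroup: str, tilt: float,
                     stratum: str | None = None,
                     rank_within: str | None = None) -> pd.DataFrame:
    """Tilt one subgroup's composition toward high-concentration clusters.

    The target subgroup's fraction f is re-weighted in odds space by
    ``exp(tilt * (r - 0.5))`` where r is the percentile rank (in (0, 1)) of
    the concentration at the cluster location among the affected clusters;
    the partition's other fractions are rescaled so it still sums to 1.
    ``tilt > 0`` over-represents the subgroup where concentrations are high;
    ``tilt = 0`` is the identity; ``-tilt`` mirrors ``+tilt``.

    ``rank_within`` names a grouping column (e.g. ``"district_id"``) inside
    which percentile ranks are computed, producing within-group exposure
    contrast in every group instead of one national gradient.
    """
    if partition not in DEFAULT_SCHEME:
        raise ValueError(f"unknown partition {partition!r}")
    groups = DEFAULT_SCHEME[partition]
    if subgroup not in groups:
        raise ValueError(f"unknown subgroup {subgroup!r} in partition {partition!r}")
    df = clusters.copy()
    mask = np.ones(len(df), dtype=bool) if stratum is None else (df["stratum"] == stratum).to_numpy()
    if tilt == 0.0 or not mask.any():
        return df
    conc = np.array([raster.value_at(x, y) for x, y in zip(df.loc[mask, "x"], df.loc[mask, "y"])])
    if rank_within is None:
        ranks = (stats.rankdata(conc) - 0.5) / len(conc)
    else:
        keys = df.loc[mask, rank_within].to_numpy()
        ranks = np.empty(len(conc))
        for key in pd.unique(keys):
            sel = keys == key
            ranks[sel] = (stats.rankdata(conc[sel]) - 0.5) / sel.sum()
    mult = np.exp(tilt * (ranks - 0.5))
    f = df.loc[mask, subgroup].to_numpy()
    f_new = f * mult / (f * mult + (1.0 - f))
    others = [g for g in groups if g != subgroup]
    rest = df.loc[mask, others].to_numpy()
    rest_total = rest.sum(axis=1)
    scale = np.divide(1.0 - f_new, rest_total, out=np.zeros_like(f_new), where=rest_total > 0)
    df.loc[mask, subgroup] = f_new
    df.loc[mask, others] = rest * scale[:, None]
    return df


def simulate_pwc_pairs(n_districts: int, delta: float, sigma: float,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two independent vectors of district log-concentration values.

    Group 1 is N(mu0 + delta*sigma, sigma^2), group 2 is N(mu0, sigma^2)
    with mu0 = log 50, so the standardized mean difference of the log values
    is exactly ``delta`` in expectation. Returns log-scale vectors;
    exponentiate before passing to the effect-size estimator, which
    log-transforms its inputs.
    """
    if n_districts < 2:
        raise ValueError("n_districts must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    mu0 = np.log(50.0)
    g1 = rng.normal(mu0 + delta * sigma, sigma, size=n_districts)
    g2 = rng.normal(mu0, sigma, size=n_districts)
    return g1, g2


def write_clusters_csv(clusters: pd.DataFrame, path) -> None:
    clusters.to_csv(path, index=False)


def read_clusters_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
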