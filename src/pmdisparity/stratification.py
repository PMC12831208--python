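"""Urban/rural stratification and agreement between classifications.

Settlement rasters carry seven classes (city, dense town, semi-dense town,
suburban/peri-urban, village, dispersed rural, no settlement); the first
four collapse to urban and the last three to rural. States are binned into
low/middle/high socio-demographic index (SDI) categories. Agreement between
two independent urban/rural labelings is summarized by the diagonal
proportion of the 2x2 crosstab and by Cohen's kappa, and state-level urban
fractions from two sources are compared by Pearson r and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import Raster

URBAN, RURAL = 1.0, 0.0


def collapse_settlement(raster: Raster) -> Raster:
    """Collapse 7-class settlement raster to binary urban(1)/rural(0).

    Classes 1-4 map to urban, 5-7 to rural. An already-binary raster
    (values within {0, 1}) is returned unchanged, so the collapse is
    idempotent. NaN cells stay NaN.
    """
    vals = raster.values
    finite = vals[np.isfinite(vals)]
    if np.all(np.isin(finite, (0.0, 1.0))):
        return raster.copy_with(vals.copy())
    if not np.all(np.isin(finite, np.arange(1, 8))):
        raise ValueError("settlement classes must be integers in 1..7")
    out = np.where(np.isfinite(vals), np.where(vals <= 4, URBAN, RURAL), np.nan)
    return raster.copy_with(out)


def sdi_class(sdi: float) -> str:
    """SDI category: low (<=0.53), middle (0.53-0.6], high (>0.6).

    The printed category bounds leave (0.53, 0.54) unassigned; such values
    fall in the middle category (the lower bound of the middle interval
    governs).
    """
    if not 0.0 < sdi < 1.0:
        raise ValueError("sdi must be in (0, 1)")
    if sdi <= 0.53:
        return "low"
    if sdi > 0.6:
        return "high"
    return "middle"


@dataclass
class ConcordanceResult:
    """Agreement between two matched urban/rural labelings."""

    crosstab: pd.DataFrame  # weighted 2x2 counts, rows = source A
    agreement: float        # diagonal proportion
    kappa: float            # Cohen's chance-corrected agreement
    n: float                # total weight

    def to_dict(self) -> dict:
        return {
            "crosstab": self.crosstab.to_dict(),
            "agreement": self.agreement,
            "kappa": self.kappa,
            "n": self.n,
        }


def concordance(labels_a, labels_b, weights=None) -> ConcordanceResult:
    """Weighted 2x2 crosstab, diagonal agreement and Cohen's kappa."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("label vectors must be nonempty and matched")
    w = np.ones(a.size) if weights is None else np.asarray(weights, dtype=float)
    cats = ("urban", "rural")
    tab = pd.DataFrame(0.0, index=list(cats), columns=list(cats))
    for ca in cats:
        for cb in cats:
            tab.loc[ca, cb] = w[(a == ca) & (b == cb)].sum()
    total = tab.to_numpy().sum()
    if total == 0:
        raise ValueError("zero total weight")
    po = np.trace(tab.to_numpy()) / total
    pa = tab.sum(axis=1).to_numpy() / total
    pb = tab.sum(axis=0).to_numpy() / total
    pe = float((pa * pb).sum())
    kappa = 1.0 if po == 1.0 else (po - pe) / (1.0 - pe)
    return ConcordanceResult(crosstab=tab, agreement=float(po),
                             kappa=float(kappa), n=float(total))


def urban_fraction_agreement(frac_a, frac_b) -> tuple[float, float]:
    """Pearson r and RMSE between two sets of regional urban fractions."""
    fa = np.asarray(frac_a, dtype=float)
    fb = np.asarray(frac_b, dtype=float)
    if fa.size < 2 or fa.shape != fb.shape:
        raise ValueError("need >= 2 matched fraction pairs")
    r = float(stats.pearsonr(fa, fb).statistic)
    rmse = float(np.sqrt(np.mean((fa - fb) ** 2)))
    return r, rmse
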