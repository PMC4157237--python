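"""Benthic survey geometry: cover, rugosity, surface-area conversion.

Line-point-intercept transects give the proportion of planar seafloor each
functional group covers (b); the chain method gives the site rugosity factor
(r = contour length / linear length >= 1); paired planar/3D specimen areas
give per-group 2D->3D conversion factors (s >= 1).  Classical cover
statistics (two-way ANOVA with type-II sums of squares plus Bonferroni
pairwise tests, preceded by Kolmogorov-Smirnov and Brown-Forsythe/Levene
checks) are also housed here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scenario import COVER_CATEGORIES

__all__ = [
    "CoverageEstimate",
    "RugosityFactor",
    "ConversionFactor",
    "transect_positions",
    "coverage_from_transects",
    "rugosity_factor",
    "conversion_factor_estimate",
    "classic_cover_tests",
]

log = logging.getLogger(__name__)


@dataclass
class CoverageEstimate:
    """Planar-seafloor cover proportion of one category at one site/season."""
    category: str
    site: str
    season: str
    b: float                      # mean proportion over transects, in [0, 1]
    sd: float
    per_transect: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.b <= 1:
            raise ValueError("cover proportion must lie in [0, 1]")


@dataclass
class RugosityFactor:
    site: str
    r: float                      # >= 1, dimensionless
    sd: float
    per_subtransect: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("rugosity factor must be >= 1")


@dataclass
class ConversionFactor:
    group: str
    s: float                      # mean 3D/2D area ratio, >= 1
    sd: float
    n: int

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("conversion factor must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def transect_positions(length_m: float, spacing_m: float) -> np.ndarray:
    """Survey point positions 0, spacing, ..., length (both ends included).

    The spacing must divide the length; a 50 m tape at 0.5 m spacing yields
    101 points.
    """
    if length_m <= 0 or spacing_m <= 0:
        raise ValueError("length and spacing must be positive")
    k = length_m / spacing_m
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"spacing {spacing_m} does not divide length {length_m}")
    return np.linspace(0.0, length_m, int(round(k)) + 1)


def coverage_from_transects(
    transects: pd.DataFrame,
    categories: tuple[str, ...] = COVER_CATEGORIES,
) -> list[CoverageEstimate]:
    """Per-category cover estimates from point-intercept label records.

    Expects columns ``site, season, transect_id, label``.  The per-transect
    proportion of a category is its point count over the transect's point
    count; the site/season estimate is the mean over transects, with the SD
    across transects retained.
    """
    unknown = sorted(set(transects["label"]) - set(categories))
    if unknown:
        raise ValueError(f"unknown transect labels: {unknown}")
    out = []
    for (site, season), sub in transects.groupby(["site", "season"]):
        per_cat = {c: [] for c in categories}
        for _, tr in sub.groupby("transect_id"):
            n = len(tr)
            counts = tr["label"].value_counts()
            for c in categories:
                per_cat[c].append(counts.get(c, 0) / n)
        for c in categories:
            props = per_cat[c]
            out.append(CoverageEstimate(
                c, site, season, float(np.mean(props)),
                float(np.std(props, ddof=1)) if len(props) > 1 else 0.0,
                props))
    return out


def rugosity_factor(pairs: pd.DataFrame, site: str) -> RugosityFactor:
    """Site rugosity from chain-method sub-transects (columns
    ``site, chain_m, linear_m``).

    A chain shorter than the tape is physically impossible and treated as
    measurement error: the ratio is clamped to 1 with a logged warning.
    """
    sub = pairs[pairs["site"] == site]
    if sub.empty:
        raise LookupError(f"no rugosity measurements for site {site!r}")
    chain = sub["chain_m"].to_numpy(dtype=float)
    linear = sub["linear_m"].to_numpy(dtype=float)
    if (chain <= 0).any() or (linear <= 0).any():
        raise ValueError("chain and linear lengths must be positive")
    ratios = chain / linear
    if (ratios < 1).any():
        log.warning("%d chain ratios < 1 at %s clamped to 1",
                    int((ratios < 1).sum()), site)
        ratios = np.maximum(ratios, 1.0)
    return RugosityFactor(site, float(np.mean(ratios)),
                          float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
                          list(ratios))


def conversion_factor_estimate(pairs: pd.DataFrame, group: str) -> ConversionFactor:
    """Group 2D->3D conversion factor from paired areas (columns
    ``group, area2d_cm2, area3d_cm2``): mean of per-specimen 3D/2D ratios."""
    sub = pairs[pairs["group"] == group]
    if sub.empty:
        raise LookupError(f"no surface pairs for group {group!r}")
    a2 = sub["area2d_cm2"].to_numpy(dtype=float)
    a3 = sub["area3d_cm2"].to_numpy(dtype=float)
    if (a2 <= 0).any() or (a3 <= 0).any():
        raise ValueError("areas must be positive")
    ratios = a3 / a2
    return ConversionFactor(group, float(np.mean(ratios)),
                            float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
                            len(ratios))


# ------------------------------------------------------- cover statistics

def classic_cover_tests(data: pd.DataFrame, response: str = "prop",
                        alpha: float = 0.05) -> dict:
    """Two-way site x season ANOVA on per-transect cover proportions.

    Expects columns ``site, season`` and the response column.  Returns a
    dict with the type-II ANOVA table, Kolmogorov-Smirnov normality and
    Brown-Forsythe (median-centred Levene) homogeneity pre-checks on the
    residuals/cells, and — when the interaction is significant at ``alpha``
    — all pairwise cell comparisons with Bonferroni-multiplied p-values.
    """
    counts = data.groupby(["site", "season"])[response].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates in every site x season cell")

    model = smf.ols(f"{response} ~ C(site) * C(season)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    resid = model.resid.to_numpy()
    ks_stat, ks_p = stats.kstest(resid, "norm",
                                 args=(resid.mean(), resid.std(ddof=1)))
    cells = [g[response].to_numpy()
             for _, g in data.groupby(["site", "season"])]
    lev_stat, lev_p = stats.levene(*cells, center="median")

    inter_p = float(anova.loc["C(site):C(season)", "PR(>F)"])
    pairwise = None
    if inter_p < alpha:
        labels = sorted(data.groupby(["site", "season"]).groups)
        m = len(labels) * (len(labels) - 1) // 2
        rows = []
        for (a, b) in itertools.combinations(labels, 2):
            xa = data[(data["site"] == a[0]) & (data["season"] == a[1])][response]
            xb = data[(data["site"] == b[0]) & (data["season"] == b[1])][response]
            t, p = stats.ttest_ind(xa, xb)
            rows.append({"cell_a": "/".join(a), "cell_b": "/".join(b),
                         "t": float(t), "p_raw": float(p),
                         "p_bonferroni": min(1.0, float(p) * m)})
        pairwise = pd.DataFrame(rows)

    return {
        "anova": anova,
        "ks": {"stat": float(ks_stat), "p": float(ks_p)},
        "levene": {"stat": float(lev_stat), "p": float(lev_p)},
        "pairwise": pairwise,
    }
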