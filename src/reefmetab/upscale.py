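"""Upscaling organism fluxes to seafloor-area and daily ecosystem rates.

A group's contribution to reef metabolism is
``c_i = p_i * s_i * b_i * r``: the individual flux per m^2 of 3D specimen
surface (p_i) times the group's 2D->3D surface conversion factor (s_i),
its planar benthic cover (b_i) and the site rugosity factor (r), giving
mmol O2 per m^2 of *planar seafloor* per hour.  Daily ecosystem production
extrapolates the incubations to a 12 h light / 12 h dark cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import BENTHIC_GROUPS, coverage_group

__all__ = [
    "contribution",
    "specimen_contributions",
    "daily_totals",
    "daily_replicates",
    "DailyProduction",
    "CONVENTIONS",
]

#: diel-extrapolation conventions for daily net production
CONVENTIONS = ("net_24h", "net_light_only")


def contribution(p: float, s: float, b: float, r: float) -> float:
    """Seafloor-area flux ``c = p * s * b * r`` (mmol O2 m^-2 seafloor h^-1).

    ``p`` is per m^2 of 3D specimen area and may be negative (net
    heterotrophy); ``s >= 1``, ``0 <= b <= 1``, ``r >= 1``.
    """
    if s < 1:
        raise ValueError("conversion factor s must be >= 1")
    if not 0 <= b <= 1:
        raise ValueError("cover proportion b must lie in [0, 1]")
    if r < 1:
        raise ValueError("rugosity factor r must be >= 1")
    return p * s * b * r


def specimen_contributions(fluxes: pd.DataFrame,
                           coverage: dict[tuple[str, str, str], float],
                           s_factors: dict[str, float],
                           rugosity: dict[str, float]) -> pd.DataFrame:
    """Per-specimen seafloor contributions, retained for inference.

    Parameters
    ----------
    fluxes:
        Per-specimen table with ``sample_id, group, site, season, p_n,
        resp, p_g`` (group at incubation level; coral genera map to the
        pooled 'coral' cover category).
    coverage:
        ``(category, site, season) -> b``.
    s_factors:
        ``incubation group -> s`` (3D/2D ratio used for that specimen).
    rugosity:
        ``site -> r``.

    Returns columns ``sample_id, group, site, season, c_n, c_resp, c_g``
    with ``group`` at the pooled functional-group level.
    """
    rows = []
    for _, rec in fluxes.iterrows():
        cat = coverage_group(rec["group"])
        key = (cat, rec["site"], rec["season"])
        if key not in coverage:
            raise KeyError(f"no coverage estimate for {key}")
        if rec["site"] not in rugosity:
            raise KeyError(f"no rugosity factor for site {rec['site']!r}")
        s = s_factors[rec["group"]]
        b = coverage[key]
        r = rugosity[rec["site"]]
        rows.append({
            "sample_id": rec["sample_id"], "group": cat,
            "site": rec["site"], "season": rec["season"],
            "c_n": contribution(rec["p_n"], s, b, r),
            "c_resp": contribution(rec["resp"], s, b, r),
            "c_g": contribution(rec["p_g"], s, b, r),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DailyProduction:
    """Daily ecosystem O2 production per m^2 planar seafloor."""
    site: str
    season: str
    daily_pn: float               # mmol O2 m^-2 seafloor d^-1
    daily_pg: float
    convention: str


def daily_totals(contribs: pd.DataFrame,
                 convention: str = "net_24h") -> DailyProduction:
    """Daily ecosystem totals from hourly group contributions.

    ``contribs`` must hold one site/season (columns ``site, season, group,
    c_n, c_resp, c_g``); group means are summed over groups and extrapolated
    to a 12 h light / 12 h dark cycle:

    - ``daily_pg = 12 * sum(c_g)`` always;
    - ``net_24h`` (default): ``daily_pn = 12 * sum(c_n) - 12 * sum(c_resp)``
      — dark-phase respiration is debited from the day's net budget;
    - ``net_light_only``: ``daily_pn = 12 * sum(c_n)``.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    sites = contribs["site"].unique()
    seasons = contribs["season"].unique()
    if len(sites) != 1 or len(seasons) != 1:
        raise ValueError("daily totals require a single site and season")
    g = contribs.groupby("group")[["c_n", "c_resp", "c_g"]].mean()
    sum_cn = float(g["c_n"].sum())
    sum_cr = float(g["c_resp"].sum())
    sum_cg = float(g["c_g"].sum())
    daily_pg = 12.0 * sum_cg
    if convention == "net_24h":
        daily_pn = 12.0 * sum_cn - 12.0 * sum_cr
    else:
        daily_pn = 12.0 * sum_cn
    return DailyProduction(str(sites[0]), str(seasons[0]),
                           daily_pn, daily_pg, convention)


def daily_replicates(contribs: pd.DataFrame,
                     convention: str = "net_24h") -> pd.DataFrame:
    """Pseudo-replicate daily totals for inference.

    Within one site/season, specimens are dealt round-robin into
    ``n = min(group count)`` replicates; replicate ``j`` sums each group's
    mean over its specimens assigned to slot ``j``.  The mean over
    replicates therefore equals the point estimate of
    :func:`daily_totals` whenever group counts are multiples of ``n``.
    Returns columns ``site, season, replicate, daily_pn, daily_pg``.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    rows = []
    for (site, season), sub in contribs.groupby(["site", "season"]):
        counts = sub.groupby("group").size()
        n = int(counts.min())
        ranked = sub.assign(_j=sub.groupby("group").cumcount() % n)
        per_rep = (ranked.groupby(["group", "_j"])[["c_n", "c_resp", "c_g"]]
                   .mean().groupby("_j").sum())
        for j, rec in per_rep.iterrows():
            pg = 12.0 * rec["c_g"]
            pn = (12.0 * rec["c_n"] - 12.0 * rec["c_resp"]
                  if convention == "net_24h" else 12.0 * rec["c_n"])
            rows.append({"site": site, "season": season, "replicate": int(j),
                         "daily_pn": pn, "daily_pg": pg})
    return pd.DataFrame(rows)
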