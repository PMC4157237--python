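"""Synthetic field-campaign data generator.

Every input table the analysis pipeline consumes can be generated here with
the statistical structure of the study scenario: incubation O2 records are
*back-computed* from drawn target fluxes so that the downstream flux pipeline
recovers each drawn flux exactly (up to float rounding); transects are i.i.d.
multinomial label draws; rugosity ratios and surface-area conversion ratios
are normal draws truncated at 1; logger series are i.i.d. normal at 2-minute
spacing.

All generators are deterministic under ``scenario.rng_seed``: each table uses
an independent child stream of the scenario seed, so generating one table
never perturbs another.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scenario import (
    COVER_CATEGORIES,
    INCUBATION_GROUPS,
    O2_MOLAR_MASS,
    PHASES,
    SEASONS,
    SITES,
    Scenario,
    coverage_group,
)

__all__ = [
    "gen_incubations",
    "gen_transects",
    "gen_rugosity",
    "gen_logger",
    "gen_surface_pairs",
    "generate_all",
    "write_tables",
    "TRANSECT_POINTS",
]

#: points per line-point-intercept transect (50 m at 0.5 m spacing, ends incl.)
TRANSECT_POINTS = 101

# child-stream tags so each table has its own deterministic RNG
_STREAMS = {"incubations": 1, "transects": 2, "rugosity": 3, "logger": 4,
            "surface_pairs": 5}


def _rng(scenario: Scenario, table: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[table], scenario.rng_seed])


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lower: float, size: int) -> np.ndarray:
    """Normal draws truncated below at ``lower`` by rejection sampling."""
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate truncated normal below bound")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    # pathological mean << lower: fall back to the bound
    out[out < lower] = lower
    return out


def _truncnorm_mean_matched(rng: np.random.Generator, mean: float, sd: float,
                            lower: float, size: int) -> np.ndarray:
    """Truncated-normal draws whose *post-truncation* mean equals ``mean``.

    The nominal (mean, sd) describe a quantity supported on
    ``[lower, inf)`` (e.g. a 3D/2D area ratio >= 1), so the location of the
    underlying normal is solved such that the truncated distribution's mean
    hits the nominal value; the nominal sd is used as the underlying scale
    (the truncated sd is necessarily smaller when the mean sits close to
    the bound).
    """
    from scipy import stats as sps
    from scipy.optimize import brentq

    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate truncated normal below bound")
        return np.full(size, float(mean))
    if mean <= lower:
        raise ValueError("target mean must exceed the truncation bound")

    def gap(mu):
        a = (lower - mu) / sd
        return sps.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - mean

    if mean - lower > 8 * sd:          # truncation numerically irrelevant
        mu = mean
    else:
        # far-tail limit: truncated mean ~ lower + sd^2/(lower - mu), so a
        # target barely above the bound needs mu ~ lower - sd^2/(mean-lower)
        lo = min(mean - 12 * sd, lower - 2 * sd * sd / (mean - lower) - sd)
        mu = brentq(gap, lo, mean + sd, xtol=1e-12)
    a = (lower - mu) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size,
                             random_state=rng)


# ----------------------------------------------------------- incubations

#: lowest admissible end-of-incubation O2 concentration (mg/L).  Field
#: protocols keep incubations short precisely to avoid hypoxia; specimens
#: whose drawn (area, flux) combination would deplete the chamber below this
#: floor are jointly redrawn.
O2_FLOOR = 0.2


def _draw_specimens(rng, scenario: Scenario, key, a2d_mean, a2d_sd,
                    s_factor, volume, blank_light, blank_dark, n):
    """Draw (area2d, light flux, dark flux) per specimen, rejecting
    combinations that would drive the chamber O2 below ``O2_FLOOR``."""
    c0 = scenario.o2_baseline

    def _end(areas, fluxes, phase, blank):
        dur = scenario.durations[phase]
        rate = fluxes * (areas * s_factor * 1e-4) / volume + blank
        return c0 + rate * dur * O2_MOLAR_MASS

    areas = np.empty(n)
    f_light = np.empty(n)
    f_dark = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        m = len(todo)
        a = _truncnorm(rng, a2d_mean, a2d_sd, 0.1 * a2d_mean, m)
        fl = rng.normal(scenario.flux_pn[key], scenario.flux_pn_sd[key], m)
        fd = -rng.normal(scenario.flux_resp[key],
                         scenario.flux_resp_sd[key], m)
        areas[todo], f_light[todo], f_dark[todo] = a, fl, fd
        ok = (_end(a, fl, "light", blank_light) >= O2_FLOOR) \
            & (_end(a, fd, "dark", blank_dark) >= O2_FLOOR)
        todo = todo[~ok]
        if len(todo) == 0:
            return areas, f_light, f_dark
    raise ValueError(f"cannot draw physically consistent incubations for "
                     f"cell {key}: chamber too small for the flux scale")

def gen_incubations(
    scenario: Scenario,
    groups: tuple[str, ...] | None = None,
    sites: tuple[str, ...] | None = None,
    seasons: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate incubation and blank records plus the drawn-flux truth table.

    For each (group, site, season) cell, ``scenario.n_replicates`` specimens
    are created; each is incubated once in the light and once in the dark.
    A target light flux ~ Normal(P_n mean, SD) and dark flux
    ~ -Normal(resp mean, SD) are drawn per specimen, and the end O2
    concentration is back-computed from chamber volume, duration, planar
    area and the group's mean 2D->3D conversion factor, including the
    *realized* mean blank drift, so that the flux pipeline inverts to the
    drawn flux exactly.

    Returns
    -------
    (incubations, blanks, truth) : three DataFrames; ``truth`` holds the
    drawn per-specimen fluxes for round-trip validation.
    """
    scenario.validate()
    groups = groups or INCUBATION_GROUPS
    sites = sites or SITES
    seasons = seasons or SEASONS
    for g in groups:
        if g not in INCUBATION_GROUPS:
            raise KeyError(f"unknown incubation group {g!r}")
    for s in sites:
        if s not in SITES:
            raise KeyError(f"unknown site {s!r}")
    for w in seasons:
        if w not in SEASONS:
            raise KeyError(f"unknown season {w!r}")

    rng = _rng(scenario, "incubations")
    c0 = scenario.o2_baseline

    # blanks first: their realized mean drift enters the back-computation
    blank_rows = []
    blank_rate_mmol: dict[tuple[str, str, str], float] = {}
    for site in sites:
        for season in seasons:
            for phase in PHASES:
                mu, sd = scenario.blank_drift[phase]
                dur = scenario.durations[phase]
                rates = rng.normal(mu, sd, scenario.n_blanks)  # mg/L/h
                for j, rate in enumerate(rates):
                    blank_rows.append({
                        "sample_id": f"BL_{site}_{season}_{phase}_{j}",
                        "site": site, "season": season, "phase": phase,
                        "o2_start_mg_l": c0,
                        "o2_end_mg_l": c0 + rate * dur,
                        "duration_h": dur, "volume_l": 0.6,
                    })
                blank_rate_mmol[(site, season, phase)] = (
                    float(np.mean(rates)) / O2_MOLAR_MASS
                )

    inc_rows, truth_rows = [], []
    for group in groups:
        a2d_mean, a2d_sd, volume = scenario.specimen_geometry[group]
        s_factor = scenario.conversion_factors[group][0]
        for site in sites:
            for season in seasons:
                key = (group, site, season)
                if key not in scenario.flux_pn:
                    raise KeyError(f"scenario has no flux cell {key}")
                n = scenario.n_replicates
                areas, f_light, f_dark = _draw_specimens(
                    rng, scenario, key, a2d_mean, a2d_sd, s_factor, volume,
                    blank_rate_mmol[(site, season, "light")],
                    blank_rate_mmol[(site, season, "dark")], n)
                for j in range(n):
                    sid = f"{group}_{site}_{season}_{j}"
                    area3d_m2 = areas[j] * s_factor * 1e-4
                    for phase, flux in (("light", f_light[j]),
                                        ("dark", f_dark[j])):
                        dur = scenario.durations[phase]
                        rate_mmol = (flux * area3d_m2 / volume
                                     + blank_rate_mmol[(site, season, phase)])
                        inc_rows.append({
                            "sample_id": sid, "group": group, "site": site,
                            "season": season, "phase": phase,
                            "o2_start_mg_l": c0,
                            "o2_end_mg_l": c0 + rate_mmol * dur * O2_MOLAR_MASS,
                            "duration_h": dur, "volume_l": volume,
                            "area2d_cm2": areas[j],
                        })
                    truth_rows.append({
                        "sample_id": sid, "group": group, "site": site,
                        "season": season, "true_pn": f_light[j],
                        "true_resp": -f_dark[j],
                        "true_pg": f_light[j] - f_dark[j],
                    })

    return (pd.DataFrame(inc_rows), pd.DataFrame(blank_rows),
            pd.DataFrame(truth_rows))


# ------------------------------------------------------------- transects

def gen_transects(scenario: Scenario, site: str, season: str,
                  n_transects: int = 3) -> pd.DataFrame:
    """Line-point-intercept label sequences: ``TRANSECT_POINTS`` i.i.d.
    multinomial draws per transect."""
    scenario.validate()
    probs = scenario.cover_probs[(site, season)]
    cats = [c for c in COVER_CATEGORIES if c in probs]
    p = np.array([probs[c] for c in cats])
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("cover probabilities must sum to 1")
    rng = np.random.default_rng(
        [_STREAMS["transects"], scenario.rng_seed,
         SITES.index(site), SEASONS.index(season)])
    rows = []
    for t in range(n_transects):
        labels = rng.choice(cats, size=TRANSECT_POINTS, p=p / p.sum())
        rows.extend({
            "site": site, "season": season, "transect_id": t,
            "point_index": i, "label": lab,
        } for i, lab in enumerate(labels))
    return pd.DataFrame(rows)


def gen_rugosity(scenario: Scenario, site: str, n: int = 9,
                 linear_m: float = 10.0) -> pd.DataFrame:
    """Chain-method sub-transect measurements: chain/linear ratios drawn
    from a normal truncated at 1, location-calibrated so the truncated
    mean equals the scenario mean."""
    scenario.validate()
    mean, sd = scenario.rugosity[site]
    rng = np.random.default_rng(
        [_STREAMS["rugosity"], scenario.rng_seed, SITES.index(site)])
    ratios = _truncnorm_mean_matched(rng, mean, sd, 1.0, n)
    return pd.DataFrame({
        "site": site,
        "chain_m": ratios * linear_m,
        "linear_m": linear_m,
    })


def gen_logger(scenario: Scenario, season: str, n_samples: int) -> pd.DataFrame:
    """Temperature/light logger series at 2-minute spacing, i.i.d. normal
    per season; light clipped at 0 lx."""
    scenario.validate()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    t_mean, t_sd, l_mean, l_sd = scenario.logger[season]
    rng = np.random.default_rng(
        [_STREAMS["logger"], scenario.rng_seed, SEASONS.index(season)])
    return pd.DataFrame({
        "season": season,
        "t_min": 2.0 * np.arange(n_samples),
        "temp_c": rng.normal(t_mean, t_sd, n_samples),
        "light_lx": np.clip(rng.normal(l_mean, l_sd, n_samples), 0, None),
    })


def gen_surface_pairs(scenario: Scenario, group: str, n: int = 10) -> pd.DataFrame:
    """Paired planar/3D specimen areas; area3d = area2d x ratio with the
    ratio drawn from a >= 1 truncated normal whose mean equals the
    scenario conversion factor."""
    scenario.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    mean, sd = scenario.conversion_factors[group]
    a2d_mean, a2d_sd, _ = scenario.specimen_geometry[group]
    rng = np.random.default_rng(
        [_STREAMS["surface_pairs"], scenario.rng_seed,
         INCUBATION_GROUPS.index(group)])
    a2d = _truncnorm(rng, a2d_mean, a2d_sd, 0.1 * a2d_mean, n)
    ratio = _truncnorm_mean_matched(rng, mean, sd, 1.0, n)
    return pd.DataFrame({
        "group": group,
        "area2d_cm2": a2d,
        "area3d_cm2": a2d * ratio,
    })


# ---------------------------------------------------------------- bundles

def generate_all(scenario: Scenario, n_transects: int = 3,
                 n_rugosity: int = 9, n_surface_pairs: int = 10,
                 n_logger: int = 720) -> dict[str, pd.DataFrame]:
    """Generate every pipeline input table for the scenario."""
    incubations, blanks, truth = gen_incubations(scenario)
    transects = pd.concat(
        [gen_transects(scenario, site, season, n_transects)
         for site in SITES for season in SEASONS], ignore_index=True)
    rugosity = pd.concat(
        [gen_rugosity(scenario, site, n_rugosity) for site in SITES],
        ignore_index=True)
    logger = pd.concat(
        [gen_logger(scenario, season, n_logger) for season in SEASONS],
        ignore_index=True)
    pairs = pd.concat(
        [gen_surface_pairs(scenario, g, n_surface_pairs)
         for g in INCUBATION_GROUPS], ignore_index=True)
    tables = {
        "incubations": incubations, "blanks": blanks,
        "drawn_fluxes": truth, "transects": transects,
        "rugosity": rugosity, "logger": logger, "surface_pairs": pairs,
    }
    _validate_tables(tables)
    return tables


def _validate_tables(tables: dict[str, pd.DataFrame]) -> None:
    inc = tables["incubations"]
    if (inc["duration_h"] <= 0).any() or (inc["volume_l"] <= 0).any():
        raise ValueError("incubation durations and volumes must be positive")
    if (inc["area2d_cm2"] <= 0).any():
        raise ValueError("planar areas must be positive")
    if (inc[["o2_start_mg_l", "o2_end_mg_l"]] < 0).to_numpy().any():
        raise ValueError("O2 concentrations must be non-negative")
    bl = tables["blanks"]
    if (bl["duration_h"] <= 0).any() or (bl["volume_l"] <= 0).any():
        raise ValueError("blank durations and volumes must be positive")
    tr = tables["transects"]
    counts = tr.groupby(["site", "season", "transect_id"]).size()
    if (counts != TRANSECT_POINTS).any():
        raise ValueError(f"every transect must have {TRANSECT_POINTS} points")
    unknown = set(tr["label"]) - set(COVER_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown transect labels: {sorted(unknown)}")
    rug = tables["rugosity"]
    if (rug["chain_m"] < rug["linear_m"] - 1e-12).any():
        raise ValueError("chain length must be >= linear length")
    sp = tables["surface_pairs"]
    if (sp["area3d_cm2"] < sp["area2d_cm2"] - 1e-12).any():
        raise ValueError("3D area must be >= planar area")


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write every table as ``<name>.csv`` (canonical serialization:
    17-significant-digit floats, no index)."""
    _validate_tables(tables)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        paths[name] = path
    return paths
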