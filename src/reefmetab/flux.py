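"""O2 flux computation from paired incubation measurements.

A specimen is incubated in a closed chamber; the dissolved O2 concentration
is read before the incubation and after removing the specimen.  The rate of
concentration change, corrected by the seawater-only blank rate, times the
chamber volume and normalized to the specimen's 3D surface area gives the
flux in mmol O2 m^-2 specimen-3D-area h^-1.  Light-phase flux is net
production P_n; the negated dark-phase flux is respiration R; gross
production is P_g = P_n + R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import O2_MOLAR_MASS

__all__ = [
    "BlankRate",
    "blank_rate",
    "specimen_flux",
    "assemble_pn_r_pg",
    "compute_fluxes",
    "lux_to_par",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlankRate:
    """Mean O2 concentration drift of seawater-only controls, mmol L^-1 h^-1."""
    site: str
    season: str
    phase: str
    rate: float  # mmol/L/h

    def __post_init__(self):
        if not np.isfinite(self.rate):
            raise ValueError("blank rate must be finite")


def blank_rate(blanks: pd.DataFrame, site: str, season: str, phase: str,
               units: str = "mg_l") -> BlankRate:
    """Mean concentration-change rate of the blanks matching
    (site, season, phase).

    Raises ``LookupError`` if no blank matches — a missing blank is never
    silently treated as zero drift.
    """
    sel = blanks[(blanks["site"] == site) & (blanks["season"] == season)
                 & (blanks["phase"] == phase)]
    if sel.empty:
        raise LookupError(f"no blank incubation for ({site}, {season}, {phase})")
    delta = sel["o2_end_mg_l"].to_numpy() - sel["o2_start_mg_l"].to_numpy()
    rates = _to_mmol(delta, units) / sel["duration_h"].to_numpy()
    return BlankRate(site, season, phase, float(np.mean(rates)))


def _to_mmol(delta_conc: np.ndarray | float, units: str):
    """Concentration difference -> mmol/L."""
    if units == "mg_l":
        return np.asarray(delta_conc, dtype=float) / O2_MOLAR_MASS
    if units == "umol_l":
        return np.asarray(delta_conc, dtype=float) / 1000.0
    raise ValueError(f"unknown concentration units {units!r}")


def specimen_flux(o2_start: float, o2_end: float, duration_h: float,
                  volume_l: float, area2d_cm2: float, s_factor: float,
                  blank: BlankRate | float = 0.0,
                  units: str = "mg_l") -> float:
    """Signed O2 flux of one incubation, mmol O2 m^-2 3D-area h^-1.

    ``flux = ((dC/dt - blank_rate) * V) / (area2d * s_factor)`` with the
    concentration change converted to mmol/L and the planar area (cm^2)
    scaled by the 2D->3D conversion factor and converted to m^2.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if area2d_cm2 <= 0:
        raise ValueError("specimen area must be positive")
    if s_factor < 1:
        raise ValueError("conversion factor must be >= 1")
    b = blank.rate if isinstance(blank, BlankRate) else float(blank)
    rate = _to_mmol(o2_end - o2_start, units) / duration_h - b
    area3d_m2 = area2d_cm2 * s_factor * 1e-4
    return float(rate * volume_l / area3d_m2)


def assemble_pn_r_pg(light_flux: float, dark_flux: float,
                     tol: float = 1e-9) -> tuple[float, float, float]:
    """Combine a specimen's light and dark fluxes into (P_n, R, P_g).

    R is the *magnitude* of dark O2 consumption.  A positive dark flux
    beyond ``tol`` (apparent O2 production in darkness) is degenerate input:
    a warning is logged and R is clamped to 0.
    """
    p_n = float(light_flux)
    resp = -float(dark_flux)
    if resp < -tol:
        log.warning("positive dark flux %.4g clamped to zero respiration",
                    dark_flux)
        resp = 0.0
    elif resp < 0:
        resp = 0.0
    return p_n, resp, p_n + resp


def compute_fluxes(incubations: pd.DataFrame, blanks: pd.DataFrame,
                   s_factors: dict[str, float],
                   units: str = "mg_l") -> pd.DataFrame:
    """Per-specimen flux table from raw incubation and blank records.

    Pairs each specimen's light and dark incubation, applies the matching
    blank correction, and returns columns
    ``sample_id, group, site, season, p_n, resp, p_g``.
    """
    cache: dict[tuple[str, str, str], BlankRate] = {}

    def _blank(site, season, phase):
        key = (site, season, phase)
        if key not in cache:
            cache[key] = blank_rate(blanks, site, season, phase, units=units)
        return cache[key]

    rows = []
    for (sid, group, site, season), sub in incubations.groupby(
            ["sample_id", "group", "site", "season"], sort=False):
        phases = dict(zip(sub["phase"], sub.index))
        if set(phases) != {"light", "dark"}:
            raise ValueError(
                f"specimen {sid!r} needs exactly one light and one dark "
                f"incubation, got {sorted(phases)}")
        if group not in s_factors:
            raise KeyError(f"no conversion factor for group {group!r}")
        flux = {}
        for phase, idx in phases.items():
            r = sub.loc[idx]
            flux[phase] = specimen_flux(
                r["o2_start_mg_l"], r["o2_end_mg_l"], r["duration_h"],
                r["volume_l"], r["area2d_cm2"], s_factors[group],
                blank=_blank(site, season, phase), units=units)
        p_n, resp, p_g = assemble_pn_r_pg(flux["light"], flux["dark"])
        rows.append({"sample_id": sid, "group": group, "site": site,
                     "season": season, "p_n": p_n, "resp": resp, "p_g": p_g})
    return pd.DataFrame(rows)


def lux_to_par(light_lx, k: float = 0.0185):
    """Convert illuminance (lx) to photosynthetically active radiation
    (umol photons m^-2 s^-1) with the linear daylight approximation
    ``PAR = k * lx``."""
    arr = np.asarray(light_lx, dtype=float)
    if (arr < 0).any():
        raise ValueError("illuminance must be non-negative")
    out = k * arr
    return float(out) if np.isscalar(light_lx) else out
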