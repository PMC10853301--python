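"""Seeded synthetic basin rosters with the structure the ranking assumes.

The generator emulates the study roster — 18 hydrologic regions holding 163
HUC04-sized basins, each with a handful of HUC08 subbasins — with the
statistical features the scoring exercises: positively skewed (log-normal)
nutrient source yields and stream concentrations with regional location
shifts, bounded Beta indices (tile-drain fraction, biotic index), Gamma
runoff, Normal log-space load residuals, and a tunable monotone coupling
between local source yield and stream concentration.  It makes no claim to
spatial realism; it exists so every pipeline stage is testable without the
study's geospatial data release.

A single integer seed drives everything; per-region substreams are spawned
deterministically from it, so the same seed and config always regenerate a
bit-identical roster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DomainError
from .io import validate_tables

__all__ = ["SyntheticConfig", "generate_roster", "plant_extreme"]

#: National median source yields, kg/km2/yr (order-of-magnitude realism).
_DEFAULT_SOURCE_MEDIANS = {
    "fertmanure_N": 3000.0,
    "fertmanure_P": 500.0,
    "wwtp_N": 100.0,
    "wwtp_P": 20.0,
    "septic_N": 50.0,
}

#: Subbasin columns set to the roster maximum for an impact-dominant plant.
_IMPACT_SUB_COLUMNS = (
    "stream_N_vwm", "stream_P_vwm", "gw_shallow_no3", "gw_ps_no3",
    "fertmanure_N", "fertmanure_P", "wwtp_N", "wwtp_P", "septic_N",
)

#: Subbasin columns spread to extremes for a variability-dominant plant,
#: with their (lower, upper) hard bounds where the schema has them.
_VARIABILITY_SPREAD_BOUNDS = {
    "stream_N_vwm": (None, None),
    "stream_P_vwm": (None, None),
    "fertmanure_N": (None, None),
    "fertmanure_P": (None, None),
    "wwtp_N": (None, None),
    "wwtp_P": (None, None),
    "septic_N": (None, None),
    "gw_shallow_no3": (None, None),
    "gw_ps_no3": (None, None),
    "runoff": (None, None),
    "tile_fraction": (0.0, 1.0),
}

_BASIN_RECEPTOR_BOUNDS = {
    "pop_served_per_km2": (None, None),
    "pct_waterbodies": (0.0, 100.0),
    "biotic_index": (0.0, 1.0),
    "delivered_N_yield": (None, None),
    "delivered_P_yield": (None, None),
}


def _default_basins_per_region(n_regions: int) -> tuple[int, ...]:
    """163 basins over 18 regions by default; other counts split evenly."""
    if n_regions == 18:
        return (10,) + (9,) * 17
    base = max(2, 163 // n_regions)
    return (base,) * n_regions


@dataclass(frozen=True)
class SyntheticConfig:
    """Roster dimensions and distribution parameters for the generator."""

    n_regions: int = 18
    basins_per_region: Sequence[int] | None = None
    subbasins_per_basin: tuple[int, int] = (4, 12)
    source_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SOURCE_MEDIANS)
    )
    log_sigma_within: float = 0.7   # subbasin spread of log yields/concentrations
    log_sigma_region: float = 0.5   # regional location shifts on the log scale
    coupling: float = 0.6           # source -> stream concentration association
    tile_beta: tuple[float, float] = (0.8, 4.0)
    runoff_gamma_shape: float = 2.0
    runoff_mean_m: float = 0.35
    biotic_beta: tuple[float, float] = (2.0, 2.0)
    resid_sigma_pct: float = 30.0   # SD of signed log-space load residuals, %
    planted_extremes: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        bpr = self.basins_per_region
        if bpr is not None and (len(bpr) != self.n_regions or any(b < 1 for b in bpr)):
            raise ConfigError("basins_per_region must list one positive count per region")
        lo, hi = self.subbasins_per_basin
        if not (1 <= lo <= hi):
            raise ConfigError("subbasins_per_basin must be a (lo, hi) range with lo >= 1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must be in [0, 1]")
        regions_seen = set()
        n_impact = 0
        for plant in self.planted_extremes:
            region, mode = plant["region"], plant["mode"]
            if mode not in ("impact_dominant", "variability_dominant"):
                raise ConfigError(f"unknown planted-extreme mode {mode!r}")
            if region in regions_seen:
                raise ConfigError(f"more than one planted extreme in region {region!r}")
            regions_seen.add(region)
            n_impact += mode == "impact_dominant"
        if n_impact > 1:
            # two basins cannot both hold national ordinal 1
            raise ConfigError("at most one impact_dominant plant per roster")

    def resolved_basins_per_region(self) -> tuple[int, ...]:
        if self.basins_per_region is not None:
            return tuple(self.basins_per_region)
        return _default_basins_per_region(self.n_regions)


def _region_id(r: int) -> str:
    return f"R{r + 1:02d}"


def _generate_region(
    rng: np.random.Generator, cfg: SyntheticConfig, region_idx: int, n_basins: int
):
    """Draw one region's basin and subbasin rows."""
    region = _region_id(region_idx)
    # Regional location shifts (shared by all the region's basins).
    shift = {
        name: rng.normal(0.0, cfg.log_sigma_region) for name in cfg.source_medians
    }
    shift_conc_N = rng.normal(0.0, cfg.log_sigma_region)
    shift_conc_P = rng.normal(0.0, cfg.log_sigma_region)
    shift_gw = rng.normal(0.0, cfg.log_sigma_region)
    biotic_shift = rng.normal(0.0, 0.6)
    tile_scale = float(np.clip(rng.lognormal(0.0, 0.6), 0.05, 3.0))

    basin_rows, sub_rows = [], []
    lo, hi = cfg.subbasins_per_basin
    rho = cfg.coupling
    noise = np.sqrt(max(0.0, 1.0 - rho**2))
    for b in range(n_basins):
        basin_id = f"{region}B{b + 1:02d}"
        k = int(rng.integers(lo, hi + 1))
        area = float(rng.lognormal(np.log(45_000.0), 0.35))
        # Basin-level agricultural intensity; subbasins vary around it.
        intensity = rng.normal(0.0, 1.0)

        z_src = 0.6 * intensity + 0.8 * rng.normal(0.0, 1.0, size=k)
        fertmanure_N = np.exp(
            np.log(cfg.source_medians["fertmanure_N"]) + shift["fertmanure_N"]
            + cfg.log_sigma_within * z_src
        )
        fertmanure_P = np.exp(
            np.log(cfg.source_medians["fertmanure_P"]) + shift["fertmanure_P"]
            + cfg.log_sigma_within * (0.9 * z_src + 0.44 * rng.normal(size=k))
        )
        wwtp_N = rng.lognormal(
            np.log(cfg.source_medians["wwtp_N"]) + shift["wwtp_N"], cfg.log_sigma_within, k
        )
        wwtp_P = wwtp_N * rng.lognormal(np.log(0.2), 0.3, k)
        septic_N = rng.lognormal(
            np.log(cfg.source_medians["septic_N"]) + shift["septic_N"],
            cfg.log_sigma_within, k,
        )
        # Stream concentrations: monotone in local source yield plus noise,
        # association strength set by the coupling coefficient.
        z_conc_N = rho * z_src + noise * rng.normal(0.0, 1.0, size=k)
        z_conc_P = rho * z_src + noise * rng.normal(0.0, 1.0, size=k)
        stream_N = np.exp(np.log(1.5) + shift_conc_N + 0.8 * z_conc_N)
        stream_P = np.exp(np.log(0.08) + shift_conc_P + 0.8 * z_conc_P)
        gw_shallow = np.exp(
            np.log(3.0) + shift_gw + 0.8 * (0.8 * rho * z_src
            + np.sqrt(1 - (0.8 * rho) ** 2) * rng.normal(size=k))
        )
        gw_ps = gw_shallow * rng.lognormal(np.log(0.4), 0.4, k)
        tile = rng.beta(cfg.tile_beta[0] * tile_scale, cfg.tile_beta[1], k)
        runoff = rng.gamma(
            cfg.runoff_gamma_shape, cfg.runoff_mean_m / cfg.runoff_gamma_shape, k
        )
        resid_N = rng.normal(0.0, cfg.resid_sigma_pct, k)
        resid_P = rng.normal(0.0, cfg.resid_sigma_pct, k)

        for j in range(k):
            sub_rows.append(
                {
                    "huc08_id": f"{basin_id}S{j + 1:02d}",
                    "basin_id": basin_id,
                    "stream_N_vwm": stream_N[j],
                    "stream_P_vwm": stream_P[j],
                    "fertmanure_N": fertmanure_N[j],
                    "fertmanure_P": fertmanure_P[j],
                    "wwtp_N": wwtp_N[j],
                    "wwtp_P": wwtp_P[j],
                    "septic_N": septic_N[j],
                    "tile_fraction": tile[j],
                    "runoff": runoff[j],
                    "gw_shallow_no3": gw_shallow[j],
                    "gw_ps_no3": gw_ps[j],
                    "resid_N": resid_N[j],
                    "resid_P": resid_P[j],
                }
            )

        a, bb = cfg.biotic_beta
        biotic = rng.beta(a * np.exp(0.3 * (intensity + biotic_shift)), bb)
        basin_rows.append(
            {
                "basin_id": basin_id,
                "region_id": region,
                "area_km2": area,
                "pop_served_per_km2": float(rng.lognormal(np.log(30.0), 1.0)),
                "pct_waterbodies": float(100.0 * rng.beta(1.2, 25.0)),
                "biotic_index": float(np.clip(biotic, 0.0, 1.0)),
                "delivered_N_yield": float(
                    0.15 * fertmanure_N.mean() * rng.lognormal(0.0, 0.4)
                ),
                "delivered_P_yield": float(
                    0.1 * fertmanure_P.mean() * rng.lognormal(0.0, 0.4)
                ),
            }
        )
    return basin_rows, sub_rows


def generate_roster(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (basins, subbasins) table pair from the config.

    Deterministic for a fixed config: the global seed spawns one substream
    per region.  Planted extremes declared in the config are applied after
    generation.  The returned tables always pass :func:`validate_tables`.
    """
    bpr = config.resolved_basins_per_region()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_regions)
    basin_rows, sub_rows = [], []
    for r, (ss, n_basins) in enumerate(zip(streams, bpr)):
        rng = np.random.default_rng(ss)
        b_rows, s_rows = _generate_region(rng, config, r, n_basins)
        basin_rows.extend(b_rows)
        sub_rows.extend(s_rows)
    basins = pd.DataFrame(basin_rows)
    subbasins = pd.DataFrame(sub_rows)
    # impact_dominant last, so its roster-maximum guarantee survives the
    # inflated values a variability plant introduces
    plants = sorted(
        config.planted_extremes, key=lambda p: p["mode"] == "impact_dominant"
    )
    for plant in plants:
        basins, subbasins, _ = plant_extreme(
            basins, subbasins, plant["region"], plant["mode"]
        )
    validate_tables(basins, subbasins)
    return basins, subbasins


def _bounded_extreme(current_max: float, bounds: tuple) -> float:
    hi = current_max * 1.05 if current_max > 0 else 1.0
    if bounds[1] is not None:
        hi = min(hi, bounds[1])
    return hi


def plant_extreme(
    basins: pd.DataFrame,
    subbasins: pd.DataFrame,
    region: str,
    mode: str,
    basin_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Overwrite one basin so a known ranking outcome is guaranteed.

    ``impact_dominant`` sets the basin to the roster maximum on every
    impact-approach variable (its median equals the roster maximum for all
    subbasin variables, receptors at the maximum), so it must take national
    ordinal 1 under the impact approach.  ``variability_dominant`` gives the
    basin the widest subbasin spreads, the roster-minimum minimum stream
    concentrations, the largest residual magnitudes, and top receptor
    values, so it must take region ordinal 1 under the variability approach
    (its region-best water-quality score keeps it eligible).

    Pure: returns modified copies plus the planted basin_id; inputs are
    untouched.
    """
    if mode not in ("impact_dominant", "variability_dominant"):
        raise DomainError(f"unknown planted-extreme mode {mode!r}")
    in_region = basins.loc[basins["region_id"] == region, "basin_id"]
    if in_region.empty:
        raise DomainError(f"region {region!r} has no basins")
    if basin_id is None:
        basin_id = sorted(in_region)[0]
    elif basin_id not in set(in_region):
        raise DomainError(f"basin {basin_id!r} is not in region {region!r}")

    basins = basins.copy()
    subbasins = subbasins.copy()
    b_mask = basins["basin_id"] == basin_id
    s_mask = subbasins["basin_id"] == basin_id

    if mode == "impact_dominant":
        for col in _IMPACT_SUB_COLUMNS:
            subbasins.loc[s_mask, col] = float(subbasins[col].max()) * 1.05
        for col, bounds in _BASIN_RECEPTOR_BOUNDS.items():
            basins.loc[b_mask, col] = _bounded_extreme(float(basins[col].max()), bounds)
        return basins, subbasins, basin_id

    # variability_dominant: alternate subbasins between a low and a high
    # extreme so the interquartile range tops the roster, keep one subbasin
    # below the roster-minimum concentration, and blow up the residuals.
    k = int(s_mask.sum())
    if k < 4:
        # with < 4 subbasins the interquartile range interpolates between a
        # low and a high value and the dominance guarantee breaks
        raise DomainError(
            f"variability_dominant plant needs >= 4 subbasins, basin {basin_id!r} has {k}"
        )
    half = np.arange(k) % 2 == 0  # low half
    for col, bounds in _VARIABILITY_SPREAD_BOUNDS.items():
        vals = pd.to_numeric(subbasins[col], errors="coerce")
        pos = vals[vals > 0]
        low = bounds[0] if bounds[0] is not None else (
            float(pos.min()) * 0.5 if len(pos) else 0.0
        )
        high = _bounded_extreme(float(vals.max()), bounds)
        col_vals = np.where(half, low, high)
        subbasins.loc[s_mask, col] = col_vals
    for col in ("resid_N", "resid_P"):
        mag = float(pd.to_numeric(subbasins[col], errors="coerce").abs().max()) * 1.05
        subbasins.loc[s_mask, col] = np.where(half, -mag, mag)
    for col, bounds in _BASIN_RECEPTOR_BOUNDS.items():
        basins.loc[b_mask, col] = _bounded_extreme(float(basins[col].max()), bounds)
    return basins, subbasins, basin_id
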