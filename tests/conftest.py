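import numpy as np
import pandas as pd
import pytest

from basinrank import SyntheticConfig, generate_roster


def make_small_tables():
    """Hand-written 3-basin / 9-subbasin roster (two regions)."""
    basins = pd.DataFrame(
        {
            "basin_id": ["A", "B", "C"],
            "region_id": ["r1", "r1", "r2"],
            "area_km2": [1000.0, 2000.0, 1500.0],
            "pop_served_per_km2": [10.0, 40.0, 25.0],
            "pct_waterbodies": [2.0, 5.0, 1.0],
            "biotic_index": [0.3, 0.7, 0.5],
            "delivered_N_yield": [100.0, 400.0, 250.0],
            "delivered_P_yield": [10.0, 40.0, 25.0],
        }
    )
    rows = []
    base = {
        "A": dict(conc_N=1.0, conc_P=0.05, src=1000.0, tile=0.1, runoff=0.3,
                  gw=2.0, resid=10.0),
        "B": dict(conc_N=3.0, conc_P=0.20, src=5000.0, tile=0.4, runoff=0.5,
                  gw=6.0, resid=40.0),
        "C": dict(conc_N=2.0, conc_P=0.10, src=2500.0, tile=0.2, runoff=0.2,
                  gw=4.0, resid=25.0),
    }
    for bid, p in base.items():
        for j, f in enumerate((0.5, 1.0, 2.0)):  # spread within basin
            rows.append(
                {
                    "huc08_id": f"{bid}{j}",
                    "basin_id": bid,
                    "stream_N_vwm": p["conc_N"] * f,
                    "stream_P_vwm": p["conc_P"] * f,
                    "fertmanure_N": p["src"] * f,
                    "fertmanure_P": p["src"] * f / 6,
                    "wwtp_N": p["src"] * f / 30,
                    "wwtp_P": p["src"] * f / 150,
                    "septic_N": p["src"] * f / 60,
                    "tile_fraction": min(1.0, p["tile"] * f),
                    "runoff": p["runoff"] * f,
                    "gw_shallow_no3": p["gw"] * f,
                    "gw_ps_no3": p["gw"] * f / 3,
                    "resid_N": p["resid"] * (f - 1.0),
                    "resid_P": -p["resid"] * (f - 1.0),
                }
            )
    return basins, pd.DataFrame(rows)


@pytest.fixture
def small_tables():
    return make_small_tables()


@pytest.fixture(scope="session")
def default_roster():
    """A full 163-basin / 18-region synthetic roster, seed 7."""
    return generate_roster(SyntheticConfig(seed=7))


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation they check)


def oracle_percentile(values, p):
    """Inclusive linear interpolation, written out from its definition."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 1:
        return v[0]
    h = 1.0 + p * (n - 1)
    lo = int(np.floor(h))
    frac = h - lo
    if lo >= n:
        return v[-1]
    return v[lo - 1] + frac * (v[lo] - v[lo - 1])


def oracle_percent_rank(values, direction="ascending"):
    """Pairwise count-strictly-less percent rank."""
    vals = list(values)
    n = len(vals)
    sign = 1.0 if direction == "ascending" else -1.0
    if n == 1:
        return [1.0]
    out = []
    for x in vals:
        less = sum(1 for y in vals if sign * y < sign * x)
        out.append(less / (n - 1))
    return out
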