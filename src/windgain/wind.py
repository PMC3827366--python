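"""Daily ocean-wind processing: U/V vectors, regimes and wind–SSTA statistics.

Wind arrives as daily U (east–west) and V (north–south) components in m/s
under the meteorological sign convention used for satellite-blended ocean
winds: a negative U means the wind comes from the East, a negative V that it
comes from the North. Direction is therefore the compass bearing the wind
blows FROM (0° = North, 90° = East, 180° = South, 270° = West), and speed is
the vector magnitude ``sqrt(u**2 + v**2)``.

SSTA (sea-surface temperature anomaly, °C) is consumed precomputed as the
difference between actual SST and a long-term climatological mean; no
satellite retrieval or climatology computation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import CorrelationResult, TwoSampleTResult, pearson, two_sample_t

__all__ = [
    "uv_to_speed_dir",
    "speed_dir_to_uv",
    "classify_regime",
    "enrich_wind_table",
    "wind_ssta_correlation",
    "year_comparison_uv",
    "CALM_MAX_MS",
    "STORM_MIN_MS",
]

#: "Weak wind" upper bound, m/s (≈ Beaufort 3 and less: no wave formation).
CALM_MAX_MS = 5.0
#: Storm threshold on mean daily wind speed, m/s (inclusive).
STORM_MIN_MS = 13.0


def uv_to_speed_dir(u, v):
    """Convert U/V wind components to (speed, meteorological direction).

    Parameters
    ----------
    u, v : array_like
        East–west and north–south components in m/s (negative U = wind from
        the East, negative V = wind from the North).

    Returns
    -------
    speed : ndarray
        ``sqrt(u**2 + v**2)`` in m/s.
    direction : ndarray
        Bearing the wind comes from, degrees in [0, 360). NaN where the
        speed is exactly zero (direction undefined in calm air).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    # The wind comes from the direction opposite to the flow vector (u, v):
    # bearing of (-u, -v) measured clockwise from North.
    direction = np.degrees(np.arctan2(-u, -v)) % 360.0
    direction = np.where(speed == 0.0, np.nan, direction)
    if np.ndim(speed) == 0:
        return float(speed), float(direction)
    return speed, direction


def speed_dir_to_uv(speed, direction):
    """Inverse of :func:`uv_to_speed_dir` (exact off the origin)."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("wind speed must be nonnegative")
    rad = np.deg2rad(np.asarray(direction, dtype=float))
    u = -speed * np.sin(rad)
    v = -speed * np.cos(rad)
    if np.ndim(u) == 0:
        return float(u), float(v)
    return u, v


def classify_regime(direction, speed, *, boundary_180: str = "westerly"):
    """Classify days into direction sector × speed class.

    Sectors: ``westerly`` for directions in [180, 360), ``easterly`` for
    [0, 180). The 180° boundary is ambiguous in compass terms; it defaults to
    the westerly sector but the tie rule is configurable
    (``boundary_180="easterly"`` flips it). Undefined directions (calm days)
    yield sector ``undefined`` while the speed class is still returned.

    Speed classes: ``calm`` (≤ 5 m/s), ``storm`` (≥ 13 m/s), else
    ``moderate``.
    """
    if boundary_180 not in ("westerly", "easterly"):
        raise ValueError("boundary_180 must be 'westerly' or 'easterly'")
    direction = np.asarray(direction, dtype=float)
    speed = np.asarray(speed, dtype=float)
    d = np.mod(direction, 360.0)
    if boundary_180 == "westerly":
        west = d >= 180.0
    else:
        west = d > 180.0
    sector = np.where(west, "westerly", "easterly").astype(object)
    sector = np.where(np.isnan(d), "undefined", sector)
    speed_class = np.where(
        speed <= CALM_MAX_MS, "calm", np.where(speed >= STORM_MIN_MS, "storm", "moderate")
    ).astype(object)
    if direction.ndim == 0:
        return str(sector[()]), str(speed_class[()])
    return sector, speed_class


def enrich_wind_table(wind: pd.DataFrame, *, boundary_180: str = "westerly") -> pd.DataFrame:
    """Add speed, direction, sector and speed class to a daily wind table.

    Expects columns ``u_ms``, ``v_ms`` (and passes anything else, e.g.
    ``date`` and ``ssta_c``, through untouched).
    """
    for col in ("u_ms", "v_ms"):
        if col not in wind.columns:
            raise ValueError(f"wind table lacks required column {col!r}")
    out = wind.copy()
    speed, direction = uv_to_speed_dir(out["u_ms"].to_numpy(), out["v_ms"].to_numpy())
    sector, speed_class = classify_regime(direction, speed, boundary_180=boundary_180)
    out["speed_ms"] = speed
    out["direction_deg"] = direction
    out["sector"] = sector
    out["speed_class"] = speed_class
    return out


def wind_ssta_correlation(wind: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between daily wind speed and daily SSTA.

    Days missing either value are dropped listwise; the reported ``n`` is the
    post-deletion count. A zero-variance input is flagged degenerate.
    """
    df = wind
    if "speed_ms" not in df.columns:
        df = enrich_wind_table(df)
    if "ssta_c" not in df.columns:
        raise ValueError("wind table lacks required column 'ssta_c'")
    return pearson(df["speed_ms"].to_numpy(), df["ssta_c"].to_numpy())


@dataclass(frozen=True)
class UVYearComparison:
    u: TwoSampleTResult
    v: TwoSampleTResult
    groups: tuple[str, str]
    #: Why the test runs on components: direction is circular, so t-tests on
    #: speed/direction themselves would be ill-defined across the 0/360 seam.
    rationale: str = (
        "independent t-tests on the U and V wind components; direction is a "
        "circular variable, so components are compared instead of "
        "speed/direction directly"
    )


def year_comparison_uv(wind: pd.DataFrame, season_col: str = "season") -> UVYearComparison:
    """Between-season comparison of wind via component-wise Student t-tests."""
    if season_col not in wind.columns:
        raise ValueError(f"wind table lacks season column {season_col!r}")
    groups = [str(g) for g in pd.unique(wind[season_col].dropna())]
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 season groups, got {groups}")
    a = wind[wind[season_col] == groups[0]]
    b = wind[wind[season_col] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each season needs at least 2 days of wind data")
    return UVYearComparison(
        u=two_sample_t(a["u_ms"].to_numpy(), b["u_ms"].to_numpy()),
        v=two_sample_t(a["v_ms"].to_numpy(), b["v_ms"].to_numpy()),
        groups=(groups[0], groups[1]),
    )
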