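"""Scenario read-outs: percent changes vs. baseline, prey aggregates, stability.

Because the web does not settle to a fixed point even after a century of
seasons, point comparisons at a single year are fragile; percent changes are
therefore averaged over the final ``window`` end-of-season values of each
period (unfished burn-in vs. fished), and both the windowed mean and the
per-year series are available.  Fluctuation is summarized as the coefficient
of variation (population sd / mean) over sliding windows of annual values at a
fixed record day; mid-season values are tracked alongside end-of-season ones
because plankton biomasses cycle within the season.
"""

from __future__ import annotations

import numpy as np

from .simulate import ScenarioResult

__all__ = [
    "ADULT_PREY_GUILDS",
    "LARVAL_PREY_GUILDS",
    "percent_change",
    "percent_change_series",
    "prey_aggregate",
    "stability_cv",
    "catch_comparison",
]

#: Zooplankton prey of adult and juvenile fish.
ADULT_PREY_GUILDS = ("daphnia", "cyclopoid", "leptodora")
#: Shared prey of whitefish and perch larvae.
LARVAL_PREY_GUILDS = ("rotifer_small", "rotifer_medium", "rotifer_large", "daphnia", "cyclopoid")

_GROUPS = {"adult_prey": ADULT_PREY_GUILDS, "larval_prey": LARVAL_PREY_GUILDS}


def _period_slice(result: ScenarioResult, period: str) -> slice:
    u = result.config.years_unfished
    if period == "unfished":
        return slice(0, u)
    if period == "fished":
        return slice(u, result.years)
    if period == "all":
        return slice(0, result.years)
    raise ValueError(f"unknown period {period!r}")


def _resolve_series(result: ScenarioResult, guild_or_group: str, day: float | None) -> np.ndarray:
    if guild_or_group in _GROUPS:
        return prey_aggregate(result, guild_or_group, day)
    return result.series(guild_or_group, day)


def percent_change_series(
    treatment: ScenarioResult,
    baseline: ScenarioResult,
    guild_or_group: str,
    period: str = "all",
    day: float | None = None,
) -> np.ndarray:
    """Per-year 100·(treatment − baseline)/baseline at a record day (default end)."""
    if treatment.years != baseline.years or treatment.config.years_unfished != baseline.config.years_unfished:
        raise ValueError("treatment and baseline runs must cover matching year ranges")
    sl = _period_slice(treatment, period)
    t = _resolve_series(treatment, guild_or_group, day)[sl]
    b = _resolve_series(baseline, guild_or_group, day)[sl]
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * (t - b) / b
    pc[b == 0] = np.nan  # undefined against a zero baseline, flagged not ±inf
    return pc


def percent_change(
    treatment: ScenarioResult,
    baseline: ScenarioResult,
    guild_or_group: str,
    period: str = "all",
    window: int = 10,
    day: float | None = None,
) -> float:
    """Percent change averaged over the terminal ``window`` years of the period.

    Positive values mean the treatment increased the end-of-season density.
    Identical runs give exactly 0.  NaN flags a zero baseline.
    """
    pc = percent_change_series(treatment, baseline, guild_or_group, period, day)
    if pc.size == 0:
        raise ValueError(f"period {period!r} contains no years")
    return float(np.mean(pc[-min(window, pc.size):]))


def prey_aggregate(result: ScenarioResult, group: str, day: float | None = None) -> np.ndarray:
    """Summed annual biomass series of a named prey group (adult_prey / larval_prey)."""
    try:
        members = _GROUPS[group]
    except KeyError:
        raise ValueError(f"unknown prey group {group!r}; expected one of {sorted(_GROUPS)}") from None
    missing = [g for g in members if g not in result.web.guild_ids]
    if missing:
        raise KeyError(f"prey group {group!r}: guilds absent from web: {missing}")
    return np.sum([result.series(g, day) for g in members], axis=0)


def stability_cv(series: np.ndarray, window_years: int = 10) -> np.ndarray:
    """Coefficient of variation (population sd / mean) over sliding windows.

    One value per window start; a nonpositive window mean yields NaN (flagged).
    CV is scale-invariant, so the statistic compares fluctuation across arms
    whose absolute biomasses differ.
    """
    series = np.asarray(series, dtype=float)
    if window_years < 2:
        raise ValueError("window must span at least 2 years")
    if series.size < window_years:
        return np.empty(0)
    out = np.empty(series.size - window_years + 1)
    for k in range(out.size):
        w = series[k : k + window_years]
        mu = w.mean()
        out[k] = np.nan if mu <= 0 else w.std() / mu
    return out


def catch_comparison(
    treatment: ScenarioResult,
    baseline: ScenarioResult,
    window: int = 10,
) -> dict[str, float]:
    """Percent change in annual per-stage catch over the fished period.

    Returns an empty mapping when no fishing years exist; stages never caught
    (zero baseline catch) are flagged NaN.
    """
    if treatment.config.years_fished == 0:
        return {}
    sl = _period_slice(treatment, "fished")
    out: dict[str, float] = {}
    for sid in treatment.fish_ids:
        t = treatment.catch_series(sid)[sl][-window:]
        b = baseline.catch_series(sid)[sl][-window:]
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = 100.0 * (t - b) / b
        pc[b == 0] = np.nan
        out[sid] = float(np.mean(pc)) if pc.size else np.nan
    return out
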