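"""Fish stage bookkeeping: end-of-season aging, recruitment and stocking.

Each fish species carries five stages (larva, juvenile/1-y, 2-y, 3-y, 4-y+).
At the end of each 90-day growth season the cohorts shift one stage up, the
final stage accumulates, and a fraction ρ of the mature stages' net
productivity — the season integral of assimilation minus metabolism,
∫ x_i B_i (y_i Σ_j F_ij − 1) dt, floored at 0 at read-out — becomes next
season's larvae.  Species without natural reproduction (whitefish) recruit
nothing; their larvae come from stocking only, injected additively at the
start of each season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .web import FoodWeb, FishSpecies, N_STAGES

__all__ = ["StockingPlan", "production_rate", "end_of_season_transition", "apply_stocking"]


@dataclass
class StockingPlan:
    """Larval biomass density (µgC m⁻³) added per species at each season start.

    ``densities`` maps species name to either a scalar applied every year or a
    per-year sequence (year index beyond the sequence reuses the final entry).
    """

    densities: dict = field(default_factory=dict)

    def density(self, species: str, year: int) -> float:
        v = self.densities.get(species, 0.0)
        if np.ndim(v) > 0:
            seq = list(v)
            v = seq[min(year, len(seq) - 1)] if seq else 0.0
        v = float(v)
        if v < 0:
            raise ValueError(f"stocking density for {species!r} in year {year} is negative")
        return v

    def __add__(self, other: "StockingPlan") -> "StockingPlan":
        names = set(self.densities) | set(other.densities)
        merged = {}
        for nm in names:
            a, b = self.densities.get(nm, 0.0), other.densities.get(nm, 0.0)
            if np.ndim(a) > 0 or np.ndim(b) > 0:
                raise TypeError("cannot add plans with per-year schedules")
            merged[nm] = float(a) + float(b)
        return StockingPlan(merged)


def production_rate(B: np.ndarray, F_rows: np.ndarray, arrays) -> np.ndarray:
    """dP_i/dt = x_i B_i (y_i Σ_j F_ij − 1) for every guild (used on fish stages).

    Integrated alongside the biomass ODE as auxiliary state; the ledger is
    floored at zero only at the season-end read-out, so a stage that loses mass
    early and gains later is credited with its net season balance.
    """
    Fsum = np.zeros(arrays.n)
    Fsum[arrays.cons_idx] = F_rows.sum(axis=1)
    return arrays.x * np.maximum(B, 0.0) * (arrays.y * Fsum - 1.0)


def end_of_season_transition(
    B_end: np.ndarray,
    production: dict[str, np.ndarray] | None,
    web: FoodWeb,
) -> np.ndarray:
    """Age fish stages and recruit larvae; all non-fish guilds carry over unchanged.

    ``production`` maps species name to the per-stage net-production read-out
    (already season-integrated); negative entries are floored at 0.  New larvae
    = ρ · Σ over mature stages, zero for species without natural reproduction.
    """
    B_end = np.asarray(B_end, dtype=float)
    if np.any(B_end < 0):
        bad = np.flatnonzero(B_end < 0).tolist()
        raise ValueError(f"negative biomass at guild indices {bad}")
    B_next = B_end.copy()
    for sp in web.fish_species:
        idx = [web.index(sid) for sid in sp.stage_ids]
        old = B_end[idx]
        recruits = 0.0
        if sp.natural_reproduction and sp.rho > 0 and production is not None:
            P = np.maximum(np.asarray(production[sp.name], dtype=float), 0.0)
            recruits = sp.rho * float(P[np.asarray(sp.mature)].sum())
        shifted = np.empty(N_STAGES)
        shifted[0] = recruits
        shifted[1:-1] = old[:-2]
        shifted[-1] = old[-2] + old[-1]      # 4-y+ accumulates
        B_next[idx] = shifted
    return B_next


def apply_stocking(B_start: np.ndarray, plan: StockingPlan, web: FoodWeb, year: int = 0) -> np.ndarray:
    """Add the planned larval density to each species' larval guild at t = 0."""
    for name in plan.densities:
        web.species(name)  # raises KeyError for unknown species
    B = np.asarray(B_start, dtype=float).copy()
    for sp in web.fish_species:
        dens = plan.density(sp.name, year)
        if dens:
            B[web.index(sp.larva_id)] += dens
    return B
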