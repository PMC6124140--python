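"""Age-selective fishing mortality and catch accounting.

Fishing acts as a continuous instantaneous mortality through every day of a
fishing-year season: stage i loses F_max · S_i · B_i per day, and the same
flux accumulates in the catch ledger dC_i/dt = F_max · S_i · B_i.  The default
policy is the 90-day-season construction F_max = 0.5/(90+1) per day with
selectivities 0 for larvae and juveniles, 1/3 for 2-y, 2/3 for 3-y and 1 for
4-y+ fish; both species are fished with the same policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .web import FoodWeb, N_STAGES

__all__ = ["DEFAULT_F_MAX", "DEFAULT_SELECTIVITY", "HarvestPolicy", "harvest_rate_vector"]

DEFAULT_F_MAX = 0.5 / (90 + 1)                       # day⁻¹
DEFAULT_SELECTIVITY = (0.0, 0.0, 1 / 3, 2 / 3, 1.0)  # larva, juvenile, 2y, 3y, 4y+


@dataclass
class HarvestPolicy:
    """Maximum instantaneous fishing mortality and per-stage selectivity."""

    F_max: float = DEFAULT_F_MAX
    S: tuple[float, ...] = DEFAULT_SELECTIVITY

    def __post_init__(self) -> None:
        self.S = tuple(float(s) for s in self.S)
        if len(self.S) != N_STAGES:
            raise ValueError(f"selectivity needs {N_STAGES} entries")
        if self.F_max < 0 or any(not 0 <= s <= 1 for s in self.S):
            raise ValueError("require F_max ≥ 0 and 0 ≤ S ≤ 1")

    def rate(self, stage_index: int, active: bool = True) -> float:
        """Per-day mortality F_max · S[stage]; 0 outside active fishing years."""
        if not active:
            return 0.0
        return self.F_max * self.S[stage_index]


def harvest_rate_vector(web: FoodWeb, policy: HarvestPolicy | None, active: bool) -> np.ndarray | None:
    """Per-guild instantaneous mortality vector for the RHS, or None when idle."""
    if policy is None or not active or policy.F_max == 0:
        return None
    rates = np.zeros(web.n_guilds)
    for sp in web.fish_species:
        for k, sid in enumerate(sp.stage_ids):
            rates[web.index(sid)] = policy.rate(k)
    return rates
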