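"""Food-web data model: guilds, feeding links, fish species scaffolds, validation and I/O.

Biomasses throughout the package are relative carbon densities in µgC m⁻³ and
rates are per day.  A web couples three layers:

* basal producers sharing one logistic carrying capacity ``K``;
* consumers (bacteria, zooplankton) with bioenergetic rates ``x`` (mass-specific
  metabolism), ``y`` (maximum consumption as a multiple of metabolism), ``B0``
  (half-saturation density), ``q`` (functional-response shape) and ``d``
  (intraspecific predator interference);
* fish guilds, each of which is one life-history stage of a :class:`FishSpecies`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Guild",
    "FeedingLink",
    "FishSpecies",
    "FoodWeb",
    "ValidationReport",
    "WebValidationError",
    "validate_web",
    "read_web_json",
    "write_web_json",
    "read_web_csv",
    "write_web_csv",
]

ROLES = ("producer", "consumer", "fish_stage")
N_STAGES = 5
STAGE_NAMES = ("larva", "juvenile", "2y", "3y", "4y+")

OMEGA_TOL = 1e-9


class WebValidationError(ValueError):
    """Raised when a food web violates a structural invariant."""


@dataclass
class Guild:
    """One node of the web: a functional guild.

    Parameters with no meaning for a role are left at 0 (e.g. ``r`` for
    consumers, ``x``/``y``/``B0`` for producers).
    """

    id: str
    name: str = ""
    role: str = "consumer"
    body_mass: float = 1.0          # µgC per individual
    r: float = 0.0                  # producer intrinsic growth rate, day⁻¹
    x: float = 0.0                  # mass-specific metabolic rate, day⁻¹
    y: float = 0.0                  # max consumption / metabolism, dimensionless
    B0: float = 0.0                 # half-saturation density, µgC m⁻³
    q: float = 1.0                  # functional-response shape exponent (≥ 1)
    d: float = 0.0                  # predator interference, per (µgC m⁻³)

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id

    @property
    def is_producer(self) -> bool:
        return self.role == "producer"


@dataclass
class FeedingLink:
    """Directed consumer→prey edge with diet preference ω and assimilation efficiency e."""

    consumer_id: str
    prey_id: str
    omega: float                    # diet preference, Σ over prey = 1 per consumer
    e: float                        # assimilation efficiency, 0 < e ≤ 1


@dataclass
class FishSpecies:
    """Five life-history stages of one fish species.

    ``stage_ids`` are ordered larva, juvenile (1-y), 2-y, 3-y, 4-y+; the last
    stage is an accumulator.  A fraction ``rho`` of the mature stages'
    season-integrated net productivity becomes next season's larvae, unless
    ``natural_reproduction`` is off (whitefish: the population persists through
    stocking only).
    """

    name: str
    stage_ids: tuple[str, ...]
    mature: tuple[bool, ...] = (False, False, True, True, True)
    rho: float = 0.0
    natural_reproduction: bool = True

    def __post_init__(self) -> None:
        self.stage_ids = tuple(self.stage_ids)
        self.mature = tuple(bool(m) for m in self.mature)
        if len(self.stage_ids) != N_STAGES:
            raise WebValidationError(
                f"species {self.name!r}: expected {N_STAGES} stages, got {len(self.stage_ids)}"
            )
        if len(self.mature) != N_STAGES:
            raise WebValidationError(f"species {self.name!r}: mature flags must have length {N_STAGES}")
        if not 0.0 <= self.rho <= 1.0:
            raise WebValidationError(f"species {self.name!r}: rho must be in [0, 1]")

    @property
    def larva_id(self) -> str:
        return self.stage_ids[0]


@dataclass
class FoodWeb:
    """Guilds + feeding links + shared producer carrying capacity + fish scaffolds."""

    guilds: list[Guild]
    links: list[FeedingLink]
    K: float                        # shared producer carrying capacity, µgC m⁻³
    fish_species: list[FishSpecies] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g.id: i for i, g in enumerate(self.guilds)}
        if len(self._index) != len(self.guilds):
            seen: set[str] = set()
            dups = [g.id for g in self.guilds if g.id in seen or seen.add(g.id)]
            raise WebValidationError(f"duplicate guild ids: {sorted(set(dups))}")

    # -- lookups -------------------------------------------------------------
    @property
    def n_guilds(self) -> int:
        return len(self.guilds)

    @property
    def guild_ids(self) -> list[str]:
        return [g.id for g in self.guilds]

    def index(self, guild_id: str) -> int:
        try:
            return self._index[guild_id]
        except KeyError:
            raise KeyError(f"unknown guild id {guild_id!r}") from None

    def guild(self, guild_id: str) -> Guild:
        return self.guilds[self.index(guild_id)]

    def species(self, name: str) -> FishSpecies:
        for sp in self.fish_species:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown fish species {name!r}")

    def prey_of(self, consumer_id: str) -> list[FeedingLink]:
        return [l for l in self.links if l.consumer_id == consumer_id]

    def fish_stage_indices(self) -> np.ndarray:
        idx = [self.index(sid) for sp in self.fish_species for sid in sp.stage_ids]
        return np.asarray(idx, dtype=int)


@dataclass
class ValidationReport:
    n_guilds: int
    n_links: int
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        head = f"{self.n_guilds} guilds, {self.n_links} links"
        if self.ok:
            return head + " (valid)"
        return head + "; violations:\n  " + "\n  ".join(self.violations)


def validate_web(web: FoodWeb, raise_on_error: bool = True) -> ValidationReport:
    """Check structural invariants; report counts, ω residuals and offenders.

    Hard violations raise :class:`WebValidationError` unless ``raise_on_error``
    is False, in which case they are listed in the report.
    """
    rep = ValidationReport(n_guilds=web.n_guilds, n_links=len(web.links))
    bad = rep.violations

    if web.n_guilds == 0:
        bad.append("no guilds")
        if raise_on_error:
            raise WebValidationError("no guilds")
        return rep
    if web.K <= 0:
        bad.append(f"carrying capacity K must be > 0, got {web.K}")

    ids = set(web.guild_ids)
    for g in web.guilds:
        if g.role not in ROLES:
            bad.append(f"guild {g.id}: unknown role {g.role!r}")
        if g.body_mass <= 0:
            bad.append(f"guild {g.id}: body_mass must be > 0")
        if g.is_producer:
            if g.r <= 0:
                bad.append(f"producer {g.id}: r must be > 0")
            if g.x != 0:
                bad.append(f"producer {g.id}: x must be 0")
        else:
            if g.x <= 0:
                bad.append(f"consumer {g.id}: x must be > 0")
            if g.y <= 0:
                bad.append(f"consumer {g.id}: y must be > 0")
            if g.B0 <= 0:
                bad.append(f"consumer {g.id}: B0 must be > 0")
            if g.q < 1:
                bad.append(f"consumer {g.id}: q must be ≥ 1")
            if g.d < 0:
                bad.append(f"consumer {g.id}: d must be ≥ 0")

    omega_sums: dict[str, float] = {}
    linked: set[str] = set()
    for l in web.links:
        if l.consumer_id not in ids:
            bad.append(f"link {l.consumer_id}->{l.prey_id}: unknown consumer")
            continue
        if l.prey_id not in ids:
            bad.append(f"link {l.consumer_id}->{l.prey_id}: unknown prey")
            continue
        linked.update((l.consumer_id, l.prey_id))
        if l.consumer_id == l.prey_id:
            bad.append(f"self-link on {l.consumer_id}")
        if web.guild(l.consumer_id).is_producer:
            bad.append(f"producer {l.consumer_id} has an outgoing feeding link")
        if not 0 < l.omega <= 1:
            bad.append(f"link {l.consumer_id}->{l.prey_id}: omega must be in (0, 1]")
        if not 0 < l.e <= 1:
            bad.append(f"link {l.consumer_id}->{l.prey_id}: e must be in (0, 1]")
        omega_sums[l.consumer_id] = omega_sums.get(l.consumer_id, 0.0) + l.omega

    for g in web.guilds:
        if g.is_producer:
            continue
        s = omega_sums.get(g.id)
        if s is None:
            bad.append(f"consumer {g.id} has no prey links")
        elif abs(s - 1.0) > OMEGA_TOL:
            bad.append(f"consumer {g.id}: diet preferences sum to {s:.12g}, not 1")

    orphans = ids - linked
    # an isolated producer is legitimate (logistic toy); flag isolated consumers only
    for oid in sorted(orphans):
        if not web.guild(oid).is_producer:
            pass  # already reported as "no prey links"

    stage_owner: dict[str, str] = {}
    for sp in web.fish_species:
        for sid in sp.stage_ids:
            if sid not in ids:
                bad.append(f"species {sp.name}: stage {sid} not a guild")
                continue
            if web.guild(sid).role != "fish_stage":
                bad.append(f"species {sp.name}: guild {sid} is not a fish_stage")
            if sid in stage_owner:
                bad.append(f"stage {sid} claimed by both {stage_owner[sid]} and {sp.name}")
            stage_owner[sid] = sp.name
    for g in web.guilds:
        if g.role == "fish_stage" and g.id not in stage_owner:
            bad.append(f"fish stage {g.id} not assigned to any species")

    if bad and raise_on_error:
        raise WebValidationError(rep.summary())
    return rep


# -- serialization ------------------------------------------------------------

_GUILD_COLS = ["id", "name", "role", "body_mass", "r", "x", "y", "B0", "q", "d"]
_LINK_COLS = ["consumer_id", "prey_id", "omega", "e"]


def _web_to_dict(web: FoodWeb) -> dict:
    return {
        "K": web.K,
        "guilds": [asdict(g) for g in web.guilds],
        "links": [asdict(l) for l in web.links],
        "fish_species": [
            {
                "name": sp.name,
                "stage_ids": list(sp.stage_ids),
                "mature": list(sp.mature),
                "rho": sp.rho,
                "natural_reproduction": sp.natural_reproduction,
            }
            for sp in web.fish_species
        ],
        "metadata": web.metadata,
    }


def _web_from_dict(doc: dict) -> FoodWeb:
    return FoodWeb(
        guilds=[Guild(**g) for g in doc["guilds"]],
        links=[FeedingLink(**l) for l in doc["links"]],
        K=float(doc["K"]),
        fish_species=[FishSpecies(**sp) for sp in doc.get("fish_species", [])],
        metadata=doc.get("metadata", {}),
    )


def write_web_json(web: FoodWeb, path: str | Path) -> None:
    """Write a single-document JSON bundle (guilds, links, K, fish_species)."""
    Path(path).write_text(json.dumps(_web_to_dict(web), indent=1, sort_keys=True))


def read_web_json(path: str | Path) -> FoodWeb:
    return _web_from_dict(json.loads(Path(path).read_text()))


def write_web_csv(web: FoodWeb, guilds_path: str | Path, links_path: str | Path) -> None:
    """Write guilds.csv / links.csv (K and fish scaffolds live in web.json only)."""
    gdf = pd.DataFrame([asdict(g) for g in web.guilds], columns=_GUILD_COLS)
    ldf = pd.DataFrame([asdict(l) for l in web.links], columns=_LINK_COLS)
    gdf.to_csv(guilds_path, index=False)
    ldf.to_csv(links_path, index=False)


def read_web_csv(
    guilds_path: str | Path,
    links_path: str | Path,
    K: float,
    fish_species: Sequence[FishSpecies] = (),
) -> FoodWeb:
    gdf = pd.read_csv(guilds_path).fillna(0.0)
    ldf = pd.read_csv(links_path)
    guilds = [Guild(**{k: row[k] for k in _GUILD_COLS if k in row}) for row in gdf.to_dict("records")]
    links = [FeedingLink(**{k: row[k] for k in _LINK_COLS}) for row in ldf.to_dict("records")]
    return FoodWeb(guilds=guilds, links=links, K=K, fish_species=list(fish_species))
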