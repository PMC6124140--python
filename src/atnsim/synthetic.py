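"""Synthetic food-web generation: exact toy webs and a Lake-Constance-like web.

The LC-like generator emulates the structure of a deep pre-alpine lake
community: ~30 functional guilds (phytoplankton size classes sharing one
carrying capacity, bacteria, a micro- to macro-zooplankton ladder) linked by
~133 feeding interactions, plus two fish species — planktivorous whitefish and
perch whose 2-year-old and older stages are piscivorous — each resolved into
five life-history stages.  Plankton topology follows a body-mass-ordered
feasibility rule (consumers eat guilds 5–10⁵ times lighter, preference peaking
near a 100:1 ratio) pruned or augmented to hit the target link count exactly;
fish diets are fixed by functionality (whitefish never eat fish; both larval
stages share one zooplankton prey set and one interference coefficient).
Everything is deterministic given the recipe's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .web import FeedingLink, FishSpecies, FoodWeb, Guild, validate_web

__all__ = [
    "AllometricConstants",
    "WebRecipe",
    "allometric_rates",
    "make_toy_web",
    "make_lc_like_web",
]


@dataclass(frozen=True)
class AllometricConstants:
    """Metabolic scaling x = a_x (M/M_ref)^exponent, capped, and role-level y."""

    a_x: float = 0.15          # day⁻¹ at the reference mass
    M_ref: float = 1.0         # µgC
    exponent: float = -0.25
    x_cap: float = 1.0         # day⁻¹; stands in for measured microbial turnover
    y_invertebrate: float = 8.0
    y_fish: float = 4.0


def allometric_rates(
    body_mass: float,
    role: str,
    constants: AllometricConstants = AllometricConstants(),
    x_override: float | None = None,
    y_override: float | None = None,
) -> tuple[float, float]:
    """(x, y) for a consumer guild from quarter-power mass scaling.

    Directly measured rates, when supplied as overrides, win over allometry.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    c = constants
    x = min(c.a_x * (body_mass / c.M_ref) ** c.exponent, c.x_cap)
    y = c.y_fish if role == "fish_stage" else c.y_invertebrate
    if x_override is not None:
        x = x_override
    if y_override is not None:
        y = y_override
    return x, y


# ---------------------------------------------------------------------------
# toy webs (exact fixtures for analytic tests)
# ---------------------------------------------------------------------------

def make_toy_web(kind: str, **kw) -> FoodWeb:
    """Deterministic miniature webs for exact tests.

    ``logistic``     one producer, no links;
    ``chain``        producer → consumer, ω = 1;
    ``competition``  two consumers sharing one producer prey, ω = 1 each.
    """
    K = kw.get("K", 100.0)
    r = kw.get("r", 1.0)
    cons = dict(x=kw.get("x", 0.2), y=kw.get("y", 6.0), B0=kw.get("B0", 50.0),
                q=kw.get("q", 1.0), d=kw.get("d", 0.0))
    e = kw.get("e", 0.45)
    if kind == "logistic":
        return FoodWeb([Guild("prod", role="producer", r=r)], [], K=K)
    if kind == "chain":
        guilds = [Guild("prod", role="producer", r=r),
                  Guild("cons", role="consumer", body_mass=10.0, **cons)]
        return FoodWeb(guilds, [FeedingLink("cons", "prod", 1.0, e)], K=K)
    if kind == "competition":
        guilds = [Guild("prod", role="producer", r=r),
                  Guild("cons_a", role="consumer", body_mass=10.0, **cons),
                  Guild("cons_b", role="consumer", body_mass=10.0, **cons)]
        links = [FeedingLink("cons_a", "prod", 1.0, e), FeedingLink("cons_b", "prod", 1.0, e)]
        return FoodWeb(guilds, links, K=K)
    raise ValueError(f"unknown toy web {kind!r}")


# ---------------------------------------------------------------------------
# LC-like web
# ---------------------------------------------------------------------------

# guild scaffold: (id, role-group, body mass µgC per individual)
_PRODUCERS = [
    ("algae_pico", 2e-7), ("algae_small", 1e-5), ("algae_medium", 5e-4),
    ("algae_large", 2e-2), ("cyanobacteria", 0.1), ("algae_colonial", 0.5),
]
_BACTERIA = [("bacteria_free", 1e-7), ("bacteria_attached", 5e-7)]
_ZOOPLANKTON = [
    ("flagellate_het", 1e-6), ("ciliate_small", 1e-4), ("ciliate_large", 1e-3),
    ("rotifer_small", 5e-3), ("rotifer_medium", 2e-2), ("rotifer_large", 8e-2),
    ("bosmina", 0.5), ("cyclopoid", 3.0), ("calanoid", 4.0), ("daphnia", 5.0),
    ("leptodora", 60.0), ("chaoborus", 150.0),
]
# bacteria tap the smallest producers (exudate/DOC shortcut; no detritus pool)
_BACTERIA_DIETS = {
    "bacteria_free": ["algae_pico"],
    "bacteria_attached": ["algae_pico", "algae_small"],
}

# calibration targets: plankton standing stocks (µgC m⁻³) the generated web is
# balanced around, and nominal fish standing stocks used for the plankton-side
# predation budget (fish themselves are driven by stocking/aging, not
# equilibrium).  Producers split half the carrying capacity, so the shared
# logistic factor at target is G* = 0.5.
_TARGET_B = {
    "bacteria_free": 5e3, "bacteria_attached": 5e3,
    "flagellate_het": 2e3, "ciliate_small": 2e3, "ciliate_large": 2e3,
    "rotifer_small": 5e3, "rotifer_medium": 5e3, "rotifer_large": 5e3,
    "bosmina": 5e3, "cyclopoid": 1.5e4, "calanoid": 1.5e4, "daphnia": 2e4,
    "leptodora": 3e3, "chaoborus": 3e3,
}
_TARGET_FISH_B = {
    "whitefish_larva": 500.0, "whitefish_juvenile": 800.0, "whitefish_2y": 1e3,
    "whitefish_3y": 1e3, "whitefish_4y": 5e3,
    "perch_larva": 300.0, "perch_juvenile": 500.0, "perch_2y": 800.0,
    "perch_3y": 800.0, "perch_4y": 2e3,
}

_LARVAL_PREY = ["rotifer_small", "rotifer_medium", "rotifer_large", "daphnia", "cyclopoid"]
_JUVENILE_PREY = ["daphnia", "cyclopoid", "leptodora", "bosmina", "calanoid"]
_ADULT_WHT_PREY = ["daphnia", "cyclopoid", "leptodora", "calanoid"]
_FISH_PREY = ["whitefish_larva", "whitefish_juvenile", "perch_larva", "perch_juvenile"]

_WHT_MASSES = (1.0e3, 1.0e6, 5.0e6, 1.5e7, 4.0e7)
_PER_MASSES = (8.0e2, 8.0e5, 4.0e6, 1.2e7, 3.0e7)


@dataclass
class WebRecipe:
    """Everything that determines one LC-like synthetic web."""

    seed: int = 1
    n_links: int = 133
    K: float = 5.0e5                     # µgC m⁻³ shared producer ceiling
    constants: AllometricConstants = field(default_factory=AllometricConstants)
    # feeding-window / preference-kernel parameters for plankton topology
    zoo_q: float = 1.2
    ratio_window: tuple[float, float] = (5.0, 1.0e5)   # consumer/prey mass ratio
    log10_ratio_opt: float = 2.0
    log10_ratio_sd: float = 0.8
    mass_jitter_sd: float = 0.10         # lognormal σ (log10) on plankton masses
    omega_jitter_sd: float = 0.25
    e_plant: float = 0.45
    e_animal: float = 0.85
    # equilibrium calibration: consumers get the B0 making their bare (d=0)
    # response equal bare_F at the target stocks, then d absorbs the surplus
    bare_F: float = 0.8
    r_bounds: tuple[float, float] = (0.05, 2.5)        # producer growth clamps, day⁻¹
    # fish parameters
    fish_d: float = 4.0e-4
    old_perch_d: float = 8.0e-4          # stronger interference: better competitor
    fish_q: float = 1.2
    fish_bare_F: float = 0.6
    perch_rho: float = 0.25              # recruited fraction of mature net production
    larval_x: float = 0.05               # day⁻¹; measured-rate override: larval metabolism
    # far exceeds the adult quarter-power scaling, making the larval stage
    # strongly food-limited (the density dependence that regulates stocking)
    larval_mass_ugC: float = 1.0e3       # metadata only: ≈ one larva per 5 m³ at 200 µgC m⁻³

    def to_dict(self) -> dict:
        d = asdict(self)
        d["constants"] = asdict(self.constants)
        return d


def _fish_guilds_and_links(recipe: WebRecipe) -> tuple[list[Guild], list[FeedingLink], list[FishSpecies]]:
    c = recipe.constants
    guilds: list[Guild] = []
    links: list[FeedingLink] = []

    def add_stage(gid: str, mass: float, d: float) -> None:
        x_over = recipe.larval_x if gid.endswith("_larva") else None
        x, y = allometric_rates(mass, "fish_stage", c, x_override=x_over)
        guilds.append(Guild(gid, role="fish_stage", body_mass=mass, x=x, y=y,
                            B0=1.0, q=recipe.fish_q, d=d))  # B0 set by calibration

    def add_diet(gid: str, prey: list[str]) -> None:
        w = 1.0 / len(prey)
        for p in prey:
            links.append(FeedingLink(gid, p, w, recipe.e_animal))

    stage_suffix = ("larva", "juvenile", "2y", "3y", "4y")
    for sp, masses in (("whitefish", _WHT_MASSES), ("perch", _PER_MASSES)):
        for suffix, mass in zip(stage_suffix, masses):
            d = recipe.old_perch_d if (sp, suffix) == ("perch", "4y") else recipe.fish_d
            add_stage(f"{sp}_{suffix}", mass, d)

    # whitefish: solely planktivorous at every stage
    add_diet("whitefish_larva", _LARVAL_PREY)
    add_diet("whitefish_juvenile", _JUVENILE_PREY)
    for s in ("2y", "3y", "4y"):
        add_diet(f"whitefish_{s}", _ADULT_WHT_PREY)
    # perch: planktivorous young, piscivorous from 2y on
    add_diet("perch_larva", _LARVAL_PREY)
    add_diet("perch_juvenile", _JUVENILE_PREY)
    add_diet("perch_2y", _FISH_PREY + ["leptodora", "chaoborus"])
    add_diet("perch_3y", _FISH_PREY + ["chaoborus"])
    add_diet("perch_4y", _FISH_PREY)

    species = [
        FishSpecies("whitefish", tuple(f"whitefish_{s}" for s in stage_suffix),
                    rho=0.0, natural_reproduction=False),
        FishSpecies("perch", tuple(f"perch_{s}" for s in stage_suffix),
                    rho=recipe.perch_rho, natural_reproduction=True),
    ]
    return guilds, links, species


def make_lc_like_web(recipe: WebRecipe | None = None) -> FoodWeb:
    """Build a 30-guild LC-like web with exactly ``recipe.n_links`` links."""
    recipe = recipe or WebRecipe()
    rng = np.random.default_rng(recipe.seed)
    c = recipe.constants

    guilds: list[Guild] = []
    mass: dict[str, float] = {}
    for gid, m0 in _PRODUCERS + _BACTERIA + _ZOOPLANKTON:
        mass[gid] = m0 * 10.0 ** rng.normal(0.0, recipe.mass_jitter_sd)
    for gid, m0 in _PRODUCERS:
        guilds.append(Guild(gid, role="producer", body_mass=mass[gid], r=1.0))  # r set by calibration
    for gid, _ in _BACTERIA + _ZOOPLANKTON:
        x, y = allometric_rates(mass[gid], "consumer", c)
        guilds.append(Guild(gid, role="consumer", body_mass=mass[gid], x=x, y=y,
                            B0=1.0, q=recipe.zoo_q, d=0.0))  # B0/d set by calibration

    fish_guilds, fish_links, species = _fish_guilds_and_links(recipe)
    guilds.extend(fish_guilds)

    # --- plankton topology: mass-window feasibility, weighted by a log-ratio kernel
    producer_ids = {gid for gid, _ in _PRODUCERS}
    plankton = [gid for gid, _ in _BACTERIA + _ZOOPLANKTON]
    prey_pool = [gid for gid, _ in _PRODUCERS] + plankton
    lo, hi = recipe.ratio_window
    candidates: list[tuple[float, str, str]] = []   # (weight, consumer, prey)
    for cid in plankton:
        fixed = _BACTERIA_DIETS.get(cid)
        if fixed is not None:
            for p in fixed:
                candidates.append((math.inf, cid, p))
            continue
        for pid in prey_pool:
            if pid == cid:
                continue
            ratio = mass[cid] / mass[pid]
            if not lo <= ratio <= hi:
                continue
            z = (math.log10(ratio) - recipe.log10_ratio_opt) / recipe.log10_ratio_sd
            w = math.exp(-0.5 * z * z) * 10.0 ** rng.normal(0.0, recipe.omega_jitter_sd)
            candidates.append((w, cid, pid))

    target = recipe.n_links - len(fish_links)
    if target < len(plankton):
        raise ValueError(f"link target {recipe.n_links} infeasible: needs ≥1 prey per consumer")
    chosen = _select_links(candidates, target, min_per_consumer=2)

    links = list(fish_links)
    by_consumer: dict[str, list[tuple[float, str]]] = {}
    for w, cid, pid in chosen:
        by_consumer.setdefault(cid, []).append((w if math.isfinite(w) else 1.0, pid))
    for cid, prey in sorted(by_consumer.items()):
        total = sum(w for w, _ in prey)
        for w, pid in sorted(prey, key=lambda t: t[1]):
            e = recipe.e_plant if pid in producer_ids or pid.startswith("bacteria") else recipe.e_animal
            links.append(FeedingLink(cid, pid, w / total, e))

    web = FoodWeb(
        guilds=guilds, links=links, K=recipe.K, fish_species=species,
        metadata={"recipe": recipe.to_dict(), "larval_mass_ugC": recipe.larval_mass_ugC},
    )
    _calibrate_to_targets(web, recipe)
    report = validate_web(web)
    if report.n_links != recipe.n_links:
        raise ValueError(f"generator produced {report.n_links} links, wanted {recipe.n_links}")
    return web


def _calibrate_to_targets(web: FoodWeb, recipe: WebRecipe) -> None:
    """Balance the plankton community at the target standing stocks.

    Given the drawn topology and diet preferences, each consumer's
    half-saturation is set so its bare (interference-free) response at the
    target prey field equals ``bare_F``, then its interference coefficient d
    absorbs the surplus so that assimilation exactly covers metabolism plus
    the predation it suffers at the targets.  Producer growth rates are set to
    balance their grazing losses at the shared logistic factor G* implied by
    the producer targets.  The result: the target state is an interior
    equilibrium of the continuous dynamics (with fish held at nominal
    stocks), with strongly interference-dominated feeding — a stable,
    persistent community by construction.
    """
    ids = web.guild_ids
    n = web.n_guilds
    idx = {g: i for i, g in enumerate(ids)}
    n_prod = sum(g.is_producer for g in web.guilds)
    prod_target = 0.5 * web.K / n_prod           # producers hold half of K: G* = 0.5
    Bstar = np.empty(n)
    for i, g in enumerate(web.guilds):
        if g.is_producer:
            Bstar[i] = prod_target
        elif g.role == "fish_stage":
            Bstar[i] = _TARGET_FISH_B.get(g.id, 1e3)
        else:
            Bstar[i] = _TARGET_B.get(g.id, 5e3)

    cons = [g for g in web.guilds if not g.is_producer]
    prey_of = {g.id: [] for g in cons}
    for l in web.links:
        prey_of[l.consumer_id].append(l)

    # half-saturation from the bare-response condition B0^q = S (1/bare_F − 1)
    for g in cons:
        S = sum(l.omega * Bstar[idx[l.prey_id]] ** g.q for l in prey_of[g.id])
        bare = recipe.fish_bare_F if g.role == "fish_stage" else recipe.bare_F
        g.B0 = (S * (1.0 / bare - 1.0)) ** (1.0 / g.q)

    # iterate: predation budget -> required response -> interference d
    for _ in range(60):
        F = {}  # (consumer, prey) -> F_ij at targets
        for g in cons:
            S = sum(l.omega * Bstar[idx[l.prey_id]] ** g.q for l in prey_of[g.id])
            den = g.B0 ** g.q * (1.0 + g.d * Bstar[idx[g.id]]) + S
            for l in prey_of[g.id]:
                F[(g.id, l.prey_id)] = l.omega * Bstar[idx[l.prey_id]] ** g.q / den
        loss = np.zeros(n)
        for l in web.links:
            k = web.guild(l.consumer_id)
            loss[idx[l.prey_id]] += k.x * k.y * Bstar[idx[k.id]] * F[(k.id, l.prey_id)] / l.e
        max_shift = 0.0
        for g in cons:
            if g.role == "fish_stage":
                continue  # fish are stocking/aging-driven, not equilibrated
            i = idx[g.id]
            F_req = (1.0 + loss[i] / (g.x * Bstar[i])) / g.y
            if F_req >= 0.95:
                raise ValueError(f"calibration infeasible: {g.id} needs response {F_req:.2f}")
            S = sum(l.omega * Bstar[idx[l.prey_id]] ** g.q for l in prey_of[g.id])
            d_new = max(0.0, (S * (1.0 / F_req - 1.0) / g.B0 ** g.q - 1.0) / Bstar[i])
            max_shift = max(max_shift, abs(d_new - g.d) * Bstar[i])
            g.d = d_new
        if max_shift < 1e-10:
            break

    # larvae of both species compete on equal terms: identical interference
    larv_d = recipe.fish_d
    for sp in web.fish_species:
        web.guild(sp.larva_id).d = larv_d

    lo, hi = recipe.r_bounds
    for g in web.guilds:
        if g.is_producer:
            i = idx[g.id]
            g.r = min(max(loss[i] / (0.5 * Bstar[i]), lo), hi)
    web.metadata["calibration_targets"] = {gid: float(Bstar[idx[gid]]) for gid in ids}


def _select_links(
    candidates: list[tuple[float, str, str]],
    target: int,
    min_per_consumer: int,
) -> list[tuple[float, str, str]]:
    """Keep exactly ``target`` links, dropping the weakest while every consumer
    retains at least ``min_per_consumer`` prey (or all its candidates)."""
    if len(candidates) < target:
        raise ValueError(
            f"only {len(candidates)} feasible plankton links for a target of {target}; "
            "widen the mass-ratio window"
        )
    per_consumer: dict[str, int] = {}
    for _, cid, _p in candidates:
        per_consumer[cid] = per_consumer.get(cid, 0) + 1
    kept = sorted(candidates, key=lambda t: (-t[0], t[1], t[2]))
    while len(kept) > target:
        for k in range(len(kept) - 1, -1, -1):
            w, cid, pid = kept[k]
            if math.isfinite(w) and per_consumer[cid] > min_per_consumer:
                del kept[k]
                per_consumer[cid] -= 1
                break
        else:
            raise ValueError("cannot prune to target while keeping minimum diets")
    return kept
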