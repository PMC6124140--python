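import numpy as np
import pytest

import atnsim as a


@pytest.fixture(scope="session")
def lc_web():
    """Default LC-like synthetic web (seed 1): 30 guilds, 133 links."""
    return a.make_lc_like_web(a.WebRecipe(seed=1))


def make_fish_toy(prey_rich: bool = True) -> a.FoodWeb:
    """Minimal web with one 5-stage fish species on a producer–zooplankton base.

    With ``prey_rich`` False the zooplankton pool is too thin to cover fish
    metabolism, so unstocked fish starve.
    """
    K = 1e5
    guilds = [
        a.Guild("alga", role="producer", body_mass=1e-4, r=1.0),
        a.Guild("zoo", role="consumer", body_mass=1.0, x=0.2, y=8.0,
                B0=2e4 if prey_rich else 2e6, q=1.2, d=1e-4),
    ]
    stage_ids = tuple(f"fish_{s}" for s in ("larva", "juv", "2y", "3y", "4y"))
    fish_x = 0.01 if prey_rich else 0.08  # starving variant: fast metabolic loss
    for sid, m in zip(stage_ids, (1e3, 1e6, 5e6, 1.5e7, 4e7)):
        guilds.append(a.Guild(sid, role="fish_stage", body_mass=m, x=fish_x, y=4.0,
                              B0=5e3 if prey_rich else 5e6, q=1.2, d=1e-4))
    links = [a.FeedingLink("zoo", "alga", 1.0, 0.45)]
    links += [a.FeedingLink(sid, "zoo", 1.0, 0.85) for sid in stage_ids]
    species = [a.FishSpecies("fish", stage_ids, rho=0.0, natural_reproduction=False)]
    return a.FoodWeb(guilds, links, K=K, fish_species=species)


@pytest.fixture()
def fish_toy():
    return make_fish_toy(prey_rich=True)


@pytest.fixture()
def starving_fish_toy():
    return make_fish_toy(prey_rich=False)


def random_small_web(rng: np.random.Generator) -> tuple[a.FoodWeb, np.ndarray]:
    """Random valid web (≤6 guilds) plus a random nonnegative state."""
    n = int(rng.integers(2, 7))
    n_prod = int(rng.integers(1, n))
    guilds = []
    for i in range(n):
        if i < n_prod:
            guilds.append(a.Guild(f"p{i}", role="producer", body_mass=rng.uniform(0.1, 10),
                                  r=rng.uniform(0.2, 2.0)))
        else:
            guilds.append(a.Guild(f"c{i}", role="consumer", body_mass=rng.uniform(0.1, 10),
                                  x=rng.uniform(0.05, 0.8), y=rng.uniform(2, 10),
                                  B0=rng.uniform(1, 50), q=rng.uniform(1.0, 1.6),
                                  d=rng.uniform(0, 0.5)))
    links = []
    for i in range(n_prod, n):
        prey = [j for j in range(n) if j != i]
        k = int(rng.integers(1, len(prey) + 1))
        chosen = rng.choice(prey, size=k, replace=False)
        w = rng.uniform(0.2, 1.0, size=k)
        w /= w.sum()
        for j, wj in zip(chosen, w):
            links.append(a.FeedingLink(guilds[i].id, guilds[j].id, float(wj),
                                       float(rng.uniform(0.3, 1.0))))
    web = a.FoodWeb(guilds, links, K=float(rng.uniform(10, 200)))
    B = rng.uniform(0, 30, size=n)
    B[rng.random(n) < 0.2] = 0.0  # exercise extinct guilds
    return web, B


def loop_rhs(B, web, harvest_rate=None):
    """Independent, loop-based term-by-term assembly of the season RHS."""
    n = web.n_guilds
    B = [max(float(b), 0.0) for b in B]
    idx = web._index
    prod_sum = sum(B[i] for i, g in enumerate(web.guilds) if g.is_producer)
    G = 1.0 - prod_sum / web.K
    dB = [0.0] * n
    F = {}
    for g in web.guilds:
        if g.is_producer:
            dB[idx[g.id]] += g.r * G * B[idx[g.id]]
            continue
        prey = [l for l in web.links if l.consumer_id == g.id]
        i = idx[g.id]
        den = g.B0 ** g.q * (1.0 + g.d * B[i]) + sum(l.omega * B[idx[l.prey_id]] ** g.q for l in prey)
        s = 0.0
        for l in prey:
            fij = l.omega * B[idx[l.prey_id]] ** g.q / den
            F[(g.id, l.prey_id)] = fij
            s += fij
        dB[i] += g.x * B[i] * (-1.0 + g.y * s)
    for l in web.links:
        k = web.guild(l.consumer_id)
        dB[idx[l.prey_id]] -= k.x * k.y * B[idx[k.id]] * F[(k.id, l.prey_id)] / l.e
    if harvest_rate is not None:
        for i in range(n):
            dB[i] -= harvest_rate[i] * B[i]
    return np.array(dB)
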