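"""Within-season biomass dynamics: functional responses and the ATN ODE right-hand side.

The daily dynamics over a growth season follow the standard allometric trophic
network (ATN) bioenergetics.  Producers grow logistically against one shared
community carrying capacity K:

    dB_i/dt = r_i G B_i − Σ_k losses_to_consumer_k,      G = 1 − Σ_producers B_p / K

Consumers (including fish stages) balance assimilation against metabolism:

    dB_i/dt = x_i B_i (−1 + y_i Σ_j F_ij) − Σ_k losses_to_consumer_k − H_i

with the saturating multi-prey functional response with intraspecific
predator interference

    F_ij = ω_ij B_j^{q_i} / ( B0_i^{q_i} (1 + d_i B_i) + Σ_k ω_ik B_k^{q_i} ).

The biomass a consumer k strips from prey i is its ingestion
x_k y_k B_k F_ki / e_ki, of which the assimilated fraction e_ki appears as
consumer gain.  H_i is the instantaneous fishing mortality loss
(``harvest`` module), nonzero only for fish stages in fishing years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .web import FoodWeb, Guild

__all__ = ["ModelArrays", "build_arrays", "functional_response", "producer_growth_factor", "atn_rhs"]


@dataclass
class ModelArrays:
    """Dense per-guild / per-link arrays compiled once from a :class:`FoodWeb`."""

    n: int
    K: float
    r: np.ndarray            # (n,) producer growth rates
    x: np.ndarray            # (n,) metabolic rates
    y: np.ndarray            # (n,) max consumption multiples
    is_producer: np.ndarray  # (n,) bool
    cons_idx: np.ndarray     # (m,) indices of guilds with ≥1 prey link
    W: np.ndarray            # (m, n) diet preferences ω, rows = consumers with prey
    inv_e: np.ndarray        # (m, n) 1/e on links, 0 elsewhere
    B0q: np.ndarray          # (m,) B0^q per consumer row
    q: np.ndarray            # (m,) shape exponents
    d: np.ndarray            # (m,) interference coefficients
    fish_idx: np.ndarray     # (f,) indices of fish-stage guilds, species stage order

    def functional_response_rows(self, B: np.ndarray) -> np.ndarray:
        """F (m, n): row c is consumer ``cons_idx[c]``'s response over all prey."""
        Bc = np.maximum(B, 0.0)
        # per-row prey powers B_j^{q_i}; rows only for consumers with prey
        Bq = np.power(Bc[None, :], self.q[:, None], where=self.W > 0, out=np.zeros_like(self.W))
        num = self.W * Bq
        den = self.B0q * (1.0 + self.d * Bc[self.cons_idx]) + num.sum(axis=1)
        return num / den[:, None]


def build_arrays(web: FoodWeb) -> ModelArrays:
    n = web.n_guilds
    r = np.array([g.r for g in web.guilds])
    x = np.array([g.x for g in web.guilds])
    y = np.array([g.y for g in web.guilds])
    is_producer = np.array([g.is_producer for g in web.guilds])

    consumers = sorted({web.index(l.consumer_id) for l in web.links})
    cons_idx = np.asarray(consumers, dtype=int)
    row_of = {gi: c for c, gi in enumerate(consumers)}
    m = len(consumers)
    W = np.zeros((m, n))
    inv_e = np.zeros((m, n))
    for l in web.links:
        c = row_of[web.index(l.consumer_id)]
        j = web.index(l.prey_id)
        W[c, j] = l.omega
        inv_e[c, j] = 1.0 / l.e
    q = np.array([web.guilds[i].q for i in consumers])
    d = np.array([web.guilds[i].d for i in consumers])
    B0q = np.array([web.guilds[i].B0 for i in consumers]) ** q
    return ModelArrays(
        n=n, K=web.K, r=r, x=x, y=y, is_producer=is_producer,
        cons_idx=cons_idx, W=W, inv_e=inv_e, B0q=B0q, q=q, d=d,
        fish_idx=web.fish_stage_indices(),
    )


def functional_response(consumer: Guild | str, B: np.ndarray, web: FoodWeb) -> np.ndarray:
    """Vector of F_ij over all guilds j for one consumer (zeros off-diet).

    Each entry lies in [0, 1) and the row sums to < 1 for finite biomasses.
    """
    cid = consumer.id if isinstance(consumer, Guild) else consumer
    arrays = build_arrays(web)
    gi = web.index(cid)
    pos = np.flatnonzero(arrays.cons_idx == gi)
    if pos.size == 0:
        raise ValueError(f"consumer {cid!r} has no prey links")
    return arrays.functional_response_rows(np.asarray(B, dtype=float))[pos[0]]


def producer_growth_factor(B: np.ndarray, web: FoodWeb | ModelArrays) -> float:
    """Shared logistic factor G = 1 − Σ_producers B_p / K, identical for all producers."""
    a = web if isinstance(web, ModelArrays) else build_arrays(web)
    return 1.0 - float(np.sum(np.maximum(B, 0.0)[a.is_producer])) / a.K


def atn_rhs(
    B: np.ndarray,
    web: FoodWeb | ModelArrays,
    harvest_rate: np.ndarray | None = None,
) -> np.ndarray:
    """dB/dt (µgC m⁻³ day⁻¹) for the within-season ODE.

    ``harvest_rate`` is an optional per-guild instantaneous mortality vector
    (day⁻¹), already gated on fishing years by the caller; loss is rate × B.
    """
    a = web if isinstance(web, ModelArrays) else build_arrays(web)
    B = np.asarray(B, dtype=float)
    if not np.all(np.isfinite(B)):
        ids = np.flatnonzero(~np.isfinite(B))
        raise FloatingPointError(f"non-finite biomass at guild indices {ids.tolist()}")
    Bc = np.maximum(B, 0.0)

    dB = np.zeros(a.n)
    G = 1.0 - Bc[a.is_producer].sum() / a.K
    dB += a.r * G * Bc                                   # producers (r = 0 elsewhere)

    if a.cons_idx.size:
        F = a.functional_response_rows(Bc)
        xyB = a.x[a.cons_idx] * a.y[a.cons_idx] * Bc[a.cons_idx]
        gain = xyB * F.sum(axis=1)                       # assimilated intake
        np.add.at(dB, a.cons_idx, gain)
        dB -= (xyB[:, None] * F * a.inv_e).sum(axis=0)   # prey loss = ingestion
    dB -= a.x * Bc                                       # metabolism (x = 0 for producers)

    if harvest_rate is not None:
        dB -= harvest_rate * Bc
    return dB
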