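# Methods

## Model

The simulator couples three layers of a lake community on a daily time step
within repeated 90-day growth seasons.

**Within-season dynamics.** All guild biomasses are relative carbon densities
(µgC m⁻³). Producers share one logistic ceiling: every producer grows as
`r_i G B_i` with a single community factor `G = 1 − Σ_p B_p / K`, so producer
guilds compete for the same resource envelope rather than each having a
private carrying capacity. Consumers follow the standard ATN bioenergetic
balance: gain `x_i y_i B_i Σ_j F_ij` minus metabolism `x_i B_i`, where the
multi-prey functional response

```
F_ij = ω_ij B_j^q / ( B0_i^q (1 + d_i B_i) + Σ_k ω_ik B_k^q )
```

saturates in total food (Σ_j F_ij < 1 always), gives scarce prey a relative
refuge for `q > 1`, and decreases with the consumer's own density through the
predator-interference term `d_i B_i`. The biomass a consumer strips from prey
is its ingestion `x y B F / e`: assimilated gain is `e × ingestion`, with
assimilation efficiency 0.45 for feeding on producers/bacteria and 0.85 for
animal prey. Metabolic rates follow quarter-power allometry
`x = a_x (M/M_ref)^(−1/4)` (defaults `a_x = 0.15 d⁻¹`, `M_ref = 1 µgC`,
capped at 1 d⁻¹ so unicellular guilds turn over at most daily); maximum
consumption is `y = 8` for invertebrates and `y = 4` for fish. Directly
measured rates, when supplied in a guild table, override allometry.

**Life history.** Each fish species is resolved into larva, juvenile (1-y),
2-y, 3-y and 4-y+ guilds, each with its own diet and rates. Alongside the
biomass ODE, the solver integrates each stage's *net production*
`dP/dt = x B (y ΣF − 1)` and, during fishing years, the *catch ledger*
`dC/dt = F_max S_age B`. At season end the cohorts shift one stage (the 4-y+
class accumulates), and new larvae are `ρ × Σ max(P, 0)` over the mature
stages (2-y+ by default). Whitefish reproduction is hard-zeroed — the
population persists only through stocking, injected additively into the
larval guild at each season start. Between seasons all other guilds carry
over unchanged (the model covers only the growth season; an optional
per-guild overwinter survival multiplier could be added for sensitivity work
but none is applied).

**Harvest.** Fishing is a continuous instantaneous mortality through every
day of a fishing-year season, `F_max = 0.5/(90+1) d⁻¹` with stage
selectivities `(0, 0, 1/3, 2/3, 1)`, identical for both species. The
scenario robustness grids vary stocking by ±50 (whitefish) and ±25 (perch)
µgC m⁻³ and the `F_max` numerator over {0.4, 0.5, 0.6}; the numerator
interpretation (0.4/91 rather than a literal 0.4 d⁻¹) follows the
construction of the baseline rate.

**Event ordering.** Each simulated year is: stocking at t = 0 → season ODE →
end-of-season transition. Fishing activates after the unfished burn-in
(default 100 + 100 years), which doubles as the spin-up toward the web's
dynamic equilibrium.

## Synthetic web generator

No public parameter table exists for the lake community the analysis is
modelled on, so the generator emulates its *structure*: 30 guilds — six
phytoplankton size classes, two bacteria guilds, twelve zooplankton guilds
(including the named rotifer size classes, *Bosmina*, *Daphnia*, calanoid and
cyclopoid copepods, *Leptodora*, *Chaoborus*) and 2 × 5 fish stages — joined
by exactly 133 feeding links.

*Topology.* Fish diets are fixed by functionality: both species' larvae share
one prey set (three rotifer classes + *Daphnia* + cyclopoids) and one
interference coefficient, so they differ in density only, not competitive
ability; whitefish stages never eat fish; perch 2-y+ eat larvae and juveniles
of both species (the 4-y+ class exclusively so, with a higher interference
coefficient — an old fish that competes better for its prey). Plankton links
are drawn by a body-mass-ordered feasibility rule — a consumer can eat guilds
5–10⁵ times lighter, with preference weight peaking at a 100:1 mass ratio
(log-normal kernel, σ = 0.8 decades, seeded jitter) — then pruned from the
weakest weight up (each consumer keeping ≥ 2 prey) to hit the target link
count exactly. Diet preferences ω are the normalized kernel weights.

*Equilibrium calibration.* Hand-picked uniform rate constants reliably
produce extinctions in a 30-guild web: a single half-saturation constant
either starves the microbial loop (whose prey stand far below crustacean food
levels) or destabilizes it, and similar grazers competitively exclude one
another. The generator therefore works backwards from target standing stocks
(producers at K/2 jointly; crustacean zooplankton 5–20 × 10³; microbial
guilds 2–5 × 10³ µgC m⁻³; fish at nominal stocked levels). For each consumer
it sets `B0` so the interference-free response at the target prey field
equals 0.8 (0.6 for fish), then solves the interference coefficient `d` so
that assimilation exactly covers metabolism plus the predation suffered at
the targets (fixed-point iteration over the predation budget); producer
growth rates are set to balance grazing losses at `G* = 0.5`. The target
state is then an interior equilibrium with strongly interference-dominated
feeding (`d B* ≈ 3–10`), which makes it both stable and invadable — any guild
perturbed downward faces relaxed intraspecific interference and abundant
prey, so persistence holds by construction. Tests confirm every guild stays
above the extinction floor for 100 years across seeds.

*Larval metabolism.* Larval stages get a measured-rate-style override
`x = 0.05 d⁻¹` (vs ≈ 0.027 from adult allometry). Larval fish have much
higher mass-specific rates than the adult quarter-power curve suggests, and
this is what makes the larval stage strongly food-limited: stocked larvae
graze their prey down within the season, so end-of-season larval biomass
rises far less than proportionally with stocking, and the two species'
larvae interact through exploitative competition. Without it, the dominant
coupling runs the other way (more whitefish larvae feed the piscivorous
perch, raising perch recruitment) and the competition signature disappears.

*Determinism.* The recipe seed drives all jitter; identical recipes
serialize byte-identically. The implied individual larval mass (≈10³ µgC,
i.e. ~one larva per 5 m³ at the 200 µgC m⁻³ baseline) is stored as metadata
only.

## Numerics

- Seasons are integrated with SciPy's LSODA (stiff-capable, adaptive) at
  `rtol 1e-8 / atol 1e-10` defaults; biomass, production and catch ledgers
  ride in one state vector so the ledgers see the solver's full accuracy.
- After each season any component below the floor ε = 10⁻⁹ µgC m⁻³ is clamped
  to ε, preventing stiff-solver undershoot below zero; inside the RHS the
  state is clipped at 0 before powers are taken. Within a season the dynamics
  cannot resurrect a guild from exactly zero (all gain terms are proportional
  to own biomass); the ε floor is below any ecologically meaningful density.
- The production ledger is floored at zero only at the season-end read-out,
  so early-season losses can be recouped before recruitment is assessed.
- Percent changes are averaged over the terminal 10 end-of-season values of
  each period: the system approaches its annual cycle slowly and single-year
  comparisons are fragile. Fluctuation is summarized as the coefficient of
  variation (population sd / mean) over 10-year sliding windows, reported at
  both record days (mid- and end-of-season) because plankton cycle within the
  season. A zero baseline yields NaN (flagged), never ±∞.
- Default initial state: producers split K equally, consumers start at
  B0/10, fish stages at 10 µgC m⁻³; the unfished period absorbs the
  transient.

## What the synthetic web does and does not show

The generator reproduces the *structure* and the *qualitative mechanism
set* of the study system — shared larval food base, stage-structured
piscivory, stocking-dependent whitefish — and the scenario machinery
reproduces the direction of every headline response (whitefish stages up
under increased whitefish stocking; perch larvae and the adult prey
aggregate down; whitefish larvae and the larval prey pool down when perch
are also stocked). It does **not** reproduce the original study's numerical
percentages, which depend on the unpublished lake parameterization; with a
transcribed parameter table dropped into `web.json` the same pipeline runs
unchanged. The calibrated synthetic web settles close to a fixed annual
cycle, so its fluctuation statistics are much smaller than those of a web
with pronounced seasonal plankton cycles; CV comparisons across arms remain
meaningful but describe this stand-in, not the original system. Other known
simplifications: no detritus pool (bacteria shortcut to the smallest
producers), no temperature or nutrient forcing, no environmental
stochasticity (the model is deterministic end to end), no hatchery-quality
or genetic effects, and a single harvest policy for both species.
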