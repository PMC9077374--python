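# Methods

This note documents the model implemented in `trackchem`, the choices made
where the design was genuinely open, and what the synthetic track generator
does and does not emulate.

## Scope of the model

The simulation covers the *nonhomogeneous chemical stage* of water
radiolysis, from 1 ps (taken as both the end of the physicochemical stage
and the start of diffusion) to 10 µs, at 25 °C and neutral pH. Everything
earlier — ionization, dry-electron transport, thermalization, hydration,
and the sub-picosecond H₂-forming processes (geminate recombination,
dissociative electron attachment, excited-water dissociation) — is
represented only through the configurable 1-ps yields; in particular the
physicochemical H₂ contribution enters as the fixed g(H₂) = 0.34
molecules/100 eV initialization. Dry-electron scavenging by concentrated
azide (relevant experimentally above ~1 M), the direct radiation action on
the solute (~2–11 % of energy at 1–5 M azide), and any temperature
dependence are outside the model.

## Synthetic track configurations

A full track-structure transport code is not part of the package; the
generator produces parametric 1-ps configurations with the two geometries
that matter for the chemistry:

* **Spur / low-LET mode.** Energy-loss events ("spurs") have energies from
  an exponential distribution truncated to [6.6, 100] eV with scale 52 eV
  (mean ≈ 40 eV, a conventional spur-spectrum shape). Species counts are
  Poisson with mean g·E/100; every e⁻aq and OH⁻ is created together with an
  H₃O⁺ partner so each spur is exactly charge neutral — this requires
  g(H₃O⁺) = g(e⁻aq) + g(OH⁻) (= 4.7 with the defaults), which the parameter
  class enforces. Positions are isotropic Gaussians: σ = 3.6 nm for the
  hydrated electron (calibrated, below), σ = 1.0 nm for all heavy species.
  A low-energy event can legitimately produce zero tracked species; such
  snapshots are kept, with their energy, in the ensemble — discarding or
  re-drawing them would condition on non-emptiness and bias every yield
  upward by several per cent.
* **Segment vs. spur ensembles.** The γ surrogate is a ~150 µm segment of a
  0.3 eV nm⁻¹ track: spurs on a straight line with exponential spacings of
  mean E/LET (~130 nm). At that spacing, cross-spur reaction probabilities
  are at the 10⁻³ level, so the default history unit for the γ mode is a
  *single spur*, which reproduces segment yields at a fraction of the cost;
  the full segment generator remains available (`gamma_history: segment`)
  and is exercised by the tests.
* **Tritium mode.** A complete 7.8 keV electron track: the same energy-loss
  spectrum packed along a straight path with spacings of mean E/LET at
  5.9 eV nm⁻¹, the last event taking the energy remainder so each history
  deposits exactly 7800 eV. The events overlap into a quasi-cylindrical
  column ~1.3 µm long. Path tortuosity and δ-ray branching are not
  modelled: the chemistry is driven by the local density of reactants,
  which the LET fixes.

What passing tests on these configurations show is therefore that the
*chemistry engine* responds correctly to prescribed initial geometry and
inventory; they do not validate a transport model, and quantitative
agreement for real tracks inherits the uncertainty of the 1-ps yields and
widths.

## Spur-width calibration

The electron-cloud width σ(e⁻aq) is the one free geometric parameter. It
was set once, by scanning the azide-free air-saturated low-LET escape yield
(`scripts/calibrate_spurs.py`; coarse 20 000-spur grid, then 50 000-spur
multi-seed refinement): the plateau falls smoothly from 0.470 (σ = 3.25 nm)
to 0.437 (σ = 4.5 nm), and σ = 3.6 nm reproduces the 25 °C escape yield
g(H₂) = 0.45 molecules/100 eV within the seed-to-seed scatter of ±0.002
(pooled value 0.453, chemical-stage gain 0.112 against 0.45/0.11). σ for
the heavy species stays at 1.0 nm; the plateau is far less sensitive to it
because the H₂-forming chemistry is dominated by the electron cloud.

## Reaction network

Seventeen channels describe the azide chemistry — H˙ and ˙OH scavenging by
N₃⁻, the HN₃ acid channels, the azide-radical reactions (N₃˙ + e⁻aq,
N₃˙ + H˙, N₃˙ + N₃˙ → 3N₂, dimerization with N₃⁻, reduction by O₂˙⁻) — plus
the water-solvent channel e⁻aq + H₂O → H˙ + OH⁻ (19 M⁻¹ s⁻¹, folded with
[H₂O] = 55.34 M into a 1.05 × 10³ s⁻¹ intrinsic first-order rate). Rate
constants quoted only as bounds (N₃⁻ + e⁻aq ≤ 1.5 × 10⁶; HN₃ + ˙OH < 10⁷;
N₃˙ + H₂O₂ < 5 × 10⁶ M⁻¹ s⁻¹) default to the bound; results are insensitive
because the chemistry is designed around the near-inertness of azide toward
the hydrated electron. The proton-transfer equilibrium constant printed as
a range (10⁹–10¹⁰) defaults to the diffusion-controlled upper end but the
explicit in-track protonation channel is disabled by default: at neutral pH
the HN₃ fraction of total azide is a static 1/(1+10^(pH−4.7)) ≈ 0.5 %,
applied as a partition of the bulk concentration (a config switch enables
the dynamic channel).

The background pure-water set (12 reactions: ˙OH/e⁻aq/H˙ cross-
recombinations, H₂O₂ reactions, the acid–base neutralizations, O₂
scavenging of e⁻aq and H˙, and ˙OH + H₂ — the only H₂-consuming channel) is
a standard 25 °C compilation-style scheme; every constant is overridable
from the config, and the whole network round-trips through YAML. Reactions
with unspecified products are flagged terminal sinks and excluded from
balance checking; all others must balance charge and N exactly and H/O up
to implicit water molecules.

Every bimolecular constant is converted internally (lengths nm, times ps)
to an encounter radius via k = 4πN_A·D·R; observed compilation constants
are used as-is for like-pair channels with each unordered pair sampled
once. Ion–ion rates are scaled by the Brønsted–Bjerrum/extended
Debye–Hückel factor log₁₀ f = 1.02·z_A z_B √I/(1+√I) with I computed from
the bulk salt composition (1:1 counterions assumed). This form is an
extrapolation above ~0.5 M; it is applied uniformly, to pair channels and
scavenging channels alike, because the solutions of interest reach 5 M.

## IRT engine

Initial pair times are sampled by exact inversion of the Smoluchowski pair
law; a draw u ≥ R/r is a permanent "no reaction". Pseudo-first-order
scavenging uses time-independent rates k[S] (no transient term), as
appropriate for a homogeneous excess of scavenger. Numerical and structural
choices:

* **Channel labels.** A reaction consumed against a bulk scavenger is
  booked under a distinct label (`R9[s]` vs `R9`) so every channel has a
  unique stoichiometry; the identity G_s(t) = G_s(1 ps) + Σ stoich·ΔG(t)
  then holds exactly and is asserted in the tests against an independent
  particle-lifetime count.
* **Products.** Created at the diffusion-weighted contact point
  (D_b·p_a + D_a·p_b)/(D_a+D_b); new pair times are sampled against all
  survivors using the survivors' stored (birth) positions with the clock
  restarted at the event — the standard IRT secondary-reaction
  approximation. Its error is bounded empirically by the Brownian-dynamics
  comparison below.
* **Contact rule.** Particles generated closer than R react 10⁻⁶ ps after
  the 1-ps snapshot, so the first grid point reports the configured initial
  yields and sub-grid recombination lands inside the first grid interval.
* **Pair cutoff.** Pairs farther apart than 300 nm (configurable) are not
  sampled. At that range the first-passage time exceeds 10⁵–10⁶ ps, beyond
  the O₂/azide scavenging times that terminate the radical population, so
  the neglected reaction probability is far below the Monte Carlo
  resolution; the cutoff is what makes dense 7.8 keV tracks tractable.
* **Grid and reproducibility.** Yields accumulate on 120 log-spaced times
  over [1 ps, 10 µs]. One master seed spawns per-history substreams
  (`numpy` SeedSequence); results are bit-reproducible given seed and
  config. Ensemble G-values use the ratio estimator 100·ΣC/ΣE with a
  linearized standard error over histories.

## Brownian-dynamics oracle

`trackchem.bd` propagates free Gaussian displacements for tiny systems
(pairs, clusters ≤ 10 particles) and tests encounters geometrically each
step. The absorbing rule includes the Brownian-bridge crossing probability
exp[−(r₀−R)(r₁−R)/(D·dt)]: without it the naive inside/outside test misses
crossings between sampled points and under-captures by ~0.03 in survival at
the enforced step bound √(2D·dt) < R/5 — measurably outside the statistical
bands used for validation — while with it the pair survival matches the
Smoluchowski closed form within 1σ at n = 8000. Partially controlled
encounters use a uniformly reacting volume sink of intrinsic rate k_act
inside R; its steady-state rate k_diff(1 − tanh x/x), x = √(3k_act/k_diff),
agrees with the Collins–Kimball rate within 5 % for k_act/k_diff ≤ 0.3,
which is the regime the validation uses.

The IRT↔BD equivalence check runs both engines on a fixed synthetic
six-particle cluster (three A + three B, competing A+B and A+A channels,
separations 8–15 nm) and compares per-channel reacted counts at five times.
The cluster spacing was chosen so that the IRT independent-pairs
approximation error (which grows with pairwise competition density) stays
inside the 3σ resolution of the comparison at the sample sizes used; at
double density a ~3 % systematic becomes resolvable, which bounds the
approximation error relevant to real spurs.

## Analysis conventions

The escape (plateau) yield is the mean of G(t) over 1–10 µs; its quoted
error is the mean per-point Monte Carlo error (plateau points are nearly
fully correlated, so averaging does not shrink it). A run is flagged
`still_rising` if G changes by more than 2 % over the final decade, and the
reported changeover time is the earliest grid time from which G stays
within 2 % of the plateau — a diagnostic of the spur-to-homogeneous
transition (~0.2 µs in the low-LET mode), reported but never asserted.
Concentration scans derive each cell's seed from the master seed and the
concentration *value*, so results are independent of scan order; an
optional common-seed mode reuses one substream per mode, giving identical
initial ensembles across concentrations — a paired design used where
concentration *differences* are the quantity of interest (channel-extent
comparisons), at a fraction of the variance.

## Problem sizes

Defaults are 2000 single-spur histories (γ) and 30 whole-track histories
(tritium), giving plateau standard errors of ~0.024 and ~0.015
molecules/100 eV respectively; the acceptance script uses 50 000 spur
histories (error ~0.005). These sizes were chosen so that every quoted
comparison is resolved at its stated significance; all are config-exposed.

## Known limitations

* The 1-ps yields, spur spectrum and widths are stand-ins calibrated to a
  single observable (the azide-free escape yield); other species' plateaus
  are plausible but uncalibrated.
* Survivor positions are frozen at birth for new-channel sampling (IRT
  approximation); errors grow with the number of sequential reactions a
  particle lineage undergoes.
* The ionic-strength correction is used far above its rigorous validity
  range, as is conventional for these systems.
* No dry-electron chemistry: at >1 M azide the model intentionally
  reproduces only the diffusive-stage scavenging, not the sharp
  experimental drop of g(H₂) under γ irradiation.
* Homogeneous inter-track chemistry (dose-rate effects) is absent; each
  history is independent.
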