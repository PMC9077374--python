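# trackchem

Monte Carlo track-chemistry simulation of irradiated water at 25 °C, built
around the **independent reaction times (IRT)** method. The package computes
time-dependent and escape radiation-chemical yields (*G*-values, molecules
per 100 eV) of molecular hydrogen — and of every other tracked species — for
two radiation qualities:

* **low-LET γ/fast-electron radiolysis** (LET ≈ 0.3 eV nm⁻¹), emulated as an
  ensemble of well-separated spherical *spurs* along a fast-proton track
  segment, and
* **tritium β-electron radiolysis** (7.8 keV electrons, mean LET ≈ 5.9
  eV nm⁻¹), emulated as dense, quasi-cylindrical *short tracks* of
  overlapping energy-loss events,

with the scavenger chemistry of aerated sodium azide solutions: N₃⁻ reacts
fast with H˙ (k = 3.15 × 10⁹ M⁻¹ s⁻¹) and very slowly with e⁻aq
(k ≤ 1.5 × 10⁶ M⁻¹ s⁻¹), dissolved O₂ (2.5 × 10⁻⁴ M, air-saturated) removes
e⁻aq and H˙ on the ~0.1 µs scale, and HN₃/N₃⁻ speciation follows
Henderson–Hasselbalch with pKa 4.7. It is aimed at radiation chemists and
modellers who want a small, auditable, pure-Python engine for scavenger
competition studies in nonhomogeneous track kinetics.

## The model

At 1 ps the physicochemical stage is summarized by configurable yields
(defaults g(e⁻aq) = 4.2, g(˙OH) = 5.0, g(H˙) = 0.6, g(H₂) = 0.34,
g(H₃O⁺) = 4.7, g(OH⁻) = 0.5, g(H₂O₂) = 0.2 molecules/100 eV) placed in
Gaussian clusters; diffusion then begins. For every reactive pair at
separation *r* the IRT method samples a reaction time from the
diffusion-controlled first-passage law

    P(T ≤ t) = (R/r) · erfc[(r − R) / √(4Dt)],

where *D* is the mutual diffusion coefficient and the encounter radius *R*
is fixed by the observed rate constant through k = 4πN_A·D·R (a
Collins–Kimball variant with a radiation boundary condition is available for
partially diffusion-controlled channels). Bulk scavengers act as
pseudo-first-order channels with rate k[S]; ionic-strength corrections
(Brønsted–Bjerrum, log₁₀ f = 1.02·z_A z_B √I/(1+√I)) apply to all
ion–ion reactions. The earliest pending event fires, products re-enter the
competition, and ensemble averages over track histories give G(t) from 1 ps
to 10 µs together with per-channel reaction extents ΔG(t).

Three inter-radical channels build hydrogen during track expansion:
e⁻aq + H˙ → H₂ + OH⁻ (k₁ = 2.5 × 10¹⁰), e⁻aq + e⁻aq → H₂ + 2OH⁻
(k₂ = 6.2 × 10⁹) and H˙ + H˙ → H₂ (k₃ = 4.6 × 10⁹ M⁻¹ s⁻¹). A step-by-step
Brownian-dynamics module (`trackchem.bd`) serves as an independent oracle
for the IRT engine on small clusters.

## Worked example

```bash
trackchem simulate --mode gamma --azide 0.01 --histories 2000 --seed 42 --out demo
```

writes `g_of_t.csv` (G(t) per species), `channels.csv` (ΔG(t) per reaction)
and `summary.json`. With the command above the summary reads

```
plateau_G_H2            0.4523
plateau_stderr          0.0243
chemical_stage_gain_H2  0.0897
G_H2_1ps                0.3626
```

i.e. in 10⁻² M azide the hydrogen yield starts at the configured ~0.34
molecules/100 eV physicochemical initialization (here 0.363 from Monte Carlo
sampling of 2000 spurs), grows by ~0.09 during spur expansion — slightly
less than the ~0.11 of azide-free water, because N₃⁻ is already removing H˙
atoms from the e⁻aq + H˙ channel — and plateaus near 0.45 once the spurs
have dissipated. The same library calls are available in Python:

```python
from trackchem import simulate, plateau
series = simulate(azide_M=0.01, n_histories=2000, seed=42)
print(plateau(series, "H2"))
```

`trackchem scan --out dir` sweeps the plateau yield over 10⁻⁴–5 M azide in
both radiation modes (the tritium short tracks give systematically higher
G(H₂) than the γ spurs — the signature of intensified intra-track
radical–radical chemistry), and `trackchem validate` runs the built-in
stochastic oracle suite (sampler distribution tests, exponential-scavenging
limit, IRT vs Brownian dynamics).

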