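"""Step-by-step Brownian-dynamics (random-flight) oracle.

A deliberately simple trajectory simulator for tiny systems, used as the
independent check of the IRT engine: displacements are free Gaussian steps,
reaction is tested geometrically every step.  Two encounter rules are
supported:

* absorbing contact sphere (fully diffusion-controlled), with the standard
  Brownian-bridge correction for crossings between sampled points: a step
  from separation r0 to r1 (both outside R) is scored as a capture with
  probability exp[-(r0-R)(r1-R)/(D dt)], which removes the leading
  discretization bias of the naive inside/outside test;
* a uniformly reacting volume sink inside the contact sphere whose total
  intrinsic rate is k_act (partially controlled; see docs/methods.md for
  the relation to the Collins-Kimball rate).

The timestep rule sqrt(2 D_max dt) < R/5 is enforced on top of the bridge
correction, keeping the residual bias well inside the statistical bands of
the comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BDParams", "bd_pair_survival", "bd_cluster"]


@dataclass
class BDParams:
    timestep_ps: float
    t_end_ps: float
    n_replicates: int = 1000
    #: None -> absorbing contact; a float -> intrinsic pair rate k_act in
    #: nm^3/ps, applied as a uniform sink of density k_act/V_R inside R.
    k_act_nm3_ps: float | None = None

    def __post_init__(self):
        if self.timestep_ps <= 0 or self.t_end_ps <= 0 or self.n_replicates < 1:
            raise ValueError("timestep, t_end and n_replicates must be positive")

    def check_step(self, d_max: float, r_min: float):
        if math.sqrt(2.0 * d_max * self.timestep_ps) >= r_min / 5.0:
            raise ValueError(
                "timestep too coarse: sqrt(2 D dt) must stay below R/5 "
                f"(got {math.sqrt(2.0 * d_max * self.timestep_ps):.3g} nm vs "
                f"R/5 = {r_min / 5.0:.3g} nm)")


def _react_probability(k_act, radius, dt):
    """Per-step reaction probability inside the contact sphere for the
    volume-sink rule: 1 - exp(-kappa dt), kappa = k_act / (4/3 pi R^3)."""
    kappa = k_act / (4.0 / 3.0 * math.pi * radius ** 3)
    return -math.expm1(-kappa * dt)


def _absorbing_hit(r_prev, r_new, radius, d_mutual, dt, rng):
    """Capture mask for one step of an absorbing pair: endpoint inside R, or
    an unobserved crossing scored by the Brownian-bridge probability."""
    hit = r_new < radius
    out = ~hit
    if out.any():
        with np.errstate(over="ignore"):
            p = np.exp(-(r_prev[out] - radius) * (r_new[out] - radius)
                       / (d_mutual * dt))
        bridge = rng.random(out.sum()) < p
        idx = np.flatnonzero(out)[bridge]
        hit = hit.copy()
        hit[idx] = True
    return hit


def bd_pair_survival(r0: float, radius: float, d_mutual: float,
                     params: BDParams, rng: np.random.Generator):
    """Survival curve of an isolated pair started at separation r0.

    The relative coordinate diffuses with the mutual D.  Returns
    (times, survival fraction, binomial stderr).
    """
    if radius > 0:
        if r0 <= radius:
            raise ValueError("start the pair outside the encounter radius")
        params.check_step(d_mutual, radius)
    n = params.n_replicates
    dt = params.timestep_ps
    steps = int(math.ceil(params.t_end_ps / dt))
    sep = np.zeros((n, 3))
    sep[:, 2] = r0
    alive = np.ones(n, dtype=bool)
    t_react = np.full(n, np.inf)
    sigma = math.sqrt(2.0 * d_mutual * dt)
    p_inside = (None if params.k_act_nm3_ps is None or radius == 0
                else _react_probability(params.k_act_nm3_ps, radius, dt))
    for s in range(1, steps + 1):
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        r_prev = np.linalg.norm(sep[idx], axis=1)
        sep[idx] += rng.standard_normal((len(idx), 3)) * sigma
        if radius == 0:
            continue
        r_new = np.linalg.norm(sep[idx], axis=1)
        if p_inside is None:
            hit = _absorbing_hit(r_prev, r_new, radius, d_mutual, dt, rng)
        else:
            hit = (r_new < radius) & (rng.random(len(idx)) < p_inside)
        if hit.any():
            j = idx[hit]
            alive[j] = False
            t_react[j] = s * dt
    times = np.arange(1, steps + 1) * dt
    surv = 1.0 - np.searchsorted(np.sort(t_react), times, side="right") / n
    err = np.sqrt(np.maximum(surv * (1.0 - surv), 1e-12) / n)
    return times, surv, err


def bd_cluster(init, network, params: BDParams, rng: np.random.Generator,
               grid_times=None):
    """Full-trajectory simulation of a small cluster (<= 10 particles).

    All pairwise encounters are tested each step against the encounter radii
    derived from the network's rate constants (with the Brownian-bridge
    crossing correction for the absorbing rule).  Returns per-channel
    cumulative reacted event counts per replicate cluster on ``grid_times``
    with binomial-style stderr.
    """
    from .irt import compile_system

    if len(init.species) > 10:
        raise ValueError("bd_cluster is an oracle for tiny systems (<= 10)")
    system = compile_system(network, scavengers={})
    sp0 = np.array([system.index[s] for s in init.species])
    npart = len(sp0)
    d_max = float(system.D[sp0].max())
    radii = system.pair_R[np.ix_(sp0, sp0)]
    r_min = radii[radii > 0].min() if (radii > 0).any() else np.inf
    if np.isfinite(r_min):
        params.check_step(d_max, r_min)

    nrep = params.n_replicates
    dt = params.timestep_ps
    steps = int(math.ceil(params.t_end_ps / dt))
    pairs = [(i, j) for i in range(npart) for j in range(i + 1, npart)
             if system.pair_rid[sp0[i], sp0[j]] >= 0]
    C = len(system.channel_ids)
    pos = np.broadcast_to(init.positions, (nrep, npart, 3)).copy()
    alive = np.ones((nrep, npart), dtype=bool)
    sig = np.sqrt(2.0 * system.D[sp0] * dt)  # per-particle step widths

    event_t = [[] for _ in range(C)]   # reaction times per channel
    event_rep = [[] for _ in range(C)]  # replicate index of each event
    p_inside = {}
    for (i, j) in pairs:
        if params.k_act_nm3_ps is not None:
            p_inside[(i, j)] = _react_probability(
                params.k_act_nm3_ps, system.pair_R[sp0[i], sp0[j]], dt)

    d_prev = {p: np.linalg.norm(pos[:, p[0]] - pos[:, p[1]], axis=1)
              for p in pairs}
    for s in range(1, steps + 1):
        pos += rng.standard_normal(pos.shape) * sig[None, :, None]
        for (i, j) in pairs:
            both = alive[:, i] & alive[:, j]
            d = np.linalg.norm(pos[:, i] - pos[:, j], axis=1)
            if not both.any():
                d_prev[(i, j)] = d
                continue
            radius = system.pair_R[sp0[i], sp0[j]]
            dmut = float(system.D[sp0[i]] + system.D[sp0[j]])
            if params.k_act_nm3_ps is None:
                hit = _absorbing_hit(d_prev[(i, j)], d, radius, dmut, dt, rng)
            else:
                hit = (d < radius) & (rng.random(nrep) < p_inside[(i, j)])
            hit &= both
            d_prev[(i, j)] = d
            if hit.any():
                ridx = system.pair_rid[sp0[i], sp0[j]]
                alive[hit, i] = False
                alive[hit, j] = False
                reps = np.flatnonzero(hit)
                event_t[ridx].extend([s * dt] * len(reps))
                event_rep[ridx].extend(reps.tolist())

    if grid_times is None:
        grid_times = np.logspace(math.log10(dt * 5), math.log10(params.t_end_ps), 20)
    grid_times = np.asarray(grid_times, dtype=float)
    # mean cumulative event count per replicate cluster, SEM over replicates
    mean = np.zeros((len(grid_times), C))
    sem = np.zeros_like(mean)
    for c in range(C):
        ts = np.array(event_t[c])
        reps = np.array(event_rep[c], dtype=int)
        for g, tq in enumerate(grid_times):
            counts = np.bincount(reps[ts <= tq], minlength=nrep)
            mean[g, c] = counts.mean()
            sem[g, c] = counts.std(ddof=1) / math.sqrt(nrep) if nrep > 1 else np.inf
    return grid_times, mean, sem, list(system.channel_ids)
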