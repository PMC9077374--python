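"""Built-in oracle suite: quantitative self-checks of the stochastic engine.

Each check returns a record with the statistic, its threshold and a pass
flag; `trackchem validate` runs them all and exits non-zero on any failure.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfc
from scipy.stats import kstest

from . import bd, fixtures, irt

__all__ = ["run_all", "check_sampler_cdf", "check_ultimate_probability",
           "check_exponential_scavenging", "check_irt_vs_bd"]


def _sample_times(r, R, D, n, rng, corrupt=False):
    """Vector of accepted pair reaction times (None draws dropped)."""
    u = rng.random(n)
    acc = u * r < R
    from scipy.special import erfcinv
    x = erfcinv(u[acc] * r / R)
    if corrupt:
        x = x * 0.8  # deliberately biased inversion (negative-control hook)
    t = (r - R) ** 2 / (4.0 * D * x * x)
    return t, acc.mean()


def check_sampler_cdf(n=100_000, r=2.0, R=1.0, D=0.01, seed=12345,
                      corrupt=False):
    """KS test of the sampled conditional reaction-time law against
    erfc[(r-R)/sqrt(4Dt)]."""
    rng = np.random.default_rng(seed)
    t, _ = _sample_times(r, R, D, n, rng, corrupt=corrupt)

    def cdf(tt):
        return erfc((r - R) / np.sqrt(4.0 * D * tt))

    stat, p = kstest(t, cdf)
    return {"name": "sampler_cdf_ks", "statistic": float(stat),
        "p_value": float(p), "threshold": "p > 0.01", "n": int(len(t)),
        "seed": seed, "passed": bool(p > 0.01)}


def check_ultimate_probability(n=100_000, r=2.0, R=1.0, D=0.01, seed=23456,
                               corrupt=False):
    """Accepted-draw frequency against the ultimate reaction probability R/r."""
    rng = np.random.default_rng(seed)
    _, frac = _sample_times(r, R, D, n, rng)
    p = R / r
    if corrupt:
        frac = frac * 0.9
    z = abs(frac - p) / np.sqrt(p * (1 - p) / n)
    return {"name": "ultimate_probability", "statistic": float(z),
            "observed": float(frac), "expected": p, "threshold": "z < 3",
            "n": n, "seed": seed, "passed": bool(z < 3.0)}


def check_exponential_scavenging(n=20_000, conc_M=1.0, seed=34567,
                                 corrupt=False):
    """Single H atom in bulk azide: survival must follow exp(-k4 [N3-] t)."""
    from . import chem, tracks

    net = chem.default_network()
    k4 = net.reaction("R4").rate_constant
    system = irt.compile_system(net, {"N3-": conc_M})
    rate = k4 * conc_M * 1e-12  # ps^-1
    rng_master = np.random.SeedSequence(seed)
    deaths = np.empty(n)
    for i, child in enumerate(rng_master.spawn(n)):
        rng = np.random.default_rng(child)
        init = tracks.InitialConfiguration(["H"], np.zeros((1, 3)), 100.0)
        h = irt.run_history(init, system, t_end=1e7, rng=rng)
        deaths[i] = h.death[0]
    t_probe = np.log(2.0) / rate  # half-life
    surv = float((deaths > t_probe).mean())
    exp_surv = float(np.exp(-rate * t_probe))
    if corrupt:
        surv *= 0.9
    z = abs(surv - exp_surv) / np.sqrt(exp_surv * (1 - exp_surv) / n)
    return {"name": "exponential_scavenging", "statistic": float(z),
            "observed": surv, "expected": exp_surv, "threshold": "z < 3",
            "n": n, "seed": seed, "passed": bool(z < 3.0)}


def check_irt_vs_bd(n_irt=4000, n_bd=3000, seed=45678, timestep_ps=1.5,
                    corrupt=False):
    """Per-channel reacted fractions of the fixture cluster: IRT vs the
    step-by-step Brownian oracle, compared at five grid times within three
    combined standard errors."""
    net = fixtures.fixture_network()
    init = fixtures.fixture_cluster()
    grid = np.array(fixtures.FIXTURE_GRID_PS)

    system = irt.compile_system(net, {})
    C = len(system.channel_ids)
    s1 = np.zeros((len(grid), C))
    s2 = np.zeros((len(grid), C))
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_irt):
        rng = np.random.default_rng(child)
        h = irt.run_history(init, system, t_end=grid[-1], rng=rng)
        c = h.channel_counts_on_grid(grid, C)
        s1 += c
        s2 += c * c
    irt_frac = s1 / n_irt
    irt_var = (s2 - n_irt * irt_frac ** 2) / (n_irt - 1)
    irt_err = np.sqrt(np.maximum(irt_var, 1e-12) / n_irt)

    rng_bd = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    params = bd.BDParams(timestep_ps=timestep_ps, t_end_ps=grid[-1],
                         n_replicates=n_bd)
    _, bd_frac, bd_err, bd_channels = bd.bd_cluster(init, net, params, rng_bd,
                                                    grid_times=grid)
    if corrupt:
        irt_frac = irt_frac * 1.5
    worst = 0.0
    for label in ("F1", "F2"):
        ci = system.channel_ids.index(label)
        cb = bd_channels.index(label)
        z = np.abs(irt_frac[:, ci] - bd_frac[:, cb]) / np.hypot(
            irt_err[:, ci], bd_err[:, cb])
        worst = max(worst, float(z.max()))
    return {"name": "irt_vs_bd_cluster", "statistic": worst,
            "threshold": "max |z| < 3", "n": {"irt": n_irt, "bd": n_bd},
            "seed": seed, "passed": bool(worst < 3.0)}


def run_all(fast: bool = False, corrupt: bool = False):
    """Run every oracle check; returns (all_passed, list of records)."""
    if fast:
        checks = [
            check_sampler_cdf(n=20_000, corrupt=corrupt),
            check_ultimate_probability(n=20_000, corrupt=corrupt),
            check_exponential_scavenging(n=2_000, corrupt=corrupt),
            check_irt_vs_bd(n_irt=800, n_bd=600, timestep_ps=2.0,
                            corrupt=corrupt),
        ]
    else:
        checks = [
            check_sampler_cdf(corrupt=corrupt),
            check_ultimate_probability(corrupt=corrupt),
            check_exponential_scavenging(corrupt=corrupt),
            check_irt_vs_bd(corrupt=corrupt),
        ]
    return all(c["passed"] for c in checks), checks
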