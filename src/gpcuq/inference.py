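"""Surrogate-accelerated Bayesian inference and optimization.

Metropolis-Hastings MCMC with a uniform prior on the reference cube and an
independent-Gaussian likelihood built from per-observation surrogates; the
surrogate replaces the forward model at every chain step, which is what
makes chains of 10^6+ steps affordable.  Also provides a multi-chain
convergence check, posterior summaries (marginals, mode, mean parameter
set, pairwise correlations), and simulated-annealing refinement of a point
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import ks_2samp

from .gprotein import ObservationPoint
from .spaces import ParameterSpace
from .surrogate import Surrogate, SurrogateEnsemble

__all__ = [
    "MCMCConfig",
    "Chain",
    "GaussianLikelihood",
    "log_likelihood",
    "mh_chain",
    "ConvergenceReport",
    "convergence_check",
    "PosteriorSummary",
    "posterior_summary",
    "AnnealSchedule",
    "simulated_annealing",
]


@dataclass(frozen=True)
class MCMCConfig:
    chain_length: int = 1_000_000
    burn_in: int = 100_000
    proposal_sd: float | np.ndarray = 0.05
    seed: int = 0
    n_chains: int = 1
    thin: int = 1

    def __post_init__(self) -> None:
        if not self.burn_in < self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if np.any(np.asarray(self.proposal_sd) <= 0):
            raise ValueError("proposal_sd must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class Chain:
    """Post-burn-in MCMC samples in cube coordinates."""

    samples: np.ndarray
    log_post: np.ndarray
    acceptance_rate: float
    seed: int

    @property
    def n(self) -> int:
        return self.samples.shape[1]


class GaussianLikelihood:
    """Independent Gaussian log-likelihood of surrogate responses vs data.

    ``logL(y) = -sum_i (s_i(y) - mean_i)^2 / (2 sd_i^2)`` up to an additive
    constant; -inf outside the cube (the uniform prior's support).
    """

    def __init__(self, surrogates: list[Surrogate], data: list[ObservationPoint]):
        if len(surrogates) != len(data):
            raise ValueError("need one surrogate per data point")
        for o in data:
            if o.sd <= 0:
                raise ValueError("all observation sds must be positive")
        self.ensemble = SurrogateEnsemble(surrogates)
        self.means = np.array([o.mean for o in data])
        self.sds = np.array([o.sd for o in data])

    def __call__(self, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        if np.any(np.abs(y) > 1.0):
            return -np.inf
        resp = self.ensemble.evaluate(y)
        return float(-0.5 * np.sum(((resp - self.means) / self.sds) ** 2))


def log_likelihood(
    y: np.ndarray, data: list[ObservationPoint], surrogates: list[Surrogate]
) -> float:
    """Convenience one-shot form of :class:`GaussianLikelihood`."""
    return GaussianLikelihood(surrogates, data)(y)


def mh_chain(
    config: MCMCConfig,
    log_like,
    space: ParameterSpace,
    start: np.ndarray | None = None,
) -> Chain:
    """Random-walk Metropolis-Hastings on the cube.

    Gaussian proposals in cube coordinates; proposals leaving the cube are
    rejected through the prior (zero density outside).  Returns post-burn-in
    samples, thinned by ``config.thin``.
    """
    n = space.n
    rng = np.random.default_rng(config.seed)
    sd = np.broadcast_to(np.asarray(config.proposal_sd, dtype=float), (n,))
    y = (
        rng.uniform(-1.0, 1.0, size=n)
        if start is None
        else np.asarray(start, dtype=float).copy()
    )
    lp = log_like(y)
    if not np.isfinite(lp):
        raise ValueError("starting point has zero posterior density")

    kept = (config.chain_length - config.burn_in) // config.thin
    samples = np.empty((kept, n))
    log_post = np.empty(kept)
    n_accept = 0
    stall = 0
    k = 0
    block = 65536
    i = 0
    while i < config.chain_length:
        m = min(block, config.chain_length - i)
        steps = rng.normal(0.0, sd, size=(m, n))
        logu = np.log(rng.uniform(size=m))
        for s in range(m):
            prop = y + steps[s]
            if np.all(np.abs(prop) <= 1.0):
                lp_prop = log_like(prop)
                if lp_prop - lp > logu[s]:
                    y = prop
                    lp = lp_prop
                    n_accept += 1
                    stall = 0
                else:
                    stall += 1
            else:
                stall += 1
            if stall >= 10_000:
                raise RuntimeError(
                    "no accepted proposal in 10^4 consecutive steps; "
                    f"proposal_sd={config.proposal_sd} is likely far too large"
                )
            j = i + s
            if j >= config.burn_in and (j - config.burn_in) % config.thin == 0:
                samples[k] = y
                log_post[k] = lp
                k += 1
        i += m
    return Chain(
        samples=samples[:k],
        log_post=log_post[:k],
        acceptance_rate=n_accept / config.chain_length,
        seed=config.seed,
    )


def tune_proposal_sd(
    log_like,
    space: ParameterSpace,
    seed: int = 0,
    target: tuple[float, float] = (0.2, 0.4),
    pilot_steps: int = 20_000,
    sd0: float = 0.1,
) -> float:
    """Pre-run tuning of the proposal scale toward a 20-40% acceptance rate.

    The tuned value is then fixed for the production chain.
    """
    sd = sd0
    for _ in range(12):
        cfg = MCMCConfig(
            chain_length=pilot_steps, burn_in=pilot_steps // 4, proposal_sd=sd, seed=seed
        )
        rate = mh_chain(cfg, log_like, space).acceptance_rate
        if rate < target[0]:
            sd /= 1.8
        elif rate > target[1]:
            sd *= 1.8
        else:
            return sd
    return sd


@dataclass
class ConvergenceReport:
    """Pairwise between-chain distribution distances, per parameter."""

    tv_distance: np.ndarray  # max over chain pairs of histogram total variation
    ks_statistic: np.ndarray  # max over chain pairs of the two-sample KS statistic
    tolerance: float
    passed: bool


def convergence_check(
    chains: list[Chain], tolerance: float = 0.1, bins: int = 50
) -> ConvergenceReport:
    """Compare the marginal distributions of independently started chains.

    For every parameter and chain pair, computes the total-variation
    distance between binned marginals (an L1 histogram distance) and the
    two-sample Kolmogorov-Smirnov statistic (rank-based); the check passes
    when both stay below ``tolerance`` for every parameter.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    n = chains[0].n
    for c in chains[1:]:
        if c.n != n:
            raise ValueError("chains have different parameter dimensions")
    edges = np.linspace(-1.0, 1.0, bins + 1)
    tv = np.zeros(n)
    ks = np.zeros(n)
    for j in range(n):
        hists = [
            np.histogram(c.samples[:, j], bins=edges)[0] / c.samples.shape[0]
            for c in chains
        ]
        for a in range(len(chains)):
            for b in range(a + 1, len(chains)):
                tv[j] = max(tv[j], 0.5 * float(np.abs(hists[a] - hists[b]).sum()))
                ks[j] = max(
                    ks[j],
                    float(
                        ks_2samp(
                            chains[a].samples[:, j], chains[b].samples[:, j]
                        ).statistic
                    ),
                )
    passed = bool(np.all(tv < tolerance) and np.all(ks < tolerance))
    return ConvergenceReport(tv_distance=tv, ks_statistic=ks, tolerance=tolerance, passed=passed)


@dataclass
class PosteriorSummary:
    """Marginal histograms (cube coordinates) and natural-unit point
    estimates; log-scaled parameters get log-spaced bins automatically
    because binning happens on the cube."""

    names: list[str]
    edges: np.ndarray  # (bins+1,) shared cube-coordinate bin edges
    histograms: np.ndarray  # (n, bins) unit-area densities on the cube
    mode: np.ndarray  # natural units
    mean: np.ndarray  # natural units (P_mean)
    mode_cube: np.ndarray
    mean_cube: np.ndarray
    correlation: np.ndarray
    ci_lo: np.ndarray  # central 95% interval, natural units
    ci_hi: np.ndarray


def posterior_summary(
    chain: Chain, space: ParameterSpace, bins: int = 100
) -> PosteriorSummary:
    """Summarize a chain: marginal mode (highest-density histogram bin),
    mean parameter set, central 95% intervals, and pairwise correlations
    of the cube coordinates."""
    if chain.samples.shape[0] == 0:
        raise ValueError("empty chain")
    Y = chain.samples
    n = chain.n
    edges = np.linspace(-1.0, 1.0, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.empty((n, bins))
    mode_cube = np.empty(n)
    for j in range(n):
        counts, _ = np.histogram(Y[:, j], bins=edges, density=True)
        hists[j] = counts
        mode_cube[j] = centers[int(np.argmax(counts))]
    mean_cube = Y.mean(axis=0)
    if Y.shape[0] > 1 and np.all(Y.std(axis=0) > 0):
        corr = np.corrcoef(Y, rowvar=False)
    else:
        corr = np.eye(n)
    corr = np.atleast_2d(corr)
    lo_c = np.percentile(Y, 2.5, axis=0)
    hi_c = np.percentile(Y, 97.5, axis=0)
    return PosteriorSummary(
        names=list(space.names),
        edges=edges,
        histograms=hists,
        mode=space.from_cube(mode_cube),
        mean=space.from_cube(mean_cube),
        mode_cube=mode_cube,
        mean_cube=mean_cube,
        correlation=corr,
        ci_lo=space.from_cube(lo_c),
        ci_hi=space.from_cube(hi_c),
    )


def save_chain(chain: Chain, space: ParameterSpace, path, sidecar: dict | None = None) -> None:
    """Chain as CSV (natural units + log-posterior) with a JSON sidecar of
    configuration and acceptance diagnostics."""
    import json
    import pandas as pd
    from pathlib import Path

    natural = space.from_cube(chain.samples)
    df = pd.DataFrame(natural, columns=space.names)
    df["log_post"] = chain.log_post
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "seed": chain.seed,
        "acceptance_rate": chain.acceptance_rate,
        "n_samples": int(chain.samples.shape[0]),
        **(sidecar or {}),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_chain(path, space: ParameterSpace) -> Chain:
    import json
    import pandas as pd
    from pathlib import Path

    df = pd.read_csv(path)
    samples = space.to_cube(df[space.names].to_numpy())
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Chain(
        samples=samples,
        log_post=df["log_post"].to_numpy(),
        acceptance_rate=float(meta.get("acceptance_rate", np.nan)),
        seed=int(meta.get("seed", -1)),
    )


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling: temperature T0 * rate^k for k = 0..n_temps-1."""

    T0: float = 1.0
    rate: float = 0.92
    n_temps: int = 80
    steps_per_temp: int = 60
    step_sd: float = 0.08


def simulated_annealing(
    objective,
    start: np.ndarray,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ``objective`` on the cube by simulated annealing.

    Gaussian moves clipped to the cube, Metropolis acceptance at the
    current temperature, geometric cooling.  Returns the best-so-far point
    (never worse than the start) and the best-objective trace.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(start, dtype=float).copy()
    f = float(objective(y))
    best_y, best_f = y.copy(), f
    trace = []
    T = schedule.T0
    for _ in range(schedule.n_temps):
        for _ in range(schedule.steps_per_temp):
            prop = np.clip(y + rng.normal(0.0, schedule.step_sd, size=y.shape), -1.0, 1.0)
            fp = float(objective(prop))
            if fp <= f or rng.uniform() < np.exp(-(fp - f) / max(T, 1e-300)):
                y, f = prop, fp
                if f < best_f:
                    best_y, best_f = y.copy(), f
        trace.append(best_f)
        T *= schedule.rate
    return best_y, np.array(trace)
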