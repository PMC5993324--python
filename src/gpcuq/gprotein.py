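"""Heterotrimeric G-protein cycle ODE model (Model 1).

Pheromone ligand L binds receptor R to form the complex RL, which catalyses
dissociation of heterotrimeric G-protein G into active Galpha (Ga) and free
Gbetagamma.  Ga hydrolyses to Gd, which reassociates with Gbg to reform G.
Two species are algebraic: ``Gd = Gt - G - Ga`` and ``Gbg = Gt - G``.  The
observable is the free-Gbg fraction ``Gbg/Gt``, measured on a grid of
(ligand dose, time) points: a time course at L = 1000 nM and a dose
response read out at T = 60 s.

Units: molecules/cell for species, seconds for time, nM for ligand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GProteinParams",
    "ObservationPoint",
    "BASELINE",
    "OBSERVATION_GRID",
    "rhs",
    "initial_state",
    "simulate",
    "response_vector",
    "mse",
    "read_observations",
    "write_observations",
]


@dataclass(frozen=True)
class GProteinParams:
    """Rate constants of the cycle plus the total G-protein pool Gt.

    kRL: nM^-1 s^-1; kRs: molecules s^-1; kGa, kG1: (molecules/cell)^-1 s^-1;
    all other rates s^-1; Gt: molecules/cell.
    """

    kRL: float = 2e-3
    kRLm: float = 1e-2
    kRs: float = 4.0
    kRd0: float = 4e-4
    kRd1: float = 4e-4
    kG1: float = 1.0
    kGa: float = 1e-5
    kGd: float = 1e-1
    Gt: float = 1e4

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if self.Gt <= 0:
            raise ValueError("Gt must be positive")

    def with_values(self, **kwargs: float) -> "GProteinParams":
        return replace(self, **kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "GProteinParams":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


#: Baseline parameter set (six literature-derived constants plus the
#: previously estimated kGa, kGd); the two-parameter studies vary only
#: kGa and kGd around this set.
BASELINE = GProteinParams()

#: The 15 (L [nM], T [s]) observation points: an eight-point time course at
#: saturating ligand and a seven-dose response at T = 60 s.
OBSERVATION_GRID: tuple[tuple[float, float], ...] = (
    (1000.0, 10.0),
    (1000.0, 30.0),
    (1000.0, 60.0),
    (1000.0, 120.0),
    (1000.0, 210.0),
    (1000.0, 300.0),
    (1000.0, 450.0),
    (1000.0, 600.0),
    (1.0, 60.0),
    (2.0, 60.0),
    (5.0, 60.0),
    (10.0, 60.0),
    (20.0, 60.0),
    (50.0, 60.0),
    (100.0, 60.0),
)


@dataclass(frozen=True)
class ObservationPoint:
    """One measured free-Gbg fraction: dose L, time T, mean +/- sd."""

    L: float
    T: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("mean must lie in [0, 1]")


def rhs(t: float, state: np.ndarray, p: GProteinParams, L: float) -> np.ndarray:
    """Time derivatives of (R, RL, G, Ga); Gd and Gbg are algebraic."""
    R, RL, G, Ga = state
    Gd = p.Gt - G - Ga
    Gbg = p.Gt - G
    dR = -p.kRL * L * R + p.kRLm * RL - p.kRd0 * R + p.kRs
    dRL = p.kRL * L * R - p.kRLm * RL - p.kRd1 * RL
    dG = -p.kGa * RL * G + p.kG1 * Gd * Gbg
    dGa = p.kGa * RL * G - p.kGd * Ga
    return np.array([dR, dRL, dG, dGa])


def initial_state(p: GProteinParams) -> np.ndarray:
    """Pre-stimulus steady state: R = kRs/kRd0, RL = 0, G = Gt, Ga = 0."""
    return np.array([p.kRs / p.kRd0, 0.0, p.Gt, 0.0])


def simulate(
    p: GProteinParams,
    L: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the cycle from the pre-stimulus state.

    Returns an array of shape (len(t_grid), 4) with columns (R, RL, G, Ga).
    ``t_grid`` must be increasing and start at 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    y0 = initial_state(p)
    if t_grid.size == 1:
        return y0[None, :]
    sol = solve_ivp(
        rhs,
        (0.0, t_grid[-1]),
        y0,
        t_eval=t_grid,
        args=(p, L),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def gbg_fraction(states: np.ndarray, p: GProteinParams) -> np.ndarray:
    return (p.Gt - states[..., 2]) / p.Gt


def response_vector(
    p: GProteinParams,
    obs: list[ObservationPoint] | tuple[tuple[float, float], ...] = OBSERVATION_GRID,
) -> np.ndarray:
    """Free-Gbg fractions at each (L, T) observation point.

    Points sharing a ligand dose share a single integration (the time-course
    block); each remaining dose is integrated to its own readout time.
    """
    pairs = [
        (o.L, o.T) if isinstance(o, ObservationPoint) else (float(o[0]), float(o[1]))
        for o in obs
    ]
    if not pairs:
        raise ValueError("observation list must be nonempty")
    out = np.empty(len(pairs))
    by_L: dict[float, list[int]] = {}
    for i, (L, _) in enumerate(pairs):
        by_L.setdefault(L, []).append(i)
    for L, idx in by_L.items():
        times = sorted({pairs[i][1] for i in idx})
        t_grid = np.unique(np.concatenate([[0.0], times]))
        states = simulate(p, L, t_grid)
        frac = gbg_fraction(states, p)
        lookup = dict(zip(t_grid, frac))
        for i in idx:
            out[i] = lookup[pairs[i][1]]
    return np.clip(out, 0.0, 1.0)


def mse(response: np.ndarray, data: list[ObservationPoint]) -> float:
    """Mean squared error of a response vector against observed means."""
    response = np.asarray(response, dtype=float)
    if response.shape[0] != len(data):
        raise ValueError(
            f"length mismatch: {response.shape[0]} responses vs {len(data)} data points"
        )
    means = np.array([o.mean for o in data])
    return float(np.mean((response - means) ** 2))


# -- CSV interface (columns L_nM, T_s, mean, sd) ---------------------------


def read_observations(path: str | Path) -> list[ObservationPoint]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        ObservationPoint(L=row.L_nM, T=row.T_s, mean=row.mean, sd=row.sd)
        for row in df.itertuples()
    ]


def write_observations(obs: list[ObservationPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "L_nM": [o.L for o in obs],
            "T_s": [o.T for o in obs],
            "mean": [o.mean for o in obs],
            "sd": [o.sd for o in obs],
        }
    )
    # %.17g guarantees bit-exact float round-trips through the reader
    df.to_csv(path, index=False, float_format="%.17g")
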