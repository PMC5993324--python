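"""Synthetic datasets emulating the study's observations.

Three generators, all fully determined by (spec, seed): noisy free-Gbg
observation sets on the standard (L, T) grid; von-Mises-shaped membrane
polarization profiles with a known polarization factor; and sample sets of
the polarization PDE's cutoff response for surrogate fitting, persisted
incrementally so expensive sampling is restartable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import gprotein, polarization
from .spaces import ParameterSpace
from .surrogate import SampleSet

__all__ = [
    "GProteinDatasetSpec",
    "generate_gprotein_dataset",
    "generate_polarization_profile",
    "make_pde_sampleset",
]


@dataclass(frozen=True)
class GProteinDatasetSpec:
    """Generating truth, observation grid, and per-point noise level."""

    params: gprotein.GProteinParams = gprotein.BASELINE
    grid: tuple[tuple[float, float], ...] = gprotein.OBSERVATION_GRID
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_gprotein_dataset(spec: GProteinDatasetSpec) -> list[gprotein.ObservationPoint]:
    """Model response on the grid plus Gaussian noise, clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    truth = gprotein.response_vector(spec.params, spec.grid)
    noisy = np.clip(truth + rng.normal(0.0, spec.noise_sd, size=truth.shape), 0.0, 1.0)
    return [
        gprotein.ObservationPoint(L=L, T=T, mean=float(m), sd=spec.noise_sd)
        for (L, T), m in zip(spec.grid, noisy)
    ]


def generate_polarization_profile(
    geometry: polarization.Geometry,
    kappa: float,
    total: float,
    center: float = np.pi,
    seed: int | None = None,
) -> np.ndarray:
    """Unimodal von-Mises-shaped membrane field scaled to a given total.

    ``kappa`` controls sharpness (0 gives a uniform field, PF = 0; PF grows
    monotonically with kappa); ``total`` is the conserved integral of the
    field over the membrane.  ``seed`` optionally jitters the peak location,
    to which PF is invariant.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if total <= 0:
        raise ValueError("total must be positive")
    if seed is not None:
        center = float(np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi))
    shape = np.exp(kappa * (np.cos(geometry.alpha - center) - 1.0))
    field = shape * (total / (shape.sum() * geometry.ds))
    return field


def make_pde_sampleset(
    space: ParameterSpace,
    count: int,
    seed: int,
    *,
    params: polarization.PolarizationParams = polarization.BASELINE,
    geometry: polarization.Geometry | None = None,
    t_end: float = 1000.0,
    dt: float = 0.05,
    checkpoint: str | Path | None = None,
) -> SampleSet:
    """Sample the cutoff response z of the polarization PDE on the cube.

    Parameters outside ``space`` stay fixed at ``params``.  Each sample i is
    simulated to steady state under its own derived seed, so the set can be
    regenerated identically and, via ``checkpoint`` (a JSON-lines file of
    finished samples), resumed after interruption or computed in parallel
    partitions.  Per-sample simulation failures are recorded with z = NaN
    and flagged rather than dropped.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    geometry = geometry or polarization.Geometry()
    Y = space.sample_uniform(count, seed)
    z = np.full(count, np.nan)
    done: dict[int, float] = {}
    path = Path(checkpoint) if checkpoint is not None else None
    if path is not None and path.exists():
        for line in path.read_text().splitlines():
            rec = json.loads(line)
            if rec["seed"] == seed and rec["count"] == count:
                done[rec["i"]] = rec["z"]
    handle = open(path, "a") if path is not None else None
    failures: list[int] = []
    try:
        for i in range(count):
            if i in done:
                z[i] = np.nan if done[i] is None else done[i]
                continue
            natural = space.from_cube(Y[i])
            p = params.with_values(**space.natural_dict(natural))
            try:
                res = polarization.simulate_to_steady(
                    p, geometry=geometry, t_end=t_end, dt=dt
                )
                c42a = res.state.field("C42a")
                pf = polarization.polarization_factor(c42a, geometry)
                z[i] = polarization.cutoff_response(pf, float(c42a.max()), p, geometry)
            except (RuntimeError, ValueError):
                failures.append(i)
            if handle is not None:
                rec = {"seed": seed, "count": count, "i": i, "z": None if np.isnan(z[i]) else z[i]}
                handle.write(json.dumps(rec) + "\n")
                handle.flush()
    finally:
        if handle is not None:
            handle.close()
    sample = SampleSet(Y=Y, Z=z, seed=seed, labels=["z"])
    sample.failed_indices = failures  # type: ignore[attr-defined]
    return sample
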