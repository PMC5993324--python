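"""Parameter spaces and the bijection onto the Legendre reference cube.

Every downstream stage (surrogate fitting, sensitivity analysis, MCMC)
operates on the reference cube ``[-1, 1]^n`` carrying the uniform product
measure; natural parameter values appear only at the model boundary.  A
:class:`ParameterSpace` owns that bijection: each parameter is mapped onto
``[-1, 1]`` linearly, either in its natural units or in ``log10`` of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParameterSpec",
    "ParameterSpace",
    "load_space",
    "save_space",
    "bundled_space",
]

_SCALES = ("linear", "log10")


@dataclass(frozen=True)
class ParameterSpec:
    """One parameter: name, natural-unit range and mapping scale.

    ``scale="log10"`` means the parameter is log-uniformly distributed over
    ``[lo, hi]``; equal multiplicative steps in the natural value correspond
    to equal additive steps on the cube.
    """

    name: str
    lo: float
    hi: float
    scale: str = "log10"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: require lo < hi, got [{self.lo}, {self.hi}]")
        if self.scale == "log10" and self.lo <= 0:
            raise ValueError(f"{self.name}: log10 scale requires lo > 0, got {self.lo}")

    def _transform(self, p: np.ndarray) -> np.ndarray:
        if self.scale == "log10":
            return np.log10(p)
        return np.asarray(p, dtype=float)

    def _lohi(self) -> tuple[float, float]:
        if self.scale == "log10":
            return np.log10(self.lo), np.log10(self.hi)
        return self.lo, self.hi

    def to_unit(self, p: np.ndarray) -> np.ndarray:
        a, b = self._lohi()
        return 2.0 * (self._transform(p) - a) / (b - a) - 1.0

    def from_unit(self, y: np.ndarray) -> np.ndarray:
        a, b = self._lohi()
        t = a + (np.asarray(y, dtype=float) + 1.0) * (b - a) / 2.0
        if self.scale == "log10":
            return 10.0**t
        return t


class ParameterSpace:
    """Ordered collection of :class:`ParameterSpec` defining the cube map."""

    def __init__(self, specs: Sequence[ParameterSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        self.specs = specs
        self.names = names

    @property
    def n(self) -> int:
        return len(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __repr__(self) -> str:
        return f"ParameterSpace({', '.join(self.names)})"

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subspace(self, names: Iterable[str]) -> "ParameterSpace":
        """Space restricted to ``names``, preserving this space's order."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"unknown parameters: {sorted(missing)}")
        return ParameterSpace([s for s in self.specs if s.name in keep])

    # -- cube bijection ----------------------------------------------------

    def to_cube(self, p: Sequence[float]) -> np.ndarray:
        """Map natural parameter values onto the reference cube [-1, 1]^n."""
        p = np.asarray(p, dtype=float)
        if p.shape[-1] != self.n:
            raise ValueError(f"expected {self.n} components, got {p.shape[-1]}")
        out = np.empty_like(p)
        for j, spec in enumerate(self.specs):
            pj = p[..., j]
            if np.any(pj < spec.lo) or np.any(pj > spec.hi):
                raise ValueError(
                    f"parameter {spec.name!r} outside its range [{spec.lo}, {spec.hi}]"
                )
            out[..., j] = spec.to_unit(pj)
        return out

    def from_cube(self, y: Sequence[float]) -> np.ndarray:
        """Inverse of :meth:`to_cube`; exact round-trip to machine precision."""
        y = np.asarray(y, dtype=float)
        if y.shape[-1] != self.n:
            raise ValueError(f"expected {self.n} components, got {y.shape[-1]}")
        if np.any(np.abs(y) > 1.0 + 1e-12):
            j = int(np.argmax(np.max(np.abs(y).reshape(-1, self.n), axis=0)))
            raise ValueError(f"cube coordinate for {self.names[j]!r} outside [-1, 1]")
        out = np.empty_like(y)
        for j, spec in enumerate(self.specs):
            out[..., j] = spec.from_unit(np.clip(y[..., j], -1.0, 1.0))
        return out

    def sample_uniform(self, count: int, seed: int | np.random.Generator) -> np.ndarray:
        """``count`` i.i.d. uniform draws on the cube, shape (count, n)."""
        if count < 1:
            raise ValueError("count must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return rng.uniform(-1.0, 1.0, size=(count, self.n))

    def natural_dict(self, p: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(p, dtype=float)))


# -- serialization ---------------------------------------------------------


def save_space(space: ParameterSpace, path: str | Path) -> None:
    payload = [
        {"name": s.name, "lo": s.lo, "hi": s.hi, "scale": s.scale} for s in space.specs
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_space(path: str | Path) -> ParameterSpace:
    payload = json.loads(Path(path).read_text())
    return ParameterSpace([ParameterSpec(**entry) for entry in payload])


def bundled_space(name: str) -> ParameterSpace:
    """Load one of the shipped parameter spaces.

    Available: ``gprotein2`` (the two free G-protein rates),
    ``gprotein8`` (all eight kinetic rates; ranges are a geometric
    reconstruction spanning two decades around the baseline estimates),
    ``polarization35`` (the full spatial-model space) and
    ``polarization15`` (the screened subset).
    """
    ref = resources.files("gpcuq").joinpath("data", f"space_{name}.json")
    if not ref.is_file():
        raise KeyError(f"no bundled space named {name!r}")
    payload = json.loads(ref.read_text())
    return ParameterSpace([ParameterSpec(**entry) for entry in payload])
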