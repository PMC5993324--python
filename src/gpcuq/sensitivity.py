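"""Global derivative-based sensitivity analysis from Legendre coefficients.

The sensitivity of a response z to cube coordinate y_j is the expectation
of the partial derivative over the uniform product measure on the cube,
``S_j = E[dz/dy_j]``.  For a Legendre expansion this is analytic: under
the product measure the expectation factorizes, E[P_m] vanishes unless
m = 0, and the half-integral of P_m' over [-1, 1] equals 1 for odd m and
0 for even m.  Hence S_j is simply the sum of the coefficients of the
pure odd-degree terms in y_j:

    S_j = sum { c_a : a_j odd, a_i = 0 for all i != j }.

Sensitivities are reported in cube coordinates, so parameters of very
different magnitudes (and log-scaled parameters) are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surrogate import Surrogate

__all__ = [
    "sensitivity_from_coeffs",
    "sensitivity_vector",
    "mean_abs_sensitivity",
    "SensitivityReport",
    "sensitivity_report",
]


def sensitivity_from_coeffs(surrogate: Surrogate, j: int) -> float:
    """S_j = E[dz/dy_j] computed exactly from the expansion coefficients."""
    idx = surrogate.basis.indices
    n = surrogate.basis.n
    if not 0 <= j < n:
        raise IndexError(f"parameter index {j} out of range for n={n}")
    others = np.delete(idx, j, axis=1)
    mask = (idx[:, j] % 2 == 1) & (others.sum(axis=1) == 0)
    return float(surrogate.coeffs[mask].sum())


def sensitivity_vector(surrogate: Surrogate) -> np.ndarray:
    return np.array(
        [sensitivity_from_coeffs(surrogate, j) for j in range(surrogate.basis.n)]
    )


def mean_abs_sensitivity(
    surrogate: Surrogate, n_points: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Monte Carlo estimate of E|dz/dy_j| using the analytic gradient.

    There is no closed form for the absolute first moment, so it is
    estimated over seeded uniform cube points.
    """
    rng = np.random.default_rng(seed)
    Y = rng.uniform(-1.0, 1.0, size=(n_points, surrogate.basis.n))
    return np.abs(surrogate.gradient(Y)).mean(axis=0)


@dataclass
class SensitivityReport:
    """Per-response sensitivity matrix with screening summary.

    ``S[j, r]`` is the sensitivity of response r to parameter j.  The
    retained set keeps parameters with ``|mean_j S| > threshold``; the
    mean of |S| over responses is reported alongside since near-sign-
    consistent sensitivities make the two criteria almost equivalent.
    """

    names: list[str]
    response_labels: list[str]
    S: np.ndarray
    threshold: float

    @property
    def mean_over_responses(self) -> np.ndarray:
        return self.S.mean(axis=1)

    @property
    def mean_abs_over_responses(self) -> np.ndarray:
        return np.abs(self.S).mean(axis=1)

    @property
    def retained(self) -> list[str]:
        keep = np.abs(self.mean_over_responses) > self.threshold
        return [n for n, k in zip(self.names, keep) if k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.S, index=self.names, columns=self.response_labels)
        df["mean"] = self.mean_over_responses
        df["mean_abs"] = self.mean_abs_over_responses
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def sensitivity_report(
    surrogates: list[Surrogate], threshold: float = 0.01
) -> SensitivityReport:
    """Sensitivity matrix over a list of response surrogates sharing one
    parameter space, plus threshold screening of the retained parameters."""
    if not surrogates:
        raise ValueError("need at least one surrogate")
    n = surrogates[0].basis.n
    for s in surrogates[1:]:
        if s.basis.n != n:
            raise ValueError("all surrogates must share one parameter space")
    S = np.column_stack([sensitivity_vector(s) for s in surrogates])
    if surrogates[0].space is not None:
        names = list(surrogates[0].space.names)
    else:
        names = [f"y{j}" for j in range(n)]
    labels = [s.response_label for s in surrogates]
    return SensitivityReport(names=names, response_labels=labels, S=S, threshold=threshold)
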