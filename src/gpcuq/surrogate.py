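"""Total-degree Legendre polynomial surrogates.

A surrogate is an expansion ``z(y) = sum_a c_a * prod_k P_{a_k}(y_k)`` over
all multi-indices ``a`` of total degree <= d, in the unnormalized Legendre
convention ``P_m(1) = 1``, defined on the reference cube ``[-1, 1]^n``.
Coefficients are fit from sampled model evaluations either by least squares
(oversampled) or by compressed sensing -- l1-minimization with a quadratic
constraint (basis-pursuit denoising) -- when the design is underdetermined.
Accuracy is estimated by k-fold cross-validation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

from .spaces import ParameterSpace

__all__ = [
    "basis_count",
    "MultiIndexBasis",
    "legendre_eval",
    "design_matrix",
    "fit_least_squares",
    "fit_l1",
    "Surrogate",
    "SurrogateEnsemble",
    "SampleSet",
    "FitReport",
    "cross_validate",
    "fit_surrogates",
]


def basis_count(n: int, d: int) -> int:
    """Number of total-degree-<=d polynomial basis terms in n variables:
    binomial(n+d, n)."""
    if n < 1 or d < 0:
        raise ValueError("require n >= 1 and d >= 0")
    return math.comb(n + d, n)


def _enumerate_indices(n: int, d: int) -> np.ndarray:
    """All multi-indices with |a| <= d in graded lexicographic order."""
    out: list[tuple[int, ...]] = []

    def compositions(total: int, parts: int, prefix: tuple[int, ...]):
        if parts == 1:
            out.append(prefix + (total,))
            return
        for first in range(total, -1, -1):
            compositions(total - first, parts - 1, prefix + (first,))

    for degree in range(d + 1):
        compositions(degree, n, ())
    return np.array(out, dtype=np.int64)


@dataclass(frozen=True)
class MultiIndexBasis:
    """Graded-lexicographically ordered total-degree multi-index set."""

    n: int
    d: int
    indices: np.ndarray = dc_field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.indices is None:
            object.__setattr__(self, "indices", _enumerate_indices(self.n, self.d))
        assert self.indices.shape == (basis_count(self.n, self.d), self.n)

    def __len__(self) -> int:
        return self.indices.shape[0]


def legendre_eval(m: int, x) -> np.ndarray | float:
    """Unnormalized Legendre polynomial P_m(x) by the three-term recurrence,
    with P_m(1) = 1."""
    if m < 0:
        raise ValueError("degree must be >= 0")
    x = np.asarray(x, dtype=float)
    return _legendre_table(m, x)[m]


def _legendre_table(d: int, x: np.ndarray) -> np.ndarray:
    """P_0..P_d evaluated at x; shape (d+1,) + x.shape."""
    P = np.empty((d + 1,) + x.shape)
    P[0] = 1.0
    if d >= 1:
        P[1] = x
    for m in range(1, d):
        P[m + 1] = ((2 * m + 1) * x * P[m] - m * P[m - 1]) / (m + 1)
    return P


def design_matrix(Y: np.ndarray, basis: MultiIndexBasis) -> np.ndarray:
    """A[i, j] = prod_k P_{a_j(k)}(Y[i, k]) — rows are samples, columns are
    basis terms."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != basis.n:
        raise ValueError(f"samples have dimension {Y.shape[1]}, basis expects {basis.n}")
    P = _legendre_table(basis.d, Y)  # (d+1, M, n)
    A = np.ones((Y.shape[0], len(basis)))
    for k in range(basis.n):
        A *= P[basis.indices[:, k], :, k].T
    return A


def fit_least_squares(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via a rank-revealing factorization.

    Requires an oversampled (rows >= cols) design; warns and returns the
    minimum-norm solution on rank deficiency.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.shape[0] < A.shape[1]:
        raise ValueError(
            f"undersampled design ({A.shape[0]} rows < {A.shape[1]} cols): use fit_l1"
        )
    x, _, rank, _ = scipy.linalg.lstsq(A, b, lapack_driver="gelsd")
    if rank < A.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {A.shape[1]}); "
            "returning the minimum-norm least-squares solution",
            stacklevel=2,
        )
    return x


def fit_l1(
    A: np.ndarray,
    b: np.ndarray,
    epsilon: float,
    *,
    tol: float = 1e-9,
    max_newton: int = 80,
) -> np.ndarray:
    """Basis-pursuit denoising: min ||x||_1 s.t. ||Ax - b||_2 <= epsilon.

    Solved as a second-order-cone program by a primal log-barrier method
    (Newton steps on the barrier of the epigraph formulation).  An
    effectively-zero epsilon is dispatched to the equality-constrained
    basis-pursuit linear program.  Underdetermined designs are the intended
    regime; the returned vector always satisfies the quadratic constraint.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    M, N = A.shape
    nb = float(np.linalg.norm(b))
    if nb <= epsilon:
        return np.zeros(N)  # zero is feasible, hence l1-optimal
    if epsilon <= 1e-6 * nb:
        return _basis_pursuit_lp(A, b, epsilon)
    return _l1qc_logbarrier(A, b, epsilon, tol=tol, max_newton=max_newton)


def _auto_epsilon(A: np.ndarray, b: np.ndarray) -> float:
    """Default l1 constraint radius: 0.05*||b||, floored just above the
    best achievable residual so the constraint set is never empty (an
    oversampled design can have a least-squares residual above 0.05*||b||)."""
    eps = 0.05 * float(np.linalg.norm(b))
    resid = A @ np.linalg.lstsq(A, b, rcond=None)[0] - b
    return max(eps, 1.05 * float(np.linalg.norm(resid)))


def _basis_pursuit_lp(A: np.ndarray, b: np.ndarray, epsilon: float) -> np.ndarray:
    """min ||x||_1 s.t. Ax = b via x = u - v, u,v >= 0 (HiGHS)."""
    M, N = A.shape
    c = np.ones(2 * N)
    res = linprog(c, A_eq=np.hstack([A, -A]), b_eq=b, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"basis-pursuit LP failed: {res.message}")
    x = res.x[:N] - res.x[N:]
    resid = float(np.linalg.norm(A @ x - b))
    if resid > max(epsilon, 1e-8 * max(1.0, float(np.linalg.norm(b)))) * (1 + 1e-6):
        raise RuntimeError(f"basis pursuit residual {resid:.3e} exceeds epsilon {epsilon:.3e}")
    return x


def _l1qc_logbarrier(
    A: np.ndarray, b: np.ndarray, epsilon: float, tol: float, max_newton: int
) -> np.ndarray:
    M, N = A.shape
    # strictly feasible start: minimum-norm interpolant (or LS solution)
    x = np.linalg.lstsq(A, b, rcond=None)[0]
    r = A @ x - b
    if np.linalg.norm(r) >= epsilon:
        raise RuntimeError(
            f"no strictly feasible point: min residual {np.linalg.norm(r):.3e} "
            f">= epsilon {epsilon:.3e}"
        )
    u = 0.95 * np.abs(x) + 0.10 * max(float(np.abs(x).max()), 1e-12)

    AtA = A.T @ A
    n_constraints = 2 * N + 1
    tau = max(1.0, n_constraints / max(float(np.sum(u)), 1e-12))
    mu = 10.0
    n_stages = int(np.ceil(np.log(n_constraints / (tau * tol)) / np.log(mu))) + 1

    for _ in range(max(n_stages, 1)):
        x, u, r = _l1qc_newton(A, AtA, b, x, u, r, epsilon, tau, max_newton)
        tau *= mu
    return x


def _l1qc_newton(A, AtA, b, x, u, r, epsilon, tau, max_newton):
    N = x.size
    for _ in range(max_newton):
        f1 = x - u
        f2 = -x - u
        fe = 0.5 * (r @ r - epsilon**2)
        atr = A.T @ r

        gx = -1.0 / f1 + 1.0 / f2 - atr / fe
        gu = tau + 1.0 / f1 + 1.0 / f2

        sig11 = 1.0 / f1**2 + 1.0 / f2**2
        sig12 = -1.0 / f1**2 + 1.0 / f2**2
        sigx = sig11 - sig12**2 / sig11

        H = -AtA / fe + np.outer(atr, atr) / fe**2
        H[np.diag_indices(N)] += sigx
        rhs = -gx + (sig12 / sig11) * gu
        try:
            dx = scipy.linalg.solve(H, rhs, assume_a="sym")
        except scipy.linalg.LinAlgError:
            break
        du = (-gu - sig12 * dx) / sig11

        # largest step keeping all constraints strictly feasible
        Adx = A @ dx
        s = 1.0
        ind = dx - du > 0
        if np.any(ind):
            s = min(s, 0.99 * float(np.min(-f1[ind] / (dx - du)[ind])))
        ind = -dx - du > 0
        if np.any(ind):
            s = min(s, 0.99 * float(np.min(-f2[ind] / (-dx - du)[ind])))
        aqe = Adx @ Adx
        bqe = 2.0 * (r @ Adx)
        cqe = r @ r - epsilon**2
        disc = bqe**2 - 4 * aqe * cqe
        if aqe > 0 and disc > 0:
            smax = (-bqe + np.sqrt(disc)) / (2 * aqe)
            if smax > 0:
                s = min(s, 0.99 * float(smax))

        phi0 = (
            tau * np.sum(u)
            - np.sum(np.log(-f1))
            - np.sum(np.log(-f2))
            - np.log(-fe)
        )
        gdot = gx @ dx + gu @ du
        alpha, beta = 0.01, 0.5
        for _bt in range(32):
            xn = x + s * dx
            un = u + s * du
            rn = r + s * Adx
            f1n = xn - un
            f2n = -xn - un
            fen = 0.5 * (rn @ rn - epsilon**2)
            if np.all(f1n < 0) and np.all(f2n < 0) and fen < 0:
                phin = (
                    tau * np.sum(un)
                    - np.sum(np.log(-f1n))
                    - np.sum(np.log(-f2n))
                    - np.log(-fen)
                )
                if phin <= phi0 + alpha * s * gdot:
                    break
            s *= beta
        else:
            break
        x, u, r = xn, un, rn
        if np.linalg.norm(np.concatenate([dx, du])) * s < 1e-12:
            break
        if -gdot * s < 1e-14 * max(abs(phi0), 1.0):
            break
    return x, u, r


@dataclass
class Surrogate:
    """One fitted Legendre expansion for a single response function."""

    basis: MultiIndexBasis
    coeffs: np.ndarray
    response_label: str = "z"
    space: ParameterSpace | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (len(self.basis),):
            raise ValueError("coefficient count must match basis size")

    def evaluate(self, y: np.ndarray) -> np.ndarray | float:
        """Evaluate at cube coordinates; warns (extrapolation) outside the
        cube rather than raising."""
        y = np.asarray(y, dtype=float)
        scalar = y.ndim == 1
        Y = np.atleast_2d(y)
        if np.any(np.abs(Y) > 1.0 + 1e-12):
            warnings.warn("evaluating surrogate outside [-1, 1]^n (extrapolation)",
                          stacklevel=2)
        out = design_matrix(Y, self.basis) @ self.coeffs
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def gradient(self, y: np.ndarray) -> np.ndarray:
        """Analytic gradient w.r.t. cube coordinates; shape (..., n)."""
        y = np.asarray(y, dtype=float)
        scalar = y.ndim == 1
        Y = np.atleast_2d(y)
        d, n = self.basis.d, self.basis.n
        P = _legendre_table(d, Y)  # (d+1, M, n)
        dP = _legendre_deriv_table(d, Y, P)
        out = np.zeros((Y.shape[0], n))
        idx = self.basis.indices
        for j in range(n):
            cols = np.ones((Y.shape[0], len(self.basis)))
            for k in range(n):
                tab = dP if k == j else P
                cols *= tab[idx[:, k], :, k].T
            out[:, j] = cols @ self.coeffs
        return out[0] if scalar else out

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path, metadata: dict | None = None) -> None:
        payload = {
            "n": self.basis.n,
            "degree": self.basis.d,
            "indices": self.basis.indices.tolist(),
            "coefficients": self.coeffs.tolist(),
            "response_label": self.response_label,
            "metadata": metadata or {},
        }
        if self.space is not None:
            payload["space"] = [
                {"name": s.name, "lo": s.lo, "hi": s.hi, "scale": s.scale}
                for s in self.space.specs
            ]
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Surrogate":
        payload = json.loads(Path(path).read_text())
        basis = MultiIndexBasis(
            payload["n"], payload["degree"], np.array(payload["indices"], dtype=np.int64)
        )
        space = None
        if "space" in payload:
            from .spaces import ParameterSpec

            space = ParameterSpace([ParameterSpec(**e) for e in payload["space"]])
        return cls(
            basis=basis,
            coeffs=np.array(payload["coefficients"]),
            response_label=payload.get("response_label", "z"),
            space=space,
        )


def _legendre_deriv_table(d: int, x: np.ndarray, P: np.ndarray) -> np.ndarray:
    """P_0'..P_d' via (x^2-1)/m * P_m' = x P_m - P_{m-1} with endpoint-safe
    recurrence dP_{m+1} = (2m+1) P_m + dP_{m-1}."""
    dP = np.zeros_like(P)
    if d >= 1:
        dP[1] = 1.0
    for m in range(1, d):
        dP[m + 1] = (2 * m + 1) * P[m] + dP[m - 1]
    return dP


class SurrogateEnsemble:
    """Several surrogates over one basis, evaluated together.

    Used on the MCMC hot path: one design row serves every response.
    """

    def __init__(self, surrogates: Sequence[Surrogate]):
        if not surrogates:
            raise ValueError("need at least one surrogate")
        basis = surrogates[0].basis
        for s in surrogates[1:]:
            if s.basis.n != basis.n or s.basis.d != basis.d:
                raise ValueError("all surrogates must share one basis")
        self.basis = basis
        self.surrogates = list(surrogates)
        self.C = np.column_stack([s.coeffs for s in surrogates])  # (B, R)
        self.labels = [s.response_label for s in surrogates]

    @property
    def n_responses(self) -> int:
        return self.C.shape[1]

    def evaluate(self, y: np.ndarray) -> np.ndarray:
        """Response vector(s) at cube point(s) y: shape (R,) or (M, R)."""
        y = np.asarray(y, dtype=float)
        scalar = y.ndim == 1
        A = design_matrix(np.atleast_2d(y), self.basis)
        out = A @ self.C
        return out[0] if scalar else out

    __call__ = evaluate


@dataclass
class SampleSet:
    """Cube-coordinate samples Y (M, n) with responses Z (M, R)."""

    Y: np.ndarray
    Z: np.ndarray
    seed: int | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        if self.Y.shape[0] != self.Z.shape[0]:
            raise ValueError("Y and Z must have the same number of rows")
        if np.any(np.abs(self.Y) > 1.0 + 1e-12):
            raise ValueError("sample coordinates must lie in [-1, 1]^n")
        if self.labels is None:
            self.labels = [f"z{i}" for i in range(self.Z.shape[1])]

    def to_csv(self, path: str | Path) -> None:
        cols = [f"y{i}" for i in range(self.Y.shape[1])] + list(self.labels)
        with open(path, "w") as f:
            f.write(f"# seed={self.seed}\n")
            f.write(",".join(cols) + "\n")
            data = np.hstack([self.Y, self.Z])
            np.savetxt(f, data, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSet":
        seed = None
        with open(path) as f:
            first = f.readline()
            if first.startswith("# seed="):
                token = first.strip().split("=", 1)[1]
                seed = int(token) if token not in ("None", "") else None
                header = f.readline()
            else:
                header = first
            names = header.strip().split(",")
            data = np.loadtxt(f, delimiter=",", ndmin=2)
        n = sum(1 for c in names if c.startswith("y") and c[1:].isdigit())
        return cls(Y=data[:, :n], Z=data[:, n:], seed=seed, labels=names[n:])


@dataclass
class FitReport:
    """Cross-validation error summary (error = surrogate - model)."""

    mean_error: np.ndarray
    sd_error: np.ndarray
    mean_abs_error: np.ndarray
    method: Literal["least_squares", "l1_quadratic"]
    epsilon: float | None
    folds: int


def cross_validate(
    samples: SampleSet,
    basis: MultiIndexBasis,
    k: int,
    method: Literal["least_squares", "l1_quadratic"] = "least_squares",
    seed: int = 0,
    epsilon: float | None = None,
) -> FitReport:
    """k-fold cross-validation of the surrogate fit.

    The sample set is split into k nearly equal folds; each fold is held
    out once while the complement is fit, and held-out errors are pooled.
    """
    M = samples.Y.shape[0]
    if not 2 <= k <= M:
        raise ValueError("need samples >= k >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    folds = np.array_split(perm, k)
    if method == "least_squares" and M - max(len(f) for f in folds) < len(basis):
        raise ValueError(
            "training folds are undersampled for least squares; use method='l1_quadratic'"
        )
    A = design_matrix(samples.Y, basis)
    R = samples.Z.shape[1]
    errors = np.empty((M, R))
    for hold in folds:
        train = np.setdiff1d(perm, hold, assume_unique=False)
        for r in range(R):
            b = samples.Z[train, r]
            if method == "least_squares":
                c = fit_least_squares(A[train], b)
            else:
                eps = _auto_epsilon(A[train], b) if epsilon is None else epsilon
                c = fit_l1(A[train], b, eps)
            errors[hold, r] = A[hold] @ c - samples.Z[hold, r]
    return FitReport(
        mean_error=errors.mean(axis=0),
        sd_error=errors.std(axis=0, ddof=1),
        mean_abs_error=np.abs(errors).mean(axis=0),
        method=method,
        epsilon=epsilon,
        folds=k,
    )


def fit_surrogates(
    samples: SampleSet,
    degree: int,
    method: Literal["least_squares", "l1_quadratic"] = "least_squares",
    space: ParameterSpace | None = None,
    epsilon: float | None = None,
) -> list[Surrogate]:
    """Fit one surrogate per response column of ``samples``."""
    n = samples.Y.shape[1]
    basis = MultiIndexBasis(n, degree)
    A = design_matrix(samples.Y, basis)
    out = []
    for r in range(samples.Z.shape[1]):
        b = samples.Z[:, r]
        if method == "least_squares":
            c = fit_least_squares(A, b)
        else:
            eps = _auto_epsilon(A, b) if epsilon is None else epsilon
            c = fit_l1(A, b, eps)
        out.append(
            Surrogate(basis=basis, coeffs=c, response_label=samples.labels[r], space=space)
        )
    return out
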