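"""Data-driven point-to-point control: the heart of the package.

Given only the data matrices (U, Y_mid, Y_T) of N episodic experiments on an
*unknown* network, the optimal control reaching a target output y_f in T
steps is

    u_hat = U (I - K (L K)^+ L) Y_T^+ y_f,        L'L = Y_mid' Q Y_mid + U' R U,

with K an orthonormal basis of the kernel of Y_T.  With full-row-rank U
(N >= mT independent experiments) this equals the model-based optimum
exactly; with fewer data but y_f in the range of Y_T it still steers the
output to y_f, at a typically larger cost.  Specializations:

    minimum energy (Q=0, R=I):   u_hat  = (Y_T U^+)^+ y_f
    cheap approximation:         u_tilde = U Y_T^+ y_f

The approximation converges to the minimum-energy control as N -> infinity
for zero-mean i.i.d. Gaussian input data.  For data corrupted by zero-mean
i.i.d. noise of known variance, asymptotically consistent corrected variants
subtract N*sigma^2*I inside the relevant pseudoinverse.

The same data also answer structural questions: y_f is reachable iff it lies
in the range of Y_T, and (with N >= mT independent inputs and T >= n) the
system is output controllable iff Y_T has full row rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._linalg import (DEFAULT_PINV_TOL, kernel_basis, numerical_rank, pinv,
                      psd_sqrt, range_residual)
from .datagen import DataMatrices, unstack_input
from .model_control import (ControlProblem, ControlSolution,
                            InfeasibleTargetError, _evaluate, _finalize)
from .systems import LinearNetworkSystem


class IndefiniteCorrectionWarning(UserWarning):
    """The noise-corrected second-moment matrix has negative eigenvalues.

    The corrected formulas are asymptotic in N; at small N the subtraction of
    N*sigma^2*I can make the matrix indefinite.  The pseudoinverse is applied
    regardless, but results should be treated with caution.
    """


class ReachabilityResult(NamedTuple):
    reachable: bool
    residual: float


@dataclass
class ControllabilityResult:
    controllable: bool
    rank_Y_T: int
    p: int
    warnings: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.controllable


@dataclass
class EmpiricalCtrb:
    """Empirical output controllability matrix and Gramian estimated from data.

    ``C_hat = Y_T U^+`` is the least-squares estimate of C_T; the empirical
    output Gramian is ``W_hat = C_hat C_hat'`` (p x p), whose eigenvectors
    rank output directions from most to least controllable.
    """

    C_hat: np.ndarray
    W_hat: np.ndarray
    eigvalues: np.ndarray    # descending
    eigvectors: np.ndarray   # columns, matching eigvalues


def _check_data(data: DataMatrices) -> None:
    if not np.any(data.U) and not np.any(data.Y_T):
        raise ValueError("degenerate all-zero data matrices")


def _check_reachable(X: np.ndarray, y_f: np.ndarray, tol: float,
                     reach_tol: float, what: str) -> None:
    ynorm = max(float(np.linalg.norm(y_f)), 1.0)
    res = range_residual(X, y_f, tol) / ynorm
    if res > reach_tol:
        raise InfeasibleTargetError(
            f"target y_f is outside the range of {what}", res)


def dd_optimal_control(data: DataMatrices, y_f: np.ndarray,
                       Q: np.ndarray | float = 0.0,
                       R: np.ndarray | float = 1.0,
                       system: LinearNetworkSystem | None = None,
                       tol: float = DEFAULT_PINV_TOL,
                       reach_tol: float = 1e-6) -> ControlSolution:
    """Optimal data-driven control for general quadratic weights Q, R.

    Scalars for ``Q``/``R`` are expanded to multiples of the identity.  If a
    ``system`` is supplied, the realized error and cost are evaluated by
    simulating it with the designed input.
    """
    _check_data(data)
    y_f = np.asarray(y_f, dtype=float).ravel()
    prob = _as_problem(data, y_f, Q, R)
    _check_reachable(data.Y_T, y_f, tol, reach_tol, "Y_T")
    G = data.U.T @ prob.R @ data.U
    if prob.Q.size and data.Y_mid.size:
        G = G + data.Y_mid.T @ prob.Q @ data.Y_mid
    L = psd_sqrt(G)
    K = kernel_basis(data.Y_T, tol)
    base = pinv(data.Y_T, tol) @ y_f
    if K.shape[1] == 0:
        coeff = base
    else:
        coeff = base - K @ (pinv(L @ K, tol) @ (L @ base))
    stacked = data.U @ coeff
    return _finalize(stacked, data.m, data.T, system, prob, "dd_optimal")


def _as_problem(data: DataMatrices, y_f: np.ndarray,
                Q: np.ndarray | float, R: np.ndarray | float) -> ControlProblem:
    if np.isscalar(Q):
        Qm = float(Q) * np.eye(data.p * (data.T - 1)) \
            if (data.T > 1 and Q != 0.0) else np.zeros((0, 0))
    else:
        Qm = np.asarray(Q, dtype=float)
    Rm = float(R) * np.eye(data.m * data.T) if np.isscalar(R) \
        else np.asarray(R, dtype=float)
    return ControlProblem(y_f=y_f, T=data.T, Q=Qm, R=Rm)


def dd_min_energy(data: DataMatrices, y_f: np.ndarray,
                  system: LinearNetworkSystem | None = None,
                  tol: float = DEFAULT_PINV_TOL,
                  reach_tol: float = 1e-6) -> ControlSolution:
    """Data-driven minimum-energy control ``(Y_T U^+)^+ y_f``."""
    _check_data(data)
    y_f = np.asarray(y_f, dtype=float).ravel()
    C_hat = data.Y_T @ pinv(data.U, tol)
    _check_reachable(C_hat, y_f, tol, reach_tol, "Y_T U^+")
    stacked = pinv(C_hat, tol) @ y_f
    prob = _as_problem(data, y_f, 0.0, 1.0)
    return _finalize(stacked, data.m, data.T, system, prob, "dd_min_energy")


def dd_min_energy_approx(data: DataMatrices, y_f: np.ndarray,
                         system: LinearNetworkSystem | None = None,
                         tol: float = DEFAULT_PINV_TOL,
                         reach_tol: float = 1e-6) -> ControlSolution:
    """Approximate data-driven control ``U Y_T^+ y_f``.

    A single pseudoinverse; suboptimal at finite N but converges to the
    minimum-energy control as N grows (Gaussian inputs), and is often the
    most numerically accurate expression in practice.
    """
    _check_data(data)
    y_f = np.asarray(y_f, dtype=float).ravel()
    _check_reachable(data.Y_T, y_f, tol, reach_tol, "Y_T")
    stacked = data.U @ (pinv(data.Y_T, tol) @ y_f)
    prob = _as_problem(data, y_f, 0.0, 1.0)
    return _finalize(stacked, data.m, data.T, system, prob,
                     "dd_min_energy_approx")


def _corrected_pinv_second_moment(X: np.ndarray, N: int,
                                  sigma: float, tol: float) -> np.ndarray:
    """(X X' - N sigma^2 I)^+ with an indefiniteness warning."""
    S = X @ X.T - N * sigma**2 * np.eye(X.shape[0])
    if sigma > 0:
        w = np.linalg.eigvalsh(0.5 * (S + S.T))
        if w[0] < -1e-8:
            warnings.warn(
                f"noise-corrected second moment is indefinite (min eig "
                f"{w[0]:.3e}); the corrected formulas are asymptotic in N",
                IndefiniteCorrectionWarning, stacklevel=3)
    return pinv(S, tol)


def dd_min_energy_noise_corrected(data: DataMatrices, y_f: np.ndarray,
                                  sigma_U: float,
                                  system: LinearNetworkSystem | None = None,
                                  tol: float = DEFAULT_PINV_TOL,
                                  reach_tol: float = 1e-6) -> ControlSolution:
    """Noise-corrected minimum-energy control for input-data noise.

    ``u = (Y_T U' (U U' - N sigma_U^2 I)^+)^+ y_f``; with ``sigma_U = 0``
    this coincides with :func:`dd_min_energy` via ``X^+ = X'(X X')^+``.
    Noise on Y_T alone needs no correction.
    """
    _check_data(data)
    if sigma_U < 0:
        raise ValueError("sigma_U must be nonnegative")
    y_f = np.asarray(y_f, dtype=float).ravel()
    C_hat = data.Y_T @ data.U.T @ _corrected_pinv_second_moment(
        data.U, data.N, sigma_U, tol)
    _check_reachable(C_hat, y_f, tol, reach_tol, "the corrected Y_T U^+")
    stacked = pinv(C_hat, tol) @ y_f
    prob = _as_problem(data, y_f, 0.0, 1.0)
    return _finalize(stacked, data.m, data.T, system, prob,
                     "dd_min_energy_corrected")


def dd_approx_noise_corrected(data: DataMatrices, y_f: np.ndarray,
                              sigma_YT: float,
                              system: LinearNetworkSystem | None = None,
                              tol: float = DEFAULT_PINV_TOL,
                              reach_tol: float = 1e-6) -> ControlSolution:
    """Noise-corrected approximate control for final-output noise.

    ``u = U Y_T' (Y_T Y_T' - N sigma_YT^2 I)^+ y_f``; with ``sigma_YT = 0``
    this coincides with :func:`dd_min_energy_approx`.  Noise on U alone needs
    no correction in this expression.
    """
    _check_data(data)
    if sigma_YT < 0:
        raise ValueError("sigma_YT must be nonnegative")
    y_f = np.asarray(y_f, dtype=float).ravel()
    _check_reachable(data.Y_T, y_f, tol, reach_tol, "Y_T")
    stacked = data.U @ (data.Y_T.T @ (_corrected_pinv_second_moment(
        data.Y_T, data.N, sigma_YT, tol) @ y_f))
    prob = _as_problem(data, y_f, 0.0, 1.0)
    return _finalize(stacked, data.m, data.T, system, prob,
                     "dd_approx_corrected")


def target_reachable(data: DataMatrices, y_f: np.ndarray,
                     tol: float = DEFAULT_PINV_TOL,
                     reach_tol: float = 1e-6) -> ReachabilityResult:
    """Whether y_f lies in the range of Y_T, with the projection residual."""
    y_f = np.asarray(y_f, dtype=float).ravel()
    res = range_residual(data.Y_T, y_f, tol)
    ynorm = max(float(np.linalg.norm(y_f)), 1.0)
    return ReachabilityResult(reachable=res / ynorm <= reach_tol, residual=res)


def data_output_controllability(data: DataMatrices, n: int,
                                tol: float = DEFAULT_PINV_TOL
                                ) -> ControllabilityResult:
    """Output controllability test purely from data.

    Valid when the input data matrix has full row rank mT (checked; an error
    otherwise) and T >= n (checked; recorded as a warning otherwise, since
    full row rank of Y_T is then sufficient but its absence inconclusive).
    The system is output controllable iff rank(Y_T) = p.
    """
    rank_U = numerical_rank(data.U, tol)
    if rank_U < data.m * data.T:
        raise ValueError(
            f"input data matrix is rank deficient (rank {rank_U} < "
            f"{data.m * data.T}); the controllability test needs mT "
            f"linearly independent experiments")
    warns: list[str] = []
    if data.T < n:
        warns.append(
            f"T = {data.T} < n = {n}: full row rank of Y_T certifies "
            f"T-step output controllability only; rank deficiency is "
            f"inconclusive about controllability over longer horizons")
    rank_Y = numerical_rank(data.Y_T, tol)
    return ControllabilityResult(controllable=rank_Y == data.p,
                                 rank_Y_T=rank_Y, p=data.p, warnings=warns)


def empirical_ctrb(data: DataMatrices,
                   tol: float = DEFAULT_PINV_TOL) -> EmpiricalCtrb:
    """Empirical controllability matrix ``Y_T U^+`` and Gramian from data."""
    _check_data(data)
    C_hat = data.Y_T @ pinv(data.U, tol)
    W_hat = C_hat @ C_hat.T
    W_hat = 0.5 * (W_hat + W_hat.T)
    w, V = np.linalg.eigh(W_hat)
    order = np.argsort(w)[::-1]
    return EmpiricalCtrb(C_hat=C_hat, W_hat=W_hat,
                         eigvalues=w[order], eigvectors=V[:, order])


def gramian_eigentargets(data: DataMatrices, k: int,
                         tol: float = DEFAULT_PINV_TOL) -> list[np.ndarray]:
    """Top-k unit eigenvectors of the empirical output Gramian.

    Ordered from the most to the least controllable output direction; the
    control energy needed to reach them is nondecreasing along the list.
    """
    if k < 1 or k > data.p:
        raise ValueError(f"k must be between 1 and p = {data.p}")
    emp = empirical_ctrb(data, tol)
    return [emp.eigvectors[:, i].copy() for i in range(k)]
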