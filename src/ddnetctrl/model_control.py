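"""Model-based point-to-point optimal control baselines.

Solves, for a known LTI network system and zero initial state,

    min_u   y_mid' Q y_mid + u' R u    s.t.   y(T) = y_f,

with Q >= 0 penalizing the intermediate outputs y(1..T-1) (stacked forward)
and R > 0 penalizing the stacked input (reverse time).  The batch closed form
is

    u* = (I - K (M K)^+ M) C_T^+ y_f,

where C_T is the T-step output controllability matrix, K an orthonormal basis
of its kernel, and M any factor with M'M = H_T' Q H_T + R.  With Q = 0 and
R = I this reduces to the minimum-norm solution C_T^+ y_f, which for an
output-controllable system coincides with the classic Gramian-based
minimum-energy input

    u*(t) = B' (A')^{T-t-1} C' W_T^{-1} y_f.

(The latter formula is often quoted without the transpose on A, which is only
correct for symmetric A; the transposed form is the general minimizer.)

An independent brute-force QP solver, kept free of the closed-form code
paths, is provided as a test oracle.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from ._linalg import (DEFAULT_PINV_TOL, kernel_basis, pinv, psd_sqrt,
                      range_residual)
from .datagen import stack_input, unstack_input
from .systems import (LinearNetworkSystem, hankel_output_matrix,
                      output_ctrb_matrix, output_gramian, simulate_lti)


def _is_diagonal(M: np.ndarray) -> bool:
    return np.count_nonzero(M - np.diag(np.diagonal(M))) == 0


def _min_eig(M: np.ndarray) -> float:
    """Smallest eigenvalue of a symmetric matrix; O(n) for diagonal ones."""
    if _is_diagonal(M):
        return float(np.min(np.diagonal(M)))
    return float(np.linalg.eigvalsh(0.5 * (M + M.T))[0])


def _max_eig(M: np.ndarray) -> float:
    if _is_diagonal(M):
        return float(np.max(np.abs(np.diagonal(M))))
    w = np.linalg.eigvalsh(0.5 * (M + M.T))
    return float(max(abs(w[0]), abs(w[-1])))


class InfeasibleTargetError(ValueError):
    """The target output is not reachable (not in the relevant range space)."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (relative residual {residual:.3e})")
        self.residual = residual


@dataclass
class ControlProblem:
    """Target, horizon and quadratic weights of the point-to-point problem."""

    y_f: np.ndarray
    T: int
    Q: np.ndarray   # p(T-1) x p(T-1), PSD
    R: np.ndarray   # mT x mT, PD

    def __post_init__(self) -> None:
        self.y_f = np.asarray(self.y_f, dtype=float).ravel()
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if self.T < 1:
            raise ValueError("horizon T must be >= 1")
        if self.Q.size and _min_eig(self.Q) < -1e-10 * max(_max_eig(self.Q),
                                                           1.0):
            raise ValueError("Q must be positive semidefinite")
        if _min_eig(self.R) <= 0:
            raise ValueError("R must be positive definite")

    @classmethod
    def from_weights(cls, y_f: np.ndarray, T: int, m: int,
                     q: float = 0.0, r: float = 1.0) -> "ControlProblem":
        """Scalar-weight convenience constructor: Q = q I, R = r I."""
        y_f = np.asarray(y_f, dtype=float).ravel()
        p = y_f.size
        # q = 0 means no intermediate-output penalty at all; an empty Q
        # avoids materializing the (possibly huge) p(T-1) zero matrix
        Q = q * np.eye(p * (T - 1)) if (T > 1 and q != 0.0) \
            else np.zeros((0, 0))
        return cls(y_f=y_f, T=T, Q=Q, R=r * np.eye(m * T))


@dataclass
class ControlSolution:
    """A designed control input and, when evaluated, its realized performance.

    ``stacked`` follows the reverse-time stacking convention; ``per_step`` is
    the (T, m) unstacked sequence.  ``realized_error`` and ``realized_cost``
    are obtained by actually simulating the system (never by formula
    shortcuts) and are None when no system was supplied for evaluation.
    """

    stacked: np.ndarray
    per_step: np.ndarray
    realized_error: float | None = None
    realized_cost: float | None = None
    y_final: np.ndarray | None = None
    method: str = ""

    @property
    def energy(self) -> float:
        """Squared Euclidean norm of the stacked input."""
        return float(self.stacked @ self.stacked)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "per_step": self.per_step.tolist(),
            "realized_error": self.realized_error,
            "realized_cost": self.realized_cost,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            m = self.per_step.shape[1]
            writer.writerow(["t"] + [f"u{j}" for j in range(m)])
            for t, row in enumerate(self.per_step):
                writer.writerow([t] + list(row))


@dataclass
class CostFactorization:
    """Square-root factor M of the input-space Gram matrix and the kernel
    basis K of the terminal constraint matrix."""

    M: np.ndarray
    K: np.ndarray


def _finalize(stacked: np.ndarray, m: int, T: int,
              sys: LinearNetworkSystem | None,
              prob: ControlProblem | None,
              method: str) -> ControlSolution:
    per_step = unstack_input(stacked, m, T)
    sol = ControlSolution(stacked=stacked, per_step=per_step, method=method)
    if sys is not None and prob is not None:
        cost, err, y_final = _evaluate(sys, per_step, prob)
        sol.realized_cost = cost
        sol.realized_error = err
        sol.y_final = y_final
    return sol


def _evaluate(sys: LinearNetworkSystem, per_step: np.ndarray,
              prob: ControlProblem) -> tuple[float, float, np.ndarray]:
    traj = simulate_lti(sys, per_step)
    y_mid = traj.outputs[1:prob.T].reshape(-1)
    u = stack_input(per_step)
    cost = float(u @ prob.R @ u)
    if prob.Q.size and y_mid.size:
        cost += float(y_mid @ prob.Q @ y_mid)
    y_final = traj.outputs[prob.T]
    err = float(np.linalg.norm(prob.y_f - y_final))
    return cost, err, y_final


def evaluate_cost(sys: LinearNetworkSystem, per_step: np.ndarray,
                  prob: ControlProblem) -> tuple[float, float]:
    """Objective value and final-state error of an input, by simulation."""
    cost, err, _ = _evaluate(sys, np.asarray(per_step, dtype=float), prob)
    return cost, err


def cost_factorization(sys: LinearNetworkSystem,
                       prob: ControlProblem,
                       tol: float = DEFAULT_PINV_TOL) -> CostFactorization:
    """M with M'M = H_T' Q H_T + R, and the kernel basis of C_T."""
    H = hankel_output_matrix(sys, prob.T)
    G = prob.R.copy()
    if prob.Q.size and H.size:
        G = G + H.T @ prob.Q @ H
    CT = output_ctrb_matrix(sys, prob.T)
    return CostFactorization(M=psd_sqrt(G), K=kernel_basis(CT, tol))


def optimal_control_model_based(sys: LinearNetworkSystem,
                                prob: ControlProblem,
                                tol: float = DEFAULT_PINV_TOL,
                                feas_tol: float = 1e-6) -> ControlSolution:
    """Batch closed-form solution of the constrained quadratic problem."""
    CT = output_ctrb_matrix(sys, prob.T)
    ynorm = max(np.linalg.norm(prob.y_f), 1.0)
    res = range_residual(CT, prob.y_f, tol) / ynorm
    if res > feas_tol:
        raise InfeasibleTargetError(
            "target y_f is outside the range of the output controllability "
            "matrix", res)
    fac = cost_factorization(sys, prob, tol)
    base = pinv(CT, tol) @ prob.y_f
    if fac.K.shape[1] == 0:
        stacked = base
    else:
        stacked = base - fac.K @ (pinv(fac.M @ fac.K, tol) @ (fac.M @ base))
    return _finalize(stacked, sys.m, prob.T, sys, prob, "model_optimal")


def min_energy_gramian(sys: LinearNetworkSystem, y_f: np.ndarray, T: int,
                       cond_max: float = 1e14,
                       evaluate: bool = True) -> ControlSolution:
    """Classic Gramian-based minimum-energy control.

    Requires the output Gramian W_T to be invertible (output controllability
    in T steps).  Known to be numerically fragile when W_T is
    ill-conditioned; that fragility is precisely what the data-driven
    expressions avoid, so no regularization is applied here.
    """
    y_f = np.asarray(y_f, dtype=float).ravel()
    W = output_gramian(sys, T)
    s = np.linalg.svd(W, compute_uv=False)
    if s[-1] <= 0 or s[0] / max(s[-1], np.finfo(float).tiny) > cond_max:
        raise np.linalg.LinAlgError(
            "output Gramian is singular (system not output controllable in "
            f"{T} steps): sigma_min = {s[-1]:.3e}")
    z = sys.C.T @ np.linalg.solve(W, y_f)
    per_step = np.empty((T, sys.m))
    for t in range(T - 1, -1, -1):   # exponent T-t-1 grows as t decreases
        per_step[t] = sys.B.T @ z
        z = sys.A.T @ z
    prob = ControlProblem.from_weights(y_f, T, sys.m)
    sol = ControlSolution(stacked=stack_input(per_step), per_step=per_step,
                          method="gramian_min_energy")
    if evaluate:
        cost, err, y_final = _evaluate(sys, per_step, prob)
        sol.realized_cost, sol.realized_error, sol.y_final = cost, err, y_final
    return sol


def brute_force_qp_oracle(sys: LinearNetworkSystem, prob: ControlProblem,
                          feas_tol: float = 1e-6) -> np.ndarray:
    """Independent dense QP solve of the same problem, for testing.

    Parametrizes the feasible set as ``u = u_p + Z z`` with ``u_p`` a
    least-squares particular solution of ``C_T u = y_f`` and ``Z`` the
    nullspace of C_T (from :func:`scipy.linalg.null_space`), then solves the
    reduced normal equations.  Deliberately shares no code with the batch
    closed form above.
    """
    CT = output_ctrb_matrix(sys, prob.T)
    if CT.shape[1] > 200:
        raise ValueError("oracle is restricted to small instances (mT <= 200)")
    u_p, *_ = np.linalg.lstsq(CT, prob.y_f, rcond=None)
    res = np.linalg.norm(CT @ u_p - prob.y_f) / max(np.linalg.norm(prob.y_f), 1.0)
    if res > feas_tol:
        raise InfeasibleTargetError("target y_f is not reachable", res)
    H = hankel_output_matrix(sys, prob.T)
    G = prob.R.copy()
    if prob.Q.size and H.size:
        G = G + H.T @ prob.Q @ H
    Z = scipy.linalg.null_space(CT)
    if Z.shape[1] == 0:
        return u_p
    z, *_ = np.linalg.lstsq(Z.T @ G @ Z, -Z.T @ G @ u_p, rcond=None)
    return u_p + Z @ z
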