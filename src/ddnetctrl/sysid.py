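"""Deterministic subspace identification baseline.

The classic two-step (identify-then-control) pipeline against which the
direct data-driven expressions are compared.  With full state measurements
(C = I), the controllability matrix is estimated by least squares,

    C_hat = argmin || Y_T - C_T U ||_F  =  Y_T U^+,

B is read off as the first m columns of C_hat, and A from the shift
invariance of the block structure [B, AB, ..., A^{T-1} B]:

    A_hat = C_hat[:, m:mT] @ pinv(C_hat[:, :(T-1)m]).

(Block columns are 0-based half-open ranges here; the classical statement of
the slicing is 1-based.)  On noiseless data from a system controllable in
T-1 steps with full-row-rank U this recovers A and B exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import mmwrite

from ._linalg import DEFAULT_PINV_TOL, numerical_rank, pinv
from .datagen import DataMatrices
from .model_control import ControlSolution, min_energy_gramian, _evaluate, \
    ControlProblem
from .systems import LinearNetworkSystem


class RankDeficientDataWarning(UserWarning):
    """U lacks full row rank; identified estimates are not guaranteed."""


@dataclass
class IdentifiedModel:
    A_hat: np.ndarray
    B_hat: np.ndarray
    #: Frobenius residuals of the two least-squares fits (C_hat fit, shift fit)
    residuals: tuple[float, float]

    @property
    def n(self) -> int:
        return self.A_hat.shape[0]

    @property
    def m(self) -> int:
        return self.B_hat.shape[1]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix) + "_A.mtx", self.A_hat)
        mmwrite(str(prefix) + "_B.mtx", self.B_hat)
        with open(str(prefix) + "_residuals.json", "w") as fh:
            json.dump({"fit_residual": self.residuals[0],
                       "shift_residual": self.residuals[1]}, fh, indent=2)


def subspace_identify(data: DataMatrices, n: int | None = None,
                      ridge: float = 0.0,
                      tol: float = DEFAULT_PINV_TOL) -> IdentifiedModel:
    """Estimate (A, B) from episodic data with full state measurement.

    Requires p = n, i.e. every node measured (C = I); with hidden nodes the
    network matrix is not identifiable from data.  Pass the state dimension
    ``n`` to have this checked.  ``ridge`` adds Tikhonov regularization to
    both regressions (off by default; the deterministic method is exact on
    noiseless data).
    """
    if data.T < 2:
        raise ValueError("identification needs a horizon T >= 2")
    if n is not None and data.p != n:
        raise ValueError(
            f"subspace identification requires full state measurement "
            f"(p = n); got p = {data.p}, n = {n}")
    if numerical_rank(data.U, tol) < data.m * data.T:
        warnings.warn(
            "input data matrix does not have full row rank; identified "
            "estimates are not guaranteed to be correct",
            RankDeficientDataWarning, stacklevel=2)

    def _solve(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
        # argmin ||Y - M X||_F (+ ridge ||M||_F): M = Y X'(X X' + ridge I)^-1
        if ridge > 0:
            return Y @ X.T @ np.linalg.inv(
                X @ X.T + ridge * np.eye(X.shape[0]))
        return Y @ pinv(X, tol)

    C_hat = _solve(data.Y_T, data.U)
    m, T = data.m, data.T
    B_hat = C_hat[:, :m].copy()
    A_hat = _solve(C_hat[:, m:m * T], C_hat[:, :(T - 1) * m])
    res_fit = float(np.linalg.norm(data.Y_T - C_hat @ data.U, "fro"))
    res_shift = float(np.linalg.norm(
        C_hat[:, m:m * T] - A_hat @ C_hat[:, :(T - 1) * m], "fro"))
    return IdentifiedModel(A_hat=A_hat, B_hat=B_hat,
                           residuals=(res_fit, res_shift))


def identify_then_control(data: DataMatrices, y_f: np.ndarray,
                          T: int | None = None,
                          true_system: LinearNetworkSystem | None = None,
                          ridge: float = 0.0,
                          tol: float = DEFAULT_PINV_TOL) -> ControlSolution:
    """Two-step baseline: identify (A, B), then Gramian minimum-energy control.

    The control is designed on the identified model; when the true system is
    supplied, the realized error and cost are evaluated by simulating the
    *true* dynamics with the designed input.
    """
    model = subspace_identify(data, n=None if true_system is None
                              else true_system.n, ridge=ridge, tol=tol)
    ident_sys = LinearNetworkSystem(model.A_hat, model.B_hat,
                                    np.eye(model.n))
    T = data.T if T is None else T
    sol = min_energy_gramian(ident_sys, y_f, T, evaluate=False)
    sol.method = "identify_then_control"
    if true_system is not None:
        prob = ControlProblem.from_weights(np.asarray(y_f, float).ravel(),
                                           T, true_system.m)
        cost, err, y_final = _evaluate(true_system, sol.per_step, prob)
        sol.realized_cost, sol.realized_error, sol.y_final = cost, err, y_final
    return sol
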