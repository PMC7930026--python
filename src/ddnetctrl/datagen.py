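"""Episodic control experiments and the data matrices they produce.

An episodic experiment resets the network state to zero, applies a T-step
input sequence, and records the resulting outputs.  N such experiments form
three data matrices, one column per episode:

    U      (mT x N)       stacked inputs, reverse time: [u(T-1); ...; u(0)]
    Y_mid  (p(T-1) x N)   intermediate outputs, forward: [y(1); ...; y(T-1)]
    Y_T    (p x N)        final outputs y(T)

For noiseless data generated from a known system, ``Y_T = C_T U`` and
``Y_mid = H_T U`` hold exactly (up to round-off), which is the algebraic
backbone of every data-driven control expression in :mod:`ddnetctrl.ddcontrol`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.io import mmread, mmwrite

from .systems import LinearNetworkSystem


def stack_input(u: np.ndarray) -> np.ndarray:
    """Stack a (T, m) input sequence in reverse time order: u(T-1) first."""
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    return u[::-1].reshape(-1)


def unstack_input(v: np.ndarray, m: int, T: int) -> np.ndarray:
    """Exact inverse of :func:`stack_input`; returns shape (T, m)."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size != m * T:
        raise ValueError(f"stacked vector has length {v.size}, expected {m * T}")
    return v.reshape(T, m)[::-1].copy()


def stack_outputs(y_mid: np.ndarray) -> np.ndarray:
    """Stack intermediate outputs y(1..T-1) in forward time order."""
    return np.asarray(y_mid, dtype=float).reshape(-1)


@dataclass
class DataMatrices:
    """The (U, Y_mid, Y_T) record of N episodic experiments."""

    U: np.ndarray
    Y_mid: np.ndarray
    Y_T: np.ndarray
    T: int
    m: int
    p: int
    #: when produced by :func:`add_noise`, the noiseless original
    ground_truth: "DataMatrices | None" = None

    def __post_init__(self) -> None:
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        self.Y_mid = np.asarray(self.Y_mid, dtype=float)
        self.Y_T = np.atleast_2d(np.asarray(self.Y_T, dtype=float))
        if self.Y_mid.ndim == 1:
            self.Y_mid = self.Y_mid.reshape(0, self.U.shape[1]) \
                if self.Y_mid.size == 0 else np.atleast_2d(self.Y_mid)
        N = self.U.shape[1]
        if self.Y_T.shape[1] != N or (self.T > 1 and self.Y_mid.shape[1] != N):
            raise ValueError("column counts (episodes) differ between matrices")
        if self.U.shape[0] != self.m * self.T:
            raise ValueError("U must have m*T rows")
        if self.Y_T.shape[0] != self.p:
            raise ValueError("Y_T must have p rows")
        if self.Y_mid.shape[0] != self.p * (self.T - 1):
            raise ValueError("Y_mid must have p*(T-1) rows")

    @property
    def N(self) -> int:
        return self.U.shape[1]

    def save(self, prefix: str | Path, meta: dict | None = None) -> None:
        """Write U/Y_mid/Y_T as Matrix Market files plus a JSON sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix) + "_U.mtx", self.U)
        mmwrite(str(prefix) + "_Ymid.mtx",
                self.Y_mid if self.Y_mid.size else np.zeros((0, self.N)))
        mmwrite(str(prefix) + "_YT.mtx", self.Y_T)
        sidecar = {"T": self.T, "m": self.m, "p": self.p, "N": self.N}
        if meta:
            sidecar.update(meta)
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, prefix: str | Path) -> "DataMatrices":
        prefix = Path(prefix)
        with open(str(prefix) + ".json") as fh:
            meta = json.load(fh)

        def _read(suffix: str) -> np.ndarray:
            M = mmread(str(prefix) + suffix)
            if hasattr(M, "todense"):
                M = M.todense()
            return np.asarray(M, dtype=float)

        return cls(U=_read("_U.mtx"), Y_mid=_read("_Ymid.mtx"),
                   Y_T=_read("_YT.mtx"), T=int(meta["T"]), m=int(meta["m"]),
                   p=int(meta["p"]))


@dataclass
class NoiseSpec:
    """Standard deviations of the additive i.i.d. zero-mean measurement noise
    on the three data matrices."""

    sigma_U: float = 0.0
    sigma_Y: float = 0.0
    sigma_YT: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_U, self.sigma_Y, self.sigma_YT) < 0:
            raise ValueError("noise standard deviations must be nonnegative")


def run_episodic_experiments(sys: LinearNetworkSystem, T: int, N: int,
                             input_std: float = 1.0,
                             seed: int = 0) -> DataMatrices:
    """Run N episodic experiments with i.i.d. Gaussian inputs.

    Each episode starts from ``x(0) = 0``; inputs have i.i.d. zero-mean
    Gaussian entries with standard deviation ``input_std`` (default: standard
    normal).  All episodes are propagated in parallel as one matrix
    recursion, so the cost is T dense products of A with an (n, N) state
    block.
    """
    if N < 1 or T < 1:
        raise ValueError("need N >= 1 episodes of T >= 1 steps")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((T, sys.m, N)) * input_std   # u[t, :, i]
    X = np.zeros((sys.n, N))
    Y_mid = np.empty((sys.p * (T - 1), N))
    for t in range(T):
        X = sys.A @ X + sys.B @ u[t]
        if t < T - 1:
            Y_mid[t * sys.p:(t + 1) * sys.p] = sys.C @ X
    Y_T = sys.C @ X
    U = u[::-1].reshape(T * sys.m, N)
    return DataMatrices(U=U, Y_mid=Y_mid, Y_T=Y_T, T=T, m=sys.m, p=sys.p)


def add_noise(data: DataMatrices, spec: NoiseSpec, seed: int = 0,
              distribution: Callable[[np.random.Generator, tuple[int, ...]],
                                     np.ndarray] | None = None) -> DataMatrices:
    """Perturb the data matrices with independent zero-mean i.i.d. noise.

    Gaussian by default; any zero-mean unit-variance sampler can be plugged
    in via ``distribution(rng, shape)`` (the theory only needs zero mean and
    finite variance).  The noiseless input is kept on the returned object's
    ``ground_truth`` attribute for downstream evaluation.
    """
    rng = np.random.default_rng(seed)
    draw = distribution or (lambda r, shape: r.standard_normal(shape))
    return DataMatrices(
        U=data.U + spec.sigma_U * draw(rng, data.U.shape),
        Y_mid=data.Y_mid + (spec.sigma_Y * draw(rng, data.Y_mid.shape)
                            if data.Y_mid.size else 0.0),
        Y_T=data.Y_T + spec.sigma_YT * draw(rng, data.Y_T.shape),
        T=data.T, m=data.m, p=data.p, ground_truth=data)


def sliding_window_matrices(u_series: np.ndarray, y_series: np.ndarray,
                            T: int,
                            window_starts: Sequence[int]) -> DataMatrices:
    """Build data matrices by sliding a length-T window over one long record.

    ``u_series`` is (L, m) and ``y_series`` (L+1, p) with ``y_series[t]``
    the output at time t.  Each window starting at ``s`` is treated as one
    episode: inputs ``u(s..s+T-1)``, outputs ``y(s+1..s+T)``.  The state at
    the window start is *assumed zero*; for windows cut from the middle of an
    ongoing trajectory this is an approximation, exact only when the
    pre-window signal is zero (or has died out).
    """
    u_series = np.asarray(u_series, dtype=float)
    y_series = np.asarray(y_series, dtype=float)
    if u_series.ndim == 1:
        u_series = u_series[:, None]
    if y_series.ndim == 1:
        y_series = y_series[:, None]
    m, p = u_series.shape[1], y_series.shape[1]
    cols_U, cols_mid, cols_T = [], [], []
    for s in window_starts:
        if s < 0 or s + T > u_series.shape[0] or s + T > y_series.shape[0] - 1:
            raise ValueError(f"window [{s}, {s + T}) out of range")
        cols_U.append(stack_input(u_series[s:s + T]))
        cols_mid.append(y_series[s + 1:s + T].reshape(-1))
        cols_T.append(y_series[s + T])
    return DataMatrices(
        U=np.column_stack(cols_U),
        Y_mid=(np.column_stack(cols_mid) if T > 1
               else np.zeros((0, len(cols_U)))),
        Y_T=np.column_stack(cols_T), T=T, m=m, p=p)
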