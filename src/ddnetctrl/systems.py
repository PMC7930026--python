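"""Linear network systems, random-graph generation, and controllability objects.

A network is a discrete-time linear time-invariant (LTI) system

    x(t+1) = A x(t) + B u(t),      y(t) = C x(t),

where ``A`` (n x n) is the weighted adjacency matrix, ``B`` (n x m) selects the
input (driver) nodes and ``C`` (p x n) the output (measured) nodes.  The module
also provides the model-side controllability objects: the T-step output
controllability matrix ``C_T = [CB, CAB, ..., C A^{T-1} B]``, the block
lower-anti-triangular map ``H_T`` from the stacked input to the intermediate
outputs ``y(1..T-1)``, and the output controllability Gramian
``W_T = C_T C_T^T``.

Stacking convention (shared with :mod:`ddnetctrl.datagen`): inputs are stacked
in *reverse* time order, ``[u(T-1); ...; u(0)]``, so that ``y(T) = C_T @
stacked`` from a zero initial state; outputs are stacked forward,
``[y(1); ...; y(T-1)]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.io import mmread, mmwrite


@dataclass
class LinearNetworkSystem:
    """The (A, B, C) triple defining the network dynamics."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.B.ndim == 1:
            self.B = self.B[:, None]
        if self.C.ndim == 1:
            self.C = self.C[None, :]
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.B.shape[0] != n:
            raise ValueError(f"B has {self.B.shape[0]} rows, expected {n}")
        if self.C.shape[1] != n:
            raise ValueError(f"C has {self.C.shape[1]} columns, expected {n}")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @property
    def p(self) -> int:
        return self.C.shape[0]

    @classmethod
    def from_node_selection(cls, A: np.ndarray,
                            input_nodes: Sequence[int],
                            output_nodes: Sequence[int]) -> "LinearNetworkSystem":
        """Build B and C as 0/1 node-selection matrices from index sets."""
        A = np.atleast_2d(np.asarray(A, dtype=float))
        n = A.shape[0]
        B = np.zeros((n, len(input_nodes)))
        for j, node in enumerate(input_nodes):
            B[node, j] = 1.0
        C = np.zeros((len(output_nodes), n))
        for i, node in enumerate(output_nodes):
            C[i, node] = 1.0
        return cls(A, B, C)


@dataclass
class GraphSpec:
    """Parameters of a random-graph draw.

    ``model`` is one of ``erdos_renyi``, ``barabasi_albert``,
    ``watts_strogatz``.  For Erdos-Renyi either give ``p_edge`` directly or an
    offset ``eps`` meaning ``p_edge = ln(n)/n + eps`` (the connectivity
    threshold plus a margin).  ``normalization`` rescales the adjacency:
    ``sqrt_n`` divides by sqrt(n), ``matrix_norm`` by the spectral 2-norm
    (``frobenius_norm`` by the Frobenius norm).
    """

    model: str
    n: int
    p_edge: float | None = None
    eps: float | None = None
    m0: int = 20
    k_avg: int | None = None
    p_rew: float | None = None
    normalization: str = "none"
    seed: int = 0
    require_connected: bool = True
    max_tries: int = 1000

    def resolved_p_edge(self) -> float:
        if self.p_edge is not None:
            return float(self.p_edge)
        if self.eps is not None:
            return float(np.log(self.n) / self.n + self.eps)
        raise ValueError("Erdos-Renyi spec needs p_edge or eps")

    def __post_init__(self) -> None:
        if self.model not in ("erdos_renyi", "barabasi_albert", "watts_strogatz"):
            raise ValueError(f"unknown graph model {self.model!r}")
        if self.p_edge is not None and not 0.0 <= self.p_edge <= 1.0:
            raise ValueError("p_edge must lie in [0, 1]")
        if self.p_rew is not None and not 0.0 <= self.p_rew <= 1.0:
            raise ValueError("p_rew must lie in [0, 1]")
        if self.model == "watts_strogatz":
            if self.k_avg is None or self.k_avg % 2 != 0:
                raise ValueError("watts_strogatz requires an even k_avg")


@dataclass
class Trajectory:
    """States x(0..T), outputs y(0..T) and inputs u(0..T-1) of one run."""

    states: np.ndarray    # (T+1, n)
    outputs: np.ndarray   # (T+1, p)
    inputs: np.ndarray    # (T, m)

    @property
    def T(self) -> int:
        return self.inputs.shape[0]


def _normalize(A: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "none":
        return A
    if normalization == "sqrt_n":
        return A / np.sqrt(A.shape[0])
    if normalization == "matrix_norm":
        nrm = np.linalg.norm(A, 2)
        return A / nrm if nrm > 0 else A
    if normalization == "frobenius_norm":
        nrm = np.linalg.norm(A, "fro")
        return A / nrm if nrm > 0 else A
    raise ValueError(f"unknown normalization {normalization!r}")


def generate_graph(spec: GraphSpec) -> np.ndarray:
    """Draw a symmetric 0/1 adjacency matrix according to ``spec``.

    Erdos-Renyi and Watts-Strogatz draws are regenerated (consuming fresh
    sub-seeds from the seeded stream) until the graph is connected, up to
    ``spec.max_tries`` attempts.  Barabasi-Albert graphs are connected by
    construction: preferential attachment with ``k_avg/2`` edges per new node,
    grown from a complete graph on ``m0`` seed nodes.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.model == "barabasi_albert":
        if spec.k_avg is None:
            raise ValueError("barabasi_albert requires k_avg")
        m_attach = max(1, spec.k_avg // 2)
        G = nx.barabasi_albert_graph(
            spec.n, m_attach, seed=int(rng.integers(2**31)),
            initial_graph=nx.complete_graph(min(spec.m0, spec.n)))
        A = nx.to_numpy_array(G, nodelist=range(spec.n))
        return _normalize(A, spec.normalization)

    for _ in range(spec.max_tries):
        sub = int(rng.integers(2**31))
        if spec.model == "erdos_renyi":
            G = nx.gnp_random_graph(spec.n, spec.resolved_p_edge(), seed=sub)
        else:  # watts_strogatz
            G = nx.watts_strogatz_graph(spec.n, spec.k_avg, spec.p_rew, seed=sub)
        if not spec.require_connected or nx.is_connected(G):
            A = nx.to_numpy_array(G, nodelist=range(spec.n))
            return _normalize(A, spec.normalization)
    raise RuntimeError(
        f"no connected graph found in {spec.max_tries} attempts for {spec}")


def select_io_nodes(A: np.ndarray, m: int, p: int, T: int,
                    seed: int = 0, sigma_min: float = 1e-10,
                    max_tries: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random distinct input/output node sets, resampled until the
    resulting output controllability matrix is well posed.

    Candidate sets are rejected until the smallest singular value of the
    T-step output controllability matrix is at least ``sigma_min``
    (default 1e-10), guaranteeing output controllability of the sampled
    system.  Returns the 0/1 selection matrices ``(B, C)``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    if m > n or p > n:
        raise ValueError("m and p cannot exceed the number of nodes")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        inp = rng.choice(n, size=m, replace=False)
        out = rng.choice(n, size=p, replace=False)
        sys = LinearNetworkSystem.from_node_selection(A, inp, out)
        CT = output_ctrb_matrix(sys, T)
        s = np.linalg.svd(CT, compute_uv=False)
        if s.size >= p and s[min(p, s.size) - 1] >= sigma_min:
            return sys.B, sys.C
    raise RuntimeError(
        f"no output-controllable node selection found in {max_tries} tries "
        f"(m={m}, p={p}, T={T}); try larger m or T")


def simulate_lti(sys: LinearNetworkSystem, inputs: np.ndarray,
                 x0: np.ndarray | None = None) -> Trajectory:
    """Exact forward recursion of the network dynamics."""
    u = np.asarray(inputs, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    T = u.shape[0]
    if T < 1:
        raise ValueError("need at least one input step")
    if u.shape[1] != sys.m:
        raise ValueError(f"inputs have {u.shape[1]} channels, expected {sys.m}")
    x = np.zeros(sys.n) if x0 is None else np.asarray(x0, dtype=float).ravel()
    if x.shape[0] != sys.n:
        raise ValueError("x0 has wrong dimension")
    states = np.empty((T + 1, sys.n))
    states[0] = x
    for t in range(T):
        states[t + 1] = sys.A @ states[t] + sys.B @ u[t]
    outputs = states @ sys.C.T
    return Trajectory(states=states, outputs=outputs, inputs=u)


def output_ctrb_matrix(sys: LinearNetworkSystem, T: int) -> np.ndarray:
    """T-step output controllability matrix ``[CB, CAB, ..., C A^{T-1} B]``.

    Maps the reverse-time-stacked input to ``y(T)`` from ``x(0) = 0``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    blocks = np.empty((T, sys.p, sys.m))
    CAk = sys.C.copy()
    for k in range(T):
        blocks[k] = CAk @ sys.B
        if k < T - 1:
            CAk = CAk @ sys.A
    return blocks.transpose(1, 0, 2).reshape(sys.p, T * sys.m)


def hankel_output_matrix(sys: LinearNetworkSystem, T: int) -> np.ndarray:
    """Map from the stacked input to the intermediate outputs y(1..T-1).

    Row block ``t`` (for ``y(t)``, t = 1..T-1) is
    ``[0 ... 0, CB, CAB, ..., C A^{t-1} B]`` with ``T - t`` leading p x m zero
    blocks, consistent with the reverse-time input stacking.  For ``T = 1``
    there are no intermediate outputs and an empty ``(0, m)`` matrix is
    returned.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    m, p = sys.m, sys.p
    H = np.zeros((p * (T - 1), m * T))
    markov = np.empty((T - 1, p, m))  # markov[k] = C A^k B
    CAk = sys.C.copy()
    for k in range(T - 1):
        markov[k] = CAk @ sys.B
        CAk = CAk @ sys.A
    for t in range(1, T):
        # block column T - t + k holds u(t - 1 - k), whose coefficient in
        # y(t) is the Markov parameter C A^k B
        for k in range(t):
            H[(t - 1) * p:t * p, (T - t + k) * m:(T - t + k + 1) * m] = markov[k]
    return H


def output_gramian(sys: LinearNetworkSystem, T: int) -> np.ndarray:
    """T-step output controllability Gramian ``W_T = C_T C_T^T`` (p x p).

    Symmetric PSD; invertible exactly when the system is output controllable
    in ``T`` steps.
    """
    CT = output_ctrb_matrix(sys, T)
    W = CT @ CT.T
    return 0.5 * (W + W.T)


# ---------------------------------------------------------------------------
# Adjacency and node-set I/O
# ---------------------------------------------------------------------------

def load_adjacency(path: str | Path, n: int | None = None) -> np.ndarray:
    """Load an adjacency matrix from .mtx, a TSV edge list, or dense text.

    Edge lists are 0-based, one edge per line ``i<TAB>j[<TAB>w]``; without an
    explicit node count ``n`` the matrix size is ``max index + 1``.  Edge-list
    input is taken as directed (entry A[i, j] = w); symmetric matrices simply
    list both directions or are symmetrized by the caller.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        M = mmread(path)
        if hasattr(M, "todense"):
            M = M.todense()
        return np.asarray(M, dtype=float)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith(("#", "%")):
                rows.append(line.split())
    widths = {len(r) for r in rows}
    if widths <= {2, 3} and len(rows) > 0:
        # edge list
        size = n if n is not None else (
            max(max(int(r[0]), int(r[1])) for r in rows) + 1)
        A = np.zeros((size, size))
        for r in rows:
            w = float(r[2]) if len(r) == 3 else 1.0
            A[int(r[0]), int(r[1])] = w
        return A
    return np.asarray([[float(v) for v in r] for r in rows])


def save_adjacency(path: str | Path, A: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, np.asarray(A, dtype=float))
    else:
        np.savetxt(path, A)


def load_node_set(path: str | Path) -> list[int]:
    """JSON array of 0-based node indices."""
    with open(path) as fh:
        data = json.load(fh)
    return [int(v) for v in data]


def save_node_set(path: str | Path, nodes: Sequence[int]) -> None:
    with open(path, "w") as fh:
        json.dump([int(v) for v in nodes], fh)
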