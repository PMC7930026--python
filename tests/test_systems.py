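"""Tests for network systems, graph generation, and controllability objects."""

import numpy as np
import networkx as nx
import pytest

from ddnetctrl import (GraphSpec, LinearNetworkSystem, Trajectory,
                       generate_graph, hankel_output_matrix, load_adjacency,
                       load_node_set, output_ctrb_matrix, output_gramian,
                       save_adjacency, save_node_set, select_io_nodes,
                       simulate_lti)
from ddnetctrl.datagen import stack_input

from conftest import make_random_system


# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------

def test_er_p1_is_complete_graph():
    A = generate_graph(GraphSpec("erdos_renyi", 5, p_edge=1.0, seed=0))
    assert np.allclose(A, np.ones((5, 5)) - np.eye(5))


def test_er_sqrt_n_normalization():
    A = generate_graph(GraphSpec("erdos_renyi", 4, p_edge=1.0,
                                 normalization="sqrt_n", seed=0))
    assert np.allclose(A, (np.ones((4, 4)) - np.eye(4)) / 2.0)


def test_er_edge_count_matches_binomial_oracle():
    # mean edge count over many seeds versus the Binomial(n choose 2, p) mean
    n, p, reps = 200, 0.1, 300
    pairs = n * (n - 1) / 2
    counts = [generate_graph(GraphSpec("erdos_renyi", n, p_edge=p,
                                       seed=s)).sum() / 2
              for s in range(reps)]
    se_mean = np.sqrt(pairs * p * (1 - p) / reps)
    assert abs(np.mean(counts) - pairs * p) < 3 * se_mean


def test_er_connectivity_retry():
    # p well below the connectivity threshold but positive: the generator
    # must keep retrying and still return a connected graph
    A = generate_graph(GraphSpec("erdos_renyi", 30, p_edge=0.13, seed=5))
    assert nx.is_connected(nx.from_numpy_array(A))


def test_er_symmetric_zero_diagonal():
    A = generate_graph(GraphSpec("erdos_renyi", 50, eps=0.05, seed=1))
    assert np.allclose(A, A.T)
    assert np.all(np.diag(A) == 0)
    assert set(np.unique(A)) <= {0.0, 1.0}


def test_watts_strogatz_degree_and_connectivity():
    A = generate_graph(GraphSpec("watts_strogatz", 60, k_avg=6, p_rew=0.0,
                                 seed=0))
    # without rewiring every node has exactly k_avg neighbours
    assert np.all(A.sum(axis=0) == 6)
    assert nx.is_connected(nx.from_numpy_array(A))


def test_watts_strogatz_rejects_odd_k():
    with pytest.raises(ValueError):
        GraphSpec("watts_strogatz", 10, k_avg=3, p_rew=0.1)


def test_barabasi_albert_connected_and_sized():
    A = generate_graph(GraphSpec("barabasi_albert", 100, k_avg=10, m0=20,
                                 seed=0))
    G = nx.from_numpy_array(A)
    assert nx.is_connected(G)
    # m0 seed clique plus 5 edges per subsequent node
    expected_edges = 20 * 19 // 2 + (100 - 20) * 5
    assert G.number_of_edges() == expected_edges


def test_matrix_norm_normalization_unit_spectral_norm():
    A = generate_graph(GraphSpec("erdos_renyi", 40, eps=0.1,
                                 normalization="matrix_norm", seed=2))
    assert np.isclose(np.linalg.norm(A, 2), 1.0)


def test_generate_graph_reproducible():
    spec = GraphSpec("erdos_renyi", 30, eps=0.1, seed=7)
    assert np.array_equal(generate_graph(spec), generate_graph(spec))


def test_unknown_model_rejected():
    with pytest.raises(ValueError):
        GraphSpec("geometric", 10, p_edge=0.5)


# ---------------------------------------------------------------------------
# node selection
# ---------------------------------------------------------------------------

def test_select_io_nodes_identity_dynamics():
    # A = 0, T = 1, m = p = n: C_T = C B is a permutation-like product with
    # sigma_min = 1 whenever the same nodes are picked; full sets always work
    B, C = select_io_nodes(np.zeros((3, 3)), 3, 3, 1, seed=0)
    CT = C @ B
    assert np.linalg.matrix_rank(CT) == 3


def test_select_io_nodes_infeasible_raises():
    # A = 0 and T = 1: y(1) = C B u(0); with m = 1 input only one output
    # row can ever be nonzero, so p = 2 outputs are never controllable
    with pytest.raises(RuntimeError):
        select_io_nodes(np.zeros((4, 4)), 1, 2, 1, seed=0, max_tries=50)


def test_select_io_nodes_guarantees_sigma_min():
    A = generate_graph(GraphSpec("erdos_renyi", 30, eps=0.2,
                                 normalization="sqrt_n", seed=3))
    B, C = select_io_nodes(A, 4, 6, 10, seed=0, sigma_min=1e-6)
    CT = output_ctrb_matrix(LinearNetworkSystem(A, B, C), 10)
    assert np.linalg.svd(CT, compute_uv=False)[-1] >= 1e-6
    # B and C are 0/1 selection matrices with distinct nodes
    assert np.all(B.sum(axis=0) == 1) and np.all(B.sum(axis=1) <= 1)
    assert np.all(C.sum(axis=1) == 1) and np.all(C.sum(axis=0) <= 1)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def test_simulate_scalar_hand_computed():
    # x(t+1) = 2 x(t) + u(t), x(0)=1, u = (1, 1): x = 1, 3, 7
    sys = LinearNetworkSystem(np.array([[2.0]]), np.array([[1.0]]),
                              np.array([[1.0]]))
    traj = simulate_lti(sys, np.ones((2, 1)), x0=np.array([1.0]))
    assert np.allclose(traj.states.ravel(), [1.0, 3.0, 7.0])
    assert np.allclose(traj.outputs.ravel(), [1.0, 3.0, 7.0])
    assert traj.T == 2


def test_simulate_matches_unrolled_power_sum():
    # independent oracle: x(T) = A^T x0 + sum_k A^{T-1-k} B u(k)
    rng = np.random.default_rng(10)
    n, m, T = 6, 2, 8
    A = rng.standard_normal((n, n)) / np.sqrt(n)
    B = rng.standard_normal((n, m))
    C = rng.standard_normal((3, n))
    u = rng.standard_normal((T, m))
    x0 = rng.standard_normal(n)
    x = np.linalg.matrix_power(A, T) @ x0
    for k in range(T):
        x = x + np.linalg.matrix_power(A, T - 1 - k) @ B @ u[k]
    traj = simulate_lti(LinearNetworkSystem(A, B, C), u, x0=x0)
    assert np.allclose(traj.states[-1], x, atol=1e-10)
    assert np.allclose(traj.outputs[-1], C @ x, atol=1e-10)


def test_simulate_validates_shapes():
    sys = LinearNetworkSystem(np.zeros((2, 2)), np.eye(2), np.eye(2))
    with pytest.raises(ValueError):
        simulate_lti(sys, np.zeros((3, 1)))      # wrong input channels
    with pytest.raises(ValueError):
        simulate_lti(sys, np.zeros((0, 2)))      # no steps
    with pytest.raises(ValueError):
        simulate_lti(sys, np.zeros((3, 2)), x0=np.zeros(5))


# ---------------------------------------------------------------------------
# controllability objects
# ---------------------------------------------------------------------------

def test_output_ctrb_matrix_hand_example():
    # A = [[0,1],[0,0]], B = e1, C = I, T = 2:
    # C_T = [B, AB] = [[1, 0], [0, 0]]  (AB = 0 since B = e1 feeds node 0)
    A = np.array([[0.0, 1.0], [0.0, 0.0]])
    B = np.array([[1.0], [0.0]])
    sys = LinearNetworkSystem(A, B, np.eye(2))
    CT = output_ctrb_matrix(sys, 2)
    assert np.allclose(CT, [[1.0, 0.0], [0.0, 0.0]])


def test_output_ctrb_maps_stacked_input_to_final_output():
    for seed in range(20):
        sys = make_random_system(7, 2, 3, 5, seed=seed)
        rng = np.random.default_rng(100 + seed)
        u = rng.standard_normal((5, 2))
        traj = simulate_lti(sys, u)
        CT = output_ctrb_matrix(sys, 5)
        assert np.allclose(CT @ stack_input(u), traj.outputs[5], atol=1e-10)


def test_hankel_matrix_maps_stacked_input_to_intermediate_outputs():
    for seed in range(20):
        sys = make_random_system(6, 2, 2, 6, seed=seed)
        rng = np.random.default_rng(200 + seed)
        u = rng.standard_normal((6, 2))
        traj = simulate_lti(sys, u)
        H = hankel_output_matrix(sys, 6)
        assert np.allclose(H @ stack_input(u),
                           traj.outputs[1:6].reshape(-1), atol=1e-10)


def test_hankel_block_structure():
    sys = make_random_system(5, 2, 3, 4, seed=0)
    H = hankel_output_matrix(sys, 4)
    p, m, T = 3, 2, 4
    assert H.shape == (p * (T - 1), m * T)
    # row block t has T - t leading zero blocks
    for t in range(1, T):
        assert np.all(H[(t - 1) * p:t * p, :(T - t) * m] == 0)
    # the block adjacent to the zeros is C B for every row block
    CB = sys.C @ sys.B
    for t in range(1, T):
        blk = H[(t - 1) * p:t * p, (T - t) * m:(T - t + 1) * m]
        assert np.allclose(blk, CB, atol=1e-12)


def test_hankel_T1_empty():
    sys = make_random_system(4, 1, 2, 3, seed=1)
    assert hankel_output_matrix(sys, 1).shape == (0, 1)


def test_output_gramian_definition_and_psd():
    sys = make_random_system(6, 2, 3, 5, seed=2)
    CT = output_ctrb_matrix(sys, 5)
    W = output_gramian(sys, 5)
    assert np.allclose(W, CT @ CT.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(W) > 0)   # output controllable by fixture


def test_output_gramian_singular_when_uncontrollable():
    # one input, zero dynamics, two outputs: rank(C_T) = 1 < p
    sys = LinearNetworkSystem(np.zeros((3, 3)),
                              np.eye(3)[:, :1], np.eye(3)[:2])
    W = output_gramian(sys, 4)
    assert np.linalg.eigvalsh(W)[0] < 1e-12


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_adjacency_roundtrip_mtx_and_dense(tmp_path):
    A = generate_graph(GraphSpec("erdos_renyi", 12, eps=0.3, seed=0))
    save_adjacency(tmp_path / "a.mtx", A)
    assert np.allclose(load_adjacency(tmp_path / "a.mtx"), A)
    save_adjacency(tmp_path / "a.txt", A)
    assert np.allclose(load_adjacency(tmp_path / "a.txt"), A)


def test_adjacency_edge_list(tmp_path):
    path = tmp_path / "edges.tsv"
    path.write_text("# comment\n0\t1\t2.5\n1\t0\t2.5\n2\t0\n")
    A = load_adjacency(path)
    assert A.shape == (3, 3)
    assert A[0, 1] == 2.5 and A[1, 0] == 2.5 and A[2, 0] == 1.0
    A4 = load_adjacency(path, n=4)
    assert A4.shape == (4, 4)


def test_node_set_roundtrip(tmp_path):
    save_node_set(tmp_path / "nodes.json", [3, 1, 4])
    assert load_node_set(tmp_path / "nodes.json") == [3, 1, 4]


def test_system_shape_validation():
    with pytest.raises(ValueError):
        LinearNetworkSystem(np.zeros((2, 3)), np.eye(2), np.eye(2))
    with pytest.raises(ValueError):
        LinearNetworkSystem(np.zeros((2, 2)), np.zeros((3, 1)), np.eye(2))
    with pytest.raises(ValueError):
        LinearNetworkSystem(np.zeros((2, 2)), np.eye(2), np.zeros((1, 3)))
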