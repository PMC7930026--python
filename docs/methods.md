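# Methods notes

This note records the mathematical model, the conventions the implementation
commits to, and the numerical choices that matter when reproducing results.
It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## Model and problem

Networks are discrete-time LTI systems `x(t+1) = A x(t) + B u(t)`,
`y(t) = C x(t)` with `A` an (optionally weighted) adjacency matrix, `B` an
`n×m` and `C` a `p×n` 0/1 node-selection matrix (arbitrary real matrices are
accepted everywhere). The point-to-point problem is

```
min_u  Σ_{t=1}^{T-1} y(t)'Q_t y(t) + Σ_{t=0}^{T-1} u(t)'R_t u(t)
s.t.   x(0) = 0,  y(T) = y_f,
```

with `Q ⪰ 0` on the stacked intermediate outputs and `R ≻ 0` on the stacked
input. All solvers work with the batch (stacked) form.

## Stacking conventions

These are load-bearing; every formula in the package assumes them.

- **Inputs are stacked in reverse time**: `u_stacked = [u(T-1); …; u(0)]`.
  With the output controllability matrix `C_T = [CB, CAB, …, C A^{T-1} B]`
  this gives `y(T) = C_T u_stacked` from rest.
- **Intermediate outputs are stacked forward**: `y_mid = [y(1); …; y(T-1)]`,
  and `y_mid = H_T u_stacked` where row block `t` of `H_T` is
  `[0 … 0, CB, …, C A^{t-1} B]` with `T-t` leading `p×m` zero blocks.
- Data matrices hold one episode per column with the same conventions, so
  `Y_T = C_T U` and `Y_mid = H_T U` exactly on noiseless data.

`stack_input` / `unstack_input` are the only places the order is encoded.

## Control expressions

- **Model-based optimum** (batch): `u* = (I − K (M K)⁺ M) C_T⁺ y_f` with `K`
  an orthonormal kernel basis of `C_T` and `M` any factor with
  `M'M = H_T' Q H_T + R`. The factor is built by symmetric eigendecomposition
  (`psd_sqrt`), not Cholesky, because the Gram matrix is routinely PSD with a
  nullspace.
- **Gramian minimum-energy control**: implemented as
  `u*(t) = B' (A')^{T−t−1} C' W_T^{−1} y_f` with `W_T = C_T C_T'`. Note the
  transpose on `A`: the formula is often quoted with `A^{T−t−1}`, which is
  correct only for symmetric `A` (the common random-network benchmarks are
  symmetric, so the difference is invisible there). The transposed form is
  the general minimizer; the package verifies it by simulation on
  nonsymmetric systems.
- **Data-driven optimum**: `û = U (I − K_{Y_T} (L K_{Y_T})⁺ L) Y_T⁺ y_f`
  with `L'L = Y_mid' Q Y_mid + U' R U`. Equals the model-based optimum
  whenever `U` has full row rank `mT`; with fewer (but informative) data it
  still reaches any `y_f` in the range of `Y_T`, at a cost that is optimal
  only within the span of the recorded experiments.
- **Minimum-energy specializations**: `û = (Y_T U⁺)⁺ y_f` and the
  one-pseudoinverse approximation `ũ = U Y_T⁺ y_f`; the latter converges to
  the former as `N → ∞` for zero-mean i.i.d. Gaussian inputs and tends to be
  the most accurate expression in floating point (it never forms the
  `mT`-sized pseudoinverse).
- **Noise corrections**: for data with additive zero-mean i.i.d. noise of
  known variance, `(Y_T U'(U U' − N σ_U² I)⁺)⁺ y_f` and
  `U Y_T'(Y_T Y_T' − N σ_{Y_T}² I)⁺ y_f`. These are asymptotic in `N`; at
  small `N` the subtraction can make the corrected second-moment matrix
  indefinite, in which case the pseudoinverse is applied anyway and an
  `IndefiniteCorrectionWarning` is raised.

Realized errors and costs on `ControlSolution` objects are always computed
by *simulating* the system with the designed input, never by algebraic
shortcut, so they measure what the formulas actually achieve in double
precision.

## Structural tests from data

With `rank(U) = mT` (checked, error otherwise) and `T ≥ n` (checked, warning
otherwise), the system is output controllable iff `rank(Y_T) = p`. A target
is reachable through the data iff its projection residual onto the range of
`Y_T` is below `1e−6` relative (configurable). The empirical controllability
matrix is `Ĉ = Y_T U⁺` and the empirical output Gramian `Ŵ = Ĉ Ĉ'` (`p×p`);
its descending eigenvectors rank output directions from easiest to hardest
to reach.

## Numerical rank: one convention everywhere

All pseudoinverses, ranks, and kernel bases truncate singular values at an
**absolute** threshold of `1e−8` (configurable via `tol=`/`--pinv-tol`).
Using a single notion of numerical rank keeps the control expressions, the
reachability test, and the controllability test mutually consistent; mixing
relative and absolute thresholds makes the rank-based tests disagree with
the ranges the controls actually use.

## Random networks and experiment generators

- Erdős–Rényi `G(n, p)` with `p = ln(n)/n + ε` by default (connectivity
  threshold plus a margin); draws are repeated with fresh sub-seeds until
  connected. Watts–Strogatz likewise. Barabási–Albert graphs attach
  `⟨k⟩/2` edges per new node to a complete seed graph on `m0` nodes and are
  connected by construction.
- Adjacency normalizations: none, `A/√n`, `A/‖A‖₂` (spectral), `A/‖A‖_F`.
  For long horizons this choice is not cosmetic: with an expanding adjacency
  (`ρ(A) > 1`) the entries of `C_T` grow like `ρ(A)^T`, and for `T` in the
  tens every method's *evaluated* error is dominated by round-off in the
  simulation itself rather than by the control design. The
  large-sparse-network benchmark and the model-uncertainty benchmark
  therefore normalize by the spectral norm (`ρ(A) = 1`).
- Input/output node sets are drawn uniformly without replacement and
  resampled until `σ_min(C_T)` exceeds a floor (default `1e−10`), so sampled
  systems are genuinely output controllable rather than borderline.
- Episodic experiments draw i.i.d. Gaussian inputs and propagate all `N`
  episodes as one `(n, N)` matrix recursion. Generator realism caveats: the
  noise model is additive i.i.d. on the data matrices (any zero-mean
  unit-variance sampler can be plugged in), and sliding-window data from a
  single long record assume the pre-window state has died out — exact only
  for episodic resets.

## Subspace identification baseline

Requires full state measurement (`C = I`; enforced). `Ĉ = Y_T U⁺`, `B̂` is
its first `m` block column, and `Â` solves the block-shift least squares
`Ĉ[:, m:mT] ≈ Â Ĉ[:, :(T−1)m]` (0-based half-open slices; classical
statements of the same slicing are 1-based). Exact on noiseless data from
systems controllable in `T−1` steps with full-row-rank `U`. The
identify-then-control pipeline designs the Gramian control on `(Â, B̂)` and
is evaluated on the true system; its degradation with network size is one of
the benchmark studies, not a bug.

## Kuramoto testbed

Ring of `n` identical oscillators,
`θ̇_i = ω + sin(θ_{i−1} − θ_i) + sin(θ_{i+1} − θ_i) + u_i`, forward Euler
with `dt = 0.01`. Splay states `θ_i = 2πqi/n + c` are equilibria indexed by
the winding number `q` (`q = 0` is synchrony). Conventions that matter:

- Experiments start exactly at the initial equilibrium and record outputs in
  deviation coordinates `θ − θ_init`, so the zero-initial-state linear
  framework applies locally; `Y_mid` is additionally recentred by the target
  deviation so `Q` penalizes distance from the *target* along the way.
- Phases live on the torus, so the target handed to the linear machinery is
  the **componentwise wrapped difference** `y_f = wrap(θ_target − θ_init)`
  in `(−π, π]` — the nearest lift of the target pattern. Unwrapped
  differences (up to `2π`) put the problem far outside the regime where the
  linearized data are informative.
- Success is basin capture, not exact arrival: after the `T`-step control
  the network runs free, and the run counts as a hit when the phase distance
  to the target — maximum absolute wrapped deviation after removing the
  global rotation by the circular mean — drops below 0.1 rad within 50 s.

## Benchmark studies

Each study returns a tidy DataFrame stamped with a SHA-256 hash of its
configuration, so every table is reproducible from `(config, seed)`. Scaled
defaults are exposed through `ddnetctrl bench --scale`; wall-clock design
times are reported but never asserted. In the model-uncertainty study the
existing edge weights are perturbed by i.i.d. *relative* uniform `[−δ, δ]`
disturbances (symmetrically), the control is designed on the perturbed model
with the conditioning guard disabled, and the error is evaluated on the true
model — the Gramian solve's degradation with `n` is the quantity of
interest.

## Limitations

- The data-driven expressions assume exact episodic resets (`x(0) = 0`);
  drifting initial states bias all estimates.
- Noise corrections need the noise variance and are asymptotic in `N`.
- Subspace identification is limited to full state measurement; with hidden
  nodes `A` is not identifiable in this deterministic setting.
- The Kuramoto control is local: transitions between distant patterns rely
  on landing in the target's basin, and success is statistical over seeds,
  not guaranteed per seed.
- Dense linear algebra throughout: memory is `O(n² + mT·N)`; networks
  beyond a few thousand nodes need care with `N` and `T`.
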