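# Methods

## Model

The package treats a recurrent spiking network as a multivariate linear
(Hawkes) point process.  Each neuron `i` fires with conditional intensity

    rate_i(t) = mu_i + sum_j ∫ g_ij(t - s) S_j(s) ds,

where `mu_i` is a constant external drive and `g_ij(t)` is a causal
interaction kernel whose integral `G_ij` is the effective synaptic weight of
the connection presynaptic `j` → postsynaptic `i` (columns of `G` are
sources; this orientation is fixed everywhere, including on disk).  All
outgoing weights of a node share its type weight: `g_E > 0` for excitatory
sources, `g_I < 0` for inhibitory ones (generalized Dale's law).  The theory
is stationary-linear and requires spectral radius `rho(G) < 1`; operations
refuse matrices with `rho >= 0.999` (configurable) because the solve is
ill-conditioned and the linear description physically unreliable near
criticality.

With `B = (I - G)^-1`, the package computes exactly:

* stationary rates `Lambda = B mu` (LU solve, factorization cached per
  network, explicit `B` only for N <= ~2000);
* integrated (zero-frequency) covariances `C = B diag(Lambda) B^T`;
* integrated joint third cumulants

      kappa^{ijk} = sum_m Lambda_m B_im B_jm B_km
                  + sum_{m,n} Lambda_n [ B_im B_jm (B-I)_mn B_kn + (2 perms) ],

  evaluated by vector contractions (O(N^2) time and memory per triplet); the
  full N^3 tensor exists only as a dense oracle for N <= 40 in tests;
* full population sums: `sum_ij C_ij` (the large-bin limit of
  Var[N_pop(T)]/T) and `sum_ijk kappa^{ijk}` (same limit for the third
  cumulant of the population count), and the distinct-triplet average
  `kbar3 = N^-3 sum_{i≠j≠k} kappa^{ijk}` via inclusion–exclusion
  (`S_distinct = S_all − 3 S_pair + 2 S_diag`, all terms reduced to matrix
  contractions, verified against brute-force triple loops).

Equal-index triples are permitted in `integrated_third_cumulant` (the
formula is valid for any index tuple, and the inclusion–exclusion needs
them) even though `kbar3` itself averages distinct triples only.

Units: with the dimensionless convention `mu = 1` all outputs are
dimensionless; with `mu` in events/s integrated cumulants of any order come
out in events/s.

## Tree-motif calculus

For homogeneous (regular, or large Erdős–Rényi) networks the average third
cumulant decomposes over six rooted-tree shapes T1–T6 with multiplicities
(1, 3, 3, 6, 6, 3).  A shape with `n` nodes, `l` leaves, internal
out-degrees `{k_v}` and branch lengths `(l_1 .. l_{n-1})` contributes

    multiplicity * (lbar/N^3) * N^n * p^(l-1) * prod_v mu^(k_v) * (N mu1)^(s - n + 1),

with `mu^(k) = p (N_E/N g_E^k + N_I/N g_I^k)` the mean common input shared
by `k` neurons, `lbar = 1/(1 - N mu1)` the homogeneous rate and `s` the
total branch length.  Signs follow a parity rule: `mu^(k)` is negative for
odd `k` in inhibition-dominated networks and `N mu1 < 0`, so the sign is
`(-1)^(#odd k_v) * (-1)^(s-n+1)`.

### A documented internal tension

The printed aggregate closed form (`kbar3_regular`, six labeled terms, and
the algebraically identical `kbar3_simplified` / leading term `ktilde3`)
does **not** equal the resummation of the per-tree formula above: three
aggregate terms carry opposite signs and the T6 aggregate term carries
`p^3` where the leaf-count rule gives `p^2`.  The package adjudicated this
numerically before freezing conventions (the matrix brackets are the ground
truth: summed with their multiplicities they reproduce the exact
inclusion–exclusion `kbar3` on explicit regular matrices, and fixed-length
T6 brackets on ER matrices match the `p^2` convention to within ~2% while
the `p^3` convention is off by a factor `1/p`).  Conventions chosen:

* `tree_term_regular` / `tree_sign` use the per-tree formula with actual
  leaf counts (p-exponents 2, 1, 1, 1, 0, 2) — this is what fixed-length
  matrix evaluations reproduce;
* `kbar3_regular`, `kbar3_simplified`, `ktilde3` implement the aggregate
  formulas digit for digit as printed;
* `motif_diagnostics()` reports both conventions next to the exact matrix
  value on any parameter set, so the discrepancy is surfaced rather than
  silently patched.

A further caveat: in the inhibition-dominated balanced regime the
narrow-degree approximation itself carries O(1) relative errors for
length-summed brackets, because type fluctuations of multi-step path sums
(bulk spectral radius `r ≈ 0.34`) are the same order as the mean input
(`|N mu1| = 0.3`).  Fixed-length contributions at small total length are
accurate (ratios 1.0–1.2 on ER matrices at N = 1000); tuples with several
long branches are fluctuation-dominated.  The canned ER comparison
therefore uses the all-ones tuple plus single-branch increments
(T1 totals 3–4, T6 totals 4–5), which is also the regime the fixed-length
figures display.

`tree_term_matrix` evaluates any shape at fixed lengths on an explicit
matrix by iterated matrix-vector contractions (never materializing node
sums).  Because fixed-length brackets are polynomials in `G`, they remain
well defined on matrices whose own dynamics are unstable; the root weight
is then the homogeneous closed-form rate passed in as a scalar (see hub
networks below), and the function raises only on floating-point overflow.

## Network generators

* **Erdős–Rényi**: every ordered pair independently with probability `p`.
* **Regular**: exact in-degree = out-degree = `K = round(pN)` (override
  available), built as a union of `K` pairwise edge-disjoint fixed-point-free
  permutations.  Pure rejection of colliding permutations is infeasible
  (two uniform permutations share one edge in expectation, so a fresh
  permutation collides with the union of `K-1` others with probability
  `≈ 1 - e^-(K-1)`); instead each permutation is repaired by random target
  swaps until disjoint, which preserves permutation structure and hence
  exact regularity.
* **Geometric hubs**: out-degrees from `P(k) = (1-1/k0)^(k-1)/k0` (mean
  `k0`), truncated at `N-1` (truncation, not resampling — a documented
  choice).  Excitatory nodes with `k > k0` (strict) are hubs; a hub sends
  `round(f k)` edges to other hubs and the remainder to non-hubs only
  (disjoint target pools, so `f` is exactly the expected hub→hub fraction);
  non-hubs and inhibitory nodes target all other nodes uniformly.  No
  self-loops or multi-edges anywhere.  `f0 = 0.35` is carried as a labeling
  constant for assortative vs disassortative wiring, not recomputed.

Spectral diagnostics report the measured `rho(G)`, the predicted rate-mode
outlier `N mu1` and the bulk radius
`r^2 = N p (1-p) (N_E/N g_E^2 + N_I/N g_I^2)`.

Strongly assortative hub networks (`f = 0.6`, `k0 = 100`, `N = 1000`) are
supercritical (`rho ≈ 1.5`: the hub-hub excitatory subnetwork alone exceeds
unity) and have no stationary linear rates; their motif brackets are still
evaluated (finite polynomials) with the regular-theory homogeneous rate as
root weight on both sides of the comparison.

## Simulator

Discrete-time simulation with exponential kernels: per-neuron synaptic
state decays by the exact factor `exp(-dt/tau)` per step and jumps by
`g/tau` (delay-shifted through a ring buffer; the delay must be an integer
multiple of `dt`).  Spike counts per step are Poisson(`max(rate, 0) * dt`)
— Poisson rather than Bernoulli so superposition holds exactly for any `dt`
in the uncoupled case.  Rectification acts only at spike generation; the
linear state is never clipped, and the fraction of clipped neuron-steps is
reported (`rectified_fraction`).  Defaults mirror the reference protocol:
`tau = 10 ms`, `delay = 2 ms`, `dt = 0.1 ms`, drive 10 Hz (an increment of
1.5 Hz decaying over 10 ms integrates to `g_E = 0.015`; −7.5 Hz gives
`g_I = −0.075`).  Burn-in default 1000 ms (= 100 tau; transient handling is
a package convention).  Runaway detection aborts once the population rate
exceeds 100× the linear prediction for 1000 consecutive steps.  Identical
seed and config give byte-identical event lists.

## Estimators

Counts are formed on disjoint, half-open bins `[bT, (b+1)T)`; a trailing
partial bin is dropped.  Integrated cumulants are estimated by joint
k-statistics divided by the bin width: order 2 uses
`sum (x-xbar)(y-ybar)/(n-1)`, order 3 uses
`n/((n-1)(n-2)) sum (x-xbar)(y-ybar)(z-zbar)` — the unique symmetric
estimators unbiased at every sample size (verified against a shared-driver
construction with known third cumulant and against Poisson identities).
The theory is the `T → ∞` limit; `T = 100 ms = 10 tau` is the working
default and estimates at 100 ms and 200 ms agree within uncertainties.
Exhaustive triplet sweeps are refused above N = 200 in favor of uniform
random samples of distinct triplets.  Optional bootstrap standard errors
resample bins with replacement, treating bins as exchangeable — residual
autocorrelation beyond one bin is ignored (documented limitation).

## Canned experiments and problem sizes

* `fig1`: ER network, N = 250 (200 E / 50 I), reference weights and
  kernel, 500 s of data, T = 100 ms, 200 sampled distinct triplets.
  Reports mean/max relative rate error, the Pearson correlation of
  predicted vs estimated off-diagonal covariances, and the through-origin
  regression slope of estimated on predicted triplet cumulants.  At this
  desk scale the rate check is sharp (~2% error) but the covariance
  correlation plateaus near 0.69 and the slope estimate has a standard
  deviation of order 1: the network is ~4× more weakly coupled than at
  N = 1000 and the series is 10× shorter than the reference 5000 s, so
  per-pair/per-triplet estimator noise exceeds the predicted signal spread.
  Running the identical pipeline at 2000 s gives r ≈ 0.88 and slope ≈ 0.89
  — the desk-scale shortfall is statistical power, not bias.  (The
  remaining ~10% slope shrinkage at long duration is the finite-bin-width
  transfer: the theory is the `T → ∞` limit.)
* `fig5`: closed forms on N ∈ {256, 512, 1024, 2048} × p ∈ [0.02, 0.3];
  the quadratic approximation ratio improves monotonically with N.
* `fig6`: fixed-length T1/T6 contributions on 3 ER realizations (N = 1000)
  vs the closed form over the single-increment grids described above.
* `fig7`: the same on 3 assortative hub realizations (f = 0.6,
  k0 = p N = 100) over the balanced ladder (1,1,1,1) → (3,3,3,3);
  magnitude ratios are compared because hub brackets do not alternate sign
  with branch-length parity the way the homogeneous theory does, and the
  hub excess grows steeply with total branch length (≈4× at total 4 to
  ≈10^5 at total 12).

All randomness descends from one root seed split deterministically per
component; theory outputs are bit-reproducible and simulations reproduce
within a seed.

## What the synthetic data does and does not show

The package's only data are its own simulations: the generators and the
Hawkes simulator *are* the data-generating process the estimators are
validated against.  Passing tests therefore demonstrate internal
consistency of theory, motif calculus, simulation and estimation — they do
not show that real spike trains satisfy the linear model (real neurons
threshold, adapt, and violate Dale-type homogeneity of weights), and the
rectification required for inhibition means the simulated process is only
approximately the linear process wherever rates graze zero
(`rectified_fraction` quantifies this per run; ~3% of neuron-steps at the
fig1 scale).

## Numerical choices

* LU factorization of `I - G`, cached per network object; explicit inverse
  only for the dense `B` needed by covariance/cumulant contractions.
* Stability guard at `rho >= 0.999`; spectral radius via dense
  eigenvalues for N <= 500, ARPACK largest-magnitude eigenvalue above.
* Series resummation caps: explicit length sums to total <= 40 by default,
  geometric tail `|N mu1|` per extra unit.
* Tie-breaks: half-open bins put a spike at exactly `t = bT` into bin `b`;
  `round(pN)` for the regular degree; `round(f k)` for hub edge counts.
* Degenerate inputs: `p = 0` gives empty graphs, zero cumulants and sign 0;
  single-node self-coupled networks are accepted by the theory layer (used
  as scalar oracles) though generators never produce autapses.
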