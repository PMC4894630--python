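"""Exact stationary rates and integrated cumulants of the linear Hawkes model.

For a stable network (spectral radius of the integrated connectivity ``G``
below 1) with external drive ``mu``, the stationary rate vector is
``Lambda = (I - G)^-1 mu``.  Writing ``B = (I - G)^-1``, the integrated
(zero-frequency) covariance matrix is ``C = B diag(Lambda) B^T`` and the
integrated joint third cumulant of any index triple (i, j, k) is

    kappa^{ijk} = sum_m Lambda_m B_im B_jm B_km
                + sum_{m,n} Lambda_n [ B_im B_jm (B - I)_mn B_kn
                                     + B_jm B_km (B - I)_mn B_in
                                     + B_im B_km (B - I)_mn B_jn ].

All third-order evaluations are contraction-based (O(N^2) memory at most);
the full N^3 tensor is only ever formed by the small dense oracle used in
tests.  Units follow the drive: with the dimensionless convention mu = 1 all
outputs are dimensionless, with mu in events/s the integrated cumulants come
out in events/s.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.linalg

from .networks import StabilityError, WeightedNetwork

#: Operations refuse matrices closer to criticality than this, where the
#: linear solve is ill-conditioned and the linear theory unreliable anyway.
DEFAULT_RHO_MAX = 0.999


def _check_stability(net: WeightedNetwork, rho_max: float = DEFAULT_RHO_MAX) -> None:
    rho = net.spectral_radius()
    if rho >= rho_max:
        raise StabilityError(
            f"spectral radius rho(G) = {rho:.6g} >= {rho_max}; "
            "stationary linear theory does not apply"
        )


def linear_response(net: WeightedNetwork, rho_max: float = DEFAULT_RHO_MAX) -> np.ndarray:
    """The integrated linear-response matrix B = (I - G)^-1, cached per network.

    Obtained from an LU factorization of (I - G); the network's cache also
    holds the factorization for right-hand-side solves.
    """
    if "B" not in net._cache:
        _check_stability(net, rho_max)
        a = np.eye(net.n) - net.g
        lu = scipy.linalg.lu_factor(a)
        net._cache["lu"] = lu
        net._cache["B"] = scipy.linalg.lu_solve(lu, np.eye(net.n))
    return net._cache["B"]


def stationary_rates(net: WeightedNetwork, mu: float | np.ndarray = 1.0,
                     rho_max: float = DEFAULT_RHO_MAX) -> np.ndarray:
    """Stationary rate vector Lambda = (I - G)^-1 mu (linear solve, no inverse)."""
    mu_vec = np.broadcast_to(np.asarray(mu, dtype=float), (net.n,)).copy()
    if (mu_vec < 0).any():
        raise ValueError("external drive mu must be nonnegative")
    _check_stability(net, rho_max)
    if "lu" not in net._cache:
        net._cache["lu"] = scipy.linalg.lu_factor(np.eye(net.n) - net.g)
    rates = scipy.linalg.lu_solve(net._cache["lu"], mu_vec)
    if (rates < 0).any():
        warnings.warn(
            "stationary rate vector has negative entries; the linear theory "
            "is outside its validity regime (rectification would bind)",
            RuntimeWarning, stacklevel=2,
        )
    return rates


def integrated_covariance(net: WeightedNetwork, rates: np.ndarray) -> np.ndarray:
    """Integrated covariance matrix C = B diag(Lambda) B^T (symmetrized on return)."""
    b = linear_response(net)
    c = (b * rates[None, :]) @ b.T
    return 0.5 * (c + c.T)


@dataclass(frozen=True)
class TripletCumulant:
    """An integrated joint third cumulant with its index triple."""

    i: int
    j: int
    k: int
    value: float


def _kappa_from_b(b: np.ndarray, bmi: np.ndarray, rates: np.ndarray,
                  i: int, j: int, k: int) -> float:
    bi, bj, bk = b[i], b[j], b[k]
    lam = rates
    term1 = float(np.dot(lam, bi * bj * bk))
    # sum_{m,n} Lambda_n x_m (B-I)_mn y_n  ==  x @ (B-I) @ (Lambda * y)
    term2 = float((bi * bj) @ bmi @ (lam * bk))
    term3 = float((bj * bk) @ bmi @ (lam * bi))
    term4 = float((bi * bk) @ bmi @ (lam * bj))
    return term1 + term2 + term3 + term4


def integrated_third_cumulant(net: WeightedNetwork, rates: np.ndarray,
                              i: int, j: int, k: int) -> TripletCumulant:
    """Integrated joint third cumulant kappa^{ijk} for any index triple.

    Equal indices are allowed; kappa^{iii} is the integrated third
    auto-cumulant (equal to the rate for a Poisson unit).
    """
    n = net.n
    for idx in (i, j, k):
        if not 0 <= idx < n:
            raise IndexError(f"node index {idx} out of range [0, {n})")
    b = linear_response(net)
    bmi = b - np.eye(n)
    return TripletCumulant(i, j, k, _kappa_from_b(b, bmi, rates, i, j, k))


def third_cumulant_series_oracle(net: WeightedNetwork, rates: np.ndarray,
                                 i: int, j: int, k: int,
                                 max_power: int) -> TripletCumulant:
    """kappa^{ijk} with B replaced by the truncated series sum_{n<=max_power} G^n.

    Converges geometrically (error ~ rho(G)^(max_power+1)) to the closed form;
    serves as an independent cross-check of the LU-based path.
    """
    n = net.n
    b_trunc = np.eye(n)
    power = np.eye(n)
    for _ in range(max_power):
        power = power @ net.g
        b_trunc += power
    bmi = b_trunc - np.eye(n)
    return TripletCumulant(i, j, k, _kappa_from_b(b_trunc, bmi, rates, i, j, k))


def dense_third_cumulant_tensor(net: WeightedNetwork, rates: np.ndarray,
                                max_n: int = 40) -> np.ndarray:
    """The full N^3 tensor of integrated third cumulants (test oracle only)."""
    if net.n > max_n:
        raise ValueError(f"dense tensor path restricted to N <= {max_n}")
    b = linear_response(net)
    bmi = b - np.eye(net.n)
    t1 = np.einsum("m,im,jm,km->ijk", rates, b, b, b)
    core = np.einsum("im,jm,mn,n,kn->ijk", b, b, bmi, rates, b)
    return t1 + core + core.transpose(2, 0, 1) + core.transpose(1, 2, 0)


@dataclass(frozen=True)
class PopulationCumulants:
    """Full sums of integrated cumulants and the distinct-triplet average.

    ``sum_c`` is the large-bin limit of Var[N_pop(T)]/T, ``sum_k3`` the
    corresponding limit for the third cumulant of the population count, and
    ``kbar3_distinct`` = (1/N^3) sum over distinct (i, j, k) of kappa^{ijk}.
    """

    sum_c: float
    sum_k3: float
    kbar3_distinct: float
    kbar3_se: float | None = None


def population_cumulants(net: WeightedNetwork, rates: np.ndarray,
                         triplet_mode: str = "exact", m: int = 1000,
                         seed: int | None = None) -> PopulationCumulants:
    """Population-count cumulants via closed-form contractions of B.

    ``triplet_mode="exact"`` evaluates the distinct-index sum by
    inclusion-exclusion over repeated-index contractions
    (S_distinct = S_all - 3 S_pair + 2 S_diag, all O(N^2) memory);
    ``triplet_mode="sampled"`` Monte-Carlo averages ``m`` uniformly drawn
    distinct triplets and reports a standard error.
    """
    b = linear_response(net)
    n = net.n
    eye = np.eye(n)
    bmi = b - eye
    lam = rates

    u = b.sum(axis=0)                     # column sums of B
    sum_c = float(u @ (lam * u))
    s_all = float(np.dot(lam, u ** 3) + 3.0 * (u ** 2) @ bmi @ (lam * u))

    if triplet_mode == "exact":
        q = (b ** 2).sum(axis=0)
        t3 = (b ** 3).sum(axis=0)
        gram = b.T @ b
        gram3 = (b ** 2).T @ b
        s_pair = float(np.dot(lam, q * u) + q @ bmi @ (lam * u)
                       + 2.0 * u @ ((gram * bmi) @ lam))
        s_diag = float(np.dot(lam, t3) + 3.0 * ((gram3 * bmi).sum(axis=0) @ lam))
        kbar3 = (s_all - 3.0 * s_pair + 2.0 * s_diag) / n ** 3
        return PopulationCumulants(sum_c, s_all, kbar3)

    if triplet_mode == "sampled":
        if m <= 0:
            raise ValueError("sampled mode requires m > 0")
        rng = np.random.default_rng(seed)
        vals = np.empty(m)
        for t in range(m):
            while True:
                i, j, k = rng.integers(0, n, size=3)
                if i != j and j != k and i != k:
                    break
            vals[t] = _kappa_from_b(b, bmi, lam, int(i), int(j), int(k))
        n_distinct = n * (n - 1) * (n - 2)
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan")
        scale = n_distinct / n ** 3
        return PopulationCumulants(sum_c, s_all, mean * scale, se * scale)

    raise ValueError(f"unknown triplet_mode {triplet_mode!r}")
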