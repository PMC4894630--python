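"""Directed weighted E/I network models and their spectral characterization.

Three generators are provided, all producing :class:`WeightedNetwork` objects
obeying a generalized Dale's law (every outgoing weight of a node equals the
node-type weight, ``g_E > 0`` for excitatory sources and ``g_I < 0`` for
inhibitory ones):

* :func:`generate_erdos_renyi` -- every ordered pair is connected
  independently with probability ``p``;
* :func:`generate_regular` -- every node has exactly ``K`` in- and out-edges;
* :func:`generate_geometric_hub` -- out-degrees follow a geometric law with
  mean ``k0``; high-out-degree excitatory nodes ("hubs") direct a fraction
  ``f`` of their edges at other hubs.

Orientation convention (the single most bug-prone one in this domain):
``G[i, j]`` is the integrated kernel of the connection *from presynaptic j to
postsynaptic i*, i.e. columns are sources.  This matches the stationary-rate
relation ``rate = (I - G)^-1 mu``.  Node indices are 0-based everywhere,
including on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

logger = logging.getLogger(__name__)

#: Boundary between assortative (f > F0_CRITICAL) and disassortative hub
#: wiring for geometric-out-degree networks.  An empirical constant of the
#: model family, not recomputed here.
F0_CRITICAL = 0.35


class ParameterError(ValueError):
    """Invalid model parameters."""


class GenerationError(RuntimeError):
    """A randomized construction failed within its retry budget."""


class StabilityError(RuntimeError):
    """The connectivity matrix has spectral radius >= 1 (or too close to it)."""


@dataclass(frozen=True)
class NeuronTypes:
    """Per-node E/I labels.

    ``labels`` is an array of the strings ``"E"``/``"I"``; counts are derived.
    """

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype="U1")
        if not np.isin(labels, ("E", "I")).all():
            raise ParameterError("type labels must be 'E' or 'I'")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_e(self) -> int:
        return int((self.labels == "E").sum())

    @property
    def n_i(self) -> int:
        return int((self.labels == "I").sum())

    @classmethod
    def block(cls, n_e: int, n_i: int) -> "NeuronTypes":
        """First ``n_e`` nodes excitatory, the remaining ``n_i`` inhibitory."""
        if n_e < 0 or n_i < 0:
            raise ParameterError("n_e and n_i must be nonnegative")
        return cls(np.array(["E"] * n_e + ["I"] * n_i))


@dataclass(frozen=True)
class RegularParams:
    """Global parameter tuple (N, N_E, N_I, p, g_E, g_I) of the homogeneous theory."""

    n: int
    n_e: int
    n_i: int
    p: float
    g_e: float
    g_i: float

    def __post_init__(self):
        if self.n_e + self.n_i != self.n:
            raise ParameterError(f"n_e + n_i = {self.n_e + self.n_i} != n = {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p = {self.p} outside [0, 1]")
        if self.n < 1:
            raise ParameterError("n must be >= 1")

    @property
    def f_e(self) -> float:
        return self.n_e / self.n

    @property
    def f_i(self) -> float:
        return self.n_i / self.n

    def is_inhibition_dominated(self) -> bool:
        """True when the mean total input N_E g_E + N_I g_I is negative."""
        return self.n_e * self.g_e + self.n_i * self.g_i < 0


@dataclass
class WeightedNetwork:
    """A directed weighted connectivity matrix with E/I node types.

    ``g[i, j]`` is the integrated interaction-kernel weight presynaptic
    ``j`` -> postsynaptic ``i``; column ``j`` holds only 0 or the type weight
    of node ``j``.
    """

    g: np.ndarray
    types: NeuronTypes
    g_e: float
    g_i: float
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2 or self.g.shape[0] != self.g.shape[1]:
            raise ParameterError("g must be a square matrix")
        if self.g.shape[0] != self.types.n:
            raise ParameterError("types length does not match matrix size")

    @property
    def n(self) -> int:
        return self.g.shape[0]

    def type_weights(self) -> np.ndarray:
        """Per-node outgoing weight g_{type(j)}."""
        return np.where(self.types.labels == "E", self.g_e, self.g_i)

    def spectral_radius(self) -> float:
        """Largest eigenvalue modulus of G (cached)."""
        if "rho" not in self._cache:
            if self.n <= 2:
                rho = float(np.max(np.abs(np.linalg.eigvals(self.g)))) if self.n else 0.0
            elif self.n <= 500:
                rho = float(np.max(np.abs(np.linalg.eigvals(self.g))))
            else:
                try:
                    vals = sp.linalg.eigs(
                        sp.csr_matrix(self.g), k=1, which="LM",
                        return_eigenvectors=False, maxiter=5000,
                    )
                    rho = float(np.max(np.abs(vals)))
                except (sp.linalg.ArpackNoConvergence, RuntimeError):
                    rho = float(np.max(np.abs(np.linalg.eigvals(self.g))))
            self._cache["rho"] = rho
        return self._cache["rho"]

    def check_dale(self) -> bool:
        """Verify the generalized Dale's law column by column."""
        w = self.type_weights()
        for j in range(self.n):
            col = self.g[:, j]
            nz = col[col != 0.0]
            if nz.size and not np.all(nz == w[j]):
                return False
        return bool(np.all(np.diag(self.g) == 0.0))


@dataclass(frozen=True)
class SpectralReport:
    """Spectral summary: measured radius, predicted rate-mode outlier and bulk radius."""

    rho: float
    outlier: float
    bulk_radius: float
    stable: bool


def _weights(types: NeuronTypes, g_e: float, g_i: float) -> np.ndarray:
    if g_e <= 0:
        raise ParameterError(f"g_e must be positive, got {g_e}")
    if g_i >= 0:
        raise ParameterError(f"g_i must be negative, got {g_i}")
    return np.where(types.labels == "E", g_e, g_i)


def generate_erdos_renyi(params: RegularParams, seed: int) -> WeightedNetwork:
    """Directed Erdős–Rényi network: each ordered pair i != j is connected
    independently with probability p, carrying the source-type weight."""
    rng = np.random.default_rng(seed)
    types = NeuronTypes.block(params.n_e, params.n_i)
    w = _weights(types, params.g_e, params.g_i)
    mask = rng.random((params.n, params.n)) < params.p
    np.fill_diagonal(mask, False)
    return WeightedNetwork(mask * w[None, :], types, params.g_e, params.g_i)


def _disjoint_permutations(n: int, k: int, rng: np.random.Generator,
                           max_sweeps: int = 10_000) -> np.ndarray:
    """Union of k pairwise edge-disjoint fixed-point-free permutations.

    Each permutation is sampled uniformly, then repaired by random target
    swaps until it avoids self-loops and all previously placed edges; the
    swap repair keeps it a permutation, so in- and out-degrees stay exactly k.
    """
    used = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(used, True)  # forbid self-loops
    rows = np.arange(n)
    for _ in range(k):
        perm = rng.permutation(n)
        for _ in range(max_sweeps):
            bad = rows[used[rows, perm]]
            if bad.size == 0:
                break
            i = int(bad[0])
            j = int(rng.integers(n))
            perm[i], perm[j] = perm[j], perm[i]
        else:
            raise GenerationError(
                "could not place a disjoint permutation within the swap budget"
            )
        used[rows, perm] = True
    adj = used.copy()
    np.fill_diagonal(adj, False)
    return adj


def generate_regular(params: RegularParams, seed: int,
                     k: int | None = None) -> WeightedNetwork:
    """Exactly K-regular directed network (in-degree = out-degree = K for
    every node), K = round(p * N) unless overridden."""
    if k is None:
        k = int(round(params.p * params.n))
    if not 1 <= k <= params.n - 1:
        raise ParameterError(
            f"regular degree K = {k} outside [1, N-1] = [1, {params.n - 1}]"
        )
    rng = np.random.default_rng(seed)
    adj = _disjoint_permutations(params.n, k, rng)
    types = NeuronTypes.block(params.n_e, params.n_i)
    w = _weights(types, params.g_e, params.g_i)
    return WeightedNetwork(adj * w[None, :], types, params.g_e, params.g_i)


def generate_geometric_hub(n: int, n_e: int, n_i: int, k0: float, f: float,
                           g_e: float, g_i: float, seed: int) -> WeightedNetwork:
    """Network with geometric out-degrees and assortative excitatory hubs.

    Out-degrees are drawn from P(k) = (1 - 1/k0)^(k-1) / k0, k >= 1 (mean
    k0), truncated at N-1.  Excitatory nodes with sampled out-degree k > k0
    are hubs; a hub sends round(f * k) edges to other hubs (sampled without
    replacement, capped at the hub-pool size) and the remainder to non-hub
    nodes.  Non-hubs and inhibitory nodes pick targets uniformly among all
    other nodes.  No self-loops, no repeated edges.
    """
    if n_e + n_i != n:
        raise ParameterError("n_e + n_i must equal n")
    if k0 <= 1:
        raise ParameterError(f"k0 must be > 1, got {k0}")
    if not 0.0 <= f <= 1.0:
        raise ParameterError(f"f = {f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    types = NeuronTypes.block(n_e, n_i)
    w = _weights(types, g_e, g_i)

    degrees = np.minimum(rng.geometric(1.0 / k0, size=n), n - 1)
    is_hub = (np.arange(n) < n_e) & (degrees > k0)
    hubs = np.flatnonzero(is_hub)
    non_hubs = np.flatnonzero(~is_hub)

    adj = np.zeros((n, n), dtype=bool)
    for j in range(n):
        kj = int(degrees[j])
        if is_hub[j]:
            other_hubs = hubs[hubs != j]
            want_hub = int(round(f * kj))
            n_hub = min(want_hub, other_hubs.size, kj)
            if n_hub < want_hub:
                logger.info(
                    "hub %d wanted %d hub targets, pool has %d; remainder "
                    "falls back to non-hub targets", j, want_hub, other_hubs.size,
                )
            hub_targets = (rng.choice(other_hubs, size=n_hub, replace=False)
                           if n_hub else np.empty(0, dtype=int))
            rest_pool = non_hubs
            n_rest = min(kj - n_hub, rest_pool.size)
            rest = (rng.choice(rest_pool, size=n_rest, replace=False)
                    if n_rest else np.empty(0, dtype=int))
            targets = np.concatenate([hub_targets, rest])
        else:
            pool = np.delete(np.arange(n), j)
            targets = rng.choice(pool, size=min(kj, pool.size), replace=False)
        adj[targets, j] = True
    np.fill_diagonal(adj, False)
    return WeightedNetwork(adj * w[None, :], types, g_e, g_i)


def hub_assortativity(net: WeightedNetwork, k0: float) -> float:
    """Measured fraction of hub out-edges that terminate on other hubs."""
    adj = net.g != 0.0
    out_deg = adj.sum(axis=0)
    is_hub = (net.types.labels == "E") & (out_deg > k0)
    if not is_hub.any():
        return float("nan")
    hub_cols = adj[:, is_hub]
    return float(hub_cols[is_hub, :].sum() / hub_cols.sum())


def spectral_stats(net: WeightedNetwork, params: RegularParams) -> SpectralReport:
    """Spectral radius plus the random-matrix predictions: rate-mode outlier
    N*mu^(1) and bulk radius r with r^2 = N p (1-p) (N_E/N g_E^2 + N_I/N g_I^2)."""
    mu1 = params.p * (params.f_e * params.g_e + params.f_i * params.g_i)
    outlier = params.n * mu1
    bulk = float(np.sqrt(
        params.n * params.p * (1.0 - params.p)
        * (params.f_e * params.g_e ** 2 + params.f_i * params.g_i ** 2)
    ))
    rho = net.spectral_radius()
    return SpectralReport(rho=rho, outlier=outlier, bulk_radius=bulk,
                          stable=rho < 1.0)
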