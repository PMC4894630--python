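"""Unbiased estimation of integrated cumulants from binned spike counts.

Spike trains are binned into disjoint windows of width ``T``; the joint
k-statistics of the count series, divided by ``T``, estimate the integrated
cumulants the theory predicts (the large-bin limit is approached once ``T``
is much larger than the interaction-kernel width).  k-statistics are the
unique symmetric polynomials that are unbiased for cumulants at every
sample size:

    order 2:  k2(x, y) = sum_t (x_t - xbar)(y_t - ybar) / (n - 1)
    order 3:  k3(x, y, z) = n / ((n-1)(n-2)) * sum_t (x_t - xbar)(y_t - ybar)(z_t - zbar)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpikeTrainSet


class EstimationError(ValueError):
    """Not enough data for the requested estimator."""


#: Estimating every one of the C(N,3) triplets is refused above this size;
#: use a random sample of triplets instead.
MAX_EXHAUSTIVE_N = 200


@dataclass
class CountMatrix:
    """N x n_bins spike counts at bin width T (ms), rows aligned with
    network node indices."""

    counts: np.ndarray
    bin_width: float  # ms

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class CumulantEstimate:
    """A k-statistic estimate on the integrated-cumulant scale (per second)."""

    order: int
    indices: tuple[int, ...]
    value: float
    se: float | None = None


def bin_spikes(spikes: SpikeTrainSet, bin_width: float) -> CountMatrix:
    """Bin events into contiguous half-open windows [b*T, (b+1)*T); a
    trailing partial bin is dropped."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if bin_width >= spikes.duration:
        raise EstimationError(
            f"bin width {bin_width} ms >= data duration {spikes.duration} ms"
        )
    n_bins = int(np.floor(spikes.duration / bin_width))
    bins = np.floor(spikes.times / bin_width).astype(np.int64)
    keep = bins < n_bins
    counts = np.zeros((spikes.n, n_bins), dtype=np.int64)
    np.add.at(counts, (spikes.ids[keep], bins[keep]), 1)
    return CountMatrix(counts, bin_width)


def _t_seconds(bin_width_ms: float) -> float:
    return bin_width_ms / 1000.0


def k_stat_rate(row: np.ndarray, bin_width: float) -> float:
    """First cumulant: mean count per bin converted to events/s."""
    row = np.asarray(row, dtype=float)
    if row.size < 1:
        raise EstimationError("need at least one bin")
    return float(row.mean()) / _t_seconds(bin_width)


def k_stat_cov(x: np.ndarray, y: np.ndarray, bin_width: float) -> CumulantEstimate:
    """Unbiased joint second k-statistic over T: estimates the integrated
    covariance C_ij (events/s)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise EstimationError("count series must have equal length")
    if n < 2:
        raise EstimationError("need at least 2 bins for order 2")
    val = float(np.dot(x - x.mean(), y - y.mean()) / (n - 1)) / _t_seconds(bin_width)
    return CumulantEstimate(2, (0, 1), val)


def k_stat_third(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                 bin_width: float) -> CumulantEstimate:
    """Unbiased joint third k-statistic over T: estimates kappa^{ijk}
    (events/s); symmetric in its arguments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if y.size != n or z.size != n:
        raise EstimationError("count series must have equal length")
    if n < 3:
        raise EstimationError("need at least 3 bins for order 3")
    s = float(np.sum((x - x.mean()) * (y - y.mean()) * (z - z.mean())))
    val = n / ((n - 1) * (n - 2)) * s / _t_seconds(bin_width)
    return CumulantEstimate(3, (0, 1, 2), val)


def all_rates(cm: CountMatrix) -> np.ndarray:
    """Per-neuron rate estimates in events/s."""
    return cm.counts.mean(axis=1) / _t_seconds(cm.bin_width)


def covariance_matrix(cm: CountMatrix) -> np.ndarray:
    """All-pairs integrated-covariance estimates (N x N, events/s)."""
    if cm.n_bins < 2:
        raise EstimationError("need at least 2 bins")
    xc = cm.counts - cm.counts.mean(axis=1, keepdims=True)
    return (xc @ xc.T) / (cm.n_bins - 1) / _t_seconds(cm.bin_width)


def sample_triplets(n: int, n_triplets: int, seed: int | None = None,
                    distinct: bool = True) -> np.ndarray:
    """Uniformly sampled index triplets (distinct indices by default)."""
    rng = np.random.default_rng(seed)
    out = np.empty((n_triplets, 3), dtype=np.int64)
    for t in range(n_triplets):
        while True:
            i, j, k = rng.integers(0, n, size=3)
            if not distinct or (i != j and j != k and i != k):
                out[t] = (i, j, k)
                break
    return out


def triplet_cumulants(cm: CountMatrix, triplets: np.ndarray | None = None,
                      n_sample: int = 1000, seed: int | None = None,
                      bootstrap: int = 0) -> list[CumulantEstimate]:
    """Third-cumulant estimates for a set of triplets.

    With ``triplets=None`` and small N, all C(N,3) combinations are used;
    above ``MAX_EXHAUSTIVE_N`` neurons an exhaustive sweep is refused and a
    uniform random sample of ``n_sample`` distinct triplets is drawn.
    Optional bootstrap standard errors resample bins with replacement
    (bins treated as exchangeable).
    """
    if triplets is None:
        if cm.n > MAX_EXHAUSTIVE_N:
            triplets = sample_triplets(cm.n, n_sample, seed)
        else:
            import itertools
            triplets = np.array(list(itertools.combinations(range(cm.n), 3)),
                                dtype=np.int64)
    counts = cm.counts.astype(float)
    xc = counts - counts.mean(axis=1, keepdims=True)
    n = cm.n_bins
    if n < 3:
        raise EstimationError("need at least 3 bins for order 3")
    factor = n / ((n - 1) * (n - 2)) / _t_seconds(cm.bin_width)
    rng = np.random.default_rng(seed)
    out = []
    for i, j, k in triplets:
        val = factor * float(np.sum(xc[i] * xc[j] * xc[k]))
        se = None
        if bootstrap > 0:
            reps = np.empty(bootstrap)
            for b in range(bootstrap):
                sel = rng.integers(0, n, size=n)
                xb, yb, zb = counts[i, sel], counts[j, sel], counts[k, sel]
                reps[b] = k_stat_third(xb, yb, zb, cm.bin_width).value
            se = float(reps.std(ddof=1))
        out.append(CumulantEstimate(3, (int(i), int(j), int(k)), val, se))
    return out


def population_count_cumulants(cm: CountMatrix) -> tuple[float, float]:
    """(variance/T, third k-statistic/T) of the per-bin population count.

    Estimates the full sums of integrated second- and third-order cumulants.
    """
    if cm.n_bins < 3:
        raise EstimationError("need at least 3 bins")
    pop = cm.counts.sum(axis=0).astype(float)
    n = pop.size
    t_s = _t_seconds(cm.bin_width)
    var = float(pop.var(ddof=1)) / t_s
    c = pop - pop.mean()
    k3 = n / ((n - 1) * (n - 2)) * float(np.sum(c ** 3)) / t_s
    return var, k3
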