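"""Time-rescaled Kingman coalescent under a piecewise-exponential size history.

The haploid coalescent with k lineages coalesces at instantaneous rate
k(k-1) / (2 N(t)), so waiting times are standard exponentials mapped through
the inverse of the cumulative intensity Lambda(t) = int_0^t dt' / N(t').
For an exponential size change within an interval both Lambda and its inverse
have closed forms, which lets thousands of replicate genealogies be rescaled
with a handful of vectorised operations.

Replicate topologies and exponential draws are independent of the demography,
so they can be drawn once (:class:`CoalescentDraws`) and re-used across every
candidate size history — common random numbers that make composite-likelihood
surfaces smooth and model comparisons noise-matched.
"""

from __future__ import annotations

import numpy as np

from .scenario import DemographicScenario

__all__ = ["SizeHistory", "CoalescentDraws", "rescaled_interval_durations", "expected_branch_spectrum"]

_G_EPS = 1e-14


class SizeHistory:
    """Backward-time size function with analytic cumulative intensity."""

    def __init__(self, times, sizes, growth) -> None:
        self.times = np.asarray(times, dtype=float)
        self.sizes = np.asarray(sizes, dtype=float)
        self.growth = np.asarray(growth, dtype=float)
        lam = np.zeros_like(self.times)
        dt = np.diff(self.times)
        for j in range(dt.size):
            lam[j + 1] = lam[j] + self._piece_intensity(j, dt[j])
        self.lam = lam

    @classmethod
    def from_scenario(cls, scenario: DemographicScenario) -> "SizeHistory":
        return cls(scenario.anchor_times, scenario.anchor_sizes, scenario._growth)

    def _piece_intensity(self, j: int, u: float) -> float:
        g, n0 = self.growth[j], self.sizes[j]
        if abs(g) < _G_EPS:
            return u / n0
        return (1.0 - np.exp(-g * u)) / (n0 * g)

    def intensity(self, t: np.ndarray) -> np.ndarray:
        """Lambda(t) = int_0^t ds / N(s), vectorised."""
        t = np.asarray(t, dtype=float)
        j = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, self.times.size - 2)
        u = t - self.times[j]
        g, n0 = self.growth[j], self.sizes[j]
        small = np.abs(g) < _G_EPS
        with np.errstate(over="ignore"):
            piece = np.where(small, u / n0, (1.0 - np.exp(-np.where(small, 0.0, g) * u)) / (n0 * np.where(small, 1.0, g)))
        out = self.lam[j] + piece
        beyond = t > self.times[-1]
        if np.any(beyond):
            out = np.where(beyond, self.lam[-1] + (t - self.times[-1]) / self.sizes[-1], out)
        return out

    def inverse_intensity(self, y: np.ndarray) -> np.ndarray:
        """Solve Lambda(t) = y for t >= 0 (vectorised, exact per piece)."""
        y = np.asarray(y, dtype=float)
        j = np.clip(np.searchsorted(self.lam, y, side="right") - 1, 0, self.lam.size - 2)
        r = y - self.lam[j]
        g, n0 = self.growth[j], self.sizes[j]
        small = np.abs(g) < _G_EPS
        gs = np.where(small, 1.0, g)
        arg = np.maximum(1.0 - n0 * gs * r, 1e-300)
        u = np.where(small, n0 * r, -np.log(arg) / gs)
        t = self.times[j] + u
        beyond = y > self.lam[-1]
        if np.any(beyond):
            t = np.where(beyond, self.times[-1] + self.sizes[-1] * (y - self.lam[-1]), t)
        return t


class CoalescentDraws:
    """Demography-independent randomness for ``reps`` replicate genealogies.

    Attributes
    ----------
    exp:
        (reps, n-1) standard-exponential waiting draws for k = n .. 2.
    classes:
        (reps, n-1, n-1) float32 tensor; ``classes[r, i, c-1]`` is the number
        of lineages subtending ``c`` sample tips while ``n - i`` lineages
        remain in replicate ``r``.  Depends only on the (uniform) topology.
    """

    def __init__(self, n: int, reps: int, rng: np.random.Generator) -> None:
        if n < 2:
            raise ValueError("sample size n must be >= 2")
        self.n = int(n)
        self.reps = int(reps)
        self.exp = rng.exponential(size=(reps, n - 1))
        self.classes = _topology_class_counts(n, reps, rng)


def _topology_class_counts(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised uniform-merge topologies; see :class:`CoalescentDraws`."""
    counts = np.ones((reps, n), dtype=np.int64)
    out = np.zeros((reps, n - 1, n - 1), dtype=np.float32)
    rows = np.arange(reps)
    for step in range(n - 1):
        k = n - step
        active = counts[:, :k]
        # histogram of subtended-tip counts across the k live lineages
        flat = active.ravel() - 1
        rep_idx = np.repeat(rows, k)
        np.add.at(out[:, step, :], (rep_idx, flat), 1.0)
        if k == 2:
            break
        i = rng.integers(0, k, size=reps)
        j = rng.integers(0, k - 1, size=reps)
        j = j + (j >= i)
        merged = active[rows, i] + active[rows, j]
        counts[rows, i] = merged
        # move the last live lineage into slot j, shrinking the live set
        counts[rows, j] = active[rows, k - 1]
    return out


def rescaled_interval_durations(history: SizeHistory, n: int, exp_draws: np.ndarray) -> np.ndarray:
    """(reps, n-1) durations in generations of the k = n..2 lineage epochs."""
    reps = exp_draws.shape[0]
    t = np.zeros(reps)
    y = np.zeros(reps)
    out = np.empty_like(exp_draws)
    for idx, k in enumerate(range(n, 1, -1)):
        y = y + exp_draws[:, idx] / (k * (k - 1) / 2.0)
        t_next = history.inverse_intensity(y)
        out[:, idx] = t_next - t
        t = t_next
    return out


def expected_branch_spectrum(history: SizeHistory, draws: CoalescentDraws) -> np.ndarray:
    """Monte-Carlo expected *unfolded* branch-length spectrum.

    Entry i-1 is the mean total branch length (generations) subtending
    exactly i of the n tips; mutations hitting that length produce
    i-frequency variants, so the normalised vector is the expected unfolded
    SFS shape under infinite sites.
    """
    durations = rescaled_interval_durations(history, draws.n, draws.exp)
    return np.tensordot(durations, draws.classes, axes=([0, 1], [0, 1])) / draws.reps


def fold_spectrum(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum of length n-1 into minor-allele classes 1..n//2."""
    n = unfolded.shape[-1] + 1
    half = n // 2
    folded = np.array([unfolded[..., j - 1] + (unfolded[..., n - j - 1] if j != n - j else 0.0)
                       for j in range(1, half + 1)])
    return np.moveaxis(folded, 0, -1) if folded.ndim > 1 else folded
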