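"""Piecewise-exponential demographic scenarios for a clonal (haploid) population.

A scenario describes effective population size through a study window bounded
by four anchor events: the original sampling, two intermediate perturbation
events, and the final (perturbed-state) sampling.  Time is measured in
generations *before* the final sampling, so ``anchor_times[0] == 0`` is the
sampling date and later entries reach back toward the original state.

The per-interval regime is summarised by a three-letter code over {K, E, C}
read *forward* in time (oldest interval first):

* ``K`` — contraction: the population shrinks across the interval,
* ``E`` — expansion: it grows,
* ``C`` — constant: the two anchor sizes are equal.

Between anchors the size changes exponentially (log-linear interpolation),
so a ``C`` interval has zero growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographicScenario",
    "ScenarioError",
    "make_scenario",
    "population_size_at",
    "default_anchor_times",
]

#: Relative tolerance under which two anchor sizes count as "equal" (code C).
C_RTOL = 1e-9


class ScenarioError(ValueError):
    """Raised when a scenario's code, sizes and times are inconsistent."""


@dataclass(frozen=True)
class DemographicScenario:
    """A forward-time piecewise-exponential population-size trajectory.

    Parameters
    ----------
    code:
        Three letters over {K, E, C}, oldest interval first.
    anchor_times:
        Generations before the final sampling, strictly increasing from 0.
    anchor_sizes:
        Haploid effective sizes at each anchor, in *backward* order
        (``anchor_sizes[i]`` is the size ``anchor_times[i]`` generations
        before sampling).  Note :func:`make_scenario` accepts sizes in
        forward chronological order, which is how the codes read.
    """

    code: str
    anchor_times: tuple[float, ...]
    anchor_sizes: tuple[float, ...]

    # derived, backward-time representation
    _growth: tuple[float, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        times = np.asarray(self.anchor_times, dtype=float)
        sizes = np.asarray(self.anchor_sizes, dtype=float)
        if times.shape != sizes.shape or times.ndim != 1 or times.size < 2:
            raise ScenarioError("anchor_times and anchor_sizes must be equal-length 1-d, >= 2 anchors")
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ScenarioError("anchor_times must start at 0 and be strictly increasing")
        if np.any(sizes < 1.0):
            raise ScenarioError("all anchor sizes must be >= 1")
        if len(self.code) != times.size - 1 or any(c not in "KEC" for c in self.code):
            raise ScenarioError(f"code must be {times.size - 1} letters over K/E/C, got {self.code!r}")
        # code letters are forward in time: letter j covers the backward
        # interval (times[m-1-j], times[m-j]) whose forward change is
        # sizes[m-j] -> sizes[m-1-j], with m = number of intervals.
        m = times.size - 1
        for j, letter in enumerate(self.code):
            older, newer = sizes[m - j], sizes[m - 1 - j]
            if letter == "C":
                ok = np.isclose(older, newer, rtol=C_RTOL, atol=0.0)
            elif letter == "K":
                ok = newer < older
            else:  # E
                ok = newer > older
            if not ok:
                raise ScenarioError(
                    f"interval {j + 1} coded {letter!r} but forward size change is "
                    f"{older:g} -> {newer:g}"
                )
        with np.errstate(divide="ignore"):
            growth = np.log(sizes[1:] / sizes[:-1]) / np.diff(times)
        # C intervals force exactly zero growth despite float fuzz
        for j, letter in enumerate(self.code):
            growth[times.size - 2 - j] = growth[times.size - 2 - j] if letter != "C" else 0.0
        object.__setattr__(self, "_growth", tuple(growth))

    @property
    def n_intervals(self) -> int:
        return len(self.anchor_times) - 1

    def size_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Population size ``t`` generations before sampling (see module doc)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ScenarioError("t must be >= 0 (generations before sampling)")
        times = np.asarray(self.anchor_times)
        sizes = np.asarray(self.anchor_sizes)
        growth = np.asarray(self._growth)
        j = np.clip(np.searchsorted(times, t_arr, side="right") - 1, 0, times.size - 2)
        dt = np.minimum(t_arr, times[-1]) - times[j]
        out = sizes[j] * np.exp(growth[j] * dt)
        # beyond the oldest anchor the size is held constant
        out = np.where(t_arr >= times[-1], sizes[-1], out)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def make_scenario(code: str, anchor_sizes, anchor_times) -> DemographicScenario:
    """Build a validated scenario from a K/E/C code.

    ``anchor_sizes`` are given in forward chronological order (original state
    first, final sampling last) — the order in which the code letters read —
    while ``anchor_times`` are generations before sampling starting at 0.
    """
    sizes_fwd = tuple(float(s) for s in anchor_sizes)
    return DemographicScenario(
        code=str(code),
        anchor_times=tuple(float(t) for t in anchor_times),
        anchor_sizes=tuple(reversed(sizes_fwd)),
    )


def population_size_at(scenario: DemographicScenario, t) -> float:
    """Size ``t`` generations before sampling; exponential between anchors."""
    return scenario.size_at(t)


def default_anchor_times(total_generations: float = 3600.0) -> tuple[float, float, float, float]:
    """Anchor times (generations before the 2015-style sampling) for the four
    perturbation anchors, spaced proportionally to the calendar gaps between
    the events (Oct 2015, Nov 2012, Oct 2011, Aug 2003 — 35, 13 and 98 months).
    """
    months = np.array([0.0, 35.0, 48.0, 146.0])
    t = months / months[-1] * float(total_generations)
    return (0.0, float(round(t[1])), float(round(t[2])), float(total_generations))
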