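"""Energy landscape on the {-1,+1}^C hypercube: minima, basins, dwell times.

States are nodes of the C-dimensional hypercube graph (edges join states at
Hamming distance 1).  A local minimum (LM) is a state strictly below all its
neighbors in energy; the global minimum (GM) is the lowest-energy state.
Basins are defined by steepest descent, and dwell statistics come from a
Metropolis random walk over the landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pmem import PMEMModel

__all__ = [
    "EnergyLandscape",
    "WalkResult",
    "ELFeatures",
    "neighbors",
    "find_minima",
    "assign_basins",
    "build_landscape",
    "random_walk",
    "dwell_features",
    "find_major_states",
]


def neighbors(index: int, n_channels: int) -> list[int]:
    """The C Hamming-1 neighbors of a state, in channel order (first channel
    flipped first)."""
    if not 0 <= index < 2**n_channels:
        raise ValueError(f"state index {index} out of range for C={n_channels}")
    return [index ^ (1 << (n_channels - 1 - m)) for m in range(n_channels)]


def _neighbor_matrix(n_channels: int) -> np.ndarray:
    idx = np.arange(2**n_channels)
    flips = 1 << np.arange(n_channels - 1, -1, -1)
    return idx[:, None] ^ flips[None, :]


def find_minima(energies: np.ndarray, n_channels: int) -> tuple[list[int], int]:
    """Local minima (strict) and the global minimum (ties: lowest index, flagged)."""
    energies = np.asarray(energies, dtype=float)
    if energies.size != 2**n_channels:
        raise ValueError("energies must have length 2^C")
    if not np.isfinite(energies).all():
        raise ValueError("energies must be finite")
    nbrs = _neighbor_matrix(n_channels)
    is_lm = (energies[:, None] < energies[nbrs]).all(axis=1)
    local_minima = np.flatnonzero(is_lm).tolist()
    if not local_minima:
        raise ValueError("degenerate landscape: no strict local minimum exists")
    global_minimum = int(np.argmin(energies))
    if (energies == energies[global_minimum]).sum() > 1:
        warnings.warn(
            "global minimum energy is tied; choosing the lowest state index",
            RuntimeWarning,
        )
    return local_minima, global_minimum


def assign_basins(
    energies: np.ndarray, n_channels: int
) -> tuple[np.ndarray, dict[int, int]]:
    """Steepest-descent basin of every state.

    From each state, repeatedly move to the lowest-energy neighbor while it is
    strictly lower than the current state (energy ties between neighbors
    broken by lowest state index); the terminating LM owns the state.
    """
    energies = np.asarray(energies, dtype=float)
    n_states = 2**n_channels
    nbrs = _neighbor_matrix(n_channels)
    # next-state pointer under steepest descent (self-pointer at an LM)
    nbr_e = energies[nbrs]
    # lowest neighbor energy, ties by lowest neighbor index
    order = np.argsort(nbrs, axis=1)
    nbrs_sorted = np.take_along_axis(nbrs, order, axis=1)
    e_sorted = np.take_along_axis(nbr_e, order, axis=1)
    best_pos = np.argmin(e_sorted, axis=1)  # first minimum = lowest index
    best_nbr = nbrs_sorted[np.arange(n_states), best_pos]
    best_e = e_sorted[np.arange(n_states), best_pos]
    pointer = np.where(best_e < energies, best_nbr, np.arange(n_states))
    # pointer-jump until fixed point; at most C jumps needed per halving step
    owner = pointer.copy()
    while True:
        nxt = pointer[owner]
        if (nxt == owner).all():
            break
        owner = nxt
    sizes: dict[int, int] = {}
    for lm, count in zip(*np.unique(owner, return_counts=True)):
        sizes[int(lm)] = int(count)
    assert sum(sizes.values()) == n_states
    return owner, sizes


@dataclass
class EnergyLandscape:
    """Energies on the hypercube plus derived attractor structure."""

    energies: np.ndarray
    n_channels: int
    local_minima: list[int]
    global_minimum: int
    basin_of: np.ndarray          # (2^C,) owning LM of each state
    basin_sizes: dict[int, int]   # LM -> number of owned states

    @property
    def n_local_minima(self) -> int:
        return len(self.local_minima)

    def mean_gap(self) -> float:
        """Mean of E(LM) - E(GM) over the non-GM local minima (0 if none)."""
        gaps = [
            self.energies[lm] - self.energies[self.global_minimum]
            for lm in self.local_minima
            if lm != self.global_minimum
        ]
        return float(np.mean(gaps)) if gaps else 0.0

    def basin_size_sd(self) -> float:
        """Population standard deviation of the LM basin sizes."""
        return float(np.std(list(self.basin_sizes.values())))


def build_landscape(model_or_energies, n_channels: int | None = None) -> EnergyLandscape:
    """Construct the full landscape from a fitted model or an energy vector."""
    if isinstance(model_or_energies, PMEMModel):
        energies = model_or_energies.energies
        n_channels = model_or_energies.n_channels
    else:
        energies = np.asarray(model_or_energies, dtype=float)
        if n_channels is None:
            n_channels = int(round(np.log2(energies.size)))
        if energies.size != 2**n_channels:
            raise ValueError("energies must have length 2^C")
    local_minima, global_minimum = find_minima(energies, n_channels)
    basin_of, basin_sizes = assign_basins(energies, n_channels)
    return EnergyLandscape(
        energies=energies,
        n_channels=n_channels,
        local_minima=local_minima,
        global_minimum=global_minimum,
        basin_of=basin_of,
        basin_sizes=basin_sizes,
    )


@dataclass
class WalkResult:
    trajectory: np.ndarray
    seed: int | None
    n_steps: int


def random_walk(
    energies: np.ndarray,
    n_channels: int,
    n_steps: int = 20_000,
    start: int | None = None,
    seed: int | None = None,
    burn_in: int = 0,
) -> WalkResult:
    """Metropolis walk: propose a uniform Hamming-1 neighbor each step; accept
    if it lowers the energy, else with probability exp(E_cur - E_prop).

    Every iteration advances time by one step, accepted or not.  The start
    state is uniform over all states when not given.  ``burn_in`` extra steps
    are simulated and discarded before the recorded trajectory (default none).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    energies = np.asarray(energies, dtype=float)
    rng = np.random.default_rng(seed)
    n_states = 2**n_channels
    if energies.size != n_states:
        raise ValueError("energies must have length 2^C")
    state = int(rng.integers(n_states)) if start is None else int(start)
    if not 0 <= state < n_states:
        raise ValueError("start state out of range")
    total = burn_in + n_steps
    flips = 1 << (n_channels - 1 - rng.integers(0, n_channels, size=total))
    log_u = np.log(rng.random(size=total))
    trajectory = np.empty(n_steps, dtype=np.int64)
    e = energies
    for t in range(total):
        prop = state ^ int(flips[t])
        d = e[state] - e[prop]
        if d > 0 or log_u[t] < d:
            state = prop
        if t >= burn_in:
            trajectory[t - burn_in] = state
    return WalkResult(trajectory=trajectory, seed=seed, n_steps=n_steps)


@dataclass
class ELFeatures:
    """Per-landscape attractor features used for group statistics."""

    n_lm: int
    mean_gap: float
    basin_size_sd: float
    gm_duration: int                       # total walk steps inside the GM basin
    major_state_durations: dict[int, float] = field(default_factory=dict)
    major_state_occupancy: dict[int, int] = field(default_factory=dict)
    n_steps: int = 0


def _mean_run_length(in_basin: np.ndarray) -> float:
    """Mean length of maximal consecutive runs of True (0.0 if never visited)."""
    if not in_basin.any():
        return 0.0
    padded = np.concatenate(([False], in_basin, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return float(np.mean(ends - starts))


def dwell_features(
    walk: WalkResult,
    landscape: EnergyLandscape,
    major_states: list[int] | None = None,
) -> ELFeatures:
    """Combine landscape structure with walk dwell statistics.

    ``gm_duration`` is the total occupancy (steps) of the GM basin.  For each
    major state, the mean dwell per visit (mean maximal run length inside the
    basin owning that state) and the total occupancy are both reported.  A
    major state that is not an LM here is mapped to the LM owning its basin,
    with a warning.
    """
    basin_labels = landscape.basin_of[walk.trajectory]
    gm_duration = int(np.sum(basin_labels == landscape.global_minimum))
    durations: dict[int, float] = {}
    occupancy: dict[int, int] = {}
    for state in major_states or ():
        owner = int(landscape.basin_of[state])
        if state not in landscape.local_minima:
            warnings.warn(
                f"major state {state} is not an LM of this landscape; "
                f"using the basin of its owning LM {owner}",
                RuntimeWarning,
            )
        in_basin = basin_labels == owner
        durations[state] = _mean_run_length(in_basin)
        occupancy[state] = int(in_basin.sum())
    return ELFeatures(
        n_lm=landscape.n_local_minima,
        mean_gap=landscape.mean_gap(),
        basin_size_sd=landscape.basin_size_sd(),
        gm_duration=gm_duration,
        major_state_durations=durations,
        major_state_occupancy=occupancy,
        n_steps=walk.n_steps,
    )


def find_major_states(
    landscapes: list[EnergyLandscape], top: int = 6
) -> tuple[list[int], list[tuple[int, int]]]:
    """States selected as an LM by *every* landscape, plus the ``top`` most
    frequent LMs (state, count) across landscapes."""
    if not landscapes:
        raise ValueError("at least one landscape is required")
    counts: dict[int, int] = {}
    for ls in landscapes:
        for lm in ls.local_minima:
            counts[lm] = counts.get(lm, 0) + 1
    shared = sorted(s for s, c in counts.items() if c == len(landscapes))
    if not shared:
        warnings.warn("no state is an LM of every landscape", RuntimeWarning)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return shared, ranked
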