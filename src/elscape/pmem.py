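"""Pairwise maximum-entropy (Ising/Boltzmann) modelling of binarized channel states.

The model over spin vectors ``s ∈ {-1,+1}^C`` is

    P(s | h, J) = exp(-E(s)) / Z,
    E(s) = - h·s - (1/2) sᵀ J s,

with fields ``h`` (per-channel baseline activity) and symmetric, zero-diagonal
couplings ``J`` (pairwise interactions).  Two estimators are provided: a
pseudo-likelihood maximizer operating on observed state counts, and an
exact-gradient moment matcher that equates model and empirical first/second
moments by full enumeration of the 2^C states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "BinaryStateSeries",
    "EmpiricalStats",
    "PMEMModel",
    "AccuracyIndex",
    "state_table",
    "encode_states",
    "decode_state",
    "state_string",
    "binarize",
    "empirical_stats",
    "boltzmann",
    "energies",
    "fit_independent_mem",
    "fit_pmem",
    "accuracy_index",
]


# ---------------------------------------------------------------------------
# state coding
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def state_table(n_channels: int) -> np.ndarray:
    """All 2^C spin vectors, row ``i`` being the decoding of state index ``i``.

    Channel 0 (the first / highest-ranked channel) is the most significant
    bit: the all-(-1) state is index 0 and flipping channel 0 adds 2^(C-1).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    idx = np.arange(2**n_channels)
    bits = (idx[:, None] >> np.arange(n_channels - 1, -1, -1)[None, :]) & 1
    table = (2 * bits - 1).astype(np.int8)
    table.setflags(write=False)
    return table


def encode_states(spins: np.ndarray) -> np.ndarray:
    """Map spin vectors (rows, entries ±1) to state indices in [0, 2^C)."""
    spins = np.asarray(spins)
    if spins.ndim == 1:
        spins = spins[None, :]
    if not np.isin(spins, (-1, 1)).all():
        raise ValueError("spin entries must be -1 or +1")
    n_channels = spins.shape[1]
    powers = 1 << np.arange(n_channels - 1, -1, -1)
    return ((spins > 0).astype(np.int64) @ powers).astype(np.int64)


def decode_state(index: int, n_channels: int) -> np.ndarray:
    """Inverse of :func:`encode_states` for a single index."""
    if not 0 <= index < 2**n_channels:
        raise ValueError(f"state index {index} out of range for C={n_channels}")
    return state_table(n_channels)[index].copy()


def state_string(index: int, n_channels: int) -> str:
    """Display form: '1' for spin +1, first channel leftmost (e.g. '0000111')."""
    return format(index, f"0{n_channels}b")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BinaryStateSeries:
    """A time series of spin vectors over the selected channels."""

    spins: np.ndarray  # (F, C), entries in {-1, +1}
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins, dtype=np.int8)
        if self.spins.ndim != 2 or self.spins.shape[0] < 1:
            raise ValueError("spins must be a non-empty (F, C) matrix")
        if not np.isin(self.spins, (-1, 1)).all():
            raise ValueError("spin entries must be -1 or +1")

    @property
    def n_samples(self) -> int:
        return self.spins.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spins.shape[1]

    def state_indices(self) -> np.ndarray:
        return encode_states(self.spins)


@dataclass
class EmpiricalStats:
    """Empirical state distribution and first/second moments."""

    probs: np.ndarray      # (2^C,) empirical state probabilities
    counts: np.ndarray     # (2^C,) occurrence counts (may be fractional weights)
    act: np.ndarray        # (C,) mean spin per channel
    cooc: np.ndarray       # (C, C) mean pairwise spin product, unit diagonal

    @property
    def n_channels(self) -> int:
        return self.act.shape[0]

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"empirical probabilities sum to {total}, not 1")
        if (self.probs < -1e-15).any():
            raise ValueError("empirical probabilities must be non-negative")


@dataclass
class PMEMModel:
    """Fitted pairwise maximum-entropy model."""

    h: np.ndarray
    J: np.ndarray
    iterations: int = 0
    final_update: float = np.nan
    converged: bool = True
    mode: str = "exact"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-12):
            raise ValueError("J must have zero diagonal")

    @property
    def n_channels(self) -> int:
        return self.h.shape[0]

    @property
    def energies(self) -> np.ndarray:
        return energies(self.h, self.J)

    @property
    def probs(self) -> np.ndarray:
        return boltzmann(self.h, self.J)

    def model_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Activation rates and co-occurrences under the model (enumeration)."""
        table = state_table(self.n_channels).astype(float)
        p = self.probs
        act = table.T @ p
        cooc = (table * p[:, None]).T @ table
        np.fill_diagonal(cooc, 1.0)
        return act, cooc


@dataclass
class AccuracyIndex:
    """Fit-quality index r = (K1 - K2)/K1 from base-2 KL divergences."""

    k1: float
    k2: float
    r: float


# ---------------------------------------------------------------------------
# binarization and empirical statistics
# ---------------------------------------------------------------------------

def binarize(signal: np.ndarray, channels=None, channel_ids=None) -> BinaryStateSeries:
    """Threshold each channel at its own mean: above the mean -> +1, else -1.

    Thresholds are computed on exactly the samples given (i.e. per stimulus
    segment, per participant, per channel).  ``channels`` optionally selects
    column indices; a zero-variance channel is an error because its mean
    threshold is meaningless.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[0] < 1:
        raise ValueError("signal must be a non-empty (time, channels) matrix")
    if channels is not None:
        signal = signal[:, list(channels)]
        if channel_ids is None:
            channel_ids = [f"ch{c}" for c in channels]
    variances = signal.var(axis=0)
    dead = np.flatnonzero(variances == 0.0)
    if dead.size:
        names = (
            [channel_ids[d] for d in dead]
            if channel_ids is not None
            else dead.tolist()
        )
        raise ValueError(f"zero-variance channel(s) cannot be binarized: {names}")
    spins = np.where(signal > signal.mean(axis=0, keepdims=True), 1, -1)
    return BinaryStateSeries(spins.astype(np.int8), channels=channel_ids)


def empirical_stats(states: BinaryStateSeries) -> EmpiricalStats:
    """State probabilities (counts / F) and per-channel moments."""
    n_channels = states.n_channels
    idx = states.state_indices()
    counts = np.bincount(idx, minlength=2**n_channels).astype(float)
    probs = counts / counts.sum()
    spins = states.spins.astype(float)
    act = spins.mean(axis=0)
    cooc = spins.T @ spins / states.n_samples
    np.fill_diagonal(cooc, 1.0)
    return EmpiricalStats(probs=probs, counts=counts, act=act, cooc=cooc)


def _stats_from_probs(probs: np.ndarray, n_channels: int) -> EmpiricalStats:
    table = state_table(n_channels).astype(float)
    act = table.T @ probs
    cooc = (table * probs[:, None]).T @ table
    np.fill_diagonal(cooc, 1.0)
    return EmpiricalStats(probs=probs, counts=probs.copy(), act=act, cooc=cooc)


def stats_from_distribution(probs: np.ndarray) -> EmpiricalStats:
    """Treat an exact 2^C distribution as 'empirical' statistics."""
    probs = np.asarray(probs, dtype=float)
    n_channels = int(round(np.log2(probs.size)))
    if 2**n_channels != probs.size:
        raise ValueError("distribution length must be a power of two")
    return _stats_from_probs(probs, n_channels)


# ---------------------------------------------------------------------------
# the Boltzmann model
# ---------------------------------------------------------------------------

def energies(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """E(s) = -h·s - (1/2) sᵀJs for every state s, in index order."""
    h = np.asarray(h, dtype=float)
    J = np.asarray(J, dtype=float)
    table = state_table(h.shape[0]).astype(float)
    return -table @ h - 0.5 * np.einsum("ic,cd,id->i", table, J, table)


def boltzmann(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Normalized Boltzmann distribution exp(-E)/Z over all states."""
    e = energies(h, J)
    w = np.exp(-(e - e.min()))  # gauge shift for numerical stability
    return w / w.sum()


def fit_independent_mem(stats: EmpiricalStats) -> PMEMModel:
    """Closed-form independent model (J = 0): h_m = atanh(<σ_m>)."""
    act = stats.act
    if (np.abs(act) >= 1.0).any():
        sat = np.flatnonzero(np.abs(act) >= 1.0).tolist()
        raise ValueError(f"saturated channel(s) {sat}: |activation| = 1, h diverges")
    h = np.arctanh(act)
    return PMEMModel(h=h, J=np.zeros((act.size, act.size)), mode="independent")


_MAX_CHANNELS = 12


def _check_enumerable(n_channels: int) -> None:
    if n_channels > _MAX_CHANNELS:
        raise ValueError(
            f"C={n_channels} channels would require enumerating 2^{n_channels} "
            f"states; refusing above C={_MAX_CHANNELS}"
        )


def fit_pmem(
    data,
    mode: str = "pl",
    learning_rate: float = 0.1,
    tol: float = 5e-6,
    max_iter: int = 200_000,
) -> PMEMModel:
    """Fit (h, J) by gradient ascent; stop when the largest parameter update
    falls below ``tol``.

    mode 'pl'    — pseudo-likelihood: ascend the sum over channels and samples
                   of the logistic conditional log-likelihood of each spin
                   given the others.  Works from state counts, so runtime is
                   independent of the number of samples.
    mode 'exact' — exact likelihood gradient: empirical minus model moments,
                   model moments computed by enumerating all 2^C states.
    """
    if mode not in ("pl", "exact"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if isinstance(data, BinaryStateSeries):
        stats = empirical_stats(data)
    elif isinstance(data, EmpiricalStats):
        stats = data
    else:
        raise TypeError("data must be a BinaryStateSeries or EmpiricalStats")
    n_channels = stats.n_channels
    _check_enumerable(n_channels)
    table = state_table(n_channels).astype(float)

    h = np.zeros(n_channels)
    J = np.zeros((n_channels, n_channels))
    weights = stats.probs  # observed states weighted by relative frequency
    support = weights > 0
    w = weights[support]
    s_obs = table[support]

    final_update = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if mode == "pl":
            theta = h[None, :] + s_obs @ J  # J symmetric, zero diagonal
            resid = w[:, None] * (s_obs - np.tanh(theta))
            grad_h = resid.sum(axis=0)
            grad_J = resid.T @ s_obs
            grad_J = grad_J + grad_J.T
            np.fill_diagonal(grad_J, 0.0)
        else:
            e = -table @ h - 0.5 * np.einsum("ic,cd,id->i", table, J, table)
            p = np.exp(-(e - e.min()))
            p /= p.sum()
            act_mod = table.T @ p
            cooc_mod = (table * p[:, None]).T @ table
            grad_h = stats.act - act_mod
            grad_J = stats.cooc - cooc_mod
            np.fill_diagonal(grad_J, 0.0)
        dh = learning_rate * grad_h
        dJ = learning_rate * grad_J
        h += dh
        J += dJ
        final_update = float(max(np.abs(dh).max(), np.abs(dJ).max()))
        if final_update < tol:
            break
    converged = bool(final_update < tol)
    if not converged:
        warnings.warn(
            f"pMEM fit ({mode}) did not converge in {max_iter} iterations "
            f"(last update {final_update:.2e})",
            RuntimeWarning,
        )
    return PMEMModel(
        h=h,
        J=J,
        iterations=iterations,
        final_update=final_update,
        converged=converged,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# accuracy index
# ---------------------------------------------------------------------------

def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 KL divergence with the 0·log(0/q) = 0 convention."""
    mask = p > 0
    if (q[mask] <= 0).any():
        raise ValueError("model assigns zero probability to an observed state")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def accuracy_index(
    empirical_probs: np.ndarray, pmem: PMEMModel, mem: PMEMModel
) -> AccuracyIndex:
    """r = (K1 - K2)/K1 where K1 (K2) is KL(empirical ‖ independent (pairwise))."""
    p = np.asarray(empirical_probs, dtype=float)
    k1 = _kl_bits(p, mem.probs)
    k2 = _kl_bits(p, pmem.probs)
    if k1 <= 1e-12:  # numerically zero: empirical is already independent
        warnings.warn(
            "empirical distribution is exactly independent (K1 = 0); r set to 0",
            RuntimeWarning,
        )
        return AccuracyIndex(k1=k1, k2=k2, r=0.0)
    return AccuracyIndex(k1=k1, k2=k2, r=(k1 - k2) / k1)
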