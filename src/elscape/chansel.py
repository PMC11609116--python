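"""Data-driven channel selection via CANDECOMP/PARAFAC tensor decomposition.

The per-category cohort data (time-points × channels × subjects) is
decomposed into a sum of rank-one tensors by alternating least squares.
Channels are then ranked by the row means of the Pearson correlation matrix
of the channel-mode factor matrix, and the top-k are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CPDResult",
    "ChannelRanking",
    "build_cohort_tensor",
    "cpd_als",
    "rank_channels",
    "select_channels",
]


@dataclass
class CPDResult:
    A: np.ndarray              # (F, T) time/frequency-mode factors, unit columns
    B: np.ndarray              # (C, T) channel-mode factors, unit columns
    D: np.ndarray              # (S, T) subject-mode factors, unit columns
    weights: np.ndarray        # (T,) non-negative component weights
    rank: int
    rel_error: float           # final relative reconstruction error
    error_history: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True

    def reconstruct(self) -> np.ndarray:
        return np.einsum("t,ft,ct,st->fcs", self.weights, self.A, self.B, self.D)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # column-wise Kronecker product, (I*J, T)
    t = u.shape[1]
    return (u[:, None, :] * v[None, :, :]).reshape(-1, t)


def _als_run(x, rank, tol, max_iter, rng):
    shape = x.shape
    factors = [rng.standard_normal((dim, rank)) for dim in shape]
    norm_x = np.linalg.norm(x)
    unfolds = [_unfold(x, m) for m in range(3)]
    history: list[float] = []
    err_prev = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # khatri-rao in reversed-mode order matches the unfolding layout
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            factors[mode] = unfolds[mode] @ kr @ np.linalg.pinv(gram)
        rec = np.einsum("ft,ct,st->fcs", *factors)
        err = np.linalg.norm(x - rec) / norm_x
        history.append(err)
        if err_prev - err < tol * max(err_prev, 1e-30):
            converged = True
            break
        err_prev = err
    return factors, history, iterations, converged


def cpd_als(
    tensor: np.ndarray,
    rank: int,
    tol: float = 1e-7,
    max_iter: int = 200,
    seed: int | None = 0,
    n_restarts: int = 5,
) -> CPDResult:
    """Rank-``rank`` CPD of a 3-way tensor by seeded ALS with restarts.

    The reconstruction error is non-increasing across sweeps (a property of
    exact alternating least squares); the best of ``n_restarts`` random
    initializations is kept.  Factor columns are normalized to unit length
    with the scales absorbed into a non-negative weight vector; the sign of
    the time- and channel-mode columns is fixed by making their
    largest-magnitude entry positive (the residual sign lives in the
    subject-mode factor).
    """
    x = np.asarray(tensor, dtype=float)
    if x.ndim != 3:
        raise ValueError("tensor must be 3-way")
    if not np.isfinite(x).all():
        raise ValueError("tensor entries must be finite")
    if np.linalg.norm(x) == 0:
        raise ValueError("degenerate all-zero tensor cannot be decomposed")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        factors, history, iterations, converged = _als_run(x, rank, tol, max_iter, rng)
        if best is None or history[-1] < best[1][-1]:
            best = (factors, history, iterations, converged)
    factors, history, iterations, converged = best
    if not converged:
        warnings.warn("CPD-ALS did not converge within max_iter", RuntimeWarning)

    a, b, d = factors
    norms = [np.linalg.norm(f, axis=0) for f in (a, b, d)]
    weights = norms[0] * norms[1] * norms[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, d = (
            np.where(n > 0, f / np.where(n > 0, n, 1.0), f)
            for f, n in zip((a, b, d), norms)
        )
    a, b, d = list((a, b, d))
    for f in (a, b):
        lead = f[np.abs(f).argmax(axis=0), np.arange(f.shape[1])]
        flip = np.where(lead < 0, -1.0, 1.0)
        f *= flip
        d *= flip
    order = np.argsort(-weights)
    return CPDResult(
        A=a[:, order],
        B=b[:, order],
        D=d[:, order],
        weights=weights[order],
        rank=rank,
        rel_error=history[-1],
        error_history=history,
        iterations=iterations,
        converged=converged,
    )


@dataclass
class ChannelRanking:
    P: np.ndarray              # (C, C) Pearson correlations of channel profiles
    row_means: np.ndarray      # (C,)
    order: list[int]           # channel indices, descending row mean
    top_k: list[int]           # first k of order


def rank_channels(B: np.ndarray, k: int | None = None) -> ChannelRanking:
    """Rank channels by the row means of the correlation matrix of ``B``.

    Each channel's profile is its row of the channel-mode factor matrix;
    ties are broken by ascending channel index.  A zero-variance profile has
    undefined correlations and is ranked last, with a warning.
    """
    B = np.asarray(B, dtype=float)
    n_channels, rank = B.shape
    if n_channels < 2 or rank < 2:
        raise ValueError("need >= 2 channels and >= 2 components to correlate")
    sd = B.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        P = np.corrcoef(B)
    P = np.clip(P, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    row_means = np.nanmean(np.where(np.isfinite(P), P, np.nan), axis=1)
    if dead.size:
        warnings.warn(
            f"channel profile(s) {dead.tolist()} have zero variance; ranked last",
            RuntimeWarning,
        )
        row_means[dead] = -np.inf
    order = sorted(range(n_channels), key=lambda c: (-row_means[c], c))
    top_k = order[: k if k is not None else n_channels]
    return ChannelRanking(P=P, row_means=row_means, order=order, top_k=top_k)


def build_cohort_tensor(
    segments: list, representation: str = "time", nperseg: int = 128
) -> np.ndarray:
    """Stack per-subject category segments into an (F, C, S) tensor.

    ``representation='time'`` uses the raw time axis as the first mode;
    ``'spectral'`` replaces it with a Welch periodogram per channel.
    """
    mats = []
    for seg in segments:
        sig = np.asarray(seg.signal if hasattr(seg, "signal") else seg, dtype=float)
        if representation == "spectral":
            _, pxx = sps.welch(sig, axis=0, nperseg=min(nperseg, sig.shape[0]))
            sig = pxx
        mats.append(sig)
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"subjects have inconsistent segment shapes: {sorted(shapes)}")
    return np.stack(mats, axis=2)


def select_channels(
    segments: list,
    rank: int = 10,
    k: int = 7,
    seed: int | None = 0,
    representation: str = "time",
    **cpd_kwargs,
) -> tuple[list[int], ChannelRanking, CPDResult]:
    """CPD + correlation ranking over one category's cohort; returns the top-k
    channel indices along with the full ranking and decomposition."""
    tensor = build_cohort_tensor(segments, representation=representation)
    if k > tensor.shape[1]:
        raise ValueError(f"k={k} exceeds the {tensor.shape[1]} available channels")
    result = cpd_als(tensor, rank=rank, seed=seed, **cpd_kwargs)
    ranking = rank_channels(result.B, k=k)
    return ranking.top_k, ranking, result
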