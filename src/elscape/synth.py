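"""Synthetic two-group cohort generator.

Generates multichannel recordings whose binarized dynamics on a small set of
"informative" channels follow group-specific Boltzmann distributions with
planted landscape differences, so the whole downstream pipeline can be
exercised and validated without any clinical data.

Both groups share one block-structured coupling architecture with two
complementary deep wells that are local minima for every subject — the
shared "major states" (``1111000``/``0000111`` in the "blocks" gauge).
The groups differ only in their baseline drive: the patient-like group
("MDD") runs the same circuitry under a stronger, frustrated field.  On the
landscape this yields more local minima, smaller minimum-to-minimum energy
gaps, more uniform basin sizes, and heavier occupancy of the global-minimum
basin (the four planted directions), while the coupling distribution — the
source of the connectivity features — is identical across groups, so energy
features carry strictly more diagnostic signal than connectivity features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import Annotation, Recording
from .pmem import BinaryStateSeries, boltzmann, state_table

__all__ = [
    "GroupParams",
    "CohortConfig",
    "GroundTruth",
    "sample_pmem_states",
    "spins_to_continuous",
    "draw_subject_params",
    "generate_state_cohort",
    "generate_cohort",
    "make_demographics",
]

CATEGORY_ORDER = ("happy", "calm", "fear", "noise")

# per-category multiplier on the planted group difference; uniform by default
# (experiments can grade it, e.g. strongest under fear) because intermediate
# interpolations of the two group architectures do not preserve the planted
# feature directions
DEFAULT_CATEGORY_GAIN = {"happy": 1.0, "calm": 1.0, "fear": 1.0, "noise": 1.0}


@dataclass
class GroupParams:
    """Per-group generating distribution for (h, J) on the shared
    architecture.

    ``j_scale`` multiplies the cohort-level coupling architecture;
    ``h_base`` is the group's deterministic field vector (length C).
    Per-subject variability enters through ``subject_sd`` (couplings),
    ``sigma_j`` (an optional extra rugged component, redrawn per subject)
    and ``h_sd`` (fields).
    """

    j_scale: float = 1.0
    h_base: tuple[float, ...] | None = None   # None -> zero field
    h_sd: float = 0.02
    subject_sd: float = 0.03
    sigma_j: float = 0.0

    def field_vector(self, n_channels: int) -> np.ndarray:
        if self.h_base is None:
            return np.zeros(n_channels)
        h = np.asarray(self.h_base, dtype=float)
        if h.shape != (n_channels,):
            raise ValueError(
                f"h_base has length {h.size}, expected {n_channels}"
            )
        return h


def _orthogonal_field(n_channels: int) -> np.ndarray:
    """All-positive unit-scale field with zero projection on the well
    pattern: it singles out the all-up mixed state as a third, high-energy
    local minimum without unbalancing the two wells."""
    pattern = _block_pattern(n_channels)
    n_up = int(np.sum(pattern > 0))
    return np.where(pattern > 0, (n_channels - n_up) / n_up, 1.0)


def default_group_params(
    n_channels: int = 7, gauge: str = "uniform"
) -> dict[str, GroupParams]:
    """Defaults tuned so that at n = 30/group the pipeline recovers the four
    planted directions (more LMs, smaller gaps, smaller basin-size spread,
    longer GM dwell in "MDD") and so that energy features out-classify
    connectivity features.

    The fields are expressed in the requested architecture gauge (they are
    related by per-channel sign flips along the block pattern).
    """
    # "blocks"-gauge values; hc singles out one mixed state as a third,
    # high-energy LM; the MDD vector is a frustrated drive tuned on the
    # shared architecture: it fragments the landscape into extra shallow
    # minima while concentrating probability mass in the GM basin
    hc_field = 0.20 * _orthogonal_field(n_channels)
    mdd_field = np.array((-0.78, 0.19, 0.38, -0.66, 0.19, -0.54, -0.81)[:n_channels])
    if gauge == "uniform":
        pattern = _block_pattern(n_channels)
        hc_field = hc_field * pattern
        mdd_field = mdd_field * pattern
    return {
        "HC": GroupParams(j_scale=1.0, h_base=tuple(hc_field)),
        "MDD": GroupParams(j_scale=1.0, h_base=tuple(mdd_field)),
    }


@dataclass
class CohortConfig:
    n_per_group: int = 30
    n_channels_full: int = 22
    n_selected: int = 7
    sampling_rate_hz: float = 7.81
    n_blocks: int = 4
    trial_s: float = 18.0
    rest_s: float = 20.0
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    # shared coupling architecture (see _architecture)
    arch_j_intra: float = 0.20
    arch_j_intra2: float = 0.25
    arch_j_inter: float = -0.12
    arch_sigma: float = 0.03
    arch_seed: int = 101
    arch_gauge: str = "uniform"   # "uniform" | "blocks" (see _architecture)
    effect: float = 1.0   # 0 = groups identical, 1 = full planted difference
    category_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_GAIN)
    )
    noise_sd: float = 0.1
    smooth_sigma: float = 0.0   # samples; 0 disables waveform smoothing
    amplitude: float = 1.0
    # stimulus-evoked response on informative channels: a mixture of slow
    # trial-locked temporal components with channel-specific gains, so the
    # cohort tensor carries shared spatio-temporal structure that channel
    # ranking can exploit.  Kept below the spin amplitude gap so
    # mean-threshold binarization is unaffected.
    evoked_amp: float = 0.5
    n_evoked_components: int = 3
    background_ar: float = 0.9
    background_shared: float = 0.0
    informative_channels: tuple[int, ...] = (1, 6, 8, 13, 15, 20, 21)
    markov_persistence: float = 0.0   # 0 = i.i.d. state draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_selected > self.n_channels_full:
            raise ValueError("n_selected cannot exceed n_channels_full")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.markov_persistence < 1:
            raise ValueError("markov_persistence must be in [0, 1)")
        if self.arch_sigma < 0:
            raise ValueError("arch_sigma must be >= 0")
        if self.arch_gauge not in ("uniform", "blocks"):
            raise ValueError("arch_gauge must be 'uniform' or 'blocks'")
        for g, p in self.group_params.items():
            if p.sigma_j < 0:
                raise ValueError(f"group_params[{g!r}].sigma_j must be >= 0")
            if p.h_sd < 0 or p.subject_sd < 0:
                raise ValueError(f"group_params[{g!r}] jitter sds must be >= 0")
            p.field_vector(self.n_selected)  # validates length
        if len(self.informative_channels) != self.n_selected:
            raise ValueError(
                "informative_channels must list exactly n_selected channel indices"
            )

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_s * self.sampling_rate_hz))


@dataclass
class GroundTruth:
    """Generating parameters and state sequences for every subject."""

    groups: dict[str, str]                                   # subject -> group
    h: dict[tuple[str, str], np.ndarray]                     # (subject, category)
    J: dict[tuple[str, str], np.ndarray]
    states: dict[tuple[str, str], np.ndarray]                # planted spin series
    informative_channels: tuple[int, ...] = ()

    def to_json(self, path) -> None:
        payload = {
            "groups": self.groups,
            "informative_channels": list(self.informative_channels),
            "subjects": {
                f"{s}|{c}": {
                    "h": self.h[(s, c)].tolist(),
                    "J": self.J[(s, c)].tolist(),
                    "states": self.states[(s, c)].tolist(),
                }
                for (s, c) in self.h
            },
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def sample_pmem_states(
    h: np.ndarray,
    J: np.ndarray,
    n_samples: int,
    seed=None,
    persistence: float = 0.0,
) -> BinaryStateSeries:
    """Draw spin vectors from the exact Boltzmann distribution P(s | h, J).

    All 2^C state probabilities are enumerated, so this refuses C > 12.
    With ``persistence`` ρ > 0 the draw is a sticky chain (keep the previous
    state with probability ρ, else redraw i.i.d.), which preserves the
    stationary distribution while adding temporal autocorrelation.
    """
    h = np.asarray(h, dtype=float)
    J = np.asarray(J, dtype=float)
    n_channels = h.shape[0]
    if n_channels > 12:
        raise ValueError(
            f"refusing to enumerate 2^{n_channels} states; C must be <= 12"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not np.allclose(J, J.T):
        raise ValueError("J must be symmetric")
    rng = np.random.default_rng(seed)
    probs = boltzmann(h, J)
    idx = rng.choice(probs.size, size=n_samples, p=probs)
    if persistence > 0:
        keep = rng.random(n_samples) < persistence
        keep[0] = False
        for t in range(1, n_samples):
            if keep[t]:
                idx[t] = idx[t - 1]
    return BinaryStateSeries(state_table(n_channels)[idx])


def spins_to_continuous(
    states: BinaryStateSeries,
    fs: float = 7.81,
    noise_sd: float = 0.0,
    seed=None,
    amplitude: float = 1.0,
    smooth_sigma: float = 0.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Emit a continuous waveform per channel that binarizes back to the spins.

    Each channel sits ``amplitude`` above ``baseline`` where the spin is +1
    and below where it is -1, optionally smoothed with a Gaussian kernel
    (``smooth_sigma`` in samples) and corrupted with Gaussian noise.  In the
    noiseless, unsmoothed limit mean-threshold binarization recovers the
    planted spins exactly (for any non-constant channel).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if states.n_samples < 1:
        raise ValueError("empty state series")
    rng = np.random.default_rng(seed)
    sig = baseline + amplitude * states.spins.astype(float)
    if smooth_sigma > 0:
        sig = gaussian_filter1d(sig, sigma=smooth_sigma, axis=0)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    return sig


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _block_pattern(n_channels: int) -> np.ndarray:
    pattern = np.ones(n_channels)
    pattern[(n_channels + 1) // 2 :] = -1.0
    return pattern


def _architecture(config: "CohortConfig") -> np.ndarray:
    """The cohort-level coupling architecture shared by both groups: two
    coupled channel blocks plus a small fixed rough component (seeded at the
    cohort level, identical for everyone).

    In the ``"blocks"`` gauge the blocks repel and the two deep wells sit at
    the complementary block patterns (``1111000``/``0000111``).  The default
    ``"uniform"`` gauge applies the spin-flip transform ε = block pattern,
    which makes every mean coupling positive (so the informative channels
    correlate positively, as channel ranking assumes) and moves the wells to
    the all-down/all-up states.  The two gauges generate landscapes with
    identical attractor structure (state relabeling only).
    """
    c = config.n_selected
    pattern = _block_pattern(c)
    up = pattern > 0
    J = np.full((c, c), config.arch_j_inter, dtype=float)
    J[np.ix_(up, up)] = config.arch_j_intra
    J[np.ix_(~up, ~up)] = config.arch_j_intra2
    np.fill_diagonal(J, 0.0)
    J += _symmetric_noise(
        np.random.default_rng(config.arch_seed), c, config.arch_sigma
    )
    if config.arch_gauge == "uniform":
        J = J * np.outer(pattern, pattern)
    return J


def _base_params(config: "CohortConfig", group: str, category: str) -> GroupParams:
    """Effective generating parameters: HC params plus a scaled step toward
    the raw MDD params (scaled by the global effect knob and the per-category
    gain)."""
    hc = config.group_params["HC"]
    if group == "HC":
        return hc
    target = config.group_params[group]
    gain = config.effect * config.category_gain.get(category, 1.0)
    if gain == 0:
        return hc  # no planted difference: groups share one generating model
    c = config.n_selected
    mix = lambda a, b: a + gain * (b - a)
    h_mix = hc.field_vector(c) + gain * (
        target.field_vector(c) - hc.field_vector(c)
    )
    return GroupParams(
        j_scale=mix(hc.j_scale, target.j_scale),
        h_base=tuple(h_mix),
        h_sd=mix(hc.h_sd, target.h_sd),
        subject_sd=mix(hc.subject_sd, target.subject_sd),
        sigma_j=mix(hc.sigma_j, target.sigma_j),
    )


def _symmetric_noise(rng, n: int, sd: float) -> np.ndarray:
    m = rng.normal(0.0, sd, size=(n, n))
    m = (m + m.T) / np.sqrt(2.0)
    np.fill_diagonal(m, 0.0)
    return m


def draw_subject_params(
    config: CohortConfig, group: str, category: str, rng
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's generating (h*, J*) for one stimulus category."""
    c = config.n_selected
    p = _base_params(config, group, category)
    J = p.j_scale * _architecture(config)
    J += _symmetric_noise(rng, c, p.subject_sd)
    if p.sigma_j > 0:
        J += _symmetric_noise(rng, c, p.sigma_j)
    h = p.field_vector(c) + rng.normal(0.0, p.h_sd, size=c)
    return h, J


def generate_state_cohort(
    config: CohortConfig,
) -> tuple[dict[tuple[str, str], BinaryStateSeries], GroundTruth]:
    """Planted binarized dynamics per (subject, category), plus ground truth.

    Each category carries ``n_blocks * samples_per_trial`` samples (all trials
    of the category concatenated), matching what segmentation of the full
    continuous recording would yield.
    """
    rng = np.random.default_rng(config.seed)
    n_cat_samples = config.n_blocks * config.samples_per_trial
    series: dict[tuple[str, str], BinaryStateSeries] = {}
    truth = GroundTruth(
        groups={}, h={}, J={}, states={},
        informative_channels=config.informative_channels,
    )
    for group in ("MDD", "HC"):
        for i in range(config.n_per_group):
            subject = f"{group.lower()}{i:03d}"
            truth.groups[subject] = group
            for category in CATEGORY_ORDER:
                h, J = draw_subject_params(config, group, category, rng)
                states = sample_pmem_states(
                    h, J, n_cat_samples,
                    seed=rng.integers(2**63),
                    persistence=config.markov_persistence,
                )
                key = (subject, category)
                series[key] = states
                truth.h[key] = h
                truth.J[key] = J
                truth.states[key] = states.spins.copy()
    return series, truth


def _latin_square(n: int, rng) -> np.ndarray:
    base = np.arange(n)
    rows = [np.roll(base, -r) for r in range(n)]
    square = np.array(rows)
    square = square[rng.permutation(n)][:, rng.permutation(n)]
    return square


def generate_cohort(config: CohortConfig) -> tuple[list[Recording], GroundTruth]:
    """Full continuous-signal cohort: informative channels driven by the
    planted state dynamics, background channels as weakly shared AR(1) noise,
    trials in a Latin-square order with rests between them."""
    state_series, truth = generate_state_cohort(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**63) + 1)
    fs = config.sampling_rate_hz
    spt = config.samples_per_trial
    rest_n = int(round(config.rest_s * fs))
    n_types = len(CATEGORY_ORDER)
    recordings: list[Recording] = []
    informative = list(config.informative_channels)
    background = [c for c in range(config.n_channels_full) if c not in informative]
    # cohort-level evoked structure: K slow temporal shapes with fixed
    # channel-specific positive gains on the informative channels
    u = np.arange(spt) / max(spt - 1, 1)
    shapes = [np.sin(np.pi * u) ** 2]
    if config.n_evoked_components >= 2:
        shapes.append(2 * (1 - u) * np.sin(np.pi * u) ** 2)   # early-weighted
    if config.n_evoked_components >= 3:
        shapes.append(2 * u * np.sin(np.pi * u) ** 2)          # late-weighted
    shapes = np.stack(shapes[: max(1, config.n_evoked_components)], axis=1)
    gain_rng = np.random.default_rng(config.arch_seed + 7)
    evoked_gains = gain_rng.uniform(
        0.3, 1.0, size=(shapes.shape[1], len(informative))
    )
    evoked = config.evoked_amp * shapes @ evoked_gains / shapes.shape[1]
    for subject, group in truth.groups.items():
        square = _latin_square(n_types, rng)
        # continuous timeline: rest, trial, rest, trial, ... per block
        trial_order = [CATEGORY_ORDER[square[b % n_types, k]]
                       for b in range(config.n_blocks) for k in range(n_types)]
        total = len(trial_order) * (rest_n + spt)
        signal = np.zeros((total, config.n_channels_full))
        annotations: list[Annotation] = []
        consumed = {c: 0 for c in CATEGORY_ORDER}
        cursor = 0
        for category in trial_order:
            cursor += rest_n  # rest precedes every trial
            t0 = consumed[category]
            chunk = state_series[(subject, category)].spins[t0 : t0 + spt]
            consumed[category] += spt
            wave = spins_to_continuous(
                BinaryStateSeries(chunk),
                fs=fs,
                noise_sd=config.noise_sd,
                seed=rng.integers(2**63),
                amplitude=config.amplitude,
                smooth_sigma=config.smooth_sigma,
            )
            signal[cursor : cursor + spt, informative] = wave
            if config.evoked_amp:
                signal[cursor : cursor + spt, informative] += evoked
            annotations.append(
                Annotation(onset=cursor / fs, duration=spt / fs, label=category)
            )
            cursor += spt
        # rest-period activity on informative channels: noise around the
        # subject's tonic (mean-spin) level per channel, so trial onsets do
        # not inject a square wave at the channel's mean activation
        tonic = config.amplitude * np.mean(
            [state_series[(subject, cat)].spins.mean(axis=0)
             for cat in CATEGORY_ORDER],
            axis=0,
        )
        mask = np.ones(total, dtype=bool)
        for ann in annotations:
            s = int(round(ann.onset * fs))
            mask[s : s + spt] = False
        signal[np.ix_(mask, informative)] = tonic[None, :] + rng.normal(
            0.0, max(config.noise_sd, 0.05), size=(mask.sum(), len(informative))
        )
        # background channels: AR(1) plus a small shared component
        shared = rng.normal(size=total)
        for ch in background:
            eps = rng.normal(size=total)
            ar = np.empty(total)
            ar[0] = eps[0]
            a = config.background_ar
            for t in range(1, total):
                ar[t] = a * ar[t - 1] + eps[t]
            ar *= np.sqrt(1 - a**2)  # unit marginal variance
            signal[:, ch] = 0.5 * ar + config.background_shared * shared
        recordings.append(
            Recording(
                subject_id=subject,
                group=group,
                channel_ids=[f"ch{c + 1}" for c in range(config.n_channels_full)],
                fs=fs,
                signal=signal,
                annotations=annotations,
            )
        )
    return recordings, truth


def make_demographics(config: CohortConfig, seed=None) -> "pd.DataFrame":
    """Synthetic Table-1-style metadata: age, gender, and two severity scales
    (patients high, controls low)."""
    import pandas as pd

    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for group in ("MDD", "HC"):
        n = config.n_per_group
        if group == "MDD":
            age = rng.normal(37.63, 13.99, n)
            phq9 = np.clip(rng.normal(15.48, 4.94, n), 10, 27)
            hamd = np.clip(rng.normal(27.25, 5.66, n), 17, 52)
        else:
            age = rng.normal(36.95, 13.18, n)
            phq9 = np.clip(rng.normal(1.43, 1.61, n), 0, 4)
            hamd = np.clip(rng.normal(4.27, 2.50, n), 0, 7)
        age = np.clip(age, 18, 60)
        gender = np.array(["male", "female"] * ((n + 1) // 2))[:n]
        for i in range(n):
            rows.append(
                {
                    "subject": f"{group.lower()}{i:03d}",
                    "group": group,
                    "age": float(age[i]),
                    "gender": gender[i],
                    "phq9": float(phq9[i]),
                    "hamd17": float(hamd[i]),
                }
            )
    return pd.DataFrame(rows)
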