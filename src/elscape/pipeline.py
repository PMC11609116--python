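"""End-to-end orchestration: recordings -> models -> landscapes -> features.

Glue used by the CLI, the test suite and the acceptance script.  The heavy
lifting lives in the per-stage modules; this file only wires them together
deterministically (all walk seeds derive from one seed sequence).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import io as eio
from .landscape import build_landscape, dwell_features, random_walk
from .pmem import (
    BinaryStateSeries,
    accuracy_index,
    binarize,
    empirical_stats,
    fit_independent_mem,
    fit_pmem,
)

__all__ = ["analyze_state_cohort", "states_from_recording", "feature_table"]

ANALYSIS_CATEGORIES = ("happy", "calm", "fear", "full")


def states_from_recording(
    rec, channels: list[int], band=(0.01, 0.2), full_excludes_noise: bool = False
) -> dict[str, BinaryStateSeries]:
    """Filter, segment and binarize one recording on the selected channels.

    ``band=None`` skips filtering (synthetic cohorts plant broadband spin
    dynamics that a hemodynamic band-pass would remove)."""
    filtered = eio.bandpass(rec, *band) if band is not None else rec
    out = {}
    for category in ANALYSIS_CATEGORIES:
        seg = eio.segment(filtered, category, full_excludes_noise=full_excludes_noise)
        out[category] = binarize(
            seg.signal,
            channels=channels,
            channel_ids=[rec.channel_ids[c] for c in channels],
        )
    return out


def analyze_state_cohort(
    series: dict[tuple[str, str], BinaryStateSeries],
    groups: dict[str, str],
    categories=ANALYSIS_CATEGORIES,
    fit_mode: str = "pl",
    fit_tol: float = 5e-6,
    fit_max_iter: int = 20_000,
    n_steps: int = 20_000,
    major_states: list[int] | None = None,
    seed: int = 0,
):
    """Fit a pMEM, build the landscape and walk it for every
    (subject, category) pair; returns (feature table, models, landscapes,
    EL features).

    The 'full' category, when absent from ``series``, is formed by
    concatenating the subject's per-category state series.
    """
    sub_seeds = {}
    seq = np.random.SeedSequence(seed)
    models, landscapes, elfeats, rows = {}, {}, {}, []
    subjects = sorted(groups)
    children = seq.spawn(len(subjects) * len(categories))
    k = 0
    for subject in subjects:
        for category in categories:
            key = (subject, category)
            if key in series:
                states = series[key]
            elif category == "full":
                parts = [
                    series[(subject, c)].spins
                    for c in ("happy", "calm", "fear", "noise")
                    if (subject, c) in series
                ]
                if not parts:
                    raise ValueError(f"no state series for subject {subject}")
                states = BinaryStateSeries(np.concatenate(parts, axis=0))
            else:
                raise ValueError(f"missing state series for {key}")
            stats = empirical_stats(states)
            with warnings.catch_warnings():
                # near-boundary empirical moments can leave the last updates
                # hovering at the tolerance; the capped fit is still usable
                warnings.simplefilter("ignore", RuntimeWarning)
                model = fit_pmem(
                    stats, mode=fit_mode, tol=fit_tol, max_iter=fit_max_iter
                )
            mem = fit_independent_mem(stats)
            acc = accuracy_index(stats.probs, model, mem)
            ls = build_landscape(model)
            walk_seed = children[k]
            k += 1
            walk = random_walk(
                ls.energies, ls.n_channels, n_steps=n_steps,
                seed=walk_seed,
            )
            feats = dwell_features(walk, ls, major_states=major_states)
            models[key] = model
            landscapes[key] = ls
            elfeats[key] = feats
            row = {
                "subject": subject,
                "group": groups[subject],
                "stimulus": category,
                "r": acc.r,
                "k1": acc.k1,
                "k2": acc.k2,
                "n_lm": feats.n_lm,
                "mean_gap": feats.mean_gap,
                "basin_size_sd": feats.basin_size_sd,
                "gm_duration": feats.gm_duration,
            }
            for s, d in feats.major_state_durations.items():
                row[f"major_{s}_duration"] = d
            rows.append(row)
    return pd.DataFrame(rows), models, landscapes, elfeats


def feature_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Long-format table with one row per (participant, stimulus)."""
    expected = {"subject", "group", "stimulus"}
    if not expected <= set(rows.columns):
        raise ValueError("not a feature table")
    return rows.sort_values(["subject", "stimulus"]).reset_index(drop=True)
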