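"""Depression-detection classifiers: connectivity (J) vs energy features.

A radial-basis-kernel maximum-margin classifier (class-balanced, tol 1e-3)
is evaluated by outer leave-one-out cross-validation over participants.
Min-max rescaling and the (C, gamma) grid search are fit inside each
training fold only — no information from the held-out participant leaks
into model selection.  A ``flat`` mode replicating a single global grid
search (the leaky textbook protocol) is provided for comparison and is
labelled as such in its report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .landscape import ELFeatures
from .pmem import PMEMModel

__all__ = [
    "FeatureVectorSet",
    "ClassificationReport",
    "default_grid",
    "build_features",
    "loocv_classifier",
    "compare_models",
]

METRICS = ("accuracy", "precision", "recall", "specificity", "f1")


def default_grid(low: int = -8, high: int = 8) -> np.ndarray:
    """Powers of ten from 10^low to 10^high inclusive (17 points by default)."""
    return 10.0 ** np.arange(low, high + 1, dtype=float)


@dataclass
class FeatureVectorSet:
    kind: str                  # "connectivity" | "energy"
    X: np.ndarray              # (participants, d), raw (unscaled) features
    y: np.ndarray              # binary labels, 1 = positive (patient) class
    subjects: list[str]
    columns: list[str]
    stimulus: str = ""


def build_features(
    models: dict[str, PMEMModel],
    features: dict[str, ELFeatures],
    labels: dict[str, str],
    kind: str,
    stimulus: str = "",
    positive_group: str = "MDD",
) -> FeatureVectorSet:
    """Assemble one row per participant.

    connectivity: the upper triangle of J (C(C-1)/2 values, row-major).
    energy: the 2^C state energies followed by the four landscape features
    (n_lm, mean_gap, basin_size_sd, gm_duration).
    Rescaling to [0, 1] is deliberately NOT applied here; it happens inside
    each cross-validation training fold.
    """
    if kind not in ("connectivity", "energy"):
        raise ValueError(f"unknown feature kind {kind!r}")
    subjects = sorted(models)
    missing = [s for s in subjects if s not in features or s not in labels]
    if missing:
        raise ValueError(f"missing landscape features or labels for {missing}")
    rows, columns = [], None
    for s in subjects:
        model = models[s]
        if kind == "connectivity":
            iu = np.triu_indices(model.n_channels, k=1)
            row = model.J[iu]
            if columns is None:
                columns = [f"J_{m}_{n}" for m, n in zip(*iu)]
        else:
            f = features[s]
            row = np.concatenate(
                [
                    model.energies,
                    [f.n_lm, f.mean_gap, f.basin_size_sd, f.gm_duration],
                ]
            )
            if columns is None:
                columns = [f"E_{i}" for i in range(model.energies.size)] + [
                    "n_lm", "mean_gap", "basin_size_sd", "gm_duration",
                ]
        rows.append(row)
    X = np.asarray(rows, dtype=float)
    y = np.array([1 if labels[s] == positive_group else 0 for s in subjects])
    return FeatureVectorSet(
        kind=kind, X=X, y=y, subjects=subjects, columns=columns, stimulus=stimulus
    )


@dataclass
class ClassificationReport:
    kind: str
    stimulus: str
    mode: str
    metrics: dict[str, float]            # mean over repeats, % except f1
    metrics_sd: dict[str, float]
    per_repeat: pd.DataFrame             # one row per repeated evaluation
    predictions: np.ndarray              # outer-LOO predictions, first repeat
    best_params: list[dict] = field(default_factory=list)


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    div = lambda a, b: a / b if b else 0.0
    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    return {
        "accuracy": 100.0 * div(tp + tn, tp + tn + fp + fn),
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "specificity": 100.0 * div(tn, tn + fp),
        "f1": div(2 * precision * recall, precision + recall),
    }


def _make_pipeline(c: float, gamma: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", MinMaxScaler()),
            (
                "svc",
                SVC(
                    kernel="rbf", C=c, gamma=gamma,
                    class_weight="balanced", tol=1e-3,
                ),
            ),
        ]
    )


def loocv_classifier(
    fvs: FeatureVectorSet,
    grid: np.ndarray | None = None,
    mode: str = "nested",
    n_repeats: int = 1,
    inner_folds: int = 3,
    seed: int | None = 0,
) -> ClassificationReport:
    """Outer leave-one-out evaluation with per-fold hyperparameter search.

    nested (default): each outer training fold runs its own stratified
    ``inner_folds``-fold grid search over (C, gamma).  flat: one grid search
    scored by leave-one-out accuracy on the full data selects a single
    (C, gamma), which is then re-evaluated by leave-one-out — this leaks the
    held-out participant into model selection and is provided only because
    it is the protocol papers commonly describe.

    Metric standard deviations come from ``n_repeats`` repeated evaluations
    with reshuffled inner partitions (flat mode is deterministic).
    """
    if mode not in ("nested", "flat"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    X, y = fvs.X, fvs.y
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("need at least two participants per class")
    param_grid = {"svc__C": grid, "svc__gamma": grid}
    rng = np.random.default_rng(seed)
    rows, all_preds, best_params = [], None, []
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(2**31))
        preds = np.empty_like(y)
        if mode == "flat":
            search = GridSearchCV(
                _make_pipeline(1.0, 1.0), param_grid,
                cv=LeaveOneOut(), scoring="accuracy", n_jobs=None,
            )
            search.fit(X, y)
            best_params.append(search.best_params_)
            pipe = _make_pipeline(
                search.best_params_["svc__C"], search.best_params_["svc__gamma"]
            )
            for train, test in LeaveOneOut().split(X):
                pipe.fit(X[train], y[train])
                preds[test] = pipe.predict(X[test])
        else:
            for train, test in LeaveOneOut().split(X):
                inner = StratifiedKFold(
                    n_splits=inner_folds, shuffle=True, random_state=rep_seed
                )
                search = GridSearchCV(
                    _make_pipeline(1.0, 1.0), param_grid,
                    cv=inner, scoring="accuracy", n_jobs=None,
                )
                search.fit(X[train], y[train])
                preds[test] = search.predict(X[test])
            best_params.append(search.best_params_)
        rows.append(_confusion_metrics(y, preds))
        if all_preds is None:
            all_preds = preds.copy()
    per_repeat = pd.DataFrame(rows)
    return ClassificationReport(
        kind=fvs.kind,
        stimulus=fvs.stimulus,
        mode=mode,
        metrics={m: float(per_repeat[m].mean()) for m in METRICS},
        metrics_sd={m: float(per_repeat[m].std(ddof=0)) for m in METRICS},
        per_repeat=per_repeat,
        predictions=all_preds,
        best_params=best_params,
    )


def compare_models(reports: list[ClassificationReport]) -> dict:
    """Table-style comparison of feature kinds across stimuli, with a two-way
    ANOVA (kind, stimulus) per metric when both factors vary."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for rep in reports:
        for _, r in rep.per_repeat.iterrows():
            rows.append({"kind": rep.kind, "stimulus": rep.stimulus, **r.to_dict()})
    long = pd.DataFrame(rows)
    table = (
        long.groupby(["kind", "stimulus"])[list(METRICS)]
        .agg(["mean", "std"])
        .round(4)
    )
    anova: dict[str, dict] = {}
    if long["kind"].nunique() > 1 and long["stimulus"].nunique() > 1:
        for metric in METRICS:
            data = long.rename(columns={metric: "y"})
            if data["y"].var() == 0:
                anova[metric] = {"kind_p": 1.0, "stimulus_p": 1.0}
                continue
            fit = smf.ols("y ~ C(kind) * C(stimulus)", data=data).fit()
            aov = sm.stats.anova_lm(fit, typ=2)
            anova[metric] = {
                "kind_F": float(aov.loc["C(kind)", "F"]),
                "kind_p": float(aov.loc["C(kind)", "PR(>F)"]),
                "stimulus_F": float(aov.loc["C(stimulus)", "F"]),
                "stimulus_p": float(aov.loc["C(stimulus)", "PR(>F)"]),
            }
    return {"table": table, "anova": anova, "long": long}
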