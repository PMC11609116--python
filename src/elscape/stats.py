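"""Group-level statistics on energy-landscape features.

Features are gated by Shapiro–Wilk normality per group × stimulus cell:
normal features go to a two-way ANOVA (group, stimulus, interaction; type-II
sums of squares on the balanced design) with Tukey HSD post-hoc stimulus
contrasts; non-normal features go to Kruskal–Wallis tests by group and by
stimulus.  Each participant contributes one row per stimulus and rows are
treated as independent observations (so e.g. 2 groups x 4 stimuli x 60
participants gives a group F with (1, 472) df); see the repeated-measures
caveat in the README.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FeatureTest",
    "StatsReport",
    "normality_gate",
    "run_group_tests",
    "demographics_tests",
]

EL_FEATURES = ("n_lm", "mean_gap", "basin_size_sd", "gm_duration")
ALPHA = 0.05


@dataclass
class FeatureTest:
    feature: str
    route: str                     # "parametric" | "nonparametric"
    shapiro_p: dict[str, float]    # per group x stimulus cell
    effects: dict[str, dict]       # test name -> {statistic, df, p}
    tukey: pd.DataFrame | None = None


@dataclass
class StatsReport:
    tests: dict[str, FeatureTest] = field(default_factory=dict)
    demographics: dict[str, dict] = field(default_factory=dict)

    def p_value(self, feature: str, effect: str = "group") -> float:
        return self.tests[feature].effects[effect]["p"]


def _validate_table(table: pd.DataFrame) -> None:
    required = {"subject", "group", "stimulus"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table is missing columns {sorted(missing)}")
    groups = sorted(table["group"].unique())
    stimuli = sorted(table["stimulus"].unique())
    if len(groups) < 2:
        raise ValueError("both groups must be present")
    combos = {(g, s) for g, s in zip(table["group"], table["stimulus"])}
    expected = {(g, s) for g in groups for s in stimuli}
    absent = expected - combos
    if absent:
        raise ValueError(f"missing group x stimulus cells: {sorted(absent)}")


def normality_gate(table: pd.DataFrame, feature: str, alpha: float = ALPHA):
    """Shapiro–Wilk per group; parametric only if both groups pass at
    ``alpha``.  Returns (route, per-group p-values).

    Gating on the two group samples (each pooling its stimuli) rather than
    on every group x stimulus cell keeps the false-nonparametric rate of a
    Gaussian feature near 1 - 0.95^2 instead of 1 - 0.95^8.
    """
    if feature not in table.columns:
        raise ValueError(f"feature {feature!r} not in table")
    cell_p: dict[str, float] = {}
    for g, cell in table.groupby("group"):
        values = cell[feature].to_numpy(dtype=float)
        if len(values) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
        if np.ptp(values) == 0:
            raise ValueError(
                f"feature {feature!r} is constant in group {g!r}; "
                "Shapiro-Wilk is undefined"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cell_p[str(g)] = float(sstats.shapiro(values).pvalue)
    route = "parametric" if all(p >= alpha for p in cell_p.values()) else "nonparametric"
    return route, cell_p


def _anova_feature(table: pd.DataFrame, feature: str) -> tuple[dict, pd.DataFrame]:
    data = table.rename(columns={feature: "y"})[["y", "group", "stimulus"]]
    model = smf.ols("y ~ C(group) * C(stimulus)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    resid_df = int(aov.loc["Residual", "df"])
    effects = {}
    for label, key in [
        ("C(group)", "group"),
        ("C(stimulus)", "stimulus"),
        ("C(group):C(stimulus)", "group:stimulus"),
    ]:
        effects[key] = {
            "test": "anova",
            "statistic": float(aov.loc[label, "F"]),
            "df": (int(aov.loc[label, "df"]), resid_df),
            "p": float(aov.loc[label, "PR(>F)"]),
        }
    tukey_res = pairwise_tukeyhsd(
        data["y"].to_numpy(), data["stimulus"].to_numpy(), alpha=ALPHA
    )
    tukey = pd.DataFrame(
        tukey_res.summary().data[1:], columns=tukey_res.summary().data[0]
    )
    return effects, tukey


def _kruskal(groups):
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        # identical samples carry no evidence against the null
        return type("KW", (), {"statistic": 0.0, "pvalue": 1.0})()
    return sstats.kruskal(*groups)


def _kruskal_feature(table: pd.DataFrame, feature: str) -> dict:
    by_group = [c[feature].to_numpy(float) for _, c in table.groupby("group")]
    by_stim = [c[feature].to_numpy(float) for _, c in table.groupby("stimulus")]
    kw_g = _kruskal(by_group)
    kw_s = _kruskal(by_stim)
    return {
        "group": {
            "test": "kruskal",
            "statistic": float(kw_g.statistic),
            "df": len(by_group) - 1,
            "p": float(kw_g.pvalue),
        },
        "stimulus": {
            "test": "kruskal",
            "statistic": float(kw_s.statistic),
            "df": len(by_stim) - 1,
            "p": float(kw_s.pvalue),
        },
    }


def run_group_tests(
    table: pd.DataFrame,
    features: tuple[str, ...] = EL_FEATURES,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> StatsReport:
    """Route each feature through the normality gate and run the matching
    group/stimulus tests.  ``fdr=True`` additionally applies a
    Benjamini–Hochberg correction across features' group effects (off by
    default)."""
    _validate_table(table)
    report = StatsReport()
    for feature in features:
        try:
            route, cell_p = normality_gate(table, feature, alpha=alpha)
        except ValueError as exc:
            if "constant" not in str(exc):
                raise
            # a cell-constant feature is certainly not Gaussian in that cell;
            # route it nonparametrically instead of failing the whole report
            warnings.warn(
                f"{exc}; routing {feature!r} to the nonparametric branch",
                RuntimeWarning,
            )
            route, cell_p = "nonparametric", {}
        if route == "parametric":
            effects, tukey = _anova_feature(table, feature)
        else:
            effects, tukey = _kruskal_feature(table, feature), None
        report.tests[feature] = FeatureTest(
            feature=feature, route=route, shapiro_p=cell_p, effects=effects, tukey=tukey
        )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ps = [report.tests[f].effects["group"]["p"] for f in features]
        _, adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        for f, q in zip(features, adj):
            report.tests[f].effects["group"]["p_fdr"] = float(q)
    return report


def demographics_tests(metadata: pd.DataFrame) -> dict[str, dict]:
    """Table-1-style block: independent-sample t-tests for numeric fields,
    chi-square for gender.  Missing fields are skipped with a warning."""
    groups = sorted(metadata["group"].unique())
    if len(groups) != 2:
        raise ValueError("demographics tests require exactly two groups")
    a = metadata[metadata["group"] == groups[0]]
    b = metadata[metadata["group"] == groups[1]]
    out: dict[str, dict] = {}
    for col in ("age", "phq9", "hamd17"):
        if col not in metadata.columns:
            warnings.warn(f"demographics field {col!r} missing; skipped", RuntimeWarning)
            continue
        t = sstats.ttest_ind(a[col], b[col])
        out[col] = {"test": "t", "statistic": float(t.statistic), "p": float(t.pvalue)}
    if "gender" in metadata.columns:
        contingency = pd.crosstab(metadata["group"], metadata["gender"]).to_numpy()
        chi2, p, dof, _ = sstats.chi2_contingency(contingency)
        out["gender"] = {"test": "chi2", "statistic": float(chi2), "df": int(dof), "p": float(p)}
    else:
        warnings.warn("demographics field 'gender' missing; skipped", RuntimeWarning)
    return out
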