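"""Statistical layer: paired tissue comparisons, mixed models with animal as
a random intercept, ANOVA with Tukey post-hoc tests, and normality checks.

Mutation count and frequency metrics are heavily right-skewed across animals,
so responses are cube-root transformed before linear modelling by default
(cube root of 0 is 0; no offset is added).  Mixed-model p-values use the Wald
normal approximation, recorded in :class:`ModelResult.method`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

TRANSFORMS = ("cube_root", "none")


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "cube_root":
        return np.cbrt(values)
    if transform == "none":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class ModelResult:
    """A fitted comparison: estimates, test statistic, p-values, provenance."""

    model: str
    statistic: float | None
    p_value: float | None
    estimates: dict[str, float] = field(default_factory=dict)
    t_values: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    transform: str = "none"
    n_animals: int | None = None
    fixed: list[str] = field(default_factory=list)
    random: str | None = None
    method: str | None = None
    warnings: list[str] = field(default_factory=list)
    pairwise: pd.DataFrame | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        if self.pairwise is not None:
            payload["pairwise"] = self.pairwise.to_dict(orient="records")
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def paired_tissue_test(liver: Sequence[float], brain: Sequence[float]) -> ModelResult:
    """Paired t-test between per-animal liver and brain totals.

    Vectors are paired by animal; df = n - 1, two-sided p.  Identical
    vectors give t = 0, p = 1; a constant non-zero difference (zero variance)
    is degenerate and flagged rather than reported as infinite.
    """
    liver = np.asarray(liver, dtype=float)
    brain = np.asarray(brain, dtype=float)
    if liver.shape != brain.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(liver)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = liver - brain
    result = ModelResult(model="paired_t", statistic=None, p_value=None,
                         n_animals=n, method=f"t, df={n - 1}, two-sided")
    if np.allclose(diffs.std(ddof=1), 0):
        if np.allclose(diffs, 0):
            result.statistic, result.p_value = 0.0, 1.0
        else:
            result.warnings.append("zero-variance non-zero differences: t undefined")
        result.estimates["mean_difference"] = float(diffs.mean())
        return result
    t_stat, p = st.ttest_rel(liver, brain)
    result.statistic, result.p_value = float(t_stat), float(p)
    result.estimates["mean_difference"] = float(diffs.mean())
    return result


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str = "animal_id",
    transform: str = "cube_root",
    interaction: bool = True,
) -> ModelResult:
    """Linear mixed model with a random intercept per animal.

    ``fixed`` lists categorical columns; with ``interaction=True`` the full
    factorial (main effects + interactions) is fitted, as in
    ``y ~ f1 * f2 + (1 | animal)``.  The response is cube-root transformed
    by default.  Singular / convergence problems are recorded as warnings on
    the result rather than raised.
    """
    if group not in data.columns:
        raise ValueError(f"grouping column {group!r} missing")
    n_animals = data[group].nunique()
    if n_animals < 2:
        raise ValueError("need at least 2 animals for a random intercept")
    work = data.copy()
    work["_y"] = _apply_transform(work[response].to_numpy(), transform)
    op = " * " if interaction else " + "
    # bare column names are wrapped as categorical; terms that already look
    # like patsy expressions (e.g. explicit Treatment coding) pass through
    terms = [f if "(" in f else f"C({f})" for f in fixed]
    formula = "_y ~ " + op.join(terms)
    result = ModelResult(model="mixed_lm", statistic=None, p_value=None,
                         transform=transform, n_animals=int(n_animals),
                         fixed=list(fixed), random=f"(1|{group})",
                         method="REML, Wald normal approximation")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if work["_y"].nunique() == 1:
            # no variance anywhere: intercept = the constant, all effects 0
            ols = smf.ols(formula, data=work).fit()
            result.estimates = {k: (0.0 if abs(v) < 1e-10 else float(v))
                                for k, v in ols.params.items()}
            result.t_values = {k: 0.0 for k in result.estimates}
            result.p_values = {k: 1.0 for k in result.estimates}
            result.warnings.append("response has no variance; all effects 0")
            return result
        model = smf.mixedlm(formula, data=work, groups=work[group])
        fit = model.fit(reml=True)
    for w in caught:
        msg = str(w.message)
        if "singular" in msg.lower() or "converge" in msg.lower() or "boundary" in msg.lower():
            result.warnings.append(msg)
    fe = fit.fe_params
    result.estimates = {k: float(v) for k, v in fe.items()}
    result.t_values = {k: float(fit.tvalues[k]) for k in fe.index}
    result.p_values = {k: float(fit.pvalues[k]) for k in fe.index}
    # headline statistic: the last fitted fixed-effect term (interaction when present)
    terms = [k for k in fe.index if k != "Intercept"]
    if terms:
        result.statistic = result.t_values[terms[-1]]
        result.p_value = result.p_values[terms[-1]]
    return result


def anova_tukey(data: pd.DataFrame, value: str, factor: str,
                transform: str = "cube_root") -> ModelResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Returns the omnibus F and p plus the full k(k-1)/2 pairwise table.
    """
    work = data.copy()
    work["_y"] = _apply_transform(work[value].to_numpy(), transform)
    groups = work[factor].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = work.groupby(factor)["_y"].count()
    if (counts < 2).any():
        raise ValueError("need at least 2 observations per group")
    result = ModelResult(model="anova_tukey", statistic=None, p_value=None,
                         transform=transform, fixed=[factor],
                         method="one-way ANOVA + Tukey HSD")
    group_means = work.groupby(factor)["_y"].mean()
    if np.allclose(group_means.var(ddof=0), 0):
        result.statistic, result.p_value = 0.0, 1.0
    else:
        ols = smf.ols(f"_y ~ C({factor})", data=work).fit()
        table = sm.stats.anova_lm(ols, typ=1)
        result.statistic = float(table["F"].iloc[0])
        result.p_value = float(table["PR(>F)"].iloc[0])
    tukey = pairwise_tukeyhsd(work["_y"].to_numpy(), work[factor].to_numpy())
    result.pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    result.estimates = {str(k): float(v) for k, v in group_means.items()}
    return result


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p for a sample of 3..5000 observations.

    Recorded for pipeline logs; it does not gate the cube-root transform,
    which is always applied to the skewed count/frequency metrics.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3..5000 observations, got {len(values)}")
    stat, p = st.shapiro(values)
    return float(stat), float(p)
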