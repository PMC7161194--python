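"""Cohort-level ancestry reporting and ancestry-adjusted association.

Covers three reporting tasks: per-group mean ancestry with standard errors
and a population-weighted national total; the rule-based selection of
reference individuals (an individual qualifies as an ancestry reference if
it meets at least ``min_criteria`` of four lines of evidence: self-report,
indigenous surname, Amerindian mtDNA haplogroup, Amerindian Y haplogroup);
and ordinary-least-squares association of a per-unit outcome with a
covariate, with and without adjustment for mean ancestry, to demonstrate
confounding of socioeconomic covariates by genetic structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ancestry import QMatrix


@dataclass
class AncestrySummary:
    """Per-group ancestry means/SEs and the weighted overall total."""

    group_means: pd.DataFrame  # index group, columns components
    group_se: pd.DataFrame
    group_n: pd.Series
    weights: pd.Series  # NaN for unweighted groups (excluded from total)
    weighted_total: pd.Series  # per component

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one row per group plus a 'Total' row."""
        out = self.group_means.copy()
        out.insert(0, "n", self.group_n)
        for c in self.group_means.columns:
            out[f"{c}_se"] = self.group_se[c]
        total = self.weighted_total.copy()
        total["n"] = self.group_n[self.weights.notna()].sum()
        out.loc["Total"] = total
        return out


def weighted_group_means(
    Q: QMatrix | pd.DataFrame,
    groups: Mapping[str, str],
    weights: Mapping[str, float],
) -> AncestrySummary:
    """Group-wise mean ancestry and a population-weighted overall mean.

    Group means are plain arithmetic means of individual proportions and
    SE = SD/sqrt(n). The weighted total averages group means with the
    supplied weights (e.g. the fraction of the national population living
    in each sampled city), renormalized over the groups that HAVE weights;
    groups without a weight (reference panels, special cohorts) contribute
    to the per-group rows but not to the total. No rounding is applied.
    """
    props = Q.proportions if isinstance(Q, QMatrix) else Q
    grp = pd.Series({s: g for s, g in groups.items() if s in props.index})
    if grp.empty:
        raise ValueError("no grouped samples present in Q")
    sub = props.loc[grp.index]
    means = sub.groupby(grp).mean()
    sds = sub.groupby(grp).std(ddof=1)
    ns = sub.groupby(grp).size()
    se = sds.div(np.sqrt(ns), axis=0).fillna(0.0)

    w = pd.Series({g: float(v) for g, v in weights.items()})
    missing_groups = [g for g in w.index if g not in means.index]
    if missing_groups:
        raise ValueError(f"weighted groups without samples: {missing_groups}")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be >= 0 and not all zero")
    w_full = pd.Series(np.nan, index=means.index)
    w_full[w.index] = w
    total = means.loc[w.index].mul(w, axis=0).sum() / w.sum()
    return AncestrySummary(means, se, ns, w_full, total)


def select_reference_individuals(
    criteria: pd.DataFrame, min_criteria: int = 2
) -> tuple[list[str], pd.Series]:
    """Apply the >= min_criteria-of-4 ancestry-evidence selection rule.

    ``criteria`` is indexed by individual with boolean (or NaN = not
    assessable, e.g. the Y-chromosome line of evidence for females)
    columns: self_report, indigenous_surname, amerindian_mtDNA,
    amerindian_Y. Missing counts as not met.
    """
    expected = ["self_report", "indigenous_surname", "amerindian_mtDNA", "amerindian_Y"]
    missing = [c for c in expected if c not in criteria.columns]
    if missing:
        raise ValueError(f"criteria table lacks columns: {missing}")
    tally = (
        criteria[expected].astype(float).fillna(0.0).astype(bool).sum(axis=1)
    )
    selected = tally.index[tally >= min_criteria].tolist()
    return selected, tally.rename("criteria_met")


@dataclass
class OLSResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float


def ols_fit(y: Sequence[float], X: pd.DataFrame | Mapping[str, Sequence[float]]) -> OLSResult:
    """Ordinary least squares with an automatic intercept.

    Thin wrapper over a QR-based OLS fit; raises on rank-deficient
    designs, naming the offending columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {list(X.columns)}")
    fit = sm.OLS(y, design).fit()
    return OLSResult(fit.params, fit.bse, fit.pvalues, float(fit.rsquared))


@dataclass
class AdjustedRegression:
    unadjusted: OLSResult  # y ~ covariate
    stage1: OLSResult  # y ~ ancestry
    stage2: OLSResult  # residuals(stage1) ~ covariate
    joint: OLSResult | None  # y ~ ancestry + covariate; None if collinear


def ancestry_adjusted_regression(
    y: Sequence[float],
    ancestry: Sequence[float],
    covariate: Sequence[float],
    covariate_name: str = "covariate",
    ancestry_name: str = "ancestry",
) -> AdjustedRegression:
    """Two-stage ancestry adjustment of a covariate association.

    Stage 1 regresses the outcome on mean ancestry; stage 2 regresses the
    stage-1 residuals on the covariate. The one-step joint model
    (outcome ~ ancestry + covariate) is reported alongside for comparison:
    when ancestry and the covariate are correlated the two-stage slope is
    attenuated relative to the unadjusted one, revealing confounding by
    population structure.
    """
    y = np.asarray(y, dtype=float)
    anc = pd.DataFrame({ancestry_name: np.asarray(ancestry, dtype=float)})
    cov = pd.DataFrame({covariate_name: np.asarray(covariate, dtype=float)})
    unadj = ols_fit(y, cov)
    stage1 = ols_fit(y, anc)
    resid = y - sm.add_constant(anc, has_constant="add").to_numpy() @ stage1.params.to_numpy()
    stage2 = ols_fit(resid, cov)
    try:
        joint = ols_fit(y, pd.concat([anc, cov], axis=1))
    except ValueError:  # ancestry and covariate collinear
        joint = None
    return AdjustedRegression(unadj, stage1, stage2, joint)
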