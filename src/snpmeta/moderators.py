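"""Heterogeneity exploration: subgroup analysis, subtype contrasts and
random-effects meta-regression.

The between-subgroup test partitions the fixed-effect Cochran Q:
``Q_total = sum_g Q_within(g) + Q_between`` exactly, where ``Q_between``
is the inverse-variance-weighted dispersion of the group fixed-effect
means around the overall fixed-effect mean, chi-square with G-1 df under
the null of equal subgroup effects. Headline per-group estimates may use
any pooling method (random effects by default); the decomposition itself
is always computed on fixed-effect weights so the identity holds exactly.

Meta-regression follows the method-of-moments generalisation of
DerSimonian–Laird: a weighted least-squares fit with weights ``1/v_i``
gives the residual ``Q_E``; the residual between-study variance is
``tau2 = max(0, (Q_E - (k - p)) / (tr(W) - tr((X'WX)^{-1} X'W^2 X)))``;
coefficients are then re-estimated with weights ``1/(v_i + tau2)`` and
tested with normal (z) statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate, GeneticModel, study_effect, build_contrast
from .exceptions import CapabilityError, DomainError, InsufficientStudiesError
from .pooling import PoolMethod, PooledResult, pool
from .study_io import StratumLabel, StudyRecord, StudyTable


@dataclass(frozen=True)
class SubgroupReport:
    group_by: str
    groups: dict[str, PooledResult]
    q_between: float
    df_between: int
    p_between: float
    overall: PooledResult


def _effects_for(table: StudyTable, model: GeneticModel
                 ) -> tuple[list[EffectEstimate], list]:
    effects, tables = [], []
    for rec in table.records:
        tables.append(build_contrast(rec, model))
        effects.append(study_effect(rec, model))
    return effects, tables


def _group_label(rec: StudyRecord, group_by: str) -> str:
    value = getattr(rec, group_by)
    return value.value if hasattr(value, "value") else str(value)


def q_between_fixed(group_effects: Sequence[Sequence[EffectEstimate]]
                    ) -> tuple[float, int]:
    """Between-group component of the fixed-effect Q decomposition."""
    group_w, group_mean = [], []
    all_w, all_wy = 0.0, 0.0
    for effs in group_effects:
        w = sum(1.0 / e.variance for e in effs)
        wy = sum(e.log_or / e.variance for e in effs)
        group_w.append(w)
        group_mean.append(wy / w)
        all_w += w
        all_wy += wy
    overall = all_wy / all_w
    q_b = sum(w * (m - overall) ** 2 for w, m in zip(group_w, group_mean))
    return q_b, len(group_effects) - 1


def subgroup_analysis(table: StudyTable, model: GeneticModel,
                      method: PoolMethod = PoolMethod.DL_RANDOM,
                      group_by: str = "ethnic_group") -> SubgroupReport:
    """Pool within each level of a study-level moderator and test between.

    ``group_by`` names a StudyRecord field (``ethnic_group``, ``design``,
    ``control_source`` ...). Empty groups never arise (groups are realized
    levels); a single realized group yields ``q_between = 0``.
    """
    by_group: dict[str, list[StudyRecord]] = {}
    for rec in table.records:
        by_group.setdefault(_group_label(rec, group_by), []).append(rec)

    groups: dict[str, PooledResult] = {}
    group_effect_lists = []
    for label, recs in by_group.items():
        sub = StudyTable(recs, table.provenance)
        effects, tabs = _effects_for(sub, model)
        groups[label] = pool(effects, method, tables=tabs)
        group_effect_lists.append(effects)

    if len(by_group) > 1:
        q_b, df_b = q_between_fixed(group_effect_lists)
        p_b = float(stats.chi2.sf(q_b, df_b))
    else:
        q_b, df_b, p_b = 0.0, 0, 1.0
    all_effects = [e for effs in group_effect_lists for e in effs]
    all_tables = [t for recs in by_group.values()
                  for t in _effects_for(StudyTable(list(recs)), model)[1]]
    overall = pool(all_effects, method, tables=all_tables)
    return SubgroupReport(group_by=group_by, groups=groups, q_between=q_b,
                          df_between=df_b, p_between=p_b, overall=overall)


@dataclass(frozen=True)
class SubtypeContrast:
    """Pooled effects in two case subtypes plus a difference test.

    The z-test on the difference of pooled log ORs treats the two strata as
    independent although they share control groups; the shared-control
    covariance is unavailable at study level, so the test is approximate
    (slightly conservative for a positive covariance).
    """

    model: GeneticModel
    stratum_a: StratumLabel
    stratum_b: StratumLabel
    pooled_a: PooledResult
    pooled_b: PooledResult
    diff_log_or: float
    diff_se: float
    diff_z: float
    diff_p: float
    independence_assumed: bool = True


def subtype_contrast(table: StudyTable, model: GeneticModel,
                     stratum_pair: tuple[StratumLabel, StratumLabel],
                     method: PoolMethod = PoolMethod.DL_RANDOM
                     ) -> SubtypeContrast:
    """Contrast two case subtypes (e.g. ER+ vs ER-) against shared controls."""
    lab_a, lab_b = stratum_pair
    eff_a: list[EffectEstimate] = []
    eff_b: list[EffectEstimate] = []
    for rec in table.records:
        strata = {s.label: s for s in rec.strata}
        if lab_a in strata and lab_b in strata:
            eff_a.append(study_effect(rec, model, stratum=strata[lab_a]))
            eff_b.append(study_effect(rec, model, stratum=strata[lab_b]))
    if not eff_a:
        raise CapabilityError(
            f"no study carries both strata {lab_a.value!r} and {lab_b.value!r}")
    if method is PoolMethod.MH_FIXED:
        raise DomainError("subtype contrast supports IV_fixed or DL_random")
    pooled_a = pool(eff_a, method)
    pooled_b = pool(eff_b, method)
    diff = pooled_a.log_or - pooled_b.log_or
    se = math.sqrt(pooled_a.se ** 2 + pooled_b.se ** 2)
    z = diff / se
    p = float(2 * stats.norm.sf(abs(z)))
    return SubtypeContrast(model=model, stratum_a=lab_a, stratum_b=lab_b,
                           pooled_a=pooled_a, pooled_b=pooled_b,
                           diff_log_or=diff, diff_se=se, diff_z=z, diff_p=p)


@dataclass(frozen=True)
class MetaRegressionResult:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2: float
    k: int

    def as_table(self) -> list[dict]:
        return [{"covariate": n, "coef": float(c), "se": float(s),
                 "z": float(z), "p": float(p)}
                for n, c, s, z, p in zip(self.names, self.coef, self.se,
                                         self.z, self.p)]


def meta_regression(effects: Sequence[EffectEstimate],
                    covariates: Optional[np.ndarray] = None,
                    names: Optional[Sequence[str]] = None,
                    add_intercept: bool = True) -> MetaRegressionResult:
    """Random-effects meta-regression of log ORs on study-level moderators.

    With no covariates (intercept only) the estimate coincides with the
    DerSimonian–Laird pooled log odds ratio.
    """
    k = len(effects)
    y = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    if covariates is None:
        X = np.ones((k, 1))
        cov_names: list[str] = []
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != k:
            X = X.T
        if X.shape[0] != k:
            raise DomainError("covariate matrix does not match the effect list")
        cov_names = list(names) if names is not None else \
            [f"x{j}" for j in range(X.shape[1])]
        if add_intercept:
            X = np.column_stack([np.ones(k), X])
    all_names = (["intercept"] + cov_names) if (covariates is None or
                                                add_intercept) else cov_names
    p = X.shape[1]
    if k <= p:
        raise InsufficientStudiesError(
            f"meta-regression needs k > {p} studies, got {k}")
    if np.linalg.matrix_rank(X) < p:
        bad = [all_names[j] for j in range(p)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) ==
               np.linalg.matrix_rank(X)]
        raise DomainError(f"rank-deficient design; collinear columns: {bad}")

    # stage 1: fixed-effect WLS, residual Q, method-of-moments tau2
    W = np.diag(1.0 / v)
    XtWX = X.T @ W @ X
    beta_fe = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ beta_fe
    q_e = float(resid @ W @ resid)
    trace_correction = np.trace(W) - np.trace(
        np.linalg.solve(XtWX, X.T @ (W @ W) @ X))
    tau2 = max(0.0, (q_e - (k - p)) / trace_correction) \
        if trace_correction > 0 else 0.0

    # stage 2: random-effects WLS
    Wr = np.diag(1.0 / (v + tau2))
    XtWrX = X.T @ Wr @ X
    beta = np.linalg.solve(XtWrX, X.T @ Wr @ y)
    cov_beta = np.linalg.inv(XtWrX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return MetaRegressionResult(names=tuple(all_names), coef=beta, se=se,
                                z=z, p=pvals, tau2=tau2, k=k)
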