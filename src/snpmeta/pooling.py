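"""Fixed- and random-effects pooling of study-level odds ratios.

Three estimators:

* ``IV_fixed``  — inverse-variance fixed effect on the log-OR scale,
  weights ``w_i = 1/v_i``;
* ``DL_random`` — DerSimonian–Laird random effects: the moment estimator
  ``tau2 = max(0, (Q - (k-1)) / (S1 - S2/S1))`` with ``S1 = sum w_i`` and
  ``S2 = sum w_i^2``, then inverse-variance pooling with weights
  ``1/(v_i + tau2)``;
* ``MH_fixed``  — Mantel–Haenszel pooling of the raw 2x2 tables,
  ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``, with the
  Robins–Breslow–Greenland variance for its log.

Heterogeneity is summarised by Cochran's Q (chi-square with k-1 df under
homogeneity) and ``I² = max(0, (Q - df)/Q)``, the fraction of total
variation attributed to between-study differences. ``tau2`` is truncated at
zero, so a homogeneous set makes DL collapse onto the fixed-effect answer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional, Sequence

from scipy import stats

from .effects import Z975, ContrastTable, EffectEstimate, GeneticModel, woolf_effect
from .exceptions import DomainError, NonEstimableError


class PoolMethod(str, Enum):
    MH_FIXED = "MH_fixed"
    IV_FIXED = "IV_fixed"
    DL_RANDOM = "DL_random"


@dataclass(frozen=True)
class PooledResult:
    model: Optional[GeneticModel]
    method: PoolMethod
    k: int
    log_or: float
    se: float
    z: float
    p_z: float
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z975 * self.se)

    def to_dict(self) -> dict:
        return {
            "model": self.model.value if self.model else None,
            "method": self.method.value, "k": self.k,
            "or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "log_or": self.log_or, "se": self.se, "z": self.z, "p_z": self.p_z,
            "q": self.q, "df": self.df, "p_q": self.p_q,
            "i2": self.i2, "tau2": self.tau2,
        }


class HeterogeneityResult(NamedTuple):
    q: float
    df: int
    p_q: float
    i2: float


def _common_model(effects: Sequence[EffectEstimate]) -> Optional[GeneticModel]:
    models = {e.model for e in effects}
    return models.pop() if len(models) == 1 else None


def _q_statistic(effects: Sequence[EffectEstimate]) -> float:
    w = [1.0 / e.variance for e in effects]
    y = [e.log_or for e in effects]
    mean = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    return sum(wi * (yi - mean) ** 2 for wi, yi in zip(w, y))


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I² index."""
    k = len(effects)
    if k < 2:
        raise DomainError("heterogeneity needs at least two studies")
    q = _q_statistic(effects)
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=p_q, i2=i2)


def _finish(model, method, k, log_or, se, q) -> PooledResult:
    z = log_or / se
    p_z = float(2 * stats.norm.sf(abs(z)))
    df = k - 1
    if df > 0:
        p_q = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    else:
        p_q, i2 = 1.0, 0.0
    return PooledResult(model=model, method=method, k=k, log_or=log_or, se=se,
                        z=z, p_z=p_z, q=q, df=df, p_q=p_q, i2=i2, tau2=0.0)


def pool_inverse_variance(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Fixed-effect inverse-variance pooled log odds ratio."""
    if not effects:
        raise DomainError("cannot pool an empty effect list")
    if any(e.se <= 0 for e in effects):
        raise DomainError("all standard errors must be positive")
    w = [1.0 / e.variance for e in effects]
    y = [e.log_or for e in effects]
    sw = sum(w)
    log_or = sum(wi * yi for wi, yi in zip(w, y)) / sw
    se = sw ** -0.5
    q = sum(wi * (yi - log_or) ** 2 for wi, yi in zip(w, y))
    return _finish(_common_model(effects), PoolMethod.IV_FIXED,
                   len(effects), log_or, se, q)


def dl_tau2(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian–Laird moment estimate of the between-study variance."""
    k = len(effects)
    if k < 2:
        return 0.0
    w = [1.0 / e.variance for e in effects]
    q = _q_statistic(effects)
    s1 = sum(w)
    s2 = sum(wi * wi for wi in w)
    c = s1 - s2 / s1
    return max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0


def pool_dersimonian_laird(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian–Laird random-effects pooled log odds ratio.

    Q (and hence I² and the heterogeneity p) are those of the fixed-effect
    weights, as in the defining method; only the pooled mean and its SE use
    the re-weighting ``1/(v_i + tau2)``.
    """
    if not effects:
        raise DomainError("cannot pool an empty effect list")
    if any(e.se <= 0 for e in effects):
        raise DomainError("all standard errors must be positive")
    tau2 = dl_tau2(effects)
    q = _q_statistic(effects) if len(effects) > 1 else 0.0
    ws = [1.0 / (e.variance + tau2) for e in effects]
    sw = sum(ws)
    log_or = sum(wi * e.log_or for wi, e in zip(ws, effects)) / sw
    se = sw ** -0.5
    res = _finish(_common_model(effects), PoolMethod.DL_RANDOM,
                  len(effects), log_or, se, q)
    return dataclasses.replace(res, tau2=tau2)


def pool_mantel_haenszel(tables: Sequence[ContrastTable],
                         study_ids: Optional[Sequence[str]] = None
                         ) -> PooledResult:
    """Mantel–Haenszel fixed-effect pooled odds ratio from raw 2x2 tables.

    The variance of the pooled log OR uses the Robins–Breslow–Greenland
    estimator; Q is computed on the per-study Woolf effects.
    """
    if not tables:
        raise DomainError("cannot pool an empty table list")
    r = s = 0.0
    sum_pr = sum_ps_qr = sum_qs = 0.0
    for t in tables:
        n = t.n
        if n <= 0:
            raise DomainError("table with zero total")
        ri = t.a * t.d / n
        si = t.b * t.c / n
        pi = (t.a + t.d) / n
        qi = (t.b + t.c) / n
        r += ri
        s += si
        sum_pr += pi * ri
        sum_ps_qr += pi * si + qi * ri
        sum_qs += qi * si
    if s == 0:
        raise NonEstimableError("Mantel-Haenszel OR non-estimable (sum b*c/n = 0)")
    log_or = math.log(r / s)
    var = sum_pr / (2 * r * r) + sum_ps_qr / (2 * r * s) + sum_qs / (2 * s * s)
    se = math.sqrt(var)

    ids = study_ids or [str(i) for i in range(len(tables))]
    woolf = [woolf_effect(t, study_id=i) for t, i in zip(tables, ids)]
    q = _q_statistic(woolf) if len(woolf) > 1 else 0.0
    return _finish(_common_model(woolf), PoolMethod.MH_FIXED,
                   len(tables), log_or, se, q)


def pool(effects: Sequence[EffectEstimate], method: PoolMethod,
         tables: Optional[Sequence[ContrastTable]] = None) -> PooledResult:
    """Dispatch to the requested pooling estimator."""
    if method is PoolMethod.IV_FIXED:
        return pool_inverse_variance(effects)
    if method is PoolMethod.DL_RANDOM:
        return pool_dersimonian_laird(effects)
    if method is PoolMethod.MH_FIXED:
        if tables is None:
            raise DomainError("Mantel-Haenszel pooling needs the raw 2x2 tables")
        return pool_mantel_haenszel(tables, [e.study_id for e in effects])
    raise ValueError(method)
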