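"""Publication-bias diagnostics and leave-one-out influence analysis.

Egger's test regresses the standardized effect ``y_i / se_i`` on precision
``1 / se_i``: under no small-study effect the fitted line passes through the
origin, and a nonzero intercept signals funnel-plot asymmetry. Begg's test
rank-correlates (Kendall) the variance-standardized deviations from the
fixed-effect mean with the study variances. Funnel asymmetry is reported,
never "corrected" — there is no trim-and-fill here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effects import EffectEstimate
from .exceptions import InsufficientStudiesError
from .pooling import PooledResult, PoolMethod, pool_dersimonian_laird, \
    pool_inverse_variance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    p: float
    slope: float
    df: int


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    z: float
    p: float
    n_pairs: int


@dataclass(frozen=True)
class BiasReport:
    egger: EggerResult
    begg: BeggResult
    funnel: list[tuple[float, float]]  # (log_or, se); plot se inverted


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger regression asymmetry test (intercept t-test with k-2 df)."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3, got {k}")
    se = np.array([e.se for e in effects])
    y = np.array([e.log_or for e in effects]) / se
    X = sm.add_constant(1.0 / se)
    fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    se_int = fit.bse[0]
    scale = max(1.0, float(np.max(np.abs(y))) ** 2)
    degenerate = (se_int == 0 or not np.isfinite(se_int)
                  or fit.ssr <= 1e-12 * scale)
    if degenerate:
        # numerically exact fit: the t-ratio is noise; an intercept at the
        # data's scale would still be evidence, a vanishing one is none
        t = 0.0 if abs(intercept) < 1e-6 * math.sqrt(scale) else math.inf
        p = 1.0 if t == 0.0 else 0.0
        se_int = 0.0
    else:
        t = intercept / se_int
        p = float(2 * stats.t.sf(abs(t), k - 2))
    return EggerResult(intercept=float(intercept), se=float(se_int),
                       t=float(t), p=p, slope=float(slope), df=k - 2)


def _kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    """Concordant-minus-discordant pair count (ties contribute zero)."""
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return s


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg–Mazumdar rank-correlation asymmetry test.

    The effect deviations from the fixed-effect mean are standardized by
    ``sqrt(v_i - v_pooled)`` (the variance of the deviation), then Kendall's
    S between those deviates and the variances is referred to the normal
    approximation with tie-corrected variance and a continuity correction.
    The reported tau uses the untied denominator ``k(k-1)/2``; ties enter
    the variance term only.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test needs k >= 3, got {k}")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    pooled = float(np.sum(w * y) / np.sum(w))
    v_pooled = 1.0 / float(np.sum(w))
    dv = v - v_pooled
    if np.any(dv <= 0):
        logger.warning("non-positive deviate variance clamped in Begg's test")
        dv = np.maximum(dv, 1e-12)
    vstar = (y - pooled) / np.sqrt(dv)

    s = _kendall_s(vstar, v)
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs

    def tie_sizes(a: np.ndarray) -> np.ndarray:
        _, counts = np.unique(a, return_counts=True)
        return counts[counts > 1]

    t_ties = tie_sizes(vstar)
    u_ties = tie_sizes(v)
    var_s = (k * (k - 1) * (2 * k + 5)
             - np.sum(t_ties * (t_ties - 1) * (2 * t_ties + 5))
             - np.sum(u_ties * (u_ties - 1) * (2 * u_ties + 5))) / 18.0
    if k > 2:
        var_s += (np.sum(t_ties * (t_ties - 1) * (t_ties - 2))
                  * np.sum(u_ties * (u_ties - 1) * (u_ties - 2))
                  ) / (9.0 * k * (k - 1) * (k - 2))
    var_s += (np.sum(t_ties * (t_ties - 1)) * np.sum(u_ties * (u_ties - 1))
              ) / (2.0 * k * (k - 1))
    if var_s <= 0 or s == 0:
        return BeggResult(kendall_tau=float(tau), z=0.0, p=1.0,
                          n_pairs=n_pairs)
    z = (abs(s) - 1) / math.sqrt(var_s)  # continuity correction
    z = max(z, 0.0)
    p = float(2 * stats.norm.sf(z))
    return BeggResult(kendall_tau=float(tau), z=float(z), p=p,
                      n_pairs=n_pairs)


def funnel_data(effects: Sequence[EffectEstimate]) -> list[tuple[float, float]]:
    """(log OR, SE) funnel coordinates; plot with the SE axis inverted."""
    if not effects:
        raise InsufficientStudiesError("funnel plot needs at least one study")
    return [(e.log_or, e.se) for e in effects]


def publication_bias(effects: Sequence[EffectEstimate]) -> BiasReport:
    return BiasReport(egger=egger_test(effects), begg=begg_test(effects),
                      funnel=funnel_data(effects))


@dataclass(frozen=True)
class InfluenceEntry:
    omitted_study: str
    pooled: PooledResult


@dataclass(frozen=True)
class InfluenceReport:
    entries: list[InfluenceEntry]
    min_or: float
    max_or: float
    crosses_null: bool  # any omission moves the 95% CI across OR = 1

    def __len__(self) -> int:
        return len(self.entries)


def influence_analysis(effects: Sequence[EffectEstimate],
                       method: PoolMethod = PoolMethod.DL_RANDOM
                       ) -> InfluenceReport:
    """Leave-one-out sensitivity: re-pool after deleting each study in turn."""
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError("influence analysis needs k >= 2")
    pooler: Callable[[Sequence[EffectEstimate]], PooledResult]
    if method is PoolMethod.DL_RANDOM:
        pooler = pool_dersimonian_laird
    elif method is PoolMethod.IV_FIXED:
        pooler = pool_inverse_variance
    else:
        raise ValueError("influence analysis supports IV_fixed or DL_random")
    full = pooler(effects)
    full_sig = full.ci_low > 1.0 or full.ci_high < 1.0
    entries = []
    crosses = False
    for i in range(k):
        sub = [e for j, e in enumerate(effects) if j != i]
        res = pooler(sub)
        entries.append(InfluenceEntry(omitted_study=effects[i].study_id,
                                      pooled=res))
        sig = res.ci_low > 1.0 or res.ci_high < 1.0
        if sig != full_sig:
            crosses = True
    ors = [e.pooled.or_ for e in entries]
    return InfluenceReport(entries=entries, min_or=min(ors), max_or=max(ors),
                           crosses_null=crosses)
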