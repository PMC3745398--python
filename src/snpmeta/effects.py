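"""Per-study 2x2 contrast tables and Woolf odds-ratio estimates.

Five genetic contrasts for a biallelic risk allele A vs other allele G:

* ``allele``       — A vs G counted on alleles (two per subject);
* ``dominant``     — carriers (AA+AG) vs GG;
* ``recessive``    — AA vs (AG+GG);
* ``heterozygous`` — AG vs GG (AA subjects dropped);
* ``homozygous``   — AA vs GG (AG subjects dropped).

The log odds ratio and its large-sample standard error follow Woolf:
``log OR = ln(ad/bc)``, ``SE = sqrt(1/a + 1/b + 1/c + 1/d)``. A single zero
cell triggers the Haldane–Anscombe continuity correction (0.5 added to all
four cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .exceptions import CapabilityError, NonEstimableError
from .study_io import StudyRecord, StratumRecord, allele_counts_from_raf

#: Normal 97.5% quantile used for all 95% confidence intervals.
Z975 = 1.959964


class GeneticModel(str, Enum):
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


#: Models computable from genotype counts only.
GENOTYPE_MODELS = (GeneticModel.DOMINANT, GeneticModel.RECESSIVE,
                   GeneticModel.HETEROZYGOUS, GeneticModel.HOMOZYGOUS)


@dataclass(frozen=True)
class ContrastTable:
    """2x2 exposure-by-status table: a,b = cases, c,d = controls."""

    model: GeneticModel
    a: float  # exposed cases
    b: float  # unexposed cases
    c: float  # exposed controls
    d: float  # unexposed controls
    corrected: bool = False

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """Study-level log odds ratio with Woolf standard error and 95% CI."""

    study_id: str
    model: GeneticModel
    log_or: float
    se: float

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def variance(self) -> float:
        return self.se ** 2

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z975 * self.se)


def _contrast_cells(genotypes, model: GeneticModel) -> tuple[float, float]:
    """(exposed, unexposed) counts for one arm under a genotype contrast."""
    rr, rn, nn = genotypes
    if model is GeneticModel.ALLELE:
        return 2 * rr + rn, rn + 2 * nn
    if model is GeneticModel.DOMINANT:
        return rr + rn, nn
    if model is GeneticModel.RECESSIVE:
        return rr, rn + nn
    if model is GeneticModel.HETEROZYGOUS:
        return rn, nn
    if model is GeneticModel.HOMOZYGOUS:
        return rr, nn
    raise ValueError(model)


def build_contrast(record: StudyRecord, model: GeneticModel,
                   stratum: Optional[StratumRecord] = None) -> ContrastTable:
    """Build the 2x2 table for ``model`` from a study record.

    Genotype-based models need genotype triples; the allele contrast also
    accepts RAF + N via the allele-count reconstruction. When ``stratum`` is
    given, its cases are contrasted against the whole study's controls.
    """
    case_gt = stratum.case_genotypes if stratum is not None else record.case_genotypes
    case_raf = stratum.raf_case if stratum is not None else record.raf_case
    case_n = stratum.n_case if stratum is not None else record.n_case

    if model in GENOTYPE_MODELS and (case_gt is None or
                                     record.control_genotypes is None):
        raise CapabilityError(
            f"{record.study_id}: model {model.value!r} needs genotype counts; "
            f"usable models: ['{GeneticModel.ALLELE.value}']")

    if case_gt is not None and record.control_genotypes is not None:
        a, b = _contrast_cells(case_gt, model)
        c, d = _contrast_cells(record.control_genotypes, model)
        return ContrastTable(model=model, a=a, b=b, c=c, d=d)

    # allele model, with RAF + N filling in for a missing genotype triple
    assert model is GeneticModel.ALLELE
    if case_gt is not None:
        a, b = _contrast_cells(case_gt, model)
    elif case_raf is not None:
        a, b = allele_counts_from_raf(case_raf, case_n)
    else:
        raise CapabilityError(f"{record.study_id}: no genotype counts or RAF")
    if record.control_genotypes is not None:
        c, d = _contrast_cells(record.control_genotypes, model)
    elif record.raf_control is not None:
        c, d = allele_counts_from_raf(record.raf_control, record.n_control)
    else:
        raise CapabilityError(f"{record.study_id}: no genotype counts or RAF")
    return ContrastTable(model=model, a=a, b=b, c=c, d=d)


def woolf_effect(table: ContrastTable, study_id: str = "") -> EffectEstimate:
    """Woolf log odds ratio and SE, continuity-corrected on zero cells."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise NonEstimableError(
            f"{study_id or 'table'}: odds ratio non-estimable "
            "(an exposure margin is empty)")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(study_id=study_id, model=table.model,
                          log_or=log_or, se=se)


def study_effect(record: StudyRecord, model: GeneticModel,
                 stratum: Optional[StratumRecord] = None) -> EffectEstimate:
    """Convenience: contrast table then Woolf estimate, labelled by study."""
    table = build_contrast(record, model, stratum=stratum)
    label = record.study_id if stratum is None \
        else f"{record.study_id}:{stratum.label.value}"
    return woolf_effect(table, study_id=label)
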