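"""Hardy–Weinberg equilibrium testing of control genotypes.

Deviation from HWE in the control arm of a case-control study commonly
signals genotyping error or population stratification, so studies whose
controls fail the test are excluded from pooling. The test is the Pearson
chi-square on the three genotype classes against expectations computed from
the estimated allele frequency, with 1 degree of freedom (one parameter, the
allele frequency, is estimated from the data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .exceptions import DomainError
from .study_io import Genotypes, StudyTable, genotype_table_from_hwe

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    passes: bool
    monomorphic: bool = False


def hwe_chi2(genotypes: Genotypes, alpha: float = DEFAULT_ALPHA) -> HWEResult:
    """Pearson chi-square goodness-of-fit test for HWE on a genotype triple."""
    rr, rn, nn = genotypes
    if min(rr, rn, nn) < 0:
        raise DomainError("negative genotype count")
    n = rr + rn + nn
    if n == 0:
        raise DomainError("empty genotype sample")
    p_hat = (2 * rr + rn) / (2 * n)
    if p_hat in (0.0, 1.0):
        expected = (n * p_hat ** 2, 2 * n * p_hat * (1 - p_hat),
                    n * (1 - p_hat) ** 2)
        return HWEResult(chi2=0.0, df=1, p_value=1.0, expected=expected,
                         passes=True, monomorphic=True)
    expected = genotype_table_from_hwe(p_hat, n)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(genotypes, expected))
    p_value = float(stats.chi2.sf(chi2, 1))
    return HWEResult(chi2=chi2, df=1, p_value=p_value, expected=expected,
                     passes=p_value >= alpha)


@dataclass(frozen=True)
class ExclusionEntry:
    study_id: str
    chi2: float | None
    p_value: float | None
    action: str  # "excluded" | "retained" | "not_testable"


def filter_studies_by_hwe(table: StudyTable, alpha: float = DEFAULT_ALPHA
                          ) -> tuple[StudyTable, list[ExclusionEntry]]:
    """Drop studies whose control genotypes deviate from HWE at ``alpha``.

    Studies carrying only allele frequencies are retained and flagged
    ``not_testable`` — the chi-square needs the genotype distribution.
    """
    kept = []
    log: list[ExclusionEntry] = []
    for rec in table.records:
        if rec.control_genotypes is None:
            kept.append(rec)
            log.append(ExclusionEntry(rec.study_id, None, None, "not_testable"))
            logger.warning("%s: HWE not testable (no control genotypes); retained",
                           rec.study_id)
            continue
        res = hwe_chi2(rec.control_genotypes, alpha=alpha)
        if res.passes:
            kept.append(rec)
            log.append(ExclusionEntry(rec.study_id, res.chi2, res.p_value,
                                      "retained"))
        else:
            log.append(ExclusionEntry(rec.study_id, res.chi2, res.p_value,
                                      "excluded"))
            logger.warning("%s: excluded, control HWE p=%.4g < %g",
                           rec.study_id, res.p_value, alpha)
    return StudyTable(kept, table.provenance), log


def write_exclusion_log(log: list[ExclusionEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("study_id\thwe_chi2\thwe_p\taction\n")
        for e in log:
            chi2 = "" if e.chi2 is None else format(e.chi2, "g")
            p = "" if e.p_value is None else format(e.p_value, "g")
            fh.write(f"{e.study_id}\t{chi2}\t{p}\t{e.action}\n")
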