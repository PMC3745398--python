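"""Synthetic case-control SNP study generator.

Generates study collections with the structure the pooling machinery
assumes, so parameter recovery can be checked end to end without external
data:

* control genotypes are multinomial draws from Hardy–Weinberg proportions
  at an ethnicity-specific risk-allele frequency ``p0`` (Beta-distributed
  across studies);
* a study-specific per-allele odds ratio ``lam_i = exp(N(ln OR, tau2))``
  introduces between-study heterogeneity on the log-OR scale;
* case genotype probabilities are the HWE probabilities re-weighted by
  exposure odds — ``(lam^2, lam, 1)`` per allele copy for a per-allele
  (log-additive) model of action — which yields the target genotype odds
  ratios exactly in expectation without fixing a disease prevalence;
* optional hormone-receptor strata draw case genotypes the same way with
  subtype-specific odds ratios against the shared control arm.

Under the per-allele model the expected case risk-allele frequency has the
closed form ``p1 = lam p0 / (lam p0 + 1 - p0)``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .study_io import (ControlSource, Design, EthnicGroup, StratumLabel,
                       StratumRecord, StudyRecord, StudyTable,
                       write_study_table)

#: Ethnicity-specific control risk-allele frequency distributions:
#: Beta parameterized by (mean, concentration). Means follow the observed
#: control frequencies for rs13387042-A (0.51 White, 0.12 East Asian,
#: 0.72 African); concentrations give the between-study spread seen in the
#: study table.
DEFAULT_RAF_DISTS: dict[EthnicGroup, tuple[float, float]] = {
    EthnicGroup.WHITE: (0.51, 100.0),
    EthnicGroup.EAST_ASIAN: (0.12, 40.0),
    EthnicGroup.AFRICAN: (0.72, 30.0),
    EthnicGroup.OTHER: (0.55, 30.0),
}

#: Study-count mix over ethnic groups in the 26-study collection (14/6/5/1).
DEFAULT_MIX: dict[EthnicGroup, float] = {
    EthnicGroup.WHITE: 14 / 26,
    EthnicGroup.EAST_ASIAN: 6 / 26,
    EthnicGroup.AFRICAN: 5 / 26,
    EthnicGroup.OTHER: 1 / 26,
}


class SubtypeSpec(BaseModel):
    """Subtype-specific per-allele odds ratios for case strata."""

    or_er_pos: float = 1.17
    or_er_neg: float = 1.08
    or_pr_pos: float = 1.18
    or_pr_neg: float = 1.10
    er_pos_fraction: float = Field(0.7, gt=0, lt=1)
    pr_pos_fraction: float = Field(0.65, gt=0, lt=1)


class SimulationConfig(BaseModel):
    """Generating parameters of a synthetic meta-analysis."""

    k: int = Field(26, ge=0)
    seed: int = 0
    ethnicity_mix: dict[EthnicGroup, float] = Field(
        default_factory=lambda: dict(DEFAULT_MIX))
    raf_dists: dict[EthnicGroup, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_RAF_DISTS))
    true_or: float = Field(1.14, gt=0)
    tau2: float = Field(0.002, ge=0)
    n_case_range: tuple[int, int] = (500, 10000)
    n_control_range: tuple[int, int] = (500, 10000)
    gwas_fraction: float = Field(5 / 26, ge=0, le=1)
    subtype_spec: Optional[SubtypeSpec] = None
    model_of_action: str = "per_allele"  # per_allele | dominant | recessive

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        total = sum(self.ethnicity_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ethnicity mix sums to {total}, expected 1")
        if self.model_of_action not in ("per_allele", "dominant", "recessive"):
            raise ValueError(f"unknown model of action {self.model_of_action!r}")
        for low, high in (self.n_case_range, self.n_control_range):
            if low <= 0 or high < low:
                raise ValueError("sample-size ranges must satisfy 0 < low <= high")
        return self


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def hwe_probs(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([p * p, 2 * p * q, q * q])


def genotype_weights(lam: float, model_of_action: str) -> np.ndarray:
    """Exposure-odds weights for (risk-hom, het, other-hom)."""
    if model_of_action == "per_allele":
        return np.array([lam * lam, lam, 1.0])
    if model_of_action == "dominant":
        return np.array([lam, lam, 1.0])
    if model_of_action == "recessive":
        return np.array([lam, 1.0, 1.0])
    raise ValueError(model_of_action)


def expected_case_raf(lam: float, p0: float) -> float:
    """Expected case risk-allele frequency under the per-allele model."""
    return lam * p0 / (lam * p0 + 1.0 - p0)


def _case_probs(p0: float, lam: float, model_of_action: str) -> np.ndarray:
    w = hwe_probs(p0) * genotype_weights(lam, model_of_action)
    return w / w.sum()


def _log_uniform_int(rng: np.random.Generator, low: int, high: int) -> int:
    if low == high:
        return low
    return int(round(np.exp(rng.uniform(np.log(low), np.log(high)))))


def simulate_study(config: SimulationConfig, study_index: int,
                   rng: np.random.Generator) -> StudyRecord:
    """Draw one synthetic study record from the generating model."""
    groups = list(config.ethnicity_mix)
    probs = np.array([config.ethnicity_mix[g] for g in groups])
    group = groups[rng.choice(len(groups), p=probs / probs.sum())]
    a, b = _beta_params(*config.raf_dists[group])
    p0 = float(np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4))
    lam = float(np.exp(rng.normal(np.log(config.true_or),
                                  np.sqrt(config.tau2))))
    n_case = _log_uniform_int(rng, *config.n_case_range)
    n_control = _log_uniform_int(rng, *config.n_control_range)

    control = tuple(int(x) for x in
                    rng.multinomial(n_control, hwe_probs(p0)))
    case = tuple(int(x) for x in
                 rng.multinomial(n_case, _case_probs(p0, lam,
                                                     config.model_of_action)))

    strata: list[StratumRecord] = []
    if config.subtype_spec is not None:
        spec = config.subtype_spec
        for frac, lab_pos, lab_neg, or_pos, or_neg in (
                (spec.er_pos_fraction, StratumLabel.ER_POS, StratumLabel.ER_NEG,
                 spec.or_er_pos, spec.or_er_neg),
                (spec.pr_pos_fraction, StratumLabel.PR_POS, StratumLabel.PR_NEG,
                 spec.or_pr_pos, spec.or_pr_neg)):
            n_pos = int(round(frac * n_case))
            n_neg = n_case - n_pos
            for n_sub, lab, or_sub in ((n_pos, lab_pos, or_pos),
                                       (n_neg, lab_neg, or_neg)):
                # subtype effects share the study's heterogeneity deviate
                lam_sub = or_sub * lam / config.true_or
                gt = tuple(int(x) for x in rng.multinomial(
                    n_sub, _case_probs(p0, lam_sub, config.model_of_action)))
                strata.append(StratumRecord(label=lab, n_case=n_sub,
                                            case_genotypes=gt))

    design = Design.GWAS if rng.random() < config.gwas_fraction \
        else Design.CANDIDATE_GENE
    return StudyRecord(
        study_id=f"sim{study_index:03d}",
        first_author="Synthetic",
        year=2013,
        ethnicity_raw=group.value,
        ethnic_group=group,
        design=design,
        control_source=ControlSource.GP,
        genotyping_method="simulated",
        n_case=n_case,
        n_control=n_control,
        case_genotypes=case,
        control_genotypes=control,
        raf_case=None,
        raf_control=None,
        strata=tuple(strata),
    )


def simulate_meta(config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None) -> StudyTable:
    """Draw a whole study collection; reproducible from ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = [simulate_study(config, i, rng) for i in range(config.k)]
    return StudyTable(records, provenance=f"simulated (seed={config.seed})")


def simulate_to_tsv(config: SimulationConfig, path) -> StudyTable:
    table = simulate_meta(config)
    write_study_table(table, path)
    return table
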