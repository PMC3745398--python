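"""End-to-end orchestration: read, filter, estimate, pool, explore, report.

The pipeline is deterministic: a run configuration plus an input table fixes
every number in the output bundle. Partial failures (a genotype-based model
requested on a frequency-only study, a non-estimable effect) are recorded
per cell and never abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import __version__
from .bias import funnel_data, influence_analysis, publication_bias
from .effects import GeneticModel, build_contrast, study_effect
from .exceptions import (CapabilityError, InsufficientStudiesError,
                         NonEstimableError)
from .hwe import filter_studies_by_hwe, write_exclusion_log
from .moderators import subgroup_analysis
from .pooling import PoolMethod, pool
from .study_io import StudyTable, read_study_table

logger = logging.getLogger(__name__)

TSV_SIG_DIGITS = 6


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    models: list[GeneticModel] = Field(
        default_factory=lambda: list(GeneticModel))
    methods: list[PoolMethod] = Field(
        default_factory=lambda: [PoolMethod.MH_FIXED, PoolMethod.IV_FIXED,
                                 PoolMethod.DL_RANDOM])
    subgroup_by: list[str] = Field(
        default_factory=lambda: ["ethnic_group", "design"])
    hwe_alpha: float = Field(0.05, gt=0, lt=1)
    headline_method: PoolMethod = PoolMethod.DL_RANDOM
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:16]


def _g(x: float) -> str:
    return format(x, f".{TSV_SIG_DIGITS}g")


def _effects_tsv(rows: list[dict], path: Path) -> None:
    cols = ["study_id", "model", "a", "b", "c", "d", "or", "ci_low",
            "ci_high", "log_or", "se"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) if c in ("study_id", "model")
                               else _g(r[c]) for c in cols) + "\n")


def run_pipeline(config: RunConfig,
                 table: Optional[StudyTable] = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the in-memory report (also serialized under
    ``config.output_dir``): per-study effects, pooled results per
    model x method, subgroup reports, bias diagnostics, influence analysis,
    the HWE exclusion log and a reproducibility manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = read_study_table(config.input_path)

    table, hwe_log = filter_studies_by_hwe(table, alpha=config.hwe_alpha)
    write_exclusion_log(hwe_log, out / "hwe_exclusions.tsv")

    report: dict = {"pooled": {}, "subgroups": {}, "skipped": [],
                    "k_input": len(table)}
    effect_rows: list[dict] = []

    for model in config.models:
        effects, tables = [], []
        for rec in table.records:
            try:
                t = build_contrast(rec, model)
                e = study_effect(rec, model)
            except (CapabilityError, NonEstimableError) as exc:
                report["skipped"].append({"study_id": rec.study_id,
                                          "model": model.value,
                                          "reason": str(exc)})
                logger.warning("skipping %s under %s: %s",
                               rec.study_id, model.value, exc)
                continue
            tables.append(t)
            effects.append(e)
            effect_rows.append({"study_id": rec.study_id, "model": model.value,
                                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                                "or": e.or_, "ci_low": e.ci_low,
                                "ci_high": e.ci_high, "log_or": e.log_or,
                                "se": e.se})
        if not effects:
            continue
        for method in config.methods:
            res = pool(effects, method, tables=tables)
            report["pooled"][f"{model.value}:{method.value}"] = res.to_dict()

        kept_ids = {e.study_id for e in effects}
        sub_table = table.subset(kept_ids)
        for group_by in config.subgroup_by:
            try:
                sr = subgroup_analysis(sub_table, model,
                                       method=config.headline_method,
                                       group_by=group_by)
            except (CapabilityError, InsufficientStudiesError) as exc:
                report["skipped"].append({"model": model.value,
                                          "subgroup": group_by,
                                          "reason": str(exc)})
                continue
            report["subgroups"][f"{model.value}:{group_by}"] = {
                "q_between": sr.q_between, "df_between": sr.df_between,
                "p_between": sr.p_between,
                "groups": {g: r.to_dict() for g, r in sr.groups.items()},
            }
        if model is GeneticModel.ALLELE:
            try:
                bias = publication_bias(effects)
                report["bias"] = {
                    "egger": asdict(bias.egger), "begg": asdict(bias.begg)}
                with open(out / "funnel.tsv", "w", encoding="utf-8") as fh:
                    fh.write("log_or\tse\n")
                    for lo, se in funnel_data(effects):
                        fh.write(f"{_g(lo)}\t{_g(se)}\n")
            except InsufficientStudiesError as exc:
                report["skipped"].append({"stage": "bias", "reason": str(exc)})
            try:
                infl = influence_analysis(effects,
                                          method=config.headline_method)
                report["influence"] = {
                    "min_or": infl.min_or, "max_or": infl.max_or,
                    "crosses_null": infl.crosses_null,
                    "entries": [{"omitted": e.omitted_study,
                                 **e.pooled.to_dict()}
                                for e in infl.entries]}
            except InsufficientStudiesError as exc:
                report["skipped"].append({"stage": "influence",
                                          "reason": str(exc)})

    _effects_tsv(effect_rows, out / "effects.tsv")
    report["manifest"] = {"config": json.loads(config.model_dump_json()),
                          "config_digest": config.digest(),
                          "package_version": __version__,
                          "n_case_total": table.n_case_total,
                          "n_control_total": table.n_control_total}
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
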