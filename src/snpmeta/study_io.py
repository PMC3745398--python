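"""Study-table data model and TSV input/output.

The unit of analysis is the *study*: one row of a tab-separated table carrying
labels (author, year), moderators (ethnic group, design, control source,
genotyping method) and the genetic data, which is either a genotype count
triple per arm (risk-allele homozygote, heterozygote, other homozygote) or a
risk-allele frequency (RAF) plus subject count. Case-only subtype strata
(ER/PR status, invasiveness) may ride along on extra rows that share the
parent study's controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .exceptions import DomainError, FormatError, TableValidationError

logger = logging.getLogger(__name__)

#: Canonical column order of the TSV dialect.
COLUMNS = [
    "study_id", "first_author", "year", "ethnicity", "design",
    "control_source", "genotyping_method", "n_case", "n_control",
    "case_rr", "case_rn", "case_nn", "ctrl_rr", "ctrl_rn", "ctrl_nn",
    "raf_case", "raf_control", "stratum",
]

#: Tolerance for RAF vs genotype-count consistency (table rounding to 2 dp).
RAF_TOLERANCE = 0.005


class EthnicGroup(str, Enum):
    WHITE = "White"
    EAST_ASIAN = "EastAsian"
    AFRICAN = "African"
    OTHER = "Other"


class Design(str, Enum):
    GWAS = "GWAS"
    CANDIDATE_GENE = "CandidateGene"


class ControlSource(str, Enum):
    GP = "GP"      # general population
    HP = "HP"      # hospital patients
    MIXED = "mixed"


class StratumLabel(str, Enum):
    ER_POS = "ERpos"
    ER_NEG = "ERneg"
    PR_POS = "PRpos"
    PR_NEG = "PRneg"
    INVASIVE = "invasive"
    IN_SITU = "in_situ"


Genotypes = tuple[int, int, int]  # (risk-hom, het, other-hom)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (platform independent)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def raf_from_genotypes(genotypes: Genotypes) -> float:
    rr, rn, nn = genotypes
    n = rr + rn + nn
    if n <= 0:
        raise DomainError("genotype triple sums to zero")
    return (2 * rr + rn) / (2 * n)


@dataclass(frozen=True)
class StratumRecord:
    """Case-only subtype stratum sharing the parent study's control arm."""

    label: StratumLabel
    n_case: int
    case_genotypes: Optional[Genotypes] = None
    raf_case: Optional[float] = None

    def __post_init__(self) -> None:
        _check_arm("stratum case", self.n_case, self.case_genotypes, self.raf_case)


@dataclass(frozen=True)
class StudyRecord:
    """One study (or one ethnicity-specific dataset of a multi-ethnic study)."""

    study_id: str
    first_author: str
    year: int
    ethnicity_raw: str
    ethnic_group: EthnicGroup
    design: Design
    control_source: ControlSource
    genotyping_method: str
    n_case: int
    n_control: int
    case_genotypes: Optional[Genotypes] = None
    control_genotypes: Optional[Genotypes] = None
    raf_case: Optional[float] = None
    raf_control: Optional[float] = None
    strata: tuple[StratumRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise TableValidationError(f"{self.study_id}: negative subject count")
        _check_arm(f"{self.study_id} case", self.n_case,
                   self.case_genotypes, self.raf_case)
        _check_arm(f"{self.study_id} control", self.n_control,
                   self.control_genotypes, self.raf_control)

    @property
    def has_genotypes(self) -> bool:
        return self.case_genotypes is not None and self.control_genotypes is not None

    def effective_raf_case(self) -> float:
        if self.case_genotypes is not None:
            return raf_from_genotypes(self.case_genotypes)
        assert self.raf_case is not None
        return self.raf_case

    def effective_raf_control(self) -> float:
        if self.control_genotypes is not None:
            return raf_from_genotypes(self.control_genotypes)
        assert self.raf_control is not None
        return self.raf_control


def _check_arm(where: str, n: int, genotypes: Optional[Genotypes],
               raf: Optional[float]) -> None:
    if genotypes is None and raf is None:
        raise TableValidationError(
            f"{where}: needs genotype counts or a risk-allele frequency")
    if genotypes is not None:
        if any(g < 0 for g in genotypes):
            raise TableValidationError(f"{where}: negative genotype count")
        if sum(genotypes) != n:
            raise TableValidationError(
                f"{where}: genotype counts sum to {sum(genotypes)}, expected {n}")
    if raf is not None and not 0.0 <= raf <= 1.0:
        raise TableValidationError(f"{where}: RAF {raf} outside [0, 1]")
    if genotypes is not None and raf is not None and n > 0:
        implied = raf_from_genotypes(genotypes)
        if abs(implied - raf) > RAF_TOLERANCE:
            raise TableValidationError(
                f"{where}: RAF {raf} inconsistent with genotype counts "
                f"(implied {implied:.4f})")


@dataclass
class StudyTable:
    """Ordered collection of study records (order is forest-plot order)."""

    records: list[StudyRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.study_id in seen:
                raise TableValidationError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, study_id: str) -> StudyRecord:
        for rec in self.records:
            if rec.study_id == study_id:
                return rec
        raise KeyError(study_id)

    def subset(self, keep: Iterable[str]) -> "StudyTable":
        keep = set(keep)
        return StudyTable([r for r in self.records if r.study_id in keep],
                          self.provenance)

    @property
    def n_case_total(self) -> int:
        return sum(r.n_case for r in self.records)

    @property
    def n_control_total(self) -> int:
        return sum(r.n_control for r in self.records)


# ---------------------------------------------------------------------------
# Ethnicity mapping
# ---------------------------------------------------------------------------

def load_ethnicity_map(path: Optional[Path] = None) -> dict[str, EthnicGroup]:
    """Load a label→group map; defaults to the map shipped with the package."""
    if path is None:
        with resources.files("snpmeta.data").joinpath("ethnicity_map.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return {row.label: EthnicGroup(row.group) for row in frame.itertuples()}


def assign_ethnic_group(ethnicity_raw: str,
                        mapping: dict[str, EthnicGroup]) -> EthnicGroup:
    """Map a free-text ethnicity to one of the four analysis groups.

    Multi-population labels ("European, Asian") resolve to the first listed
    population. Unmapped labels fall back to ``Other`` with a warning.
    """
    first = ethnicity_raw.split(",")[0].strip()
    group = mapping.get(first) or mapping.get(ethnicity_raw.strip())
    if group is None:
        logger.warning("ethnicity %r not in mapping; assigning Other",
                       ethnicity_raw)
        return EthnicGroup.OTHER
    return group


# ---------------------------------------------------------------------------
# Allele / genotype arithmetic
# ---------------------------------------------------------------------------

def allele_counts_from_raf(raf: float, n: int) -> tuple[int, int]:
    """(risk, non-risk) allele counts for ``n`` subjects at frequency ``raf``.

    Counts are rounded half-away-from-zero; they conserve 2N exactly.
    """
    if not 0.0 <= raf <= 1.0:
        raise DomainError(f"allele frequency {raf} outside [0, 1]")
    if n <= 0:
        raise DomainError("subject count must be positive")
    risk = round_half_away(2 * n * raf)
    return risk, 2 * n - risk


def allele_table_from_raf(raf_case: float, n_case: int,
                          raf_control: float, n_control: int):
    """Reconstruct the allele-contrast 2x2 table from frequencies and sizes.

    Used for studies that publish RAF and subject counts but not genotype
    distributions; exposure is carriage of the risk allele, with two alleles
    counted per subject.
    """
    from .effects import ContrastTable, GeneticModel

    a, b = allele_counts_from_raf(raf_case, n_case)
    c, d = allele_counts_from_raf(raf_control, n_control)
    return ContrastTable(model=GeneticModel.ALLELE, a=a, b=b, c=c, d=d)


def genotype_table_from_hwe(raf: float, n: float) -> tuple[float, float, float]:
    """Expected genotype counts (n p^2, 2n p(1-p), n (1-p)^2) under HWE."""
    if not 0.0 <= raf <= 1.0:
        raise DomainError(f"allele frequency {raf} outside [0, 1]")
    if n <= 0:
        raise DomainError("sample size must be positive")
    p, q = raf, 1.0 - raf
    return n * p * p, 2 * n * p * q, n * q * q


# ---------------------------------------------------------------------------
# TSV reading / writing
# ---------------------------------------------------------------------------

def _parse_int(value, where: str, column: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        as_float = float(value)
    except ValueError:
        raise TableValidationError(f"{where}: column {column!r} not numeric: {value!r}")
    if as_float != int(as_float):
        raise TableValidationError(f"{where}: column {column!r} not an integer: {value!r}")
    return int(as_float)

def _parse_float(value, where: str, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise TableValidationError(f"{where}: column {column!r} not numeric: {value!r}")


def _triple(row, prefix: str, where: str) -> Optional[Genotypes]:
    vals = [_parse_int(row[f"{prefix}_{g}"], where, f"{prefix}_{g}")
            for g in ("rr", "rn", "nn")]
    if all(v is None for v in vals):
        return None
    if any(v is None for v in vals):
        raise TableValidationError(f"{where}: partial genotype triple {prefix}_*")
    return (vals[0], vals[1], vals[2])  # type: ignore[return-value]


def read_study_table(path, ethnicity_map: Optional[dict[str, EthnicGroup]] = None,
                     provenance: str = "") -> StudyTable:
    """Read a study table from the TSV dialect documented in :data:`COLUMNS`.

    Rows with a non-empty ``stratum`` column are case-only subtype strata and
    are attached to the whole-study row with the same ``study_id``, which must
    appear first. Empty optional cells become absent fields, never zeros.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if ethnicity_map is None:
        ethnicity_map = load_ethnicity_map()

    records: list[StudyRecord] = []
    index: dict[str, int] = {}
    for i, row in frame.iterrows():
        where = f"{path} row {i + 2}"  # 1-based with header
        study_id = row["study_id"].strip()
        if not study_id:
            raise TableValidationError(f"{where}: empty study_id")
        where = f"{where} ({study_id})"
        stratum = row["stratum"].strip()
        if stratum:
            if study_id not in index:
                raise TableValidationError(
                    f"{where}: stratum row precedes its whole-study row")
            try:
                label = StratumLabel(stratum)
            except ValueError:
                raise TableValidationError(f"{where}: unknown stratum {stratum!r}")
            n_case = _parse_int(row["n_case"], where, "n_case")
            if n_case is None:
                raise TableValidationError(f"{where}: stratum row lacks n_case")
            srec = StratumRecord(
                label=label, n_case=n_case,
                case_genotypes=_triple(row, "case", where),
                raf_case=_parse_float(row["raf_case"], where, "raf_case"))
            parent = records[index[study_id]]
            records[index[study_id]] = replace(parent,
                                               strata=parent.strata + (srec,))
            continue

        if study_id in index:
            raise TableValidationError(f"{where}: duplicate study_id")
        n_case = _parse_int(row["n_case"], where, "n_case")
        n_control = _parse_int(row["n_control"], where, "n_control")
        if n_case is None or n_control is None:
            raise TableValidationError(f"{where}: missing subject counts")
        rec = StudyRecord(
            study_id=study_id,
            first_author=row["first_author"].strip(),
            year=_parse_int(row["year"], where, "year") or 0,
            ethnicity_raw=row["ethnicity"].strip(),
            ethnic_group=assign_ethnic_group(row["ethnicity"], ethnicity_map),
            design=Design(row["design"].strip()),
            control_source=ControlSource(row["control_source"].strip()),
            genotyping_method=row["genotyping_method"].strip(),
            n_case=n_case,
            n_control=n_control,
            case_genotypes=_triple(row, "case", where),
            control_genotypes=_triple(row, "ctrl", where),
            raf_case=_parse_float(row["raf_case"], where, "raf_case"),
            raf_control=_parse_float(row["raf_control"], where, "raf_control"),
        )
        index[study_id] = len(records)
        records.append(rec)
    return StudyTable(records, provenance=provenance or str(path))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_study_table(table: StudyTable, path) -> None:
    """Write a table back to the TSV dialect (round-trips all field values)."""
    rows = []
    for rec in table.records:
        cg = rec.case_genotypes or (None, None, None)
        ng = rec.control_genotypes or (None, None, None)
        rows.append([rec.study_id, rec.first_author, rec.year, rec.ethnicity_raw,
                     rec.design.value, rec.control_source.value,
                     rec.genotyping_method, rec.n_case, rec.n_control,
                     cg[0], cg[1], cg[2], ng[0], ng[1], ng[2],
                     rec.raf_case, rec.raf_control, ""])
        for s in rec.strata:
            sg = s.case_genotypes or (None, None, None)
            rows.append([rec.study_id, rec.first_author, rec.year,
                         rec.ethnicity_raw, rec.design.value,
                         rec.control_source.value, rec.genotyping_method,
                         s.n_case, "", sg[0], sg[1], sg[2], "", "", "",
                         s.raf_case, "", s.label.value])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def load_example_table() -> StudyTable:
    """The 26-study breast-cancer table for rs13387042 shipped with the package."""
    with resources.as_file(
            resources.files("snpmeta.data").joinpath("table1.tsv")) as p:
        return read_study_table(p, provenance="shipped 26-study rs13387042 table")
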