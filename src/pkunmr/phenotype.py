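"""Genotype/phenotype stratification and per-phenotype summaries.

Patients are stratified by their genotype/phenotype value (GPV): GPV in
[0, 2.7] is classical PKU, GPV in (2.7, 7] is mild PKU/HPA.  When GPV is
unavailable, a serum Phe above 1200 umol/L falls back to classical PKU;
anything else is left undetermined (a candidate for metabolome projection).
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from statistics import mean as _mean, stdev as _stdev

from .errors import InvalidParameterError

__all__ = [
    "PatientRecord",
    "PhenotypeConfig",
    "stratify_gpv",
    "flag_inconsistencies",
    "group_summary",
    "load_table2_fixture",
    "read_metadata_csv",
    "write_metadata_csv",
]

CPKU = "cPKU"
MPKU = "mPKU"
UNDETERMINED = "undetermined"


@dataclass
class PatientRecord:
    patient_id: str
    phe_serum: float
    gpv: float | None = None
    phenotype: str = UNDETERMINED
    allele1: str | None = None
    allele2: str | None = None
    sapropterin: bool = False
    protein_intake: float | None = None
    age: float | None = None
    sex: str | None = None
    response: float | None = None  # synthetic planted response (simulation only)

    def __post_init__(self) -> None:
        if self.phe_serum < 0:
            raise InvalidParameterError(f"{self.patient_id}: phe_serum must be >= 0")
        if self.protein_intake is not None and self.protein_intake < 0:
            raise InvalidParameterError(f"{self.patient_id}: protein_intake must be >= 0")


@dataclass(frozen=True)
class PhenotypeConfig:
    cpku_gpv_max: float = 2.7
    mpku_gpv_max: float = 7.0
    classical_phe_threshold: float = 1200.0

    def __post_init__(self) -> None:
        if not (0 < self.cpku_gpv_max < self.mpku_gpv_max):
            raise InvalidParameterError("require 0 < cpku_gpv_max < mpku_gpv_max")


def stratify_gpv(record: PatientRecord, config: PhenotypeConfig = PhenotypeConfig()) -> str:
    """Assign a phenotype from GPV, with the high-Phe fallback when GPV is missing."""
    if record.gpv is not None:
        if record.gpv < 0:
            raise InvalidParameterError(f"{record.patient_id}: negative gpv {record.gpv}")
        if record.gpv <= config.cpku_gpv_max:
            return CPKU
        if record.gpv <= config.mpku_gpv_max:
            return MPKU
        return UNDETERMINED
    if record.phe_serum > config.classical_phe_threshold:
        return CPKU
    return UNDETERMINED


def flag_inconsistencies(
    records: list[PatientRecord], config: PhenotypeConfig = PhenotypeConfig()
) -> list[str]:
    """Report records whose stored phenotype label disagrees with the GPV rule.

    Stored labels are never overwritten; disagreements (which occur in the
    packaged reference cohort) are surfaced for the run report.
    """
    flags = []
    for rec in records:
        derived = stratify_gpv(rec, config)
        if derived != UNDETERMINED and rec.phenotype not in (UNDETERMINED, derived):
            flags.append(
                f"patient {rec.patient_id}: labeled {rec.phenotype} but GPV rule gives {derived}"
            )
    return flags


def group_summary(records: list[PatientRecord], field_name: str) -> dict[str, dict]:
    """Per-phenotype n, arithmetic mean and sample SD (n-1) of a numeric field."""
    valid = {f.name for f in fields(PatientRecord)}
    if field_name not in valid:
        raise InvalidParameterError(f"unknown field {field_name!r}")
    groups: dict[str, list[float]] = {}
    for rec in records:
        value = getattr(rec, field_name)
        if value is None:
            continue
        groups.setdefault(rec.phenotype, []).append(float(value))
    out = {}
    for pheno, values in sorted(groups.items()):
        if len(values) < 2:
            warnings.warn(
                f"group {pheno!r} has {len(values)} record(s); SD undefined", stacklevel=2
            )
            sd = None
        else:
            sd = _stdev(values)
        out[pheno] = {"n": len(values), "mean": _mean(values), "sd": sd}
    return out


_CSV_COLUMNS = [
    "patient_id", "phe_serum", "gpv", "phenotype", "allele1", "allele2",
    "sapropterin", "protein_intake", "age", "sex", "response",
]


def _parse_float(text: str) -> float | None:
    text = text.strip()
    if text in ("", "NA", "NaN", "nan"):
        return None
    return float(text)


def read_metadata_csv(path: str | Path) -> list[PatientRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    phe_serum=float(row["phe_serum"]),
                    gpv=_parse_float(row.get("gpv", "") or ""),
                    phenotype=row.get("phenotype", UNDETERMINED) or UNDETERMINED,
                    allele1=(row.get("allele1") or None),
                    allele2=(row.get("allele2") or None),
                    sapropterin=(row.get("sapropterin", "no").strip().lower()
                                 in ("yes", "true", "1")),
                    protein_intake=_parse_float(row.get("protein_intake", "") or ""),
                    age=_parse_float(row.get("age", "") or ""),
                    sex=(row.get("sex") or None),
                    response=_parse_float(row.get("response", "") or ""),
                )
            )
    return records


def write_metadata_csv(records: list[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.patient_id,
                f"{rec.phe_serum:.10g}",
                "" if rec.gpv is None else f"{rec.gpv:.10g}",
                rec.phenotype,
                rec.allele1 or "",
                rec.allele2 or "",
                "yes" if rec.sapropterin else "no",
                "" if rec.protein_intake is None else f"{rec.protein_intake:.10g}",
                "" if rec.age is None else f"{rec.age:.10g}",
                rec.sex or "",
                "" if rec.response is None else f"{rec.response:.10g}",
            ])


def load_table2_fixture() -> list[PatientRecord]:
    """The packaged 51-patient reference cohort (IDs, Phe, GPV, labels, diet)."""
    path = resources.files("pkunmr.data").joinpath("table2_patients.csv")
    with resources.as_file(path) as p:
        return read_metadata_csv(p)
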