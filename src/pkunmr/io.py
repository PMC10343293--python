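"""Table IO, pipeline configuration and the run report.

All writers use a fixed dialect: UTF-8, comma separator, '.' decimal,
mandatory headers.  Missing values are written as empty cells; "NA" and
"NaN" are accepted on read.  Readers validate rather than guess: duplicate
sample ids, non-numeric cells and a missing group column are hard errors
naming the offending row/column.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import ClassifierConfig
from .errors import FormatError, InvalidParameterError
from .phenotype import PhenotypeConfig
from .spectral_binning import BinningConfig
from .synthetic_cohort import CohortConfig
from .targeted_stats import StatsConfig

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "PipelineConfig",
    "RunReport",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def read_concentration_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a samples x metabolites CSV with ``sample_id`` and ``group`` columns.

    Returns ``(table, labels)`` where the table is indexed by sample id with
    one float column per metabolite (NaN = below LOD / missing).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if "group" not in df.columns:
        raise FormatError(f"{path}: missing required column 'group'")
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate sample_id(s): {', '.join(dupes)}")
    labels = pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")
    meta_cols = df.columns.difference(["sample_id", "group"], sort=False)
    values = {}
    for col in meta_cols:
        parsed = []
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, "
                    f"row {i + 2} (sample {df['sample_id'].iloc[i]!r})"
                ) from None
        values[col] = parsed
    table = pd.DataFrame(values, index=pd.Index(df["sample_id"], name="sample_id"))
    return table, labels


def write_concentration_table(table: pd.DataFrame, labels, path: str | Path) -> None:
    out = table.copy()
    out.insert(0, "group", np.asarray(labels))
    out.to_csv(path, index_label="sample_id", na_rep="")


def _build_section(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise InvalidParameterError(
            f"unknown config key(s) at {path}: {', '.join(sorted(unknown))}"
        )
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            coerced[f.name] = value
    return cls(**coerced)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, nested configuration for the end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    seed: int = 0
    outdir: str = "pkunmr_out"
    log_level: str = "INFO"
    simulate: bool = True
    run_classifier: bool = True
    concentration_table: str | None = None  # input CSV when simulate is false
    metadata_table: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "cohort": CohortConfig,
            "binning": BinningConfig,
            "classifier": ClassifierConfig,
            "stats": StatsConfig,
            "phenotype": PhenotypeConfig,
        }
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise InvalidParameterError(
                f"unknown config key(s) at <root>: {', '.join(sorted(unknown))}"
            )
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise InvalidParameterError(f"config section {key!r} must be a mapping")
                kwargs[key] = _build_section(sections[key], value, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [encode(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            out[f.name] = encode(value)
        # the panel can be huge; record only its size in the snapshot
        if isinstance(out.get("cohort"), dict) and out["cohort"].get("panel"):
            out["cohort"]["panel"] = f"<{len(self.cohort.panel)} metabolites>"
        return out


@dataclass
class RunReport:
    version: str
    config: dict
    seed: int
    stage_shapes: dict
    comparison_table: list
    confusion: dict | None
    accuracy_percent: float | None
    phenotype_summary: dict
    warnings: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text()))
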