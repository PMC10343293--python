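"""Synthetic case/control cohort generator.

Produces concentration tables (mmol/mol creatinine), patient metadata and
synthetic 1D spectra with the statistical structure the downstream analysis
assumes.  The default panel couples 24 analytes calibrated to published
group moments with 74 frozen null analytes whose case and control moments
are identical, so both the targeted screen and the untargeted classifier
are exercisable without any external data.

Concentrations are drawn from per-analyte moment-matched lognormals
(independent across analytes); metadata follows the documented covariate
structure (serum Phe increasing with age, lower natural protein intake for
the classical phenotype, and a planted linear response for regression
recovery tests).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .phenotype import PatientRecord
from .spectrum import Spectrum

__all__ = [
    "MetaboliteSpec",
    "CohortConfig",
    "lognormal_params_from_moments",
    "generate_concentrations",
    "generate_metadata",
    "synthesize_spectrum",
    "load_table3_fixture",
    "load_default_panel",
    "intermediate_panel",
    "CREATININE_SHIFT",
    "CREATININE_AREA",
    "WATER_ARTIFACT_SHIFT",
]

CREATININE_SHIFT = 3.05  # CH3 singlet used as the scaling reference
CREATININE_AREA = 1000.0  # fixed reference area; concentrations are per-creatinine
WATER_ARTIFACT_SHIFT = 5.2  # broad residual inside the excluded 4.5-6.0 ppm window
_PPM_MIN, _PPM_MAX = 0.6, 9.4


@dataclass(frozen=True)
class MetaboliteSpec:
    """Per-analyte simulation parameters (one group of moments per class)."""

    name: str
    mean_control: float
    sd_control: float
    mean_case: float
    sd_case: float
    lod: float = 0.0
    peaks: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mean_control <= 0 or self.mean_case <= 0:
            raise InvalidParameterError(f"{self.name}: means must be positive")
        if self.sd_control < 0 or self.sd_case < 0:
            raise InvalidParameterError(f"{self.name}: SDs must be nonnegative")
        if self.lod < 0:
            raise InvalidParameterError(f"{self.name}: lod must be nonnegative")
        for shift, area in self.peaks:
            if not (_PPM_MIN <= shift <= _PPM_MAX):
                raise InvalidParameterError(
                    f"{self.name}: peak at {shift} ppm outside [{_PPM_MIN}, {_PPM_MAX}]"
                )
            if area <= 0:
                raise InvalidParameterError(f"{self.name}: peak areas must be positive")

    @property
    def is_null(self) -> bool:
        return self.mean_control == self.mean_case and self.sd_control == self.sd_case


@dataclass(frozen=True)
class CohortConfig:
    n_case: int = 51
    n_control: int = 51
    panel: tuple[MetaboliteSpec, ...] | None = None  # None -> packaged default
    seed: int = 0
    age_range: tuple[float, float] = (0.25, 33.0)
    # per-phenotype serum Phe (mean, sd) in umol/L
    phe_case_distributions: dict = field(
        default_factory=lambda: {"cPKU": (777.0, 467.0), "mPKU": (421.0, 255.0)}
    )
    cpku_fraction: float = 37 / 51
    phe_age_slope: float = 20.0  # umol/L per year; detectable at n=51
    protein_intake_distributions: dict = field(
        default_factory=lambda: {"cPKU": (0.40, 0.20), "mPKU": (1.00, 0.70)}
    )
    # planted standardized response: age, protein intake, serum Phe
    response_betas: tuple[float, float, float] = (-0.5, 0.4, 0.0)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise InvalidParameterError("need at least 2 samples per group")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise InvalidParameterError("age_range must be increasing and positive")
        if not (0 <= self.cpku_fraction <= 1):
            raise InvalidParameterError("cpku_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")

    def with_panel(self, panel: Sequence[MetaboliteSpec]) -> "CohortConfig":
        return replace(self, panel=tuple(panel))


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of a lognormal with the given arithmetic moments.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2.  sd = 0 yields
    the degenerate point mass at ``mean``.
    """
    if mean <= 0:
        raise InvalidParameterError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise InvalidParameterError(f"sd must be nonnegative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _parse_peaks(text: str) -> tuple[tuple[float, float], ...]:
    if not text:
        return ()
    out = []
    for item in text.split("|"):
        shift, _, area = item.partition(":")
        out.append((float(shift), float(area)))
    return tuple(out)


def load_table3_fixture() -> pd.DataFrame:
    """Packaged reference table of the 24 calibrated analytes.

    Columns: per-group n/mean/SD (mmol/mol creatinine), the printed p-value
    and fold change, and the invented peak list used by the spectrum
    synthesizer.
    """
    with resources.files("pkunmr.data").joinpath("table3_panel.csv").open() as fh:
        return pd.read_csv(fh)


def load_default_panel(lod: float = 0.0) -> tuple[MetaboliteSpec, ...]:
    """24 calibrated + 74 frozen null analytes as simulation specs."""
    specs = []
    t3 = load_table3_fixture()
    for row in t3.itertuples(index=False):
        specs.append(
            MetaboliteSpec(
                name=row.name,
                mean_control=row.mean_control,
                sd_control=row.sd_control,
                mean_case=row.mean_case,
                sd_case=row.sd_case,
                lod=lod,
                peaks=_parse_peaks(row.peaks),
            )
        )
    with resources.files("pkunmr.data").joinpath("null_panel.csv").open() as fh:
        for rec in csv.DictReader(fh):
            m, s = float(rec["mean"]), float(rec["sd"])
            specs.append(
                MetaboliteSpec(
                    name=rec["name"],
                    mean_control=m,
                    sd_control=s,
                    mean_case=m,
                    sd_case=s,
                    lod=lod,
                    peaks=_parse_peaks(rec["peaks"]),
                )
            )
    return tuple(specs)


def intermediate_panel(panel: Sequence[MetaboliteSpec]) -> tuple[MetaboliteSpec, ...]:
    """Panel whose case means sit at the geometric midpoint of the two groups.

    Used to synthesize mild-phenotype-like samples expected to project
    between the case and control centroids.
    """
    out = []
    for spec in panel:
        mid = math.sqrt(spec.mean_case * spec.mean_control)
        sd_mid = math.sqrt(spec.sd_case * spec.sd_control) if spec.sd_case * spec.sd_control > 0 else 0.0
        out.append(replace(spec, mean_case=mid, sd_case=sd_mid))
    return tuple(out)


def _resolved_panel(config: CohortConfig) -> tuple[MetaboliteSpec, ...]:
    if config.panel is None:
        return load_default_panel()
    if not config.panel:
        raise InvalidParameterError("panel must contain at least one metabolite")
    return tuple(config.panel)


def generate_concentrations(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a samples x metabolites concentration table plus group labels.

    Case rows use case moments, control rows control moments; draws below an
    analyte's LOD are set to missing (NaN).  Output is bit-identical under a
    fixed seed.
    """
    panel = _resolved_panel(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    labels = np.array(["PKU"] * config.n_case + ["control"] * config.n_control)
    case_mask = labels == "PKU"

    data = np.empty((n, len(panel)))
    for j, spec in enumerate(panel):
        for mask, mean, sd in (
            (case_mask, spec.mean_case, spec.sd_case),
            (~case_mask, spec.mean_control, spec.sd_control),
        ):
            cnt = int(mask.sum())
            if sd == 0:
                vals = np.full(cnt, mean)
            else:
                mu, sigma = lognormal_params_from_moments(mean, sd)
                vals = rng.lognormal(mu, sigma, size=cnt)
            data[mask, j] = vals
        if spec.lod > 0:
            col = data[:, j]
            col[col < spec.lod] = np.nan

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    table = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"),
                         columns=[s.name for s in panel])
    return table, pd.Series(labels, index=table.index, name="group")


def generate_metadata(config: CohortConfig) -> list[PatientRecord]:
    """Draw patient records for the case arm of the cohort.

    Ages are uniform over the configured range; serum Phe is drawn per
    phenotype around its configured mean with a positive, zero-mean-centred
    age slope; natural protein intake is lower for the classical phenotype.
    A planted response (``response`` field of each record) is linear in the
    cohort z-scores of age and protein intake with the configured
    standardized coefficients, enabling regression-recovery tests.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_case
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    n_cpku = int(round(config.cpku_fraction * n))
    phenos = np.array(["cPKU"] * n_cpku + ["mPKU"] * (n - n_cpku))
    rng.shuffle(phenos)

    age_mid = (lo + hi) / 2.0
    phe = np.empty(n)
    intake = np.empty(n)
    for pheno in ("cPKU", "mPKU"):
        mask = phenos == pheno
        mean, sd = config.phe_case_distributions[pheno]
        slope_part = config.phe_age_slope * (ages[mask] - age_mid)
        resid_sd = math.sqrt(max(sd**2 - (config.phe_age_slope**2) * np.var(ages), 0.0))
        phe[mask] = mean + slope_part + rng.normal(0, resid_sd, size=int(mask.sum()))
        im, isd = config.protein_intake_distributions[pheno]
        mu, sigma = lognormal_params_from_moments(im, isd)
        intake[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    phe = np.clip(phe, 1.0, None)

    b_age, b_prot, b_phe = config.response_betas
    z_age = (ages - ages.mean()) / ages.std(ddof=1)
    z_prot = (intake - intake.mean()) / intake.std(ddof=1)
    z_phe = (phe - phe.mean()) / phe.std(ddof=1)
    model = b_age * z_age + b_prot * z_prot + b_phe * z_phe
    resid_var = max(1.0 - np.var(model, ddof=1), 0.05)
    response = model + rng.normal(0, math.sqrt(resid_var), size=n)

    records = []
    for i in range(n):
        gpv = rng.uniform(0.0, 2.7) if phenos[i] == "cPKU" else rng.uniform(2.8, 6.9)
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                phe_serum=float(phe[i]),
                gpv=float(round(gpv, 1)),
                phenotype=str(phenos[i]),
                sapropterin=bool(rng.random() < 0.18),
                protein_intake=float(intake[i]),
                age=float(ages[i]),
                sex="F" if rng.random() < 0.5 else "M",
                response=float(response[i]),
            )
        )
    return records


def _lorentzian_area_normalized(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    return (hwhm / math.pi) / ((ppm - center) ** 2 + hwhm**2)


def synthesize_spectrum(
    concentrations,
    panel: Sequence[MetaboliteSpec],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 2**14,
    ppm_range: tuple[float, float] = (0.5, 9.5),
    hwhm: float = 0.002,
    creatinine_area: float = CREATININE_AREA,
    water_artifact_area: float = 50.0,
) -> Spectrum:
    """Render one sample's concentration row as a Lorentzian stick spectrum.

    Each analyte contributes peaks with area = concentration x relative
    area.  A creatinine reference singlet (fixed area) and a broad artifact
    inside the 4.5-6.0 ppm water window are always present; Gaussian
    baseline noise is added when ``noise_sd > 0``.  Missing concentrations
    contribute nothing.
    """
    if isinstance(concentrations, (pd.Series, dict)):
        conc = np.array([float(concentrations[s.name]) for s in panel])
    else:
        conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (len(panel),):
        raise InvalidParameterError(
            f"expected {len(panel)} concentrations, got shape {conc.shape}"
        )
    if np.any(conc[~np.isnan(conc)] < 0):
        raise InvalidParameterError("concentrations must be nonnegative")

    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    trace = creatinine_area * _lorentzian_area_normalized(ppm, CREATININE_SHIFT, hwhm)
    trace = trace + water_artifact_area * _lorentzian_area_normalized(
        ppm, WATER_ARTIFACT_SHIFT, 0.15
    )
    for c, spec in zip(conc, panel):
        if np.isnan(c) or c == 0:
            continue
        for shift, rel_area in spec.peaks:
            trace += c * rel_area * _lorentzian_area_normalized(ppm, shift, hwhm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum(ppm, trace, {"noise_sd": noise_sd, "seed": seed})
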