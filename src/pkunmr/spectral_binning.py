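"""Creatinine scaling and fixed-width spectral binning into a bucket table.

Each spectrum is scaled so the integral over the creatinine reference
window equals one, then segmented from 0.6 to 9.4 ppm into consecutive
half-open bins of 0.0088 ppm (1000 bins with the defaults).  Bin values are
trapezoidal integrals of the trace; bins intersecting the open residual
water interval (4.5, 6.0) ppm are dropped, retaining 829 bins.

Integrals are computed on the piecewise-linear interpolant of the sampled
trace, so the sum over contiguous bins telescopes exactly to the integral
over the whole region (conservation holds to floating-point precision).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateSpectrumError, InvalidParameterError
from .spectrum import Spectrum

__all__ = [
    "BinningConfig",
    "BucketTable",
    "scale_to_creatinine",
    "bin_spectrum",
    "assemble_bucket_table",
    "bin_edges",
]


@dataclass(frozen=True)
class BinningConfig:
    bin_width: float = 0.0088
    region_start: float = 0.6
    region_end: float = 9.4
    exclude_start: float = 4.5
    exclude_end: float = 6.0
    creatinine_window: tuple[float, float] = (3.00, 3.10)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be positive")
        if not self.region_start < self.region_end:
            raise InvalidParameterError("region_start must be < region_end")
        if not (self.region_start <= self.exclude_start < self.exclude_end <= self.region_end):
            raise InvalidParameterError("exclusion interval must lie inside the region")
        lo, hi = self.creatinine_window
        if not lo < hi:
            raise InvalidParameterError("creatinine window must be a proper interval")
        ratio = (self.region_end - self.region_start) / self.bin_width
        if abs(ratio - round(ratio)) > 1e-6:
            raise InvalidParameterError(
                f"region width must be an integer number of bins (got {ratio:.6f})"
            )

    @property
    def n_bins(self) -> int:
        n = (self.region_end - self.region_start) / self.bin_width
        return int(round(n))


def bin_edges(config: BinningConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left edges, right edges and the retained (non-water) mask of all bins.

    Bins are half-open ``[left, left + width)``; a bin is dropped when its
    interval intersects the open exclusion interval.
    """
    n = config.n_bins
    lefts = config.region_start + config.bin_width * np.arange(n)
    rights = lefts + config.bin_width
    rights[-1] = config.region_end  # guard the last edge against drift
    retained = ~((rights > config.exclude_start) & (lefts < config.exclude_end))
    return lefts, rights, retained


def _integral_to(ppm: np.ndarray, intensity: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Exact trapezoid integral of the piecewise-linear trace from ppm[0] to each x."""
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (intensity[1:] + intensity[:-1]) * np.diff(ppm))]
    )
    idx = np.clip(np.searchsorted(ppm, xs, side="right") - 1, 0, len(ppm) - 2)
    x0 = ppm[idx]
    y0 = intensity[idx]
    slope = (intensity[idx + 1] - y0) / (ppm[idx + 1] - x0)
    dx = xs - x0
    return cum[idx] + dx * (y0 + 0.5 * slope * dx)


def integrate_window(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the trace over [lo, hi] (clipped to the axis)."""
    lo = max(lo, spectrum.ppm[0])
    hi = min(hi, spectrum.ppm[-1])
    if hi <= lo:
        return 0.0
    vals = _integral_to(spectrum.ppm, spectrum.intensity, np.array([lo, hi]))
    return float(vals[1] - vals[0])


def scale_to_creatinine(spectrum: Spectrum, config: BinningConfig = BinningConfig()) -> Spectrum:
    """Divide the trace by its integral over the creatinine reference window."""
    lo, hi = config.creatinine_window
    ref = integrate_window(spectrum, lo, hi)
    if ref <= 0:
        raise DegenerateSpectrumError(
            f"creatinine window [{lo}, {hi}] ppm integral is {ref:.3g} (must be > 0)"
        )
    out = spectrum.scaled(1.0 / ref)
    out.meta["creatinine_scale"] = ref
    return out


def bin_spectrum(
    spectrum: Spectrum,
    config: BinningConfig = BinningConfig(),
    exclude_water: bool = True,
) -> np.ndarray:
    """Vector of per-bin trapezoidal integrals (water bins dropped by default)."""
    if spectrum.ppm[0] > config.region_start or spectrum.ppm[-1] < config.region_end:
        raise CoverageError(
            f"spectrum covers [{spectrum.ppm[0]:.3f}, {spectrum.ppm[-1]:.3f}] ppm, "
            f"binning needs [{config.region_start}, {config.region_end}]"
        )
    lefts, rights, retained = bin_edges(config)
    edges = np.append(lefts, rights[-1])
    cum = _integral_to(spectrum.ppm, spectrum.intensity, edges)
    integrals = np.diff(cum)
    return integrals[retained] if exclude_water else integrals


@dataclass
class BucketTable:
    """Samples x retained-bins matrix of creatinine-scaled bin integrals."""

    values: pd.DataFrame  # rows: sample ids, columns: bin labels
    bin_left: np.ndarray
    bin_right: np.ndarray
    bin_index: np.ndarray  # indices into the full (pre-exclusion) bin grid
    scaling_factors: np.ndarray  # creatinine integrals divided out per sample
    config: BinningConfig = field(default_factory=BinningConfig)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def to_csv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.insert(0, "creatinine_scale", self.scaling_factors)
        df.to_csv(path, index_label="sample_id")

    @classmethod
    def read_csv(cls, path: str | Path, config: BinningConfig = BinningConfig()) -> "BucketTable":
        df = pd.read_csv(path, index_col="sample_id")
        scales = df.pop("creatinine_scale").to_numpy()
        lefts = np.array([float(c.split("_")[1]) for c in df.columns])
        idx = np.round((lefts - config.region_start) / config.bin_width).astype(int)
        return cls(df, lefts, lefts + config.bin_width, idx, scales, config)


def assemble_bucket_table(
    spectra: Sequence[Spectrum],
    config: BinningConfig = BinningConfig(),
    sample_ids: Sequence[str] | None = None,
) -> BucketTable:
    """Scale each spectrum to creatinine, bin it, and stack rows in input order.

    Spectra on grids differing from the first spectrum's are linearly
    interpolated onto it (recorded in the table's metadata implicitly via
    identical bin edges).
    """
    if not spectra:
        raise InvalidParameterError("need at least one spectrum")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(spectra))]
    if len(sample_ids) != len(spectra):
        raise InvalidParameterError("sample_ids length must match spectra")

    ref_ppm = spectra[0].ppm
    lefts, rights, retained = bin_edges(config)
    rows, scales = [], []
    for sid, spec in zip(sample_ids, spectra):
        if spec.ppm.shape != ref_ppm.shape or not np.allclose(spec.ppm, ref_ppm):
            spec = Spectrum(ref_ppm, np.interp(ref_ppm, spec.ppm, spec.intensity), dict(spec.meta))
        try:
            scaled = scale_to_creatinine(spec, config)
            rows.append(bin_spectrum(scaled, config))
        except (DegenerateSpectrumError, CoverageError) as exc:
            raise type(exc)(f"sample {sid}: {exc}") from exc
        scales.append(scaled.meta["creatinine_scale"])

    idx = np.flatnonzero(retained)
    columns = [f"bin_{lefts[i]:.4f}" for i in idx]
    values = pd.DataFrame(np.vstack(rows), index=pd.Index(sample_ids, name="sample_id"),
                          columns=columns)
    return BucketTable(values, lefts[idx], rights[idx], idx, np.array(scales), config)
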