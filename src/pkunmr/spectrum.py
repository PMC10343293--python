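"""1D NMR spectrum container plus plain-text readers/writers.

Spectra are stored with an ascending ppm axis internally; readers accept
either axis direction (the instrument convention is descending ppm) and
normalize on load.  Supported formats are JCAMP-DX (``##XYPOINTS`` or AFFN
``##XYDATA=(X++(Y..Y))``) and two-column ppm/intensity CSV.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["Spectrum", "read_spectrum", "write_jcampdx", "write_csv"]


@dataclass
class Spectrum:
    """Intensity-vs-chemical-shift trace on a strictly increasing ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise FormatError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size < 2:
            raise FormatError("a spectrum needs at least two points")
        if self.ppm[0] > self.ppm[-1]:  # descending axis -> normalize
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        if np.any(np.diff(self.ppm) <= 0):
            raise FormatError("ppm axis must be strictly monotonic")

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.ppm, self.intensity * factor, dict(self.meta))

    def __len__(self) -> int:
        return self.ppm.size


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum from JCAMP-DX (.dx/.jdx) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() in {".dx", ".jdx", ".jcamp"}:
        return _read_jcampdx(path)
    return _read_two_column_csv(path)


def _read_two_column_csv(path: Path) -> Spectrum:
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1)
    except ValueError as exc:
        raise FormatError(f"{path}: not a two-column numeric CSV: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns (ppm, intensity)")
    return Spectrum(data[:, 0], data[:, 1], {"source": str(path)})


def _read_jcampdx(path: Path) -> Spectrum:
    lines = Path(path).read_text().splitlines()
    xs: list[float] = []
    ys: list[float] = []
    mode = None
    xfactor = yfactor = 1.0
    for raw in lines:
        line = raw.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "XYDATA":
                mode = "xydata"
            elif key == "END":
                mode = None
            continue
        if mode == "xypoints" and line:
            for pair in line.split(";"):
                pair = pair.strip()
                if not pair:
                    continue
                try:
                    x, y = (float(v) for v in pair.split(","))
                except ValueError as exc:
                    raise FormatError(f"{path}: bad XYPOINTS pair {pair!r}") from exc
                xs.append(x * xfactor)
                ys.append(y * yfactor)
        elif mode == "xydata" and line:
            vals = line.replace(",", " ").split()
            try:
                x0 = float(vals[0])
                yvals = [float(v) for v in vals[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: bad XYDATA line {line!r}") from exc
            xs.append(x0 * xfactor)
            ys.extend(v * yfactor for v in yvals)

    if mode is None and not xs:
        raise FormatError(f"{path}: no ##XYPOINTS or ##XYDATA block found")
    if len(xs) == len(ys):
        return Spectrum(np.array(xs), np.array(ys), {"source": str(path)})
    # XYDATA: xs are per-line anchors; reconstruct a uniform grid
    n = len(ys)
    if len(xs) < 2:
        raise FormatError(f"{path}: cannot reconstruct abscissa from one line")
    per_line = (len(ys)) / len(xs)
    step = (xs[1] - xs[0]) / per_line
    grid = xs[0] + step * np.arange(n)
    return Spectrum(grid, np.array(ys), {"source": str(path)})


def write_jcampdx(spec: Spectrum, path: str | Path, title: str = "spectrum") -> None:
    """Write as JCAMP-DX with an ``##XYPOINTS=(XY..XY)`` block (ppm abscissa)."""
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##NPOINTS={len(spec)}",
        f"##FIRSTX={spec.ppm[0]:.10g}",
        f"##LASTX={spec.ppm[-1]:.10g}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines.extend(f"{x:.10g}, {y:.10g}" for x, y in zip(spec.ppm, spec.intensity))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def write_csv(spec: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ppm,intensity\n")
        for x, y in zip(spec.ppm, spec.intensity):
            fh.write(f"{x:.10g},{y:.10g}\n")
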