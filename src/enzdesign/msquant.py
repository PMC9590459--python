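"""Adduct m/z, extracted-ion chromatograms, standard curves, normalization.

Implements the quantification arithmetic of an HPLC-qTOF workflow: exact
monoisotopic masses from molecular formulas, single-charge adduct m/z with
electron-mass correction, EIC extraction at ppm tolerance, trapezoidal peak
integration, least-squares standard curves, and per-product normalization to
percentages of total yield.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from enzdesign.errors import InputError, ParameterError

#: Monoisotopic element masses (Da).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Fe": 55.9349375,
}

ELECTRON_MASS = 0.00054857990907

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts, e.g. ``MolecularFormula.parse("C30H50O2")``."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts or sum(n for _, n in self.counts) < 1:
            raise InputError("formula must contain at least one atom")
        for el, n in self.counts:
            if el not in MONOISOTOPIC_MASS:
                raise InputError(f"unknown element {el!r}")
            if n < 0:
                raise InputError(f"negative count for {el}")

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        text = text.strip()
        if not text:
            raise InputError("empty formula")
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise InputError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise InputError(f"cannot parse formula {text!r}")
        return cls(counts=tuple(sorted(counts.items())))

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Exact monoisotopic mass in Da."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)


ADDUCTS = {
    "[M+H]+": (MONOISOTOPIC_MASS["H"] - ELECTRON_MASS),
    "[M-H]-": (-MONOISOTOPIC_MASS["H"] + ELECTRON_MASS),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS),
}


def adduct_mz(f: MolecularFormula, adduct: str = "[M+H]+") -> float:
    """Singly-charged adduct m/z with electron-mass correction.

    ``[M+H]+ = M + m(H) - m(e)`` and analogously for the other adducts.
    """
    # tolerate the typographic minus sometimes pasted from documents
    adduct = adduct.replace("−", "-")
    if adduct not in ADDUCTS:
        raise InputError(f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    return monoisotopic_mass(f) + ADDUCTS[adduct]


# ---------------------------------------------------------------------------
# chromatograms


@dataclass
class SpectraSeries:
    """Scans of (retention time in min, m/z array, intensity array)."""

    times: np.ndarray
    mz: list[np.ndarray]
    intensity: list[np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) == 0:
            raise InputError("spectra series has no scans")
        if not (np.diff(self.times) > 0).all():
            raise InputError("retention times must be strictly increasing")
        if len(self.mz) != len(self.times) or len(self.intensity) != len(self.times):
            raise InputError("per-scan arrays do not match time axis")
        for inten in self.intensity:
            if (np.asarray(inten) < 0).any():
                raise InputError("intensities must be non-negative")


@dataclass
class Chromatogram:
    """An extracted-ion trace at a target m/z."""

    times: np.ndarray
    intensities: np.ndarray
    target_mz: float
    tol_ppm: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise InputError("times and intensities differ in length")
        if len(self.times) and not (np.diff(self.times) > 0).all():
            raise InputError("retention times must be strictly increasing")


def extract_eic(s: SpectraSeries, target_mz: float, tol_ppm: float = 20.0) -> Chromatogram:
    """Sum, per scan, the peak intensities within ppm tolerance of the target."""
    if len(s.times) == 0:
        raise InputError("empty scan list")
    tol = target_mz * tol_ppm * 1e-6
    intensities = np.array(
        [
            float(np.asarray(inten)[np.abs(np.asarray(mz) - target_mz) <= tol].sum())
            for mz, inten in zip(s.mz, s.intensity)
        ]
    )
    return Chromatogram(times=s.times.copy(), intensities=intensities,
                        target_mz=float(target_mz), tol_ppm=float(tol_ppm))


def integrate_peak(c: Chromatogram, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the trace over [t_start, t_end]."""
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError("window end must exceed start")
    if t0 < c.times[0] - 1e-12 or t1 > c.times[-1] + 1e-12:
        raise InputError(
            f"window [{t0}, {t1}] outside time range [{c.times[0]}, {c.times[-1]}]"
        )
    mask = (c.times >= t0) & (c.times <= t1)
    return float(np.trapezoid(c.intensities[mask], c.times[mask]))


# ---------------------------------------------------------------------------
# standard curves and normalization


@dataclass
class StandardCurve:
    """Least-squares line ``area = slope * concentration + intercept``."""

    compound: str
    slope: float
    intercept: float
    r_squared: float


def fit_standard_curve(
    points: Sequence[tuple[float, float]], compound: str = ""
) -> StandardCurve:
    """Ordinary least squares of area on concentration; r² reported."""
    if len(points) < 2:
        raise InputError("need at least 2 calibration points")
    conc = np.array([p[0] for p in points], dtype=float)
    area = np.array([p[1] for p in points], dtype=float)
    if np.allclose(conc, conc[0]):
        raise InputError("all concentrations identical; cannot fit a line")
    A = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), *_ = np.linalg.lstsq(A, area, rcond=None)
    pred = slope * conc + intercept
    ss_res = float(((area - pred) ** 2).sum())
    ss_tot = float(((area - area.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StandardCurve(compound=compound, slope=float(slope),
                         intercept=float(intercept), r_squared=r2)


def quantify_and_normalize(
    areas: Mapping[str, float],
    curves: Mapping[str, StandardCurve],
    shared_curve_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Convert peak areas to yields and percentages of total yield.

    ``shared_curve_map`` routes a compound to another compound's curve (e.g.
    a product quantified against a structurally similar standard).  Yields
    are floored at zero; percentages sum to 100 when the total is positive.
    """
    shared_curve_map = shared_curve_map or {}
    yields: dict[str, float] = {}
    for compound, area in areas.items():
        curve_id = shared_curve_map.get(compound, compound)
        if curve_id not in curves:
            raise InputError(f"no standard curve for compound {compound!r} (curve {curve_id!r})")
        curve = curves[curve_id]
        if curve.slope <= 0:
            raise InputError(f"non-positive slope in curve {curve_id!r}")
        yields[compound] = max(0.0, (float(area) - curve.intercept) / curve.slope)
    total = sum(yields.values())
    if total <= 0:
        raise InputError("total yield is zero")
    percentages = {c: 100.0 * y / total for c, y in yields.items()}
    return yields, percentages


# ---------------------------------------------------------------------------
# I/O


def read_spectra_csv(path: str) -> SpectraSeries:
    """Long-format CSV with columns time, mz, intensity (header required)."""
    scans: dict[float, list[tuple[float, float]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"time", "mz", "intensity"} <= set(reader.fieldnames):
            raise InputError("spectra CSV needs columns: time, mz, intensity")
        for row in reader:
            scans.setdefault(float(row["time"]), []).append(
                (float(row["mz"]), float(row["intensity"]))
            )
    if not scans:
        raise InputError(f"no scans in {path}")
    times = sorted(scans)
    mz = [np.array([p[0] for p in scans[t]]) for t in times]
    inten = [np.array([p[1] for p in scans[t]]) for t in times]
    return SpectraSeries(times=np.array(times), mz=mz, intensity=inten)


def write_spectra_csv(s: SpectraSeries, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "mz", "intensity"])
        for t, mz, inten in zip(s.times, s.mz, s.intensity):
            for m, i in zip(mz, inten):
                writer.writerow([f"{t:.6f}", f"{m:.6f}", f"{i:.6f}"])


def write_quant_tsv(
    yields: Mapping[str, float], percentages: Mapping[str, float], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("compound\tyield\tpercent_of_total\n")
        for compound in yields:
            fh.write(f"{compound}\t{yields[compound]:.6f}\t{percentages[compound]:.4f}\n")
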