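"""Cellular censuses: molecules per cell from primary measurements.

Three independent quantities feed the accounting stage:

* cell volume from diameter, assuming spherical geometry (1 fL = 1 um^3);
* protein molecules per cell from tryptophan autofluorescence of
  denatured lysates, using a proteome Trp mass fraction of 0.69% and an
  average protein of 472 aa x 110 Da;
* ribosomes per cell from electropherogram 18S/28S rRNA peak areas,
  corrected for purification yield measured with an mRNA spike-in; the
  functional ribosome count is capped by the scarcer subunit (the 60S,
  counted via 28S rRNA).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants


@dataclass
class CellGeometry:
    diameter_um: float
    volume_fl: float


@dataclass
class LinearCalibration:
    """Least-squares line fluorescence = slope * amount + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def amount(self, fluorescence: float) -> float:
        """Invert the calibration for an observed fluorescence."""
        return (fluorescence - self.intercept) / self.slope


@dataclass
class ProteinCensus:
    mass_pg_per_cell: float
    proteins_per_cell: float
    proteins_per_fl: float | None = None


@dataclass
class RiboCensus:
    copies_18s_per_cell: float
    copies_28s_per_cell: float
    functional_ribosomes_per_cell: float
    rna_yield: float
    ribosomes_per_fl: float | None = None


def volume_from_diameter(diameter_um: float) -> CellGeometry:
    """Spherical cell volume in fL from diameter in um: V = pi/6 * d^3."""
    if diameter_um < 0:
        raise ValueError("diameter must be non-negative")
    return CellGeometry(diameter_um=diameter_um, volume_fl=math.pi / 6.0 * diameter_um**3)


def fit_trp_standard_curve(
    standards: Sequence[tuple[float, float]],
    through_origin: bool = False,
) -> LinearCalibration:
    """Fit the tryptophan standard curve (amount, fluorescence) by least squares.

    Ordinary least squares with a free intercept by default; the
    through-origin option suits blank-subtracted readings.
    """
    if len(standards) < 2:
        raise ValueError("at least 2 standards are required")
    x = np.asarray([s[0] for s in standards], dtype=float)
    y = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("standards must span at least two distinct amounts")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearCalibration(slope=slope, intercept=intercept, r_squared=r2)


def protein_mass_per_cell(
    lysate_fluorescence: float,
    blank: float,
    curve: LinearCalibration,
    sampled_fraction: float,
    n_cells: float,
    trp_mass_fraction: float = DEFAULT_CONSTANTS.trp_mass_fraction,
) -> float:
    """Protein mass per cell (pg) from a lysate well's Trp fluorescence.

    The blank-subtracted fluorescence is converted to ng Trp via the
    calibration, divided by the proteome Trp mass fraction to give total
    protein in the well, scaled up by the sampled fraction of the
    lysate, and divided by the number of cells lysed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not (0 < sampled_fraction <= 1):
        raise ValueError("sampled_fraction must be in (0, 1]")
    net = lysate_fluorescence - blank
    if net < 0:
        raise ValueError("lysate fluorescence is below blank")
    trp_ng = net / curve.slope
    protein_ng_in_well = trp_ng / trp_mass_fraction
    total_protein_ng = protein_ng_in_well / sampled_fraction
    return total_protein_ng * 1e3 / n_cells  # ng -> pg


def protein_count(
    mass_pg_per_cell: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Protein molecules per cell from protein mass, at 472 aa x 110 Da per protein."""
    if mass_pg_per_cell < 0:
        raise ValueError("mass must be non-negative")
    return mass_pg_per_cell * 1e-12 / constants.avg_protein_mass_g


def integrate_electropherogram(
    trace: pd.DataFrame,
    windows: Mapping[str, tuple[float, float]],
    baseline: bool = True,
) -> dict[str, dict[str, float]]:
    """Trapezoidal peak areas per migration window, plus fraction of total.

    Each window's area is integrated above a straight baseline drawn
    between the minima at the window edges (instrument smoothing is not
    modeled). Windows must be non-overlapping and inside the trace
    support. Returns ``{species: {"area": ..., "fraction": ...}}`` with
    fractions relative to the summed window areas.
    """
    pos = trace["position"].to_numpy(dtype=float)
    sig = trace["signal"].to_numpy(dtype=float)
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (_, (a1, b1)), (_, (a2, _b2)) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("windows must be non-overlapping")
    areas: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        if lo < pos[0] or hi > pos[-1] or hi <= lo:
            raise ValueError(f"window {name!r} outside trace support")
        mask = (pos >= lo) & (pos <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window {name!r} contains fewer than 2 samples")
        x, y = pos[mask], sig[mask]
        if baseline:
            base = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
            y = np.clip(y - base, 0.0, None)
        areas[name] = float(np.trapezoid(y, x))
    total = sum(areas.values())
    return {
        name: {"area": a, "fraction": a / total if total > 0 else 0.0}
        for name, a in areas.items()
    }


def rna_yield(sample_spikein_peak: float, standard_spikein_peaks: Sequence[float]) -> float:
    """Purification yield: sample spike-in peak over the mean of standard peaks.

    The exogenous mRNA spike-in is added before purification, so its
    fractional recovery relative to unpurified standard wells measures
    the fraction of RNA surviving purification. Values marginally above
    1 (noise) are clipped to 1 with a warning; yield is physically
    bounded.
    """
    if len(standard_spikein_peaks) < 2:
        raise ValueError("at least 2 standard spike-in peaks are required")
    if any(p <= 0 for p in standard_spikein_peaks):
        raise ValueError("standard spike-in peaks must be positive")
    if sample_spikein_peak <= 0:
        raise ValueError("sample spike-in peak must be positive")
    y = sample_spikein_peak / (sum(standard_spikein_peaks) / len(standard_spikein_peaks))
    if y > 1.0:
        warnings.warn(f"RNA yield {y:.3f} > 1; clipping to 1", stacklevel=2)
        return 1.0
    return y


def rrna_copies_per_cell(
    total_rna_ng_per_ul: float,
    frac_species: float,
    eluate_volume_ul: float,
    species: str,
    organism: str,
    yield_fraction: float,
    n_cells: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """rRNA copies per cell from eluate concentration, species fraction, and yield.

    copies = (conc * volume * fraction / molar_mass) * N_A / (yield * n_cells)
    """
    if not (0 < yield_fraction <= 1):
        raise ValueError("yield_fraction must be in (0, 1]")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    key = f"{organism}_{species}"
    try:
        molar_mass = constants.rrna_molar_mass_g_per_mol[key]
    except KeyError:
        raise KeyError(
            f"unknown rRNA species {key!r}; expected one of "
            f"{sorted(constants.rrna_molar_mass_g_per_mol)}"
        ) from None
    mass_g = total_rna_ng_per_ul * eluate_volume_ul * frac_species * 1e-9
    moles = mass_g / molar_mass
    return moles * constants.avogadro / (yield_fraction * n_cells)


def functional_ribosomes(copies_18s: float, copies_28s: float) -> float:
    """Maximal translating ribosomes: the scarcer of the 40S- and 60S-derived counts."""
    if copies_18s < 0 or copies_28s < 0:
        raise ValueError("copy numbers must be non-negative")
    return min(copies_18s, copies_28s)


def ribosome_census_from_traces(
    sample_trace: pd.DataFrame,
    standard_trace: pd.DataFrame,
    windows: Mapping[str, tuple[float, float]],
    eluate_volume_ul: float,
    n_cells: float,
    organism: str = "mouse",
    n_standard_wells: int = 2,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> RiboCensus:
    """Full ribosome census from a sample and a spike-in standard electropherogram.

    Windows must include ``"spike"``, ``"18S"`` and ``"28S"``. Peak
    areas are read as ng of RNA (the instrument calibration); the total
    eluate concentration is the summed area over the eluate volume.
    """
    sample = integrate_electropherogram(sample_trace, windows)
    standard = integrate_electropherogram(standard_trace, {"spike": windows["spike"]})
    y = rna_yield(
        sample["spike"]["area"],
        [standard["spike"]["area"]] * max(n_standard_wells, 2),
    )
    total_ng = sum(v["area"] for v in sample.values())
    conc = total_ng / eluate_volume_ul
    copies = {}
    for sp in ("18S", "28S"):
        copies[sp] = rrna_copies_per_cell(
            total_rna_ng_per_ul=conc,
            frac_species=sample[sp]["fraction"],
            eluate_volume_ul=eluate_volume_ul,
            species=sp,
            organism=organism,
            yield_fraction=y,
            n_cells=n_cells,
            constants=constants,
        )
    return RiboCensus(
        copies_18s_per_cell=copies["18S"],
        copies_28s_per_cell=copies["28S"],
        functional_ribosomes_per_cell=functional_ribosomes(copies["18S"], copies["28S"]),
        rna_yield=y,
    )


def protein_census_from_plate(
    plate: pd.DataFrame,
    sampled_fraction: float,
    n_cells: float,
    volume_fl: float | None = None,
    trp_mass_fraction: float = DEFAULT_CONSTANTS.trp_mass_fraction,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ProteinCensus:
    """Protein census from a Trp-fluorescence plate table.

    Expects columns ``role`` (standard|blank|lysate), ``trp_amount_ng``
    and ``fluorescence``; standards are fit with a free intercept, the
    blank is the mean blank-well reading, and lysate wells are averaged.
    """
    standards = plate[plate["role"] == "standard"]
    blanks = plate[plate["role"] == "blank"]
    lysates = plate[plate["role"] == "lysate"]
    if standards.empty or lysates.empty:
        raise ValueError("plate must contain standard and lysate wells")
    curve = fit_trp_standard_curve(
        list(zip(standards["trp_amount_ng"], standards["fluorescence"]))
    )
    blank = float(blanks["fluorescence"].mean()) if not blanks.empty else curve.intercept
    masses = [
        protein_mass_per_cell(
            float(f), blank, curve, sampled_fraction, n_cells, trp_mass_fraction
        )
        for f in lysates["fluorescence"]
    ]
    mass = float(np.mean(masses))
    count = protein_count(mass, constants)
    return ProteinCensus(
        mass_pg_per_cell=mass,
        proteins_per_cell=count,
        proteins_per_fl=count / volume_fl if volume_fl else None,
    )


# Default integration windows (migration units) around the generated peak
# centers; wide enough that Gaussian tail truncation is negligible.
DEFAULT_RRNA_WINDOWS: dict[str, tuple[float, float]] = {
    "spike": (700.0, 1300.0),
    "18S": (1500.0, 2100.0),
    "28S": (3600.0, 4400.0),
}
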