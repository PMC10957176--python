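"""Synthetic-data generators for every measurement the pipeline consumes.

Each generator emulates the structure of one assay — flow-cytometric
ribopuromycylation (RPM) run-off time courses, Bioanalyzer rRNA
electropherograms with an mRNA spike-in, tryptophan-fluorescence protein
plates, A254 polysome profiles, and CFSE dye-dilution time courses — and
returns the simulated dataset together with a :class:`SyntheticTruth`
record holding the generating parameters, so every downstream estimator
can be tested as a round trip against known ground truth.

All generators are deterministic given (spec, seed); seeds are explicit
and there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

# Fixed electropherogram peak centers in abstract migration units,
# mirroring spike-in mRNA ~1000 nt, 18S ~1800 nt, 28S ~4000 nt.
SPIKE_POS = 1000.0
POS_18S = 1800.0
POS_28S = 4000.0


@dataclass
class SyntheticTruth:
    """Ground-truth parameter bundle emitted alongside a synthetic dataset."""

    dataset: str
    params: dict[str, float | int | str | list[float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"dataset": self.dataset, "params": self.params}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(dataset=d["dataset"], params=d["params"])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sigma of a lognormal with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


def _median_preserving_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with median exactly 1.

    The log-scale mean is 0, so the population median of ``x * noise`` is
    ``x``; the arithmetic mean is inflated by exp(sigma^2/2), as real
    right-skewed fluorescence distributions are.
    """
    if cv == 0:
        return np.ones(size)
    sigma = _lognormal_sigma(cv)
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# RPM run-off (ribosome transit assay) events
# ---------------------------------------------------------------------------


class RtaSimSpec(BaseModel):
    """Design of a simulated RPM run-off time course.

    The deterministic per-cell signal at chase time ``t`` is

        S(t) = background + mean_signal * [(1 - stalled_frac) * 2^(-t/t_half)
                                           + stalled_frac]

    i.e. the run-off-competent span decays with half-life ``t_half_s``
    toward a plateau contributed by stalled ribosomes, on top of
    cellular autofluorescence.
    """

    t_half_s: float = Field(gt=0)
    stalled_frac: float = Field(ge=0, le=1)
    mean_signal: float = Field(gt=0)
    background_mean: float = Field(ge=0)
    cv: float = Field(ge=0)
    chase_times_s: list[float]
    cells_per_timepoint: int = Field(ge=1)
    seed: int

    @model_validator(mode="after")
    def _check_times(self) -> "RtaSimSpec":
        t = self.chase_times_s
        if len(t) == 0:
            raise ValueError("chase_times_s must be non-empty")
        if any(x < 0 for x in t):
            raise ValueError("chase_times_s must be non-negative")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("chase_times_s must be strictly increasing")
        return self

    def deterministic_signal(self, t: np.ndarray | float) -> np.ndarray | float:
        """Noise-free total signal (background included) at chase time t."""
        decay = (1.0 - self.stalled_frac) * np.power(2.0, -np.asarray(t, dtype=float) / self.t_half_s)
        return self.background_mean + self.mean_signal * (decay + self.stalled_frac)


def gen_rta_events(spec: RtaSimSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-cell RPM events for a harringtonine run-off time course.

    Returns a flow-event table with one row per cell: the sample
    population (treatment ``"HAR"``) carries the decaying signal, and a
    matched ``"background"`` population carries autofluorescence only, so
    the summarizer can background-subtract exactly as with real
    unstained/pre-treated controls. Per-cell dispersion is multiplicative
    lognormal with median 1, so population medians converge to the
    deterministic curve.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.cells_per_timepoint
    rows = []
    for t in spec.chase_times_s:
        s_det = float(spec.deterministic_signal(t))
        signal = s_det * _median_preserving_lognormal(rng, spec.cv, n)
        bg = spec.background_mean * _median_preserving_lognormal(rng, spec.cv, n)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(2 * n),
                    "condition": "synthetic",
                    "treatment": ["HAR"] * n + ["background"] * n,
                    "chase_time_s": t,
                    "signal": np.concatenate([signal, bg]),
                }
            )
        )
    events = pd.concat(rows, ignore_index=True)
    truth = SyntheticTruth(
        dataset="rta_events",
        params={
            "t_half_s": spec.t_half_s,
            "stalled_frac": spec.stalled_frac,
            "mean_signal": spec.mean_signal,
            "background_mean": spec.background_mean,
            "plateau": spec.mean_signal * spec.stalled_frac,
            "span": spec.mean_signal * (1.0 - spec.stalled_frac),
            "cv": spec.cv,
            "seed": spec.seed,
        },
    )
    return events, truth


# ---------------------------------------------------------------------------
# Bioanalyzer electropherogram
# ---------------------------------------------------------------------------


class BioanalyzerSimSpec(BaseModel):
    """Design of a simulated rRNA electropherogram with an mRNA spike-in.

    Peak areas are generated in nanograms of RNA directly (the
    instrument's dye calibration is not modeled). The sample trace
    carries cellular 18S and 28S rRNA plus the spike-in, all attenuated
    by the purification yield; the paired standard trace carries the
    spike-in at full mass.
    """

    copies_18s_per_cell: float = Field(ge=0)
    copies_28s_per_cell: float = Field(ge=0)
    n_cells: float = Field(gt=0)
    rna_yield: float = Field(gt=0, le=1)
    spike_in_ng: float = Field(gt=0)
    eluate_volume_ul: float = Field(gt=0)
    peak_width: float = Field(default=30.0, gt=0)
    noise_sd: float = Field(default=0.0, ge=0)
    seed: int = 0
    organism: str = "mouse"
    constants: PhysicalConstants = Field(default_factory=lambda: DEFAULT_CONSTANTS)

    def rrna_mass_ng(self, species: str) -> float:
        """Total cellular mass of one rRNA species before purification, ng."""
        copies = {"18S": self.copies_18s_per_cell, "28S": self.copies_28s_per_cell}[species]
        mm = self.constants.rrna_molar_mass_g_per_mol[f"{self.organism}_{species}"]
        grams = copies * self.n_cells * mm / self.constants.avogadro
        return grams * 1e9


def _gaussian_trace(positions: np.ndarray, centers: Sequence[float], areas: Sequence[float], sd: float) -> np.ndarray:
    signal = np.zeros_like(positions)
    for c, a in zip(centers, areas):
        signal += a / (sd * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * ((positions - c) / sd) ** 2)
    return signal


def gen_electropherogram(
    spec: BioanalyzerSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a sample electropherogram and a spike-in-only standard trace.

    Returns ``(sample_trace, standard_trace, truth)``; traces are
    DataFrames with columns ``position`` (migration units) and ``signal``
    (ng per migration unit, so trapezoidal peak area is ng of RNA).
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.arange(200.0, 5000.0 + 1e-9, 2.0)
    recovered = {
        "spike": spec.spike_in_ng * spec.rna_yield,
        "18S": spec.rrna_mass_ng("18S") * spec.rna_yield,
        "28S": spec.rrna_mass_ng("28S") * spec.rna_yield,
    }
    sample = _gaussian_trace(
        positions,
        [SPIKE_POS, POS_18S, POS_28S],
        [recovered["spike"], recovered["18S"], recovered["28S"]],
        spec.peak_width,
    )
    standard = _gaussian_trace(positions, [SPIKE_POS], [spec.spike_in_ng], spec.peak_width)
    if spec.noise_sd > 0:
        sample = np.clip(sample + rng.normal(0, spec.noise_sd, sample.size), 0, None)
        standard = np.clip(standard + rng.normal(0, spec.noise_sd, standard.size), 0, None)
    sample_df = pd.DataFrame({"position": positions, "signal": sample})
    standard_df = pd.DataFrame({"position": positions, "signal": standard})
    truth = SyntheticTruth(
        dataset="electropherogram",
        params={
            "copies_18s_per_cell": spec.copies_18s_per_cell,
            "copies_28s_per_cell": spec.copies_28s_per_cell,
            "n_cells": spec.n_cells,
            "rna_yield": spec.rna_yield,
            "spike_in_ng": spec.spike_in_ng,
            "eluate_volume_ul": spec.eluate_volume_ul,
            "organism": spec.organism,
            "seed": spec.seed,
        },
    )
    return sample_df, standard_df, truth


# ---------------------------------------------------------------------------
# Tryptophan fluorescence plate
# ---------------------------------------------------------------------------

TRP_FLUOR_SLOPE = 12.0  # a.u. per ng Trp, arbitrary instrument gain
TRP_FLUOR_BLANK = 5.0  # a.u., buffer autofluorescence


def gen_trp_plate(
    mass_per_cell_pg: float,
    n_cells: float,
    standards_ng_trp: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    sampled_fraction: float = 0.02,
    trp_mass_fraction: float = DEFAULT_CONSTANTS.trp_mass_fraction,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a tryptophan-fluorescence protein-quantitation plate.

    Fluorescence (350 nm emission after 295 nm excitation) is linear in
    tryptophan content on top of a blank. Lysate wells receive
    ``sampled_fraction`` of a lysate of ``n_cells`` cells at
    ``mass_per_cell_pg`` pg protein per cell; their Trp content is
    protein mass times the proteome Trp mass fraction (0.69% default).
    """
    if mass_per_cell_pg < 0:
        raise ValueError("mass_per_cell_pg must be non-negative")
    if len(standards_ng_trp) < 2:
        raise ValueError("at least 2 Trp standards are required")
    if not (0 < sampled_fraction <= 1):
        raise ValueError("sampled_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for i, amt in enumerate(standards_ng_trp):
        f = TRP_FLUOR_BLANK + TRP_FLUOR_SLOPE * amt + rng.normal(0, noise_sd)
        rows.append(
            {"well": f"S{i + 1}", "role": "standard", "trp_amount_ng": amt, "fluorescence": f}
        )
    for i in range(3):
        rows.append(
            {
                "well": f"B{i + 1}",
                "role": "blank",
                "trp_amount_ng": 0.0,
                "fluorescence": TRP_FLUOR_BLANK + rng.normal(0, noise_sd),
            }
        )
    total_mass_ng = mass_per_cell_pg * n_cells * 1e-3  # pg -> ng
    trp_in_well_ng = total_mass_ng * sampled_fraction * trp_mass_fraction
    for i in range(3):
        rows.append(
            {
                "well": f"L{i + 1}",
                "role": "lysate",
                "trp_amount_ng": np.nan,
                "fluorescence": TRP_FLUOR_BLANK + TRP_FLUOR_SLOPE * trp_in_well_ng + rng.normal(0, noise_sd),
            }
        )
    plate = pd.DataFrame(rows)
    truth = SyntheticTruth(
        dataset="trp_plate",
        params={
            "mass_per_cell_pg": mass_per_cell_pg,
            "n_cells": n_cells,
            "sampled_fraction": sampled_fraction,
            "trp_mass_fraction": trp_mass_fraction,
            "slope": TRP_FLUOR_SLOPE,
            "blank": TRP_FLUOR_BLANK,
            "seed": seed,
        },
    )
    return plate, truth


# ---------------------------------------------------------------------------
# Polysome profile
# ---------------------------------------------------------------------------

# Gradient layout in arbitrary depth units (denser = larger position).
SUBUNIT_CENTERS = (8.0, 13.0)
MONOSOME_CENTER = 22.0
POLYSOME_START = 32.0
POLYSOME_SPACING = 8.0
DEFAULT_REGIONS = {"subunits": (0.0, 17.0), "monosome": (17.0, 28.0), "polysomes": (28.0, 100.0)}


def gen_polysome_profile(
    frac_monosome: float,
    n_polysome_peaks: int = 4,
    peak_sd: float = 1.2,
    seed: int = 0,
    noise_sd: float = 0.0,
    total_area: float = 10.0,
    subunit_area: float = 1.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate an A254 sucrose-gradient profile.

    The 80S (monosome) peak carries ``frac_monosome`` of the assembled-
    ribosome area; the remainder is split over ``n_polysome_peaks``
    polysome peaks with geometrically decreasing weights. Free-subunit
    peaks sit below the monosome region and are excluded from the
    monosome/polysome partition.
    """
    if not (0 <= frac_monosome <= 1):
        raise ValueError("frac_monosome must be in [0, 1]")
    if n_polysome_peaks < 1:
        raise ValueError("n_polysome_peaks must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.arange(0.0, 100.0 + 1e-9, 0.1)
    centers = list(SUBUNIT_CENTERS) + [MONOSOME_CENTER]
    areas = [subunit_area * 0.4, subunit_area * 0.6, total_area * frac_monosome]
    poly_total = total_area * (1.0 - frac_monosome)
    weights = np.power(0.7, np.arange(n_polysome_peaks))
    weights /= weights.sum()
    for k in range(n_polysome_peaks):
        centers.append(POLYSOME_START + k * POLYSOME_SPACING)
        areas.append(poly_total * weights[k])
    signal = _gaussian_trace(positions, centers, areas, peak_sd)
    if noise_sd > 0:
        signal = np.clip(signal + rng.normal(0, noise_sd, signal.size), 0, None)
    profile = pd.DataFrame({"position": positions, "a254": signal})
    truth = SyntheticTruth(
        dataset="polysome_profile",
        params={
            "frac_monosome": frac_monosome,
            "n_polysome_peaks": n_polysome_peaks,
            "total_area": total_area,
            "seed": seed,
        },
    )
    return profile, truth


# ---------------------------------------------------------------------------
# CFSE dye-dilution time course
# ---------------------------------------------------------------------------


class CfseSimSpec(BaseModel):
    """Design of a simulated CFSE dilution time course.

    Mean generation number follows g(t) = max(0, (t - lag)/doubling_time)
    and per-cell fluorescence is initial_mfi / 2^g with median-preserving
    lognormal dispersion.
    """

    initial_mfi: float = Field(gt=0)
    timepoints_hr: list[float]
    doubling_time_hr: float = Field(gt=0)
    lag_hr: float = Field(ge=0)
    cv: float = Field(ge=0)
    cells_per_timepoint: int = Field(default=1000, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CfseSimSpec":
        if len(self.timepoints_hr) == 0:
            raise ValueError("timepoints_hr must be non-empty")
        if any(t < 0 for t in self.timepoints_hr):
            raise ValueError("timepoints_hr must be non-negative")
        return self

    def mean_generations(self, t_hr: float) -> float:
        return max(0.0, (t_hr - self.lag_hr) / self.doubling_time_hr)


def gen_cfse_timecourse(spec: CfseSimSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-cell CFSE fluorescence at each observation time."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in spec.timepoints_hr:
        g = spec.mean_generations(t)
        mfi_det = spec.initial_mfi / 2.0**g
        mfi = mfi_det * _median_preserving_lognormal(rng, spec.cv, spec.cells_per_timepoint)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(spec.cells_per_timepoint),
                    "time_hr": t,
                    "mfi": mfi,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = SyntheticTruth(
        dataset="cfse_timecourse",
        params={
            "initial_mfi": spec.initial_mfi,
            "doubling_time_hr": spec.doubling_time_hr,
            "lag_hr": spec.lag_hr,
            "cv": spec.cv,
            "seed": spec.seed,
        },
    )
    return table, truth
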