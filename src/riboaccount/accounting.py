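"""Protein-synthesis-capacity accounting.

Combines the censuses (proteins and functional ribosomes per cell), the
elongation rate, and the measured doubling time into the headline
resource balance: the minimal time for the ribosome pool to duplicate
the proteome,

    T0 = (P/R) * L / k        (P/R proteins per ribosome, L residues
                               per protein, k residues per second),

the corrected duplication time once defective ribosomal products
(DRiPs), inactive ribosomes, and first-order proteome turnover are
accounted for, the elongation rate that the measured doubling time
would require, and the paradox ratio (duplication time over measured
doubling time).

With productive synthesis rate s = (R*k/L) * f_active * (1 - f_drip)
proteins/s and degradation rate lambda = ln2 / protein half-life, the
proteome obeys dP/dt = s - lambda*P; the corrected duplication time is
the time to reach 2*P0 from P0:

    Tc = (1/lambda) * ln[(s/lambda - P0) / (s/lambda - 2*P0)],

feasible only when the steady state s/lambda exceeds 2*P0; as
lambda -> 0 this reduces to the degradation-free P0/s. Infeasibility is
a reported state, not an exception: it is the scientifically meaningful
outcome (the capacity paradox itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, SECONDS_PER_HOUR

REPORT_SCHEMA_VERSION = "1"


@dataclass
class AccountingInput:
    """Inputs to the duplication-time accounting."""

    proteins_per_cell: float
    functional_ribosomes: float
    elongation_rate_aa_per_s: float
    avg_protein_length_aa: float = DEFAULT_CONSTANTS.avg_protein_length_aa
    measured_doubling_hr: float | None = None
    drip_fraction: float = 0.30
    protein_half_life_hr: float | None = 32.0
    active_ribosome_fraction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.proteins_per_cell, self.functional_ribosomes) <= 0:
            raise ValueError("protein and ribosome counts must be positive")
        if self.elongation_rate_aa_per_s <= 0 or self.avg_protein_length_aa <= 0:
            raise ValueError("rate and protein length must be positive")
        if not (0 <= self.drip_fraction < 1):
            raise ValueError("drip_fraction must be in [0, 1)")
        if not (0 < self.active_ribosome_fraction <= 1):
            raise ValueError("active_ribosome_fraction must be in (0, 1]")
        if self.protein_half_life_hr is not None and self.protein_half_life_hr <= 0:
            raise ValueError("protein_half_life_hr must be positive (or None for no turnover)")

    @property
    def protein_per_ribosome(self) -> float:
        return self.proteins_per_cell / self.functional_ribosomes


@dataclass
class AccountingResult:
    """Duplication-time accounting outcome."""

    protein_per_ribosome: float
    min_duplication_hr: float
    corrected_duplication_hr: float | None
    feasible: bool
    paradox_ratio: float | None = None
    required_rate_aa_per_s: float | None = None


def min_duplication_time(
    p_over_r: float,
    protein_length_aa: float = DEFAULT_CONSTANTS.avg_protein_length_aa,
    rate_aa_per_s: float = 6.0,
) -> float:
    """Minimal proteome duplication time in hours: (P/R) * L / k.

    Assumes every functional ribosome elongates continuously at
    ``rate_aa_per_s`` with no degradation or secretion losses.
    """
    if p_over_r <= 0 or protein_length_aa <= 0:
        raise ValueError("ratio and protein length must be positive")
    if rate_aa_per_s <= 0:
        raise ValueError("elongation rate must be positive")
    return p_over_r * protein_length_aa / rate_aa_per_s / SECONDS_PER_HOUR


def paradox_ratio(duplication_hr: float, doubling_hr: float) -> float:
    """Fold excess of required synthesis time over observed doubling time."""
    if duplication_hr <= 0:
        raise ValueError("duplication time must be positive")
    if doubling_hr <= 0:
        raise ValueError("doubling time must be positive")
    return duplication_hr / doubling_hr


def required_elongation_rate(
    p_over_r: float,
    protein_length_aa: float = DEFAULT_CONSTANTS.avg_protein_length_aa,
    doubling_hr: float = 6.8,
) -> float:
    """Elongation rate (aa/s) needed to duplicate the proteome within ``doubling_hr``."""
    if p_over_r <= 0 or protein_length_aa <= 0 or doubling_hr <= 0:
        raise ValueError("inputs must be positive")
    return p_over_r * protein_length_aa / (doubling_hr * SECONDS_PER_HOUR)


def corrected_duplication_time(inp: AccountingInput) -> tuple[float | None, bool]:
    """Duplication time with DRiP loss, inactive ribosomes, and proteome turnover.

    Returns ``(hours, feasible)``. When the productive synthesis rate
    cannot outpace degradation at twice the current proteome size the
    doubling is infeasible and hours is ``None``.
    """
    p0 = inp.proteins_per_cell
    s = (
        inp.functional_ribosomes
        * inp.elongation_rate_aa_per_s
        / inp.avg_protein_length_aa
        * inp.active_ribosome_fraction
        * (1.0 - inp.drip_fraction)
    )  # productive proteins per second
    if inp.protein_half_life_hr is None or math.isinf(inp.protein_half_life_hr):
        return (2.0 * p0 - p0) / s / SECONDS_PER_HOUR, True
    lam = math.log(2.0) / (inp.protein_half_life_hr * SECONDS_PER_HOUR)
    steady = s / lam
    if steady <= 2.0 * p0:
        return None, False
    tc_s = (1.0 / lam) * math.log((steady - p0) / (steady - 2.0 * p0))
    return tc_s / SECONDS_PER_HOUR, True


def concentration_fold_change(protein_fold: float, volume_fold: float) -> float:
    """Net fold change in protein concentration: protein fold over volume fold."""
    if protein_fold <= 0 or volume_fold <= 0:
        raise ValueError("fold changes must be positive")
    return protein_fold / volume_fold


def run_accounting(inp: AccountingInput) -> AccountingResult:
    """Compute the full accounting from one input bundle."""
    t0 = min_duplication_time(
        inp.protein_per_ribosome, inp.avg_protein_length_aa, inp.elongation_rate_aa_per_s
    )
    tc, feasible = corrected_duplication_time(inp)
    ratio = None
    req = None
    if inp.measured_doubling_hr is not None:
        ratio = paradox_ratio(t0, inp.measured_doubling_hr)
        req = required_elongation_rate(
            inp.protein_per_ribosome, inp.avg_protein_length_aa, inp.measured_doubling_hr
        )
    return AccountingResult(
        protein_per_ribosome=inp.protein_per_ribosome,
        min_duplication_hr=t0,
        corrected_duplication_hr=tc,
        feasible=feasible,
        paradox_ratio=ratio,
        required_rate_aa_per_s=req,
    )
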