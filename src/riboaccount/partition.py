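"""Monosome vs polysome partition of ribosomes and of translation.

A254 sucrose-gradient profiles give the fraction ``m`` of assembled
ribosomes sedimenting as monosomes (80S); absorbance is rRNA-dominated
and hence ribosome-mass-weighted, so region areas need no per-peak
ribosome multiplier. Dot-blot puromycin (PMY) to RPL7 ratios give the
fraction ``f`` of monosomes that are actively translating, with the
polysome ratio defined as 100% translating. Combining the two, and
assuming equal elongation rates, the share of overall translation
occurring in monosomes is

    share = f*m / (f*m + (1 - m)).

Free 40S/60S subunits carry no nascent chains and are excluded from
both numerator and denominator of ``m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class DotBlotQuant:
    """Dot-blot intensities for the monosome and polysome pools."""

    pmy_mono: float
    pmy_poly: float
    rpl7_mono: float
    rpl7_poly: float
    pmy_background: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pmy_mono, self.pmy_poly, self.pmy_background) < 0:
            raise ValueError("intensities must be non-negative")
        if self.rpl7_mono <= 0 or self.rpl7_poly <= 0:
            raise ValueError("RPL7 signals must be positive")


def trapezoid_auc(
    profile: pd.DataFrame,
    region: tuple[float, float],
    baseline: bool = False,
    signal_column: str = "a254",
) -> float:
    """Trapezoidal area of the profile over ``region``, optionally above a linear baseline."""
    pos = profile["position"].to_numpy(dtype=float)
    sig = profile[signal_column].to_numpy(dtype=float)
    lo, hi = region
    if lo < pos[0] or hi > pos[-1] or hi <= lo:
        raise ValueError("region outside profile support")
    mask = (pos >= lo) & (pos <= hi)
    if mask.sum() < 2:
        raise ValueError("region contains fewer than 2 samples")
    x, y = pos[mask], sig[mask]
    if baseline:
        base = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
        y = np.clip(y - base, 0.0, None)
    return float(np.trapezoid(y, x))


def monosome_ribosome_fraction(
    profile: pd.DataFrame,
    regions: Mapping[str, tuple[float, float]],
    polysome_recovery_correction: float = 0.0,
) -> float:
    """Fraction of assembled ribosomes in the 80S peak: AUC(80S)/(AUC(80S)+AUC(polysomes)).

    ``regions`` must define ``"monosome"`` and ``"polysomes"``.
    ``polysome_recovery_correction`` optionally inflates the polysome
    area by the stated fraction (PMY treatment reduces recovered
    polysomes by ~5-10%); default off.
    """
    mono = trapezoid_auc(profile, regions["monosome"])
    poly = trapezoid_auc(profile, regions["polysomes"])
    if not (0 <= polysome_recovery_correction < 1):
        raise ValueError("polysome_recovery_correction must be in [0, 1)")
    poly = poly / (1.0 - polysome_recovery_correction)
    total = mono + poly
    if total <= 0:
        raise ValueError("no area in monosome or polysome regions")
    return mono / total


def translating_monosome_fraction(blot: DotBlotQuant) -> float:
    """Fraction of monosomes actively translating, from PMY/RPL7 ratios.

    The monosome PMY/RPL7 ratio is expressed relative to the polysome
    ratio, which is defined as 100% translating. A single anti-PMY
    antibody background is subtracted from both dots. Results are
    clipped to [0, 1] with a warning.
    """
    poly_net = blot.pmy_poly - blot.pmy_background
    if poly_net <= 0:
        raise ValueError("polysome PMY signal must exceed background")
    mono_net = blot.pmy_mono - blot.pmy_background
    if mono_net < 0:
        warnings.warn(
            "monosome PMY signal below background; reporting 0 translating",
            stacklevel=2,
        )
        return 0.0
    f = (mono_net / blot.rpl7_mono) / (poly_net / blot.rpl7_poly)
    if f > 1.0:
        warnings.warn(f"translating monosome fraction {f:.3f} > 1; clipping", stacklevel=2)
        return 1.0
    return f


def monosome_translation_share(f: float, m: float) -> float:
    """Share of overall translation occurring in monosomes.

    ``f`` is the translating fraction of monosomes, ``m`` the monosome
    fraction of assembled ribosomes; polysomal ribosomes are assumed
    100% translating and elongation rates equal.
    """
    if not (0 <= f <= 1 and 0 <= m <= 1):
        raise ValueError("f and m must be in [0, 1]")
    denom = f * m + (1.0 - m)
    if denom == 0:
        raise ValueError("no translating ribosomes (m=1, f=0)")
    return f * m / denom


def implied_monosome_fraction(f: float, share: float) -> float:
    """Invert the share formula for m given f and the observed share.

    share = f*m/(f*m + 1 - m)  =>  m = share / (f + share - f*share).
    Well-posed for f, share in (0, 1).
    """
    if not (0 < f <= 1) or not (0 <= share < 1):
        raise ValueError("require f in (0,1] and share in [0,1)")
    return share / (f + share - f * share)
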