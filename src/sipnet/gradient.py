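"""CsCl density-gradient fractionation profiles for DNA-SIP.

In a stable-isotope-probing experiment, DNA extracted from soil is
ultracentrifuged on a CsCl gradient and collected as ordered fractions of
increasing buoyant density. Unlabeled ("light") DNA bands near
1.62 g ml⁻¹; ¹³C-labeled ("heavy") DNA from organisms that assimilated
labeled substrate bands near 1.66 g ml⁻¹. Each fraction carries a
fluorometric DNA quantity and a δ¹³C value (‰ vs the VPDB standard;
natural abundance is about −28.7‰).

This module models a fractionated gradient and the two decisions the
analysis makes on it: which fraction represents the light/heavy DNA pool,
and where each measured channel peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .exceptions import DegenerateProfileError, SelectionError

#: δ¹³C of unlabeled DNA, ‰ (natural ¹³C abundance in this soil system).
NATURAL_ABUNDANCE_D13C = -28.7

#: Default half-window for matching a fraction to a target density,
#: g ml⁻¹ — half the typical spacing of a 10-fraction gradient.
DEFAULT_DENSITY_TOLERANCE = 0.005

#: Default δ¹³C margin above baseline to call a sample enriched, ‰.
DEFAULT_ENRICHMENT_MARGIN = 5.0

#: Densities are compared at instrument precision (3 decimals).
_DENSITY_DECIMALS = 3


@dataclass(frozen=True)
class GradientFraction:
    """One collected fraction of a CsCl gradient."""

    index: int
    buoyant_density: float  # g ml⁻¹
    dna_quantity: float  # arbitrary fluorometric units, ≥ 0
    delta13C: float  # ‰ vs standard

    def __post_init__(self) -> None:
        if self.buoyant_density <= 0:
            raise ValueError(f"buoyant_density must be > 0, got {self.buoyant_density}")
        if self.dna_quantity < 0:
            raise ValueError(f"dna_quantity must be >= 0, got {self.dna_quantity}")


@dataclass
class GradientProfile:
    """An ordered set of gradient fractions for one sample.

    Fractions are stored sorted by buoyant density; densities must be
    strictly monotone after sorting (no duplicated fraction densities).
    """

    fractions: list[GradientFraction]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ValueError("a gradient profile needs at least 2 fractions")
        self.fractions = sorted(self.fractions, key=lambda f: f.buoyant_density)
        densities = [f.buoyant_density for f in self.fractions]
        if any(b <= a for a, b in zip(densities, densities[1:])):
            raise ValueError("fraction densities must be strictly increasing")

    @property
    def densities(self) -> list[float]:
        return [f.buoyant_density for f in self.fractions]

    def channel(self, name: Literal["dna", "delta13C"]) -> list[float]:
        if name == "dna":
            return [f.dna_quantity for f in self.fractions]
        if name == "delta13C":
            return [f.delta13C for f in self.fractions]
        raise ValueError(f"unknown channel {name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": [f.index for f in self.fractions],
                "density_g_per_ml": [f.buoyant_density for f in self.fractions],
                "dna_ng": [f.dna_quantity for f in self.fractions],
                "delta13C_permil": [f.delta13C for f in self.fractions],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "GradientProfile":
        fractions = [
            GradientFraction(
                index=int(row["fraction"]),
                buoyant_density=float(row["density_g_per_ml"]),
                dna_quantity=float(row["dna_ng"]),
                delta13C=float(row["delta13C_permil"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(fractions=fractions, label=label)


def select_fraction(
    profile: GradientProfile,
    target_density: float,
    tolerance: float = DEFAULT_DENSITY_TOLERANCE,
) -> GradientFraction:
    """Select the fraction closest in buoyant density to ``target_density``.

    The light-DNA pool is conventionally taken at 1.62 g ml⁻¹ and the
    heavy-DNA pool at 1.66 g ml⁻¹. Raises :class:`SelectionError` if the
    closest fraction is farther than ``tolerance`` from the target.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    best = min(profile.fractions, key=lambda f: abs(f.buoyant_density - target_density))
    gap = abs(best.buoyant_density - target_density)
    if gap > tolerance:
        raise SelectionError(
            f"no fraction within {tolerance} g/ml of {target_density}; "
            f"closest is {best.buoyant_density} g/ml"
        )
    return best


def peak_density(
    profile: GradientProfile, channel: Literal["dna", "delta13C"]
) -> float:
    """Buoyant density at which a measured channel peaks.

    Ties (after rounding densities to instrument precision, 3 decimals)
    break toward the higher density. A flat channel has no peak and raises
    :class:`DegenerateProfileError`.
    """
    values = profile.channel(channel)
    if max(values) == min(values):
        raise DegenerateProfileError(f"channel {channel!r} is flat; no peak")
    vmax = max(values)
    # fractions are density-sorted, so the last argmax is the highest density
    best_i = max(i for i, v in enumerate(values) if v == vmax)
    return round(profile.fractions[best_i].buoyant_density, _DENSITY_DECIMALS)


def is_enriched(
    delta13C: float,
    baseline: float = NATURAL_ABUNDANCE_D13C,
    margin: float = DEFAULT_ENRICHMENT_MARGIN,
) -> bool:
    """Whether a δ¹³C reading indicates ¹³C enrichment above background.

    True iff ``delta13C > baseline + margin``. The default margin of 5‰
    keeps unplanted bulk soil (≈ −24.3‰) below the enrichment call while
    clearly labeled samples (≳ 0‰) pass.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    return delta13C > baseline + margin
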