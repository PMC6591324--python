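"""CDNB-conjugation kinetics to specific activity.

Absorbance slope at 344 nm is converted with the product's extinction
coefficient (default 9.6 mM^-1 cm^-1) and expressed as nmol conjugated per
minute per mg protein. The reaction volume has no default and must be given.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_EPSILON_MM_CM = 9.6


@dataclass(frozen=True)
class AssayMeasurement:
    delta_a_per_min: float
    reaction_volume_ml: float
    protein_mg: float
    path_cm: float = 1.0
    epsilon_mm_cm: float = DEFAULT_EPSILON_MM_CM

    def __post_init__(self):
        if self.delta_a_per_min < 0:
            raise ValueError("absorbance slope must be non-negative")
        for name in ("reaction_volume_ml", "protein_mg", "path_cm", "epsilon_mm_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def specific_activity(m: AssayMeasurement) -> float:
    """Specific activity in nmol/min/mg.

    rate[mM/min] = dA / (epsilon * path); 1 mM = 1000 nmol/mL, so
    nmol/min = rate * volume_mL * 1000.
    """
    rate_mm_per_min = m.delta_a_per_min / (m.epsilon_mm_cm * m.path_cm)
    nmol_per_min = rate_mm_per_min * m.reaction_volume_ml * 1000.0
    return nmol_per_min / m.protein_mg
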