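"""Physical constants for yttrium-90 dosimetry.

All dose operations take a :class:`PhysicsConstants` instance explicitly so
that the assumptions behind every Gray are visible and overridable; there are
no hidden module-level globals.

Default values (decisions, pinned here in one place):

* half-life 64.05 h (⁹⁰Y, pure β⁻ emitter for dosimetric purposes),
* mean β energy per decay 0.9267 MeV (ICRP-107),
* soft-tissue density 1.03 g/ml, lung density 0.26 g/ml,
* reference lung mass 1.0 kg (anterior+posterior pair combined).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import yaml

#: J per MeV (CODATA).
MEV_TO_J = 1.602176634e-13


@dataclass(frozen=True)
class PhysicsConstants:
    """Pinned ⁹⁰Y decay/tissue constants used by every dose calculation."""

    half_life_h: float = 64.05
    mean_beta_energy_mev: float = 0.9267
    soft_tissue_density_g_ml: float = 1.03
    lung_density_g_ml: float = 0.26
    lung_mass_kg: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"physics constant {name!r} must be finite and > 0, got {value}")

    @property
    def decay_constant_per_s(self) -> float:
        return math.log(2.0) / (self.half_life_h * 3600.0)

    @property
    def residence_time_s(self) -> float:
        """Time integral of a unit permanent implant: T½ / ln 2 in seconds."""
        return (self.half_life_h * 3600.0) / math.log(2.0)

    @property
    def beta_energy_j(self) -> float:
        return self.mean_beta_energy_mev * MEV_TO_J

    @property
    def gy_kg_per_gbq(self) -> float:
        """Absorbed energy in J (= Gy·kg) per GBq of permanently implanted ⁹⁰Y.

        1 GBq × (T½/ln 2) s × Ē_β J ≈ 49.4 Gy·kg/GBq — the mono-compartment
        MIRD factor; derived, never hard-coded downstream.
        """
        return 1e9 * self.residence_time_s * self.beta_energy_j

    def density_g_ml(self, role: str) -> float:
        """Tissue density for a segmentation role name."""
        return self.lung_density_g_ml if role.startswith("lung") else self.soft_tissue_density_g_ml

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhysicsConstants":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
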