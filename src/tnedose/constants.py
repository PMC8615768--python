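"""Physical constants for local-absorption electron dosimetry of 177Lu.

The mean emitted electron (beta + conversion/Auger) energy of 177Lu is
147 keV per decay.  Under the local-absorption assumption the absorbed
fraction for electrons is 1 and photon contributions are neglected, so an
activity concentration maps linearly onto an absorbed-dose rate:

    dose_rate [Gy/h] = C [MBq/g] * phi_e * E_e [keV/decay] * k

where ``k`` converts (MBq/g)*(keV/decay) into Gy/h and is fixed by SI
definitions, not configurable:

    k = 1e6 decay/(s*MBq) * 1.602176634e-16 J/keV * 3600 s/h * 1000 g/kg
"""

from dataclasses import dataclass

#: Joules per keV (exact, from the 2019 SI definition of the elementary charge).
JOULE_PER_KEV = 1.602176634e-16

#: Unit conversion (MBq/g)*(keV/decay) -> Gy/h.
K_GY_PER_H = 1e6 * JOULE_PER_KEV * 3600.0 * 1000.0

#: Mean emitted electron energy of 177Lu per decay (keV/decay).
E_ELECTRON_KEV = 147.0

#: Absorbed fraction for electrons under local absorption.
PHI_ELECTRON = 1.0

#: Hours in the "28 day" bookkeeping point used throughout (exactly 672 h).
HOURS_28_DAYS = 672.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Electron dosimetry constants; defaults are the 177Lu values."""

    E_e: float = E_ELECTRON_KEV      # keV/decay
    phi_e: float = PHI_ELECTRON      # dimensionless
    k: float = K_GY_PER_H            # (MBq/g * keV/decay) -> Gy/h

    @property
    def gy_per_h_per_mbq_per_g(self) -> float:
        """Dose rate in Gy/h produced by 1 MBq/g (about 0.0848 for 177Lu)."""
        return self.phi_e * self.E_e * self.k


LU177 = PhysicalConstants()
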