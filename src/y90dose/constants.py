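"""Physical constants for yttrium-90 dosimetry.

All region- and voxel-level dose formulas in this package reduce to the
product of a cumulated activity and the mean beta energy released per decay.
For Y-90 (pure beta emitter, no biological clearance after microsphere
embolisation) the cumulated activity is simply ``A(t=0)/lambda``, so a single
radionuclide constant — the energy released per becquerel of initial
activity — carries the whole dose calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Joules per keV.
J_PER_KEV = 1.602176634e-16


@dataclass(frozen=True)
class Y90Constants:
    """Y-90 decay data and the derived dose constants.

    The exact energy-per-initial-activity constant is 49.8 nJ/Bq; the dose
    equations use the conventional rounded value of 50 Gy·kg/GBq throughout,
    so that 1 GBq retained in 1 kg of tissue delivers 50 Gy.
    """

    #: Mean beta energy per decay (keV).
    delta_beta_kev: float = 933.0
    #: Physical decay constant (s^-1), half-life 64.1 h.
    lambda_per_s: float = 3.00e-6
    #: Decay constant in h^-1.
    lambda_per_h: float = 0.0108
    #: Default sublethal-damage repair rate for tumours (h^-1).
    mu_dna_repair_per_h: float = 0.46
    #: Rounded dose constant used by all dose equations (Gy·kg/GBq).
    dose_constant_gy_kg_per_gbq: float = 50.0
    #: Soft tissue density (g/cm^3).
    density_soft_tissue_g_cm3: float = 1.04
    #: Lung density (g/cm^3); exposed for reference, no lung kernel is shipped.
    density_lung_g_cm3: float = 0.25
    #: CSDA range of the mean-energy beta in soft tissue (mm).
    csda_range_soft_tissue_mm: float = 3.85

    @property
    def energy_per_decay_j(self) -> float:
        """Mean energy released per decay (J)."""
        return self.delta_beta_kev * J_PER_KEV

    @property
    def kev_s_per_bq(self) -> float:
        """Energy released per Bq of initial activity, in keV·s (3.11e8)."""
        return self.delta_beta_kev / self.lambda_per_s

    @property
    def j_per_bq(self) -> float:
        """Energy released per Bq of initial activity (~49.8e-9 J)."""
        return self.energy_per_decay_j / self.lambda_per_s


#: Module-level singleton used throughout the package.
Y90 = Y90Constants()
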