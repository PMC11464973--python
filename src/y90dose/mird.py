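"""Region-based (compartmental) Y-90 dosimetry.

Implements the MIRD-style absorbed-dose calculators used for
radioembolisation treatment planning:

* single-compartment dose (local-deposition hypothesis, absorbed fraction 1),
* the three-compartment partition model (tumour / normal liver / lung) driven
  by the lung shunt fraction and the tumour-to-normal uptake ratio,
* multi-compartment absorbed-dose coefficients from fractions of injected
  activity (FIA),
* post-therapy dosimetry from an activity concentration.

Activities are expressed at the time of administration; with permanently
trapped microspheres there is no biological elimination, so the cumulated
activity is ``A(0)/lambda``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .constants import Y90


@dataclass(frozen=True)
class CompartmentSpec:
    """A named tissue compartment.

    At least one of ``activity_gbq``, ``fia`` or ``mean_counts`` must be
    given; ``mass_kg`` must be strictly positive.
    """

    name: str
    mass_kg: float
    activity_gbq: float | None = None
    fia: float | None = None
    mean_counts: float | None = None

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"compartment {self.name!r}: mass must be > 0")
        if self.activity_gbq is None and self.fia is None and self.mean_counts is None:
            raise ValueError(
                f"compartment {self.name!r}: one of activity_gbq, fia, mean_counts required"
            )
        if self.activity_gbq is not None and self.activity_gbq < 0:
            raise ValueError("activity must be >= 0")
        if self.fia is not None and not 0 <= self.fia <= 1:
            raise ValueError("fia must be in [0, 1]")
        if self.mean_counts is not None and self.mean_counts < 0:
            raise ValueError("mean_counts must be >= 0")


@dataclass(frozen=True)
class PartitionInput:
    """Inputs of the partition model.

    ``lung_mass_kg`` defaults to 1.0 kg; the classical partition model does
    not fix a lung mass, so override it when patient-specific data exist.
    """

    administered_activity_gbq: float
    lsf: float
    tn_ratio: float
    tumour_mass_kg: float
    normal_liver_mass_kg: float
    lung_mass_kg: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.lsf < 1:
            raise ValueError("lsf must be in [0, 1)")
        if self.tn_ratio <= 0:
            raise ValueError("tn_ratio must be > 0")
        for m in (self.tumour_mass_kg, self.normal_liver_mass_kg, self.lung_mass_kg):
            if m <= 0:
                raise ValueError("masses must be > 0")
        if self.administered_activity_gbq < 0:
            raise ValueError("administered activity must be >= 0")


@dataclass(frozen=True)
class PartitionResult:
    """Partition-model activities (GBq) and absorbed doses (Gy)."""

    activity_tumour_gbq: float
    activity_normal_liver_gbq: float
    activity_lung_gbq: float
    dose_tumour_gy: float
    dose_normal_liver_gy: float
    dose_lung_gy: float

    @property
    def total_activity_gbq(self) -> float:
        return (
            self.activity_tumour_gbq
            + self.activity_normal_liver_gbq
            + self.activity_lung_gbq
        )


def cumulated_activity(a0_bq: float) -> float:
    """Time-integrated activity (Bq·s) of an initial activity ``a0_bq``.

    With no biological elimination, the integral of ``A0 exp(-lambda t)``
    is ``A0/lambda``.
    """
    if a0_bq < 0:
        raise ValueError("activity must be >= 0")
    return a0_bq / Y90.lambda_per_s


def dose_single_compartment(activity_gbq: float, mass_kg: float) -> float:
    """Absorbed dose (Gy) for a compartment that absorbs all its own energy.

    D = 50 * A[GBq] / M[kg], the local-deposition hypothesis (absorbed
    fraction phi = 1, negligible bremsstrahlung).
    """
    if mass_kg <= 0:
        raise ValueError("mass must be > 0")
    if activity_gbq < 0:
        raise ValueError("activity must be >= 0")
    return Y90.dose_constant_gy_kg_per_gbq * activity_gbq / mass_kg


def lung_shunt_fraction(counts_lung: float, counts_liver: float) -> float:
    """Lung shunt fraction from total scintigraphic counts in lung and liver."""
    if counts_lung < 0 or counts_liver < 0:
        raise ValueError("counts must be >= 0")
    total = counts_lung + counts_liver
    if total <= 0:
        raise ValueError("counts_lung + counts_liver must be > 0")
    return counts_lung / total


def tn_ratio(mean_counts_tumour: float, mean_counts_normal: float) -> float:
    """Tumour-to-normal-liver uptake ratio from *average* (per-voxel) counts.

    The ratio is defined on activity concentrations, so the inputs must be
    mean counts per unit volume, not totals.
    """
    if mean_counts_normal <= 0:
        raise ValueError("normal-liver mean counts must be > 0")
    if mean_counts_tumour < 0:
        raise ValueError("tumour mean counts must be >= 0")
    return mean_counts_tumour / mean_counts_normal


def partition_model(inp: PartitionInput) -> PartitionResult:
    """Three-compartment partition dosimetry.

    Activities::

        A_T = A (1 - LSF) M_T r / (M_N + M_T r)
        A_N = A (1 - LSF) - A_T
        A_L = A LSF

    and each dose is ``50 A_x / M_x``. Activity is conserved exactly.
    """
    a = inp.administered_activity_gbq
    denom = inp.normal_liver_mass_kg + inp.tumour_mass_kg * inp.tn_ratio
    if denom <= 0:
        raise ValueError("M_N + M_T * r must be > 0")
    a_t = inp.tumour_mass_kg * inp.tn_ratio / denom * (1 - inp.lsf) * a
    a_n = (1 - inp.lsf) * a - a_t
    a_l = inp.lsf * a
    return PartitionResult(
        activity_tumour_gbq=a_t,
        activity_normal_liver_gbq=a_n,
        activity_lung_gbq=a_l,
        dose_tumour_gy=dose_single_compartment(a_t, inp.tumour_mass_kg),
        dose_normal_liver_gy=dose_single_compartment(a_n, inp.normal_liver_mass_kg),
        dose_lung_gy=dose_single_compartment(a_l, inp.lung_mass_kg),
    )


def dose_coefficient_multicompartment(fia: float, mass_kg: float) -> float:
    """Absorbed-dose coefficient d_c (Gy per GBq administered) = fia*50/M."""
    if mass_kg <= 0:
        raise ValueError("mass must be > 0")
    if not 0 <= fia <= 1:
        raise ValueError("fia must be in [0, 1]")
    return fia * Y90.dose_constant_gy_kg_per_gbq / mass_kg


def fia_from_counts(counts: dict[str, float]) -> dict[str, float]:
    """Fractions of injected activity from per-compartment total counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total counts must be > 0")
    return {k: v / total for k, v in counts.items()}


def multicompartment_doses(
    compartments: list[CompartmentSpec], administered_activity_gbq: float = 1.0
) -> dict[str, dict[str, float]]:
    """Dose coefficients and doses for a set of FIA-specified compartments.

    A compartment set whose FIAs do not sum to 1 is allowed (it may
    deliberately cover only part of the injected activity) but triggers a
    warning.
    """
    fias = [c.fia for c in compartments]
    if any(f is None for f in fias):
        raise ValueError("all compartments need a fia for multicompartment dosimetry")
    total_fia = sum(fias)  # type: ignore[arg-type]
    if abs(total_fia - 1.0) > 1e-6:
        warnings.warn(
            f"compartment FIAs sum to {total_fia:.4f}, not 1; "
            "doses are per the stated fractions only",
            stacklevel=2,
        )
    out: dict[str, dict[str, float]] = {}
    for c in compartments:
        dc = dose_coefficient_multicompartment(c.fia, c.mass_kg)  # type: ignore[arg-type]
        out[c.name] = {
            "fia": float(c.fia),  # type: ignore[arg-type]
            "mass_kg": c.mass_kg,
            "dose_coeff_gy_per_gbq": dc,
            "dose_gy": dc * administered_activity_gbq,
            "activity_gbq": c.fia * administered_activity_gbq,  # type: ignore[operator]
        }
    return out


def dose_from_concentration(c0_bq_cm3: float, density_g_cm3: float = 1.04) -> float:
    """Absorbed dose (Gy) from an initial activity concentration (Bq/cm^3).

    D = c0 * 50e-6 / rho. This is the post-therapy PET dosimetry formula; at
    soft-tissue density 1.04 g/cm^3 the factor is 48.08e-6 Gy per Bq/cm^3
    (sometimes quoted rounded as 48).
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be > 0")
    if c0_bq_cm3 < 0:
        raise ValueError("concentration must be >= 0")
    return c0_bq_cm3 * Y90.dose_constant_gy_kg_per_gbq * 1e-6 / density_g_cm3
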