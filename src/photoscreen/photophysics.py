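"""Thermodynamic and excited-state feasibility rules for Type I behaviour.

A Type I photosensitizer must (i) reach its triplet manifold efficiently —
intersystem crossing (ISC) is taken as efficient for channels with
ΔE(S1−Tn) < 0.3 eV — and (ii) be thermodynamically able to transfer an
electron to molecular oxygen: its ground-state reduction potential must lie
below −0.33 V vs. NHE, the O2/O2·− couple.  Energy transfer to oxygen
(Type II, singlet-oxygen generation) is energetically open when
ΔE(T1−S0) exceeds the 1O2 excitation thresholds 0.98 eV (1Δg) or 1.63 eV
(1Σg+); these rules state energetic accessibility only — kinetic
suppression of energy transfer is outside the model.

Photoinduced electron-transfer free energy follows the Rehm–Weller form
ΔG = E_ox − E_red − E_0-0 (all on a common electrode reference; negative ⇒
favourable).
"""

from __future__ import annotations

from dataclasses import dataclass

#: O2 + e− → O2·− couple, volts vs. NHE.
O2_REDUCTION_POTENTIAL_NHE = -0.33
#: 1O2 excitation thresholds, eV: first excited state 1Δg, second 1Σg+.
SINGLET_OXYGEN_FIRST_EV = 0.98
SINGLET_OXYGEN_SECOND_EV = 1.63
#: ISC channel gap criterion, eV.
ISC_GAP_THRESHOLD_EV = 0.3
#: Planck constant × speed of light in eV·nm.
HC_EV_NM = 1239.842

#: Offset added when converting Ag/AgCl potentials to the NHE scale.  The
#: default +0.20 V reproduces the matched experimental pairs (−1.38 →
#: −1.18 V, −1.42 → −1.22 V); the textbook value 0.197 V is selectable.
AG_AGCL_TO_NHE_OFFSET = 0.20

KNOWN_REFERENCES = ("NHE", "Ag/AgCl")


class PhotophysicsError(ValueError):
    pass


@dataclass(frozen=True)
class RedoxProfile:
    """Oxidation/reduction potentials (V vs. declared reference) and E0-0 (eV)."""

    e_ox: float
    e_red: float
    e00: float
    reference: str = "NHE"

    def __post_init__(self):
        if self.reference not in KNOWN_REFERENCES:
            raise PhotophysicsError(f"unknown electrode reference {self.reference!r}")
        if self.e00 < 0:
            raise PhotophysicsError("excitation energy E0-0 must be non-negative")


@dataclass(frozen=True)
class IscChannel:
    singlet_index: int
    triplet_index: int
    gap_ev: float
    soc_cm1: float | None = None


def convert_reference_potential(
    value: float, from_ref: str, to_ref: str, agcl_offset: float = AG_AGCL_TO_NHE_OFFSET
) -> float:
    """Convert an electrode potential between NHE and Ag/AgCl scales.

    Ag/AgCl → NHE adds ``agcl_offset`` (default +0.20 V); the reverse
    subtracts it, so a round trip is the identity.
    """
    for ref in (from_ref, to_ref):
        if ref not in KNOWN_REFERENCES:
            raise PhotophysicsError(f"unknown electrode reference {ref!r}")
    if from_ref == to_ref:
        return value
    if from_ref == "Ag/AgCl":  # to NHE
        return value + agcl_offset
    return value - agcl_offset  # NHE -> Ag/AgCl


def rehm_weller_dg(profile: RedoxProfile) -> float:
    """ΔG = E_ox − E_red − E_0-0 in eV; negative ⇒ electron transfer favourable."""
    return profile.e_ox - profile.e_red - profile.e00


def oxygen_reduction_feasible(e_red_nhe: float) -> bool:
    """True iff the PS/PS·− potential lies strictly below −0.33 V vs. NHE.

    A photosensitizer radical anion below the O2/O2·− couple can pass its
    electron to oxygen, yielding superoxide.  The input must already be on
    the NHE scale (convert first if measured vs. Ag/AgCl).
    """
    return e_red_nhe < O2_REDUCTION_POTENTIAL_NHE


def singlet_oxygen_energy_feasible(gap_t1_s0: float) -> dict:
    """Energetic accessibility of the two 1O2 formation channels.

    ``first_channel`` (3O2 → 1Δg) requires T1 strictly above 0.98 eV;
    ``second_channel`` (3O2 → 1Σg+) strictly above 1.63 eV.  Accessibility
    does not imply 1O2 is produced — kinetics may suppress energy transfer.
    """
    if gap_t1_s0 < 0:
        raise PhotophysicsError("ΔE(T1−S0) must be non-negative")
    return {
        "first_channel": gap_t1_s0 > SINGLET_OXYGEN_FIRST_EV,
        "second_channel": gap_t1_s0 > SINGLET_OXYGEN_SECOND_EV,
    }


def isc_channels(
    s1: float,
    triplets,
    threshold: float = ISC_GAP_THRESHOLD_EV,
    soc=None,
) -> list:
    """All S1→Tn channels with |S1 − Tn| strictly below the gap threshold.

    ``soc`` optionally supplies spin-orbit coupling constants (cm⁻¹)
    aligned with ``triplets``; they are attached to the returned channels.
    """
    triplets = list(triplets)
    if not triplets:
        raise PhotophysicsError("triplet list must be non-empty")
    if any(b < a for a, b in zip(triplets, triplets[1:])):
        raise PhotophysicsError("triplet energies must be non-decreasing")
    if soc is not None and len(soc) != len(triplets):
        raise PhotophysicsError("SOC list must align with triplet list")
    channels = []
    for n, t in enumerate(triplets, start=1):
        gap = abs(s1 - t)
        if gap < threshold:
            channels.append(
                IscChannel(
                    singlet_index=1,
                    triplet_index=n,
                    gap_ev=gap,
                    soc_cm1=None if soc is None else soc[n - 1],
                )
            )
    return channels


def wavelength_to_energy(lambda_nm: float) -> float:
    """Photon energy in eV from wavelength in nm (E = hc/λ = 1239.842/λ)."""
    if lambda_nm <= 0:
        raise PhotophysicsError("wavelength must be positive")
    return HC_EV_NM / lambda_nm
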