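"""pH-dependent speciation of ionizable PFAS.

Relative species abundances follow the Henderson-Hasselbalch equilibrium.
For a monoprotic acid HA with dissociation constant Ka = 10^-pKa,

    A(HA)  = 1 / (1 + 10^(pH - pKa))
    A(A-)  = 10^(pH - pKa) / (1 + 10^(pH - pKa))

and for a diprotic acid H2A the three closed-form fractions are

    a0 = [H]^2 / D,  a1 = K1 [H] / D,  a2 = K1 K2 / D,   D = [H]^2 + K1 [H] + K1 K2.

Compounds without an ionizable group (e.g. fluorotelomer alcohols) have a
single species with abundance 1 at every pH.

From the abundances two descriptors are derived: the effective molecular
weight (abundance-weighted species MW) and the charge density

    charge density [C/g] = F * (sum_i A_i z_i) / MW_eff,

with F the Faraday constant.  The sign separates cationic (> 0), neutral or
zwitterionic (~ 0), and anionic (< 0) speciation at the given pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .registry import PFASCompound, RegistryError

__all__ = ["FARADAY", "SpeciationState", "speciate", "effective_mw", "charge_density"]

#: Faraday constant [C/mol] (CODATA, rounded).
FARADAY = 96485.0


@dataclass(frozen=True)
class SpeciationState:
    """Speciation of one compound at one pH.

    ``abundances`` is ordered like the compound's species list (most
    protonated first) and sums to 1.  ``net_charge`` is the abundance-weighted
    molar charge, ``mw_effective`` the abundance-weighted molecular weight
    [g/mol], and ``charge_density`` the descriptor F * net_charge / MW_eff
    [C/g].
    """

    compound_id: str
    ph: float
    abundances: tuple[float, ...]
    net_charge: float
    mw_effective: float
    charge_density: float


def _fractions(pka: tuple[float, ...], ph: float) -> tuple[float, ...]:
    if len(pka) == 0:
        return (1.0,)
    if len(pka) == 1:
        r = 10.0 ** (ph - pka[0])
        return (1.0 / (1.0 + r), r / (1.0 + r))
    # diprotic closed form in terms of [H+] and the two Ka values
    h = 10.0 ** (-ph)
    k1 = 10.0 ** (-pka[0])
    k2 = 10.0 ** (-pka[1])
    t0, t1, t2 = h * h, k1 * h, k1 * k2
    d = t0 + t1 + t2
    return (t0 / d, t1 / d, t2 / d)


def speciate(compound: PFASCompound, ph: float) -> SpeciationState:
    """Compute species abundances and derived descriptors at ``ph``."""
    if not math.isfinite(ph):
        raise ValueError(f"ph must be finite, got {ph!r}")
    if len(compound.species) != len(compound.pka) + 1:
        raise RegistryError(f"{compound.id}: malformed species list")
    abund = _fractions(compound.pka, ph)
    mw_eff = sum(a * s.mw for a, s in zip(abund, compound.species))
    net_z = sum(a * s.z for a, s in zip(abund, compound.species))
    return SpeciationState(
        compound_id=compound.id,
        ph=ph,
        abundances=abund,
        net_charge=net_z,
        mw_effective=mw_eff,
        charge_density=FARADAY * net_z / mw_eff,
    )


def effective_mw(state: SpeciationState, compound: PFASCompound) -> float:
    """Abundance-weighted molecular weight [g/mol] of ``compound`` in ``state``."""
    if len(state.abundances) != len(compound.species):
        raise RegistryError(
            f"{compound.id}: {len(state.abundances)} abundances for "
            f"{len(compound.species)} species"
        )
    return sum(a * s.mw for a, s in zip(state.abundances, compound.species))


def charge_density(state: SpeciationState) -> float:
    """Charge density descriptor F * net_charge / MW_eff [C/g]."""
    if state.mw_effective <= 0:
        raise RegistryError("mw_effective must be > 0")
    return FARADAY * state.net_charge / state.mw_effective
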