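"""PFAS compound registry.

Holds identity and physicochemical data for the per- and polyfluoroalkyl
substances (PFAS) the sorption model covers: neutral molecular weight,
octanol-water partition coefficient (log KOW), water solubility, acid
dissociation constants (pKa, up to two), and the ordered list of ionization
species with their net molar charges.  Properties are curated inputs; nothing
here estimates them.

The bundled table covers the PFCA, PFSA, FOSA, FOSAA, FTS, FTOH, PFPA, PFPiA,
PFECA, PFAES and cationic/zwitterionic subfamilies.  Entries whose ionization
scheme or property values rest on structural analogy rather than measured data
carry ``provisional=True``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "ATOMIC_WEIGHTS",
    "PROTON_MASS",
    "SUBFAMILIES",
    "RegistryError",
    "IonicSpecies",
    "PFASCompound",
    "CompoundRegistry",
    "parse_formula",
    "formula_mw",
    "fluorine_mass_fraction",
    "validate_cas",
]

# Standard atomic weights, 3 decimals (IUPAC 2021 abridged values).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
}

#: Mass removed per dissociated proton [g/mol].
PROTON_MASS = 1.008

SUBFAMILIES = frozenset(
    {
        "PFCA",
        "PFSA",
        "FOSA",
        "FTS",
        "PFPA",
        "FTOH",
        "PFECA",
        "FOSAA",
        "PFAES",
        "PFPiA",
        "cationic_zwitterionic",
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class RegistryError(ValueError):
    """Malformed compound definition or failed registry lookup."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula (e.g. ``C8HF15O2``) into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise RegistryError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise RegistryError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(count) if count else 1)
    if pos != len(formula) or not counts:
        raise RegistryError(f"cannot parse formula {formula!r}")
    return counts


def formula_mw(formula: str) -> float:
    """Molecular weight [g/mol] of an empirical formula."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in parse_formula(formula).items())


def fluorine_mass_fraction(formula: str) -> float:
    """Fluorine mass fraction (w/w) of a formula; the %F load is F*100."""
    counts = parse_formula(formula)
    return counts.get("F", 0) * ATOMIC_WEIGHTS["F"] / formula_mw(formula)


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number's checksum digit (e.g. ``335-67-1``)."""
    if not re.fullmatch(r"\d{2,7}-\d{2}-\d", cas):
        return False
    digits = [int(c) for c in cas.replace("-", "")]
    body, check = digits[:-1], digits[-1]
    total = sum(i * d for i, d in enumerate(reversed(body), start=1))
    return total % 10 == check


@dataclass(frozen=True)
class IonicSpecies:
    """One ionization state of a compound.

    ``z`` is the net molar charge of the species; ``protonation_level`` counts
    the dissociable protons still attached (the most protonated species of a
    compound with two pKa values has level 2).
    """

    label: str
    z: int
    mw: float
    protonation_level: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise RegistryError(f"species {self.label!r}: mw must be > 0")
        if self.protonation_level < 0:
            raise RegistryError(f"species {self.label!r}: negative protonation level")


@dataclass
class PFASCompound:
    """Identity, properties, and ionization scheme of one PFAS.

    ``mw_neutral`` is the molecular weight of the most protonated species
    (matching ``formula``).  ``species`` is ordered from most to least
    protonated, one more entry than ``pka``; adjacent species differ by one
    proton.  ``n_fluorinated_carbons`` drives chain-length analyses.
    """

    id: str
    name: str
    abbreviation: str
    cas: str | None
    formula: str
    mw_neutral: float
    log_kow: float
    solubility: float | None
    pka: tuple[float, ...]
    species: tuple[IonicSpecies, ...]
    subfamily: str
    n_fluorinated_carbons: int
    provisional: bool = False

    def __post_init__(self) -> None:
        self.pka = tuple(self.pka)
        self.species = tuple(
            s if isinstance(s, IonicSpecies) else IonicSpecies(**s) for s in self.species
        )
        self.validate()

    def validate(self) -> None:
        if self.mw_neutral <= 0:
            raise RegistryError(f"{self.id}: mw_neutral must be > 0")
        if not 0 <= len(self.pka) <= 2:
            raise RegistryError(f"{self.id}: expected 0-2 pKa values")
        if list(self.pka) != sorted(self.pka):
            raise RegistryError(f"{self.id}: pKa values must be sorted ascending")
        if len(self.species) != len(self.pka) + 1:
            raise RegistryError(
                f"{self.id}: need {len(self.pka) + 1} species, got {len(self.species)}"
            )
        if self.subfamily not in SUBFAMILIES:
            raise RegistryError(f"{self.id}: unknown subfamily {self.subfamily!r}")
        if self.cas is not None and not validate_cas(self.cas):
            raise RegistryError(f"{self.id}: CAS {self.cas!r} fails checksum")
        n_prot = len(self.pka)
        for step, sp in enumerate(self.species):
            if sp.protonation_level != n_prot - step:
                raise RegistryError(f"{self.id}: species out of protonation order")
            expected_mw = self.mw_neutral - step * PROTON_MASS
            if abs(sp.mw - expected_mw) > 0.01:
                raise RegistryError(
                    f"{self.id}: species {sp.label!r} mw {sp.mw} != {expected_mw:.3f}"
                )
        for a, b in zip(self.species, self.species[1:]):
            if b.z != a.z - 1:
                raise RegistryError(f"{self.id}: deprotonation must lower z by 1")
        if abs(formula_mw(self.formula) - self.mw_neutral) > 0.05:
            raise RegistryError(
                f"{self.id}: formula mass {formula_mw(self.formula):.3f} "
                f"disagrees with mw_neutral {self.mw_neutral}"
            )

    @property
    def fluorine_fraction(self) -> float:
        return fluorine_mass_fraction(self.formula)

    @classmethod
    def from_dict(cls, d: dict) -> "PFASCompound":
        species = []
        n_prot = len(d.get("pka", []))
        mw_neutral = float(d["mw_neutral"])
        for step, s in enumerate(d["species"]):
            mw = s.get("mw", mw_neutral - step * PROTON_MASS)
            species.append(
                IonicSpecies(
                    label=s["label"],
                    z=int(s["z"]),
                    mw=float(mw),
                    protonation_level=int(s.get("protonation_level", n_prot - step)),
                )
            )
        return cls(
            id=d["id"],
            name=d["name"],
            abbreviation=d["abbreviation"],
            cas=d.get("cas"),
            formula=d["formula"],
            mw_neutral=float(d["mw_neutral"]),
            log_kow=float(d["log_kow"]),
            solubility=None if d.get("solubility") in (None, "") else float(d["solubility"]),
            pka=tuple(float(p) for p in d.get("pka", [])),
            species=tuple(species),
            subfamily=d["subfamily"],
            n_fluorinated_carbons=int(d["n_fluorinated_carbons"]),
            provisional=bool(d.get("provisional", False)),
        )


class CompoundRegistry:
    """Lookup table of :class:`PFASCompound` keyed by id, abbreviation, CAS or name."""

    def __init__(self, compounds: Sequence[PFASCompound]):
        self._compounds: dict[str, PFASCompound] = {}
        self._aliases: dict[str, str] = {}
        for c in compounds:
            if c.id in self._compounds:
                raise RegistryError(f"duplicate compound id {c.id!r}")
            self._compounds[c.id] = c
            for alias in (c.id, c.abbreviation, c.name, c.cas):
                if alias:
                    self._aliases[alias.casefold()] = c.id

    def get(self, key: str) -> PFASCompound:
        cid = self._aliases.get(str(key).casefold())
        if cid is None:
            raise RegistryError(f"unknown compound {key!r}")
        return self._compounds[cid]

    def __contains__(self, key: str) -> bool:
        return str(key).casefold() in self._aliases

    def __iter__(self) -> Iterator[PFASCompound]:
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    @property
    def ids(self) -> list[str]:
        return list(self._compounds)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "CompoundRegistry":
        return cls([PFASCompound.from_dict(r) for r in records])

    @classmethod
    def from_json(cls, path: str | Path) -> "CompoundRegistry":
        with open(path) as fh:
            return cls.from_records(json.load(fh))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundRegistry":
        """CSV dialect: one row per compound; ``pka`` semicolon-separated;
        species encoded as ``label:z`` pairs, semicolon-separated, most
        protonated first."""
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pka = [float(p) for p in row["pka"].split(";") if p.strip()]
                species = []
                for part in row["species"].split(";"):
                    label, z = part.rsplit(":", 1)
                    species.append({"label": label.strip(), "z": int(z)})
                rec = dict(row)
                rec["pka"] = pka
                rec["species"] = species
                records.append(rec)
        return cls.from_records(records)

    @classmethod
    def bundled(cls) -> "CompoundRegistry":
        """The registry shipped with the package (47 modeled PFAS plus the
        compounds excluded as anomalous in the source dataset)."""
        data = resources.files("pfasorption").joinpath("data/compounds.json")
        return cls.from_records(json.loads(data.read_text()))
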