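"""Redox stoichiometry of anaerobic alkane oxidation coupled to sulfate reduction.

Builds and validates the reactions linking complete oxidation of C1–C5
n-alkanes (and acetate / H2) to dissimilatory sulfate reduction,

    CnH2n+2 + (3n+1)/4 SO4^2- -> n HCO3^- + (3n+1)/4 HS^- + H2O + (n-1)/4 H+

where the sulfate coefficient follows from electron balance: the alkane
donates 6n+2 electrons on complete oxidation of its carbon to bicarbonate,
and each sulfate accepts 8 (S(+VI) -> S(-II)).

Coefficients are exact `fractions.Fraction`s so that element, charge and
electron balance are testable identities, not float comparisons.  The
literature reaction table is shipped verbatim (including its one
charge-imbalanced entry) under ``source="table6"``; independently derived
balanced reactions carry ``source="derived"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Mapping

__all__ = [
    "AlkaneSpecies",
    "Reaction",
    "BalanceReport",
    "ALKANES",
    "alkane",
    "derive_alkane_sulfate_reaction",
    "table6_reaction",
    "check_reaction_balance",
    "predicted_ratios",
    "delta_g0",
    "load_thermo_table",
]

# Atom composition and charge per species.  Names double as the CSV vocabulary.
SPECIES_ATOMS: dict[str, dict[str, int]] = {
    "CH4": {"C": 1, "H": 4},
    "C2H6": {"C": 2, "H": 6},
    "C3H8": {"C": 3, "H": 8},
    "C4H10": {"C": 4, "H": 10},
    "C5H12": {"C": 5, "H": 12},
    "CH3COO-": {"C": 2, "H": 3, "O": 2},
    "H2": {"H": 2},
    "SO4-2": {"S": 1, "O": 4},
    "HCO3-": {"C": 1, "H": 1, "O": 3},
    "HS-": {"H": 1, "S": 1},
    "H+": {"H": 1},
    "H2O": {"H": 2, "O": 1},
}

SPECIES_CHARGE: dict[str, int] = {
    "CH4": 0, "C2H6": 0, "C3H8": 0, "C4H10": 0, "C5H12": 0,
    "CH3COO-": -1, "H2": 0, "SO4-2": -2, "HCO3-": -1, "HS-": -1,
    "H+": 1, "H2O": 0,
}

# Total formal oxidation state carried by each element within a species
# (summed over atoms; H is +1 except in H2, O is -2, the redox-active atom
# takes up the remainder so totals sum to the species charge).
SPECIES_OXSTATE: dict[str, dict[str, Fraction]] = {
    "CH4": {"C": Fraction(-4), "H": Fraction(4)},
    "C2H6": {"C": Fraction(-6), "H": Fraction(6)},
    "C3H8": {"C": Fraction(-8), "H": Fraction(8)},
    "C4H10": {"C": Fraction(-10), "H": Fraction(10)},
    "C5H12": {"C": Fraction(-12), "H": Fraction(12)},
    "CH3COO-": {"C": Fraction(0), "H": Fraction(3), "O": Fraction(-4)},
    "H2": {"H": Fraction(0)},
    "SO4-2": {"S": Fraction(6), "O": Fraction(-8)},
    "HCO3-": {"C": Fraction(4), "H": Fraction(1), "O": Fraction(-6)},
    "HS-": {"S": Fraction(-2), "H": Fraction(1)},
    "H+": {"H": Fraction(1)},
    "H2O": {"H": Fraction(2), "O": Fraction(-2)},
}

#: Species that can act as the electron donor of a reaction.
DONOR_SPECIES = frozenset({"CH4", "C2H6", "C3H8", "C4H10", "C5H12", "CH3COO-", "H2"})

R_GAS_KJ = 8.314462618e-3  # kJ mol-1 K-1
T_STANDARD_K = 298.15


@dataclass(frozen=True)
class AlkaneSpecies:
    """A C1–C5 n-alkane with the physical constants the pipeline needs.

    ``solubility_standard`` is the equilibrium aqueous solubility in water at
    standard conditions, in mM (C1–C4 defaults: 0.9, 1.3, 1.0, 0.8).
    """

    name: str
    n_carbons: int
    formula: str
    solubility_standard: float

    def __post_init__(self) -> None:
        if not 1 <= self.n_carbons <= 5:
            raise ValueError(f"n_carbons must be in 1..5, got {self.n_carbons}")
        expected = _alkane_formula(self.n_carbons)
        if self.formula != expected:
            raise ValueError(
                f"formula {self.formula!r} inconsistent with CnH2n+2 for n={self.n_carbons}"
            )

    @property
    def electrons_donated(self) -> int:
        """Electrons released per molecule on complete oxidation to HCO3-."""
        return 6 * self.n_carbons + 2


def _alkane_formula(n: int) -> str:
    return f"C{n}H{2 * n + 2}" if n > 1 else "CH4"


ALKANES: dict[str, AlkaneSpecies] = {
    "methane": AlkaneSpecies("methane", 1, "CH4", 0.9),
    "ethane": AlkaneSpecies("ethane", 2, "C2H6", 1.3),
    "propane": AlkaneSpecies("propane", 3, "C3H8", 1.0),
    "butane": AlkaneSpecies("butane", 4, "C4H10", 0.8),
    # pentane solubility not constrained by the incubation study; CRC-order estimate
    "pentane": AlkaneSpecies("pentane", 5, "C5H12", 0.4),
}


def alkane(key: str | int | AlkaneSpecies) -> AlkaneSpecies:
    """Resolve an alkane by name ('propane'), carbon number (3) or identity."""
    if isinstance(key, AlkaneSpecies):
        return key
    if isinstance(key, int):
        for sp in ALKANES.values():
            if sp.n_carbons == key:
                return sp
        raise ValueError(f"no C{key} alkane in registry (1..5 supported)")
    try:
        return ALKANES[key.lower()]
    except KeyError:
        raise ValueError(f"unknown alkane {key!r}") from None


@dataclass(frozen=True)
class Reaction:
    """A redox reaction as signed stoichiometric coefficients.

    Reactants carry negative coefficients, products positive.  ``delta_g0``
    (kJ per mol sulfate) is attached only for literature reactions; computed
    values come from :func:`delta_g0`.
    """

    species_coefficients: Mapping[str, Fraction]
    delta_g0: float | None = None
    source: str = "derived"
    id: int | None = None

    def __post_init__(self) -> None:
        for name, coeff in self.species_coefficients.items():
            if name not in SPECIES_ATOMS:
                raise KeyError(f"unknown species {name!r}")
            if coeff == 0:
                raise ValueError(f"zero coefficient for {name!r}")

    def coefficient(self, species: str) -> Fraction:
        return self.species_coefficients.get(species, Fraction(0))

    @property
    def donor(self) -> str:
        donors = [s for s, c in self.species_coefficients.items()
                  if c < 0 and s in DONOR_SPECIES]
        if len(donors) != 1:
            raise ValueError(f"expected exactly one electron donor, found {donors}")
        return donors[0]

    def scaled(self, factor: Fraction) -> "Reaction":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Reaction(
            {s: c * factor for s, c in self.species_coefficients.items()},
            delta_g0=self.delta_g0, source=self.source, id=self.id,
        )

    def equation(self) -> str:
        """Render as a plain-text chemical equation."""
        def side(sign: int) -> str:
            terms = []
            for s, c in self.species_coefficients.items():
                if (c < 0) == (sign < 0):
                    mag = abs(c)
                    coeff = "" if mag == 1 else f"{mag} "
                    terms.append(f"{coeff}{s}")
            return " + ".join(terms) if terms else "0"

        return f"{side(-1)} -> {side(+1)}"

    def to_csv_rows(self) -> list[tuple[str, str]]:
        return [(s, str(c)) for s, c in self.species_coefficients.items()]


@dataclass
class BalanceReport:
    """Residuals of a reaction balance check, reactant side minus product side.

    ``electron_residual`` is electrons donated minus electrons accepted from
    formal oxidation-state accounting; for an element-balanced reaction it
    equals minus the charge residual.
    """

    element_residuals: dict[str, Fraction] = field(default_factory=dict)
    charge_residual: Fraction = Fraction(0)
    electron_residual: Fraction = Fraction(0)

    @property
    def balanced(self) -> bool:
        return (
            all(v == 0 for v in self.element_residuals.values())
            and self.charge_residual == 0
            and self.electron_residual == 0
        )


def derive_alkane_sulfate_reaction(species: AlkaneSpecies | str | int) -> Reaction:
    """Balanced complete oxidation of an n-alkane by sulfate.

    CnH2n+2 + (3n+1)/4 SO4^2- -> n HCO3^- + (3n+1)/4 HS^- + H2O + (n-1)/4 H+

    The sulfate coefficient is the electron-balance ratio
    (6n+2 donated) / (8 accepted) = (3n+1)/4.
    """
    sp = alkane(species)
    n = sp.n_carbons
    s = Fraction(3 * n + 1, 4)
    coeffs: dict[str, Fraction] = {
        sp.formula: Fraction(-1),
        "SO4-2": -s,
        "HCO3-": Fraction(n),
        "HS-": s,
        "H2O": Fraction(1),
    }
    h = Fraction(n - 1, 4)
    if h != 0:
        coeffs["H+"] = h
    rxn = Reaction(coeffs, source="derived")
    report = check_reaction_balance(rxn)
    assert report.balanced, f"internal error: derived reaction unbalanced: {report}"
    return rxn


def _rxn(spec: dict[str, int | Fraction], dg0: float, rid: int) -> Reaction:
    return Reaction({s: Fraction(c) for s, c in spec.items()},
                    delta_g0=dg0, source="table6", id=rid)


# The literature reaction set, verbatim.  Entry 5 (butane) is reproduced with
# its printed coefficients even though it is charge-imbalanced (reactant side
# carries 26 more negative charges than the product side).
_TABLE6: dict[int, Reaction] = {
    1: _rxn({"SO4-2": -1, "CH3COO-": -1, "HCO3-": 2, "HS-": 1}, -47.7, 1),
    2: _rxn({"SO4-2": -1, "CH4": -1, "HCO3-": 1, "HS-": 1, "H2O": 1}, -33.0, 2),
    3: _rxn({"SO4-2": -14, "C2H6": -8, "HS-": 14, "HCO3-": 16, "H2O": 8, "H+": 2},
            -39.81, 3),
    4: _rxn({"SO4-2": -5, "C3H8": -2, "HCO3-": 6, "HS-": 5, "H+": 1, "H2O": 2},
            -33.06, 4),
    5: _rxn({"SO4-2": -26, "C4H10": -9, "H2O": -4, "HCO3-": 36, "H+": 36, "HS-": 26},
            -14.0, 5),
    6: _rxn({"SO4-2": -1, "HCO3-": -2, "H2": -8, "H+": -2,
             "CH3COO-": 1, "HS-": 1, "H2O": 8}, -336.5, 6),
}


def table6_reaction(rid: int) -> Reaction:
    """Literature reaction *rid* (1..6) with its printed coefficients and ΔG°.

    1 acetate, 2 methane, 3 ethane, 4 propane, 5 butane (as printed —
    charge-imbalanced), 6 autotrophic acetogenesis from H2.
    """
    if rid not in _TABLE6:
        raise ValueError(f"reaction id must be in 1..6, got {rid}")
    return _TABLE6[rid]


def check_reaction_balance(reaction: Reaction) -> BalanceReport:
    """Element, charge and electron residuals (reactants minus products).

    Electron residual is donated minus accepted electrons: per element, the
    change in total formal oxidation state from reactant side to product side
    is summed separately over oxidations (donations) and reductions
    (acceptances).
    """
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    ox_delta: dict[str, Fraction] = {}
    for name, coeff in reaction.species_coefficients.items():
        atoms = SPECIES_ATOMS[name]
        for el, count in atoms.items():
            elements[el] = elements.get(el, Fraction(0)) - coeff * count
        charge -= coeff * SPECIES_CHARGE[name]
        for el, ox in SPECIES_OXSTATE[name].items():
            ox_delta[el] = ox_delta.get(el, Fraction(0)) + coeff * ox
    donated = sum((d for d in ox_delta.values() if d > 0), Fraction(0))
    accepted = -sum((d for d in ox_delta.values() if d < 0), Fraction(0))
    return BalanceReport(
        element_residuals=elements,
        charge_residual=charge,
        electron_residual=donated - accepted,
    )


def predicted_ratios(reaction: Reaction) -> dict[str, Fraction]:
    """Donor:sulfate and carbon:sulfate molar ratios of a reaction.

    For alkane reactions the donor:sulfate ratio is the stoichiometric
    prediction 4/(3n+1) mol alkane per mol sulfate.
    """
    s = reaction.coefficient("SO4-2")
    if s == 0:
        raise ValueError("reaction contains no sulfate")
    donor = reaction.donor
    donor_coeff = abs(reaction.coefficient(donor))
    bicarb = abs(reaction.coefficient("HCO3-"))
    if reaction.source == "derived":
        n_c = SPECIES_ATOMS[donor].get("C", 0)
        carbon = donor_coeff * n_c
    else:
        carbon = bicarb
    return {
        "alkane_to_sulfate": donor_coeff / abs(s),
        "carbon_to_sulfate": carbon / abs(s),
    }


def load_thermo_table(path=None) -> dict[str, float]:
    """Standard Gibbs energies of formation (kJ/mol), aqueous species.

    The packaged table is assembled from standard thermodynamic compilations
    (CRC-style values); dissolved gases use their aqueous-phase ΔGf°, H2 the
    gas-phase reference.  Compilations differ by a few kJ/mol, hence the ±5
    kJ/(mol sulfate) tolerance used when comparing computed reaction energies
    to published ones.
    """
    if path is None:
        ref = resources.files("alkox.data").joinpath("gibbs_formation.csv")
        with ref.open("r", newline="") as fh:
            return _read_thermo(fh)
    with open(path, newline="") as fh:
        return _read_thermo(fh)


def _read_thermo(fh) -> dict[str, float]:
    table = {}
    for row in csv.DictReader(fh):
        table[row["species"]] = float(row["delta_gf_kj_per_mol"])
    return table


def delta_g0(reaction: Reaction, thermo_table: Mapping[str, float] | None = None,
             ph7: bool = False) -> float:
    """Standard reaction Gibbs energy, kJ per mol sulfate.

    Σ (signed coefficient × ΔGf°), normalised by the sulfate coefficient.
    Standard state is 1 M / 1 atm / 298.15 K.  With ``ph7=True`` the proton
    activity is shifted to 1e-7 via an explicit RT·ln(1e-7) term per mol H+
    produced; the default is the strict 1 M standard state, which is what the
    published per-sulfate energies are numerically consistent with.
    """
    table = load_thermo_table() if thermo_table is None else thermo_table
    missing = sorted(set(reaction.species_coefficients) - set(table))
    if missing:
        raise LookupError(f"thermo table missing species: {missing}")
    s = reaction.coefficient("SO4-2")
    if s == 0:
        raise ValueError("reaction contains no sulfate to normalise by")
    total = sum(float(c) * table[name]
                for name, c in reaction.species_coefficients.items())
    if ph7:
        import math
        h = float(reaction.coefficient("H+"))
        total += h * R_GAS_KJ * T_STANDARD_K * math.log(1e-7)
    return total / abs(float(s))
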