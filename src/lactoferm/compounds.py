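"""Compound registry: carbon content, molar mass and electron equivalents.

Every organic acid, alcohol and gas tracked by the HPLC/GC protocol is
registered with its neutral (protonated) formula.  Electron equivalents
follow the degree-of-reduction convention: the number of electrons released
by complete oxidation of one molecule to CO2 and H2O, i.e.

    e_equiv = 4*C + H - 2*O

so CO2 itself carries zero electron equivalents and H2 carries two.
Electron equivalents are always computed on the neutral acid form (e.g.
C3H6O3 for lactate), which sidesteps charge bookkeeping for the dissociated
species while giving the same per-carbon electron densities (lactate 4,
acetate 4, propionate 14/3, butyrate 5 e- per C).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class UnknownCompoundError(KeyError):
    """Raised when a compound name is not present in the registry."""


@dataclass(frozen=True)
class Compound:
    """A chemical species with its balance-relevant bookkeeping numbers.

    Attributes
    ----------
    name:
        Registry identifier (lower case for organics, e.g. ``"lactate"``).
    c_atoms, h_atoms, o_atoms:
        Atom counts of the neutral (acid) form.
    molar_mass:
        Molar mass of the neutral form, g/mol.
    """

    name: str
    c_atoms: int
    h_atoms: int
    o_atoms: int
    molar_mass: float

    def __post_init__(self) -> None:
        if min(self.c_atoms, self.h_atoms, self.o_atoms) < 0:
            raise ValueError(f"{self.name}: negative atom counts")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.c_atoms == self.h_atoms == self.o_atoms == 0:
            raise ValueError(f"{self.name}: empty formula")
        # computed eagerly so an unsupported (super-oxidised) species fails
        # at registration, not at first use
        electron_equivalents(self.c_atoms, self.h_atoms, self.o_atoms)

    @property
    def electron_equiv(self) -> int:
        """mol e- released per mol on full oxidation to CO2/H2O."""
        return electron_equivalents(self.c_atoms, self.h_atoms, self.o_atoms)

    @property
    def carbon_equiv(self) -> int:
        """mol C per mol compound."""
        return self.c_atoms


def electron_equivalents(c: int, h: int, o: int) -> int:
    """Degree of reduction of a CcHhOo species: ``4c + h - 2o``.

    Raises
    ------
    ValueError
        If the counts are negative, all zero, or the formula is more
        oxidised than the CO2/H2O reference state (negative result).
    """
    if min(c, h, o) < 0:
        raise ValueError("atom counts must be non-negative")
    if c == h == o == 0:
        raise ValueError("empty formula")
    gamma = 4 * c + h - 2 * o
    if gamma < 0:
        raise ValueError(
            f"C{c}H{h}O{o} is more oxidised than the CO2/H2O reference "
            f"(degree of reduction {gamma} < 0)"
        )
    return gamma


class CompoundRegistry:
    """Lookup table of :class:`Compound` entries, loadable from CSV."""

    def __init__(self, compounds: dict[str, Compound] | None = None):
        self._compounds: dict[str, Compound] = dict(compounds or {})

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def __iter__(self):
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    def get(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise UnknownCompoundError(
                f"unknown compound {name!r}; registered: "
                f"{sorted(self._compounds)}"
            ) from None

    def register(self, compound: Compound, overwrite: bool = False) -> None:
        if compound.name in self._compounds and not overwrite:
            raise ValueError(f"{compound.name} already registered")
        self._compounds[compound.name] = compound

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundRegistry":
        """Load a registry from a delimited table.

        Expected columns: ``name, c_atoms, h_atoms, o_atoms, molar_mass``.
        """
        reg = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                reg.register(
                    Compound(
                        name=row["name"],
                        c_atoms=int(row["c_atoms"]),
                        h_atoms=int(row["h_atoms"]),
                        o_atoms=int(row["o_atoms"]),
                        molar_mass=float(row["molar_mass"]),
                    )
                )
        return reg


def default_registry() -> CompoundRegistry:
    """The packaged registry (carboxylates C2-C6, alcohols, H2, CO2, CH4)."""
    source = resources.files("lactoferm.data").joinpath("compounds.csv")
    with resources.as_file(source) as path:
        return CompoundRegistry.from_csv(path)


# module-level singleton; users needing extensions work on their own copy
REGISTRY = default_registry()


def mm_to_mass_rate(rate_mm_per_day: float, compound: str | Compound,
                    registry: CompoundRegistry | None = None) -> float:
    """Convert a molar rate (mM/d) to a mass rate (g/L/d).

    Uses the neutral-acid molar mass; 10 mM/d acetate -> 0.60 g/L/d.
    """
    comp = _resolve(compound, registry)
    if not _is_finite(rate_mm_per_day):
        raise ValueError("rate must be finite")
    return rate_mm_per_day * comp.molar_mass / 1000.0


def mass_to_mm_rate(rate_g_per_l_day: float, compound: str | Compound,
                    registry: CompoundRegistry | None = None) -> float:
    """Inverse of :func:`mm_to_mass_rate` (g/L/d -> mM/d)."""
    comp = _resolve(compound, registry)
    if not _is_finite(rate_g_per_l_day):
        raise ValueError("rate must be finite")
    return rate_g_per_l_day * 1000.0 / comp.molar_mass


def mmol_to_carbon_and_electrons(
    amount_mmol: float, compound: str | Compound,
    registry: CompoundRegistry | None = None,
) -> tuple[float, float]:
    """mmol of a compound -> (mmol C, mmol e-) it carries."""
    comp = _resolve(compound, registry)
    if amount_mmol < 0:
        raise ValueError("amount must be non-negative")
    return amount_mmol * comp.carbon_equiv, amount_mmol * comp.electron_equiv


def _resolve(compound: str | Compound,
             registry: CompoundRegistry | None) -> Compound:
    if isinstance(compound, Compound):
        return compound
    return (registry or REGISTRY).get(compound)


def _is_finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")
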