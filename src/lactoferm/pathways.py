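"""Metabolic reaction network and extent decomposition for cathodic
lactate electrofermentation.

Four reactions describe the observed product spectrum:

  R1  fermentation        3 lactate -> 2 propionate + acetate + CO2
  R2  acetogenesis        4 H2 + 2 CO2 -> acetate        (Wood-Ljungdahl)
  R3  chain elongation    lactate + acetate -> butyrate + CO2
  R4  H2 evolution        2 e-(cathode) -> H2

All species are written in their carbon-skeleton form; bicarbonate is
accounted as CO2.  Each reaction is carbon-balanced and electron-balanced
under the degree-of-reduction convention (e- coefficient counts cathodic
electrons explicitly), which the test-suite verifies against an
independent atom-counting oracle.

Measured concentration changes are attributed to reaction extents
algebraically, not by least squares: propionate is produced by R1 alone,
so it fixes the fermentation extent; butyrate fixes chain elongation;
the acetate left over after fermentation and elongation are accounted for
fixes acetogenesis.  The residual on lactate exposes substrate routed to
fates outside the network (growth, aerobic loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compounds import REGISTRY

SPECIES = ("lactate", "propionate", "acetate", "butyrate", "H2", "CO2")

#: electrons drawn from the cathode per H2 (the H2/H+ couple)
ELECTRONS_PER_H2 = 2


class StoichiometryError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    """A reaction over the network species plus cathodic electrons.

    ``stoichiometry`` maps species name -> signed coefficient (negative =
    consumed); ``electrons`` is the number of cathodic electrons consumed
    per extent unit (positive = drawn from the electrode).
    """

    name: str
    stoichiometry: dict[str, float]
    electrons: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.stoichiometry) - set(SPECIES)
        if unknown:
            raise StoichiometryError(f"{self.name}: unknown species {unknown}")
        c = self.carbon_imbalance()
        if abs(c) > 1e-9:
            raise StoichiometryError(
                f"{self.name}: carbon imbalance of {c:+g} mol C per extent"
            )
        e = self.electron_imbalance()
        if abs(e) > 1e-9:
            raise StoichiometryError(
                f"{self.name}: electron imbalance of {e:+g} mol e- per extent"
            )

    def carbon_imbalance(self) -> float:
        return sum(
            coeff * REGISTRY.get(sp).carbon_equiv
            for sp, coeff in self.stoichiometry.items()
        )

    def electron_imbalance(self) -> float:
        """Degree-of-reduction balance including cathodic electrons."""
        return (
            sum(
                coeff * REGISTRY.get(sp).electron_equiv
                for sp, coeff in self.stoichiometry.items()
            )
            - self.electrons
        )


def builtin_network() -> list[Reaction]:
    """The four-reaction network, each validated on construction."""
    return [
        Reaction(
            name="fermentation",
            stoichiometry={
                "lactate": -3, "propionate": 2, "acetate": 1, "CO2": 1,
            },
        ),
        Reaction(
            name="acetogenesis",
            stoichiometry={"H2": -4, "CO2": -2, "acetate": 1},
        ),
        Reaction(
            name="chain_elongation",
            stoichiometry={
                "lactate": -1, "acetate": -1, "butyrate": 1, "CO2": 1,
            },
        ),
        Reaction(
            name="h2_evolution",
            stoichiometry={"H2": 1},
            electrons=ELECTRONS_PER_H2,
        ),
    ]


@dataclass
class PathwayExtents:
    """Extents (mmol, per reaction as written) plus bookkeeping outputs."""

    xi_ferm: float
    xi_acet: float
    xi_ce: float
    xi_her: float = 0.0
    residual: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def co2_net(self) -> float:
        """Net CO2 produced: fermentation + elongation - acetogenic fixation."""
        return self.xi_ferm - 2.0 * self.xi_acet + self.xi_ce

    @property
    def h2_demand(self) -> float:
        """mmol H2 consumed by acetogenesis."""
        return 4.0 * self.xi_acet

    @property
    def charge_demand(self) -> float:
        """mmol cathodic e- needed to supply ``h2_demand`` via H2 evolution."""
        return ELECTRONS_PER_H2 * self.h2_demand


def theoretical_combined_yields() -> tuple[float, float, float]:
    """Yields per mol lactate when fermentation runs coupled to
    acetogenesis consuming all fermentation-derived CO2.

    Per 3 mol lactate, fermentation yields 2 propionate + 1 acetate +
    1 CO2; recycling that CO2 through acetogenesis (2 CO2 per acetate)
    adds 0.5 acetate.  Returns (propionate yield, acetate yield,
    propionate:acetate ratio) = (2/3, 1/2, 4/3).
    """
    network = {r.name: r for r in builtin_network()}
    ferm = network["fermentation"]
    acet = network["acetogenesis"]
    lactate = -ferm.stoichiometry["lactate"]          # 3
    xi_acet = ferm.stoichiometry["CO2"] / (-acet.stoichiometry["CO2"])  # 0.5
    prop = ferm.stoichiometry["propionate"] / lactate
    ace = (
        ferm.stoichiometry["acetate"]
        + xi_acet * acet.stoichiometry["acetate"]
    ) / lactate
    return prop, ace, prop / ace


def fermentation_only_ratio() -> float:
    """Propionate:acetate ratio of fermentation alone (2.0)."""
    ferm = builtin_network()[0]
    return ferm.stoichiometry["propionate"] / ferm.stoichiometry["acetate"]


def decompose_extents(
    deltas: dict[str, float],
    h2_out: float = 0.0,
    charge: float = 0.0,
) -> PathwayExtents:
    """Attribute observed net changes (mmol) to reaction extents.

    ``deltas`` gives net production (positive) or consumption (negative)
    of lactate, propionate, acetate and butyrate over a production-phase
    window.  Product deltas must be non-negative.  ``h2_out`` (captured
    headspace H2, mmol) and ``charge`` (delivered, mmol e-) let the H2
    evolution extent be inferred as well.

    Attribution: propionate is only made by fermentation, so
    xi_ferm = d_propionate / 2; butyrate is only made by elongation, so
    xi_ce = d_butyrate; acetate closes acetogenesis:
    xi_acet = d_acetate - xi_ferm + xi_ce.  A negative xi_acet (less
    acetate than fermentation alone predicts) is floored at zero and the
    shortfall reported as residual(acetate).  residual(lactate) compares
    the observed lactate change against the network's demand.
    """
    d_prop = deltas.get("propionate", 0.0)
    d_ace = deltas.get("acetate", 0.0)
    d_but = deltas.get("butyrate", 0.0)
    for name, d in (("propionate", d_prop), ("acetate", d_ace),
                    ("butyrate", d_but)):
        if d < 0:
            raise StoichiometryError(
                f"net {name} change is negative ({d:.3g} mmol); choose a "
                "production-phase window (or split the window at the "
                "onset of consumption)"
            )

    xi_ce = d_but
    xi_ferm = d_prop / 2.0
    xi_acet = d_ace - xi_ferm + xi_ce

    flags: list[str] = []
    residual = {sp: 0.0 for sp in SPECIES}
    if xi_acet < 0:
        # fermentation alone over-predicts acetate: no acetogenesis and an
        # unexplained acetate deficit (e.g. aerobic consumption)
        residual["acetate"] = xi_acet
        flags.append(
            f"acetate deficit of {-xi_acet:.3g} mmol relative to "
            "fermentation stoichiometry; acetogenesis extent floored at 0"
        )
        xi_acet = 0.0

    ext = PathwayExtents(
        xi_ferm=xi_ferm, xi_acet=xi_acet, xi_ce=xi_ce,
        residual=residual, flags=flags,
    )

    if "lactate" in deltas:
        predicted = -3.0 * xi_ferm - xi_ce
        residual["lactate"] = deltas["lactate"] - predicted

    # H2 evolution extent: electrons delivered bound it above, captured H2
    # plus acetogenic demand bound it below
    if charge > 0:
        ext.xi_her = charge / ELECTRONS_PER_H2
        residual["H2"] = h2_out - (ext.xi_her - ext.h2_demand)
    elif h2_out > 0 or ext.h2_demand > 0:
        ext.xi_her = h2_out + ext.h2_demand
    return ext


def reconstruct_deltas(extents: PathwayExtents) -> dict[str, float]:
    """Net species changes (mmol) implied by an extents vector.

    Inverse of :func:`decompose_extents` on its image; H2 is the net
    after acetogenic consumption.
    """
    totals = {sp: 0.0 for sp in SPECIES}
    xi = {
        "fermentation": extents.xi_ferm,
        "acetogenesis": extents.xi_acet,
        "chain_elongation": extents.xi_ce,
        "h2_evolution": extents.xi_her,
    }
    for rxn in builtin_network():
        for sp, coeff in rxn.stoichiometry.items():
            totals[sp] += coeff * xi[rxn.name]
    return totals


def predicted_ratio(extents: PathwayExtents) -> float:
    """Propionate:acetate ratio implied by the extents,
    ``2 xi_ferm / (xi_ferm + xi_acet - xi_ce)``."""
    denom = extents.xi_ferm + extents.xi_acet - extents.xi_ce
    if denom <= 0:
        raise StoichiometryError(
            "predicted ratio undefined: reconstructed acetate is not positive"
        )
    return 2.0 * extents.xi_ferm / denom


def decompose_cycle(exp, cycle, h2_out: float = 0.0, charge: float = 0.0,
                    floor_products: bool = False) -> PathwayExtents:
    """Decompose one batch cycle of a :class:`~lactoferm.datamodel.CellExperiment`.

    Net species changes include product withdrawn with samples and product
    migrated to the anolyte, and lactate consumption is corrected for
    withdrawn unconsumed substrate, so extents are comparable across
    sampling regimes.  ``floor_products=True`` clips slightly negative
    measured product changes to zero (measurement noise around a zero
    level) instead of raising.
    """
    from .rates import product_formed_in_cycle, substrate_consumed_in_cycle

    deltas = {
        sp: product_formed_in_cycle(exp, sp, cycle)
        for sp in ("propionate", "acetate", "butyrate")
        if exp.get_series(sp, "cathode") is not None
        or any(comp == sp for _, comp, _ in exp.anolyte_end)
    }
    if floor_products:
        deltas = {sp: max(d, 0.0) for sp, d in deltas.items()}
    if exp.get_series("lactate", "cathode") is not None:
        deltas["lactate"] = -substrate_consumed_in_cycle(exp, "lactate", cycle)
    return decompose_extents(deltas, h2_out=h2_out, charge=charge)


def co2_recycled(extents: PathwayExtents) -> tuple[float, float, bool]:
    """CO2 fixed by acetogenesis, split into (recycled from fermentation +
    elongation, externally sourced, external-flag).

    Acetogenesis fixes 2 CO2 per extent unit.  The share attributable to
    in-cell recycling is capped at the CO2 the other reactions produced;
    any excess must have entered from outside and raises the flag.
    """
    fixed = 2.0 * extents.xi_acet
    produced = extents.xi_ferm + extents.xi_ce
    recycled = min(fixed, produced)
    external = fixed - recycled
    return recycled, external, external > 1e-12
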