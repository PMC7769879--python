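"""Carbon and electron balances, charge integration, and performance metrics.

The balance ledger follows the accounting used for two-chamber cathodic
electrofermentation: electrons enter as the degree-of-reduction content of
the fed substrates plus the charge delivered to the cathode, and leave as
the electron content of residual substrates, soluble products (both
chambers, plus withdrawn samples) and headspace H2:

    EB(%) = 100 * sum(Q_out) / (sum(Q_in) + integral(i dt) / F)

The electrofermentation coefficient relates delivered charge to the
electron content of the soluble fermentation products *formed* (compounds
that were themselves fed as substrate are excluded; gases are excluded):

    eta_EF = (integral(i dt) / F) / sum(Q_out, soluble products formed)

Specific energy consumption is the electrical energy per kg of acid
produced: E_C = I_avg * V_cell * t / sum(m_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .compounds import REGISTRY, CompoundRegistry
from .datamodel import CellExperiment, CurrentTrace, GasReading, withdrawn_moles

FARADAY = constants.value("Faraday constant")  # 96485.33... C/mol
R_GAS = constants.R

#: gases never count toward the soluble-product denominator of eta_EF
GASES = frozenset({"H2", "CO2", "CH4", "O2"})


@dataclass
class LedgerEntry:
    """Amount of one compound expressed as mmol, mmol C and mmol e-."""

    mmol: float | None
    mmol_c: float
    mmol_e: float

    @classmethod
    def from_mmol(cls, compound: str, amount: float,
                  registry: CompoundRegistry | None = None) -> "LedgerEntry":
        comp = (registry or REGISTRY).get(compound)
        return cls(
            mmol=amount,
            mmol_c=amount * comp.carbon_equiv,
            mmol_e=amount * comp.electron_equiv,
        )


@dataclass
class BalanceLedger:
    """Inlet/outlet carbon and electron inventory for one cell (or cycle).

    ``inlet`` holds substrates fed (initial charge plus re-additions);
    ``outlet`` holds residual substrates and soluble products, summed over
    cathode chamber, anolyte and withdrawn samples; ``gas_out`` holds
    headspace gases.  ``charge_in`` is the delivered cathodic charge in
    mmol e-.  Entries may be built from mmol via the registry or entered
    directly as C/e- pairs (e.g. when re-deriving a published ledger).
    """

    cell_id: str
    inlet: dict[str, LedgerEntry] = field(default_factory=dict)
    charge_in: float = 0.0
    outlet: dict[str, LedgerEntry] = field(default_factory=dict)
    gas_out: dict[str, LedgerEntry] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def fed_compounds(self) -> set[str]:
        return {k for k, v in self.inlet.items() if v.mmol_e > 0 or v.mmol_c > 0}


def integrate_charge(trace: CurrentTrace,
                     window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of |current| over ``window``, in mmol e-.

    Current is taken in magnitude: cathodic (reduction) current is
    conventionally negative but delivers electrons all the same.
    """
    t = trace.times
    i = np.abs(trace.currents)
    t0, tf = window if window is not None else trace.span()
    lo, hi = trace.span()
    if not (lo <= t0 < tf <= hi):
        raise ValueError(
            f"window [{t0}, {tf}] h empty or outside trace span [{lo}, {hi}] h"
        )
    grid = np.unique(np.concatenate([[t0, tf], t[(t > t0) & (t < tf)]]))
    vals = np.interp(grid, t, i)
    coulombs = float(np.trapezoid(vals, grid)) * 3600.0 * 1e-3  # mA*h -> C
    return coulombs / FARADAY * 1000.0  # mmol e-


def average_current(trace: CurrentTrace,
                    window: tuple[float, float] | None = None,
                    exclude_potential: float | None = None) -> float:
    """Time-averaged |current| (mA), optionally excluding the spans run at
    a given applied potential (e.g. a -1.2 V start-up)."""
    t0, tf = window if window is not None else trace.span()
    exclude: list[tuple[float, float]] = []
    if exclude_potential is not None:
        exclude = [
            (a, b) for a, b, p in trace.applied_potential_segments
            if p == exclude_potential
        ]
    t = trace.times
    i = np.abs(trace.currents)
    grid_pts = [t0, tf] + [x for seg in exclude for x in seg]
    grid = np.unique(np.concatenate([grid_pts, t[(t > t0) & (t < tf)]]))
    grid = grid[(grid >= t0) & (grid <= tf)]
    vals = np.interp(grid, t, i)
    total, charge = 0.0, 0.0
    for a, b, va, vb in zip(grid, grid[1:], vals, vals[1:]):
        mid = (a + b) / 2
        if any(x0 <= mid <= x1 for x0, x1 in exclude):
            continue
        charge += (va + vb) / 2 * (b - a)
        total += b - a
    if total <= 0:
        raise ValueError("averaging window is empty after exclusions")
    return charge / total


def carbon_balance(ledger: BalanceLedger) -> float:
    """Percent of fed carbon recovered in outlet compounds and gases."""
    inlet_c = sum(e.mmol_c for e in ledger.inlet.values())
    if inlet_c <= 0:
        raise ValueError("carbon balance undefined: no inlet carbon")
    outlet_c = sum(e.mmol_c for e in ledger.outlet.values()) + sum(
        e.mmol_c for e in ledger.gas_out.values()
    )
    balance = 100.0 * outlet_c / inlet_c
    if balance > 100.0:
        ledger.flags.append(
            f"carbon balance {balance:.1f}% exceeds 100%: inputs inconsistent"
        )
    return balance


def electron_balance(ledger: BalanceLedger) -> float:
    """Percent of (fed + delivered) electrons recovered in outlet species."""
    inlet_e = sum(e.mmol_e for e in ledger.inlet.values()) + ledger.charge_in
    if inlet_e <= 0:
        raise ValueError("electron balance undefined: no inlet electrons")
    outlet_e = sum(e.mmol_e for e in ledger.outlet.values()) + sum(
        e.mmol_e for e in ledger.gas_out.values()
    )
    balance = 100.0 * outlet_e / inlet_e
    if balance > 100.0:
        ledger.flags.append(
            f"electron balance {balance:.1f}% exceeds 100%: inputs inconsistent"
        )
    return balance


def ef_coefficient(ledger: BalanceLedger,
                   exclude: set[str] | None = None) -> float:
    """Delivered charge over the electron content of soluble products formed.

    Compounds fed as substrate in this cell are excluded from the
    denominator by default (they were not *formed*), as are gases.  A
    cell with no delivered charge (non-electrochemical control) returns 0.
    """
    if ledger.charge_in == 0.0:
        return 0.0
    excluded = (exclude if exclude is not None else ledger.fed_compounds)
    product_e = sum(
        e.mmol_e
        for name, e in ledger.outlet.items()
        if name not in excluded and name not in GASES
    )
    if product_e <= 0:
        raise ValueError(
            "eta_EF undefined: no electron content in soluble products formed"
        )
    return ledger.charge_in / product_e


def energy_consumption(i_avg_ma: float, v_cell: float, duration_h: float,
                       masses_kg: dict[str, float]) -> float:
    """Specific energy consumption, kWh per kg of product acids."""
    total_kg = sum(masses_kg.values())
    if total_kg <= 0:
        raise ValueError("energy consumption undefined: zero product mass")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    kwh = abs(i_avg_ma) / 1000.0 * v_cell * duration_h / 1000.0
    return kwh / total_kg


def gas_amount(fraction: float, bag_volume_l: float,
               temperature_k: float = 298.15,
               pressure_pa: float = 101325.0) -> float:
    """Ideal-gas mmol from a headspace-bag molar fraction."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if min(bag_volume_l, temperature_k, pressure_pa) <= 0:
        raise ValueError("volume, temperature and pressure must be positive")
    return fraction * pressure_pa * bag_volume_l / 1000.0 / (
        R_GAS * temperature_k
    ) * 1000.0


def _gas_mmol(g: GasReading) -> float:
    if g.amount_mmol is not None:
        return g.amount_mmol
    return gas_amount(g.fraction, g.bag_volume_l, g.temperature_k, g.pressure_pa)


def ledger_from_experiment(
    exp: CellExperiment,
    cycle_index: int | None = None,
    registry: CompoundRegistry | None = None,
) -> BalanceLedger:
    """Build a :class:`BalanceLedger` from an experiment record.

    By default the ledger aggregates the whole run (all cycles); pass
    ``cycle_index`` for a per-cycle ledger.  Inlet = amounts present at the
    start of the window plus additions during it; outlet = residual amounts
    at the end plus anolyte content plus sample withdrawals plus gases.
    O2 readings carry no electron equivalents and are skipped with a flag.
    """
    reg = registry or REGISTRY
    ledger = BalanceLedger(cell_id=exp.cell_id)
    if cycle_index is None:
        cycles = sorted(exp.cycles, key=lambda c: c.t_start)
    else:
        cycles = [exp.cycle(cycle_index)]
    t0, tf = cycles[0].t_start, cycles[-1].t_end
    v = exp.working_volume

    def add(store: dict[str, LedgerEntry], comp: str, mmol: float) -> None:
        if mmol <= 0:
            return
        entry = LedgerEntry.from_mmol(comp, mmol, reg)
        if comp in store:
            store[comp].mmol += mmol
            store[comp].mmol_c += entry.mmol_c
            store[comp].mmol_e += entry.mmol_e
        else:
            store[comp] = entry

    cathode = [s for s in exp.series if s.chamber == "cathode"]
    for s in cathode:
        initial = s.at(t0) * v
        added = sum(
            m for c in cycles for _, comp, m in c.additions if comp == s.compound
        )
        if initial + added > 0:
            add(ledger.inlet, s.compound, initial + added)
        residual = s.at(tf) * v
        pulled = sum(withdrawn_moles(s, c) for c in cycles)
        add(ledger.outlet, s.compound, residual + pulled)

    indices = {c.index for c in cycles}
    last = max(indices)
    for idx, comp, conc in exp.anolyte_end:
        if idx == last:
            add(ledger.outlet, comp, conc * v)

    for g in exp.gas:
        if g.cycle_index not in indices:
            continue
        if g.compound == "O2":
            ledger.flags.append(
                "O2 reading skipped: oxygen carries no electron equivalents "
                "in the degree-of-reduction accounting"
            )
            continue
        add(ledger.gas_out, g.compound, _gas_mmol(g))

    if exp.current is not None:
        lo, hi = exp.current.span()
        ledger.charge_in = integrate_charge(
            exp.current, (max(t0, lo), min(tf, hi))
        )
    return ledger
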