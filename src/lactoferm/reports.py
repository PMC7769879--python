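"""Delimited report tables: per-batch yields/rates, balance ledgers,
pathway extents and CV peak lists.

Rounding follows common reporting practice for these quantities:
balances to 1 decimal (percent), the electrofermentation coefficient to
2 decimals, rates to 2 decimals.  Missing measurements render as "n.d."
(not detected) and inapplicable cells as "n.a.".
"""

from __future__ import annotations

import pandas as pd

from .balances import (
    BalanceLedger,
    average_current,
    carbon_balance,
    ef_coefficient,
    electron_balance,
)
from .compounds import mm_to_mass_rate
from .datamodel import CellExperiment
from .pathways import PathwayExtents, co2_recycled
from .rates import cycle_yield, interval_rates, max_rate
from .voltammetry import PeakSet

PRODUCTS = ("propionate", "acetate", "butyrate")


def rates_report(exp: CellExperiment,
                 substrate: str = "lactate") -> pd.DataFrame:
    """One row per batch cycle: duration, average current, molar yields
    and highest production rates (mM/d and g/L/d) per product."""
    rows = []
    for cyc in sorted(exp.cycles, key=lambda c: c.t_start):
        row: dict = {
            "cell": exp.cell_id,
            "batch": cyc.index,
            "duration_h": round(cyc.duration_h, 1),
        }
        if exp.current is not None:
            lo, hi = exp.current.span()
            window = (max(cyc.t_start, lo), min(cyc.t_end, hi))
            row["avg_current_mA"] = round(
                average_current(exp.current, window, exclude_potential=-1.2),
                2,
            )
        else:
            row["avg_current_mA"] = "n.a."
        for product in PRODUCTS:
            series = exp.get_series(product, "cathode")
            try:
                y = cycle_yield(exp, product, cyc, substrate=substrate)
                row[f"yield_{product}"] = round(y.yield_mol_per_mol, 2)
            except ValueError:
                row[f"yield_{product}"] = "n.d."
            if series is not None and len(series.points) >= 2:
                peak = max_rate(interval_rates(series), window=cyc)
                row[f"max_rate_{product}_mM_d"] = round(peak, 2)
                row[f"max_rate_{product}_g_L_d"] = round(
                    mm_to_mass_rate(peak, product), 2
                )
            else:
                row[f"max_rate_{product}_mM_d"] = "n.d."
                row[f"max_rate_{product}_g_L_d"] = "n.d."
        rows.append(row)
    return pd.DataFrame(rows)


def balance_report(ledgers: list[BalanceLedger]) -> pd.DataFrame:
    """Ledger table: per-compound inlet/outlet C and e- inventories,
    delivered charge, balances and the electrofermentation coefficient."""
    compounds = ["lactate", "acetate", "propionate", "butyrate"]
    rows = []
    for led in ledgers:
        row: dict = {"cell": led.cell_id}
        for comp in compounds:
            entry = led.inlet.get(comp)
            row[f"in_{comp}_C"] = round(entry.mmol_c, 1) if entry else 0.0
            row[f"in_{comp}_e"] = round(entry.mmol_e, 1) if entry else 0.0
        row["in_current_e"] = round(led.charge_in, 1)
        for comp in compounds:
            entry = led.outlet.get(comp)
            row[f"out_{comp}_C"] = round(entry.mmol_c, 1) if entry else 0.0
            row[f"out_{comp}_e"] = round(entry.mmol_e, 1) if entry else 0.0
        for gas in ("H2", "CO2"):
            entry = led.gas_out.get(gas)
            row[f"out_{gas}_{'e' if gas == 'H2' else 'C'}"] = (
                round(entry.mmol_e if gas == "H2" else entry.mmol_c, 1)
                if entry
                else "n.d."
            )
        row["carbon_balance_pct"] = round(carbon_balance(led), 1)
        row["electron_balance_pct"] = round(electron_balance(led), 1)
        if led.charge_in > 0:
            row["eta_EF"] = round(ef_coefficient(led), 2)
        else:
            row["eta_EF"] = "n.a."
        row["flags"] = "; ".join(led.flags) if led.flags else ""
        rows.append(row)
    return pd.DataFrame(rows)


def extents_report(extents: dict[int, PathwayExtents]) -> pd.DataFrame:
    """Per-window reaction extents, CO2 recycling split, and residuals."""
    rows = []
    for window, ext in sorted(extents.items()):
        recycled, external, flagged = co2_recycled(ext)
        rows.append(
            {
                "window": window,
                "xi_fermentation_mmol": round(ext.xi_ferm, 3),
                "xi_acetogenesis_mmol": round(ext.xi_acet, 3),
                "xi_chain_elongation_mmol": round(ext.xi_ce, 3),
                "xi_h2_evolution_mmol": round(ext.xi_her, 3),
                "co2_net_mmol": round(ext.co2_net, 3),
                "co2_recycled_mmol": round(recycled, 3),
                "co2_external_mmol": round(external, 3),
                "h2_demand_mmol": round(ext.h2_demand, 3),
                "charge_demand_mmol_e": round(ext.charge_demand, 3),
                "residual_lactate_mmol": round(
                    ext.residual.get("lactate", 0.0), 3
                ),
                "residual_acetate_mmol": round(
                    ext.residual.get("acetate", 0.0), 3
                ),
                "flags": "; ".join(ext.flags + (
                    ["external CO2 required"] if flagged else []
                )),
            }
        )
    return pd.DataFrame(rows)


def peaks_report(peak_sets: list[PeakSet]) -> pd.DataFrame:
    """Flat list of detected peaks and paired redox couples."""
    rows = []
    for ps in peak_sets:
        for p in ps.peaks:
            rows.append(
                {
                    "cell": ps.cell_id,
                    "stage": ps.stage,
                    "cycle": ps.cycle_index,
                    "kind": "peak",
                    "direction": p.direction,
                    "potential_V": round(p.potential, 3),
                    "magnitude_mA": round(p.magnitude, 4),
                    "prominence_mA": round(p.prominence, 4),
                    "midpoint_V": "",
                    "separation_V": "",
                }
            )
        for c in ps.couples:
            rows.append(
                {
                    "cell": ps.cell_id,
                    "stage": ps.stage,
                    "cycle": ps.cycle_index,
                    "kind": "couple",
                    "direction": "",
                    "potential_V": "",
                    "magnitude_mA": "",
                    "prominence_mA": "",
                    "midpoint_V": round(c.midpoint, 3),
                    "separation_V": round(c.separation, 3),
                }
            )
    return pd.DataFrame(rows)
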