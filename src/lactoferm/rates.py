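"""Interval production rates and per-cycle molar yields.

Rates are taken literally between consecutive samples — no smoothing —
so the interval rates telescope exactly back to the net concentration
change.  Yields are whole-cycle molar ratios on the substrate consumed,
with product that left the sampled chamber (withdrawn with samples, or
migrated to the anolyte) counted in the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datamodel import BatchCycle, CellExperiment, ConcentrationSeries, withdrawn_moles

HOURS_PER_DAY = 24.0


@dataclass
class RateSeries:
    """Per-interval rates (mM/d) at interval midpoints."""

    compound: str
    t_mid: list[float] = field(default_factory=list)     # h
    rates: list[float] = field(default_factory=list)     # mM/d
    t_edges: list[float] = field(default_factory=list)   # sample times, h


@dataclass
class CycleYield:
    cycle_index: int
    product: str
    yield_mol_per_mol: float
    product_formed_mmol: float
    substrate_consumed_mmol: float


def interval_rates(series: ConcentrationSeries) -> RateSeries:
    """Rate between each consecutive sample pair, in mM per day.

    Negative values indicate consumption and are preserved.
    """
    t = series.times
    c = series.concentrations
    if len(t) < 2:
        raise ValueError("need at least two samples to compute rates")
    rs = RateSeries(compound=series.compound, t_edges=list(map(float, t)))
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        if dt <= 0:
            raise ValueError(f"duplicate or unordered timestamps at {t[i]} h")
        rs.t_mid.append(float((t[i] + t[i + 1]) / 2))
        rs.rates.append(float((c[i + 1] - c[i]) / dt * HOURS_PER_DAY))
    return rs


def max_rate(rates: RateSeries, window: BatchCycle | None = None) -> float:
    """Highest positive interval rate (mM/d); 0 when nothing was produced.

    With ``window`` given, only intervals lying fully inside the cycle
    count (Table-style "highest production rate" is reported per batch).
    """
    if not rates.rates:
        raise ValueError("empty rate series")
    candidates = []
    for i, r in enumerate(rates.rates):
        if window is not None:
            lo, hi = rates.t_edges[i], rates.t_edges[i + 1]
            if lo < window.t_start or hi > window.t_end:
                continue
        candidates.append(r)
    positive = [r for r in candidates if r > 0]
    return max(positive) if positive else 0.0


def net_change(rates: RateSeries) -> float:
    """Telescoped net concentration change (mM) implied by the rates."""
    total = 0.0
    for i, r in enumerate(rates.rates):
        total += r * (rates.t_edges[i + 1] - rates.t_edges[i]) / HOURS_PER_DAY
    return total


def product_formed_in_cycle(
    exp: CellExperiment, product: str, cycle: BatchCycle
) -> float:
    """mmol of ``product`` formed during ``cycle``, counting product that was
    withdrawn with samples and product found in the anolyte at cycle end."""
    v = exp.working_volume
    s = exp.get_series(product, "cathode")
    formed = 0.0
    if s is not None:
        formed += (s.at(cycle.t_end) - s.at(cycle.t_start)) * v
        formed += withdrawn_moles(s, cycle)
    for idx, comp, conc in exp.anolyte_end:
        if idx == cycle.index and comp == product:
            prev = sum(
                c2 for i2, c2m, c2 in exp.anolyte_end
                if i2 == cycle.index - 1 and c2m == product
            )
            formed += (conc - prev) * v
    # product added as substrate during the cycle is not "formed"
    formed -= sum(m for _, comp, m in cycle.additions if comp == product)
    return formed


def substrate_consumed_in_cycle(
    exp: CellExperiment, substrate: str, cycle: BatchCycle
) -> float:
    """mmol of ``substrate`` consumed: (present at start + added) minus
    (residual at end + withdrawn unconsumed)."""
    v = exp.working_volume
    s = exp.get_series(substrate, "cathode")
    if s is None:
        raise ValueError(f"no cathode series for substrate {substrate!r}")
    start = s.at(cycle.t_start) * v
    added = sum(m for _, comp, m in cycle.additions if comp == substrate)
    residual = s.at(cycle.t_end) * v
    withdrawn = withdrawn_moles(s, cycle)
    return start + added - residual - withdrawn


def cycle_yield(
    exp: CellExperiment,
    product: str,
    cycle: BatchCycle,
    substrate: str = "lactate",
) -> CycleYield:
    """Molar yield of ``product`` on ``substrate`` over one batch cycle."""
    consumed = substrate_consumed_in_cycle(exp, substrate, cycle)
    if consumed <= 0:
        raise ValueError(
            f"cycle {cycle.index}: no net {substrate} consumption "
            f"({consumed:.3g} mmol); yield undefined"
        )
    formed = max(product_formed_in_cycle(exp, product, cycle), 0.0)
    return CycleYield(
        cycle_index=cycle.index,
        product=product,
        yield_mol_per_mol=formed / consumed,
        product_formed_mmol=formed,
        substrate_consumed_mmol=consumed,
    )
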