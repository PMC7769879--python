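"""Seeded generators of synthetic cell experiments and voltammograms.

The batch simulator emulates the study conditions of a two-chamber
cathodic electrofermentation cell run on lactate: 150 mL working volume,
batch cycles of 5-7 days with the substrate restored to 20 mM at each
cycle start, daily 1 mL catholyte sampling, zero-order butyrate migration
across the membrane (0.35 mM/d, the abiotic-control rate), and additive
Gaussian measurement noise on the recorded concentrations.  Product
formation follows the built-in reaction network applied to logistic
cumulative-extent curves — a three-parameter sigmoid per reaction, chosen
for shape rather than any asserted rate law.  Ground-truth extents are
returned alongside the experiment so decomposition, balances, rates and
yields can all be checked against known answers.

The delivered-current trace is constructed from the H2-evolution extent
so that its trapezoidal charge integral matches the electron demand of
the simulated acetogenesis (plus any abiotic baseline, which becomes
excess headspace H2).  On noiseless runs with full gas capture both the
carbon and the electron balance therefore close at 100% exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .balances import FARADAY, integrate_charge
from .datamodel import (
    BatchCycle,
    CellExperiment,
    ConcentrationSeries,
    CurrentTrace,
    GasReading,
)
from .pathways import ELECTRONS_PER_H2, PathwayExtents, builtin_network
from .voltammetry import GRID_STEP_V, Branch, CVCycle, Voltammogram

_SOLUBLE = ("lactate", "propionate", "acetate", "butyrate")


@dataclass(frozen=True)
class LogisticExtent:
    """Cumulative extent curve: logistic in time, pinned to 0 at cycle
    start and to ``total_mmol`` at cycle end."""

    total_mmol: float
    midpoint_h: float = 72.0      # relative to cycle start
    steepness_per_h: float = 0.05

    def __post_init__(self) -> None:
        if self.total_mmol < 0:
            raise ValueError("extent total must be non-negative")
        if self.steepness_per_h <= 0:
            raise ValueError("steepness must be positive")

    def at(self, tau: float | np.ndarray, duration_h: float) -> np.ndarray:
        f = lambda x: 1.0 / (1.0 + np.exp(-self.steepness_per_h * (x - self.midpoint_h)))
        f0, f1 = f(0.0), f(duration_h)
        return self.total_mmol * (f(np.asarray(tau, float)) - f0) / (f1 - f0)


@dataclass(frozen=True)
class SimCycle:
    duration_h: float = 158.4
    lactate_restore_mm: float = 20.0
    extents: dict[str, LogisticExtent] = field(default_factory=dict)
    # keys: fermentation, acetogenesis, chain_elongation


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition defaults for the synthetic cell.

    ``noise_sd_mm`` is the HPLC-like measurement noise (mM, 1 sigma,
    truncated so concentrations stay non-negative).  ``current_baseline_ma``
    is abiotic background current; its charge surfaces as headspace H2.
    """

    seed: int = 0
    working_volume_l: float = 0.150
    cycles: tuple[SimCycle, ...] = (
        # 20 mM lactate in 150 mL is 3.0 mmol; fermenting 2.4 mmol of it
        # (0.8 extent units) with acetogenesis recycling most of the CO2
        # reproduces the observed ~10 mM propionate / ~7 mM acetate scale
        SimCycle(extents={
            "fermentation": LogisticExtent(0.8),
            "acetogenesis": LogisticExtent(0.3),
        }),
    )
    butyrate_feed_mm: float = 0.0          # fed on the first cycle only
    butyrate_migration_mm_d: float = 0.35  # zero-order membrane loss
    sample_interval_h: float = 24.0
    sample_volume_ml: float = 1.0
    noise_sd_mm: float = 0.5
    # quantification floor of the concentration assay: noisy readings below
    # it are recorded as zero, as in routine HPLC-RID carboxylate monitoring
    detection_limit_mm: float = 1.0
    current_baseline_ma: float = 0.0
    gas_capture_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.working_volume_l <= 0:
            raise ValueError("working volume must be positive")
        if self.noise_sd_mm < 0 or self.butyrate_migration_mm_d < 0:
            raise ValueError("noise and migration must be non-negative")
        if not (0.0 <= self.gas_capture_fraction <= 1.0):
            raise ValueError("gas capture fraction must lie in [0, 1]")


class InfeasibleScheduleError(ValueError):
    """The extent schedule would drive a species below zero."""


def simulate_batch(
    params: SimulationParams,
) -> tuple[CellExperiment, list[PathwayExtents]]:
    """Run the synthetic cell; returns the experiment and per-cycle truth."""
    rng = np.random.default_rng(params.seed)
    v = params.working_volume_l
    stoich = {r.name: r.stoichiometry for r in builtin_network()}

    # moles in the cathode chamber; anode only accumulates migrated butyrate
    n = {sp: 0.0 for sp in _SOLUBLE}
    n["lactate"] = params.cycles[0].lactate_restore_mm * v
    n["butyrate"] = params.butyrate_feed_mm * v
    anode_butyrate = 0.0

    samples: dict[str, list[tuple[float, float]]] = {sp: [] for sp in _SOLUBLE}
    anode_samples: list[tuple[float, float]] = []
    cycles_out: list[BatchCycle] = []
    gas_out: list[GasReading] = []
    anolyte_end: list[tuple[int, str, float]] = []
    current_pts: list[tuple[float, float]] = []
    truth: list[PathwayExtents] = []

    t_cycle_start = 0.0
    mig_rate = params.butyrate_migration_mm_d * v / 24.0  # mmol/h
    dt = 0.05

    for ci, cyc in enumerate(params.cycles, start=1):
        d = cyc.duration_h
        additions: list[tuple[float, str, float]] = []
        if ci > 1:
            top_up = max(cyc.lactate_restore_mm * v - n["lactate"], 0.0)
            if top_up > 0:
                additions.append((t_cycle_start, "lactate", top_up))

        sample_taus = np.arange(0.0, d - 1e-9, params.sample_interval_h)
        sample_taus = np.append(sample_taus, d)
        withdrawals = []

        def extent_at(tau: float) -> dict[str, float]:
            return {
                name: float(curve.at(tau, d))
                for name, curve in cyc.extents.items()
            }

        prev_xi = extent_at(0.0)
        withdrawn = {sp: 0.0 for sp in _SOLUBLE}
        next_sample = 0
        tau = 0.0
        while tau < d - 1e-9:
            # record (pre-addition, pre-withdrawal) sample if due; at a
            # cycle boundary the previous end-of-cycle sample already
            # recorded this instant, so only the withdrawal happens
            while next_sample < len(sample_taus) and sample_taus[next_sample] <= tau + 1e-9:
                if not (ci > 1 and tau == 0.0):
                    _record_sample(
                        samples, n, v, t_cycle_start + tau, rng, params
                    )
                if params.sample_volume_ml > 0:
                    for sp in _SOLUBLE:
                        pulled = n[sp] / v * params.sample_volume_ml / 1000.0
                        n[sp] -= pulled
                        withdrawn[sp] += pulled
                    withdrawals.append(
                        (t_cycle_start + tau, params.sample_volume_ml, "cathode")
                    )
                next_sample += 1
            if tau == 0.0 and additions:
                n["lactate"] += additions[0][2]

            step = min(dt, d - tau)
            xi = extent_at(tau + step)
            for name, x in xi.items():
                dxi = x - prev_xi[name]
                for sp, coeff in stoich[name].items():
                    if sp in n:
                        n[sp] += coeff * dxi
            prev_xi = xi
            moved = min(mig_rate * step, n["butyrate"])
            n["butyrate"] -= moved
            anode_butyrate += moved
            if n["lactate"] < -1e-9:
                raise InfeasibleScheduleError(
                    f"extent schedule exhausts lactate at "
                    f"{t_cycle_start + tau + step:.1f} h (cycle {ci})"
                )
            tau += step

        # end-of-cycle sample (no withdrawal at the final instant)
        _record_sample(samples, n, v, t_cycle_start + d, rng, params)
        anode_samples.append((t_cycle_start + d, anode_butyrate / v))
        anolyte_end.append((ci, "butyrate", anode_butyrate / v))

        xi_end = extent_at(d)
        xi_acet = xi_end.get("acetogenesis", 0.0)

        # current trace: demand-driven HER plus abiotic baseline
        her_curve = cyc.extents.get("acetogenesis")
        tgrid = np.linspace(0.0, d, max(int(d / 0.1), 4) + 1)
        if her_curve is not None and xi_acet > 0:
            q = (
                ELECTRONS_PER_H2 * 4.0 * her_curve.at(tgrid, d)
            )  # mmol e- delivered for acetogenic H2
            dq = np.gradient(q, tgrid)  # mmol e-/h
            i_ma = dq * FARADAY / 3600.0  # mmol e-/h -> mA
            # rescale so the trapezoidal charge of the emitted trace equals
            # the acetogenic electron demand exactly
            q_trapz = float(np.trapezoid(i_ma, tgrid)) * 3.6 / FARADAY * 1000.0
            i_ma *= (ELECTRONS_PER_H2 * 4.0 * xi_acet) / q_trapz
        else:
            i_ma = np.zeros_like(tgrid)
        i_ma = -(i_ma + params.current_baseline_ma)  # cathodic sign
        pts = list(zip(t_cycle_start + tgrid, i_ma))
        if current_pts and pts and pts[0][0] <= current_pts[-1][0]:
            pts = pts[1:]  # drop duplicated boundary instant
        current_pts.extend(pts)

        cycles_out.append(
            BatchCycle(
                index=ci,
                t_start=t_cycle_start,
                t_end=t_cycle_start + d,
                additions=additions,
                withdrawals=withdrawals,
            )
        )
        truth.append(
            PathwayExtents(
                xi_ferm=xi_end.get("fermentation", 0.0),
                xi_acet=xi_acet,
                xi_ce=xi_end.get("chain_elongation", 0.0),
            )
        )
        t_cycle_start += d

    has_current = any(abs(i) > 0 for _, i in current_pts)
    current = None
    if has_current:
        span = current_pts[-1][0]
        segments = (
            [(0.0, 24.0, -1.2), (24.0, span, -1.0)]
            if span > 24.0 else [(0.0, span, -1.2)]
        )
        current = CurrentTrace(
            cell_id="sim",
            points=[(float(t), float(i)) for t, i in current_pts],
            applied_potential_segments=segments,
        )

    # headspace gases per cycle: H2 from charge not consumed by
    # acetogenesis, CO2 from the net pathway balance
    for ci, (cyc, ext) in enumerate(zip(params.cycles, truth), start=1):
        if current is not None:
            window = (cycles_out[ci - 1].t_start, cycles_out[ci - 1].t_end)
            charge = integrate_charge(current, window)
        else:
            charge = 0.0
        ext.xi_her = charge / ELECTRONS_PER_H2
        h2_free = max(ext.xi_her - ext.h2_demand, 0.0)
        if h2_free > 0:
            gas_out.append(
                GasReading(
                    cycle_index=ci, compound="H2",
                    amount_mmol=h2_free * params.gas_capture_fraction,
                )
            )
        if ext.co2_net > 0:
            gas_out.append(
                GasReading(
                    cycle_index=ci, compound="CO2",
                    amount_mmol=ext.co2_net * params.gas_capture_fraction,
                )
            )

    series = [
        ConcentrationSeries(
            cell_id="sim", chamber="cathode", compound=sp, points=pts
        )
        for sp, pts in samples.items()
    ]
    series.append(
        ConcentrationSeries(
            cell_id="sim", chamber="anode", compound="butyrate",
            points=anode_samples,
        )
    )
    exp = CellExperiment(
        cell_id="sim",
        working_volume=v,
        cycles=cycles_out,
        series=series,
        current=current,
        gas=gas_out,
        anolyte_end=anolyte_end,
    )
    return exp, truth


def _record_sample(samples, n, v, t, rng, params) -> None:
    for sp in _SOLUBLE:
        conc = n[sp] / v
        if params.noise_sd_mm > 0:
            conc += rng.normal(0.0, params.noise_sd_mm)
            # sub-detection readings are reported as zero, which keeps a
            # truly absent compound at zero instead of half-rectified noise
            if conc < params.detection_limit_mm:
                conc = 0.0
        samples[sp].append((float(t), float(conc)))


def null_params(**overrides) -> SimulationParams:
    """A single quiet cycle: no reactions, no migration, no noise."""
    base = SimulationParams(
        cycles=(SimCycle(extents={}),),
        butyrate_migration_mm_d=0.0,
        noise_sd_mm=0.0,
        sample_volume_ml=0.0,
    )
    return replace(base, **overrides)


# --------------------------------------------------------------------------
# synthetic voltammograms


@dataclass(frozen=True)
class CVPeakSpec:
    center_v: float
    height_ma: float
    width_mv: float          # Gaussian sigma
    direction: str           # "reduction" | "oxidation"


def simulate_cv(
    peaks: list[CVPeakSpec],
    baseline_ma: float = 0.05,
    her_onset_v: float = -0.9,
    her_tau_v: float = 0.06,
    her_scale_ma: float = 0.05,
    noise_sd_ma: float = 0.0,
    seed: int = 0,
    n_cycles: int = 4,
    window: tuple[float, float] = (-1.2, 0.0),
    cell_id: str = "sim",
    stage: str = "end",
) -> Voltammogram:
    """Four-cycle synthetic voltammogram on a 1 mV grid.

    Each branch carries a capacitive offset (+/- ``baseline_ma``),
    Gaussian faradaic peaks on the branch matching their direction, an
    exponential hydrogen-evolution tail below ``her_onset_v``, and seeded
    Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window
    for p in peaks:
        if not (lo <= p.center_v <= hi):
            raise ValueError(f"peak centre {p.center_v} V outside window")
    grid = np.arange(lo, hi + GRID_STEP_V / 2, GRID_STEP_V)

    def her(e: np.ndarray) -> np.ndarray:
        tail = np.where(
            e < her_onset_v,
            np.exp((her_onset_v - e) / her_tau_v) - 1.0,
            0.0,
        )
        return -her_scale_ma * tail

    def branch(direction: str) -> Branch:
        sign = -1.0 if direction == "reduction" else 1.0
        current = sign * baseline_ma + her(grid)
        for p in peaks:
            if p.direction != direction:
                continue
            sigma = p.width_mv / 1000.0
            shape = np.exp(-0.5 * ((grid - p.center_v) / sigma) ** 2)
            current = current + (
                -p.height_ma if direction == "reduction" else p.height_ma
            ) * shape
        if noise_sd_ma > 0:
            current = current + rng.normal(0.0, noise_sd_ma, size=grid.shape)
        # cathodic sweep is recorded from 0 toward -1.2 V
        if direction == "reduction":
            return Branch(potential=grid[::-1].copy(), current=current[::-1].copy())
        return Branch(potential=grid.copy(), current=current.copy())

    cycles = [
        CVCycle(index=k, cathodic=branch("reduction"), anodic=branch("oxidation"))
        for k in range(1, n_cycles + 1)
    ]
    return Voltammogram(cell_id=cell_id, stage=stage, cycles=cycles)
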