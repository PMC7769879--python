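"""Domain model of a two-chamber electrofermentation cell experiment.

Units are normalised on construction: time in hours, concentration in mM,
current in mA, potential in V vs Ag/AgCl, volume in L.  One day is exactly
24 h for rate conversion.  Validation errors carry the offending field so
a malformed input file fails with a named message rather than downstream
nonsense.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .compounds import REGISTRY

Chamber = Literal["cathode", "anode"]

#: fraction of working volume that may be withdrawn before the experiment
#: is flagged (sampling protocols keep total withdrawal under 5%)
WITHDRAWAL_WARN_FRACTION = 0.05


class InterpolationError(ValueError):
    """Requested time outside the sampled span of a series."""


class _Model(BaseModel):
    model_config = ConfigDict(frozen=False, extra="forbid")


class ConcentrationSeries(_Model):
    """Concentration of one compound in one chamber over time."""

    cell_id: str
    chamber: Chamber
    compound: str
    points: list[tuple[float, float]]  # (time h, concentration mM)

    @model_validator(mode="after")
    def _check(self) -> "ConcentrationSeries":
        t = np.asarray([p[0] for p in self.points], dtype=float)
        c = np.asarray([p[1] for p in self.points], dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"series {self.cell_id}/{self.chamber}/{self.compound}: "
                "times must be strictly increasing"
            )
        if np.any(c < 0):
            raise ValueError(
                f"series {self.cell_id}/{self.chamber}/{self.compound}: "
                "negative concentration"
            )
        if self.compound not in REGISTRY:
            raise ValueError(f"unknown compound {self.compound!r}")
        return self

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)

    def at(self, time_h: float) -> float:
        """Linearly interpolated concentration (mM) at ``time_h``.

        Extrapolation is refused: between-sample behaviour is interpolated
        linearly but nothing is asserted outside the sampled span.
        """
        t = self.times
        if len(t) == 0:
            raise InterpolationError("empty series")
        if not (t[0] <= time_h <= t[-1]):
            raise InterpolationError(
                f"time {time_h} h outside sampled span [{t[0]}, {t[-1]}] h "
                f"for {self.compound} ({self.chamber})"
            )
        return float(np.interp(time_h, t, self.concentrations))


class CurrentTrace(_Model):
    """Chronoamperometric record with its applied-potential schedule."""

    cell_id: str
    points: list[tuple[float, float]]  # (time h, current mA)
    applied_potential_segments: list[tuple[float, float, float]] = []
    # (t_start h, t_end h, potential V vs Ag/AgCl)

    @model_validator(mode="after")
    def _check(self) -> "CurrentTrace":
        t = self.times
        if len(t) < 2:
            raise ValueError("current trace needs at least two points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("current trace times must be strictly increasing")
        segs = sorted(self.applied_potential_segments)
        for (a0, a1, _), (b0, b1, _) in zip(segs, segs[1:]):
            if b0 < a1:
                raise ValueError("applied-potential segments overlap")
        if segs:
            if segs[0][0] > t[0] or segs[-1][1] < t[-1]:
                raise ValueError(
                    "applied-potential segments do not cover the trace span"
                )
        return self

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def currents(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)

    def span(self) -> tuple[float, float]:
        t = self.times
        return float(t[0]), float(t[-1])


class BatchCycle(_Model):
    """One feeding cycle: boundaries, substrate additions, sampling events."""

    index: int
    t_start: float
    t_end: float
    additions: list[tuple[float, str, float]] = []  # (time h, compound, mmol)
    withdrawals: list[tuple[float, float, Chamber]] = []
    # (time h, volume mL, chamber)

    @model_validator(mode="after")
    def _check(self) -> "BatchCycle":
        if not self.t_start < self.t_end:
            raise ValueError(f"cycle {self.index}: t_start must precede t_end")
        for t, comp, mmol in self.additions:
            if not (self.t_start <= t <= self.t_end):
                raise ValueError(
                    f"cycle {self.index}: addition at {t} h outside cycle"
                )
            if comp not in REGISTRY:
                raise ValueError(f"unknown compound {comp!r} in addition")
            if mmol < 0:
                raise ValueError("addition amount must be non-negative")
        for t, vol, _ in self.withdrawals:
            if not (self.t_start <= t <= self.t_end):
                raise ValueError(
                    f"cycle {self.index}: withdrawal at {t} h outside cycle"
                )
            if vol <= 0:
                raise ValueError("withdrawal volume must be positive")
        return self

    @property
    def duration_h(self) -> float:
        return self.t_end - self.t_start


class GasReading(_Model):
    """End-of-cycle headspace gas amount, direct or via bag fraction."""

    cycle_index: int
    compound: Literal["H2", "CO2", "O2", "CH4"]
    amount_mmol: Optional[float] = None
    fraction: Optional[float] = None
    bag_volume_l: Optional[float] = None
    temperature_k: float = 298.15
    pressure_pa: float = 101325.0

    @model_validator(mode="after")
    def _check(self) -> "GasReading":
        if self.amount_mmol is None:
            if self.fraction is None or self.bag_volume_l is None:
                raise ValueError(
                    "gas reading needs amount_mmol, or fraction + bag volume"
                )
            if not (0.0 <= self.fraction <= 1.0):
                raise ValueError("gas fraction must lie in [0, 1]")
            if self.bag_volume_l <= 0:
                raise ValueError("bag volume must be positive")
        elif self.amount_mmol < 0:
            raise ValueError("gas amount must be non-negative")
        return self


class CellExperiment(_Model):
    """Complete record of one cell (or non-electrochemical control bottle).

    Controls carry no :class:`CurrentTrace`; ``is_control`` reflects that.
    Anolyte end-of-cycle carboxylate levels are kept separately because the
    anode chamber is only sampled at cycle boundaries.
    """

    cell_id: str
    working_volume: float  # L
    cycles: list[BatchCycle]
    series: list[ConcentrationSeries]
    current: Optional[CurrentTrace] = None
    gas: list[GasReading] = []
    anolyte_end: list[tuple[int, str, float]] = []
    # (cycle_index, compound, concentration mM)

    @model_validator(mode="after")
    def _check(self) -> "CellExperiment":
        if self.working_volume <= 0:
            raise ValueError("working volume must be positive")
        if not self.cycles:
            raise ValueError("experiment needs at least one cycle")
        spans = [(c.t_start, c.t_end) for c in self.cycles]
        for s in self.series:
            for t, _ in s.points:
                if not any(a <= t <= b for a, b in spans):
                    raise ValueError(
                        f"sample at {t} h ({s.compound}, {s.chamber}) "
                        "outside every cycle"
                    )
        cycle_ids = {c.index for c in self.cycles}
        for g in self.gas:
            if g.cycle_index not in cycle_ids:
                raise ValueError(f"gas reading for unknown cycle {g.cycle_index}")
        for idx, comp, conc in self.anolyte_end:
            if idx not in cycle_ids:
                raise ValueError(f"anolyte entry for unknown cycle {idx}")
            if comp not in REGISTRY:
                raise ValueError(f"unknown compound {comp!r} in anolyte record")
            if conc < 0:
                raise ValueError("anolyte concentration must be non-negative")
        return self

    @property
    def is_control(self) -> bool:
        return self.current is None

    def get_series(self, compound: str,
                   chamber: Chamber = "cathode") -> Optional[ConcentrationSeries]:
        for s in self.series:
            if s.compound == compound and s.chamber == chamber:
                return s
        return None

    def cycle(self, index: int) -> BatchCycle:
        for c in self.cycles:
            if c.index == index:
                return c
        raise KeyError(f"no cycle with index {index}")

    def withdrawn_volume_fraction(self) -> float:
        total_ml = sum(
            v for c in self.cycles for _, v, ch in c.withdrawals
            if ch == "cathode"
        )
        return total_ml / 1000.0 / self.working_volume


def moles_in_chamber(series: ConcentrationSeries, time_h: float,
                     volume_l: float) -> float:
    """mmol present in a chamber at ``time_h`` (linear interpolation)."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return series.at(time_h) * volume_l


def withdrawn_moles(series: ConcentrationSeries, cycle: BatchCycle,
                    convention: str = "at_withdrawal") -> float:
    """mmol of ``series.compound`` removed with samples during ``cycle``.

    ``convention`` selects the concentration assigned to each withdrawal:
    ``"at_withdrawal"`` (interpolated at the sampling instant, the default)
    or ``"cycle_average"`` (time-averaged concentration over the cycle).
    """
    pulls = [(t, v) for t, v, ch in cycle.withdrawals if ch == series.chamber]
    if not pulls:
        return 0.0
    if convention == "at_withdrawal":
        return sum(series.at(t) * v / 1000.0 for t, v in pulls)
    if convention == "cycle_average":
        t = series.times
        mask = (t >= cycle.t_start) & (t <= cycle.t_end)
        if not mask.any():
            raise InterpolationError("no samples inside cycle")
        c = series.concentrations[mask]
        tt = t[mask]
        avg = (
            float(np.trapezoid(c, tt) / (tt[-1] - tt[0]))
            if len(tt) > 1 else float(c[0])
        )
        return sum(avg * v / 1000.0 for _, v in pulls)
    raise ValueError(f"unknown withdrawal convention {convention!r}")
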