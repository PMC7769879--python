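"""Cyclic voltammogram processing: smoothing, first-derivative analysis,
peak detection, redox-couple pairing, and onset-potential shifts.

Conventions: potentials in V vs Ag/AgCl, currents in mA, cathodic
(reduction) current negative.  Each cycle holds a cathodic sweep (toward
negative potential) and an anodic return sweep; the two branches are
processed separately on a uniform 1 mV potential grid.  Smoothing is
Savitzky-Golay (centred local polynomial fit) with a 25 mV window and
order 2 by default, enough to resolve couples separated by ~50 mV
without splitting noise into spurious extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import find_peaks, savgol_filter

Direction = Literal["reduction", "oxidation"]

GRID_STEP_V = 0.001           # 1 mV resampling grid
DEFAULT_WINDOW = (-1.2, 0.0)  # V vs Ag/AgCl
DEFAULT_SMOOTH_MV = 25.0
DEFAULT_POLY_ORDER = 2
DEFAULT_CYCLE = 3             # report the third replicate cycle
DEFAULT_PAIRING_V = 0.10


@dataclass
class Branch:
    """One sweep of a cycle, ordered as recorded."""

    potential: np.ndarray  # V
    current: np.ndarray    # mA


@dataclass
class CVCycle:
    index: int
    cathodic: Branch  # sweep toward negative potentials
    anodic: Branch    # return sweep


@dataclass
class Voltammogram:
    cell_id: str
    stage: Literal["begin", "end"]
    cycles: list[CVCycle]
    scan_rate_mv_s: float = 1.0
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.scan_rate_mv_s <= 0:
            raise ValueError("scan rate must be positive")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be (V_min, V_max) with V_min < V_max")


@dataclass
class Peak:
    potential: float    # V
    direction: Direction
    magnitude: float    # mA, baseline-subtracted height
    prominence: float   # mA


@dataclass
class RedoxCouple:
    e_red: float
    e_ox: float

    @property
    def midpoint(self) -> float:
        return (self.e_red + self.e_ox) / 2.0

    @property
    def separation(self) -> float:
        return abs(self.e_ox - self.e_red)


@dataclass
class PeakSet:
    cell_id: str
    stage: str
    cycle_index: int
    peaks: list[Peak] = field(default_factory=list)
    couples: list[RedoxCouple] = field(default_factory=list)


def select_cycle(vg: Voltammogram, k: int = DEFAULT_CYCLE) -> CVCycle:
    """Cycle with 1-based index ``k`` (the third replicate by default)."""
    for cycle in vg.cycles:
        if cycle.index == k:
            return cycle
    raise IndexError(
        f"cycle {k} not recorded; available cycles: "
        f"{sorted(c.index for c in vg.cycles)}"
    )


def _resample(branch: Branch) -> tuple[np.ndarray, np.ndarray]:
    """Uniform 1 mV grid over the branch span, ascending potential."""
    e = np.asarray(branch.potential, dtype=float)
    i = np.asarray(branch.current, dtype=float)
    order = np.argsort(e, kind="stable")
    e, i = e[order], i[order]
    e_u, idx = np.unique(e, return_index=True)
    # average duplicated potentials
    if len(e_u) < len(e):
        sums = np.zeros(len(e_u))
        counts = np.zeros(len(e_u))
        pos = np.searchsorted(e_u, e)
        np.add.at(sums, pos, i)
        np.add.at(counts, pos, 1)
        i_u = sums / counts
    else:
        i_u = i[idx]
    grid = np.arange(e_u[0], e_u[-1] + GRID_STEP_V / 2, GRID_STEP_V)
    return grid, np.interp(grid, e_u, i_u)


def _smooth(current: np.ndarray, smooth_window_mv: float,
            poly_order: int) -> np.ndarray:
    win = int(round(smooth_window_mv / (GRID_STEP_V * 1000.0)))
    win = max(win | 1, poly_order + 2 + ((poly_order + 2) % 2 == 0))
    if win > len(current):
        raise ValueError(
            f"smoothing window ({win} points) exceeds branch length "
            f"({len(current)} points)"
        )
    return savgol_filter(current, window_length=win, polyorder=poly_order)


def first_derivative(
    branch: Branch,
    smooth_window_mv: float = DEFAULT_SMOOTH_MV,
    poly_order: int = DEFAULT_POLY_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """dI/dE (mA/V) of a smoothed branch on the uniform potential grid.

    Central differences in the interior, one-sided at the endpoints;
    invariant under any constant current offset.
    """
    grid, current = _resample(branch)
    smoothed = _smooth(current, smooth_window_mv, poly_order)
    return grid, np.gradient(smoothed, grid)


def detect_peaks(
    branch: Branch,
    direction: Direction,
    prominence_threshold: float = 0.01,
    smooth_window_mv: float = DEFAULT_SMOOTH_MV,
    poly_order: int = DEFAULT_POLY_ORDER,
    baseline: Literal["linear", "none"] = "linear",
) -> list[Peak]:
    """Faradaic peaks on one branch, sorted by potential.

    The smoothed branch has a per-branch linear baseline subtracted (the
    chord between its endpoints, standing in for the capacitive current),
    then local extrema in the peak direction with prominence at or above
    ``prominence_threshold`` (mA) are kept.  Returns an empty list for a
    flat branch.
    """
    grid, current = _resample(branch)
    smoothed = _smooth(current, smooth_window_mv, poly_order)
    if baseline == "linear":
        chord = np.interp(
            grid, [grid[0], grid[-1]], [smoothed[0], smoothed[-1]]
        )
        signal = smoothed - chord
    else:
        signal = smoothed
    # reduction peaks are minima of (negative) cathodic current
    oriented = -signal if direction == "reduction" else signal
    idx, props = find_peaks(oriented, prominence=prominence_threshold)
    peaks = [
        Peak(
            potential=float(grid[j]),
            direction=direction,
            magnitude=float(abs(signal[j])),
            prominence=float(p),
        )
        for j, p in zip(idx, props["prominences"])
    ]
    return sorted(peaks, key=lambda p: p.potential)


def detect_cycle_peaks(cycle: CVCycle, prominence_threshold: float = 0.01,
                       **kwargs) -> list[Peak]:
    """Reduction peaks from the cathodic branch and oxidation peaks from
    the anodic branch of one cycle, merged and sorted by potential."""
    red = detect_peaks(cycle.cathodic, "reduction", prominence_threshold,
                       **kwargs)
    ox = detect_peaks(cycle.anodic, "oxidation", prominence_threshold,
                      **kwargs)
    return sorted(red + ox, key=lambda p: p.potential)


def pair_couples(peaks: list[Peak],
                 max_separation: float = DEFAULT_PAIRING_V) -> list[RedoxCouple]:
    """Greedy nearest-potential pairing of reduction/oxidation peaks.

    All opposite-direction pairs within ``max_separation`` are ranked by
    potential distance and paired greedily; each peak joins at most one
    couple.
    """
    reductions = [p for p in peaks if p.direction == "reduction"]
    oxidations = [p for p in peaks if p.direction == "oxidation"]
    candidates = sorted(
        (
            (abs(r.potential - o.potential), ir, io)
            for ir, r in enumerate(reductions)
            for io, o in enumerate(oxidations)
            if abs(r.potential - o.potential) <= max_separation
        ),
    )
    used_r: set[int] = set()
    used_o: set[int] = set()
    couples = []
    for _, ir, io in candidates:
        if ir in used_r or io in used_o:
            continue
        used_r.add(ir)
        used_o.add(io)
        couples.append(
            RedoxCouple(
                e_red=reductions[ir].potential,
                e_ox=oxidations[io].potential,
            )
        )
    return sorted(couples, key=lambda c: c.midpoint)


def onset_potential(branch: Branch, threshold_ma: float) -> float:
    """Most positive potential at which |current| first exceeds the
    threshold, scanning the cathodic branch from positive to negative."""
    grid, current = _resample(branch)
    above = np.abs(current) >= threshold_ma
    if not above.any():
        raise ValueError(
            f"|current| never reaches {threshold_ma} mA "
            f"(max {np.abs(current).max():.3g} mA)"
        )
    # grid ascends; walk from the most positive end down
    hits = np.nonzero(above)[0]
    return float(grid[hits[-1]])


def onset_shift(begin_cycle: CVCycle, end_cycle: CVCycle,
                threshold_ma: float) -> float:
    """Shift of the cathodic onset potential between two scans (end -
    begin, V); positive means the overpotential shrank."""
    return onset_potential(end_cycle.cathodic, threshold_ma) - onset_potential(
        begin_cycle.cathodic, threshold_ma
    )
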