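"""Readers and writers for the delimited-text experiment formats.

A cell experiment is described by a YAML manifest plus flat CSV tables:

``manifest.yaml``::

    cell_id: LB1
    working_volume_l: 0.150
    timeseries: timeseries.csv      # cell_id, chamber, time_h, compound, conc_mM
    current: current.csv            # cell_id, time_h, current_mA, potential_V
    gas: gas.csv                    # cell_id, cycle, compound, amount_mmol
                                    #   (or fraction, bag_volume_L, temp_K, pressure_Pa)
    anolyte_end: anolyte.csv        # cell_id, cycle, compound, conc_mM
    cycles:
      - index: 1
        t_start_h: 0.0
        t_end_h: 158.4
        additions: [{time_h: 0.0, compound: lactate, mmol: 3.0}]
        withdrawals: [{time_h: 24.0, volume_ml: 1.0, chamber: cathode}]

All files are comma-delimited UTF-8 with a header row and "." decimals.
``current`` and ``gas``/``anolyte_end`` are optional (controls have no
current trace).  Loading validates every model invariant; a write/reload
round trip preserves all numeric fields exactly (floats are serialised
with ``repr`` precision).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import (
    WITHDRAWAL_WARN_FRACTION,
    BatchCycle,
    CellExperiment,
    ConcentrationSeries,
    CurrentTrace,
    GasReading,
)


class ManifestError(ValueError):
    """Malformed manifest or referenced data file."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ManifestError(f"{what}: missing columns {missing}")


def _read_csv(path: Path, what: str) -> pd.DataFrame:
    if not path.exists():
        raise ManifestError(f"{what}: file not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def load_experiment(manifest_path: str | Path) -> CellExperiment:
    """Read a manifest and its referenced tables into a validated model."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ManifestError("manifest must be a key-value mapping")
    base = manifest_path.parent

    for key in ("cell_id", "working_volume_l", "timeseries", "cycles"):
        if key not in cfg:
            raise ManifestError(f"manifest missing required key {key!r}")
    cell_id = str(cfg["cell_id"])

    cycles = []
    for c in cfg["cycles"]:
        cycles.append(
            BatchCycle(
                index=int(c["index"]),
                t_start=float(c["t_start_h"]),
                t_end=float(c["t_end_h"]),
                additions=[
                    (float(a["time_h"]), str(a["compound"]), float(a["mmol"]))
                    for a in c.get("additions", [])
                ],
                withdrawals=[
                    (float(w["time_h"]), float(w["volume_ml"]), w["chamber"])
                    for w in c.get("withdrawals", [])
                ],
            )
        )

    ts = _read_csv(base / cfg["timeseries"], "timeseries")
    _require_columns(
        ts, ["cell_id", "chamber", "time_h", "compound", "conc_mM"], "timeseries"
    )
    ts = ts[ts["cell_id"] == cell_id]
    series = []
    for (chamber, compound), grp in ts.groupby(["chamber", "compound"], sort=True):
        grp = grp.sort_values("time_h")
        series.append(
            ConcentrationSeries(
                cell_id=cell_id,
                chamber=chamber,
                compound=compound,
                points=list(
                    zip(grp["time_h"].astype(float), grp["conc_mM"].astype(float))
                ),
            )
        )

    current = None
    if cfg.get("current"):
        cur = _read_csv(base / cfg["current"], "current")
        _require_columns(
            cur, ["cell_id", "time_h", "current_mA", "potential_V"], "current"
        )
        cur = cur[cur["cell_id"] == cell_id].sort_values("time_h")
        segments = _potential_segments(
            cur["time_h"].to_numpy(float), cur["potential_V"].to_numpy(float)
        )
        current = CurrentTrace(
            cell_id=cell_id,
            points=list(
                zip(cur["time_h"].astype(float), cur["current_mA"].astype(float))
            ),
            applied_potential_segments=segments,
        )

    gas: list[GasReading] = []
    if cfg.get("gas"):
        gdf = _read_csv(base / cfg["gas"], "gas")
        _require_columns(gdf, ["cell_id", "cycle", "compound"], "gas")
        for _, row in gdf[gdf["cell_id"] == cell_id].iterrows():
            kwargs: dict = {
                "cycle_index": int(row["cycle"]),
                "compound": row["compound"],
            }
            if "amount_mmol" in gdf.columns and pd.notna(row.get("amount_mmol")):
                kwargs["amount_mmol"] = float(row["amount_mmol"])
            else:
                kwargs["fraction"] = float(row["fraction"])
                kwargs["bag_volume_l"] = float(row["bag_volume_L"])
                if pd.notna(row.get("temp_K")):
                    kwargs["temperature_k"] = float(row["temp_K"])
                if pd.notna(row.get("pressure_Pa")):
                    kwargs["pressure_pa"] = float(row["pressure_Pa"])
            gas.append(GasReading(**kwargs))

    anolyte_end: list[tuple[int, str, float]] = []
    if cfg.get("anolyte_end"):
        adf = _read_csv(base / cfg["anolyte_end"], "anolyte_end")
        _require_columns(adf, ["cell_id", "cycle", "compound", "conc_mM"],
                         "anolyte_end")
        for _, row in adf[adf["cell_id"] == cell_id].iterrows():
            anolyte_end.append(
                (int(row["cycle"]), str(row["compound"]), float(row["conc_mM"]))
            )

    exp = CellExperiment(
        cell_id=cell_id,
        working_volume=float(cfg["working_volume_l"]),
        cycles=cycles,
        series=series,
        current=current,
        gas=gas,
        anolyte_end=anolyte_end,
    )
    frac = exp.withdrawn_volume_fraction()
    if frac > WITHDRAWAL_WARN_FRACTION:
        warnings.warn(
            f"{cell_id}: withdrawn volume is {100 * frac:.1f}% of the working "
            f"volume (> {100 * WITHDRAWAL_WARN_FRACTION:.0f}%); concentration "
            "series may understate true production",
            stacklevel=2,
        )
    return exp


def _potential_segments(times, potentials):
    """Collapse a per-point potential column into constant segments."""
    if len(times) == 0:
        return []
    segments = []
    start = times[0]
    pot = potentials[0]
    for t, p in zip(times[1:], potentials[1:]):
        if p != pot:
            segments.append((float(start), float(t), float(pot)))
            start, pot = t, p
    segments.append((float(start), float(times[-1]), float(pot)))
    return segments


def write_experiment(exp: CellExperiment, out_dir: str | Path) -> Path:
    """Write an experiment back to manifest + CSV files; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "cell_id": exp.cell_id,
            "chamber": s.chamber,
            "time_h": t,
            "compound": s.compound,
            "conc_mM": c,
        }
        for s in exp.series
        for t, c in s.points
    ]
    pd.DataFrame(
        rows, columns=["cell_id", "chamber", "time_h", "compound", "conc_mM"]
    ).to_csv(out / "timeseries.csv", index=False)

    cfg: dict = {
        "cell_id": exp.cell_id,
        "working_volume_l": exp.working_volume,
        "timeseries": "timeseries.csv",
        "cycles": [
            {
                "index": c.index,
                "t_start_h": c.t_start,
                "t_end_h": c.t_end,
                "additions": [
                    {"time_h": t, "compound": comp, "mmol": m}
                    for t, comp, m in c.additions
                ],
                "withdrawals": [
                    {"time_h": t, "volume_ml": v, "chamber": ch}
                    for t, v, ch in c.withdrawals
                ],
            }
            for c in exp.cycles
        ],
    }

    if exp.current is not None:
        seg = exp.current.applied_potential_segments

        def pot_at(t: float) -> float:
            for a, b, p in seg:
                if a <= t <= b:
                    return p
            return seg[-1][2] if seg else 0.0

        pd.DataFrame(
            {
                "cell_id": exp.cell_id,
                "time_h": exp.current.times,
                "current_mA": exp.current.currents,
                "potential_V": [pot_at(t) for t in exp.current.times],
            }
        ).to_csv(out / "current.csv", index=False)
        cfg["current"] = "current.csv"

    if exp.gas:
        pd.DataFrame(
            [
                {
                    "cell_id": exp.cell_id,
                    "cycle": g.cycle_index,
                    "compound": g.compound,
                    "amount_mmol": g.amount_mmol,
                    "fraction": g.fraction,
                    "bag_volume_L": g.bag_volume_l,
                    "temp_K": g.temperature_k,
                    "pressure_Pa": g.pressure_pa,
                }
                for g in exp.gas
            ]
        ).to_csv(out / "gas.csv", index=False)
        cfg["gas"] = "gas.csv"

    if exp.anolyte_end:
        pd.DataFrame(
            [
                {
                    "cell_id": exp.cell_id,
                    "cycle": idx,
                    "compound": comp,
                    "conc_mM": conc,
                }
                for idx, comp, conc in exp.anolyte_end
            ]
        ).to_csv(out / "anolyte.csv", index=False)
        cfg["anolyte_end"] = "anolyte.csv"

    manifest = out / "manifest.yaml"
    with open(manifest, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return manifest
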