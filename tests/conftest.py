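"""Shared fixtures: published balance-ledger rows and simulator presets."""

from __future__ import annotations

import pytest
from hypothesis import settings

from lactoferm.balances import BalanceLedger, LedgerEntry

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from lactoferm.simulate import LogisticExtent, SimCycle, SimulationParams


def _entry(c: float, e: float) -> LedgerEntry:
    return LedgerEntry(mmol=None, mmol_c=c, mmol_e=e)


# Published carbon/electron ledgers of the five electrofermentation cells
# and eight non-electrochemical controls, in mmol C / mmol e- per compound.
# inlet: substrates fed; charge: delivered cathodic charge (mmol e-);
# outlet: residual substrates + soluble products; gas: headspace.
# expected: printed carbon balance (%), electron balance (%), eta_EF.
TABLE2_ROWS: dict[str, dict] = {
    "LB1": {
        "inlet": {"lactate": (36.6, 146.5), "butyrate": (9.9, 49.5)},
        "charge": 123.8,
        "outlet": {
            "lactate": (2.5, 9.9),
            "acetate": (7.9, 31.6),
            "propionate": (12.8, 59.6),
            "butyrate": (9.0, 45.0),
        },
        "gas": {"H2": (0.0, 71.0), "CO2": (0.7, 0.0)},
        "expected": {"carbon": 70.6, "electron": 67.9, "eta_ef": 1.36},
    },
    "LB2": {
        "inlet": {"lactate": (38.6, 154.3), "butyrate": (9.7, 48.4)},
        "charge": 94.1,
        "outlet": {
            "lactate": (2.5, 9.9),
            "acetate": (8.8, 35.2),
            "propionate": (11.5, 53.4),
            "butyrate": (5.5, 27.7),
        },
        "gas": {"H2": (0.0, 0.0), "CO2": (0.2, 0.0)},
        "expected": {"carbon": 58.9, "electron": 42.5, "eta_ef": 1.06},
    },
    "L1": {
        "inlet": {"lactate": (22.3, 89.4)},
        "charge": 34.7,
        "outlet": {
            "lactate": (0.0, 0.0),
            "acetate": (5.5, 22.0),
            "propionate": (6.8, 31.5),
            "butyrate": (0.4, 2.0),
        },
        "gas": {},
        "expected": {"carbon": 56.6, "electron": 44.7, "eta_ef": 0.63},
    },
    "L2": {
        "inlet": {"lactate": (23.0, 92.2)},
        "charge": 83.9,
        "outlet": {
            "lactate": (0.0, 0.0),
            "acetate": (5.6, 22.2),
            "propionate": (8.0, 37.1),
            "butyrate": (0.3, 1.7),
        },
        "gas": {},
        "expected": {"carbon": 60.1, "electron": 34.7, "eta_ef": 1.38},
    },
    "L3": {
        "inlet": {"lactate": (66.9, 267.5)},
        "charge": 36.9,
        "outlet": {
            "lactate": (7.6, 30.3),
            "acetate": (12.4, 49.7),
            "propionate": (29.1, 135.8),
            "butyrate": (7.3, 36.4),
        },
        "gas": {},
        "expected": {"carbon": 84.3, "electron": 82.8, "eta_ef": 0.17},
    },
    "C_LB1_pH5": {
        "inlet": {"lactate": (9.0, 36.0), "butyrate": (11.4, 57.0)},
        "charge": 0.0,
        "outlet": {
            "lactate": (6.4, 25.8),
            "acetate": (0.2, 0.7),
            "propionate": (0.1, 0.3),
            "butyrate": (10.2, 51.0),
        },
        "gas": {},
        "expected": {"carbon": 82.9, "electron": 83.7, "eta_ef": None},
    },
    "C_LB2_pH5": {
        "inlet": {"lactate": (8.8, 35.2), "butyrate": (11.0, 54.9)},
        "charge": 0.0,
        "outlet": {
            "lactate": (2.9, 11.6),
            "acetate": (1.3, 5.4),
            "propionate": (0.1, 0.5),
            "butyrate": (10.7, 53.3),
        },
        "gas": {},
        "expected": {"carbon": 76.0, "electron": 78.7, "eta_ef": None},
    },
    "C_LB1_pH7": {
        "inlet": {"lactate": (9.0, 36.0), "butyrate": (12.0, 59.8)},
        "charge": 0.0,
        "outlet": {
            "lactate": (0.1, 0.2),
            "acetate": (2.5, 10.0),
            "propionate": (3.9, 18.2),
            "butyrate": (11.1, 55.4),
        },
        "gas": {},
        "expected": {"carbon": 83.7, "electron": 87.5, "eta_ef": None},
    },
    "C_LB2_pH7": {
        "inlet": {"lactate": (9.2, 36.7), "butyrate": (12.0, 59.8)},
        "charge": 0.0,
        "outlet": {
            "lactate": (0.1, 0.3),
            "acetate": (2.5, 10.1),
            "propionate": (3.5, 16.5),
            "butyrate": (9.5, 47.3),
        },
        "gas": {},
        "expected": {"carbon": 73.9, "electron": 77.0, "eta_ef": None},
    },
    "C_L1_pH5": {
        "inlet": {"lactate": (9.0, 36.0)},
        "charge": 0.0,
        "outlet": {
            "lactate": (1.0, 3.9),
            "acetate": (1.5, 6.0),
            "propionate": (2.0, 9.4),
            "butyrate": (2.0, 10.0),
        },
        "gas": {},
        "expected": {"carbon": 72.4, "electron": 81.7, "eta_ef": None},
    },
    "C_L2_pH5": {
        "inlet": {"lactate": (8.9, 35.5)},
        "charge": 0.0,
        "outlet": {
            "lactate": (0.1, 0.3),
            "acetate": (2.2, 8.7),
            "propionate": (1.4, 6.6),
            "butyrate": (2.6, 13.0),
        },
        "gas": {},
        "expected": {"carbon": 70.7, "electron": 80.7, "eta_ef": None},
    },
    "C_L1_pH7": {
        "inlet": {"lactate": (8.5, 34.2)},
        "charge": 0.0,
        "outlet": {
            "lactate": (0.0, 0.2),
            "acetate": (2.1, 8.4),
            "propionate": (3.0, 14.2),
            "butyrate": (0.0, 0.0),
        },
        "gas": {},
        "expected": {"carbon": 60.5, "electron": 66.5, "eta_ef": None},
    },
    "C_L2_pH7": {
        "inlet": {"lactate": (9.2, 36.9)},
        "charge": 0.0,
        "outlet": {
            "lactate": (0.1, 0.2),
            "acetate": (2.2, 8.7),
            "propionate": (4.1, 19.3),
            "butyrate": (0.1, 0.5),
        },
        "gas": {},
        "expected": {"carbon": 70.2, "electron": 77.9, "eta_ef": None},
    },
}


def ledger_from_row(cell: str, row: dict) -> BalanceLedger:
    return BalanceLedger(
        cell_id=cell,
        inlet={k: _entry(c, e) for k, (c, e) in row["inlet"].items()},
        charge_in=row["charge"],
        outlet={k: _entry(c, e) for k, (c, e) in row["outlet"].items()},
        gas_out={k: _entry(c, e) for k, (c, e) in row["gas"].items()},
    )


@pytest.fixture
def table2_ledgers() -> dict[str, tuple[BalanceLedger, dict]]:
    return {
        cell: (ledger_from_row(cell, row), row["expected"])
        for cell, row in TABLE2_ROWS.items()
    }


@pytest.fixture
def noiseless_params() -> SimulationParams:
    """Single quiet-instrument cycle: default extents, no noise."""
    return SimulationParams(noise_sd_mm=0.0)


@pytest.fixture
def ferm_only_params() -> SimulationParams:
    """High-substrate cycle running fermentation alone, noise-free."""
    return SimulationParams(
        noise_sd_mm=0.0,
        butyrate_migration_mm_d=0.0,
        sample_volume_ml=0.0,
        cycles=(
            SimCycle(
                duration_h=381.6,
                lactate_restore_mm=150.0,
                extents={"fermentation": LogisticExtent(6.0, midpoint_h=150.0)},
            ),
        ),
    )
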