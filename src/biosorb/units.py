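"""Batch-sorption bookkeeping: uptake capacity, removal ratio, unit conversion.

Canonical internal units are mg/L for concentrations, mg/g for uptake,
litres for volume and grams for dry biomass; molar (mM) inputs are
converted at the I/O boundary.  Salt stoichiometry is taken as 1:1 metal
per formula unit (CdSO4, MnCl2·4H2O), so the molar concentration of the
salt equals the molar concentration of the metal ion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError, InvalidRecordError, ParseError, UndefinedRatioError

__all__ = [
    "MetalSpec",
    "BatchRecord",
    "METALS",
    "uptake_capacity",
    "removal_ratio",
    "molar_to_mass_conc",
    "read_batch_records",
    "augment_batch_table",
]

BATCH_COLUMNS = ["Ci_mg_L", "Cf_mg_L", "V_L", "M_g"]


@dataclass(frozen=True)
class MetalSpec:
    """A metal ion: short symbol and molar mass in g/mol."""

    symbol: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.symbol:
            raise DomainError("metal symbol must be nonempty")
        if not self.molar_mass > 0:
            raise DomainError(f"molar mass must be positive, got {self.molar_mass}")


#: Built-in metals of the study system (divalent cations sorbed by biomass).
METALS: dict[str, MetalSpec] = {
    "Cd": MetalSpec("Cd", 112.41),
    "Mn": MetalSpec("Mn", 54.938),
}


@dataclass(frozen=True)
class BatchRecord:
    """One batch sorption experiment.

    Parameters
    ----------
    Ci, Cf : float
        Initial and final (equilibrium) metal concentration in solution, mg/L.
    V : float
        Liquid volume, L.
    M : float
        Dry biosorbent mass, g.
    """

    Ci: float
    Cf: float
    V: float
    M: float

    def __post_init__(self) -> None:
        if self.Ci < 0:
            raise InvalidRecordError(f"Ci must be >= 0, got {self.Ci}")
        if not (0 <= self.Cf <= self.Ci):
            raise InvalidRecordError(
                f"Cf must satisfy 0 <= Cf <= Ci, got Cf={self.Cf}, Ci={self.Ci}"
            )
        if not self.V > 0:
            raise InvalidRecordError(f"V must be positive, got {self.V}")
        if not self.M > 0:
            raise InvalidRecordError(f"M must be positive, got {self.M}")


def uptake_capacity(rec: BatchRecord) -> float:
    """Equilibrium metal uptake Qe = (Ci - Cf) * V / M, in mg metal per g biomass.

    Zero exactly when no metal was removed (Ci == Cf).
    """
    return (rec.Ci - rec.Cf) * rec.V / rec.M


def removal_ratio(Ci: float, Cf: float) -> float:
    """Removal ratio Re = 100 * (Ci - Cf) / Ci, in percent (0..100)."""
    if Ci == 0:
        raise UndefinedRatioError("removal ratio undefined for Ci = 0")
    if Ci < 0 or Cf < 0 or Cf > Ci:
        raise InvalidRecordError(
            f"require 0 <= Cf <= Ci with Ci > 0, got Ci={Ci}, Cf={Cf}"
        )
    return min(100.0, max(0.0, 100.0 * (Ci - Cf) / Ci))


def molar_to_mass_conc(c_mM: float, metal: MetalSpec) -> float:
    """Convert a molar metal concentration (mM) to mg/L.

    mM x g/mol = mg/L; exact for the 1:1 salts used here.
    """
    if c_mM < 0:
        raise DomainError(f"concentration must be >= 0, got {c_mM} mM")
    return c_mM * metal.molar_mass


def read_batch_records(path: str | Path) -> list[BatchRecord]:
    """Read batch records from a CSV with header Ci_mg_L, Cf_mg_L, V_L, M_g.

    Raises :class:`ParseError` with a 1-based data line number on the first
    malformed or physically invalid row.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = [getattr(row, c) for c in BATCH_COLUMNS]
        if any(pd.isna(v) for v in vals):
            raise ParseError(f"{path}: non-numeric or missing value", line=i)
        try:
            records.append(BatchRecord(*(float(v) for v in vals)))
        except (InvalidRecordError, ValueError) as exc:
            raise ParseError(f"{path}: invalid record: {exc}", line=i) from exc
    return records


def augment_batch_table(records: list[BatchRecord]) -> pd.DataFrame:
    """Tabulate records with derived Qe_mg_g and Re_percent columns appended."""
    rows = []
    for r in records:
        rows.append(
            {
                "Ci_mg_L": r.Ci,
                "Cf_mg_L": r.Cf,
                "V_L": r.V,
                "M_g": r.M,
                "Qe_mg_g": uptake_capacity(r),
                "Re_percent": removal_ratio(r.Ci, r.Cf) if r.Ci > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=BATCH_COLUMNS + ["Qe_mg_g", "Re_percent"])
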