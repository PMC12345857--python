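"""Proportion of days covered (PDC) from pharmacy dispensing records.

The adherence measure used throughout the package: each dispensing record
covers ``days_supply`` consecutive days starting at its fill date; when a
refill arrives before the previous supply is exhausted the new supply is
*banked* — its coverage starts the day after the previous supply runs out
(the standard same-drug early-refill convention).  Coverage is clipped to a
fixed measurement window split into consecutive equal-length periods
(12 x 30 days by default), and each period's PDC is the fraction of its days
covered.  A period is "adherent" when its PDC is at least 0.8 (inclusive).

Fills dated before the window start contribute whatever of their supply
overhangs into the window (carry-in supply).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.8
DEFAULT_N_PERIODS = 12
DEFAULT_PERIOD_LENGTH = 30


@dataclass(frozen=True)
class DispensingRecord:
    """One pharmacy fill: who, when, how many days of drug, which drug."""

    patient_id: str
    fill_date: date
    days_supply: int
    drug: str = "OET"

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(
                f"days_supply must be >= 1, got {self.days_supply} "
                f"for patient {self.patient_id}"
            )


@dataclass(frozen=True)
class AdherencePanel:
    """Per-patient monthly PDC and binary adherence over the study window.

    ``overall_pdc`` is covered days over the *full* window divided by the
    window length (not the mean of the monthly PDCs); it feeds the
    GBTM-vs-binary classification comparison only.
    """

    patient_id: str
    period_pdc: np.ndarray
    period_binary: np.ndarray
    overall_pdc: float
    overall_binary: int


@dataclass(frozen=True)
class DiscordanceReport:
    """Cross-tabulation of trajectory-based vs whole-window binary adherence."""

    n_both: int
    n_gbtm_only: int
    n_binary_only: int
    n_neither: int
    gbtm_only_pdc_range: tuple[float, float] | None
    binary_only_pdc_range: tuple[float, float] | None

    @property
    def n_discordant(self) -> int:
        return self.n_gbtm_only + self.n_binary_only


def compute_coverage(
    records: list[DispensingRecord],
    window_start: date,
    window_days: int,
) -> np.ndarray:
    """Boolean covered-day mask over ``window_days`` days from ``window_start``.

    Fills are processed in date order with banked supply: a fill that occurs
    while the previous supply is still on hand starts covering the day the
    previous supply ends. Coverage before the window start or past its end is
    discarded; each day is covered at most once.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    covered = np.zeros(window_days, dtype=bool)
    supply_end = -(10**9)  # day offset at which the on-hand supply runs out
    for rec in sorted(records, key=lambda r: r.fill_date):
        if rec.days_supply < 1:
            raise ValueError("days_supply must be >= 1")
        offset = (rec.fill_date - window_start).days
        start = max(offset, supply_end)
        supply_end = start + rec.days_supply
        lo, hi = max(start, 0), min(supply_end, window_days)
        if lo < hi:
            covered[lo:hi] = True
    return covered


def compute_monthly_pdc(
    records: list[DispensingRecord],
    window_start: date,
    n_periods: int = DEFAULT_N_PERIODS,
    period_length: int = DEFAULT_PERIOD_LENGTH,
) -> np.ndarray:
    """PDC for each consecutive ``period_length``-day period.

    An empty record list yields an all-zero vector: a patient with no fills
    is fully non-adherent, not invalid.
    """
    covered = compute_coverage(records, window_start, n_periods * period_length)
    return covered.reshape(n_periods, period_length).mean(axis=1)


def binarize(pdc: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary adherence indicator: 1 where PDC >= threshold (inclusive)."""
    pdc = np.asarray(pdc, dtype=float)
    if np.any((pdc < 0) | (pdc > 1)):
        raise ValueError("PDC values must lie in [0, 1]")
    return (pdc >= threshold).astype(int)


def build_panel(
    records: list[DispensingRecord],
    window_start: date,
    n_periods: int = DEFAULT_N_PERIODS,
    period_length: int = DEFAULT_PERIOD_LENGTH,
    threshold: float = DEFAULT_THRESHOLD,
    patient_id: str | None = None,
) -> AdherencePanel:
    """Assemble one patient's :class:`AdherencePanel` from their records."""
    if patient_id is None:
        patient_id = records[0].patient_id if records else "unknown"
    covered = compute_coverage(records, window_start, n_periods * period_length)
    period_pdc = covered.reshape(n_periods, period_length).mean(axis=1)
    overall_pdc = float(covered.mean())
    return AdherencePanel(
        patient_id=patient_id,
        period_pdc=period_pdc,
        period_binary=binarize(period_pdc, threshold),
        overall_pdc=overall_pdc,
        overall_binary=int(overall_pdc >= threshold),
    )


def build_panels(
    records: list[DispensingRecord],
    window_start: date,
    patient_ids: list[str] | None = None,
    n_periods: int = DEFAULT_N_PERIODS,
    period_length: int = DEFAULT_PERIOD_LENGTH,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[AdherencePanel]:
    """Group records by patient and build a panel per patient.

    ``patient_ids`` fixes the roster (and its order); patients with no
    in-window fills get an all-zero panel, with a warning.
    """
    by_patient: dict[str, list[DispensingRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    if patient_ids is None:
        patient_ids = sorted(by_patient)
    n_empty = sum(1 for pid in patient_ids if not by_patient.get(pid))
    if n_empty:
        warnings.warn(
            f"{n_empty} patient(s) have no dispensing records; "
            "their panels are all-zero",
            UserWarning,
            stacklevel=2,
        )
    return [
        build_panel(
            by_patient.get(pid, []),
            window_start,
            n_periods,
            period_length,
            threshold,
            patient_id=pid,
        )
        for pid in patient_ids
    ]


def compare_classifications(
    panels: list[AdherencePanel],
    assignments: np.ndarray,
    adherent_group: int,
) -> DiscordanceReport:
    """Cross-tabulate whole-window binary adherence against membership in the
    adherent trajectory group, and report the overall-PDC range of the
    discordant patients (those the trajectory model calls adherent but the
    single 12-month threshold does not, and vice versa)."""
    assignments = np.asarray(assignments)
    if len(panels) != len(assignments):
        raise ValueError(
            f"{len(panels)} panels but {len(assignments)} assignments"
        )
    in_adherent = assignments == adherent_group
    overall_bin = np.array([p.overall_binary for p in panels], dtype=bool)
    overall_pdc = np.array([p.overall_pdc for p in panels])

    gbtm_only = in_adherent & ~overall_bin
    binary_only = ~in_adherent & overall_bin

    def _range(mask: np.ndarray) -> tuple[float, float] | None:
        if not mask.any():
            return None
        vals = overall_pdc[mask]
        return float(vals.min()), float(vals.max())

    return DiscordanceReport(
        n_both=int((in_adherent & overall_bin).sum()),
        n_gbtm_only=int(gbtm_only.sum()),
        n_binary_only=int(binary_only.sum()),
        n_neither=int((~in_adherent & ~overall_bin).sum()),
        gbtm_only_pdc_range=_range(gbtm_only),
        binary_only_pdc_range=_range(binary_only),
    )


# ---------------------------------------------------------------------------
# File contracts
# ---------------------------------------------------------------------------

def read_dispensing_csv(path) -> list[DispensingRecord]:
    """Read dispensing records from CSV (patient_id, fill_date, days_supply, drug)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "fill_date", "days_supply"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dispensing CSV missing columns: {sorted(missing)}")
    if "drug" not in df.columns:
        df["drug"] = "OET"
    dates = pd.to_datetime(df["fill_date"]).dt.date
    return [
        DispensingRecord(row.patient_id, d, int(row.days_supply), row.drug)
        for row, d in zip(df.itertuples(index=False), dates)
    ]


def records_to_frame(records: list[DispensingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "fill_date": [r.fill_date.isoformat() for r in records],
            "days_supply": [r.days_supply for r in records],
            "drug": [r.drug for r in records],
        }
    )


def panels_to_frame(panels: list[AdherencePanel]) -> pd.DataFrame:
    """Wide panel table: pdc_01..pdc_T, bin_01..bin_T, overall columns."""
    n_periods = len(panels[0].period_pdc) if panels else DEFAULT_N_PERIODS
    out: dict[str, list] = {"patient_id": [p.patient_id for p in panels]}
    for t in range(n_periods):
        out[f"pdc_{t + 1:02d}"] = [float(p.period_pdc[t]) for p in panels]
    for t in range(n_periods):
        out[f"bin_{t + 1:02d}"] = [int(p.period_binary[t]) for p in panels]
    out["overall_pdc"] = [p.overall_pdc for p in panels]
    out["overall_binary"] = [p.overall_binary for p in panels]
    return pd.DataFrame(out)


def frame_to_panels(df: pd.DataFrame) -> list[AdherencePanel]:
    pdc_cols = sorted(c for c in df.columns if c.startswith("pdc_"))
    bin_cols = sorted(c for c in df.columns if c.startswith("bin_"))
    return [
        AdherencePanel(
            patient_id=str(row["patient_id"]),
            period_pdc=row[pdc_cols].to_numpy(dtype=float),
            period_binary=row[bin_cols].to_numpy(dtype=int),
            overall_pdc=float(row["overall_pdc"]),
            overall_binary=int(row["overall_binary"]),
        )
        for _, row in df.iterrows()
    ]


def binary_matrix(panels: list[AdherencePanel]) -> np.ndarray:
    """N x T matrix of binary monthly indicators — the GBTM input."""
    return np.array([p.period_binary for p in panels], dtype=float)


__all__ = [
    "DispensingRecord",
    "AdherencePanel",
    "DiscordanceReport",
    "compute_coverage",
    "compute_monthly_pdc",
    "binarize",
    "build_panel",
    "build_panels",
    "compare_classifications",
    "read_dispensing_csv",
    "records_to_frame",
    "panels_to_frame",
    "frame_to_panels",
    "binary_matrix",
]
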