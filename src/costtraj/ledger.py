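"""Event-level cost allocation and death-anchored monthly aggregation.

Hospital resource consumption arrives as a ledger of dated events (drug
administrations, admissions, consultations, diagnostics ...).  This module
turns that ledger into per-patient daily costs and then into a patients x 12
matrix of monthly costs over the last year of life, where month 1 is the
30-day window ending at death and month 12 the window 331-360 days before
death.  Costs are price-inflated to reference-year euros and conserved
throughout: the total of the matrix equals the total of the ledger up to
integer rounding.

Months are 30-day retrospective windows anchored at the death date rather
than calendar months, so the mask of observed months is a deterministic
function of survival time: a patient surviving ``s`` days contributes
``min(12, ceil(s / 30))`` observed months, the earliest of which may be
partial and carries the unadjusted sum of its observed days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from statistics import median
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REFERENCE_YEAR = 2017
N_MONTHS = 12

CATEGORIES = (
    "medication",
    "transfusion",
    "local_treatment",
    "consultation",
    "hospitalization",
    "diagnostic",
)

RECEPTOR_STATUSES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "TN")
LAST_TX_TYPES = ("chemo_only", "hormonal_only", "targeted_based", "none")

#: Columns of the canonical patient table.
PATIENT_COLUMNS = [
    "patient_id",
    "diagnosis_date",
    "death_date",
    "age",
    "n_metastatic_sites",
    "receptor_status",
    "metabolic",
    "cardiovascular",
    "other_malignancy",
    "pulmonary",
    "death_in_hospital",
    "intravenous_last_tx",
    "last_tx_type",
    "locoregional_radical",
]


class UnknownCostCodeError(KeyError):
    """A ledger event references a cost code absent from the price table."""


@dataclass
class ResourceEvent:
    """One dated consumption of a hospital resource.

    ``start_date``/``end_date`` span the administration period (inclusive);
    single-day events may leave ``end_date`` unset.  ``quantity`` times the
    unit price of ``cost_code``, inflated from ``price_year`` to reference
    euros, is the event's total cost.  Missing quantities or dates are
    permitted on input and must be resolved by :func:`impute_missing` before
    allocation.
    """

    patient_id: str
    category: str
    start_date: date | None
    end_date: date | None
    quantity: float | None
    cost_code: str
    price_year: int
    quantity_imputed: bool = False
    dates_imputed: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown resource category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if (
            self.start_date is not None
            and self.end_date is not None
            and self.end_date < self.start_date
        ):
            raise ValueError(
                f"event for patient {self.patient_id!r}: end_date "
                f"{self.end_date} precedes start_date {self.start_date}"
            )
        if self.quantity is not None and self.quantity < 0:
            raise ValueError(
                f"event for patient {self.patient_id!r}: negative quantity "
                f"{self.quantity}"
            )


@dataclass
class UnitCostTable:
    """Unit prices per cost code plus a consumer-price-index series.

    Prices are quoted in euros of the year recorded on the event; the CPI
    series converts them to reference-year (2017) euros.
    """

    prices: dict[str, float]
    cpi: dict[int, float]

    def __post_init__(self) -> None:
        bad = [c for c, p in self.prices.items() if p < 0]
        if bad:
            raise ValueError(f"negative unit prices for codes {bad}")
        bad = [y for y, v in self.cpi.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive CPI values for years {bad}")
        if REFERENCE_YEAR not in self.cpi:
            raise ValueError(f"CPI series must include the reference year {REFERENCE_YEAR}")

    def price(self, cost_code: str) -> float:
        try:
            return self.prices[cost_code]
        except KeyError:
            raise UnknownCostCodeError(
                f"unknown cost_code {cost_code!r}; not in the unit-cost table"
            ) from None


def inflate_to_2017(amount: float, year: int, costs: UnitCostTable) -> float:
    """Inflate ``amount`` from ``year`` euros to reference-year euros.

    Uses the CPI ratio cpi(2017) / cpi(year).
    """
    if year not in costs.cpi:
        raise ValueError(f"year {year} absent from the CPI series")
    return amount * costs.cpi[REFERENCE_YEAR] / costs.cpi[year]


def allocate_interval_costs(
    total: float, start: date, end: date | None = None
) -> dict[date, float]:
    """Spread ``total`` uniformly over every day of [start, end] inclusive."""
    if end is None:
        end = start
    n_days = (end - start).days + 1
    if n_days <= 0:
        raise ValueError(f"empty interval: {start} .. {end}")
    per_day = total / n_days
    return {start + timedelta(days=k): per_day for k in range(n_days)}


def event_total_cost(event: ResourceEvent, costs: UnitCostTable) -> float:
    """Total reference-euro cost of one event: quantity x price, inflated."""
    if event.quantity is None:
        raise ValueError(
            f"event for patient {event.patient_id!r} has no quantity; "
            "run impute_missing first"
        )
    raw = event.quantity * costs.price(event.cost_code)
    return inflate_to_2017(raw, event.price_year, costs)


def allocate_event_daily(
    event: ResourceEvent, costs: UnitCostTable
) -> dict[date, float]:
    """Allocate one event's cost uniformly over its administration span.

    Treatments spanning several days are split equally between the first and
    the last day of administration (inclusive); single-date events map
    entirely to that date.  The daily amounts sum to the event's total
    inflated cost.
    """
    if event.start_date is None:
        raise ValueError(
            f"event for patient {event.patient_id!r} has no start_date; "
            "run impute_missing first"
        )
    total = event_total_cost(event, costs)
    return allocate_interval_costs(total, event.start_date, event.end_date)


@dataclass
class ImputePolicy:
    """Rules for resolving missing quantities and dates in a ledger.

    Missing quantities are replaced by the median observed quantity within
    the same resource category.  Missing dates are replaced by the midpoint
    of the enclosing treatment-sequence interval for that patient (supplied
    in ``sequences``; typically diagnosis-to-death when no finer sequence
    timing exists).  Every imputed field is flagged on the returned events so
    downstream analyses can be rerun excluding them.
    """

    sequences: dict[str, tuple[date, date]] = field(default_factory=dict)
    quantity_rule: str = "category_median"
    date_rule: str = "sequence_midpoint"


def impute_missing(
    events: Iterable[ResourceEvent], policy: ImputePolicy
) -> list[ResourceEvent]:
    """Return events with quantities and start dates filled in and flagged."""
    events = list(events)
    medians: dict[str, float] = {}
    for cat in CATEGORIES:
        observed_q = [
            e.quantity for e in events if e.category == cat and e.quantity is not None
        ]
        if observed_q:
            medians[cat] = float(median(observed_q))

    out: list[ResourceEvent] = []
    for e in events:
        changes: dict = {}
        if e.quantity is None:
            if e.category not in medians:
                raise ValueError(
                    f"cannot impute quantity: no observed quantities in "
                    f"category {e.category!r}"
                )
            changes["quantity"] = medians[e.category]
            changes["quantity_imputed"] = True
        if e.start_date is None:
            try:
                seq_start, seq_end = policy.sequences[e.patient_id]
            except KeyError:
                raise ValueError(
                    f"cannot impute dates for patient {e.patient_id!r}: no "
                    "treatment-sequence interval in the policy"
                ) from None
            mid = seq_start + timedelta(days=(seq_end - seq_start).days // 2)
            changes["start_date"] = mid
            if e.end_date is None:
                changes["end_date"] = mid
            changes["dates_imputed"] = True
        out.append(replace(e, **changes) if changes else e)
    return out


@dataclass
class MonthlyCostMatrix:
    """Patients x 12 death-anchored monthly cost counts with a mask.

    ``values[:, m-1]`` holds integer euro costs of month ``m``, where month 1
    is the 30-day window ending at death.  ``observed`` marks months in which
    the patient was alive and diagnosed; values at unobserved cells are zero
    and excluded from all likelihoods.
    """

    values: np.ndarray
    observed: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        n = len(self.patient_ids)
        if self.values.shape != (n, N_MONTHS) or self.observed.shape != (n, N_MONTHS):
            raise ValueError(
                f"values/observed must be ({n}, {N_MONTHS}); got "
                f"{self.values.shape} and {self.observed.shape}"
            )
        if (self.values < 0).any():
            raise ValueError("monthly cost values must be non-negative")
        if (self.values[~self.observed] != 0).any():
            raise ValueError("unobserved cells must carry zero cost")
        if not self.observed.any(axis=1).all():
            bad = self.patient_ids[~self.observed.any(axis=1)]
            raise ValueError(f"patients with no observed months: {list(bad)}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"m{m}": self.values[:, m - 1] for m in range(1, N_MONTHS + 1)}
        cols.update(
            {f"obs{m}": self.observed[:, m - 1].astype(int) for m in range(1, N_MONTHS + 1)}
        )
        return pd.DataFrame({"patient_id": self.patient_ids, **cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MonthlyCostMatrix":
        values = df[[f"m{m}" for m in range(1, N_MONTHS + 1)]].to_numpy()
        observed = df[[f"obs{m}" for m in range(1, N_MONTHS + 1)]].to_numpy().astype(bool)
        return cls(values=values, observed=observed, patient_ids=df["patient_id"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "MonthlyCostMatrix":
        return cls.from_frame(pd.read_csv(path))


def n_observed_months(survival_days: int) -> int:
    """Number of observed death-anchored months for a given survival time."""
    return min(N_MONTHS, math.ceil(survival_days / 30))


def month_of_day(days_before_death: int) -> int | None:
    """Death-anchored month index of a day, or None if beyond 12 months.

    Month ``m`` collects days (30(m-1), 30m] before death; the death day
    itself (0 days before) falls into month 1.
    """
    m = max(1, math.ceil(days_before_death / 30))
    return m if m <= N_MONTHS else None


def observation_mask(survival_days: np.ndarray) -> np.ndarray:
    """Boolean (n, 12) mask of observed months from survival days."""
    s = np.asarray(survival_days)
    n_obs = np.minimum(N_MONTHS, np.ceil(s / 30).astype(int))
    return np.arange(1, N_MONTHS + 1)[None, :] <= n_obs[:, None]


def aggregate_monthly(
    daily: Mapping[str, Mapping[date, float]],
    patients: pd.DataFrame,
    scale: float = 1.0,
) -> MonthlyCostMatrix:
    """Aggregate per-patient daily costs into the monthly cost matrix.

    Month ``m`` collects the costs of days (30(m-1), 30m] before death.
    Months entirely before the advanced-disease diagnosis are masked
    unobserved; the month containing the diagnosis stays observed and carries
    the unadjusted sum of its observed days.  Costs dated more than 360 days
    before death fall outside the analysis window and are dropped.  Euro
    totals are divided by ``scale`` and rounded half-up to integers (the
    count units of the trajectory model).

    Raises if any cost is dated outside a patient's [diagnosis, death] window.
    """
    patients = patients.reset_index(drop=True)
    ids = patients["patient_id"].to_numpy()
    idx = {pid: i for i, pid in enumerate(ids)}
    diagnosis = pd.to_datetime(patients["diagnosis_date"]).dt.date.to_numpy()
    death = pd.to_datetime(patients["death_date"]).dt.date.to_numpy()
    survival = np.array([(d - g).days for g, d in zip(diagnosis, death)])
    if (survival <= 0).any():
        bad = ids[survival <= 0]
        raise ValueError(f"death on or before diagnosis for patients {list(bad)}")

    raw = np.zeros((len(ids), N_MONTHS))
    for pid, day_map in daily.items():
        if pid not in idx:
            raise ValueError(f"daily costs for unknown patient {pid!r}")
        i = idx[pid]
        for d, amount in day_map.items():
            if d < diagnosis[i] or d > death[i]:
                raise ValueError(
                    f"cost for patient {pid!r} dated {d} outside the "
                    f"[{diagnosis[i]}, {death[i]}] lifetime window"
                )
            m = month_of_day((death[i] - d).days)
            if m is not None:
                raw[i, m - 1] += amount

    observed = observation_mask(survival)
    values = np.floor(raw / scale + 0.5).astype(np.int64)  # round half-up
    values[~observed] = 0
    return MonthlyCostMatrix(values=values, observed=observed, patient_ids=ids)


def allocate_ledger_daily(
    events: Iterable[ResourceEvent], costs: UnitCostTable
) -> dict[str, dict[date, float]]:
    """Allocate every ledger event to days, merged per patient."""
    out: dict[str, dict[date, float]] = {}
    for e in events:
        day_map = out.setdefault(e.patient_id, {})
        for d, amt in allocate_event_daily(e, costs).items():
            day_map[d] = day_map.get(d, 0.0) + amt
    return out


def summarize_trend(
    matrix: MonthlyCostMatrix,
    by_category: Mapping[str, MonthlyCostMatrix] | None = None,
) -> pd.DataFrame:
    """Per-month mean and SD of costs over patients observed in that month.

    Returns one row per month (1 = last month before death); the mean of the
    12 monthly means is attached as ``grand_mean`` metadata column on every
    row.  Months with no observed patients are reported as missing.  When
    ``by_category`` maps category names to per-category matrices, category
    means are appended as extra columns.
    """
    rows = []
    for m in range(1, N_MONTHS + 1):
        obs = matrix.observed[:, m - 1]
        vals = matrix.values[obs, m - 1]
        row = {
            "month": m,
            "n": int(obs.sum()),
            "mean": float(vals.mean()) if obs.any() else np.nan,
            "sd": float(vals.std(ddof=1)) if obs.sum() > 1 else np.nan,
        }
        if by_category:
            for cat, cm in by_category.items():
                cobs = cm.observed[:, m - 1]
                row[f"mean_{cat}"] = (
                    float(cm.values[cobs, m - 1].mean()) if cobs.any() else np.nan
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["grand_mean"] = df["mean"].mean()
    return df


# ---------------------------------------------------------------------------
# Plain-text IO


def read_unit_costs(prices_path, cpi_path) -> UnitCostTable:
    """Read (cost_code, price, price_year) and (year, index) CSVs."""
    prices_df = pd.read_csv(prices_path)
    cpi_df = pd.read_csv(cpi_path)
    prices = dict(zip(prices_df["cost_code"], prices_df["price"].astype(float)))
    cpi = dict(zip(cpi_df["year"].astype(int), cpi_df["index"].astype(float)))
    return UnitCostTable(prices=prices, cpi=cpi)


def write_unit_costs(costs: UnitCostTable, prices_path, cpi_path) -> None:
    pd.DataFrame(
        {"cost_code": list(costs.prices), "price": list(costs.prices.values())}
    ).to_csv(prices_path, index=False)
    pd.DataFrame(
        {"year": list(costs.cpi), "index": list(costs.cpi.values())}
    ).to_csv(cpi_path, index=False)


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return pd.Timestamp(value).date()


def read_ledger(path) -> list[ResourceEvent]:
    """Read a resource-event ledger CSV; empty fields are missing values."""
    df = pd.read_csv(path)
    events = []
    for row in df.itertuples(index=False):
        q = getattr(row, "quantity")
        events.append(
            ResourceEvent(
                patient_id=str(row.patient_id),
                category=row.category,
                start_date=_parse_date(row.start_date),
                end_date=_parse_date(row.end_date),
                quantity=None if pd.isna(q) else float(q),
                cost_code=str(row.cost_code),
                price_year=int(row.price_year),
            )
        )
    return events


def write_ledger(events: Iterable[ResourceEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "category": e.category,
                "start_date": e.start_date.isoformat() if e.start_date else "",
                "end_date": e.end_date.isoformat() if e.end_date else "",
                "quantity": e.quantity if e.quantity is not None else "",
                "cost_code": e.cost_code,
                "price_year": e.price_year,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "diagnosis_date", "death_date") if c not in df]
    if missing:
        raise ValueError(f"patient table lacks required columns {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


def survival_days(patients: pd.DataFrame) -> np.ndarray:
    """Days from advanced-disease diagnosis to death, per patient."""
    return (
        (pd.to_datetime(patients["death_date"]) - pd.to_datetime(patients["diagnosis_date"]))
        .dt.days.to_numpy()
    )
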