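"""Installation monitoring records and per-treatment pools.

The raw unit of observation is a single total-N effluent concentration
(mg/L) measured at one household installation on one date.  An installation
is summarised by its *performance*: the arithmetic mean of its
concentrations over the life cycle of the system.  Per-treatment pools of
performances are the sequences the bandit experiments sample through,
either in chronological order (nonstationary data set) or in a seeded
random order (stationary data set).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PoolExhaustedError, ValidationError

REQUIRED_COLUMNS = ("installation_id", "treatment_id", "record_date", "n_effluent_mg_l")

#: Pool ordering modes.
CHRONOLOGICAL = "chronological"
SHUFFLED = "shuffled"


@dataclass
class InstallationRecord:
    """All measurements for one household installation.

    Parameters
    ----------
    installation_id
        Opaque identifier of the installation.
    treatment_id
        Label of the treatment technology installed.
    record_dates
        Measurement dates, ascending.
    concentrations
        Total-N effluent concentrations in mg/L, aligned with
        ``record_dates``.  Strictly positive (log-normal support).
    """

    installation_id: str
    treatment_id: str
    record_dates: Sequence[_dt.date]
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.size == 0:
            raise ValidationError(
                f"installation {self.installation_id!r} has no concentrations"
            )
        if len(self.record_dates) != self.concentrations.size:
            raise ValidationError(
                f"installation {self.installation_id!r}: {len(self.record_dates)} "
                f"dates but {self.concentrations.size} concentrations"
            )
        if not np.all(np.isfinite(self.concentrations)) or np.any(
            self.concentrations <= 0
        ):
            raise ValidationError(
                f"installation {self.installation_id!r} has nonpositive or "
                "nonfinite concentrations (log-normal support requires > 0)"
            )

    @property
    def first_date(self) -> _dt.date:
        return min(self.record_dates)


@dataclass
class TreatmentPool:
    """Ordered installation performances for one treatment.

    Draws consume the sequence front-to-back without replacement; the
    ``cursor`` tracks how many values have been consumed.  Shuffling
    permutes the order but never the multiset of values.
    """

    treatment_id: str
    performances: np.ndarray
    mode: str = CHRONOLOGICAL
    cursor: int = 0

    def __post_init__(self) -> None:
        self.performances = np.asarray(self.performances, dtype=float)
        if self.mode not in (CHRONOLOGICAL, SHUFFLED):
            raise ValidationError(f"unknown pool mode {self.mode!r}")
        if not 0 <= self.cursor <= self.performances.size:
            raise ValidationError("cursor out of range")

    def __len__(self) -> int:
        return int(self.performances.size)

    @property
    def remaining(self) -> int:
        return len(self) - self.cursor

    def draw(self, k: int) -> np.ndarray:
        """Consume and return the next ``k`` performances in pool order."""
        if k < 0:
            raise ValidationError("draw count must be >= 0")
        if k == 0:
            return np.empty(0, dtype=float)
        if self.cursor + k > len(self):
            raise PoolExhaustedError(self.treatment_id, k, self.remaining)
        out = self.performances[self.cursor : self.cursor + k].copy()
        self.cursor += k
        return out

    def fresh(self) -> "TreatmentPool":
        """A copy of this pool with the cursor reset to 0."""
        return TreatmentPool(self.treatment_id, self.performances.copy(), self.mode, 0)


def draw(pool: TreatmentPool, k: int) -> np.ndarray:
    """Functional alias for :meth:`TreatmentPool.draw`."""
    return pool.draw(k)


def load_records(path, *, sep: str = ",") -> list[InstallationRecord]:
    """Read a monitoring CSV into installation records.

    Expects a UTF-8 header row with columns ``installation_id``,
    ``treatment_id``, ``record_date`` (ISO-8601) and ``n_effluent_mg_l``
    (positive float), one measurement per row.  Rows are grouped by
    installation and date-sorted within each record.
    """
    df = pd.read_csv(path, sep=sep, dtype={"installation_id": str, "treatment_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []

    conc = pd.to_numeric(df["n_effluent_mg_l"], errors="coerce")
    bad = conc.isna() | (conc <= 0) | ~np.isfinite(conc)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValidationError(
            f"nonpositive or nonnumeric n_effluent_mg_l at row(s) {rows}"
        )
    try:
        dates = pd.to_datetime(df["record_date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable record_date: {exc}") from exc

    work = pd.DataFrame(
        {
            "installation_id": df["installation_id"],
            "treatment_id": df["treatment_id"],
            "record_date": dates,
            "conc": conc.astype(float),
        }
    )
    records = []
    for iid, grp in work.groupby("installation_id", sort=True):
        treatments = grp["treatment_id"].unique()
        if len(treatments) != 1:
            raise ValidationError(
                f"installation {iid!r} maps to multiple treatments: "
                f"{sorted(treatments)}"
            )
        grp = grp.sort_values("record_date", kind="stable")
        records.append(
            InstallationRecord(
                installation_id=str(iid),
                treatment_id=str(treatments[0]),
                record_dates=list(grp["record_date"]),
                concentrations=grp["conc"].to_numpy(),
            )
        )
    return records


def installation_performance(record: InstallationRecord) -> float:
    """Life-cycle performance: mean N effluent concentration (mg/L)."""
    if record.concentrations.size == 0:  # unreachable via constructor, kept defensive
        raise ValidationError("record has no concentrations")
    return float(np.mean(record.concentrations))


def build_pools(
    records: Iterable[InstallationRecord],
    mode: str = CHRONOLOGICAL,
    seed: int | None = None,
    treatments: Sequence[str] | None = None,
) -> dict[str, TreatmentPool]:
    """Reduce records to per-treatment ordered pools of performances.

    ``chronological`` orders each pool by first record date (ties broken by
    installation_id); ``shuffled`` applies a seeded uniform permutation.
    When ``treatments`` is given, any record with a label outside it is
    rejected.
    """
    if mode not in (CHRONOLOGICAL, SHUFFLED):
        raise ValidationError(f"unknown pool mode {mode!r}")
    records = list(records)
    if treatments is not None:
        known = set(treatments)
        for rec in records:
            if rec.treatment_id not in known:
                raise ValidationError(
                    f"unknown treatment label {rec.treatment_id!r} "
                    f"(known: {sorted(known)})"
                )
        labels = sorted(known)
    else:
        labels = sorted({rec.treatment_id for rec in records})

    rng = np.random.default_rng(seed)
    pools: dict[str, TreatmentPool] = {}
    for label in labels:
        group = [r for r in records if r.treatment_id == label]
        group.sort(key=lambda r: (r.first_date, r.installation_id))
        values = np.array([installation_performance(r) for r in group], dtype=float)
        if mode == SHUFFLED:
            values = values[rng.permutation(values.size)]
        pools[label] = TreatmentPool(label, values, mode=mode)
    return pools
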