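"""Canonical data model for a response-evaluation cohort.

A cohort row is one patient with paired PSMA-positive total tumor volumes
(baseline PET and ~12-week interim PET, in mL), independent per-reader
new-lesion calls, an optional consensus new-lesion call, paired serum PSA
values (ng/mL), and right-censored overall survival (months).

Cohorts are stored as plain CSV with fixed snake_case columns (see
:data:`COLUMNS`); reading validates every row and reports offending rows by
patient id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import CohortValidationError, SchemaError

#: Documented CSV column order. ``readerK_nl`` columns hold the independent
#: masked reads; ``consensus_nl`` may be empty (derived downstream).
COLUMNS = (
    "patient_id",
    "baseline_vol_ml",
    "interim_vol_ml",
    "reader1_nl",
    "reader2_nl",
    "reader3_nl",
    "consensus_nl",
    "psa_baseline",
    "psa_interim",
    "os_months",
    "os_event",
)

_MANDATORY = tuple(c for c in COLUMNS if c != "consensus_nl")


@dataclass
class PatientRecord:
    """One subject of a response-evaluation cohort.

    Volumes are total PSMA-positive tumor volume (PSMA-VOL) in mL on the
    baseline and interim scans; ``reader_calls`` are the binary new-lesion
    judgments of the independent masked readers; ``os_months`` / ``os_event``
    encode right-censored overall survival from treatment start.
    """

    patient_id: str
    baseline_vol: float
    interim_vol: float
    reader_calls: tuple[int, ...]
    psa_baseline: float
    psa_interim: float
    os_months: float
    os_event: int
    consensus_new_lesion: int | None = None

    def validate(self) -> None:
        pid = self.patient_id
        for name, value in (
            ("baseline_vol", self.baseline_vol),
            ("interim_vol", self.interim_vol),
            ("psa_baseline", self.psa_baseline),
            ("psa_interim", self.psa_interim),
            ("os_months", self.os_months),
        ):
            if not math.isfinite(value):
                raise CohortValidationError(f"patient {pid!r}: {name} is not finite")
            if value < 0:
                raise CohortValidationError(
                    f"patient {pid!r}: {name} = {value} is negative"
                )
        if self.os_event not in (0, 1):
            raise CohortValidationError(
                f"patient {pid!r}: os_event must be 0 or 1, got {self.os_event}"
            )
        if any(c not in (0, 1) for c in self.reader_calls):
            raise CohortValidationError(
                f"patient {pid!r}: reader calls must be binary, got {self.reader_calls}"
            )
        if self.consensus_new_lesion is not None and self.consensus_new_lesion not in (0, 1):
            raise CohortValidationError(
                f"patient {pid!r}: consensus_nl must be 0, 1 or absent"
            )


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique patient ids."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.patient_id in seen:
                raise CohortValidationError(
                    f"duplicate patient_id {rec.patient_id!r} in cohort"
                )
            seen.add(rec.patient_id)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view following the documented CSV column order."""
        rows = []
        for rec in self.records:
            row = {
                "patient_id": rec.patient_id,
                "baseline_vol_ml": rec.baseline_vol,
                "interim_vol_ml": rec.interim_vol,
                "psa_baseline": rec.psa_baseline,
                "psa_interim": rec.psa_interim,
                "os_months": rec.os_months,
                "os_event": rec.os_event,
                "consensus_nl": (
                    "" if rec.consensus_new_lesion is None else rec.consensus_new_lesion
                ),
            }
            for k, call in enumerate(rec.reader_calls, start=1):
                row[f"reader{k}_nl"] = call
            rows.append(row)
        n_readers = max((len(r.reader_calls) for r in self.records), default=3)
        cols = list(COLUMNS)
        if n_readers != 3:
            reader_cols = [f"reader{k}_nl" for k in range(1, n_readers + 1)]
            cols = cols[:3] + reader_cols + cols[6:]
        return pd.DataFrame(rows, columns=cols)


def _parse_float(cell, column: str, row_index: int) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row_index}: malformed numeric value {cell!r} in column {column!r}"
        ) from None


def _parse_flag(cell, column: str, row_index: int) -> int:
    value = _parse_float(cell, column, row_index)
    if value not in (0.0, 1.0):
        raise CohortValidationError(
            f"row {row_index}: column {column!r} must be 0 or 1, got {cell!r}"
        )
    return int(value)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` if a mandatory column is missing or a numeric
    cell is malformed (reported with its row index), and
    :class:`CohortValidationError` if a row violates a record invariant
    (reported with its patient id). Extra columns are ignored with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    reader_cols = sorted(
        (c for c in frame.columns if c.startswith("reader") and c.endswith("_nl")),
        key=lambda c: int(c[len("reader"):-len("_nl")]),
    )
    mandatory = [c for c in _MANDATORY if not c.startswith("reader")]
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if not reader_cols:
        raise SchemaError(f"{path}: no readerK_nl columns found")
    known = set(mandatory) | set(reader_cols) | {"consensus_nl"}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: ignoring unrecognized column(s) {extra}", stacklevel=2)

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        consensus_cell = row.get("consensus_nl", "")
        consensus = (
            None
            if str(consensus_cell).strip() == ""
            else _parse_flag(consensus_cell, "consensus_nl", i)
        )
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            baseline_vol=_parse_float(row["baseline_vol_ml"], "baseline_vol_ml", i),
            interim_vol=_parse_float(row["interim_vol_ml"], "interim_vol_ml", i),
            reader_calls=tuple(
                _parse_flag(row[c], c, i) for c in reader_cols
            ),
            psa_baseline=_parse_float(row["psa_baseline"], "psa_baseline", i),
            psa_interim=_parse_float(row["psa_interim"], "psa_interim", i),
            os_months=_parse_float(row["os_months"], "os_months", i),
            os_event=_parse_flag(row["os_event"], "os_event", i),
            consensus_new_lesion=consensus,
        )
        records.append(rec)
    cohort = Cohort(records=records, provenance={"source": str(path)})
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a validated cohort to CSV; lossless round-trip with :func:`read_cohort`."""
    cohort.validate()
    frame = cohort.to_dataframe()
    # repr-based float formatting keeps 15+ significant digits (shortest repr).
    frame.to_csv(Path(path), index=False)


def cohort_from_arrays(
    patient_ids: Sequence[str],
    baseline_vol: Iterable[float],
    interim_vol: Iterable[float],
    reader_calls: Iterable[Sequence[int]],
    psa_baseline: Iterable[float],
    psa_interim: Iterable[float],
    os_months: Iterable[float],
    os_event: Iterable[int],
    consensus: Iterable[int | None] | None = None,
    provenance: dict | None = None,
) -> Cohort:
    """Assemble a validated cohort from parallel per-patient sequences."""
    consensus_list = list(consensus) if consensus is not None else [None] * len(patient_ids)
    records = [
        PatientRecord(
            patient_id=str(pid),
            baseline_vol=float(b),
            interim_vol=float(iv),
            reader_calls=tuple(int(c) for c in calls),
            psa_baseline=float(pb),
            psa_interim=float(pi),
            os_months=float(t),
            os_event=int(e),
            consensus_new_lesion=None if cns is None else int(cns),
        )
        for pid, b, iv, calls, pb, pi, t, e, cns in zip(
            patient_ids,
            baseline_vol,
            interim_vol,
            reader_calls,
            psa_baseline,
            psa_interim,
            os_months,
            os_event,
            consensus_list,
        )
    ]
    cohort = Cohort(records=records, provenance=provenance or {})
    cohort.validate()
    return cohort
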