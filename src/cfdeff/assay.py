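"""Per-culture assay records: data model, CSV I/O and the Diff statistic.

The atomic observation is one air-liquid-interface culture's short-circuit
current response (delta I_sc, in uA/cm^2) labelled by patient, aliquot
(group sample), treatment arm and replicate.  Functional correction is
summarised by the Diff statistic: the treated culture's delta I_sc minus
the mean delta I_sc of the vehicle (DMSO) controls run alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ArgumentError, SchemaError

#: Canonical treatment labels.  The field is an open string so named
#: correctors ("lumacaftor", "corrector_b", ...) can be used directly.
VEHICLE = "vehicle"
CORRECTOR = "corrector"

#: Required columns of the assay-table interchange CSV.
ASSAY_COLUMNS = (
    "patient_id",
    "aliquot_id",
    "treatment",
    "replicate_id",
    "delta_isc_uA_cm2",
)


@dataclass(frozen=True)
class AssayRecord:
    """One culture's measured response with its grouping labels."""

    patient_id: str
    aliquot_id: str
    treatment: str
    replicate_id: str
    delta_isc: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_isc):
            raise ArgumentError(
                f"delta_isc must be finite, got {self.delta_isc!r} for "
                f"({self.patient_id}, {self.aliquot_id}, {self.treatment}, "
                f"{self.replicate_id})"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.aliquot_id, self.treatment, self.replicate_id)


@dataclass(frozen=True)
class DiffResult:
    """Corrector response relative to the mean of its vehicle controls."""

    diff: float
    treated_value: float
    control_mean: float
    n_controls: int


def compute_diff(treated: float, controls: Sequence[float]) -> DiffResult:
    """Diff = delta_isc(treated) - mean(delta_isc of vehicle controls).

    All controls from the same run are equally applicable to each treated
    culture, so the control summary is their arithmetic mean.
    """
    if len(controls) == 0:
        raise ArgumentError("compute_diff requires at least one control value")
    control_mean = sum(controls) / len(controls)
    return DiffResult(
        diff=treated - control_mean,
        treated_value=treated,
        control_mean=control_mean,
        n_controls=len(controls),
    )


def _check_duplicates(records: Sequence[AssayRecord]) -> None:
    seen: set[tuple[str, str, str, str]] = set()
    for rec in records:
        if rec.key in seen:
            raise SchemaError(
                "duplicate (patient_id, aliquot_id, treatment, replicate_id) "
                f"key: {rec.key}"
            )
        seen.add(rec.key)


def records_from_frame(frame: pd.DataFrame) -> list[AssayRecord]:
    """Validate a DataFrame with the assay-table columns into records."""
    missing = [c for c in ASSAY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"assay table is missing required column(s): {missing}")
    # parse with Python float for exact shortest-repr round trips
    values = []
    for idx, raw in frame["delta_isc_uA_cm2"].items():
        try:
            value = float(raw)
            if not math.isfinite(value):
                raise ValueError
        except (TypeError, ValueError):
            # +2: one for the header line, one for 0- vs 1-based row numbers
            raise SchemaError(
                f"non-numeric delta_isc_uA_cm2 at file row {int(idx) + 2}: {raw!r}"
            ) from None
        values.append(value)
    records = [
        AssayRecord(
            patient_id=str(row.patient_id),
            aliquot_id=str(row.aliquot_id),
            treatment=str(row.treatment),
            replicate_id=str(row.replicate_id),
            delta_isc=float(v),
        )
        for row, v in zip(frame.itertuples(index=False), values)
    ]
    _check_duplicates(records)
    return records


def read_assay_table(path, **csv_options) -> list[AssayRecord]:
    """Read a per-culture assay CSV (comma-separated, UTF-8, dot decimal).

    Returns an empty list for a header-only file.  Raises SchemaError on
    missing columns, non-numeric responses (with the offending row number)
    or duplicate record keys.
    """
    csv_options.setdefault("dtype", str)
    frame = pd.read_csv(path, **csv_options)
    return records_from_frame(frame)


def records_to_frame(records: Iterable[AssayRecord]) -> pd.DataFrame:
    rows = [
        (r.patient_id, r.aliquot_id, r.treatment, r.replicate_id, r.delta_isc)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(ASSAY_COLUMNS))


def write_assay_table(records: Iterable[AssayRecord], path) -> None:
    """Write records to the interchange CSV.

    Responses are serialised with repr (shortest round-trip decimal), so
    write-then-read reproduces the floats bit-exactly.
    """
    frame = records_to_frame(records)
    frame["delta_isc_uA_cm2"] = frame["delta_isc_uA_cm2"].map(repr)
    frame.to_csv(path, index=False)


def diff_by_patient(
    records: Sequence[AssayRecord],
    treated: str = CORRECTOR,
    control: str = VEHICLE,
) -> pd.DataFrame:
    """Per-culture Diff values for every patient in a record collection.

    Each treated culture is compared against the mean of that patient's
    control cultures (per-culture Diff; the treated-group mean is a trivial
    aggregate of the result).
    """
    frame = records_to_frame(records)
    out = []
    for patient, sub in frame.groupby("patient_id", sort=True):
        controls = sub.loc[sub["treatment"] == control, "delta_isc_uA_cm2"]
        if controls.empty:
            raise ArgumentError(f"patient {patient!r} has no {control!r} cultures")
        for _, row in sub[sub["treatment"] == treated].iterrows():
            d = compute_diff(float(row["delta_isc_uA_cm2"]), controls.tolist())
            out.append(
                (
                    patient,
                    row["aliquot_id"],
                    row["replicate_id"],
                    d.diff,
                    d.treated_value,
                    d.control_mean,
                    d.n_controls,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "patient_id",
            "aliquot_id",
            "replicate_id",
            "diff",
            "treated_value",
            "control_mean",
            "n_controls",
        ],
    )
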