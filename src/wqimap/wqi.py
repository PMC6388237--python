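"""Water quality index: per-indicator sub-indices and their unweighted sum.

The index aggregates heterogeneous constituents into one scalar

.. math:: I = \\sum_{i=1}^{n} I_i

with three sub-index rules:

* general constituents — the ratio to the regulatory limit,
  :math:`I_i = C_i / S_i` (equals 1 exactly at the limit);
* pH — a deviation score from neutrality, :math:`I_{pH} = (C_{pH} - 7)/1.5`
  (the ``literal`` mode; an ``absolute`` mode takes ``|C_pH - 7|/1.5``);
* microbial counts (total and thermotolerant coliforms) — 0 for a
  non-detect, otherwise ``ln(C_i + 1) + 1``, which jumps to 1 at the
  first detected organism and grows logarithmically thereafter; a
  ``log10`` rule can be swapped in.

The sum is unweighted; no weighted or geometric-mean variants are
provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    EmptyRecordError,
    InvalidMeasurementError,
    InvalidStandardError,
    UnknownIndicatorError,
)
from .standards import MonitoringRecord, StandardsTable

PH_MODES = ("literal", "absolute")
MICROBIAL_RULES = ("ln", "log10")
MISSING_POLICIES = ("skip", "strict")


def general_subindex(ci: float, si: float) -> float:
    """Sub-index for a general constituent: Ci / Si.

    Linear in Ci and exactly 1 at the regulatory limit.
    """
    if not si > 0:
        raise InvalidStandardError(f"limit Si must be positive, got {si}")
    if ci < 0:
        raise InvalidMeasurementError(f"concentration Ci must be >= 0, got {ci}")
    return ci / si


def ph_subindex(cph: float, mode: str = "literal") -> float:
    """pH sub-index: (CpH - 7) / 1.5, optionally in absolute value.

    ``literal`` keeps the sign (negative for acidic water); ``absolute``
    scores acid and alkaline deviations symmetrically.
    """
    if mode not in PH_MODES:
        raise ValueError(f"mode must be one of {PH_MODES}, got {mode!r}")
    if not (0.0 < cph < 14.0):
        raise InvalidMeasurementError(f"pH must lie in (0, 14), got {cph}")
    value = (cph - 7.0) / 1.5
    return abs(value) if mode == "absolute" else value


def microbial_subindex(ci: float, rule: str = "ln") -> float:
    """Sub-index for a coliform count per 100 mL.

    0 for a non-detect; for Ci > 0, ``ln(Ci + 1) + 1`` (default) or
    ``log10(Ci + 1) + 1``.  Strictly increasing on Ci > 0 with a jump
    discontinuity at 0 (right limit 1): any detection is penalized
    against the zero-tolerance standard.
    """
    if rule not in MICROBIAL_RULES:
        raise ValueError(f"rule must be one of {MICROBIAL_RULES}, got {rule!r}")
    if ci < 0:
        raise InvalidMeasurementError(f"microbial count must be >= 0, got {ci}")
    if ci == 0:
        return 0.0
    log = math.log if rule == "ln" else math.log10
    return log(ci + 1.0) + 1.0


@dataclass(frozen=True)
class WqiOptions:
    """Scoring options: pH mode, microbial log rule, missing-value policy."""

    ph_mode: str = "literal"
    microbial_rule: str = "ln"
    missing_policy: str = "skip"

    def __post_init__(self) -> None:
        if self.ph_mode not in PH_MODES:
            raise ValueError(f"ph_mode must be one of {PH_MODES}")
        if self.microbial_rule not in MICROBIAL_RULES:
            raise ValueError(f"microbial_rule must be one of {MICROBIAL_RULES}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")


@dataclass
class WQIResult:
    """Per-indicator sub-indices and their unweighted sum for one record."""

    point_id: str
    subindices: dict[str, float]
    total: float
    n_indicators_used: int


def compute_wqi(
    record: MonitoringRecord,
    standards: StandardsTable,
    options: WqiOptions | None = None,
) -> WQIResult:
    """Score one record: dispatch each measurement to its category's
    sub-index rule and sum the sub-indices.

    With ``missing_policy="skip"`` (default) absent indicators are left
    out of the sum and ``n_indicators_used`` reflects only those present;
    ``"strict"`` raises if any standards indicator is unmeasured.
    """
    options = options or WqiOptions()
    if not record.measurements:
        raise EmptyRecordError(f"record {record.point_id!r} has no measurements")
    unknown = [c for c in record.measurements if c not in standards]
    if unknown:
        raise UnknownIndicatorError(
            f"record {record.point_id!r}: no standards entry for {unknown}"
        )
    if options.missing_policy == "strict":
        missing = [c for c in standards.codes if c not in record.measurements]
        if missing:
            raise InvalidMeasurementError(
                f"record {record.point_id!r}: missing indicators {missing} "
                "(strict missing policy)"
            )

    subindices: dict[str, float] = {}
    for code, ci in record.measurements.items():
        entry = standards[code]
        if entry.category == "general":
            subindices[code] = general_subindex(ci, entry.limit)
        elif entry.category == "ph":
            subindices[code] = ph_subindex(ci, mode=options.ph_mode)
        else:
            subindices[code] = microbial_subindex(ci, rule=options.microbial_rule)

    return WQIResult(
        point_id=record.point_id,
        subindices=subindices,
        total=sum(subindices.values()),
        n_indicators_used=len(subindices),
    )


@dataclass
class RecordIssue:
    """A record that failed scoring, with the reason."""

    index: int
    point_id: str
    message: str


@dataclass
class ScoreReport:
    """Batch scoring output: results in input order plus per-record issues."""

    results: list[WQIResult] = field(default_factory=list)
    issues: list[RecordIssue] = field(default_factory=list)


def score_records(
    records: Sequence[MonitoringRecord],
    standards: StandardsTable,
    options: WqiOptions | None = None,
) -> ScoreReport:
    """Score a batch of records; failures are reported, never dropped
    silently.  Result order follows input order for the records that
    scored successfully."""
    report = ScoreReport()
    for i, rec in enumerate(records):
        try:
            report.results.append(compute_wqi(rec, standards, options))
        except Exception as exc:  # collected, not raised: batch semantics
            report.issues.append(RecordIssue(i, rec.point_id, str(exc)))
    return report
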