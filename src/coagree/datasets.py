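"""Record types, CSV input/output and measurement-level quality control.

The unit of observation is one monitor reading of one subject at one time
point (a :class:`MeasurementRecord`).  Two monitors observe each subject:
a thermodilution-calibrated *reference* monitor that repeats its injection
until two consecutive cardiac-index readings agree, and an uncalibrated
pulse-contour *test* monitor whose two simultaneous readings are averaged.
Quality control turns raw records into :class:`PairedSample` objects and
flags (rather than deletes) samples that fail any of three rules:

* the reference injection series never produced two consecutive readings
  within the replicate-discrepancy limit (``replicate_unresolved``);
* the two monitors disagree on systolic pressure by more than the limit,
  relative to the reference reading (``sbp_discrepancy``);
* the test monitor's baseline dP/dt exceeds the resonance limit, which
  flags *every* sample of that subject (``dpdt_exceeded``) because the
  underlying waveform-resonance concern is a property of the catheter,
  not of a single time point.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)


class Timepoint(str, Enum):
    """Study time points, in chronological order."""

    BASELINE = "baseline"
    ROSC15 = "rosc15"
    ROSC30 = "rosc30"
    ROSC60 = "rosc60"

    @property
    def order(self) -> int:
        return TIMEPOINT_ORDER.index(self)


TIMEPOINT_ORDER: tuple[Timepoint, ...] = (
    Timepoint.BASELINE,
    Timepoint.ROSC15,
    Timepoint.ROSC30,
    Timepoint.ROSC60,
)


class Method(str, Enum):
    REFERENCE = "reference"
    TEST = "test"


class QcFlag(str, Enum):
    SBP_DISCREPANCY = "sbp_discrepancy"
    DPDT_EXCEEDED = "dpdt_exceeded"
    REPLICATE_UNRESOLVED = "replicate_unresolved"


#: hemodynamic variables carried by every record, in column order
VARIABLES: tuple[str, ...] = ("ci", "svi", "svri", "svv", "hr", "sbp")

#: variables that must be strictly positive when present
_POSITIVE = ("ci", "svi", "svri", "sbp", "hr")

#: the frozen CSV column layout
COLUMNS: tuple[str, ...] = (
    "subject_id",
    "timepoint",
    "method",
    "replicate_index",
    "ci",
    "svi",
    "svri",
    "svv",
    "hr",
    "sbp",
    "dpdt",
)


@dataclass(frozen=True)
class MeasurementRecord:
    """One monitor reading of one subject at one time point.

    Units: ci L/min/m^2, svi mL/m^2, svri dyn.s.cm^-5.m^-2, svv percent,
    hr beats/min, sbp mmHg; dpdt is the dimensionless maximal
    pressure/time ratio reported only by the test monitor.
    """

    subject_id: str
    timepoint: Timepoint
    method: Method
    replicate_index: int
    ci: float | None = None
    svi: float | None = None
    svri: float | None = None
    svv: float | None = None
    hr: float | None = None
    sbp: float | None = None
    dpdt: float | None = None

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be a positive integer, got {self.replicate_index}"
            )
        for name in _POSITIVE:
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")
        if self.svv is not None and not (0.0 <= self.svv <= 100.0):
            raise ValidationError(f"svv must lie in [0, 100], got {self.svv}")

    @property
    def key(self) -> tuple[str, Timepoint, Method, int]:
        return (self.subject_id, self.timepoint, self.method, self.replicate_index)


@dataclass(frozen=True)
class QcPolicy:
    """Measurement-level quality-control limits.

    ``replicate_discrepancy_limit`` is the maximal relative discrepancy
    (|a-b| / pair mean) between two consecutive reference injections;
    ``sbp_discrepancy_limit`` is the maximal inter-monitor systolic
    pressure disagreement relative to the reference reading;
    ``dpdt_limit`` is the waveform-resonance bound on the test monitor's
    baseline dP/dt; ``max_replicate_draws`` caps how many injections are
    scanned before a group is declared unresolved.
    """

    replicate_discrepancy_limit: float = 0.10
    sbp_discrepancy_limit: float = 0.10
    dpdt_limit: float = 1.7
    max_replicate_draws: int = 6

    def __post_init__(self) -> None:
        for name in ("replicate_discrepancy_limit", "sbp_discrepancy_limit", "dpdt_limit"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"QcPolicy.{name} must be strictly positive")
        if self.max_replicate_draws < 1:
            raise ValidationError("QcPolicy.max_replicate_draws must be >= 1")


@dataclass(frozen=True)
class ResolvedSummary:
    """Replicate-resolved per-(subject, timepoint, method) summary values."""

    subject_id: str
    timepoint: Timepoint
    method: Method
    values: Mapping[str, float | None]
    resolved: bool
    n_replicates: int
    replicate_pair: tuple[int, ...] = ()


@dataclass(frozen=True)
class PairedSample:
    """QC-annotated reference/test value pair for one subject x time point."""

    subject_id: str
    timepoint: Timepoint
    ref: Mapping[str, float | None]
    test: Mapping[str, float | None]
    qc_flags: frozenset[QcFlag] = frozenset()

    @property
    def is_clean(self) -> bool:
        return not self.qc_flags


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path) -> list[MeasurementRecord]:
    """Read a measurement CSV and return validated records.

    Raises :class:`SchemaError` when a mandatory column is missing and
    :class:`ValidationError` (listing line numbers and fields) when any
    row is malformed.  A header-only file yields an empty list.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: file is empty (no header row)")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

        records: list[MeasurementRecord] = []
        problems: list[str] = []
        seen: set[tuple] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                record = _parse_row(row)
            except ValidationError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            if record.key in seen:
                problems.append(f"line {lineno}: duplicate key {record.key}")
                continue
            seen.add(record.key)
            records.append(record)
        if problems:
            raise ValidationError(f"{path}: {len(problems)} malformed row(s): " + "; ".join(problems))
    return records


def _parse_row(row: Mapping[str, str]) -> MeasurementRecord:
    def number(name: str) -> float | None:
        raw = (row.get(name) or "").strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(f"field {name!r}: not a number: {raw!r}") from None

    try:
        timepoint = Timepoint(row["timepoint"].strip())
    except ValueError:
        raise ValidationError(f"field 'timepoint': unknown value {row['timepoint']!r}") from None
    try:
        method = Method(row["method"].strip())
    except ValueError:
        raise ValidationError(f"field 'method': unknown value {row['method']!r}") from None
    raw_index = (row.get("replicate_index") or "").strip()
    try:
        replicate_index = int(raw_index)
    except ValueError:
        raise ValidationError(f"field 'replicate_index': not an integer: {raw_index!r}") from None

    return MeasurementRecord(
        subject_id=row["subject_id"].strip(),
        timepoint=timepoint,
        method=method,
        replicate_index=replicate_index,
        ci=number("ci"),
        svi=number("svi"),
        svri=number("svri"),
        svv=number("svv"),
        hr=number("hr"),
        sbp=number("sbp"),
        dpdt=number("dpdt"),
    )


def write_dataset(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write records to CSV in the frozen column layout.

    Floats are written with ``repr`` so a write/read round trip
    reproduces values exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COLUMNS)
        for record in records:
            row = []
            for name in COLUMNS:
                value = getattr(record, name)
                if value is None:
                    row.append("")
                elif isinstance(value, Enum):
                    row.append(value.value)
                elif isinstance(value, float):
                    row.append(repr(value))
                else:
                    row.append(str(value))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Replicate resolution and pairing
# ---------------------------------------------------------------------------

def _summarise(replicates: Sequence[MeasurementRecord], indices: Sequence[int]) -> dict[str, float | None]:
    """Mean of each variable over the replicates at the given positions."""
    chosen = [replicates[i] for i in indices]
    out: dict[str, float | None] = {}
    for name in VARIABLES + ("dpdt",):
        values = [getattr(r, name) for r in chosen if getattr(r, name) is not None]
        out[name] = sum(values) / len(values) if values else None
    return out


def _resolve_group(
    replicates: Sequence[MeasurementRecord],
    policy: QcPolicy,
    apply_discrepancy_rule: bool,
) -> ResolvedSummary:
    replicates = sorted(replicates, key=lambda r: r.replicate_index)
    first = replicates[0]
    if len(replicates) == 1:
        return ResolvedSummary(
            first.subject_id, first.timepoint, first.method,
            _summarise(replicates, [0]), resolved=True, n_replicates=1,
            replicate_pair=(first.replicate_index,),
        )

    if not apply_discrepancy_rule:
        # plain two-reading averaging (the test monitor's protocol)
        return ResolvedSummary(
            first.subject_id, first.timepoint, first.method,
            _summarise(replicates, [0, 1]), resolved=True, n_replicates=len(replicates),
            replicate_pair=(replicates[0].replicate_index, replicates[1].replicate_index),
        )

    n_scan = min(len(replicates), policy.max_replicate_draws)
    for i in range(n_scan - 1):
        a, b = replicates[i].ci, replicates[i + 1].ci
        if a is None or b is None:
            continue
        mean = (a + b) / 2.0
        if mean > 0 and abs(a - b) / mean <= policy.replicate_discrepancy_limit:
            return ResolvedSummary(
                first.subject_id, first.timepoint, first.method,
                _summarise(replicates, [i, i + 1]), resolved=True,
                n_replicates=len(replicates),
                replicate_pair=(replicates[i].replicate_index, replicates[i + 1].replicate_index),
            )
    return ResolvedSummary(
        first.subject_id, first.timepoint, first.method,
        _summarise(replicates, [0, 1]), resolved=False, n_replicates=len(replicates),
        replicate_pair=(replicates[0].replicate_index, replicates[1].replicate_index),
    )


def resolve_replicates(
    records: Iterable[MeasurementRecord],
    policy: QcPolicy | None = None,
) -> dict[tuple[str, Timepoint, Method], ResolvedSummary]:
    """Collapse replicate readings into one summary per (subject, timepoint, method).

    For the reference method the cardiac-index series is scanned in
    replicate order for the first *consecutive* pair whose relative
    discrepancy (|a-b| / pair mean) is within the policy limit; the
    summary is the mean of that pair (all variables averaged over the
    same two replicates).  If no pair within ``max_replicate_draws``
    replicates qualifies, the group is marked unresolved (a status, not
    an error) and summarised by its first two replicates.  For the test
    method the summary is simply the mean of the first two readings, per
    the study protocol.  A single replicate resolves to itself.
    """
    policy = policy or QcPolicy()
    groups: dict[tuple[str, Timepoint, Method], list[MeasurementRecord]] = defaultdict(list)
    for record in records:
        groups[(record.subject_id, record.timepoint, record.method)].append(record)
    return {
        key: _resolve_group(reps, policy, apply_discrepancy_rule=(key[2] is Method.REFERENCE))
        for key, reps in groups.items()
    }


def pair_and_filter(
    records: Iterable[MeasurementRecord],
    policy: QcPolicy | None = None,
) -> list[PairedSample]:
    """Pair reference/test summaries and attach quality-control flags.

    Flagged samples are retained (so decisions remain reversible) but
    carry a non-empty ``qc_flags`` set and are skipped by the analysis
    stages.  A (subject, timepoint) with only one method is skipped with
    a logged warning.
    """
    policy = policy or QcPolicy()
    summaries = resolve_replicates(records, policy)

    by_pair: dict[tuple[str, Timepoint], dict[Method, ResolvedSummary]] = defaultdict(dict)
    for (subject, timepoint, method), summary in summaries.items():
        by_pair[(subject, timepoint)][method] = summary

    # subjects whose baseline test dP/dt exceeds the resonance limit
    dpdt_subjects: set[str] = set()
    for (subject, timepoint), pair in by_pair.items():
        if timepoint is Timepoint.BASELINE and Method.TEST in pair:
            dpdt = pair[Method.TEST].values.get("dpdt")
            if dpdt is not None and dpdt > policy.dpdt_limit:
                dpdt_subjects.add(subject)

    samples: list[PairedSample] = []
    order = {tp: i for i, tp in enumerate(TIMEPOINT_ORDER)}
    for (subject, timepoint) in sorted(by_pair, key=lambda k: (k[0], order[k[1]])):
        pair = by_pair[(subject, timepoint)]
        if Method.REFERENCE not in pair or Method.TEST not in pair:
            present = next(iter(pair)).value
            logger.warning(
                "subject %s at %s has only the %s method; skipped",
                subject, timepoint.value, present,
            )
            continue
        ref, test = pair[Method.REFERENCE], pair[Method.TEST]
        flags: set[QcFlag] = set()
        if not ref.resolved or not test.resolved:
            flags.add(QcFlag.REPLICATE_UNRESOLVED)
        sbp_ref, sbp_test = ref.values.get("sbp"), test.values.get("sbp")
        if sbp_ref is not None and sbp_test is not None:
            if abs(sbp_ref - sbp_test) / sbp_ref > policy.sbp_discrepancy_limit:
                flags.add(QcFlag.SBP_DISCREPANCY)
        if subject in dpdt_subjects:
            flags.add(QcFlag.DPDT_EXCEEDED)
        samples.append(
            PairedSample(subject, timepoint, dict(ref.values), dict(test.values), frozenset(flags))
        )
    return samples


def clean_samples(samples: Iterable[PairedSample]) -> list[PairedSample]:
    """The analysis-ready subset: samples with no QC flags."""
    return [s for s in samples if s.is_clean]


def qc_summary(samples: Iterable[PairedSample]) -> dict[str, int]:
    """Counts of pairs per QC outcome (a pair may carry several flags)."""
    samples = list(samples)
    counts = {"n_pairs": len(samples), "n_clean": sum(s.is_clean for s in samples)}
    for flag in QcFlag:
        counts[flag.value] = sum(flag in s.qc_flags for s in samples)
    return counts


def samples_to_frame(samples: Iterable[PairedSample], clean_only: bool = True) -> pd.DataFrame:
    """Tidy DataFrame with one row per paired sample (ref_*/test_* columns)."""
    rows = []
    for s in samples:
        if clean_only and not s.is_clean:
            continue
        row: dict[str, object] = {"subject_id": s.subject_id, "timepoint": s.timepoint.value}
        for name in VARIABLES:
            row[f"ref_{name}"] = s.ref.get(name)
            row[f"test_{name}"] = s.test.get(name)
        row["qc_flags"] = ",".join(sorted(f.value for f in s.qc_flags))
        rows.append(row)
    columns = ["subject_id", "timepoint"]
    for name in VARIABLES:
        columns += [f"ref_{name}", f"test_{name}"]
    columns.append("qc_flags")
    return pd.DataFrame(rows, columns=columns)
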