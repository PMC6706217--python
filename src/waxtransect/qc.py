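"""Replicate-based measurement QC and outlier flagging.

Repeated measurements of the same physical sample (lab re-runs and field
splits alike) share a ``replicate_group``.  The coefficient of variance
(CV = 100 · SD / mean, n−1 denominator) across a group separates
quantities dominated by instrument/extraction noise (absolute per-chain
concentrations) from quantities that are robust because the noise largely
cancels (ACL, ratio, anything built from relative abundances).

Outlier flagging makes the "abnormally small compared to similar samples
at the same site" judgement explicit: within each (species × site) group
of at least 3 records, a value is flagged when its distance from the group
median exceeds k times the scaled MAD (median absolute deviation × 1.4826,
the factor that makes MAD estimate a normal SD).  Flags are advisory;
actual exclusion requires either an explicit exclusion list or an
auto-exclude opt-in, so the analyst's judgement stays in the loop and on
the record.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .core_model import AlkaneProfile, ChainWindow, MetricRecord
from .errors import UndefinedMetricError, UnknownIdentifierError
from .metrics import compute_acl, compute_ratio

__all__ = [
    "ReplicateReport",
    "OutlierFlag",
    "Exclusion",
    "replicate_cv",
    "replicate_report_frame",
    "flag_outliers",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

#: Scale factor making the MAD a consistent estimator of a normal SD.
MAD_SCALE = 1.4826

#: Quantities summarised per replicate group, besides per-chain concentrations.
SUMMARY_QUANTITIES = ("total_concentration", "acl", "ratio")


@dataclass(frozen=True)
class ReplicateReport:
    """Coefficients of variance (%) across one replicate group.

    ``cv_pct`` maps a quantity name — ``total_concentration``, ``acl``,
    ``ratio`` or a chain column like ``C29`` — to its CV, or to ``None``
    when undefined (mean zero, or the quantity undefined for a member);
    ``reasons`` explains each ``None``.
    """

    replicate_group: str
    n_measurements: int
    cv_pct: dict[str, float | None]
    reasons: dict[str, str]


@dataclass(frozen=True)
class OutlierFlag:
    """Advisory flag for one suspect value within a (species × site) group."""

    sample_id: str
    species: str
    site_id: str
    response: str
    value: float
    robust_z: float


@dataclass(frozen=True)
class Exclusion:
    """One entry of an exclusion list: which sample to remove and why.

    ``response`` records which quantity triggered the decision; the sample
    is removed from all analysis, matching how transect studies treat
    suspect measurements.
    """

    sample_id: str
    response: str = "*"
    reason: str = "manual exclusion"


def _cv(values: Sequence[float]) -> tuple[float | None, str | None]:
    n = len(values)
    mean = sum(values) / n
    if mean == 0:
        return None, "mean is zero"
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return 100.0 * sd / abs(mean), None


def replicate_cv(
    profiles: Sequence[AlkaneProfile], window: ChainWindow | None = None
) -> list[ReplicateReport]:
    """Per-group CVs of total concentration, per-chain concentration, ACL
    and ratio.

    Groups with fewer than two measurements are ignored; no groups at all
    yields an empty list with a logged warning.  CV is invariant under
    rescaling all of a group's values by a positive constant.
    """
    window = window or ChainWindow.default()
    groups: dict[str, list[AlkaneProfile]] = defaultdict(list)
    for p in profiles:
        if p.replicate_group:
            groups[p.replicate_group].append(p)
    groups = {g: ms for g, ms in groups.items() if len(ms) >= 2}
    if not groups:
        logger.warning("no replicate groups with >= 2 measurements")
        return []

    reports = []
    for g in sorted(groups):
        members = groups[g]
        cv_pct: dict[str, float | None] = {}
        reasons: dict[str, str] = {}

        def record(name: str, values: list[float] | None, why: str | None = None):
            if values is None:
                cv_pct[name] = None
                reasons[name] = why or "undefined"
                return
            cv, reason = _cv(values)
            cv_pct[name] = cv
            if reason:
                reasons[name] = reason

        record("total_concentration", [m.total_concentration for m in members])
        for n in window:
            record(f"C{n}", [m.conc.get(n, 0.0) for m in members])
        try:
            record("acl", [compute_acl(m, window) for m in members])
        except UndefinedMetricError:
            record("acl", None, "ACL undefined for a group member")
        try:
            record("ratio", [compute_ratio(m) for m in members])
        except UndefinedMetricError:
            record("ratio", None, "ratio undefined for a group member")
        reports.append(
            ReplicateReport(
                replicate_group=g,
                n_measurements=len(members),
                cv_pct=cv_pct,
                reasons=reasons,
            )
        )
    return reports


def replicate_report_frame(reports: Sequence[ReplicateReport]) -> pd.DataFrame:
    """Long-format QC table: one row per group × quantity."""
    rows = []
    for r in reports:
        for q, cv in r.cv_pct.items():
            rows.append(
                {
                    "replicate_group": r.replicate_group,
                    "n_measurements": r.n_measurements,
                    "quantity": q,
                    "cv_pct": float("nan") if cv is None else cv,
                    "reason": r.reasons.get(q, ""),
                }
            )
    return pd.DataFrame(
        rows, columns=["replicate_group", "n_measurements", "quantity", "cv_pct", "reason"]
    )


def _response_value(record: MetricRecord, response: str) -> float | None:
    if response == "acl":
        return record.acl
    if response == "ratio":
        return record.ratio
    if response.startswith("C") and response[1:].isdigit():
        rel = record.rel_abund.get(int(response[1:]))
        return None if rel is None else 100.0 * rel
    raise UnknownIdentifierError(
        f"unknown response '{response}'; expected 'acl', 'ratio' or a chain column like 'C29'"
    )


def flag_outliers(
    records: Sequence[MetricRecord], response: str, k: float = 3.0
) -> list[OutlierFlag]:
    """Robust within-(species × site) outlier flags for one response.

    A value is flagged when ``|value − median| > k · 1.4826 · MAD`` in its
    (species × site) group, for groups with at least 3 defined values.
    When the MAD is zero only values differing from the median can be
    flagged, so an all-equal group never flags.  Pure function — flagging
    is idempotent and the input records are untouched.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    groups: dict[tuple[str, str], list[tuple[MetricRecord, float]]] = defaultdict(list)
    for r in records:
        if r.excluded:
            continue
        v = _response_value(r, response)
        if v is not None and math.isfinite(v):
            groups[(r.species, r.site_id)].append((r, v))

    flags = []
    for (species, site_id), pairs in sorted(groups.items()):
        if len(pairs) < 3:
            continue
        values = sorted(v for _, v in pairs)
        med = _median(values)
        mad = _median(sorted(abs(v - med) for v in values))
        scale = MAD_SCALE * mad
        for rec, v in pairs:
            dev = abs(v - med)
            if dev > k * scale:
                z = math.inf if scale == 0 else dev / scale
                flags.append(
                    OutlierFlag(
                        sample_id=rec.sample_id,
                        species=species,
                        site_id=site_id,
                        response=response,
                        value=v,
                        robust_z=z,
                    )
                )
    return flags


def _median(sorted_values: Sequence[float]) -> float:
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return sorted_values[mid]
    return 0.5 * (sorted_values[mid - 1] + sorted_values[mid])


def apply_exclusions(
    records: Sequence[MetricRecord], exclusions: Iterable[Exclusion]
) -> list[MetricRecord]:
    """Return records with ``excluded`` set for every listed sample.

    Idempotent; re-excluding an already-excluded record keeps one reason.
    Unknown sample ids raise :class:`UnknownIdentifierError` listing them.
    """
    exclusions = list(exclusions)
    by_id = {r.sample_id for r in records}
    unknown = sorted({e.sample_id for e in exclusions} - by_id)
    if unknown:
        raise UnknownIdentifierError(
            f"exclusion list references unknown sample_id(s): {', '.join(unknown)}"
        )
    reason_for = {}
    for e in exclusions:
        reason_for.setdefault(e.sample_id, f"{e.reason} (response: {e.response})")
    out = []
    for r in records:
        if r.sample_id in reason_for and not r.excluded:
            out.append(
                replace(r, excluded=True, exclusion_reason=reason_for[r.sample_id])
            )
        else:
            out.append(r)
    return out
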