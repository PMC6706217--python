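"""Chain-length metrics: ACL, the C31/(C31+C29) ratio, species summaries.

The average chain length (ACL) is the concentration-weighted mean carbon
number over a homolog window::

    ACL = sum(C_n * n) / sum(C_n)

where ``C_n`` is the concentration of the n-alkane with ``n`` carbon atoms.
The literal sum runs over every measured homolog, even and odd; the
``odd_only`` switch restricts it to odd chains, the convention common in the
leaf-wax literature.  The default window is C23-C33, the range the data
cover.

The ratio C31/(C31+C29) contrasts the two homologs that dominate most
higher-plant waxes; as a fraction of one it is bounded, easy to interpret
and variance-standardised.  Higher values mean longer-chain dominance.

Both metrics are invariant under rescaling all concentrations, so they can
be computed indifferently on concentrations or relative abundances.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import AlkaneProfile, ChainWindow, MetricRecord
from .errors import UndefinedMetricError, UnknownIdentifierError
from .quantification import to_relative_abundance

__all__ = [
    "compute_acl",
    "compute_ratio",
    "compute_metrics",
    "records_to_frame",
    "species_mean_distribution",
    "odd_even_preference",
]


def compute_acl(
    profile: AlkaneProfile,
    window: ChainWindow | None = None,
    *,
    odd_only: bool = False,
) -> float:
    """Concentration-weighted mean carbon number over ``window``.

    Bounded by the smallest and largest carbon number with positive
    concentration in the window; raises :class:`UndefinedMetricError` when
    the window total is zero.
    """
    window = window or ChainWindow.default()
    carbons = window.odd if odd_only else window.carbons
    num = 0.0
    den = 0.0
    for n in carbons:
        c = profile.conc.get(n, 0.0)
        num += c * n
        den += c
    if den <= 0:
        raise UndefinedMetricError(
            f"sample '{profile.sample_id}': zero total concentration over "
            f"window C{carbons[0]}-C{carbons[-1]}; ACL undefined"
        )
    return num / den


def compute_ratio(profile: AlkaneProfile) -> float:
    """C31 / (C31 + C29), a fraction in [0, 1].

    Strictly increasing in C31 and decreasing in C29; undefined (raises)
    when both are zero.
    """
    c29 = profile.conc.get(29, 0.0)
    c31 = profile.conc.get(31, 0.0)
    if c29 + c31 <= 0:
        raise UndefinedMetricError(
            f"sample '{profile.sample_id}': C29 + C31 == 0; ratio undefined"
        )
    return c31 / (c31 + c29)


def compute_metrics(
    profiles: Sequence[AlkaneProfile],
    window: ChainWindow | None = None,
    *,
    odd_only: bool = False,
) -> list[MetricRecord]:
    """Derive relative abundances, ACL and the ratio for each profile.

    A profile whose C29 and C31 are both zero gets ``ratio = None`` and is
    flagged (not dropped); correlation stages skip the missing value and
    report the reduced n.  Profiles with zero total concentration cannot be
    standardised and raise :class:`UndefinedMetricError`.
    """
    window = window or ChainWindow.default()
    records = []
    for p in profiles:
        rel = to_relative_abundance(p)
        acl = compute_acl(p, window, odd_only=odd_only)
        try:
            ratio: float | None = compute_ratio(p)
            reason = None
        except UndefinedMetricError:
            ratio = None
            reason = "ratio undefined (C29 + C31 == 0)"
        records.append(
            MetricRecord(
                sample_id=p.sample_id,
                species=p.species,
                site_id=p.site_id,
                replicate_group=p.replicate_group,
                rel_abund=rel,
                acl=acl,
                ratio=ratio,
                exclusion_reason=reason,
            )
        )
    return records


def records_to_frame(
    records: Sequence[MetricRecord], window: ChainWindow | None = None
) -> pd.DataFrame:
    """Tabulate metric records; relative abundances appear as percentage
    columns ``C23`` ... ``C33``."""
    window = window or ChainWindow.default()
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "species": r.species,
            "site_id": r.site_id,
            "replicate_group": r.replicate_group,
            "acl": r.acl,
            "ratio": float("nan") if r.ratio is None else r.ratio,
        }
        for n in window:
            rel = r.rel_abund.get(n)
            row[f"C{n}"] = float("nan") if rel is None else 100.0 * rel
        row["excluded"] = r.excluded
        row["exclusion_reason"] = r.exclusion_reason or ""
        rows.append(row)
    return pd.DataFrame(rows)


def species_mean_distribution(
    records: Sequence[MetricRecord],
    species: str,
    window: ChainWindow | None = None,
) -> pd.DataFrame:
    """Per-chain mean and sample SD of relative abundance (%) for one
    species across the transect, excluding flagged records.

    Returns a frame with columns ``carbon_number``, ``mean_pct``, ``sd_pct``
    and ``n`` (the same measurement count for every chain).  Means sum to
    100%; SD uses the n-1 denominator, with SD = 0 for a single record.
    """
    window = window or ChainWindow.default()
    known = sorted({r.species for r in records})
    if species not in known:
        raise UnknownIdentifierError(
            f"unknown species '{species}'; known species: {', '.join(known)}"
        )
    used = [r for r in records if r.species == species and not r.excluded]
    if not used:
        raise UnknownIdentifierError(
            f"species '{species}' has no non-excluded records"
        )
    n = len(used)
    rows = []
    for c in window:
        vals = [100.0 * r.rel_abund.get(c, 0.0) for r in used]
        mean = sum(vals) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        else:
            sd = 0.0
        rows.append({"carbon_number": c, "mean_pct": mean, "sd_pct": sd, "n": n})
    return pd.DataFrame(rows)


def odd_even_preference(
    profile: AlkaneProfile, window: ChainWindow | None = None
) -> dict[int, bool]:
    """Flag, for each odd chain in the window, whether its concentration
    strictly exceeds both adjacent even chains that are present.

    A missing neighbour is vacuously satisfied, so an odd chain with no
    measured even neighbours is flagged True.  Equal concentrations fail
    the strict comparison, so a flat profile has all flags False... except
    when no even neighbour was measured at all.
    """
    window = window or ChainWindow.default()
    flags: dict[int, bool] = {}
    for n in window.odd:
        ok = True
        for m in (n - 1, n + 1):
            if m in window.carbons and m in profile.conc:
                if not profile.conc.get(n, 0.0) > profile.conc[m]:
                    ok = False
        flags[n] = ok
    return flags
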