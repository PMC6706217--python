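"""Domain types and delimited-table I/O for leaf-wax n-alkane transect data.

The analysis revolves around three tables:

* ``profiles.csv`` — one row per measurement: sample identity, species, site,
  optional replicate group, dry leaf mass (g) and one concentration column per
  n-alkane homolog, named ``C23`` ... ``C33`` (µg per g dry leaf).
* ``sites.csv`` — one row per site: elevation (m a.s.l.), mean annual
  temperature (°C), mean relative air humidity (%), mean annual
  precipitation (mm/yr).
* derived outputs (metrics, correlations, QC) written by the other modules.

Tables are UTF-8, comma-delimited with a ``.`` decimal separator by default;
every writer prefixes a ``#`` metadata header line and every reader skips
``#`` comment lines, so outputs round-trip through the same readers.

A chain column that is absent from a profile table means "not measured",
which is distinct from a recorded value of 0 ("below detection").  The
``absent_as_zero`` flag collapses the two, filling the default C23-C33
window with zeros.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CHAIN_MIN",
    "CHAIN_MAX",
    "ChainWindow",
    "AlkaneProfile",
    "SiteEnvironment",
    "MetricRecord",
    "CorrelationResult",
    "read_profiles",
    "write_profiles",
    "read_environment",
    "write_environment",
    "join_dataset",
    "sites_frame",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

#: Leaf-wax n-alkanes of higher plants fall between C20 and C37.
CHAIN_MIN = 20
CHAIN_MAX = 37

_CHAIN_COL_RE = re.compile(r"^C(\d+)$")

PROFILE_COLUMNS = ("sample_id", "species", "site_id", "replicate_group", "dry_mass_g")
SITE_COLUMNS = ("site_id", "elevation_m", "mat_c", "rh_pct", "map_mm")


@dataclass(frozen=True)
class ChainWindow:
    """An ordered window of n-alkane carbon numbers.

    The default window is C23-C33 inclusive, the homolog range in which
    leaf-wax n-alkanes are routinely identified on a GC-MS full-scan run.
    """

    carbons: tuple[int, ...]

    def __post_init__(self) -> None:
        carbons = tuple(int(c) for c in self.carbons)
        object.__setattr__(self, "carbons", carbons)
        if not carbons:
            raise ValidationError("ChainWindow must contain at least one carbon number")
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValidationError(f"carbon numbers must be strictly increasing: {carbons}")
        bad = [c for c in carbons if not (CHAIN_MIN <= c <= CHAIN_MAX)]
        if bad:
            raise ValidationError(
                f"carbon numbers {bad} outside the leaf-wax range [{CHAIN_MIN}, {CHAIN_MAX}]"
            )

    @classmethod
    def default(cls) -> "ChainWindow":
        return cls(tuple(range(23, 34)))

    @property
    def odd(self) -> tuple[int, ...]:
        return tuple(c for c in self.carbons if c % 2 == 1)

    @property
    def even(self) -> tuple[int, ...]:
        return tuple(c for c in self.carbons if c % 2 == 0)

    @property
    def columns(self) -> tuple[str, ...]:
        """Table column names, ``C23`` style."""
        return tuple(f"C{c}" for c in self.carbons)

    def __iter__(self):
        return iter(self.carbons)

    def __len__(self) -> int:
        return len(self.carbons)


@dataclass(frozen=True)
class AlkaneProfile:
    """Per-carbon-number n-alkane concentrations of one measurement.

    Concentrations are µg per g dry leaf (already standardised by the dry
    mass used for extraction).  ``replicate_group`` is shared by repeated
    measurements of the same physical sample and is ``None`` for samples
    measured once.
    """

    sample_id: str
    species: str
    site_id: str
    dry_mass_g: float
    conc: Mapping[int, float]
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.dry_mass_g is None or not self.dry_mass_g > 0:
            raise ValidationError(
                f"sample '{self.sample_id}': dry_mass_g must be > 0, got {self.dry_mass_g}"
            )
        conc = {int(k): float(v) for k, v in self.conc.items()}
        object.__setattr__(self, "conc", conc)
        for n, v in conc.items():
            if not (CHAIN_MIN <= n <= CHAIN_MAX):
                raise ValidationError(
                    f"sample '{self.sample_id}': carbon number {n} outside [{CHAIN_MIN}, {CHAIN_MAX}]"
                )
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"sample '{self.sample_id}': concentration for C{n} must be finite and >= 0, got {v}"
                )

    @property
    def total_concentration(self) -> float:
        """Total n-alkane concentration, µg/g dry leaf."""
        return float(sum(self.conc.values()))

    def with_conc(self, conc: Mapping[int, float]) -> "AlkaneProfile":
        return replace(self, conc=dict(conc))


@dataclass(frozen=True)
class SiteEnvironment:
    """One site's elevation and the three environmental covariates."""

    site_id: str
    elevation_m: float
    mat_c: float    # mean annual temperature, °C
    rh_pct: float   # mean relative air humidity, %
    map_mm: float   # mean annual precipitation, mm/yr

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValidationError(
                f"site '{self.site_id}': rh_pct must lie in [0, 100], got {self.rh_pct}"
            )
        if self.map_mm < 0:
            raise ValidationError(
                f"site '{self.site_id}': map_mm must be >= 0, got {self.map_mm}"
            )


@dataclass
class MetricRecord:
    """Derived per-sample quantities: relative abundances, ACL, ratio.

    ``rel_abund`` maps carbon number to the fraction of total concentration
    (values sum to 1).  ``ratio`` is ``None`` when C29 + C31 == 0, in which
    case the record is flagged rather than dropped.  ``excluded`` marks
    records removed from all downstream analysis (outliers).
    """

    sample_id: str
    species: str
    site_id: str
    rel_abund: dict[int, float]
    acl: float
    ratio: float | None
    replicate_group: str | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """One (group × response × environmental variable) Spearman outcome.

    ``group`` is a species name or ``"site_total"``; ``rs`` and ``p`` are
    ``None`` for undefined correlations (zero variance, too few points),
    with ``reason`` saying why.
    """

    group: str
    response: str
    env_var: str
    n: int
    rs: float | None
    p: float | None
    significant: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    *,
    delimiter: str = ",",
) -> None:
    """Write ``frame`` as a delimited table with a ``#`` metadata header."""
    from . import __version__

    items = {"waxtransect": f"v{__version__}"}
    if metadata:
        items.update(metadata)
    header = "# " + ", ".join(
        v if k == "waxtransect" else f"{k}={v}" for k, v in items.items()
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, sep=delimiter, index=False)


def read_table(path: str | Path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited table, skipping ``#`` metadata/comment lines."""
    return pd.read_csv(
        path, sep=delimiter, comment="#", encoding="utf-8",
        float_precision="round_trip",
    )


def _chain_columns(columns: Iterable[str]) -> dict[str, int]:
    """Map chain column names (``C23``...) to carbon numbers, sorted."""
    found: dict[str, int] = {}
    for col in columns:
        m = _CHAIN_COL_RE.match(str(col))
        if m:
            found[col] = int(m.group(1))
    return dict(sorted(found.items(), key=lambda kv: kv[1]))


def read_profiles(
    path: str | Path,
    *,
    delimiter: str = ",",
    absent_as_zero: bool = False,
    errors: str = "raise",
) -> list[AlkaneProfile] | tuple[list[AlkaneProfile], list[tuple[int, str, str]]]:
    """Read an n-alkane profile table.

    Parameters
    ----------
    path
        Delimited file with header columns ``sample_id``, ``species``,
        ``site_id``, ``replicate_group`` (may be empty), ``dry_mass_g`` and
        one column per carbon number (``C23`` ... ``C33``).
    absent_as_zero
        Treat chain columns missing from the table (within the default
        C23-C33 window) and empty cells as concentration 0 instead of
        "not measured".
    errors
        ``"raise"`` (default) raises :class:`ValidationError` on the first
        bad row; ``"collect"`` returns ``(profiles, invalid)`` where
        ``invalid`` is a list of ``(row_index, sample_id, message)``.

    Unknown columns are ignored with a logged warning; row order is
    preserved.
    """
    if errors not in ("raise", "collect"):
        raise ValueError(f"errors must be 'raise' or 'collect', got {errors!r}")
    df = read_table(path, delimiter=delimiter)
    mandatory = ["sample_id", "species", "site_id", "dry_mass_g"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    chain_cols = _chain_columns(df.columns)
    known = set(mandatory) | {"replicate_group"} | set(chain_cols)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", path, ", ".join(unknown))
    if not chain_cols and not absent_as_zero:
        raise FormatError(f"{path}: no chain concentration columns (C23...C33) found")

    window = ChainWindow.default()
    profiles: list[AlkaneProfile] = []
    invalid: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        sample_id = str(row["sample_id"])
        conc: dict[int, float] = {}
        for col, n in chain_cols.items():
            v = row[col]
            if pd.isna(v):
                if absent_as_zero:
                    conc[n] = 0.0
                continue  # structurally absent: not measured
            conc[n] = float(v)
        if absent_as_zero:
            for n in window:
                conc.setdefault(n, 0.0)
        rg = row.get("replicate_group")
        rg = None if (rg is None or pd.isna(rg) or str(rg) == "") else str(rg)
        try:
            profiles.append(
                AlkaneProfile(
                    sample_id=sample_id,
                    species=str(row["species"]),
                    site_id=str(row["site_id"]),
                    dry_mass_g=float(row["dry_mass_g"]),
                    conc=conc,
                    replicate_group=rg,
                )
            )
        except (ValidationError, ValueError) as exc:
            if errors == "raise":
                raise ValidationError(str(exc)) from exc
            invalid.append((int(idx), sample_id, str(exc)))
    if errors == "collect":
        return profiles, invalid
    return profiles


def write_profiles(
    profiles: Sequence[AlkaneProfile],
    path: str | Path,
    *,
    delimiter: str = ",",
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write profiles as a table; chains never measured in any profile are
    omitted entirely (structural absence survives the round trip)."""
    carbons = sorted({n for p in profiles for n in p.conc})
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "species": p.species,
            "site_id": p.site_id,
            "replicate_group": p.replicate_group or "",
            "dry_mass_g": p.dry_mass_g,
        }
        for n in carbons:
            row[f"C{n}"] = p.conc.get(n, "")
        rows.append(row)
    columns = list(PROFILE_COLUMNS) + [f"C{n}" for n in carbons]
    frame = pd.DataFrame(rows, columns=columns)
    write_table(frame, path, metadata, delimiter=delimiter)


def read_environment(
    path: str | Path, *, delimiter: str = ","
) -> list[SiteEnvironment]:
    """Read the per-site environment table (one record per site).

    Duplicate ``site_id`` values raise :class:`ValidationError`; a file with
    only a header yields an empty list with a logged warning.
    """
    df = read_table(path, delimiter=delimiter)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    dupes = df["site_id"].astype(str)[df["site_id"].astype(str).duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{path}: duplicate site_id(s): {', '.join(map(str, dupes))}")
    if df.empty:
        logger.warning("%s: site table is empty", path)
        return []
    return [
        SiteEnvironment(
            site_id=str(r.site_id),
            elevation_m=float(r.elevation_m),
            mat_c=float(r.mat_c),
            rh_pct=float(r.rh_pct),
            map_mm=float(r.map_mm),
        )
        for r in df.itertuples(index=False)
    ]


def write_environment(
    sites: Sequence[SiteEnvironment],
    path: str | Path,
    *,
    delimiter: str = ",",
    metadata: Mapping[str, object] | None = None,
) -> None:
    write_table(sites_frame(sites), path, metadata, delimiter=delimiter)


def sites_frame(sites: Sequence[SiteEnvironment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "elevation_m": s.elevation_m,
                "mat_c": s.mat_c,
                "rh_pct": s.rh_pct,
                "map_mm": s.map_mm,
            }
            for s in sites
        ],
        columns=list(SITE_COLUMNS),
    )


def join_dataset(
    profiles: Sequence[AlkaneProfile], sites: Sequence[SiteEnvironment]
) -> pd.DataFrame:
    """Join profiles with their site covariates, one row per profile.

    Every ``profile.site_id`` must exist in ``sites``; orphans raise
    :class:`ValidationError` listing the offending site ids.  Concentration
    values are carried through unchanged.
    """
    site_map = {s.site_id: s for s in sites}
    orphans = sorted({p.site_id for p in profiles} - set(site_map))
    if orphans:
        raise ValidationError(f"profiles reference unknown site_id(s): {', '.join(orphans)}")
    carbons = sorted({n for p in profiles for n in p.conc})
    rows = []
    for p in profiles:
        s = site_map[p.site_id]
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "species": p.species,
            "site_id": p.site_id,
            "replicate_group": p.replicate_group,
            "dry_mass_g": p.dry_mass_g,
        }
        for n in carbons:
            row[f"C{n}"] = p.conc.get(n, float("nan"))
        row.update(
            elevation_m=s.elevation_m, mat_c=s.mat_c, rh_pct=s.rh_pct, map_mm=s.map_mm
        )
        rows.append(row)
    return pd.DataFrame(rows)
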