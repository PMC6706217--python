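"""Internal-standard quantification and relative-abundance standardisation.

GC-MS peak areas become absolute amounts by comparison with a known mass of
internal standard added before extraction (60 µg by default), then become
concentrations per g dry leaf by dividing by the dry mass extracted (0.1 g
is typical).  A per-chain response factor (RF, default 1.0) corrects for
compound-specific detector response when a calibration is available::

    conc[n] = (area[n] / is_area) * is_amount_ug / (rf[n] * dry_mass_g)

Relative abundances standardise a profile to its total n-alkane
concentration, removing between-sample differences in absolute wax yield.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .core_model import AlkaneProfile, read_table
from .errors import FormatError, QuantificationError, UndefinedMetricError, ValidationError

__all__ = [
    "DEFAULT_IS_AMOUNT_UG",
    "DEFAULT_DRY_MASS_G",
    "PeakTable",
    "quantify",
    "to_relative_abundance",
    "read_peaks",
    "read_response_factors",
]

logger = logging.getLogger(__name__)

#: Internal-standard mass added per extraction, µg.
DEFAULT_IS_AMOUNT_UG = 60.0
#: Dry leaf mass extracted, g.
DEFAULT_DRY_MASS_G = 0.1


@dataclass(frozen=True)
class PeakTable:
    """Integrated peak areas of one GC-MS run, plus the quantities needed to
    convert them to µg per g dry leaf.

    The internal standard is modelled as a single designated reference area;
    ``response_factor`` entries default to 1.0 for chains not listed.
    """

    sample_id: str
    dry_mass_g: float
    is_area: float
    areas: Mapping[int, float]
    is_amount_ug: float = DEFAULT_IS_AMOUNT_UG
    response_factor: Mapping[int, float] = field(default_factory=dict)
    species: str = ""
    site_id: str = ""
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if not self.dry_mass_g > 0:
            raise ValidationError(
                f"sample '{self.sample_id}': dry_mass_g must be > 0, got {self.dry_mass_g}"
            )
        if not self.is_amount_ug > 0:
            raise ValidationError(
                f"sample '{self.sample_id}': is_amount_ug must be > 0, got {self.is_amount_ug}"
            )
        for n, a in self.areas.items():
            if not math.isfinite(a) or a < 0:
                raise ValidationError(
                    f"sample '{self.sample_id}': area for C{n} must be finite and >= 0, got {a}"
                )
        for n, rf in self.response_factor.items():
            if not rf > 0:
                raise ValidationError(
                    f"sample '{self.sample_id}': response factor for C{n} must be > 0, got {rf}"
                )


def quantify(peaks: PeakTable) -> AlkaneProfile:
    """Convert a peak table to an :class:`AlkaneProfile` in µg/g dry leaf.

    Linear in each peak area, inversely proportional to dry mass; chains
    with zero area get concentration 0.  Raises
    :class:`QuantificationError` if the internal-standard area is not
    positive.
    """
    if not peaks.is_area > 0:
        raise QuantificationError(
            f"sample '{peaks.sample_id}': internal-standard area must be > 0, got {peaks.is_area}"
        )
    conc = {
        n: (area / peaks.is_area)
        * peaks.is_amount_ug
        / (peaks.response_factor.get(n, 1.0) * peaks.dry_mass_g)
        for n, area in peaks.areas.items()
    }
    return AlkaneProfile(
        sample_id=peaks.sample_id,
        species=peaks.species,
        site_id=peaks.site_id,
        dry_mass_g=peaks.dry_mass_g,
        conc=conc,
        replicate_group=peaks.replicate_group,
    )


def to_relative_abundance(profile: AlkaneProfile) -> dict[int, float]:
    """Standardise a profile to total n-alkane concentration.

    Returns ``{carbon_number: fraction}`` summing to 1.  Fractions are
    multiplied by 100 only at output time.  An all-zero profile has no
    defined composition and raises :class:`UndefinedMetricError`.
    """
    total = profile.total_concentration
    if total <= 0:
        raise UndefinedMetricError(
            f"sample '{profile.sample_id}': all concentrations are zero; "
            "relative abundances are undefined"
        )
    return {n: v / total for n, v in profile.conc.items()}


def read_peaks(
    path: str | Path,
    *,
    delimiter: str = ",",
    response_factors: Mapping[int, float] | None = None,
) -> list[PeakTable]:
    """Read a peak-area table.

    Columns: ``sample_id``, ``dry_mass_g``, ``is_amount_ug``, ``is_area``,
    chain area columns ``C23`` ... ``C33``; optional ``species``,
    ``site_id``, ``replicate_group``.
    """
    from .core_model import _chain_columns  # shared column convention

    df = read_table(path, delimiter=delimiter)
    mandatory = ["sample_id", "dry_mass_g", "is_amount_ug", "is_area"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    chain_cols = _chain_columns(df.columns)
    if not chain_cols:
        raise FormatError(f"{path}: no chain area columns (C23...C33) found")
    out = []
    for r in df.to_dict("records"):
        areas = {
            n: float(r[col]) for col, n in chain_cols.items() if not _isna(r[col])
        }
        out.append(
            PeakTable(
                sample_id=str(r["sample_id"]),
                dry_mass_g=float(r["dry_mass_g"]),
                is_amount_ug=float(r["is_amount_ug"]),
                is_area=float(r["is_area"]),
                areas=areas,
                response_factor=dict(response_factors or {}),
                species=str(r.get("species", "") or ""),
                site_id=str(r.get("site_id", "") or ""),
                replicate_group=(None if _isna(r.get("replicate_group")) else str(r["replicate_group"])),
            )
        )
    return out


def read_response_factors(path: str | Path, *, delimiter: str = ",") -> dict[int, float]:
    """Read per-chain response factors from a two-column table
    (``carbon_number``, ``rf``)."""
    df = read_table(path, delimiter=delimiter)
    missing = [c for c in ("carbon_number", "rf") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return {int(r.carbon_number): float(r.rf) for r in df.itertuples(index=False)}


def _isna(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v == ""
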