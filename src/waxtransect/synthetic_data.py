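"""Synthetic elevation-transect generator for leaf-wax n-alkane analysis.

Emulates a tropical montane transect: 14 sites spanning 653-3,507 m
a.s.l., mean annual temperature cooling with elevation at a fixed lapse
rate (21.6 °C at the bottom down to ~7.2 °C at the top), relative air
humidity and precipitation likewise monotone in elevation (99.8→96.1 %,
2,448→1,580 mm), so all three covariates are mutually rank-correlated by
construction — the collinearity any elevation transect carries.

Six tree species occupy overlapping elevation bands (partial site
occupancy), each with:

* a Gaussian chain-length envelope over C23-C33 (``baseline_center``,
  ``baseline_width``) whose odd chains are multiplied by ``oep_factor``
  — the odd-over-even preference of higher-plant waxes — and whose C23
  weight can be damped with ``c23_boost`` < 1 to reproduce the common
  C23 anomaly;
* an environmental response ``beta``: carbons of envelope-centre shift per
  unit of each covariate, measured about the transect mean, so a positive
  ``beta["mat_c"]`` lengthens chains toward the warm end;
* a lognormal total-concentration model and independent per-compound
  multiplicative lognormal measurement noise (``noise_cv``).

Replicate groups re-measure a sample's expected profile with fresh noise;
"abnormally small" outliers are injected by multiplying one dominant chain
(C31 by default) by a small factor.  Every random draw comes from a stream
keyed by (master seed, logical entity), so adding a species or changing
the replicate plan does not perturb unrelated draws, and identical
configurations are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    AlkaneProfile,
    ChainWindow,
    SiteEnvironment,
    write_environment,
    write_profiles,
    write_table,
)
from .errors import ValidationError

__all__ = [
    "SpeciesModel",
    "SyntheticConfig",
    "SyntheticDataset",
    "default_species",
    "default_config",
    "generate_sites",
    "generate_profiles",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

_ENV_VARS = ("mat_c", "rh_pct", "map_mm")


@dataclass(frozen=True)
class SpeciesModel:
    """Generative parameters of one species.

    ``site_occupancy`` is either an explicit set of site ids or an
    ``(elevation_low_m, elevation_high_m)`` band; ``beta`` maps an
    environmental variable to the envelope-centre shift per unit of that
    covariate (carbons/°C, carbons/%, carbons/mm).
    """

    name: str
    site_occupancy: tuple[float, float] | frozenset[str]
    baseline_center: float = 29.5    # mean carbon number of the envelope
    baseline_width: float = 1.5      # envelope SD, carbon units
    oep_factor: float = 10.0         # odd-chain multiplier, >= 1
    c23_boost: float = 1.0           # extra multiplier on C23 (< 1 damps it)
    beta: Mapping[str, float] = field(default_factory=dict)
    total_conc_mean: float = 60.0    # µg/g dry leaf
    total_conc_cv: float = 0.5
    noise_cv: float = 0.15           # per-compound measurement noise

    def __post_init__(self) -> None:
        if not self.baseline_width > 0:
            raise ValidationError(f"{self.name}: baseline_width must be > 0")
        if self.oep_factor < 1:
            raise ValidationError(f"{self.name}: oep_factor must be >= 1")
        if not self.total_conc_mean > 0:
            raise ValidationError(f"{self.name}: total_conc_mean must be > 0")
        if self.noise_cv < 0:
            raise ValidationError(f"{self.name}: noise_cv must be >= 0")
        unknown = set(self.beta) - set(_ENV_VARS)
        if unknown:
            raise ValidationError(f"{self.name}: unknown beta keys {sorted(unknown)}")

    def occupies(self, site: SiteEnvironment) -> bool:
        if isinstance(self.site_occupancy, frozenset):
            return site.site_id in self.site_occupancy
        lo, hi = self.site_occupancy
        return lo <= site.elevation_m <= hi


def default_species() -> tuple[SpeciesModel, ...]:
    """Six-species community patterned on a montane transect study design.

    One wide-ranging lowland-to-mid species responds to the hydrological
    covariates; two mid/upper species respond to temperature with the same
    sign, one upper species responds with the opposite sign, one
    high-elevation species has a temperature response but so short a
    sampled gradient that it rarely reaches significance, and one species
    occupies too few sites to enter the per-species analysis at all.
    Three species carry the C23 anomaly (C23 below its even neighbour).
    """
    return (
        SpeciesModel(
            name="Guarea kunthiana",
            site_occupancy=(600.0, 2250.0),     # 8 low/mid sites
            baseline_center=29.2,
            baseline_width=1.5,
            oep_factor=10.0,
            c23_boost=0.08,
            beta={"rh_pct": 0.12, "map_mm": 0.0002},
        ),
        SpeciesModel(
            name="Miconia theaezans",
            site_occupancy=(1300.0, 2650.0),    # 7 mid sites
            baseline_center=29.8,
            baseline_width=1.6,
            oep_factor=9.0,
            c23_boost=0.08,
            beta={"mat_c": 0.15},
        ),
        SpeciesModel(
            name="Miconia clathrantha",
            site_occupancy=(1950.0, 3100.0),    # 6 mid/upper sites
            baseline_center=30.1,
            baseline_width=2.0,
            oep_factor=11.0,
            beta={"mat_c": 0.15},
        ),
        SpeciesModel(
            name="Miconia bracteolata",
            site_occupancy=(2600.0, 3300.0),    # 4 upper sites
            baseline_center=29.0,
            baseline_width=1.5,
            oep_factor=8.0,
            c23_boost=0.08,
            beta={"mat_c": -0.08},
        ),
        SpeciesModel(
            name="Miconia corymbiformis",
            site_occupancy=(3050.0, 3550.0),    # 3 summit sites, short gradient
            baseline_center=28.8,
            baseline_width=2.0,
            oep_factor=9.0,
            beta={"mat_c": 0.15},
        ),
        SpeciesModel(
            name="Miconia sp. A",
            site_occupancy=(600.0, 900.0),      # 2 sites: below eligibility
            baseline_center=29.5,
            baseline_width=2.0,
            oep_factor=10.0,
            beta={},
        ),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of a simulated transect.

    Defaults reproduce the study conditions the generator emulates: 14
    sites over 653-3,507 m, MAT 21.6 °C at the bottom falling at
    14.4 °C / 2,854 m, RH 99.8→96.1 %, MAP 2,448→1,580 mm, six species
    with partial occupancy sampled ~3 individuals per occupied site
    (≈90 samples), 14 replicate measurements (two triplicates, one
    duplicate, three field splits of two) and two injected "abnormally
    small" C31 outliers.
    """

    n_sites: int = 14
    elevation_range_m: tuple[float, float] = (653.0, 3507.0)
    mat_at_min_elev_c: float = 21.6
    lapse_rate_c_per_m: float = 14.4 / 2854.0
    mat_noise_sd_c: float = 0.3
    rh_at_min_elev_pct: float = 99.8
    rh_slope_pct_per_m: float = -3.7 / 2854.0
    rh_noise_sd_pct: float = 0.15
    map_at_min_elev_mm: float = 2448.0
    map_slope_mm_per_m: float = -868.0 / 2854.0
    map_noise_sd_mm: float = 30.0
    species: tuple[SpeciesModel, ...] = field(default_factory=default_species)
    samples_per_species_site: int = 3
    replicate_spec: tuple[int, ...] = (3, 3, 2, 2, 2, 2)   # 14 measurements
    n_outliers: int = 2
    outlier_factor: float = 0.1
    outlier_chain: int = 31
    dry_mass_g: float = 0.1
    window: ChainWindow = field(default_factory=ChainWindow.default)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range_m
        if not hi > lo:
            raise ValidationError(f"degenerate elevation range: {self.elevation_range_m}")
        if self.n_sites < 2:
            raise ValidationError("need at least 2 sites")
        if not (0.0 < self.outlier_factor):
            raise ValidationError("outlier_factor must be > 0")


@dataclass(frozen=True)
class SyntheticDataset:
    sites: tuple[SiteEnvironment, ...]
    profiles: tuple[AlkaneProfile, ...]
    truth: pd.DataFrame

    def write(self, out_dir: str | Path, *, seed: int | None = None) -> dict[str, Path]:
        out_dir = Path(out_dir)
        meta = {} if seed is None else {"seed": seed}
        paths = {
            "sites": out_dir / "sites.csv",
            "profiles": out_dir / "profiles.csv",
            "truth": out_dir / "truth.csv",
        }
        write_environment(list(self.sites), paths["sites"], metadata=meta)
        write_profiles(list(self.profiles), paths["profiles"], metadata=meta)
        write_table(self.truth, paths["truth"], meta)
        return paths


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Independent stream keyed by (master seed, logical entity)."""
    tag = zlib.crc32(":".join(map(str, key)).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed) & 0x7FFFFFFF, tag)))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draws with the given arithmetic mean and CV."""
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def generate_sites(config: SyntheticConfig) -> list[SiteEnvironment]:
    """Evenly spaced sites along the elevation range, covariates linear in
    elevation plus site-level Gaussian noise; deterministic given the seed."""
    lo, hi = config.elevation_range_m
    elev = np.linspace(lo, hi, config.n_sites)
    rng = _rng(config.seed, "sites")
    noise = rng.normal(size=(3, config.n_sites))
    mat = (
        config.mat_at_min_elev_c
        - config.lapse_rate_c_per_m * (elev - lo)
        + config.mat_noise_sd_c * noise[0]
    )
    rh = (
        config.rh_at_min_elev_pct
        + config.rh_slope_pct_per_m * (elev - lo)
        + config.rh_noise_sd_pct * noise[1]
    )
    mp = (
        config.map_at_min_elev_mm
        + config.map_slope_mm_per_m * (elev - lo)
        + config.map_noise_sd_mm * noise[2]
    )
    width = len(str(config.n_sites))
    return [
        SiteEnvironment(
            site_id=f"S{i + 1:0{width}d}",
            elevation_m=float(elev[i]),
            mat_c=float(mat[i]),
            rh_pct=float(np.clip(rh[i], 0.0, 100.0)),
            map_mm=float(max(mp[i], 0.0)),
        )
        for i in range(config.n_sites)
    ]


def _expected_rel_abund(
    species: SpeciesModel,
    site: SiteEnvironment,
    env_means: Mapping[str, float],
    window: ChainWindow,
) -> np.ndarray:
    """Discretised Gaussian envelope with OEP and C23 adjustments,
    renormalised to sum to 1."""
    center = species.baseline_center + sum(
        b * (getattr(site, v) - env_means[v]) for v, b in species.beta.items()
    )
    carbons = np.asarray(window.carbons, dtype=np.float64)
    w = np.exp(-0.5 * ((carbons - center) / species.baseline_width) ** 2)
    odd = (carbons.astype(int) % 2) == 1
    w[odd] *= species.oep_factor
    w[carbons.astype(int) == 23] *= species.c23_boost
    total = w.sum()
    if total <= 0:
        raise ValidationError(f"{species.name}: degenerate chain envelope at {site.site_id}")
    return w / total


def _measure(
    rng: np.random.Generator,
    expected_conc: np.ndarray,
    noise_cv: float,
) -> np.ndarray:
    """One measurement: independent multiplicative lognormal noise per chain."""
    if noise_cv == 0:
        return expected_conc.copy()
    factors = _lognormal(rng, 1.0, noise_cv, size=expected_conc.size)
    return expected_conc * factors


def generate_profiles(
    config: SyntheticConfig, sites: Sequence[SiteEnvironment]
) -> tuple[list[AlkaneProfile], pd.DataFrame]:
    """Draw all measurements and return ``(profiles, truth)``.

    ``truth`` is a long table recording what was injected: per-species
    betas and envelope parameters, replicate group memberships and the
    outlier sample ids with their factor — enough for parameter-recovery
    and outlier-recall checks without re-deriving anything.
    """
    window = config.window
    env_means = {
        v: float(np.mean([getattr(s, v) for s in sites])) for v in _ENV_VARS
    }
    carbons = np.asarray(window.carbons, dtype=np.float64)

    profiles: list[AlkaneProfile] = []
    expectations: dict[str, tuple[SpeciesModel, np.ndarray]] = {}
    truth_rows: list[dict[str, object]] = []
    seen_abbrevs: set[str] = set()

    for species in config.species:
        occupied = [s for s in sites if species.occupies(s)]
        if not occupied:
            logger.warning("species '%s' occupies no sites; skipped", species.name)
            continue
        rng = _rng(config.seed, "species", species.name)
        abbrev = _abbreviate(species.name, seen_abbrevs)
        for v in _ENV_VARS:
            truth_rows.append(
                {"kind": "beta", "name": species.name, "key": v,
                 "value": float(species.beta.get(v, 0.0))}
            )
        truth_rows.append(
            {"kind": "envelope", "name": species.name, "key": "baseline_center",
             "value": species.baseline_center}
        )
        for site in occupied:
            rel = _expected_rel_abund(species, site, env_means, window)
            for i in range(config.samples_per_species_site):
                total = float(_lognormal(rng, species.total_conc_mean, species.total_conc_cv))
                expected = total * rel
                measured = _measure(rng, expected, species.noise_cv)
                sample_id = f"{abbrev}-{site.site_id}-{i + 1}"
                profiles.append(
                    AlkaneProfile(
                        sample_id=sample_id,
                        species=species.name,
                        site_id=site.site_id,
                        dry_mass_g=config.dry_mass_g,
                        conc=dict(zip(window.carbons, measured.tolist())),
                    )
                )
                expectations[sample_id] = (species, expected)

    profiles = _add_replicates(config, profiles, expectations, truth_rows)
    profiles = _inject_outliers(config, profiles, truth_rows)
    truth = pd.DataFrame(truth_rows, columns=["kind", "name", "key", "value"])
    return profiles, truth


def _abbreviate(name: str, seen: set[str]) -> str:
    """Short unique sample-id prefix: genus initial + start of the epithet."""
    parts = name.split()
    epithet = "".join(ch for ch in (parts[1] if len(parts) > 1 else "sp") if ch.isalnum())
    abbrev = (parts[0][0] + epithet[:3]).upper()
    candidate = abbrev
    k = 2
    while candidate in seen:
        candidate = f"{abbrev}{k}"
        k += 1
    seen.add(candidate)
    return candidate


def _add_replicates(config, profiles, expectations, truth_rows):
    """Promote some base samples to replicate groups with fresh re-measurements."""
    if not config.replicate_spec:
        return profiles
    rng = _rng(config.seed, "replicates")
    n_groups = len(config.replicate_spec)
    if len(profiles) < n_groups:
        logger.warning("too few samples for %d replicate groups; skipping", n_groups)
        return profiles
    chosen = rng.choice(len(profiles), size=n_groups, replace=False)
    out = list(profiles)
    for g, (pos, size) in enumerate(zip((int(c) for c in chosen), config.replicate_spec), start=1):
        base = out[pos]
        group = f"RG{g}"
        out[pos] = replace(base, replicate_group=group)
        species, expected = expectations[base.sample_id]
        truth_rows.append(
            {"kind": "replicate", "name": base.sample_id, "key": group, "value": float(size)}
        )
        for j in range(2, size + 1):
            measured = _measure(rng, expected, species.noise_cv)
            out.append(
                AlkaneProfile(
                    sample_id=f"{base.sample_id}-r{j}",
                    species=base.species,
                    site_id=base.site_id,
                    dry_mass_g=base.dry_mass_g,
                    conc=dict(zip(config.window.carbons, measured.tolist())),
                    replicate_group=group,
                )
            )
    return out


def _inject_outliers(config, profiles, truth_rows):
    """Multiply the outlier chain of a few non-replicate samples by a small
    factor, emulating abnormally small values spotted at a site."""
    if config.n_outliers <= 0:
        return profiles
    rng = _rng(config.seed, "outliers")
    candidates = [
        i for i, p in enumerate(profiles)
        if p.replicate_group is None and p.conc.get(config.outlier_chain, 0.0) > 0
    ]
    if len(candidates) < config.n_outliers:
        logger.warning("too few candidates for %d outliers", config.n_outliers)
        return profiles
    chosen = rng.choice(len(candidates), size=config.n_outliers, replace=False)
    out = list(profiles)
    for idx in sorted(int(c) for c in chosen):
        i = candidates[idx]
        p = out[i]
        conc = dict(p.conc)
        conc[config.outlier_chain] *= config.outlier_factor
        out[i] = p.with_conc(conc)
        truth_rows.append(
            {"kind": "outlier", "name": p.sample_id, "key": f"C{config.outlier_chain}",
             "value": config.outlier_factor}
        )
    return out


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic transect: sites, profiles and the truth
    table; fully reproducible from ``config.seed``."""
    config = config or SyntheticConfig()
    sites = generate_sites(config)
    profiles, truth = generate_profiles(config, sites)
    return SyntheticDataset(tuple(sites), tuple(profiles), truth)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study conditions with a chosen seed."""
    return replace(SyntheticConfig(), seed=seed, **overrides) if overrides else SyntheticConfig(seed=seed)
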