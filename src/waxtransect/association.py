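"""Spearman rank correlation of chain-length responses with environment.

Two designs are supported, mirroring how transect studies separate
within-species from pooled signals:

* **species response** — one correlation per species per response per
  environmental variable, restricted to species sampled at a minimum number
  of distinct sites (default 3);
* **site total response** — all species' samples pooled into a single
  correlation per response per environmental variable.

Responses are the ACL, the C31/(C31+C29) ratio and the relative abundances
of the odd chains C23-C33 (the odd homologs dominate the higher-plant
signal).  Environmental variables are mean annual temperature, mean
relative air humidity and mean annual precipitation; because all three are
driven by elevation they are mutually rank-correlated, and the analysis
reports — it does not attempt to remove — that collinearity.

Significance uses a fixed two-sided alpha (default 0.01, strict ``p <
alpha``) with no multiple-testing correction; the number of tests performed
is annotated on the output instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import CorrelationResult
from .errors import InsufficientDataError

__all__ = [
    "DEFAULT_RESPONSES",
    "DEFAULT_ENV_VARS",
    "AnalysisDesign",
    "SpearmanResult",
    "spearman",
    "species_response",
    "site_total_response",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_RESPONSES = ("acl", "ratio", "C23", "C25", "C27", "C29", "C31", "C33")
DEFAULT_ENV_VARS = ("mat_c", "rh_pct", "map_mm")

#: Largest n for which the exact permutation p-value is used (no ties).
EXACT_MAX_N = 9


@dataclass(frozen=True)
class AnalysisDesign:
    """Parameters of the correlation analysis."""

    alpha: float = 0.01
    min_sites_per_species: int = 3
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    env_vars: tuple[str, ...] = DEFAULT_ENV_VARS

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_sites_per_species < 2:
            raise ValueError(
                f"min_sites_per_species must be >= 2, got {self.min_sites_per_species}"
            )


@dataclass(frozen=True)
class SpearmanResult:
    rs: float | None
    p: float | None
    n: int
    reason: str | None = None


@lru_cache(maxsize=None)
def _null_abs_rs(n: int) -> np.ndarray:
    """Sorted |rs| over all n! rank permutations (tie-free null)."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.float64)
    d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
    rs = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.sort(np.abs(rs))


def _exact_p(rs: float, n: int) -> float:
    """Two-sided exact p: fraction of permutations with |rs'| >= |rs|."""
    null = _null_abs_rs(n)
    idx = np.searchsorted(null, abs(rs) - 1e-12, side="left")
    return float(null.size - idx) / null.size


def spearman(
    x: Sequence[float], y: Sequence[float], *, exact_max_n: int = EXACT_MAX_N
) -> SpearmanResult:
    """Spearman rank-order correlation with a two-sided p-value.

    Ranks use average-rank tie handling and ``rs`` is the Pearson
    correlation of the ranks (the tie-corrected form).  For n <=
    ``exact_max_n`` with no ties the p-value is exact, from full
    enumeration of the permutation null; otherwise it uses the
    t-approximation with n - 2 degrees of freedom.

    Zero variance in either variable makes the correlation undefined; the
    result carries ``rs = p = None`` and a reason rather than a fabricated
    0.  Fewer than 3 observations raise :class:`InsufficientDataError`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        return SpearmanResult(None, None, n, "zero variance in x")
    if np.ptp(y) == 0:
        return SpearmanResult(None, None, n, "zero variance in y")

    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rs = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rs = max(-1.0, min(1.0, rs))

    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= exact_max_n and not has_ties:
        p = _exact_p(rs, n)
    elif abs(rs) == 1.0:
        p = 0.0
    else:
        t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rs, min(p, 1.0), n)


def _correlate_group(
    frame: pd.DataFrame, group: str, design: AnalysisDesign
) -> list[CorrelationResult]:
    """All (response × env_var) correlations for one already-filtered group."""
    out = []
    for response in design.responses:
        for env_var in design.env_vars:
            sub = frame[[response, env_var]].dropna()
            n = len(sub)
            if n < 3:
                out.append(
                    CorrelationResult(
                        group, response, env_var, n, None, None, False,
                        reason="insufficient data (n < 3)",
                    )
                )
                continue
            res = spearman(sub[env_var].to_numpy(), sub[response].to_numpy())
            significant = res.p is not None and res.p < design.alpha
            out.append(
                CorrelationResult(
                    group, response, env_var, res.n, res.rs, res.p, significant,
                    reason=res.reason,
                )
            )
    return out


def _check_columns(dataset: pd.DataFrame, design: AnalysisDesign) -> None:
    needed = {"species", "site_id", "excluded", *design.responses, *design.env_vars}
    missing = sorted(needed - set(dataset.columns))
    if missing:
        raise ValueError(f"dataset is missing column(s): {', '.join(missing)}")


def species_response(
    dataset: pd.DataFrame, design: AnalysisDesign | None = None
) -> list[CorrelationResult]:
    """Per-species correlations for species sampled at enough sites.

    ``dataset`` is a joined analysis table (one row per sample) with the
    response columns, the environmental covariates and an ``excluded``
    flag.  Excluded samples are omitted everywhere, including from the
    site-count eligibility test.  Undefined correlations are emitted with a
    reason so the output cardinality is always
    ``n_eligible_species × n_responses × n_env_vars``.
    """
    design = design or AnalysisDesign()
    _check_columns(dataset, design)
    used = dataset[~dataset["excluded"].astype(bool)]
    eligible = sorted(
        sp
        for sp, grp in used.groupby("species")
        if grp["site_id"].nunique() >= design.min_sites_per_species
    )
    if not eligible:
        logger.warning("no species sampled at >= %d sites", design.min_sites_per_species)
        return []
    out: list[CorrelationResult] = []
    for sp in eligible:
        out.extend(_correlate_group(used[used["species"] == sp], sp, design))
    return out


def site_total_response(
    dataset: pd.DataFrame, design: AnalysisDesign | None = None
) -> list[CorrelationResult]:
    """Pooled correlations over all non-excluded samples of every species,
    reported under the group name ``"site_total"``."""
    design = design or AnalysisDesign()
    _check_columns(dataset, design)
    used = dataset[~dataset["excluded"].astype(bool)]
    if used.empty:
        logger.warning("no non-excluded samples to pool")
        return []
    return _correlate_group(used, "site_total", design)


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Long-format correlation table (one row per group × response × env)."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "response": r.response,
                "env_var": r.env_var,
                "n": r.n,
                "rs": float("nan") if r.rs is None else r.rs,
                "p": float("nan") if r.p is None else r.p,
                "significant": r.significant,
                "reason": r.reason or "",
            }
            for r in results
        ],
        columns=["group", "response", "env_var", "n", "rs", "p", "significant", "reason"],
    )
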