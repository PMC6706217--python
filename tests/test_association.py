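"""Spearman engine and the species / site-total correlation designs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from waxtransect import AnalysisDesign, InsufficientDataError, spearman
from waxtransect.association import site_total_response, species_response


def brute_force_spearman(x, y):
    """Independent oracle: closed-form rho and exhaustive permutation p.

    Valid only for tie-free inputs: rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d
    the rank differences, and the two-sided p is the fraction of the n!
    equally likely rank permutations with |rho'| >= |rho|.
    """
    n = len(x)
    rx = [sorted(x).index(v) for v in x]
    ry = [sorted(y).index(v) for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    rho = 1 - 6 * d2 / (n * (n * n - 1))
    count = 0
    for perm in itertools.permutations(range(n)):
        d2p = sum((a - b) ** 2 for a, b in zip(rx, perm))
        rhop = 1 - 6 * d2p / (n * (n * n - 1))
        if abs(rhop) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / math.factorial(n)


class TestSpearmanEngine:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]).rs == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10]).rs == pytest.approx(-1.0)

    def test_textbook_five_point_case(self):
        # d = (1,-1,1,-1,0), sum d^2 = 4: rho = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rs == pytest.approx(0.8, abs=1e-12)
        _, p_oracle = brute_force_spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = list(rng.permutation(n).astype(float))
        for _ in range(5):
            y = list(rng.permutation(n).astype(float))
            res = spearman(x, y)
            rho_o, p_o = brute_force_spearman(x, y)
            assert res.rs == pytest.approx(rho_o, abs=1e-12)
            assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_tied_data_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        y = x * 0.5 + rng.normal(size=30)
        res = spearman(x, y)
        ref_rs, ref_p = stats.spearmanr(x, y)
        assert res.rs == pytest.approx(ref_rs, abs=1e-12)
        assert res.p == pytest.approx(ref_p, rel=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a, b = spearman(x, y), spearman(y, x)
        assert a.rs == pytest.approx(b.rs, abs=1e-12)
        assert -1.0 <= a.rs <= 1.0

    @given(
        data=st.lists(
            st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
            min_size=4, max_size=12, unique_by=(lambda t: t[0], lambda t: t[1]),
        ),
        shift=st.floats(-5.0, 5.0),
    )
    def test_invariance_under_strictly_increasing_transforms(self, data, shift):
        x = [float(a) for a, _ in data]
        y = [float(b) for _, b in data]
        base = spearman(x, y)
        fx = [math.exp(0.01 * v) + shift for v in x]      # strictly increasing
        gy = [v ** 3 for v in y]                          # strictly increasing
        tr = spearman(fx, gy)
        assert tr.rs == pytest.approx(base.rs, abs=1e-9)
        assert tr.p == pytest.approx(base.p, abs=1e-9)

    def test_zero_variance_reported_not_fabricated(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.rs is None and res.p is None
        assert "variance" in res.reason

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            spearman([1.0, 2.0], [3.0, 4.0])


def _dataset(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "species", "site_id", "excluded", "acl", "ratio",
                 "C23", "C25", "C27", "C29", "C31", "C33",
                 "mat_c", "rh_pct", "map_mm"],
    )


def _rows(species, sites, acl_fn, n_per_site=3, start=0):
    rows = []
    rng = np.random.default_rng(start)
    for j, (site, mat) in enumerate(sites):
        for i in range(n_per_site):
            acl = acl_fn(mat) + 0.01 * rng.normal()
            rows.append(
                [f"{species}-{j}-{i}", species, site, False, acl, 0.5,
                 1.0, 2.0, 10.0, 40.0, 30.0, 5.0, mat, 90.0 + mat / 10, 2000.0 + mat]
            )
    return rows


SITES = [(f"S{i}", 7.0 + i) for i in range(8)]


class TestCorrelationDesigns:
    def test_species_below_site_minimum_absent(self):
        rows = _rows("wide", SITES[:5], lambda m: 29 + 0.1 * m)
        rows += _rows("narrow", SITES[:2], lambda m: 29.0)
        results = species_response(_dataset(rows), AnalysisDesign())
        assert {r.group for r in results} == {"wide"}

    def test_output_cardinality(self):
        rows = _rows("a", SITES[:4], lambda m: 29.0 + 0.01 * m)
        rows += _rows("b", SITES[4:8], lambda m: 29.0 - 0.01 * m)
        results = species_response(_dataset(rows), AnalysisDesign())
        assert len(results) == 2 * 8 * 3  # species x responses x env vars

    def test_programmed_large_effect_is_significant(self):
        rows = _rows("resp", SITES, lambda m: 28.0 + 0.2 * m)
        results = species_response(_dataset(rows), AnalysisDesign())
        hit = next(r for r in results if r.response == "acl" and r.env_var == "mat_c")
        assert hit.rs > 0.5 and hit.significant

    def test_site_total_of_one_species_equals_species_result(self):
        rows = _rows("only", SITES, lambda m: 28.0 + 0.1 * m)
        df = _dataset(rows)
        design = AnalysisDesign()
        sp = {(r.response, r.env_var): r for r in species_response(df, design)}
        for r in site_total_response(df, design):
            mate = sp[(r.response, r.env_var)]
            assert r.group == "site_total"
            assert r.n == mate.n
            if mate.rs is None:
                assert r.rs is None
            else:
                assert r.rs == pytest.approx(mate.rs, abs=1e-12)

    def test_opposing_species_attenuate_the_pooled_signal(self):
        rows = _rows("up", SITES, lambda m: 29.0 + 0.15 * m, start=1)
        rows += _rows("down", SITES, lambda m: 33.3 - 0.15 * m, start=2)
        df = _dataset(rows)
        design = AnalysisDesign()
        per_species = {
            r.group: abs(r.rs)
            for r in species_response(df, design)
            if r.response == "acl" and r.env_var == "mat_c"
        }
        pooled = next(
            r for r in site_total_response(df, design)
            if r.response == "acl" and r.env_var == "mat_c"
        )
        assert abs(pooled.rs) < min(per_species.values())

    def test_pooled_n_counts_all_non_excluded_samples(self):
        rows = _rows("a", SITES[:4], lambda m: 29.0)
        rows += _rows("b", SITES[4:], lambda m: 30.0)
        df = _dataset(rows)
        df.loc[0, "excluded"] = True
        pooled = site_total_response(df, AnalysisDesign())
        assert all(r.n == len(df) - 1 for r in pooled if r.reason is None)

    def test_excluded_samples_do_not_count_toward_eligibility(self):
        rows = _rows("sp", SITES[:3], lambda m: 29.0 + 0.1 * m)
        df = _dataset(rows)
        df.loc[df["site_id"] == "S2", "excluded"] = True  # only 2 sites remain
        assert species_response(df, AnalysisDesign()) == []

    def test_environmental_collinearity_is_reported_not_removed(self):
        """All three mutually rank-correlated covariates appear in the output;
        the design never drops one for redundancy."""
        rows = _rows("sp", SITES, lambda m: 29.0 + 0.1 * m)
        df = _dataset(rows)
        env = df.drop_duplicates("site_id")
        for a, b in itertools.combinations(["mat_c", "rh_pct", "map_mm"], 2):
            assert abs(spearman(env[a], env[b]).rs) > 0.9
        results = species_response(df, AnalysisDesign())
        assert {r.env_var for r in results} == {"mat_c", "rh_pct", "map_mm"}
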